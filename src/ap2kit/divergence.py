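"""Duplicate-pair functional divergence from stress expression correlation.

Each duplicated gene pair is compared over its log2 fold-change vectors across
the concatenated stress x timepoint grid (20 points for 4 stresses x 5
timepoints).  A high Pearson correlation (>= 0.5 by default) indicates
subfunctionalization — the copies retained overlapping parts of the ancestral
regulatory program — while a near-zero or negative correlation (<= 0.1 by
default) indicates neofunctionalization; everything in between stays
unclassified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .duplication_synteny import DuplicationEvent

__all__ = ["DivergencePair", "DivergenceParams", "pair_pcc", "classify_divergence",
           "divergence_table"]


@dataclass
class DivergenceParams:
    sub_min_pcc: float = 0.5    # PCC >= this -> subfunctionalization
    neo_max_pcc: float = 0.1    # PCC <= this -> neofunctionalization
    min_points: int = 10        # pairwise-complete points required to classify

    def __post_init__(self) -> None:
        if not self.neo_max_pcc < self.sub_min_pcc:
            raise ValueError("neo_max_pcc must be < sub_min_pcc")


@dataclass
class DivergencePair:
    gene_a: str
    gene_b: str
    pcc: Optional[float]        # None when undefined (constant vector)
    n_points: int
    classification: str         # subfunctionalization | neofunctionalization | unclassified
    reason: str = ""


def pair_pcc(vector_a: Sequence[float], vector_b: Sequence[float]) -> Optional[float]:
    """Pearson correlation on pairwise-complete points; None if undefined."""
    a = np.asarray(vector_a, dtype=float)
    b = np.asarray(vector_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors differ in length")
    complete = np.isfinite(a) & np.isfinite(b)
    a, b = a[complete], b[complete]
    if len(a) < 3:
        raise ValueError(f"need >= 3 pairwise-complete points, got {len(a)}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None  # constant vector: correlation undefined
    return float(np.corrcoef(a, b)[0, 1])


def classify_pcc(pcc: Optional[float], n_points: int,
                 params: Optional[DivergenceParams] = None) -> tuple[str, str]:
    """Map a PCC (already computed) to a divergence class with a reason string."""
    params = params or DivergenceParams()
    if pcc is None:
        return "unclassified", "PCC undefined (constant vector)"
    if n_points < params.min_points:
        return "unclassified", f"only {n_points} complete points (< {params.min_points})"
    if pcc >= params.sub_min_pcc:
        return "subfunctionalization", ""
    if pcc <= params.neo_max_pcc:
        return "neofunctionalization", ""
    return "unclassified", f"PCC {pcc:.3f} between thresholds"


def classify_divergence(events: Sequence[DuplicationEvent], log2fc: pd.DataFrame,
                        params: Optional[DivergenceParams] = None) -> list[DivergencePair]:
    """Classify every within-event gene pair by expression correlation.

    ``log2fc`` is the gene x condition matrix from the stress DE stage.
    Tandem clusters contribute all their internal pairs; pairs with a gene
    missing from the matrix are skipped with a warning.
    """
    params = params or DivergenceParams()
    out = []
    seen = set()
    for ev in events:
        for i, ga in enumerate(ev.gene_ids):
            for gb in ev.gene_ids[i + 1:]:
                key = frozenset((ga, gb))
                if key in seen:
                    continue
                seen.add(key)
                if ga not in log2fc.index or gb not in log2fc.index:
                    warnings.warn(f"pair {ga}/{gb} skipped: gene absent from the log2FC matrix")
                    continue
                va = log2fc.loc[ga].to_numpy(dtype=float)
                vb = log2fc.loc[gb].to_numpy(dtype=float)
                complete = int((np.isfinite(va) & np.isfinite(vb)).sum())
                try:
                    pcc = pair_pcc(va, vb)
                except ValueError:
                    warnings.warn(f"pair {ga}/{gb}: fewer than 3 complete points")
                    continue
                cls, reason = classify_pcc(pcc, complete, params)
                out.append(DivergencePair(gene_a=ga, gene_b=gb, pcc=pcc,
                                          n_points=complete, classification=cls, reason=reason))
    return out


def divergence_table(pairs: Sequence[DivergencePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.gene_a, p.gene_b,
          float("nan") if p.pcc is None else p.pcc,
          p.n_points, p.classification, p.reason) for p in pairs],
        columns=["gene_a", "gene_b", "pcc", "n_points", "classification", "reason"],
    ).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
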