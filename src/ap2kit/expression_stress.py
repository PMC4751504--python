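"""Abundance normalization, tissue profiling, probe filtering and stress DE.

Differential expression under abiotic stress follows the SAM recipe: a
moderated d-statistic d = (mean_stress - mean_control) / (s + s0) with s the
two-sample pooled standard error and s0 a fudge factor, significance by label
permutation with a median-based false-discovery rate, and calls gated jointly
on |log2 fold change| > 1 and q <= 0.05 (both configurable; a fold-change-only
mode is available because unreplicated microarray contrasts admit no
permutation test).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, FormatError

__all__ = ["StressExpressionSet", "DEParams", "ProbeRecord",
           "compute_rpkm", "tissue_profile", "probe_filter", "read_probe_table",
           "sam_d_statistic", "permutation_qvalues", "de_call", "stress_de"]

STRESSES = ("cold", "heat", "drought", "salt")
TISSUES = ("root", "stem", "leaf")
DEFAULT_TIMEPOINTS = (1.0, 2.0, 5.0, 10.0, 24.0)


@dataclass
class DEParams:
    fc_threshold: float = 1.0        # on the log2 scale
    q_max: float = 0.05
    n_permutations: int = 1000
    s0: Union[float, str] = "auto"   # "auto" = median of per-gene pooled SEs
    rng_seed: int = 0
    pseudocount: float = 1.0         # added before log2
    fc_only: bool = False            # gate on fold change alone (ignore q)

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if not (0 < self.q_max < 1):
            raise ValueError("q_max must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class ProbeRecord:
    probe_id: str
    gene_id: Optional[str]
    mismatches: int
    n_genomic_hits: int
    in_exon: bool


@dataclass
class StressExpressionSet:
    genes: list[str]
    conditions: list[tuple[str, float]]       # (stress, timepoint_hours)
    log2fc: pd.DataFrame                      # gene x condition
    d_stat: pd.DataFrame
    qvalue: pd.DataFrame                      # NaN where no permutation test possible
    call: pd.DataFrame                        # "up" | "down" | "none"

    @staticmethod
    def condition_name(stress: str, timepoint: float) -> str:
        tp = int(timepoint) if float(timepoint).is_integer() else timepoint
        return f"{stress}_{tp}h"


# ---------------------------------------------------------------------------
# Normalization and profiling
# ---------------------------------------------------------------------------

def compute_rpkm(counts: ExpressionTable, exon_lengths: dict[str, int]) -> ExpressionTable:
    """RPKM(g, s) = counts(g, s) * 1e9 / (exon_length_g * library_size_s)."""
    if counts.units != "counts":
        raise ValueError("compute_rpkm expects a counts table")
    missing = [g for g in counts.gene_ids if g not in exon_lengths or exon_lengths[g] <= 0]
    if missing:
        raise ValueError(f"genes without positive exon length: {', '.join(missing[:5])}")
    libsize = counts.values.sum(axis=0)
    if (libsize == 0).any():
        zero = list(libsize.index[libsize == 0])
        raise ValueError(f"zero library size for samples: {', '.join(zero)}")
    lengths = pd.Series({g: float(exon_lengths[g]) for g in counts.gene_ids})
    rpkm = counts.values.mul(1e9).div(libsize, axis=1).div(lengths, axis=0)
    return ExpressionTable(values=rpkm, metadata=counts.metadata, units="RPKM")


def tissue_profile(rpkm: ExpressionTable, member_gene_ids: Sequence[str],
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-member mean log2(RPKM + pseudocount) in root, stem and leaf.

    Replicate samples of a tissue are averaged on the log scale; members
    absent from the table get NA rows with a warning.
    """
    log2 = np.log2(rpkm.values + pseudocount)
    cond = rpkm.metadata.loc[rpkm.sample_ids, "condition"]
    out = pd.DataFrame(index=list(member_gene_ids), columns=list(TISSUES), dtype=float)
    for tissue in TISSUES:
        cols = [s for s in rpkm.sample_ids if cond[s] == tissue]
        if not cols:
            continue
        means = log2[cols].mean(axis=1)
        for g in member_gene_ids:
            if g in means.index:
                out.loc[g, tissue] = means[g]
    absent = [g for g in member_gene_ids if g not in rpkm.values.index]
    if absent:
        warnings.warn(f"{len(absent)} member(s) absent from the expression table: "
                      + ", ".join(absent[:5]))
    return out


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

def probe_filter(probes: Sequence[ProbeRecord]) -> list[ProbeRecord]:
    """Retain probes with a perfect, unique, exonic alignment to a single gene."""
    return [p for p in probes
            if p.mismatches == 0 and p.n_genomic_hits == 1 and p.in_exon
            and p.gene_id is not None]


def read_probe_table(path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    required = {"probe_id", "gene_id", "mismatches", "n_genomic_hits", "in_exon"}
    if not required.issubset(df.columns):
        raise FormatError(f"probe table lacks columns: {sorted(required - set(df.columns))}")
    records = []
    for _, r in df.iterrows():
        gid = None if pd.isna(r["gene_id"]) or r["gene_id"] == "" else str(r["gene_id"])
        records.append(ProbeRecord(probe_id=str(r["probe_id"]), gene_id=gid,
                                   mismatches=int(r["mismatches"]),
                                   n_genomic_hits=int(r["n_genomic_hits"]),
                                   in_exon=bool(r["in_exon"])))
    return records


# ---------------------------------------------------------------------------
# SAM-style statistics
# ---------------------------------------------------------------------------

def _pooled_se(stress: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Two-sample pooled standard error per gene (rows are genes)."""
    n1, n2 = stress.shape[1], control.shape[1]
    ss1 = ((stress - stress.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((control - control.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))


def sam_d_statistic(stress_values: np.ndarray, control_values: np.ndarray,
                    s0: float) -> Union[float, np.ndarray]:
    """SAM's moderated statistic d = (mean_s - mean_c) / (pooled SE + s0).

    Accepts 1-D replicate vectors (one gene) or 2-D gene x replicate arrays.
    """
    stress = np.atleast_2d(np.asarray(stress_values, dtype=float))
    control = np.atleast_2d(np.asarray(control_values, dtype=float))
    if stress.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("sam_d_statistic needs >= 2 replicates per group")
    s = _pooled_se(stress, control)
    if np.any((s == 0) & (s0 == 0)):
        raise ValueError("zero variance in both groups with s0 = 0")
    d = (stress.mean(axis=1) - control.mean(axis=1)) / (s + s0)
    return float(d[0]) if np.asarray(stress_values).ndim == 1 else d


def _label_splits(n1: int, n2: int, n_permutations: int, rng: np.random.Generator
                  ) -> list[np.ndarray]:
    """Index sets (of size n1, into n1+n2 columns) defining permuted group A."""
    total = n1 + n2
    n_distinct = math.comb(total, n1)
    if n_distinct < 20:
        warnings.warn(f"only {n_distinct} distinct label splits: using exact enumeration")
    if n_distinct <= n_permutations:
        return [np.array(c) for c in itertools.combinations(range(total), n1)]
    return [rng.permutation(total)[:n1] for _ in range(n_permutations)]


def permutation_qvalues(values: np.ndarray, is_stress: np.ndarray,
                        params: Optional[DEParams] = None,
                        s0: Optional[float] = None) -> tuple[np.ndarray, np.ndarray, float]:
    """SAM permutation q-values for one contrast.

    ``values`` is the gene x sample matrix (log2 scale) of the pooled stress +
    control samples; ``is_stress`` marks the stress columns.  For each gene's
    threshold t = |d_g|, FDR(t) = median over permutations of #{|d*| >= t}
    divided by #{observed |d| >= t}; q(g) is the minimum FDR over thresholds
    t' <= |d_g|, capped at 1.  Returns (d, q, s0).
    """
    params = params or DEParams()
    values = np.asarray(values, dtype=float)
    is_stress = np.asarray(is_stress, dtype=bool)
    stress, control = values[:, is_stress], values[:, ~is_stress]
    n1, n2 = stress.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("permutation test needs >= 2 replicates per group")

    if s0 is None:
        s0 = float(np.median(_pooled_se(stress, control))) if params.s0 == "auto" else float(params.s0)
    d = sam_d_statistic(stress, control, s0)

    rng = np.random.default_rng(params.rng_seed)
    pooled = np.concatenate([stress, control], axis=1)
    splits = _label_splits(n1, n2, params.n_permutations, rng)
    abs_perm = np.empty((len(splits), values.shape[0]))
    all_cols = np.arange(n1 + n2)
    for k, grp_a in enumerate(splits):
        mask = np.zeros(n1 + n2, dtype=bool)
        mask[grp_a] = True
        abs_perm[k] = np.abs(sam_d_statistic(pooled[:, mask], pooled[:, ~mask], s0))

    abs_d = np.abs(d)
    order = np.argsort(-abs_d, kind="stable")  # descending |d|
    sorted_abs = abs_d[order]
    # counts at each gene's threshold
    obs_counts = np.arange(1, len(abs_d) + 1)  # #{|d| >= t_g} for descending order
    # handle ties: genes with equal |d| share the larger count
    for i in range(len(sorted_abs) - 2, -1, -1):
        if sorted_abs[i] == sorted_abs[i + 1]:
            obs_counts[i] = obs_counts[i + 1]
    # median over permutations of #{|d*| >= t}
    perm_sorted = np.sort(abs_perm, axis=1)
    perm_counts = np.empty((len(splits), len(sorted_abs)))
    for k in range(len(splits)):
        perm_counts[k] = len(abs_d) - np.searchsorted(perm_sorted[k], sorted_abs, side="left")
    med_counts = np.median(perm_counts, axis=0)
    fdr = np.minimum(med_counts / obs_counts, 1.0)
    # q(g) = min FDR over thresholds t' <= |d_g| (i.e. at or after g in the order)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return d, q, s0


def de_call(log2fc: np.ndarray, qvalue: np.ndarray,
            params: Optional[DEParams] = None) -> np.ndarray:
    """Up/down/none calls: |log2FC| beyond the threshold and q <= q_max."""
    params = params or DEParams()
    log2fc = np.asarray(log2fc, dtype=float)
    qvalue = np.asarray(qvalue, dtype=float)
    sig = np.ones_like(log2fc, dtype=bool) if params.fc_only else (qvalue <= params.q_max)
    call = np.full(log2fc.shape, "none", dtype=object)
    call[(log2fc > params.fc_threshold) & sig] = "up"
    call[(log2fc < -params.fc_threshold) & sig] = "down"
    return call


def stress_de(table: ExpressionTable, params: Optional[DEParams] = None) -> StressExpressionSet:
    """Full stress DE workflow over every (stress, timepoint) contrast.

    Controls are all samples with condition "control".  Contrasts with fewer
    than 2 replicates in either group fall back to fold-change-only calls
    (q = NA) with a loud warning.
    """
    params = params or DEParams()
    meta = table.metadata.loc[table.sample_ids]
    log2 = np.log2(table.values + params.pseudocount)
    control_cols = [s for s in table.sample_ids if meta.loc[s, "condition"] == "control"]
    if not control_cols:
        raise ValueError("no control samples in the table")

    conditions = []
    for s in table.sample_ids:
        c = meta.loc[s, "condition"]
        if c in STRESSES:
            tp = float(meta.loc[s, "timepoint_hours"])
            if (c, tp) not in conditions:
                conditions.append((c, tp))
    conditions.sort(key=lambda ct: (STRESSES.index(ct[0]), ct[1]))

    genes = table.gene_ids
    names = [StressExpressionSet.condition_name(*c) for c in conditions]
    log2fc = pd.DataFrame(index=genes, columns=names, dtype=float)
    d_stat = pd.DataFrame(index=genes, columns=names, dtype=float)
    qvalue = pd.DataFrame(index=genes, columns=names, dtype=float)
    call = pd.DataFrame(index=genes, columns=names, dtype=object)

    ctrl = log2[control_cols].to_numpy()
    for (stress, tp), name in zip(conditions, names):
        cols = [s for s in table.sample_ids
                if meta.loc[s, "condition"] == stress and float(meta.loc[s, "timepoint_hours"]) == tp]
        vals = log2[cols].to_numpy()
        fc = vals.mean(axis=1) - ctrl.mean(axis=1)
        log2fc[name] = fc
        if vals.shape[1] < 2 or ctrl.shape[1] < 2:
            warnings.warn(f"contrast {name}: < 2 replicates per group; "
                          "fold-change-only calls, q reported as NA")
            qvalue[name] = np.nan
            call[name] = de_call(fc, np.full(len(fc), np.nan),
                                 DEParams(**{**params.__dict__, "fc_only": True}))
            continue
        pooled = np.concatenate([vals, ctrl], axis=1)
        is_stress = np.zeros(pooled.shape[1], dtype=bool)
        is_stress[: vals.shape[1]] = True
        d, q, _ = permutation_qvalues(pooled, is_stress, params)
        d_stat[name] = d
        qvalue[name] = q
        call[name] = de_call(fc, q, params)

    return StressExpressionSet(genes=genes, conditions=conditions,
                               log2fc=log2fc, d_stat=d_stat, qvalue=qvalue, call=call)
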