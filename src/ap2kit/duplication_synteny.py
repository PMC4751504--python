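"""Pairwise alignment metrics and duplication/synteny detection.

Tandem duplicates are neighboring homologous family members on one chromosome
separated by at most a fixed number of intervening genes (counted on the full
annotation's gene order, default 1); segmental duplicates are homologous pairs
anchored in one intra-species synteny block.  Homology is judged on global
protein alignments: "similarity" is the fraction of aligned residue pairs with
a positive substitution score, "coverage" the fraction of the longer sequence
that is aligned.

Alignments use Bio.Align.PairwiseAligner with affine gaps; a gap of length k
costs ``gap_open + (k - 1) * gap_extend`` (EMBOSS-needle-like 10/0.5 defaults
with BLOSUM62).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import SyntenyBlock

__all__ = ["AlignMetrics", "DupParams", "DuplicationEvent",
           "global_align", "local_align", "tandem_clusters", "segmental_pairs",
           "map_orthologs"]


@dataclass
class AlignMetrics:
    identity: float    # identical aligned pairs / aligned pairs
    similarity: float  # positive-score aligned pairs / aligned pairs
    coverage: float    # aligned pairs / len(longer sequence)
    score: float

    def __post_init__(self) -> None:
        assert self.identity <= self.similarity + 1e-12


@dataclass
class DupParams:
    """Thresholds for duplication detection.

    ``relaxed`` mode uses the published >= 40% similarity / >= 60% matching
    length criteria; ``stringent`` mode uses tighter 70% / 80% defaults.
    """

    mode: str = "stringent"
    min_similarity: Optional[float] = None
    min_coverage: Optional[float] = None
    max_intervening: int = 1
    metric: str = "similarity"  # which AlignMetrics field the threshold applies to

    _DEFAULTS = {"stringent": (0.70, 0.80), "relaxed": (0.40, 0.60)}

    def __post_init__(self) -> None:
        if self.mode not in self._DEFAULTS:
            raise ValueError(f"unknown mode {self.mode!r}")
        sim, cov = self._DEFAULTS[self.mode]
        if self.min_similarity is None:
            self.min_similarity = sim
        if self.min_coverage is None:
            self.min_coverage = cov
        if not (0 < self.min_similarity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass
class DuplicationEvent:
    kind: str                       # "tandem" | "segmental"
    gene_ids: list[str]
    chromosomes: list[str]
    pair_metrics: dict[tuple[str, str], AlignMetrics] = field(default_factory=dict)
    block_id: Optional[str] = None
    cluster_id: Optional[str] = None


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

def _aligner(matrix_name: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    try:
        matrix = substitution_matrices.load(matrix_name)
    except FileNotFoundError as exc:
        raise ValueError(f"unknown substitution matrix {matrix_name!r}") from exc
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _metrics(alignment, a: str, b: str, matrix) -> AlignMetrics:
    aligned_pairs = 0
    identical = 0
    positive = 0
    for (sa, ea), (sb, eb) in zip(*alignment.aligned):
        for i, j in zip(range(sa, ea), range(sb, eb)):
            aligned_pairs += 1
            if a[i] == b[j]:
                identical += 1
            if matrix[a[i], b[j]] > 0:
                positive += 1
    denom = max(aligned_pairs, 1)
    return AlignMetrics(
        identity=identical / denom,
        similarity=positive / denom,
        coverage=aligned_pairs / max(len(a), len(b)),
        score=float(alignment.score),
    )


def _align(a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float, mode: str):
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _aligner(matrix_name, gap_open, gap_extend, mode)
    alignment = aligner.align(a, b)[0]  # first optimal alignment: deterministic
    matrix = aligner.substitution_matrix
    return alignment, _metrics(alignment, a, b, matrix)


def global_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                 gap_open: float = 10.0, gap_extend: float = 0.5):
    """Needleman-Wunsch with affine gaps; returns (alignment, AlignMetrics)."""
    return _align(a, b, matrix_name, gap_open, gap_extend, "global")


def local_align(a: str, b: str, matrix_name: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.5):
    """Smith-Waterman with affine gaps; coverage is against the longer full sequence."""
    return _align(a, b, matrix_name, gap_open, gap_extend, "local")


# ---------------------------------------------------------------------------
# Tandem / segmental duplication
# ---------------------------------------------------------------------------

def _passes(metrics: AlignMetrics, params: DupParams) -> bool:
    value = getattr(metrics, params.metric)
    return value >= params.min_similarity and metrics.coverage >= params.min_coverage


def tandem_clusters(members: Sequence, all_genes_ordered: dict[str, list[str]],
                    params: Optional[DupParams] = None) -> list[DuplicationEvent]:
    """Detect tandem clusters among family members.

    ``members`` need attributes ``gene_id``, ``chromosome`` and ``sequence``;
    ``all_genes_ordered`` maps chromosome -> full annotation gene order (used
    to count intervening genes).  Clusters are connected components (size >= 2)
    of the graph joining members on the same chromosome with at most
    ``max_intervening`` genes between them and passing the similarity and
    coverage thresholds.
    """
    params = params or DupParams()
    position: dict[str, tuple[str, int]] = {}
    for chrom, order in all_genes_ordered.items():
        for i, gid in enumerate(order):
            position[gid] = (chrom, i)
    for m in members:
        if m.gene_id not in position:
            raise ValueError(f"member gene {m.gene_id} absent from the gene order")

    graph = nx.Graph()
    graph.add_nodes_from(m.gene_id for m in members)
    metrics_cache: dict[tuple[str, str], AlignMetrics] = {}
    by_id = {m.gene_id: m for m in members}
    ids = sorted(by_id)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            chrom_a, pos_a = position[ga]
            chrom_b, pos_b = position[gb]
            if chrom_a != chrom_b:
                continue
            if abs(pos_a - pos_b) - 1 > params.max_intervening:
                continue
            _, metrics = global_align(by_id[ga].sequence, by_id[gb].sequence)
            if _passes(metrics, params):
                graph.add_edge(ga, gb)
                metrics_cache[(ga, gb)] = metrics

    events = []
    components = sorted((sorted(c) for c in nx.connected_components(graph) if len(c) >= 2),
                        key=lambda c: (position[c[0]][0], position[c[0]][1]))
    for k, comp in enumerate(components, start=1):
        comp = sorted(comp, key=lambda g: position[g][1])
        pair_metrics = {pair: m for pair, m in metrics_cache.items()
                        if pair[0] in comp and pair[1] in comp}
        events.append(DuplicationEvent(
            kind="tandem", gene_ids=comp,
            chromosomes=[position[comp[0]][0]],
            pair_metrics=pair_metrics, cluster_id=f"tandem_{k}",
        ))
    return events


def _in_region(member, region: tuple[str, int, int]) -> bool:
    chrom, start, end = region
    return member.chromosome == chrom and member.start < end and member.end > start


def segmental_pairs(members: Sequence, blocks: Sequence[SyntenyBlock],
                    params: Optional[DupParams] = None,
                    tandem_events: Sequence[DuplicationEvent] = ()) -> list[DuplicationEvent]:
    """Detect segmental duplicate pairs supported by intra-species synteny blocks.

    A pair is reported when both genes are anchors of (or fall inside the two
    regions of) one intra-species block, pass the similarity/coverage
    thresholds, and do not already share a tandem cluster.
    """
    params = params or DupParams()
    by_id = {m.gene_id: m for m in members}
    same_cluster = set()
    for ev in tandem_events:
        for i, ga in enumerate(ev.gene_ids):
            for gb in ev.gene_ids[i + 1:]:
                same_cluster.add(frozenset((ga, gb)))

    events = []
    seen_pairs = set()
    for block in blocks:
        if block.species_a != block.species_b:
            continue
        side_a = {ga for ga, _ in block.anchor_pairs if ga in by_id}
        side_b = {gb for _, gb in block.anchor_pairs if gb in by_id}
        side_a |= {m.gene_id for m in members if _in_region(m, block.region_a)}
        side_b |= {m.gene_id for m in members if _in_region(m, block.region_b)}
        for ga in sorted(side_a):
            for gb in sorted(side_b):
                if ga == gb:
                    continue
                key = frozenset((ga, gb))
                if key in seen_pairs or key in same_cluster:
                    continue
                _, metrics = global_align(by_id[ga].sequence, by_id[gb].sequence)
                if not _passes(metrics, params):
                    continue
                seen_pairs.add(key)
                pair = tuple(sorted((ga, gb)))
                events.append(DuplicationEvent(
                    kind="segmental", gene_ids=list(pair),
                    chromosomes=[by_id[pair[0]].chromosome, by_id[pair[1]].chromosome],
                    pair_metrics={pair: metrics}, block_id=block.block_id,
                ))
    return events


def map_orthologs(members: Sequence, blocks: Sequence[SyntenyBlock],
                  focal_species: str) -> tuple[pd.DataFrame, pd.Series]:
    """Map family members to cross-species orthologs via synteny-block anchors.

    Returns (table, per-species summary counts).  Every cross-species block
    anchoring a member yields one row; members in no block are absent.
    """
    member_ids = {m.gene_id for m in members}
    rows = []
    for block in blocks:
        if block.species_a == block.species_b:
            continue
        for ga, gb in block.anchor_pairs:
            if block.species_a == focal_species and ga in member_ids:
                rows.append((ga, block.species_b, gb, block.block_id))
            elif block.species_b == focal_species and gb in member_ids:
                rows.append((gb, block.species_a, ga, block.block_id))
    table = pd.DataFrame(rows, columns=["member_id", "species", "ortholog_gene_id", "block_id"])
    table = table.sort_values(["member_id", "species", "block_id"]).reset_index(drop=True)
    summary = table.groupby("species")["member_id"].nunique() if len(table) else pd.Series(dtype=int)
    return table, summary
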