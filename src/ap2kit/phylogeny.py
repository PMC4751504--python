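"""Profile-anchored alignment, distances, neighbor-joining and group labeling.

Domain subsequences are made column-homologous by aligning each one to the
profile consensus (insertions relative to the consensus are projected out),
giving a deterministic multiple alignment over the L profile columns.  Trees
are built with canonical Saitou-Nei neighbor joining on p-distances
(pairwise deletion; a Poisson correction is available), bootstrap supports
come from column resampling, and DREB/ERF subfamily + subgroup labels are
propagated from labeled anchor sequences placed in the same tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .domain_profile import DomainProfile
from .duplication_synteny import global_align
from .io_formats import SequenceRecord
from .tree import PhyloTree, TreeNode

__all__ = ["AnchoredMSA", "DistanceMatrix", "GroupAnchor",
           "anchor_msa", "p_distance", "nj_tree", "bootstrap_support", "label_groups"]


@dataclass
class AnchoredMSA:
    sequence_ids: list[str]
    rows: list[str]          # residue-or-gap strings, all of length L
    profile_name: str

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError("MSA rows differ in length")
        for sid, row in zip(self.sequence_ids, self.rows):
            if row.count("-") == len(row):
                raise ValueError(f"row {sid} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, column_index: np.ndarray) -> "AnchoredMSA":
        rows = ["".join(row[j] for j in column_index) for row in self.rows]
        return AnchoredMSA(sequence_ids=list(self.sequence_ids), rows=rows,
                           profile_name=self.profile_name)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.isfinite(self.d).all() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")


@dataclass
class GroupAnchor:
    sequence: SequenceRecord
    label: str  # e.g. "DREB", "ERF", "A1", "B4-I"


def anchor_msa(profile: DomainProfile,
               members_hits: Sequence[tuple[str, str]],
               min_occupancy: float = 0.30) -> AnchoredMSA:
    """Map domain subsequences onto the profile's consensus columns.

    Each subsequence is globally aligned to the consensus (BLOSUM62, 10/0.5
    gaps); residues land in the consensus column they align to, insertions
    relative to the consensus are discarded, deletions become gaps.  Rows
    occupying fewer than ``min_occupancy`` of the columns are dropped with a
    warning.
    """
    consensus = profile.consensus
    L = len(consensus)
    ids, rows = [], []
    for sid, subseq in members_hits:
        alignment, _ = global_align(consensus, subseq)
        row = ["-"] * L
        for (cs, ce), (ss, se) in zip(*alignment.aligned):
            for c, s in zip(range(cs, ce), range(ss, se)):
                row[c] = subseq[s]
        occupancy = sum(1 for c in row if c != "-") / L
        if occupancy < min_occupancy:
            warnings.warn(f"dropping {sid}: only {occupancy:.0%} of profile columns occupied")
            continue
        ids.append(sid)
        rows.append("".join(row))
    return AnchoredMSA(sequence_ids=ids, rows=rows, profile_name=profile.domain_name)


def p_distance(msa: AnchoredMSA, model: str = "p",
               on_zero_overlap: str = "error") -> DistanceMatrix:
    """Pairwise-deletion p-distances (optionally Poisson-corrected).

    ``model`` is "p" (mismatches / compared sites) or "poisson"
    (-ln(1 - p)).  Pairs sharing no non-gap column raise an error, or take
    the maximum distance when ``on_zero_overlap="max"`` (used by bootstrap
    replicates, where resampling can empty a sparse pair).
    """
    n = len(msa.rows)
    if n < 3:
        raise ValueError("need >= 3 rows for a distance matrix")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    d = np.zeros((n, n))
    max_seen = 0.0
    zero_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gap[i] & ~gap[j]
            compared = int(both.sum())
            if compared == 0:
                zero_pairs.append((i, j))
                d[i, j] = d[j, i] = np.nan
                continue
            p = float((arr[i][both] != arr[j][both]).sum()) / compared
            if model == "poisson":
                p = min(p, 0.999)  # keep the correction finite
                p = -np.log1p(-p)
            elif model != "p":
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = p
            max_seen = max(max_seen, p)
    if zero_pairs:
        if on_zero_overlap == "max":
            for i, j in zero_pairs:
                d[i, j] = d[j, i] = max_seen if max_seen > 0 else 1.0
        else:
            i, j = zero_pairs[0]
            raise ValueError(
                f"no shared non-gap columns between {msa.sequence_ids[i]} and {msa.sequence_ids[j]}")
    return DistanceMatrix(ids=list(msa.sequence_ids), d=d)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou-Nei neighbor joining.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    joined; exact Q ties are broken on the smallest leaf labels under the
    candidate nodes, which keeps the result deterministic and invariant to
    the input row order.  Branch lengths follow the standard NJ formulas,
    with negative values clamped to zero (raw value retained).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [TreeNode(label=tid) for tid in dm.ids]
    node_keys = [str(tid) for tid in dm.ids]  # min leaf label below each node

    def set_length(node: TreeNode, raw: float) -> None:
        node.raw_length = float(raw)
        node.length = max(0.0, float(raw))

    while len(nodes) > 3:
        m = len(nodes)
        # summing each row in sorted order makes r (hence Q and the tie
        # structure) bit-identical under any permutation of the input rows
        r = np.sort(d, axis=1).sum(axis=1)
        Q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        qmin = flat.min()
        ties = np.flatnonzero(flat == qmin)
        k = int(min(ties, key=lambda t: tuple(sorted((node_keys[int(iu[0][t])],
                                                      node_keys[int(iu[1][t])])))))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode()
        set_length(nodes[i], li)
        set_length(nodes[j], lj)
        parent.children = [nodes[i], nodes[j]]
        new_row = (d[i, :] + d[j, :] - d[i, j]) / 2
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = new_row[keep]
        d = d_new
        nodes = [nodes[x] for x in keep] + [parent]
        node_keys = [node_keys[x] for x in keep] + [min(node_keys[i], node_keys[j])]

    # final trifurcation
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    root = TreeNode()
    set_length(nodes[0], (d01 + d02 - d12) / 2)
    set_length(nodes[1], (d01 + d12 - d02) / 2)
    set_length(nodes[2], (d02 + d12 - d01) / 2)
    root.children = list(nodes)
    return PhyloTree(root=root)


def bootstrap_support(msa: AnchoredMSA, B: int = 1000, rng_seed: int = 0,
                      model: str = "p") -> PhyloTree:
    """NJ tree with internal-edge bootstrap supports from column resampling.

    Each internal edge of the full-data tree is annotated with the number of
    replicate trees (out of B) containing the same leaf bipartition.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    full = nj_tree(p_distance(msa, model=model))
    biparts = full.bipartitions()
    counts = {side: 0 for side in biparts}
    rng = np.random.default_rng(rng_seed)
    ncol = msa.n_columns
    for _ in range(B):
        cols = rng.integers(0, ncol, size=ncol)
        rep_msa = msa.resample_columns(cols)
        rep = nj_tree(p_distance(rep_msa, model=model, on_zero_overlap="max"))
        rep_sides = set(rep.bipartitions())
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for side, node in biparts.items():
        node.support = counts[side]
    full.n_bootstrap = B
    return full


def label_groups(tree: PhyloTree, anchors: Sequence[GroupAnchor]) -> dict[str, str]:
    """Propagate anchor labels to query leaves through the tree.

    For each non-anchor leaf the smallest edge-bipartition side containing it
    and at least one anchor decides: if all anchors on that side share one
    label it is assigned, otherwise the leaf stays "unclassified".
    """
    anchor_labels = {a.sequence.id: a.label for a in anchors}
    leaf_set = set(tree.leaf_labels())
    present = {aid for aid in anchor_labels if aid in leaf_set}
    if not present:
        raise ValueError("no anchor leaves present in the tree")

    all_leaves = frozenset(leaf_set)
    sides = set()
    for node, clade in tree.clades().items():
        if node is tree.root:
            continue
        sides.add(clade)
        sides.add(all_leaves - clade)

    result: dict[str, str] = {}
    for leaf in sorted(leaf_set):
        if leaf in anchor_labels:
            result[leaf] = anchor_labels[leaf]
            continue
        candidates = [s for s in sides if leaf in s and s & present]
        candidates.sort(key=lambda s: (len(s), tuple(sorted(s))))
        side = candidates[0]
        labels = {anchor_labels[a] for a in side & present}
        result[leaf] = labels.pop() if len(labels) == 1 else "unclassified"
    return result
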