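"""Independent brute-force oracles, coded as direct transcriptions of the
textbook formulas and kept free of the package's implementation paths."""

import itertools
import math

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# Needleman-Wunsch by exhaustive enumeration (affine gaps, open + (k-1)*extend)
# ---------------------------------------------------------------------------

def nw_enumerate(a, b, matrix, gap_open, gap_extend):
    """Optimal global alignment score by recursion over all alignments."""
    best = [-math.inf]

    def rec(i, j, prev, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + matrix[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "D", score - (gap_extend if prev == "D" else gap_open))
        if j < len(b):
            rec(i, j + 1, "I", score - (gap_extend if prev == "I" else gap_open))

    rec(0, 0, None, 0.0)
    return best[0]


# ---------------------------------------------------------------------------
# Neighbor joining, direct transcription with plain lists
# ---------------------------------------------------------------------------

def nj_transcription(ids, dmat):
    """Saitou-Nei NJ returning {canonical edge key: branch length}.

    Edge keys are frozensets of the leaf labels on the side of the edge not
    containing the alphabetically smallest label (leaf edges keyed by the
    single leaf).  Negative branch lengths are clamped to zero, matching the
    published convention of reporting non-negative lengths.
    """
    ids = list(ids)
    ref = min(ids)
    all_leaves = frozenset(ids)

    def canonical(side):
        side = frozenset(side)
        return side if ref not in side else all_leaves - side

    d = {}
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            d[(a, b)] = float(dmat[i][j])
    # each active node: (key, set of leaves below)
    active = [(tid, frozenset([tid])) for tid in ids]
    edges = {}

    def clamp(x):
        return max(0.0, x)

    while len(active) > 3:
        n = len(active)
        r = {k: sum(d[(k, other)] for other, _ in active if other != k) for k, _ in active}
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                ki, kj = active[i][0], active[j][0]
                q = (n - 2) * d[(ki, kj)] - r[ki] - r[kj]
                if best is None or q < best[0]:
                    best = (q, i, j)
        _, i, j = best
        (ki, li), (kj, lj) = active[i], active[j]
        bi = d[(ki, kj)] / 2 + (r[ki] - r[kj]) / (2 * (n - 2))
        bj = d[(ki, kj)] - bi
        edges[canonical(li)] = clamp(bi)
        edges[canonical(lj)] = clamp(bj)
        new_key = ("u", ki, kj)
        new_set = li | lj
        for k, _ in active:
            if k in (ki, kj):
                continue
            d[(new_key, k)] = d[(k, new_key)] = (d[(ki, k)] + d[(kj, k)] - d[(ki, kj)]) / 2
        active = [x for x in active if x[0] not in (ki, kj)] + [(new_key, new_set)]

    (k0, l0), (k1, l1), (k2, l2) = active
    d01, d02, d12 = d[(k0, k1)], d[(k0, k2)], d[(k1, k2)]
    edges[canonical(l0)] = clamp((d01 + d02 - d12) / 2)
    edges[canonical(l1)] = clamp((d01 + d12 - d02) / 2)
    edges[canonical(l2)] = clamp((d02 + d12 - d01) / 2)
    return edges


def tree_edge_lengths(tree):
    """Canonical {edge key: length} for a PhyloTree (same keys as the oracle)."""
    all_leaves = frozenset(tree.leaf_labels())
    ref = min(all_leaves)
    out = {}
    for node, clade in tree.clades().items():
        if node is tree.root:
            continue
        side = clade if ref not in clade else all_leaves - clade
        out[side] = node.length
    return out


# ---------------------------------------------------------------------------
# Random additive trees
# ---------------------------------------------------------------------------

def random_additive_tree(n_leaves, rng):
    """Random binary topology with uniform branch lengths.

    Returns (labels, distance matrix, set of non-trivial splits canonicalized
    against the alphabetically smallest label).
    """
    labels = [f"L{chr(ord('a') + i)}" if i < 26 else f"L{i}" for i in range(n_leaves)]
    graph = nx.Graph()
    nodes = list(labels)
    counter = itertools.count()
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        u = f"internal{next(counter)}"
        graph.add_edge(nodes[i], u, weight=float(rng.uniform(0.1, 1.0)))
        graph.add_edge(nodes[j], u, weight=float(rng.uniform(0.1, 1.0)))
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [u]
    root = f"internal{next(counter)}"
    for x in nodes:
        graph.add_edge(x, root, weight=float(rng.uniform(0.1, 1.0)))

    dist = dict(nx.all_pairs_dijkstra_path_length(graph))
    d = np.array([[dist[a][b] for b in labels] for a in labels])

    ref = min(labels)
    all_leaves = frozenset(labels)
    splits = set()
    for a, b in graph.edges():
        g2 = graph.copy()
        g2.remove_edge(a, b)
        side = frozenset(x for x in nx.node_connected_component(g2, a) if x in all_leaves)
        side = side if ref not in side else all_leaves - side
        if 2 <= len(side) <= n_leaves - 2:
            splits.add(side)
    return labels, d, splits


# ---------------------------------------------------------------------------
# SAM q-values by brute force (exact enumeration of label splits)
# ---------------------------------------------------------------------------

def sam_q_bruteforce(values, n_stress, s0):
    """q-values for a genes x (stress+control) matrix, enumerating all splits.

    Direct evaluation of: d = (m1 - m2) / (pooled SE + s0); FDR at threshold
    t = median over splits of #{|d*| >= t} divided by #{|d| >= t}; q(g) =
    min FDR over thresholds t' <= |d_g|, capped at 1.
    """
    values = [list(map(float, row)) for row in values]
    n_total = len(values[0])

    def dstat(row, idx_a):
        a = [row[i] for i in idx_a]
        b = [row[i] for i in range(n_total) if i not in idx_a]
        ma = sum(a) / len(a)
        mb = sum(b) / len(b)
        ssa = sum((x - ma) ** 2 for x in a)
        ssb = sum((x - mb) ** 2 for x in b)
        s = math.sqrt((1 / len(a) + 1 / len(b)) * (ssa + ssb) / (len(a) + len(b) - 2))
        return (ma - mb) / (s + s0)

    obs_idx = tuple(range(n_stress))
    d = [dstat(row, obs_idx) for row in values]
    splits = list(itertools.combinations(range(n_total), n_stress))
    perm_abs = [[abs(dstat(row, split)) for row in values] for split in splits]

    abs_d = [abs(x) for x in d]
    fdr = []
    for t in abs_d:
        obs_count = sum(1 for x in abs_d if x >= t)
        counts = sorted(sum(1 for x in perm if x >= t) for perm in perm_abs)
        k = len(counts)
        med = (counts[k // 2] if k % 2 else (counts[k // 2 - 1] + counts[k // 2]) / 2)
        fdr.append(min(1.0, med / obs_count))
    q = []
    for g in range(len(d)):
        q.append(min(fdr[h] for h in range(len(d)) if abs_d[h] <= abs_d[g]))
    return d, q
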