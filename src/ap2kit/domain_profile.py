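"""Position-specific scoring models for protein domains.

A :class:`DomainProfile` is a gapless log-odds matrix (PSSM) built from a seed
alignment.  Proteins are scanned with a sliding window; significance comes
from a Gumbel null fitted to maximum window scores of background-shuffled
sequences, giving each hit an E-value (the expected number of equally good
matches in a database of ``D`` null sequences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io_formats import AMINO_ACIDS, FormatError, SequenceRecord

__all__ = ["DomainProfile", "DomainHit", "build_profile", "scan_sequence", "calibrate_null",
           "write_profile", "read_profile"]

# Profile alphabet: the 20 amino acids plus X (unknown; score pinned to 0).
ALPHABET = AMINO_ACIDS + "X"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}
_EULER_GAMMA = 0.5772156649015329

PathLike = Union[str, Path]


def encode(residues: str) -> np.ndarray:
    """Map residues onto alphabet indices; unknown letters behave like X."""
    return np.array([_AA_INDEX.get(a, _AA_INDEX["X"]) for a in residues], dtype=np.int64)


@dataclass
class DomainProfile:
    domain_name: str
    scores: np.ndarray            # L x 21 log-odds, base 2; column for X is 0
    consensus: str                # length-L argmax residues
    background: np.ndarray        # 21-vector, sums to 1
    null_mu: Optional[float] = None     # Gumbel location of null max-window scores
    null_beta: Optional[float] = None   # Gumbel scale (> 0)
    calibration_n: int = 0
    calibration_scores: Optional[np.ndarray] = None
    pseudocount: float = 0.1
    gap_threshold: float = 0.5

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.null_mu is not None and self.null_beta is not None

    def evalue(self, score: float, database_size: int = 1) -> float:
        """Expected number of >= score max-window matches among D null sequences."""
        if not self.calibrated:
            raise ValueError(f"profile {self.domain_name!r} is not calibrated")
        z = (score - self.null_mu) / self.null_beta
        # 1 - Gumbel CDF = 1 - exp(-exp(-z)), computed stably
        p = -math.expm1(-math.exp(-z)) if z > -30 else 1.0
        return database_size * p


@dataclass
class DomainHit:
    protein_id: str
    domain_name: str
    start: int   # 0-based half-open on the protein
    end: int
    score: float          # bits
    evalue: float = math.inf
    truncated: bool = False

    @property
    def hit_length(self) -> int:
        return self.end - self.start


def build_profile(seed_alignment: Sequence[SequenceRecord], domain_name: str,
                  pseudocount: float = 0.1, gap_threshold: float = 0.5) -> DomainProfile:
    """Build a log-odds PSSM from an aligned seed.

    Match columns are the alignment columns with fewer than ``gap_threshold``
    gaps.  Per-column score for residue a is
    ``log2(((c_a + pc) / (n_col + 21 * pc)) / background_a)`` with the
    background estimated from the whole seed under the same pseudocounting.
    The score of X is pinned to 0 in every column.
    """
    if len(seed_alignment) < 5:
        raise ValueError(f"seed alignment needs >= 5 sequences, got {len(seed_alignment)}")
    lengths = {len(r.residues) for r in seed_alignment}
    if len(lengths) != 1:
        raise FormatError("ragged seed alignment: sequences differ in aligned length")
    n_seq = len(seed_alignment)
    width = lengths.pop()
    rows = np.array([[c for c in r.residues] for r in seed_alignment])

    # background over the whole seed (non-gap residues), pseudocounted over 21 letters
    total = np.zeros(21)
    for a, i in _AA_INDEX.items():
        total[i] = np.sum(rows == a)
    unknown = np.sum((rows != "-")) - total.sum()  # non-standard letters count as X
    total[_AA_INDEX["X"]] += unknown
    background = (total + pseudocount) / (total.sum() + 21 * pseudocount)

    match_cols = [j for j in range(width) if np.mean(rows[:, j] == "-") < gap_threshold]
    if len(match_cols) < 10:
        raise ValueError(f"profile too short: {len(match_cols)} match columns (< 10)")

    L = len(match_cols)
    scores = np.zeros((L, 21))
    consensus_chars = []
    for out_j, j in enumerate(match_cols):
        col = rows[:, j]
        counts = np.zeros(21)
        for a, i in _AA_INDEX.items():
            counts[i] = np.sum(col == a)
        counts[_AA_INDEX["X"]] += np.sum(col != "-") - counts.sum()
        n_col = counts.sum()
        freqs = (counts + pseudocount) / (n_col + 21 * pseudocount)
        scores[out_j] = np.log2(freqs / background)
        scores[out_j, _AA_INDEX["X"]] = 0.0
        # consensus: argmax count over the 20 standard residues, ties alphabetical
        aa_counts = counts[:20]
        consensus_chars.append(AMINO_ACIDS[int(np.argmax(aa_counts))])

    return DomainProfile(
        domain_name=domain_name, scores=scores, consensus="".join(consensus_chars),
        background=background, pseudocount=pseudocount, gap_threshold=gap_threshold,
    )


def _window_scores(profile: DomainProfile, idx: np.ndarray) -> np.ndarray:
    """Scores of all full-width windows (empty array if sequence shorter than L)."""
    L = profile.length
    n = len(idx)
    if n < L:
        return np.zeros(0)
    S = profile.scores[:, idx]  # L x n lookup
    out = np.zeros(n - L + 1)
    for i in range(L):
        out += S[i, i:i + n - L + 1]
    return out


def scan_sequence(profile: DomainProfile, seq: SequenceRecord,
                  database_size: int = 1, min_truncated: int = 8) -> list[DomainHit]:
    """Scan one protein with a gapless sliding window of the profile width.

    Candidate windows with positive score are accepted greedily best-first,
    discarding windows overlapping an accepted hit by more than L/2.
    Windows shorter than L hanging off either sequence end are allowed and
    flagged ``truncated``.  E-values require a calibrated profile and refer to
    a database of ``database_size`` sequences.
    """
    residues = seq.residues
    n = len(residues)
    if n == 0:
        return []
    L = profile.length
    idx = encode(residues)

    candidates: list[tuple[float, int, int, bool]] = []  # (score, start, end, truncated)
    full = _window_scores(profile, idx)
    for p in range(len(full)):
        if full[p] > 0:
            candidates.append((float(full[p]), p, p + L, False))

    # truncated windows: domain running off the C-terminus (profile prefix at the
    # sequence tail) and off the N-terminus (profile suffix at the sequence head)
    max_k = min(L - 1, n)
    for k in range(min_truncated, max_k + 1):
        if k == L:
            continue
        tail = idx[n - k:]
        s = float(profile.scores[np.arange(k), tail].sum())
        if s > 0:
            candidates.append((s, n - k, n, True))
        head = idx[:k]
        s = float(profile.scores[np.arange(L - k, L), head].sum())
        if s > 0:
            candidates.append((s, 0, k, True))

    # greedy best-score-first acceptance with overlap > L/2 exclusion
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[tuple[float, int, int, bool]] = []
    for score, start, end, trunc in candidates:
        overlapping = False
        for _, a_start, a_end, _ in accepted:
            overlap = min(end, a_end) - max(start, a_start)
            if overlap > L / 2:
                overlapping = True
                break
        if not overlapping:
            accepted.append((score, start, end, trunc))

    hits = []
    for score, start, end, trunc in sorted(accepted, key=lambda c: c[1]):
        ev = profile.evalue(score, database_size) if profile.calibrated else math.inf
        hits.append(DomainHit(protein_id=seq.id, domain_name=profile.domain_name,
                              start=start, end=end, score=score, evalue=ev, truncated=trunc))
    return hits


def calibrate_null(profile: DomainProfile, n_shuffles: int = 1000,
                   length: int = 300, rng_seed: int = 0) -> DomainProfile:
    """Fit a Gumbel null to maximum window scores of background-sampled sequences.

    ``n_shuffles`` i.i.d. sequences of the given length are drawn from the
    profile background; the Gumbel location/scale are fitted to their maximum
    full-window scores by the method of moments.  Deterministic per seed.
    """
    if n_shuffles < 200:
        raise ValueError("n_shuffles must be >= 200 for a stable Gumbel fit")
    if length < profile.length:
        raise ValueError("calibration length must be >= profile length")
    rng = np.random.default_rng(rng_seed)
    maxima = np.zeros(n_shuffles)
    p = profile.background / profile.background.sum()
    for i in range(n_shuffles):
        idx = rng.choice(21, size=length, p=p)
        maxima[i] = _window_scores(profile, idx).max()
    var = maxima.var(ddof=1)
    beta = math.sqrt(6.0 * var) / math.pi
    mu = maxima.mean() - _EULER_GAMMA * beta
    profile.null_mu = mu
    profile.null_beta = beta
    profile.calibration_n = n_shuffles
    profile.calibration_scores = maxima
    return profile


# ---------------------------------------------------------------------------
# Serialization (versioned TSV with header comment lines)
# ---------------------------------------------------------------------------

def write_profile(profile: DomainProfile, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# ap2kit-profile\tv1\n")
        fh.write(f"# domain_name\t{profile.domain_name}\n")
        fh.write(f"# consensus\t{profile.consensus}\n")
        mu = "" if profile.null_mu is None else repr(float(profile.null_mu))
        beta = "" if profile.null_beta is None else repr(float(profile.null_beta))
        fh.write(f"# null_mu\t{mu}\n# null_beta\t{beta}\n")
        fh.write(f"# calibration_n\t{profile.calibration_n}\n")
        fh.write("# background\t" + "\t".join(repr(float(x)) for x in profile.background) + "\n")
        fh.write("pos\t" + "\t".join(ALPHABET) + "\n")
        for i in range(profile.length):
            fh.write(str(i) + "\t" + "\t".join(repr(float(x)) for x in profile.scores[i]) + "\n")


def read_profile(path: PathLike) -> DomainProfile:
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# "):
                parts = line[2:].split("\t")
                meta[parts[0]] = parts[1] if len(parts) > 1 else ""
                if parts[0] == "background":
                    meta["background"] = "\t".join(parts[1:])
            elif line.startswith("pos\t") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")[1:]])
    profile = DomainProfile(
        domain_name=meta["domain_name"],
        scores=np.array(rows),
        consensus=meta["consensus"],
        background=np.array([float(x) for x in meta["background"].split("\t")]),
        null_mu=float(meta["null_mu"]) if meta.get("null_mu") else None,
        null_beta=float(meta["null_beta"]) if meta.get("null_beta") else None,
        calibration_n=int(meta.get("calibration_n", 0)),
    )
    return profile
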