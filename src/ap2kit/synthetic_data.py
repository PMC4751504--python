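"""Synthetic genomes, proteomes, annotations and expression sets with planted truth.

The generator emulates the inputs of a genome-wide AP2/EREBP survey: an
annotated five-chromosome genome whose proteome contains planted family
members (double-AP2, AP2+B3 and single-domain architectures, the latter split
into DREB-like and ERF-like sequence variants), background decoys, truncated
splice isoforms, tandem clusters and segmental pairs with identity-tuned
duplicate copies, synteny blocks, and a 4-stress x 5-timepoint expression
series with planted fold-change effects and planted duplicate-pair
correlations.  Everything is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .domain_profile import DomainProfile, build_profile, calibrate_null
from .duplication_synteny import global_align
from .io_formats import ExpressionTable, GeneModel, SequenceRecord, SyntenyBlock, Transcript
from .phylogeny import GroupAnchor

__all__ = ["SimParams", "SyntheticTruth", "MemberTruth", "make_seed_alignment",
           "default_profiles", "group_variants", "gen_proteome_gff", "gen_reference_sets",
           "gen_synteny_blocks", "gen_expression", "gen_probe_table", "minimal_truth"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Hand-written ~60-residue consensus strings resembling the two DNA-binding
# domains (AP2: beta-sheet + helix architecture; B3: the second RAV domain).
# These are synthetic stand-ins for curated seed alignments, not database
# sequences.
AP2_CONSENSUS = "SKYRGVRQRPWGKWVAEIRDPRKGVRVWLGTFDTAEEAARAYDRAALRFRGPRAKLNFP"
B3_CONSENSUS = "KVLLQKELKNSDVGSLGRIVLPKKEAEVHLPELEARDGISIAMEDIGTSRVWNMRYRFWPNNNSRMYLLENTG"

STRESSES = ("cold", "heat", "drought", "salt")
TISSUES = ("root", "stem", "leaf")


@dataclass
class SimParams:
    rng_seed: int = 42
    n_chromosomes: int = 5
    n_decoys: int = 200
    n_ap2_members: int = 12
    n_rav_members: int = 8
    n_single_members: int = 40          # includes the tandem-cluster genes
    domain_mutation_rate: float = 0.05
    member_length: tuple[int, int] = (250, 450)
    decoy_length: tuple[int, int] = (150, 500)
    isoform_fraction: float = 0.2
    tandem_clusters: tuple = ((6, 0.85), (2, 0.80), (2, 0.90), (2, 0.85))
    identity_tolerance: float = 0.03
    segmental_identities: tuple = (0.80, 0.75)
    n_group_positions: int = 12          # substitutions separating DREB-like / ERF-like
    n_anchors_per_group: int = 5
    anchor_mutation_rate: float = 0.03
    n_queries: int = 3
    # expression design
    timepoints: tuple = (1.0, 2.0, 5.0, 10.0, 24.0)
    n_replicates: int = 3
    noise_sd: float = 0.25
    baseline_mean: float = 5.0
    baseline_sd: float = 1.0
    latent_sd: float = 1.5               # sd of per-gene condition profiles
    n_de_effects: int = 30
    de_effect: float = 2.0
    pair_rho_tandem: float = 0.9
    pair_rho_segmental: tuple = (-0.5, 0.9)
    n_tissue_replicates: int = 2
    tissue_shift_sd: float = 2.0
    n_unprobed_members: int = 1
    integer_counts: bool = True

    def __post_init__(self) -> None:
        n_cluster_genes = sum(size for size, _ in self.tandem_clusters)
        if n_cluster_genes + 2 * len(self.segmental_identities) > self.n_single_members:
            raise ValueError("not enough single-domain members for the planted duplications")


@dataclass
class MemberTruth:
    gene_id: str
    protein_id: str
    subfamily: str              # AP2 | RAV | DREB | ERF
    n_ap2: int
    n_b3: int
    domain_offsets: list[tuple[str, int, int]] = field(default_factory=list)


@dataclass
class SyntheticTruth:
    members: dict[str, MemberTruth] = field(default_factory=dict)
    decoys: list[str] = field(default_factory=list)
    isoforms: dict[str, list[str]] = field(default_factory=dict)
    tandem_clusters: list[tuple[list[str], float]] = field(default_factory=list)
    segmental_pairs: list[tuple[str, str, float, str]] = field(default_factory=list)
    de_effects: list[tuple[str, str, float, float]] = field(default_factory=list)
    pair_rho: list[tuple[str, str, float]] = field(default_factory=list)
    all_gene_ids: list[str] = field(default_factory=list)
    unprobed_genes: list[str] = field(default_factory=list)

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Truth as plain DataFrames, for TSV export and test harnesses."""
        members = pd.DataFrame(
            [(m.gene_id, m.protein_id, m.subfamily, m.n_ap2, m.n_b3) for m in self.members.values()],
            columns=["gene_id", "protein_id", "subfamily", "n_ap2", "n_b3"])
        tandem = pd.DataFrame(
            [(i + 1, ",".join(genes), ident) for i, (genes, ident) in enumerate(self.tandem_clusters)],
            columns=["cluster", "gene_ids", "target_identity"])
        segmental = pd.DataFrame(self.segmental_pairs,
                                 columns=["gene_a", "gene_b", "target_identity", "block_id"])
        effects = pd.DataFrame(self.de_effects, columns=["gene_id", "stress", "timepoint_hours", "log2_effect"])
        rho = pd.DataFrame(self.pair_rho, columns=["gene_a", "gene_b", "rho"])
        return {"members": members, "tandem": tandem, "segmental": segmental,
                "de_effects": effects, "pair_rho": rho}


# ---------------------------------------------------------------------------
# Seeds, profiles and group variants
# ---------------------------------------------------------------------------

def make_seed_alignment(domain_name: str, n_seqs: int = 30, sub_rate: float = 0.15,
                        rng_seed: int = 7) -> list[SequenceRecord]:
    """A synthetic aligned seed: the domain consensus substituted i.i.d. per row,
    with two columns made gappy to exercise match-column selection."""
    consensus = {"AP2": AP2_CONSENSUS, "B3": B3_CONSENSUS}[domain_name]
    rng = np.random.default_rng([rng_seed, len(consensus)])
    gap_cols = rng.choice(len(consensus), size=2, replace=False)
    records = []
    for k in range(n_seqs):
        chars = list(consensus)
        for i in range(len(chars)):
            if rng.random() < sub_rate:
                chars[i] = AMINO_ACIDS[rng.integers(20)]
        for col in gap_cols:
            if rng.random() < 0.6:
                chars[col] = "-"
        records.append(SequenceRecord(id=f"{domain_name}_seed_{k + 1}", residues="".join(chars)))
    return records


def default_profiles(calibration_length: int = 300, n_shuffles: int = 1000,
                     rng_seed: int = 7) -> dict[str, DomainProfile]:
    """Build and calibrate the AP2 and B3 profiles from the synthetic seeds."""
    profiles = {}
    for name in ("AP2", "B3"):
        profile = build_profile(make_seed_alignment(name, rng_seed=rng_seed), name)
        calibrate_null(profile, n_shuffles=n_shuffles, length=calibration_length,
                       rng_seed=rng_seed)
        profiles[name] = profile
    return profiles


def group_variants(profile: DomainProfile, params: SimParams) -> dict[str, str]:
    """DREB-like and ERF-like variant consensi: disjoint fixed substitution sets
    applied to the AP2 profile consensus (deterministic per params seed)."""
    rng = np.random.default_rng([params.rng_seed, 101])
    L = len(profile.consensus)
    positions = rng.choice(L, size=2 * params.n_group_positions, replace=False)
    variants = {}
    for label, pos in (("DREB", positions[: params.n_group_positions]),
                       ("ERF", positions[params.n_group_positions:])):
        chars = list(profile.consensus)
        for p in pos:
            current = chars[p]
            chars[p] = AMINO_ACIDS[(AMINO_ACIDS.index(current) + 7) % 20]
        variants[label] = "".join(chars)
    return variants


# ---------------------------------------------------------------------------
# Proteome + annotation
# ---------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            new = AMINO_ACIDS[rng.integers(20)]
            while new == chars[i]:
                new = AMINO_ACIDS[rng.integers(20)]
            chars[i] = new
    return "".join(chars)


def _tune_copy(rng: np.random.Generator, founder: str, target_identity: float,
               tolerance: float, max_rounds: int = 40) -> str:
    """Duplicate ``founder`` with i.i.d. substitutions, adjusting the rate until
    the realized global-alignment identity is within tolerance of the target."""
    rate = 1.0 - target_identity
    for _ in range(max_rounds):
        copy = _mutate(rng, founder, rate)
        _, metrics = global_align(founder, copy)
        if abs(metrics.identity - target_identity) <= tolerance:
            return copy
        rate = min(0.95, max(0.005, rate + (metrics.identity - target_identity)))
    raise RuntimeError(f"could not reach identity {target_identity} within {max_rounds} rounds")


def _build_gene_model(rng: np.random.Generator, gene_id: str, chrom: str, cursor: int,
                      protein_lengths: list[int], n_exons: int) -> tuple[GeneModel, int]:
    """Lay out a gene with ``n_exons`` exons for its primary protein; secondary
    (isoform) transcripts reuse a truncated prefix of the exon chain."""
    cds_len = 3 * protein_lengths[0]
    n_exons = min(n_exons, cds_len)
    if n_exons > 1:
        cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0] + list(cuts) + [cds_len]
    exon_lens = [int(b - a) for a, b in zip(bounds, bounds[1:])]
    intron_lens = [int(rng.integers(60, 300)) for _ in range(n_exons - 1)]

    start = cursor
    exons = []
    pos = start
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = pos
    transcripts = [Transcript(transcript_id=f"{gene_id}.t1", exons=exons,
                              protein_id=f"{gene_id}.1")]
    for k, plen in enumerate(protein_lengths[1:], start=2):
        want = 3 * plen
        sub = []
        for s, e in exons:
            take = min(e - s, want)
            if take <= 0:
                break
            sub.append((s, s + take))
            want -= take
        transcripts.append(Transcript(transcript_id=f"{gene_id}.t{k}", exons=sub,
                                      protein_id=f"{gene_id}.{k}"))
    model = GeneModel(gene_id=gene_id, chromosome=chrom, start=start, end=end,
                      strand="+" if rng.random() < 0.5 else "-", transcripts=transcripts)
    return model, end + int(rng.integers(500, 3000))


def gen_proteome_gff(params: SimParams, profiles: dict[str, DomainProfile]
                     ) -> tuple[list[SequenceRecord], list[GeneModel], SyntheticTruth]:
    """Generate the annotated synthetic proteome with planted family members.

    Returns (protein records, gene models, truth).  Member proteins carry
    profile-consensus-derived domains (mutated at ``domain_mutation_rate``) in
    background flanks; decoys are pure background; tandem/segmental duplicates
    are identity-tuned copies of founder members; a fraction of member genes
    get truncated secondary isoforms.
    """
    rng = np.random.default_rng([params.rng_seed, 1])
    ap2 = profiles["AP2"]
    b3 = profiles["B3"]
    variants = group_variants(ap2, params)
    truth = SyntheticTruth()

    def plant(domains: list[tuple[str, str]], length: int) -> tuple[str, list[tuple[str, int, int]]]:
        """Background protein with the given (name, consensus) domains planted in order."""
        seq = list(_random_residues(rng, length))
        offsets = []
        pos = int(rng.integers(15, 41))
        for name, consensus in domains:
            dom = _mutate(rng, consensus, params.domain_mutation_rate)
            seq[pos:pos + len(dom)] = list(dom)
            offsets.append((name, pos, pos + len(dom)))
            pos += len(dom) + int(rng.integers(15, 41))
        return "".join(seq), offsets

    def member_length(min_needed: int) -> int:
        lo, hi = params.member_length
        return int(rng.integers(max(lo, min_needed), max(hi, min_needed + 1)))

    # ---- plan membership -------------------------------------------------
    proteins: dict[str, str] = {}
    member_order: list[str] = []
    gene_counter = [0]

    def new_gene_id() -> str:
        gene_counter[0] += 1
        return f"Sg{gene_counter[0]:04d}"

    def add_member(subfamily: str, sequence: str,
                   offsets: list[tuple[str, int, int]]) -> str:
        gid = new_gene_id()
        pid = f"{gid}.1"
        proteins[pid] = sequence
        n_ap2 = sum(1 for n, _, _ in offsets if n == "AP2")
        n_b3 = sum(1 for n, _, _ in offsets if n == "B3")
        truth.members[gid] = MemberTruth(gene_id=gid, protein_id=pid, subfamily=subfamily,
                                         n_ap2=n_ap2, n_b3=n_b3, domain_offsets=offsets)
        member_order.append(gid)
        return gid

    for _ in range(params.n_ap2_members):
        L = member_length(2 * len(ap2.consensus) + 120)
        seq, offs = plant([("AP2", ap2.consensus), ("AP2", ap2.consensus)], L)
        add_member("AP2", seq, offs)
    for _ in range(params.n_rav_members):
        L = member_length(len(ap2.consensus) + len(b3.consensus) + 120)
        seq, offs = plant([("AP2", ap2.consensus), ("B3", b3.consensus)], L)
        add_member("RAV", seq, offs)

    n_cluster_genes = sum(size for size, _ in params.tandem_clusters)
    n_segmental_genes = 2 * len(params.segmental_identities)
    n_scatter = params.n_single_members - n_cluster_genes - n_segmental_genes

    single_groups = ["DREB" if i % 2 == 0 else "ERF" for i in range(n_scatter)]
    scatter_singles = []
    for grp in single_groups:
        L = member_length(len(ap2.consensus) + 120)
        seq, offs = plant([("AP2", variants[grp])], L)
        scatter_singles.append(add_member(grp, seq, offs))

    cluster_gene_lists: list[list[str]] = []
    for size, identity in params.tandem_clusters:
        L = member_length(len(ap2.consensus) + 120)
        founder_seq, offs = plant([("AP2", variants["DREB"])], L)
        genes = [add_member("DREB", founder_seq, offs)]
        for _ in range(size - 1):
            copy = _tune_copy(rng, founder_seq, identity, params.identity_tolerance)
            offs_c = [(n, s, e) for n, s, e in offs]
            genes.append(add_member("DREB", copy, offs_c))
        cluster_gene_lists.append(genes)
        truth.tandem_clusters.append((genes, identity))

    segmental_gene_pairs: list[tuple[str, str]] = []
    for k, identity in enumerate(params.segmental_identities):
        L = member_length(len(ap2.consensus) + 120)
        founder_seq, offs = plant([("AP2", variants["ERF"])], L)
        ga = add_member("ERF", founder_seq, offs)
        copy = _tune_copy(rng, founder_seq, identity, params.identity_tolerance)
        gb = add_member("ERF", copy, [(n, s, e) for n, s, e in offs])
        segmental_gene_pairs.append((ga, gb))
        truth.segmental_pairs.append((ga, gb, identity, f"block_seg_{k + 1}"))

    decoys = []
    for _ in range(params.n_decoys):
        gid = new_gene_id()
        lo, hi = params.decoy_length
        proteins[f"{gid}.1"] = _random_residues(rng, int(rng.integers(lo, hi)))
        decoys.append(gid)
    truth.decoys = decoys

    # ---- isoforms --------------------------------------------------------
    iso_candidates = [g for g in member_order]
    n_iso = int(round(params.isoform_fraction * len(iso_candidates)))
    iso_genes = sorted(rng.choice(iso_candidates, size=n_iso, replace=False))
    for gid in iso_genes:
        primary = proteins[f"{gid}.1"]
        first_end = truth.members[gid].domain_offsets[0][2]
        cut = max(int(0.7 * len(primary)), first_end + 10)
        if cut >= len(primary):
            continue
        proteins[f"{gid}.2"] = primary[:cut]
        truth.isoforms[gid] = [f"{gid}.1", f"{gid}.2"]

    # ---- chromosome layout ----------------------------------------------
    # atomic blocks: tandem clusters stay contiguous (first cluster gets one
    # intervening decoy); everything else is a singleton block
    blocks: list[list[str]] = []
    used_decoys = set()
    for ci, genes in enumerate(cluster_gene_lists):
        block = list(genes)
        if ci == 0 and decoys:
            inter = decoys[0]
            used_decoys.add(inter)
            block = [genes[0], inter] + genes[1:]
        blocks.append(block)
    loose = ([g for g in member_order if not any(g in c for c in cluster_gene_lists)]
             + [d for d in decoys if d not in used_decoys])
    blocks.extend([[g] for g in loose])

    order = rng.permutation(len(blocks))
    chroms = [f"Bd{i + 1}" for i in range(params.n_chromosomes)]
    per_chrom: dict[str, list[str]] = {c: [] for c in chroms}
    for bi in order:
        per_chrom[chroms[int(rng.integers(params.n_chromosomes))]].extend(blocks[bi])
    # segmental pair mates must sit on different chromosomes
    for ga, gb in segmental_gene_pairs:
        ca = next(c for c in chroms if ga in per_chrom[c])
        cb = next(c for c in chroms if gb in per_chrom[c])
        if ca == cb:
            per_chrom[cb].remove(gb)
            target = chroms[(chroms.index(cb) + 1) % len(chroms)]
            per_chrom[target].append(gb)

    models = []
    all_gene_ids = []
    for chrom in chroms:
        cursor = int(rng.integers(1000, 5000))
        for gid in per_chrom[chrom]:
            plens = [len(proteins[f"{gid}.1"])]
            if gid in truth.isoforms:
                plens.append(len(proteins[f"{gid}.2"]))
            if gid in truth.members:
                sub = truth.members[gid].subfamily
                n_exons = (int(rng.integers(5, 10)) if sub == "AP2"
                           else int(rng.integers(1, 3)) if sub == "RAV"
                           else 1 if rng.random() < 0.7 else 2)
            else:
                n_exons = int(rng.integers(1, 10))
            model, cursor = _build_gene_model(rng, gid, chrom, cursor, plens, n_exons)
            models.append(model)
            all_gene_ids.append(gid)
    truth.all_gene_ids = all_gene_ids

    records = [SequenceRecord(id=pid, residues=seq)
               for pid, seq in sorted(proteins.items())]
    return records, models, truth


def gen_reference_sets(params: SimParams, profiles: dict[str, DomainProfile]
                       ) -> tuple[list[GroupAnchor], list[SequenceRecord]]:
    """Labeled group anchors (DREB/ERF variant domains) and BLAST-style query
    proteins for the similarity route."""
    rng = np.random.default_rng([params.rng_seed, 2])
    ap2 = profiles["AP2"]
    variants = group_variants(ap2, params)
    anchors = []
    for label, consensus in variants.items():
        for k in range(params.n_anchors_per_group):
            seq = _mutate(rng, consensus, params.anchor_mutation_rate)
            anchors.append(GroupAnchor(
                sequence=SequenceRecord(id=f"{label}_anchor_{k + 1}", residues=seq),
                label=label))
    queries = []
    for k in range(params.n_queries):
        flank_n = _random_residues(rng, int(rng.integers(30, 80)))
        flank_c = _random_residues(rng, int(rng.integers(30, 80)))
        dom = _mutate(rng, ap2.consensus, 0.10)
        queries.append(SequenceRecord(id=f"query_{k + 1}", residues=flank_n + dom + flank_c))
    return anchors, queries


def gen_synteny_blocks(params: SimParams, truth: SyntheticTruth,
                       models: Sequence[GeneModel]) -> list[SyntenyBlock]:
    """Intra-species blocks supporting the planted segmental pairs, plus
    cross-species blocks anchoring members to rice/sorghum/maize orthologs."""
    by_id = {m.gene_id: m for m in models}
    blocks = []
    for ga, gb, _, block_id in truth.segmental_pairs:
        a, b = by_id[ga], by_id[gb]
        blocks.append(SyntenyBlock(
            block_id=block_id, species_a="brachypodium", species_b="brachypodium",
            anchor_pairs=[(ga, gb)],
            region_a=(a.chromosome, max(0, a.start - 50000), a.end + 50000),
            region_b=(b.chromosome, max(0, b.start - 50000), b.end + 50000)))
    members = sorted(truth.members)
    counts = {"rice": 10, "sorghum": 9, "maize": 8}
    for si, (species, n) in enumerate(counts.items()):
        chosen = members[:n]
        pairs = [(g, f"{species}_g{i + 1}") for i, g in enumerate(chosen)]
        # the duplicated-pair pattern: both mates of the first segmental pair
        # anchored to the same foreign gene
        if truth.segmental_pairs:
            ga, gb, _, _ = truth.segmental_pairs[0]
            shared = f"{species}_shared"
            pairs += [(ga, shared), (gb, shared)]
        g0 = by_id[pairs[0][0]]
        blocks.append(SyntenyBlock(
            block_id=f"block_{species}", species_a="brachypodium", species_b=species,
            anchor_pairs=pairs,
            region_a=(g0.chromosome, 0, 10_000_000),
            region_b=(f"{species}_chr1", 0, 10_000_000)))
    return blocks


def minimal_truth(n_genes: int, n_members: int = 0) -> SyntheticTruth:
    """A sequence-free truth scaffold (gene ids only) for expression-only runs."""
    truth = SyntheticTruth()
    truth.all_gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    for gid in truth.all_gene_ids[:n_members]:
        truth.members[gid] = MemberTruth(gene_id=gid, protein_id=f"{gid}.1",
                                         subfamily="DREB", n_ap2=1, n_b3=0)
    truth.decoys = truth.all_gene_ids[n_members:]
    return truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def attenuated_rho(target: float, latent_sd: float, noise_sd: float,
                   n_stress: int, n_control: int) -> float:
    """Latent mixing weight giving an expected observed PCC equal to target.

    Observed log2FC = latent + fold-change noise of variance
    sd^2 (1/n_s + 1/n_c); correlation is attenuated by
    latent_var / (latent_var + fc_var), so the mixing weight is the target
    divided by that factor.
    """
    if latent_sd <= 0:
        raise ValueError("pair correlations need latent_sd > 0")
    fc_var = noise_sd ** 2 * (1.0 / n_stress + 1.0 / n_control)
    rho = target * (latent_sd ** 2 + fc_var) / latent_sd ** 2
    if abs(rho) > 1:
        raise ValueError(f"target correlation {target} unattainable at this noise level")
    return rho


def gen_expression(params: SimParams, truth: SyntheticTruth
                   ) -> tuple[ExpressionTable, ExpressionTable, SyntheticTruth]:
    """Stress and tissue expression tables with planted effects and correlations.

    Baseline log2 abundances are Normal(baseline_mean, baseline_sd); each gene
    gets a latent per-condition profile (sd ``latent_sd``); planted fold-change
    effects and pairwise-correlated latent profiles are recorded in the truth;
    values are 2**x with replicate noise, rounded to counts by default.
    """
    rng = np.random.default_rng([params.rng_seed, 3])
    genes = list(truth.all_gene_ids)
    conditions = [(s, t) for s in STRESSES for t in params.timepoints]
    n_cond = len(conditions)
    gi = {g: k for k, g in enumerate(genes)}

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, size=len(genes))
    latent = (rng.normal(0.0, params.latent_sd, size=(len(genes), n_cond))
              if params.latent_sd > 0 else np.zeros((len(genes), n_cond)))

    # planted pair correlations via latent mixing
    truth.pair_rho = []
    planted_pair_genes: set[str] = set()
    if params.latent_sd > 0:
        pair_specs: list[tuple[str, str, float]] = []
        for genes_c, _ in truth.tandem_clusters:
            pair_specs.append((genes_c[0], genes_c[1], params.pair_rho_tandem))
        for k, (ga, gb, _, _) in enumerate(truth.segmental_pairs):
            rho = params.pair_rho_segmental[k % len(params.pair_rho_segmental)]
            pair_specs.append((ga, gb, rho))
        for ga, gb, rho in pair_specs:
            mix = attenuated_rho(rho, params.latent_sd, params.noise_sd,
                                 params.n_replicates, params.n_replicates)
            za = latent[gi[ga]]
            zb_own = rng.normal(0.0, params.latent_sd, size=n_cond)
            latent[gi[gb]] = mix * za + math.sqrt(1 - mix ** 2) * zb_own
            truth.pair_rho.append((ga, gb, rho))
            planted_pair_genes |= {ga, gb}

    # planted DE effects on members outside the correlated pairs
    truth.de_effects = []
    if params.n_de_effects > 0:
        eligible = [g for g in sorted(truth.members) if g not in planted_pair_genes]
        cond_idx = {c: k for k, c in enumerate(conditions)}
        for _ in range(params.n_de_effects):
            g = eligible[int(rng.integers(len(eligible)))]
            c = conditions[int(rng.integers(n_cond))]
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effect = sign * params.de_effect
            latent[gi[g], cond_idx[c]] += effect
            truth.de_effects.append((g, c[0], c[1], effect))

    def realize(x: np.ndarray) -> np.ndarray:
        v = np.power(2.0, x)
        return np.maximum(np.round(v), 0.0) if params.integer_counts else v

    # stress table: controls + every condition, n_replicates each
    columns, data, meta_rows = [], [], []
    for r in range(params.n_replicates):
        sid = f"control_r{r + 1}"
        columns.append(sid)
        meta_rows.append((sid, "control", float("nan"), r + 1))
        data.append(realize(baseline + rng.normal(0, params.noise_sd, size=len(genes))))
    for ci, (stress, tp) in enumerate(conditions):
        for r in range(params.n_replicates):
            sid = f"{stress}_{int(tp) if tp.is_integer() else tp}h_r{r + 1}"
            columns.append(sid)
            meta_rows.append((sid, stress, tp, r + 1))
            data.append(realize(baseline + latent[:, ci]
                                + rng.normal(0, params.noise_sd, size=len(genes))))
    stress_values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    stress_meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "timepoint_hours",
                                                   "replicate"]).set_index("sample_id")
    stress_table = ExpressionTable(values=stress_values, metadata=stress_meta, units="counts")

    # tissue table: member-specific tissue shifts
    shifts = {g: rng.normal(0, params.tissue_shift_sd, size=len(TISSUES))
              for g in sorted(truth.members)}
    columns, data, meta_rows = [], [], []
    for ti, tissue in enumerate(TISSUES):
        for r in range(params.n_tissue_replicates):
            sid = f"{tissue}_r{r + 1}"
            columns.append(sid)
            meta_rows.append((sid, tissue, float("nan"), r + 1))
            x = baseline + rng.normal(0, params.noise_sd, size=len(genes))
            for g, sh in shifts.items():
                x[gi[g]] += sh[ti]
            data.append(realize(x))
    tissue_values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    tissue_meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "timepoint_hours",
                                                   "replicate"]).set_index("sample_id")
    tissue_table = ExpressionTable(values=tissue_values, metadata=tissue_meta, units="counts")

    return stress_table, tissue_table, truth


def gen_probe_table(params: SimParams, truth: SyntheticTruth) -> pd.DataFrame:
    """Probe-alignment summary: one clean probe per gene except a few unprobed
    members, plus junk probes exercising every rejection rule."""
    rng = np.random.default_rng([params.rng_seed, 4])
    member_ids = sorted(truth.members)
    unprobed = list(rng.choice([g for g in member_ids
                                if g not in {x for p in truth.pair_rho for x in p[:2]}],
                               size=min(params.n_unprobed_members, len(member_ids)),
                               replace=False))
    truth.unprobed_genes = unprobed
    rows = []
    k = 0
    for g in truth.all_gene_ids:
        if g in unprobed:
            continue
        k += 1
        rows.append((f"probe_{k:05d}", g, 0, 1, True))
    rows.append((f"probe_{k + 1:05d}", truth.all_gene_ids[0], 1, 1, True))   # mismatch
    rows.append((f"probe_{k + 2:05d}", truth.all_gene_ids[0], 0, 2, True))   # multi-hit
    rows.append((f"probe_{k + 3:05d}", truth.all_gene_ids[0], 0, 1, False))  # intronic
    rows.append((f"probe_{k + 4:05d}", None, 0, 1, False))                   # unmapped
    return pd.DataFrame(rows, columns=["probe_id", "gene_id", "mismatches",
                                       "n_genomic_hits", "in_exon"])
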