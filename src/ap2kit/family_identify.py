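"""Assemble and classify the AP2/EREBP family from a scanned proteome.

Candidates come from two routes — a calibrated profile scan (E-value gate)
and local-alignment similarity to known family queries.  Isoforms are
collapsed to one protein per gene (longest), then the published exclusion
rules are applied (splice variants, short domains, divergent domains,
no domain), surviving members are classified by domain architecture
(2x AP2 -> AP2 subfamily, AP2 + B3 -> RAV, single AP2 -> DREB/ERF, resolved
later by phylogeny), and named in chromosomal order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .domain_profile import DomainHit, DomainProfile, scan_sequence
from .duplication_synteny import local_align
from .io_formats import GeneModel, SequenceRecord, natural_chrom_key

__all__ = ["FamilyMember", "ExclusionRecord", "IdentifyParams", "Candidate",
           "collect_candidates", "collapse_isoforms", "exclusion_filter",
           "classify_architecture", "assign_names", "identify_family",
           "members_table", "exclusions_table"]

SUBFAMILIES = ("AP2", "RAV", "DREB", "ERF", "DREB_ERF_unresolved")


@dataclass
class IdentifyParams:
    evalue_max: float = 1.0          # profile-hit significance gate (E < 1.0)
    sim_min_identity: float = 0.40   # similarity route: local identity floor
    sim_min_coverage: float = 0.60   # similarity route: coverage floor
    short_fraction: float = 0.5      # best hit shorter than this fraction of L -> short_domain
    family_domain: str = "AP2"
    b3_domain: str = "B3"

    def __post_init__(self) -> None:
        if not (0 < self.sim_min_identity <= 1 and 0 < self.sim_min_coverage <= 1
                and 0 < self.short_fraction <= 1):
            raise ValueError("fractions must lie in (0, 1]")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be > 0")


@dataclass
class Candidate:
    record: SequenceRecord
    hits: list[DomainHit]
    evidence: str  # "profile" | "similarity" | "both"


@dataclass
class FamilyMember:
    protein_id: str
    gene_id: str
    gene: GeneModel
    sequence: str
    hits: list[DomainHit] = field(default_factory=list)
    subfamily: Optional[str] = None
    assigned_name: Optional[str] = None
    evidence: str = "profile"
    multi_ap2_warning: bool = False

    @property
    def chromosome(self) -> str:
        return self.gene.chromosome

    @property
    def start(self) -> int:
        return self.gene.start

    @property
    def end(self) -> int:
        return self.gene.end


@dataclass
class ExclusionRecord:
    protein_id: str
    reason: str  # splice_variant | short_domain | divergent_domain | no_domain
    detail: str = ""


def collect_candidates(proteome: Sequence[SequenceRecord],
                       profiles: Sequence[DomainProfile],
                       query_set: Sequence[SequenceRecord],
                       params: Optional[IdentifyParams] = None) -> list[Candidate]:
    """Gather family candidates via profile scan and/or query similarity.

    A protein is a candidate if it has a profile hit at E < ``evalue_max``
    (database size = number of scanned proteins) or a local alignment to any
    query at >= ``sim_min_identity`` identity over >= ``sim_min_coverage``
    coverage.  All candidates carry their scan hits regardless of route.
    """
    params = params or IdentifyParams()
    if not query_set:
        raise ValueError("query_set must be non-empty")
    for profile in profiles:
        if not profile.calibrated:
            raise ValueError(f"profile {profile.domain_name!r} is not calibrated")
    D = len(proteome)
    candidates = []
    for rec in proteome:
        hits: list[DomainHit] = []
        for profile in profiles:
            hits.extend(scan_sequence(profile, rec, database_size=D))
        by_profile = any(h.evalue < params.evalue_max for h in hits)
        by_similarity = False
        for query in query_set:
            _, metrics = local_align(rec.residues, query.residues)
            if (metrics.identity >= params.sim_min_identity
                    and metrics.coverage >= params.sim_min_coverage):
                by_similarity = True
                break
        if by_profile or by_similarity:
            evidence = ("both" if by_profile and by_similarity
                        else "profile" if by_profile else "similarity")
            candidates.append(Candidate(record=rec, hits=hits, evidence=evidence))
    return candidates


def collapse_isoforms(candidates: Sequence[Candidate],
                      gene_models: Sequence[GeneModel],
                      ) -> tuple[list[FamilyMember], list[ExclusionRecord]]:
    """Keep one protein per gene (longest isoform; ties: smallest protein id)."""
    protein_to_gene: dict[str, GeneModel] = {}
    for g in gene_models:
        for pid in g.protein_ids:
            protein_to_gene[pid] = g
    per_gene: dict[str, list[Candidate]] = {}
    for cand in candidates:
        gene = protein_to_gene.get(cand.record.id)
        if gene is None:
            raise ValueError(f"candidate protein {cand.record.id!r} maps to no gene")
        per_gene.setdefault(gene.gene_id, []).append(cand)

    members, exclusions = [], []
    gene_by_id = {g.gene_id: g for g in gene_models}
    for gene_id in sorted(per_gene):
        group = sorted(per_gene[gene_id], key=lambda c: (-len(c.record.residues), c.record.id))
        keep = group[0]
        members.append(FamilyMember(
            protein_id=keep.record.id, gene_id=gene_id, gene=gene_by_id[gene_id],
            sequence=keep.record.residues, hits=keep.hits, evidence=keep.evidence,
        ))
        for other in group[1:]:
            exclusions.append(ExclusionRecord(
                protein_id=other.record.id, reason="splice_variant",
                detail=f"isoform of {gene_id}; kept {keep.record.id}"))
    return members, exclusions


def exclusion_filter(members: Sequence[FamilyMember],
                     profiles: Sequence[DomainProfile],
                     params: Optional[IdentifyParams] = None,
                     ) -> tuple[list[FamilyMember], list[ExclusionRecord]]:
    """Apply the short/divergent/no-domain exclusion rules to collapsed members."""
    params = params or IdentifyParams()
    family_profile = next((p for p in profiles if p.domain_name == params.family_domain), None)
    if family_profile is None:
        raise ValueError(f"no profile named {params.family_domain!r}")
    L = family_profile.length

    retained, exclusions = [], []
    for member in members:
        family_hits = [h for h in member.hits if h.domain_name == params.family_domain]
        if not family_hits:
            exclusions.append(ExclusionRecord(member.protein_id, "no_domain",
                                              f"no {params.family_domain} hit"))
            continue
        best = max(family_hits, key=lambda h: h.score)
        if best.hit_length < params.short_fraction * L:
            exclusions.append(ExclusionRecord(
                member.protein_id, "short_domain",
                f"best hit covers {best.hit_length}/{L} columns"))
            continue
        if not (best.evalue < params.evalue_max):
            exclusions.append(ExclusionRecord(
                member.protein_id, "divergent_domain",
                f"best E = {best.evalue:.3g} >= {params.evalue_max}"))
            continue
        retained.append(member)
    return retained, exclusions


def classify_architecture(member: FamilyMember,
                          params: Optional[IdentifyParams] = None) -> str:
    """Assign a subfamily from the member's significant domain hits.

    Two complete (non-truncated) AP2 domains -> AP2; one AP2 plus a B3 domain
    -> RAV; a single AP2 domain -> DREB/ERF (left unresolved here, resolved by
    the phylogeny); three or more AP2 domains -> AP2 with a warning flag.
    """
    params = params or IdentifyParams()
    sig = [h for h in member.hits if h.evalue < params.evalue_max]
    ap2 = [h for h in sig if h.domain_name == params.family_domain]
    ap2_full = [h for h in ap2 if not h.truncated]
    b3 = [h for h in sig if h.domain_name == params.b3_domain]
    if not ap2:
        raise ValueError(f"{member.protein_id}: zero AP2 hits (should have been excluded)")
    if len(ap2_full) >= 3:
        member.multi_ap2_warning = True
        label = "AP2"
    elif len(ap2_full) == 2:
        label = "AP2"
    elif b3:
        label = "RAV"
    else:
        label = "DREB_ERF_unresolved"
    member.subfamily = label
    return label


def assign_names(members: Sequence[FamilyMember], species_prefix: str) -> list[FamilyMember]:
    """Name members '<prefix><SUBFAMILY>-<k>' in chromosomal order per subfamily."""
    unresolved = [m.protein_id for m in members if m.subfamily not in ("AP2", "RAV", "DREB", "ERF")]
    if unresolved:
        raise ValueError(f"unresolved subfamily for: {', '.join(sorted(unresolved))}")
    for subfamily in ("AP2", "RAV", "DREB", "ERF"):
        group = [m for m in members if m.subfamily == subfamily]
        group.sort(key=lambda m: (natural_chrom_key(m.chromosome), m.start, m.end, m.gene_id))
        for k, m in enumerate(group, start=1):
            m.assigned_name = f"{species_prefix}{subfamily}-{k}"
    return list(members)


def identify_family(proteome: Sequence[SequenceRecord],
                    gene_models: Sequence[GeneModel],
                    profiles: Sequence[DomainProfile],
                    query_set: Sequence[SequenceRecord],
                    params: Optional[IdentifyParams] = None,
                    ) -> tuple[list[FamilyMember], list[ExclusionRecord]]:
    """Run candidate collection, isoform collapse, exclusion and architecture
    classification end to end; naming waits for DREB/ERF resolution."""
    params = params or IdentifyParams()
    candidates = collect_candidates(proteome, profiles, query_set, params)
    members, exclusions = collapse_isoforms(candidates, gene_models)
    retained, more = exclusion_filter(members, profiles, params)
    exclusions.extend(more)
    for member in retained:
        classify_architecture(member, params)
    return retained, exclusions


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------

def members_table(members: Sequence[FamilyMember],
                  params: Optional[IdentifyParams] = None) -> pd.DataFrame:
    params = params or IdentifyParams()
    rows = []
    for m in members:
        sig = [h for h in m.hits if h.evalue < params.evalue_max]
        n_ap2 = sum(1 for h in sig if h.domain_name == params.family_domain and not h.truncated)
        n_b3 = sum(1 for h in sig if h.domain_name == params.b3_domain)
        best = min((h.evalue for h in m.hits), default=math.inf)
        rows.append((m.protein_id, m.gene_id, m.chromosome, m.start, m.end, m.gene.strand,
                     m.subfamily, m.assigned_name, n_ap2, n_b3, best, m.evidence))
    df = pd.DataFrame(rows, columns=["protein_id", "gene_id", "chrom", "start", "end", "strand",
                                     "subfamily", "assigned_name", "n_AP2", "n_B3",
                                     "best_evalue", "evidence"])
    return df.sort_values(["chrom", "start", "gene_id"],
                          key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s
                          ).reset_index(drop=True)


def exclusions_table(exclusions: Sequence[ExclusionRecord]) -> pd.DataFrame:
    return pd.DataFrame([(e.protein_id, e.reason, e.detail) for e in exclusions],
                        columns=["protein_id", "reason", "detail"]).sort_values(
        ["reason", "protein_id"]).reset_index(drop=True)
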