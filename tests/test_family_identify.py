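import math

import numpy as np
import pytest

from ap2kit import family_identify as fi
from ap2kit import synthetic_data as sd
from ap2kit.domain_profile import DomainHit
from ap2kit.io_formats import GeneModel, SequenceRecord, Transcript

AA = "ACDEFGHIKLMNPQRSTVWY"


def gene(gene_id, chrom="Bd1", start=0, end=1000, protein_ids=("p",)):
    return GeneModel(gene_id=gene_id, chromosome=chrom, start=start, end=end, strand="+",
                     transcripts=[Transcript(transcript_id=f"{gene_id}.t{i}",
                                             exons=[(start, end)], protein_id=pid)
                                  for i, pid in enumerate(protein_ids)])


def fake_member(protein_id="p1", gene_id="g1", hits=(), **gene_kw):
    g = gene(gene_id, protein_ids=(protein_id,), **gene_kw)
    return fi.FamilyMember(protein_id=protein_id, gene_id=gene_id, gene=g,
                           sequence="M" * 100, hits=list(hits))


def hit(domain="AP2", start=0, end=57, score=100.0, evalue=1e-20, truncated=False):
    return DomainHit(protein_id="p", domain_name=domain, start=start, end=end,
                     score=score, evalue=evalue, truncated=truncated)


class TestCollectCandidates:
    def test_routes(self, profiles, rng):
        ap2 = profiles["AP2"]
        member = SequenceRecord(id="m1", residues="".join(rng.choice(list(AA), 30))
                                + ap2.consensus + "".join(rng.choice(list(AA), 30)))
        decoy = SequenceRecord(id="d1", residues="".join(rng.choice(list(AA), 200)))
        # similar to the query but with the domain region scrambled: similarity
        # route only, no usable AP2 domain
        query = SequenceRecord(id="q1", residues="".join(rng.choice(list(AA), 60))
                               + ap2.consensus + "".join(rng.choice(list(AA), 60)))
        degenerate = SequenceRecord(
            id="s1", residues=query.residues[:60] + query.residues[60:60 + 57][::-1]
            + query.residues[117:])
        cands = fi.collect_candidates([member, decoy, degenerate],
                                      [profiles["AP2"], profiles["B3"]], [query])
        by_id = {c.record.id: c for c in cands}
        assert by_id["m1"].evidence == "profile"
        assert "d1" not in by_id
        assert by_id["s1"].evidence == "similarity"

    def test_uncalibrated_profile_rejected(self, profiles):
        from ap2kit.domain_profile import build_profile
        raw = build_profile(sd.make_seed_alignment("AP2"), "AP2")
        with pytest.raises(ValueError, match="not calibrated"):
            fi.collect_candidates([SequenceRecord(id="x", residues="MKV")], [raw],
                                  [SequenceRecord(id="q", residues="MKV")])

    def test_empty_query_set_rejected(self, profiles):
        with pytest.raises(ValueError, match="query_set"):
            fi.collect_candidates([], list(profiles.values()), [])


class TestCollapseIsoforms:
    def _candidates(self, lengths, ids=None):
        ids = ids or [f"g1.{i + 1}" for i in range(len(lengths))]
        return [fi.Candidate(record=SequenceRecord(id=pid, residues="M" * n),
                             hits=[], evidence="profile")
                for pid, n in zip(ids, lengths)]

    def test_longest_kept(self):
        cands = self._candidates([300, 250])
        members, excl = fi.collapse_isoforms(cands, [gene("g1", protein_ids=("g1.1", "g1.2"))])
        assert [m.protein_id for m in members] == ["g1.1"]
        assert [(e.protein_id, e.reason) for e in excl] == [("g1.2", "splice_variant")]

    def test_single_isoform_no_exclusion(self):
        cands = self._candidates([300], ids=["g1.1"])
        members, excl = fi.collapse_isoforms(cands, [gene("g1", protein_ids=("g1.1",))])
        assert len(members) == 1 and excl == []

    def test_tie_broken_by_protein_id(self):
        cands = self._candidates([300, 300], ids=["g1.b", "g1.a"])
        members, _ = fi.collapse_isoforms(
            cands, [gene("g1", protein_ids=("g1.a", "g1.b"))])
        assert members[0].protein_id == "g1.a"

    def test_unmapped_protein_rejected(self):
        cands = self._candidates([300], ids=["orphan.1"])
        with pytest.raises(ValueError, match="orphan.1"):
            fi.collapse_isoforms(cands, [gene("g1", protein_ids=("g1.1",))])


class TestExclusionFilter:
    def test_reasons(self, profiles):
        L = profiles["AP2"].length
        short = fake_member("p_short", "g1", hits=[hit(end=int(0.3 * L), truncated=True)])
        divergent = fake_member("p_div", "g2", hits=[hit(evalue=5.0)])
        none = fake_member("p_none", "g3", hits=[hit(domain="B3")])
        good = fake_member("p_good", "g4", hits=[hit()])
        retained, excl = fi.exclusion_filter([short, divergent, none, good],
                                             list(profiles.values()))
        assert [m.protein_id for m in retained] == ["p_good"]
        assert {e.protein_id: e.reason for e in excl} == {
            "p_short": "short_domain", "p_div": "divergent_domain", "p_none": "no_domain"}

    def test_partition_no_loss(self, small_genome, profiles):
        """retained + excluded exactly partitions the candidate set."""
        g = small_genome
        cands = fi.collect_candidates(g["records"], list(profiles.values()), g["queries"])
        members, excl1 = fi.collapse_isoforms(cands, g["models"])
        retained, excl2 = fi.exclusion_filter(members, list(profiles.values()))
        seen = ({m.protein_id for m in retained}
                | {e.protein_id for e in excl1} | {e.protein_id for e in excl2})
        assert seen == {c.record.id for c in cands}
        assert len(retained) + len(excl1) + len(excl2) == len(cands)


class TestClassifyArchitecture:
    @pytest.mark.parametrize("hits,expected", [
        ([hit(start=0, end=57), hit(start=100, end=157)], "AP2"),
        ([hit(start=0, end=57), hit(domain="B3", start=100, end=170)], "RAV"),
        ([hit(start=0, end=57)], "DREB_ERF_unresolved"),
    ])
    def test_architectures(self, hits, expected):
        member = fake_member(hits=hits)
        assert fi.classify_architecture(member) == expected
        assert member.subfamily == expected

    def test_three_domains_warns(self):
        member = fake_member(hits=[hit(start=s, end=s + 57) for s in (0, 100, 200)])
        assert fi.classify_architecture(member) == "AP2"
        assert member.multi_ap2_warning

    def test_zero_ap2_hits_rejected(self):
        member = fake_member(hits=[hit(domain="B3")])
        with pytest.raises(ValueError, match="zero AP2"):
            fi.classify_architecture(member)


class TestAssignNames:
    def _member(self, gene_id, subfamily, chrom, start, end=None):
        m = fake_member(f"{gene_id}.1", gene_id, hits=[hit()],
                        chrom=chrom, start=start, end=end or start + 10)
        m.subfamily = subfamily
        return m

    def test_chromosomal_order_with_natural_chroms(self):
        members = [self._member("gx", "DREB", "Bd2", 50),
                   self._member("gy", "DREB", "Bd1", 100),
                   self._member("gz", "DREB", "Bd10", 5)]
        fi.assign_names(members, "Bd")
        names = {m.gene_id: m.assigned_name for m in members}
        assert names == {"gy": "BdDREB-1", "gx": "BdDREB-2", "gz": "BdDREB-3"}

    def test_tie_broken_by_end_then_gene_id(self):
        members = [self._member("gb", "ERF", "Bd1", 100, 300),
                   self._member("ga", "ERF", "Bd1", 100, 200),
                   self._member("g0", "ERF", "Bd1", 100, 200)]
        fi.assign_names(members, "Bd")
        names = {m.gene_id: m.assigned_name for m in members}
        assert names == {"g0": "BdERF-1", "ga": "BdERF-2", "gb": "BdERF-3"}

    def test_single_rav(self):
        members = [self._member("g1", "RAV", "Bd2", 10)]
        fi.assign_names(members, "Bd")
        assert members[0].assigned_name == "BdRAV-1"

    def test_unresolved_rejected(self):
        members = [self._member("g1", "DREB_ERF_unresolved", "Bd1", 10)]
        with pytest.raises(ValueError, match="unresolved"):
            fi.assign_names(members, "Bd")

    def test_invariant_to_input_order(self):
        def build():
            return [self._member("ga", "DREB", "Bd1", 10),
                    self._member("gb", "DREB", "Bd2", 10),
                    self._member("gc", "ERF", "Bd1", 5)]
        m1 = fi.assign_names(build(), "Bd")
        m2 = fi.assign_names(build()[::-1], "Bd")
        assert ({m.gene_id: m.assigned_name for m in m1}
                == {m.gene_id: m.assigned_name for m in m2})


class TestEndToEndIdentification:
    def test_planted_truth_recovered(self, small_genome, profiles):
        g = small_genome
        members, exclusions = fi.identify_family(
            g["records"], g["models"], list(profiles.values()), g["queries"])
        truth = g["truth"]
        found = {m.gene_id for m in members}
        assert found == set(truth.members)  # sensitivity 1, FDR 0
        # architectures match the planted ones exactly
        for m in members:
            want = truth.members[m.gene_id]
            if want.subfamily in ("DREB", "ERF"):
                assert m.subfamily == "DREB_ERF_unresolved"
            else:
                assert m.subfamily == want.subfamily
        # splice variants all excluded as such
        iso_secondary = {pids[1] for pids in truth.isoforms.values()}
        splice_excluded = {e.protein_id for e in exclusions if e.reason == "splice_variant"}
        assert iso_secondary <= splice_excluded

    def test_members_table_shape(self, small_genome, profiles):
        g = small_genome
        members, _ = fi.identify_family(g["records"], g["models"],
                                        list(profiles.values()), g["queries"])
        df = fi.members_table(members)
        assert list(df.columns) == ["protein_id", "gene_id", "chrom", "start", "end",
                                    "strand", "subfamily", "assigned_name", "n_AP2",
                                    "n_B3", "best_evalue", "evidence"]
        assert len(df) == len(members)
        assert (df["best_evalue"] < 1.0).all()
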