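import math

import numpy as np
import pandas as pd
import pytest

from ap2kit import expression_stress as es
from ap2kit import synthetic_data as sd
from ap2kit.io_formats import ExpressionTable

from oracles import sam_q_bruteforce


def make_table(values, conditions, timepoints=None, units="counts"):
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({
        "sample_id": samples, "condition": conditions,
        "timepoint_hours": timepoints or [np.nan] * len(samples),
        "replicate": list(range(1, len(samples) + 1)),
    }).set_index("sample_id")
    return ExpressionTable(values=pd.DataFrame(values, index=genes, columns=samples),
                           metadata=meta, units=units)


class TestRpkm:
    def test_arithmetic(self):
        table = make_table(np.array([[10.0], [999_990.0]]), ["control"])
        # library size 1e6; gene length 1000 -> RPKM = 10
        rpkm = es.compute_rpkm(table, {"g0": 1000, "g1": 1000})
        assert rpkm.values.iloc[0, 0] == pytest.approx(10.0)
        assert rpkm.units == "RPKM"

    def test_zero_counts_zero_rpkm(self):
        table = make_table(np.array([[0.0], [100.0]]), ["control"])
        rpkm = es.compute_rpkm(table, {"g0": 500, "g1": 500})
        assert rpkm.values.iloc[0, 0] == 0.0

    def test_depth_scale_invariance(self, rng):
        counts = rng.integers(1, 100, size=(20, 2)).astype(float)
        lengths = {f"g{i}": int(rng.integers(200, 3000)) for i in range(20)}
        t1 = make_table(counts, ["control", "control"])
        t2 = make_table(counts * np.array([2.0, 1.0]), ["control", "control"])
        r1 = es.compute_rpkm(t1, lengths)
        r2 = es.compute_rpkm(t2, lengths)
        pd.testing.assert_frame_equal(r1.values, r2.values)

    def test_total_conservation(self, rng):
        counts = rng.integers(0, 500, size=(30, 3)).astype(float)
        lengths = {f"g{i}": int(rng.integers(200, 3000)) for i in range(30)}
        table = make_table(counts, ["control"] * 3)
        rpkm = es.compute_rpkm(table, lengths)
        lens = np.array([lengths[g] for g in table.gene_ids])
        total = counts.sum(axis=0)
        recovered = (rpkm.values.to_numpy() * lens[:, None] / 1e3 * total[None, :] / 1e6).sum(axis=0)
        assert np.allclose(recovered, total, rtol=1e-6)

    def test_zero_library_rejected(self):
        table = make_table(np.zeros((2, 1)), ["control"])
        with pytest.raises(ValueError, match="library"):
            es.compute_rpkm(table, {"g0": 100, "g1": 100})


class TestTissueProfile:
    def test_log2_with_pseudocount(self):
        table = make_table(np.array([[7.0]]), ["root"], units="RPKM")
        out = es.tissue_profile(table, ["g0"])
        assert out.loc["g0", "root"] == pytest.approx(3.0)

    def test_zero_maps_to_zero(self):
        table = make_table(np.array([[0.0]]), ["leaf"], units="RPKM")
        out = es.tissue_profile(table, ["g0"])
        assert out.loc["g0", "leaf"] == pytest.approx(0.0)

    def test_replicates_averaged_on_log_scale(self):
        # log2(4)=2 and log2(16)=4 average to 3 on the log scale
        table = make_table(np.array([[3.0, 15.0]]), ["stem", "stem"], units="RPKM")
        out = es.tissue_profile(table, ["g0"])
        assert out.loc["g0", "stem"] == pytest.approx(3.0)

    def test_absent_member_gets_na_with_warning(self):
        table = make_table(np.array([[7.0]]), ["root"], units="RPKM")
        with pytest.warns(UserWarning, match="absent"):
            out = es.tissue_profile(table, ["g0", "ghost"])
        assert math.isnan(out.loc["ghost", "root"])


class TestProbeFilter:
    def probe(self, **kw):
        base = dict(probe_id="p", gene_id="g", mismatches=0, n_genomic_hits=1, in_exon=True)
        base.update(kw)
        return es.ProbeRecord(**base)

    def test_rules(self):
        probes = [self.probe(probe_id="ok"),
                  self.probe(probe_id="mm", mismatches=1),
                  self.probe(probe_id="multi", n_genomic_hits=2),
                  self.probe(probe_id="intron", in_exon=False),
                  self.probe(probe_id="nogene", gene_id=None)]
        assert [p.probe_id for p in es.probe_filter(probes)] == ["ok"]

    def test_order_independent(self, rng):
        probes = [self.probe(probe_id=f"p{i}", mismatches=int(rng.integers(0, 2)),
                             n_genomic_hits=int(rng.integers(1, 3)))
                  for i in range(30)]
        kept1 = {p.probe_id for p in es.probe_filter(probes)}
        kept2 = {p.probe_id for p in es.probe_filter(probes[::-1])}
        assert kept1 == kept2

    def test_read_probe_table(self, tmp_path):
        path = tmp_path / "probes.tsv"
        sd_params = sd.SimParams(n_decoys=5, n_ap2_members=2, n_rav_members=1,
                                 n_single_members=10, tandem_clusters=((2, 0.85),),
                                 segmental_identities=(0.8,))
        truth = sd.minimal_truth(10, n_members=4)
        df = sd.gen_probe_table(sd_params, truth)
        df.to_csv(path, sep="\t", index=False)
        probes = es.read_probe_table(path)
        assert len(probes) == len(df)
        retained = es.probe_filter(probes)
        assert {p.gene_id for p in retained} == set(truth.all_gene_ids) - set(truth.unprobed_genes)


class TestSamDStatistic:
    def test_identical_groups_zero(self):
        assert es.sam_d_statistic([1.0, 2, 3], [1.0, 2, 3], s0=0.1) == 0.0

    def test_constant_shift_zero_variance(self):
        # within-group variance 0 -> d = c / s0
        assert es.sam_d_statistic([5.0, 5, 5], [2.0, 2, 2], s0=0.5) == pytest.approx(3 / 0.5)

    def test_4v4_hand_computed(self):
        stress = [8.1, 7.9, 8.3, 8.0]
        control = [6.9, 7.2, 7.0, 7.1]
        # independent step-by-step evaluation of the pooled-SE formula
        ms, mc = sum(stress) / 4, sum(control) / 4
        ss = sum((x - ms) ** 2 for x in stress) + sum((x - mc) ** 2 for x in control)
        s = math.sqrt((1 / 4 + 1 / 4) * ss / 6)
        expected = (ms - mc) / (s + 0.2)
        assert es.sam_d_statistic(stress, control, s0=0.2) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_zero_s0_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            es.sam_d_statistic([5.0, 5], [2.0, 2], s0=0.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            es.sam_d_statistic([5.0], [2.0, 2.1], s0=0.1)


class TestPermutationQvalues:
    def test_exact_enumeration_matches_bruteforce_3v3(self, rng):
        values = rng.normal(5, 1, size=(12, 6))
        values[:3, :3] += 2.5  # a few real effects
        is_stress = np.array([True] * 3 + [False] * 3)
        params = es.DEParams(n_permutations=100, rng_seed=1, s0=0.2)
        d, q, s0 = es.permutation_qvalues(values, is_stress, params)
        d_o, q_o = sam_q_bruteforce(values.tolist(), 3, 0.2)
        assert np.allclose(d, d_o)
        assert np.allclose(q, q_o)

    def test_largest_d_has_smallest_q(self, rng):
        values = rng.normal(0, 1, size=(40, 8))
        values[0, :4] += 5
        is_stress = np.array([True] * 4 + [False] * 4)
        d, q, _ = es.permutation_qvalues(values, is_stress, es.DEParams(rng_seed=2))
        top = int(np.argmax(np.abs(d)))
        assert q[top] == q.min()

    def test_few_permutations_warns(self, rng):
        values = rng.normal(0, 1, size=(10, 4))
        is_stress = np.array([True, True, False, False])  # C(4,2)=6 < 20
        with pytest.warns(UserWarning, match="exact enumeration"):
            es.permutation_qvalues(values, is_stress, es.DEParams(rng_seed=0))

    def test_null_data_mostly_insignificant(self, rng):
        values = rng.normal(5, 1, size=(200, 8))
        is_stress = np.array([True] * 4 + [False] * 4)
        _, q, _ = es.permutation_qvalues(values, is_stress, es.DEParams(rng_seed=3))
        assert np.mean(q <= 0.05) <= 0.05 + 0.025


class TestDeCall:
    @pytest.mark.parametrize("fc,q,expected", [
        (1.5, 0.01, "up"), (0.5, 0.001, "none"), (-2.0, 0.2, "none"),
        (-1.5, 0.04, "down"), (1.0, 0.01, "none"),
    ])
    def test_joint_gate(self, fc, q, expected):
        assert es.de_call(np.array([fc]), np.array([q]))[0] == expected

    def test_fc_only_mode(self):
        call = es.de_call(np.array([2.0]), np.array([np.nan]), es.DEParams(fc_only=True))
        assert call[0] == "up"


class TestStressDeWorkflow:
    def test_null_false_positive_calibration(self):
        """Median fraction of q <= 0.05 over all-null datasets stays near nominal."""
        fps = []
        for seed in range(5):
            params = sd.SimParams(rng_seed=300 + seed, latent_sd=0.0, n_de_effects=0,
                                  n_replicates=4)
            truth = sd.minimal_truth(150)
            table, _, _ = sd.gen_expression(params, truth)
            res = es.stress_de(table, es.DEParams(rng_seed=seed))
            fps.append(float(np.mean(res.qvalue.to_numpy() <= 0.05)))
        assert np.median(fps) <= 0.075

    def test_power_monotone_in_effect_size(self):
        recalls = []
        for effect in (0.5, 1.5, 2.5):
            params = sd.SimParams(rng_seed=7, latent_sd=0.0, n_de_effects=25,
                                  de_effect=effect)
            truth = sd.minimal_truth(120, n_members=40)
            table, _, truth = sd.gen_expression(params, truth)
            res = es.stress_de(table, es.DEParams(rng_seed=7))
            truth_set = {(g, res.condition_name(s, t)) for g, s, t, _ in truth.de_effects}
            called = {(g, c) for g in res.call.index for c in res.call.columns
                      if res.call.loc[g, c] != "none"}
            recalls.append(len(truth_set & called) / len(truth_set))
        assert recalls == sorted(recalls)
        assert recalls[-1] >= 0.8

    def test_unreplicated_contrast_falls_back_to_fc_only(self):
        params = sd.SimParams(rng_seed=9, latent_sd=0.0, n_de_effects=0, n_replicates=1,
                              timepoints=(1.0,))
        truth = sd.minimal_truth(20)
        table, _, _ = sd.gen_expression(params, truth)
        with pytest.warns(UserWarning, match="fold-change-only"):
            res = es.stress_de(table, es.DEParams(rng_seed=0))
        assert res.qvalue.isna().all().all()
        assert set(np.unique(res.call.to_numpy())) <= {"up", "down", "none"}

    def test_no_controls_rejected(self, rng):
        table = make_table(rng.integers(1, 50, size=(5, 4)).astype(float),
                           ["cold"] * 4, timepoints=[1.0] * 4)
        with pytest.raises(ValueError, match="control"):
            es.stress_de(table, es.DEParams(rng_seed=0))
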