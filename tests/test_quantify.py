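"""Bias correction, relative abundance, standardization and QC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import singpcr as s
from singpcr import quantify as q


def frame(rows, cols=("sample_id", "amplicon_id", "n_target", "n_competitor")):
    return pd.DataFrame(rows, columns=list(cols))


class TestFractions:
    def test_observed_fraction(self):
        fr = s.compute_fractions(
            frame([("S", "a", 600, 400), ("S", "b", 0, 500), ("S", "c", 0, 0)])
        )
        g = fr.set_index("amplicon_id").gamma_hs
        assert g["a"] == pytest.approx(0.6)
        assert g["b"] == 0.0
        assert np.isnan(g["c"])

    def test_qc_depth_threshold_is_strict_less_than(self):
        rows = [("S1", "lo", 100, 50), ("S2", "lo", 100, 50),
                ("S1", "ok", 100, 100), ("S2", "ok", 100, 100)]
        fr = s.qc_filter(s.compute_fractions(frame(rows)), min_mean_reads=200)
        by = fr.drop_duplicates("amplicon_id").set_index("amplicon_id")
        assert not by.loc["lo", "qc_pass"] and by.loc["lo", "qc_reason"] == "low_depth"
        assert by.loc["ok", "qc_pass"]  # mean of exactly 200 passes

    def test_qc_impurity_flag_overrides_depth(self):
        rows = [("S1", "a", 500, 500)]
        fr = s.qc_filter(s.compute_fractions(frame(rows)), purity_flags={"a": True})
        assert not fr.qc_pass.iloc[0] and fr.qc_reason.iloc[0] == "impure"

    def test_reference_fraction_is_mean_of_raw_fractions(self):
        rng = np.random.default_rng(0)
        rows = [("S", f"a{i}", int(t), int(c)) for i, (t, c) in
                enumerate(rng.integers(1, 1000, size=(30, 2)))]
        fr = s.compute_fractions(frame(rows))
        p = s.estimate_reference_fractions(fr)
        assert p["S"] == pytest.approx(fr.gamma_hs.mean())  # brute-force mean


class TestBiasCorrectionSingle:
    def test_sample_identical_to_reference_recovers_composition(self):
        assert q.correct_bias_single(0.6, 0.6, 0.35) == pytest.approx(0.35)

    def test_unbiased_reference_is_identity(self):
        assert q.correct_bias_single(0.42, 0.55, 0.55) == pytest.approx(0.42)

    def test_hand_computed_example(self):
        # wA = 0.5/0.6, wB = 0.5/0.4; odds 3 * (0.8333/1.25) = 2 -> 2/3
        assert q.correct_bias_single(0.75, 0.6, 0.5) == pytest.approx(2 / 3, abs=1e-4)

    @pytest.mark.parametrize("gref", [0.0, 1.0])
    def test_degenerate_reference_rejected(self, gref):
        with pytest.raises(ValueError):
            q.correct_bias_single(0.5, gref, 0.5)

    @given(
        g=st.floats(0.01, 0.99),
        gref=st.floats(0.05, 0.95),
        p=st.floats(0.05, 0.95),
    )
    def test_fixed_point_and_monotonicity(self, g, gref, p):
        assert q.correct_bias_single(gref, gref, p) == pytest.approx(p, abs=1e-12)
        lo = q.correct_bias_single(g * 0.99, gref, p)
        hi = q.correct_bias_single(min(g * 1.01, 1.0), gref, p)
        assert lo < hi  # strictly increasing in the observed fraction


class TestBiasCorrectionMulti:
    def test_single_reference_reduces_exactly(self):
        a = q.correct_bias_multi(0.7, [(0.6, 0.5)])
        b = q.correct_bias_single(0.7, 0.6, 0.5)
        assert a == pytest.approx(b, abs=1e-15)

    def test_identical_references_equal_single(self):
        a = q.correct_bias_multi(0.7, [(0.6, 0.5)] * 4)
        assert a == pytest.approx(q.correct_bias_single(0.7, 0.6, 0.5), abs=1e-15)

    def test_hand_computed_two_reference_example(self):
        # wA = (0.5/0.6 + 0.6/0.75)/2 = 0.81667, wB = (1.25 + 1.6)/2 = 1.425
        got = q.correct_bias_multi(0.7, [(0.6, 0.5), (0.75, 0.6)])
        assert got == pytest.approx(0.57214, abs=2e-4)

    def test_degenerate_references_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            got = q.correct_bias_multi(0.7, [(0.6, 0.5), (1.0, 0.5)])
        assert got == pytest.approx(q.correct_bias_single(0.7, 0.6, 0.5))
        with pytest.raises(ValueError):
            q.correct_bias_multi(0.7, [])

    def test_constant_bias_recovered_exactly_with_true_compositions(self):
        """With one constant beta and exact reference fractions, multi-point
        weight averaging inverts the bias exactly (not just approximately)."""
        beta = 1.7
        refs = []
        for f in (0.2, 0.5, 0.8):
            g = beta * f / (beta * f + 1 - f)
            refs.append((g, f))
        f0 = 0.35
        g0 = beta * f0 / (beta * f0 + 1 - f0)
        assert q.correct_bias_multi(g0, refs) == pytest.approx(f0, abs=1e-12)


class TestGdnaSet:
    def test_unbiased_identical_samples_unchanged(self):
        rows = [(f"S{j}", f"a{i}", 300, 300) for j in range(3) for i in range(4)]
        fr = s.correct_gdna_set(s.qc_filter(s.compute_fractions(frame(rows))))
        assert np.allclose(fr.gamma_hs_c, fr.gamma_hs)

    def test_leave_one_out_never_uses_own_sample(self):
        """With only two samples, each is corrected solely by the other."""
        rows = [("S1", "a", 600, 400), ("S2", "a", 300, 700)]
        fr = s.qc_filter(s.compute_fractions(frame(rows)), min_mean_reads=100)
        out = s.correct_gdna_set(fr).set_index("sample_id")
        p = s.estimate_reference_fractions(fr)
        exp1 = q.correct_bias_single(0.6, 0.3, p["S2"])
        exp2 = q.correct_bias_single(0.3, 0.6, p["S1"])
        assert out.loc["S1", "gamma_hs_c"] == pytest.approx(exp1)
        assert out.loc["S2", "gamma_hs_c"] == pytest.approx(exp2)

    def test_requires_two_samples(self):
        fr = s.qc_filter(s.compute_fractions(frame([("S1", "a", 10, 10)])))
        with pytest.raises(ValueError):
            s.correct_gdna_set(fr)

    def test_corrected_fractions_recover_truth(self, gdna_mixture_run):
        """Constant per-amplicon bias across samples is fully removed: the
        corrected fraction tracks the true molecule fraction and the
        across-amplicon scatter collapses."""
        specs, pairs, bias, designs, counts, truth = gdna_mixture_run
        fr = s.correct_gdna_set(s.qc_filter(s.compute_fractions(counts)))
        m = fr.merge(truth, on=["sample_id", "amplicon_id"])
        assert (m.gamma_hs_c - m.f_true).abs().mean() < 0.02
        for _, block in fr.groupby("sample_id"):
            assert q.cv(block.gamma_hs_c) < q.cv(block.gamma_hs)


@pytest.fixture(scope="module")
def gdna_reference():
    rows = []
    beta = {"a": 2.0, "b": 0.5}
    for j, f in enumerate((0.3, 0.5, 0.7), start=1):
        for amp, b in beta.items():
            g = b * f / (b * f + 1 - f)
            rows.append((f"G{j}", amp, int(round(10000 * g)), int(round(10000 * (1 - g)))))
    fr = s.qc_filter(s.compute_fractions(frame(rows)))
    return fr, beta


class TestCdnaSet:

    def test_planted_bias_removed(self, gdna_reference):
        gfr, beta = gdna_reference
        f0 = 0.4
        rows = []
        for amp, b in beta.items():
            g = b * f0 / (b * f0 + 1 - f0)
            rows.append(("F1", amp, int(round(20000 * g)), int(round(20000 * (1 - g)))))
        cfr = s.qc_filter(s.compute_fractions(frame(rows)))
        # true compositions for the references: self-estimation over two
        # amplicons with reciprocal biases averages out by construction
        out = s.correct_cdna_set(cfr, gfr)
        assert np.allclose(out.gamma_hs_c, f0, atol=0.01)

    def test_amplicon_without_reference_dropped_with_reason(self, gdna_reference):
        gfr, _ = gdna_reference
        cfr = s.qc_filter(s.compute_fractions(frame([("F1", "zz", 100, 100)])))
        out = s.correct_cdna_set(cfr, gfr)
        assert np.isnan(out.gamma_hs_c.iloc[0])
        assert out.correction_reason.iloc[0] == "no_reference"

    def test_unbiased_references_leave_fractions_unchanged(self):
        rows = [(f"G{j}", "a", 500, 500) for j in range(1, 4)]
        gfr = s.qc_filter(s.compute_fractions(frame(rows)))
        cfr = s.qc_filter(s.compute_fractions(frame([("F1", "a", 420, 580)])))
        out = s.correct_cdna_set(cfr, gfr)
        assert out.gamma_hs_c.iloc[0] == pytest.approx(0.42)


class TestRelativeAbundance:
    def test_copy_aware_conversion(self):
        cm = s.CopyModel(copy_class={"x": "x_linked"}, competitor_sex="male")
        df = pd.DataFrame(
            {
                "sample_id": ["S"] * 3,
                "amplicon_id": ["a", "x", "b"],
                "gamma_hs_c": [0.5, 0.5, 1.0],
            }
        )
        out = s.to_relative_abundance(df, cm).set_index("amplicon_id")
        assert out.loc["a", "ra_hp"] == pytest.approx(1.0)
        assert out.loc["x", "ra_hp"] == pytest.approx(0.5)
        assert np.isnan(out.loc["b", "ra_hp"])  # no competitor reads

    def test_standardize_scales_to_unit_mean(self):
        df = pd.DataFrame(
            {
                "sample_id": ["S", "S"],
                "amplicon_id": ["a", "b"],
                "ra_hp": [4.0, 1.0],
            }
        )
        out = s.standardize(df, standard=["a", "b"])
        assert list(out.stdqt) == pytest.approx([1.6, 0.4])
        assert out.groupby("sample_id").stdqt.mean().iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_standardize_autosomal_requires_copy_model(self):
        df = pd.DataFrame({"sample_id": ["S"], "amplicon_id": ["a"], "ra_hp": [1.0]})
        with pytest.raises(ValueError):
            s.standardize(df, standard="autosomal")
        with pytest.raises(ValueError):
            s.standardize(df, standard=[])

    def test_average_stdqt_skips_missing(self):
        df = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3"],
                "amplicon_id": ["a"] * 3,
                "stdqt": [1.0, np.nan, 3.0],
            }
        )
        assert s.average_stdqt(df)["a"] == pytest.approx(2.0)


class TestSummaryStats:
    def test_rmsd(self):
        assert q.rmsd([1, 2, 3], [1, 2, 3]) == 0.0
        assert q.rmsd([1.1, 0.9], [1.0, 1.0]) == pytest.approx(0.1)

    def test_cv_two_fold_landmark(self):
        # {1,2}: sd/mean = (1/sqrt(2))/1.5 = 0.4714, the two-fold marker
        assert q.cv([1.0, 2.0]) == pytest.approx(0.4714, abs=1e-4)
        assert q.cv([5.0, 5.0, 5.0]) == 0.0

    @given(st.lists(st.floats(0.1, 100), min_size=2, max_size=20))
    def test_stats_match_brute_force(self, values):
        v = np.array(values)
        assert q.cv(values) == pytest.approx(np.std(v, ddof=1) / v.mean(), rel=1e-12)
        assert q.rmsd(values, np.ones_like(v)) == pytest.approx(
            np.sqrt(((v - 1.0) ** 2).mean()), rel=1e-12
        )

    def test_measurement_window(self):
        win = q.measurement_window([20.0, 1.0, 0.05001, 0.01])
        assert win["fold"] == pytest.approx(20.0 / 0.05001)
        assert win["n"] == 3


class TestMultilocus:
    def test_two_fold_loci_give_landmark_cv(self):
        df = pd.DataFrame(
            {
                "sample_id": ["S", "S", "S", "S"],
                "amplicon_id": ["a1", "a2", "b1", "b2"],
                "stdqt": [1.0, 2.0, 3.0, 3.0],
            }
        )
        gene_map = {"a1": "gA", "a2": "gA", "b1": "gB", "b2": "gB"}
        per_gs, per_gene = s.multilocus_summary(df, gene_map)
        cvs = per_gs.set_index("gene_id").locus_cv
        assert cvs["gA"] == pytest.approx(0.4714, abs=1e-4)
        assert cvs["gB"] == 0.0
        ratios = per_gene.set_index("gene_id").locus_ratio
        assert ratios["gA"] == pytest.approx(0.5)

    def test_rt_efficiency_ratio_recovered(self, small_panel):
        """A 2:1 reverse-transcription efficiency between the loci of a gene
        appears as a 2:1 StdQt ratio."""
        _, pairs = small_panel
        amps = [p.amplicon_id for p in pairs]
        gene_map = {p.amplicon_id: p.gene_id for p in pairs}
        expr = {a: 1000.0 for a in amps}
        rt = {a: (2.0 if a.endswith(("0", "2", "4", "6", "8")) else 1.0) for a in amps}
        bias = s.BiasModel.constant(amps, mean_depth=30000, depth_sd_log=0.05)
        designs = s.make_cdna_designs(expr, [s.spike_mass_for_mean_ra(expr, 2.0)])
        counts, _ = s.simulate_cdna_counts(pairs, designs, bias, rt_efficiency=rt, seed=31)
        fr = s.compute_fractions(counts)
        fr["gamma_hs_c"] = fr["gamma_hs"]  # no bias planted
        cm = s.CopyModel.from_pairs(pairs)
        quant = s.standardize(s.to_relative_abundance(fr, cm), "all")
        _, per_gene = s.multilocus_summary(quant, gene_map)
        two_locus = per_gene[per_gene.n_loci == 2]
        assert not two_locus.empty
        assert np.allclose(two_locus.locus_ratio, 2.0, rtol=0.1)


class TestStrengthBias:
    def test_planted_directional_bias_detected(self, gdna_mixture_run):
        """S-class amplicons simulated with stronger enrichment show a
        significant rank-sum shift against W-class amplicons."""
        specs, pairs, *_ = gdna_mixture_run
        classes = {sp.amplicon_id: sp.strength_class for sp in specs}
        amps = [p.amplicon_id for p in pairs]
        bias = s.BiasModel.lognormal(
            amps, sd_log=0.3, mean_depth=5000,
            strength_classes=classes, strength_log_shift=0.6, seed=41,
        )
        designs = s.make_gdna_designs((0.5,))
        counts, _ = s.simulate_gdna_counts(pairs, designs, bias, seed=42)
        fr = s.compute_fractions(counts).set_index("amplicon_id")
        stat, p = s.strength_bias_test(fr.gamma_hs, pd.Series(classes))
        assert p < 0.05
        med = fr.gamma_hs.groupby(pd.Series(classes)).median()
        assert med["S"] > med["W"]

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        g = pd.Series(rng.random(40), index=[f"a{i}" for i in range(40)])
        cls = pd.Series(["W", "S"] * 20, index=g.index)
        swapped = cls.map({"W": "S", "S": "W"})
        u1, p1 = s.strength_bias_test(g, cls)
        u2, p2 = s.strength_bias_test(g, swapped)
        assert p1 == pytest.approx(p2)
        assert u1 + u2 == pytest.approx(20 * 20)

    def test_null_calibration(self):
        """Under identical W/S distributions the p-value is ~uniform."""
        rng = np.random.default_rng(2)
        ps = []
        idx = [f"a{i}" for i in range(60)]
        cls = pd.Series(["W", "S"] * 30, index=idx)
        for _ in range(200):
            g = pd.Series(rng.random(60), index=idx)
            ps.append(s.strength_bias_test(g, cls)[1])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.0 <= frac < 0.12

    def test_empty_class_rejected(self):
        g = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            s.strength_bias_test(g, pd.Series({"a": "W", "b": "W"}))


class TestCopiesAndCrossPlatform:
    def test_spikein_copy_arithmetic(self):
        assert s.spikein_copy_estimate(1.0) == pytest.approx(303.03, abs=0.01)
        assert s.spikein_copy_estimate(1.0, ra=0.05) == pytest.approx(15.15, abs=0.01)
        assert s.spikein_copy_estimate(0.0) == 0.0

    def test_cross_platform_bias_transfer(self):
        idx = ["g1", "g2", "g3"]
        ref_a = pd.Series([1.0, 2.0, 4.0], index=idx)
        other_a = pd.Series([2.0, 2.0, 1.0], index=idx)  # planted biases 2, 1, 0.25
        truth_b = pd.Series([3.0, 1.0, 0.5], index=idx)
        other_b = truth_b * (other_a / ref_a)
        got = s.cross_platform_bias_correct(ref_a, other_a, other_b)
        assert np.allclose(got, truth_b)
        # identical platforms: correction is the identity
        same = s.cross_platform_bias_correct(ref_a, ref_a, truth_b)
        assert np.allclose(same, truth_b)
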