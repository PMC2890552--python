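import numpy as np
import pandas as pd
import pytest

from retqtl import normalize
from retqtl import synthetic_data as sim
from retqtl.io_formats import Orientation, Spot, TwoColorChip

from conftest import make_chip, matrix_from_values


class TestLogRatios:
    def test_equal_channels_give_zero_m(self):
        chip = make_chip(spots=[Spot("p1", "g1", 100.0, 100.0)])
        ma = normalize.compute_log_ratios(chip)
        assert ma.loc["p1", "M"] == pytest.approx(0.0)
        assert ma.loc["p1", "A"] == pytest.approx(np.log2(100), abs=1e-9)

    def test_doubling_gives_m_one(self):
        chip = make_chip(spots=[Spot("p1", "g1", 100.0, 200.0)])
        assert normalize.compute_log_ratios(chip).loc["p1", "M"] == pytest.approx(1.0)

    def test_zero_or_flagged_is_missing_not_error(self):
        chip = make_chip(spots=[Spot("p1", "g1", 0.0, 50.0),
                                Spot("p2", "g2", 10.0, 10.0, flagged=True)])
        ma = normalize.compute_log_ratios(chip)
        assert ma["M"].isna().all()


class TestLowess:
    def test_constant_signal_removed(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(6, 14, 200)
        m = np.full(200, 0.7)
        assert np.abs(normalize.lowess_correct(m, a)).max() < 1e-6

    def test_noiseless_linear_trend_removed(self):
        # oracle: a local linear fit reproduces an exact line, so the
        # residual must vanish
        rng = np.random.default_rng(1)
        a = rng.uniform(6, 14, 300)
        m = 0.5 * a
        assert np.abs(normalize.lowess_correct(m, a)).max() < 1e-3

    def test_banana_dye_bias_flattened(self):
        # nonlinear trend: residual association of M with A-bin means must
        # drop from strong to negligible
        rng = np.random.default_rng(2)
        a = rng.uniform(6, 14, 2000)
        strain = rng.choice([0.0, 1.0], size=2000, p=[0.9, 0.1])
        m = np.sin(a / 2.0) + strain
        corrected = normalize.lowess_correct(m, a)

        def bin_mean_corr(values):
            bins = np.digitize(a, np.linspace(6, 14, 8))
            mean_by_bin = {b: values[bins == b].mean() for b in np.unique(bins)}
            return np.corrcoef(values, [mean_by_bin[b] for b in bins])[0, 1]

        assert abs(bin_mean_corr(m)) > 0.8
        assert abs(bin_mean_corr(corrected)) < 0.1

    def test_missing_values_pass_through(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(6, 14, 50)
        m = rng.normal(0, 1, 50)
        m[::5] = np.nan
        out = normalize.lowess_correct(m, a)
        assert np.isnan(out[::5]).all()
        assert not np.isnan(np.delete(out, slice(None, None, 5))).any()

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="span"):
            normalize.lowess_correct(np.ones(5), np.arange(5.0))


class TestRescale:
    def test_known_sds_rescaled_to_median(self, tiny_design):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 1, 100)
        base = (base - base.mean()) / base.std(ddof=1)
        cols = {}
        sds = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0, 1.0, 2.0]
        for chip, sd in zip(tiny_design.chip_ids, sds):
            cols[chip] = base * sd
        mat = matrix_from_values(pd.DataFrame(cols), tiny_design, stage="lowess")
        out = normalize.rescale_chips(mat)
        got = out.values.std(axis=0, ddof=1)
        assert np.allclose(got, np.median(sds), atol=1e-12)

    def test_equal_sds_identity(self, tiny_design):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 60)
        cols = {chip: base.copy() for chip in tiny_design.chip_ids}
        mat = matrix_from_values(pd.DataFrame(cols), tiny_design, stage="lowess")
        out = normalize.rescale_chips(mat)
        pd.testing.assert_frame_equal(out.values, mat.values)

    def test_random_matrix_postcondition(self, tiny_design):
        rng = np.random.default_rng(6)
        vals = pd.DataFrame(rng.normal(0, 1, (80, 8)),
                            columns=tiny_design.chip_ids)
        vals.iloc[rng.random((80, 8)) < 0.1] = np.nan
        mat = matrix_from_values(vals, tiny_design, stage="lowess")
        target = np.median(vals.std(axis=0, ddof=1))
        out = normalize.rescale_chips(mat)
        assert np.allclose(out.values.std(axis=0, ddof=1), target, atol=1e-12)

    def test_zero_sd_chip_is_error(self, tiny_design):
        vals = pd.DataFrame(np.ones((10, 8)), columns=tiny_design.chip_ids)
        vals.iloc[:, 1:] = np.random.default_rng(0).normal(size=(10, 7))
        mat = matrix_from_values(vals, tiny_design, stage="lowess")
        with pytest.raises(ValueError, match="degenerate"):
            normalize.rescale_chips(mat)


class TestDyeEffectAndOrientation:
    def _mat(self, tiny_design, orient1_value, orient2_value, n_genes=5):
        cols = {}
        for chip in tiny_design.chip_ids:
            o = tiny_design.orientation_of(chip)
            v = orient1_value if o is Orientation.C_ON_CY5 else orient2_value
            cols[chip] = np.full(n_genes, v)
        return matrix_from_values(pd.DataFrame(cols), tiny_design)

    def test_pure_dye_bias(self, tiny_design):
        mat = self._mat(tiny_design, 0.5, 0.5)
        d = normalize.estimate_dye_effect(mat)
        assert np.allclose(d, 0.5)

    def test_strain_plus_dye_construction(self, tiny_design):
        # strain effect 0.3 and dye effect 0.5: orientations read 0.8 / 0.2
        mat = self._mat(tiny_design, 0.8, 0.2)
        d = normalize.estimate_dye_effect(mat)
        assert np.allclose(d, 0.5)
        corrected = normalize.remove_dye_and_orient(mat, d)
        assert np.allclose(corrected.values, 0.3)
        assert corrected.stage == "dye_corrected_oriented"

    def test_zero_dye_keeps_orient1_flips_orient2(self, tiny_design):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(0, 1, (20, 8)),
                            columns=tiny_design.chip_ids)
        mat = matrix_from_values(vals, tiny_design)
        zero = pd.Series(0.0, index=vals.index)
        out = normalize.remove_dye_and_orient(mat, zero)
        for chip in tiny_design.chip_ids:
            if tiny_design.orientation_of(chip) is Orientation.C_ON_CY5:
                assert np.allclose(out.values[chip], vals[chip])
            else:
                assert np.allclose(out.values[chip], -vals[chip])

    def test_masked_mean_matches_bruteforce(self, tiny_design):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(rng.normal(0, 1, (50, 8)),
                            columns=tiny_design.chip_ids)
        vals.iloc[rng.random((50, 8)) < 0.25] = np.nan
        mat = matrix_from_values(vals, tiny_design)
        d = normalize.estimate_dye_effect(mat)
        c1 = [c for c in tiny_design.chip_ids
              if tiny_design.orientation_of(c) is Orientation.C_ON_CY5]
        c2 = [c for c in tiny_design.chip_ids
              if tiny_design.orientation_of(c) is Orientation.B6A_ON_CY5]
        for gene in vals.index:
            m1 = np.nanmean(vals.loc[gene, c1].to_numpy(float))
            m2 = np.nanmean(vals.loc[gene, c2].to_numpy(float))
            expect = (m1 + m2) / 2
            if np.isnan(expect):
                assert np.isnan(d[gene])
            else:
                assert d[gene] == pytest.approx(expect)

    def test_gene_all_missing_in_one_orientation_gives_missing_d(self, tiny_design):
        vals = pd.DataFrame(np.ones((3, 8)), columns=tiny_design.chip_ids)
        c1 = [c for c in tiny_design.chip_ids
              if tiny_design.orientation_of(c) is Orientation.C_ON_CY5]
        vals.loc[vals.index[0], c1] = np.nan
        mat = matrix_from_values(vals, tiny_design)
        d = normalize.estimate_dye_effect(mat)
        assert np.isnan(d.iloc[0]) and not np.isnan(d.iloc[1])


class TestMissingFilter:
    def _matrix_with_missing(self, tiny_design, miss1, miss2):
        # tiny design has 4 chips per orientation: generalized threshold 2
        vals = pd.DataFrame(np.ones((1, 8)), columns=tiny_design.chip_ids)
        c1 = [c for c in tiny_design.chip_ids
              if tiny_design.orientation_of(c) is Orientation.C_ON_CY5]
        c2 = [c for c in tiny_design.chip_ids
              if tiny_design.orientation_of(c) is Orientation.B6A_ON_CY5]
        vals.loc[vals.index[0], c1[:miss1]] = np.nan
        vals.loc[vals.index[0], c2[:miss2]] = np.nan
        return matrix_from_values(vals, tiny_design,
                                  stage="dye_corrected_oriented")

    def test_canonical_rule_boundary_four_of_eight(self):
        chips, design, _ = sim.gen_two_color_experiment(
            n_genes=10, effect_frac=0.5, sigma=0.0, missing_rate=0.0,
            dye_bias={"id": "none"}, gene_dye_sd=0.0, chip_scale_sd=0.0, seed=0)
        mat, _ = normalize.normalize_pipeline(chips, design, apply_lowess=False)
        # 16 chips, 8 per orientation: threshold is 4 missing
        c1 = mat.chips_with(orientation=Orientation.C_ON_CY5)
        vals = mat.values.copy()
        vals.loc[vals.index[0], c1[:4]] = np.nan   # removed (4 of 8)
        vals.loc[vals.index[1], c1[:3]] = np.nan   # kept (3 and 0)
        mat2 = normalize.RatioMatrix(vals, mat.design,
                                     stage="dye_corrected_oriented", level="gene")
        filtered, n_removed = normalize.filter_missing(mat2)
        assert n_removed == 1
        assert vals.index[0] not in filtered.values.index
        assert vals.index[1] in filtered.values.index

    def test_kept_when_below_threshold_in_both(self, tiny_design):
        mat = self._matrix_with_missing(tiny_design, 1, 1)
        _, n_removed = normalize.filter_missing(mat)
        assert n_removed == 0

    def test_complete_matrix_removes_nothing(self, tiny_design):
        mat = self._matrix_with_missing(tiny_design, 0, 0)
        filtered, n_removed = normalize.filter_missing(mat)
        assert n_removed == 0 and filtered.values.shape[0] == 1


class TestEndToEnd:
    def test_noiseless_limit_recovers_effects_exactly(self):
        chips, design, truth = sim.gen_two_color_experiment(
            n_genes=100, sigma=0.0, missing_rate=0.0, dye_bias={"id": "none"},
            gene_dye_sd=0.0, chip_scale_sd=0.0, effect_frac=0.2, seed=2)
        mat, _ = normalize.normalize_pipeline(chips, design, apply_lowess=False)
        s = pd.Series(truth.strain_effect_4m)
        err = (mat.values.mean(axis=1) - s[mat.values.index]).abs().max()
        assert err < 1e-8

    def test_dye_effect_recovery_and_bias(self, normalized_default):
        matrix, audit, truth = normalized_default
        d_hat = audit["dye_effect"]
        d_true = pd.Series(truth.gene_dye_effect)
        common = d_hat.index.intersection(d_true.index)
        r = np.corrcoef(d_hat[common], d_true[common])[0, 1]
        assert r > 0.9
        s_true = pd.Series(truth.strain_effect_4m)
        est = matrix.values.mean(axis=1)
        bias = float((est - s_true[est.index]).mean())
        assert abs(bias) < 0.02

    def test_orientation_relabel_invariance(self):
        chips, design, _ = sim.gen_two_color_experiment(n_genes=80, seed=9)
        mat_a, _ = normalize.normalize_pipeline(chips, design)
        # relabel: swap which orientation is listed first in the design sheet
        entries = design.entries.iloc[::-1]
        design_b = normalize.ChipDesign(entries)
        mat_b, _ = normalize.normalize_pipeline(chips, design_b)
        pd.testing.assert_frame_equal(
            mat_a.values.sort_index(axis=1), mat_b.values.sort_index(axis=1),
            atol=1e-10, rtol=0)

    def test_mask_is_monotone_across_stages(self):
        chips, design, _ = sim.gen_two_color_experiment(
            n_genes=100, missing_rate=0.1, seed=10)
        probe_mat = normalize.build_ratio_matrix(chips, design)
        gene_mat = normalize.collapse_probes_to_genes(probe_mat)
        n0 = gene_mat.n_non_missing
        rescaled = normalize.rescale_chips(gene_mat)
        assert rescaled.n_non_missing <= n0
        d = normalize.estimate_dye_effect(rescaled)
        oriented = normalize.remove_dye_and_orient(rescaled, d)
        assert oriented.n_non_missing <= rescaled.n_non_missing
        filtered, _ = normalize.filter_missing(oriented)
        assert filtered.n_non_missing <= oriented.n_non_missing

    def test_probe_collapse_uses_median(self, tiny_design):
        chips, design, _ = sim.gen_two_color_experiment(
            n_genes=10, probes_per_gene=3, sigma=0.1, seed=12)
        probe_mat = normalize.build_ratio_matrix(chips, design)
        gene_mat = normalize.collapse_probes_to_genes(probe_mat)
        gene_of = probe_mat.values.attrs["gene_of"]
        g = gene_mat.values.index[0]
        probes = [p for p, gg in gene_of.items() if gg == g]
        chip = probe_mat.values.columns[0]
        expect = np.nanmedian(probe_mat.values.loc[probes, chip])
        assert gene_mat.values.loc[g, chip] == pytest.approx(expect)
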