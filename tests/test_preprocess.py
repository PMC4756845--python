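"""Correction pipeline: model-based and baseline corrections, dye bias,
quantile normalisation, composition."""

import numpy as np
import pandas as pd
import pytest

from enmix import (
    PipelineConfig,
    baseline_correct,
    compute_beta,
    dye_bias_correct,
    enmix_correct,
    quantile_normalize,
    run_pipeline,
    split_six_parts,
)
from enmix.simulate import SimulationSpec, simulate_array


@pytest.fixture(scope="module")
def corrected_oob(small_array_module):
    x, manifest, truth = small_array_module
    corrected, diag = enmix_correct(x, manifest, "oob")
    return corrected, diag


@pytest.fixture(scope="module")
def small_array_module():
    spec = SimulationSpec(seed=101, n_probes=8000, n_samples=3, with_bead_counts=True)
    x, truth = simulate_array(spec)
    return x, x.manifest, truth


class TestEnmixCorrect:
    def test_moves_intensities_toward_true_signal_in_every_part(
            self, small_array_module, corrected_oob):
        x, manifest, truth = small_array_module
        corrected, _ = corrected_oob
        raw_parts = split_six_parts(x, manifest).parts
        cor_parts = split_six_parts(corrected, manifest).parts
        for name in raw_parts:
            truth_x = truth.X_M if name.endswith("-M") else truth.X_U
            tx = truth_x.loc[raw_parts[name].index].to_numpy()
            err_raw = np.abs(raw_parts[name].to_numpy() - tx).mean()
            err_cor = np.abs(cor_parts[name].to_numpy() - tx).mean()
            assert err_cor < err_raw, name

    def test_strictly_positive_and_rank_preserving(self, small_array_module,
                                                   corrected_oob):
        x, manifest, _ = small_array_module
        corrected, _ = corrected_oob
        assert (corrected.M.to_numpy() > 0).all()
        assert (corrected.U.to_numpy() > 0).all()
        raw_parts = split_six_parts(x, manifest).parts
        cor_parts = split_six_parts(corrected, manifest).parts
        for name in raw_parts:
            for col in raw_parts[name].columns:
                order_raw = np.argsort(raw_parts[name][col].to_numpy(), kind="stable")
                order_cor = np.argsort(cor_parts[name][col].to_numpy(), kind="stable")
                assert (order_raw == order_cor).all()

    def test_est_route_runs_and_reports_class_backgrounds(self):
        # the est route pools M+U per probe class x channel and needs
        # >= 5000 pooled values, so the array must be larger
        spec = SimulationSpec(seed=31, n_probes=18_000, n_samples=1)
        one, _ = simulate_array(spec)
        manifest = one.manifest
        corrected, diag = enmix_correct(one, manifest, "est")
        d = diag["samples"][one.samples[0]]
        assert d["II-green-M"]["background"]["probe_class"] == "typeII"
        assert d["I-green-M"]["background"]["probe_class"] == "typeI"
        assert (corrected.M.to_numpy() > 0).all()

    def test_oob_without_oob_data_is_error(self, small_array_module):
        x, manifest, _ = small_array_module
        bare = x.copy()
        bare.oob_M = bare.oob_U = None
        with pytest.raises(ValueError, match="oob"):
            enmix_correct(bare, manifest, "oob")

    def test_degenerate_part_error_carries_part_label(self, small_array_module):
        x, manifest, _ = small_array_module
        broken = x.copy()
        i_red = manifest.ids_of("I", "red")
        broken.M.loc[i_red] = 1234.0
        with pytest.raises(ValueError, match="I-red-M"):
            enmix_correct(broken, manifest, "neg")


class TestBaselineCorrect:
    def test_q5_subtracts_fifth_percentile(self, small_array_module):
        x, manifest, _ = small_array_module
        corrected, diag = baseline_correct(x, manifest, "q5")
        s = x.samples[0]
        ctrl = x.negative_controls(s, "red")
        expected = float(np.percentile(ctrl, 5))  # linear interpolation convention
        assert diag["offsets"][s]["red"] == pytest.approx(expected)
        i_red = manifest.ids_of("I", "red")
        np.testing.assert_allclose(
            corrected.M.loc[i_red, s],
            np.maximum(x.M.loc[i_red, s] - expected, 0.0))

    def test_q5_percentile_brute_force_on_uniform_grid(self):
        ctrl = np.arange(100.0, 201.0)  # 101 equally spaced values
        assert np.percentile(ctrl, 5) == pytest.approx(105.0)

    def test_lumi1_floors_below_median_to_zero(self, small_array_module):
        x, manifest, _ = small_array_module
        corrected, diag = baseline_correct(x, manifest, "lumi1")
        s = x.samples[0]
        med = float(np.median(x.negative_controls(s, "red")))
        assert diag["offsets"][s]["red"] == pytest.approx(med)
        assert diag["truncated_fraction"][s] > 0
        assert (corrected.M.to_numpy() >= 0).all()

    def test_lumi2_uses_methylated_mode(self, small_array_module):
        x, manifest, _ = small_array_module
        _, diag = baseline_correct(x, manifest, "lumi2")
        assert all(v["red"] > 0 for v in diag["offsets"].values())

    def test_subtraction_truncates_where_model_correction_does_not(
            self, small_array_module, corrected_oob):
        x, manifest, _ = small_array_module
        _, qdiag = baseline_correct(x, manifest, "q5")
        assert all(v > 0 for v in qdiag["truncated_fraction"].values())
        _, ediag = corrected_oob
        assert ediag["truncated_fraction"] == 0.0

    def test_missing_controls_is_error(self, small_array_module):
        x, manifest, _ = small_array_module
        bare = x.copy()
        bare.controls = None
        with pytest.raises(ValueError):
            baseline_correct(bare, manifest, "q5")


class TestDyeBias:
    def test_balanced_channels_identity(self, small_array_module):
        x, manifest, _ = small_array_module
        balanced = x.copy()
        sel_r = balanced.controls["control_type"] == "nonpolymorphic_red"
        sel_g = balanced.controls["control_type"] == "nonpolymorphic_green"
        balanced.controls.loc[sel_r, "red"] = 5000.0
        balanced.controls.loc[sel_g, "green"] = 5000.0
        out = dye_bias_correct(balanced, manifest)
        np.testing.assert_allclose(out.M.to_numpy(), balanced.M.to_numpy())

    def test_two_to_one_imbalance_scaling(self, small_array_module):
        x, manifest, _ = small_array_module
        skew = x.copy()
        sel_r = skew.controls["control_type"] == "nonpolymorphic_red"
        sel_g = skew.controls["control_type"] == "nonpolymorphic_green"
        skew.controls.loc[sel_r, "red"] = 8000.0
        skew.controls.loc[sel_g, "green"] = 4000.0
        out = dye_bias_correct(skew, manifest)
        i_red = manifest.ids_of("I", "red")
        s = x.samples[0]
        np.testing.assert_allclose(out.M.loc[i_red, s], 0.75 * skew.M.loc[i_red, s])
        i_green = manifest.ids_of("I", "green")
        np.testing.assert_allclose(out.M.loc[i_green, s], 1.5 * skew.M.loc[i_green, s])
        # control channel means agree after correction
        from scipy.stats import trim_mean
        r = trim_mean(out.nonpolymorphic_controls(s, "red"), 0.2)
        g = trim_mean(out.nonpolymorphic_controls(s, "green"), 0.2)
        assert r == pytest.approx(g, rel=1e-9)

    def test_reduces_type_two_beta_bias_under_simulated_imbalance(self):
        spec = SimulationSpec(seed=55, n_probes=6000, n_samples=2,
                              dye_imbalance=1.4)
        x, truth = simulate_array(spec)
        manifest = x.manifest
        out = dye_bias_correct(x, manifest)
        type2 = manifest.ids_of("II")
        tb = truth.true_beta.loc[type2].to_numpy()
        # true betas are dye-contaminated too (the truth carries the dye
        # factor); compare against the dye-free methylation fraction
        xm = truth.X_M.loc[type2].to_numpy()
        xu = truth.X_U.loc[type2].to_numpy() / 1.4  # U of type II is red
        clean = xm / (xm + xu + 100.0)
        bias = lambda M, U: np.abs(
            compute_beta(M.loc[type2].to_numpy(), U.loc[type2].to_numpy()) - clean
        ).mean()
        assert bias(out.M, out.U) < bias(x.M, x.U)


class TestQuantileNormalize:
    def test_per_stratum_sorted_vectors_identical(self, small_array_module):
        x, manifest, _ = small_array_module
        out = quantile_normalize(x, manifest)
        is_one = (manifest.table["design_type"] == "I").to_numpy()
        for target in (out.M, out.U):
            for mask in (is_one, ~is_one):
                block = target.iloc[mask].to_numpy()
                ref = np.sort(block[:, 0])
                for j in range(1, block.shape[1]):
                    np.testing.assert_allclose(np.sort(block[:, j]), ref)

    def test_permuted_identical_columns_are_fixed_point(self):
        import enmix.array_data as ad

        mf = ad.ProbeManifest(pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(6)],
            "design_type": ["II"] * 6, "channel": [""] * 6}))
        vals = np.array([5.0, 1.0, 3.0, 2.0, 4.0, 6.0])
        M = pd.DataFrame({"a": vals, "b": vals[::-1]}, index=mf.probe_ids)
        x = ad.IntensitySet(M=M, U=M * 2)
        out = quantile_normalize(x, mf)
        np.testing.assert_allclose(out.M["a"], vals)
        np.testing.assert_allclose(out.M["b"], vals[::-1])

    def test_column_means_equal_within_stratum(self, small_array_module):
        x, manifest, _ = small_array_module
        out = quantile_normalize(x, manifest)
        is_one = (manifest.table["design_type"] == "I").to_numpy()
        means = out.M.iloc[is_one].mean(axis=0).to_numpy()
        assert np.ptp(means) < 1e-8 * means.mean()

    def test_single_sample_warns_and_returns_identity(self, small_array_module):
        x, manifest, _ = small_array_module
        one = x.copy()
        one.M = one.M.iloc[:, :1]
        one.U = one.U.iloc[:, :1]
        with pytest.warns(UserWarning):
            out = quantile_normalize(one, manifest)
        np.testing.assert_allclose(out.M.to_numpy(), one.M.to_numpy())


class TestPipeline:
    def test_step_order_enforced(self):
        with pytest.raises(ValueError):
            PipelineConfig(steps=("quantile", "enmix"))
        with pytest.raises(ValueError):
            PipelineConfig(steps=("enmix", "enmix"))

    def test_empty_step_list_is_identity_on_betas(self, small_array_module):
        x, manifest, _ = small_array_module
        _, beta, _ = run_pipeline(x, manifest, PipelineConfig(steps=()))
        expected = compute_beta(x.M.to_numpy(float), x.U.to_numpy(float))
        np.testing.assert_allclose(beta.values.to_numpy(), expected)

    def test_deterministic_given_seed(self, small_array_module):
        x, manifest, _ = small_array_module
        cfg = PipelineConfig(background_method="neg", steps=("enmix",),
                             subsample_seed=7)
        _, b1, _ = run_pipeline(x, manifest, cfg)
        _, b2, _ = run_pipeline(x, manifest, cfg)
        assert (b1.values.to_numpy() == b2.values.to_numpy()).all()

    def test_yaml_round_trip(self, tmp_path):
        cfg = PipelineConfig(background_method="est", steps=("enmix", "quantile"),
                             beta_offset=50.0, subsample_seed=3)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = PipelineConfig.from_yaml(p)
        assert back.background_method == "est"
        assert back.steps == ("enmix", "quantile")
        assert back.beta_offset == 50.0

    def test_beta_hook_applied(self, small_array_module):
        x, manifest, _ = small_array_module
        calls = []

        def hook(beta_frame):
            calls.append(beta_frame.shape)
            return beta_frame

        run_pipeline(x, manifest, PipelineConfig(steps=(), beta_hook=hook))
        assert calls == [x.M.shape]
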