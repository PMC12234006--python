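"""Generator closed forms, ground-truth bookkeeping and determinism."""

import numpy as np
import pytest
from scipy import stats

from protongate import synth
from protongate.synth import ScenarioConfig


class TestWaterChain:
    def test_jitter_free_lattice(self):
        fr = synth.make_water_chain(5, 2.8, 0.0)
        waters = fr.select("water")
        np.testing.assert_allclose(
            fr.positions[waters, 0], [2.8, 5.6, 8.4, 11.2, 14.0], atol=1e-12
        )
        np.testing.assert_allclose(fr.positions[waters, 1:], 0.0, atol=1e-12)
        # anchors one spacing beyond each end
        assert fr.positions[0, 0] == 0.0
        sink_mid = fr.positions[fr.select("name CA")].mean(axis=0)
        np.testing.assert_allclose(sink_mid, [6 * 2.8, 0.0, 0.0], atol=1e-12)

    def test_single_water_bridges_anchors(self):
        fr = synth.make_water_chain(1, 3.5, 0.0)
        assert len(fr.select("water")) == 1
        np.testing.assert_allclose(fr.positions[fr.select("water")][0], [3.5, 0, 0])

    def test_jittered_neighbor_distances_recompute(self):
        fr = synth.make_water_chain(5, 2.8, 0.1, seed=7)
        w = fr.positions[fr.select("water")]
        gaps = np.linalg.norm(np.diff(w, axis=0), axis=1)
        assert gaps.mean() == pytest.approx(2.8, abs=0.15)
        assert fr.metadata["spacing"] == 2.8

    @pytest.mark.parametrize("kwargs", [{"n_waters": 0}, {"spacing": -1.0}, {"spacing": 0.0}])
    def test_invalid_parameters_rejected_by_name(self, kwargs):
        args = {"n_waters": 5, "spacing": 2.8, **kwargs}
        with pytest.raises(ValueError, match="n_waters|spacing"):
            synth.make_water_chain(**args)


class TestWireTrajectory:
    def test_extreme_wet_fractions(self):
        _, wet = synth.make_wire_trajectory(20, 1.0, seed=1)
        assert all(wet)
        _, dry = synth.make_wire_trajectory(20, 0.0, seed=1)
        assert not any(dry)

    def test_wet_count_within_binomial_interval(self):
        _, labels = synth.make_wire_trajectory(200, 0.3, seed=11)
        lo, hi = stats.binom.interval(0.99, 200, 0.3)
        assert lo <= sum(labels) <= hi

    def test_wet_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="wet_fraction"):
            synth.make_wire_trajectory(5, 1.5)


class TestZZDataset:
    def test_zero_noise_matches_closed_form(self):
        cfg = ScenarioConfig(
            "t", 0, {"k_true": 2.0, "r1": 2.0, "delays": [0.1], "residues": ["A"]}
        )
        df = synth.make_zz_dataset(cfg)
        decay = np.exp(-0.2)
        assert df["I_AA"].iloc[0] == pytest.approx(0.5 * (1 + np.exp(-0.4)) * decay, rel=1e-12)
        assert df["I_AB"].iloc[0] == pytest.approx(0.5 * (1 - np.exp(-0.4)) * decay, rel=1e-12)
        assert df["I_AA"].iloc[0] == df["I_BB"].iloc[0]

    def test_no_exchange_means_zero_cross_peaks(self):
        cfg = ScenarioConfig(
            "t", 0, {"k_true": 1e-300, "r1": 1.0, "delays": [0.05, 0.1], "residues": ["A", "B"]}
        )
        df = synth.make_zz_dataset(cfg)
        np.testing.assert_allclose(df["I_AB"], 0.0, atol=1e-250)

    def test_ground_truth_recorded_not_in_columns(self):
        df = synth.make_zz_dataset(synth.get_preset("zz_low_pH"))
        assert df.attrs["ground_truth"]["k_true"] == 4.0
        assert set(df.columns) == {"residue", "t_s", "I_AA", "I_BB", "I_AB", "I_BA"}

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError, match="residue|delay"):
            synth.make_zz_dataset(
                ScenarioConfig("t", 0, {"k_true": 1, "r1": 1, "delays": [], "residues": ["A"]})
            )


class TestTitrationDataset:
    def test_midpoint_is_half_amplitude(self):
        cfg = ScenarioConfig(
            "t",
            0,
            {
                "pka_true": [7.0],
                "ph_grid": [5.0, 6.0, 6.5, 7.0, 7.5, 8.0, 9.0],
                "curves": {("R1", "H"): {"endpoint": 8.0, "amplitudes": [1.0]},
                           ("R2", "H"): {"endpoint": 7.5, "amplitudes": [0.4]}},
            },
        )
        df = synth.make_titration_dataset(cfg)
        r1 = df[(df.residue == "R1") & (df.pH == 7.0)]
        assert r1["shift_ppm"].iloc[0] == pytest.approx(8.5, rel=1e-12)
        # high-pH limit → endpoint
        cfg.parameters["ph_grid"] = [5, 6, 7, 8, 9, 20.0]
        df = synth.make_titration_dataset(cfg)
        assert df[(df.residue == "R1") & (df.pH == 20.0)]["shift_ppm"].iloc[0] == pytest.approx(
            8.0, abs=1e-12
        )

    def test_descending_pka_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            synth.make_titration_dataset(
                ScenarioConfig(
                    "t",
                    0,
                    {"pka_true": [7.1, 5.6], "ph_grid": list(range(4, 11)), "curves": {}},
                )
            )


class TestUmbrellaDataset:
    def test_flat_pmf_gaussian_sd(self):
        cfg = ScenarioConfig(
            "t", 1, {"pmf_form": "zero", "centers": [0.0], "kappa": 10.0,
                     "n_samples": 20000, "kT": 0.596}
        )
        (w,) = synth.make_umbrella_dataset(cfg)
        expected = np.sqrt(0.596 / 10.0)
        assert w.samples.std() == pytest.approx(expected, rel=0.02)
        assert abs(w.samples.mean()) < 3 * expected / np.sqrt(20000) * 2

    def test_stiff_bias_collapses_to_center(self):
        cfg = ScenarioConfig(
            "t", 1, {"pmf_form": "double_well", "pmf_params": {"barrier": 3.0},
                     "centers": [4.0], "kappa": 1e5, "n_samples": 500, "kT": 0.596}
        )
        (w,) = synth.make_umbrella_dataset(cfg)
        assert np.all(np.abs(w.samples - 4.0) < 0.05)

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError, match="force constant"):
            synth.make_umbrella_dataset(
                ScenarioConfig("t", 1, {"centers": [0.0], "kappa": -1.0,
                                        "n_samples": 500, "kT": 0.596})
            )


class TestAssayTraces:
    def test_flat_pyranine_normalizes_to_one(self):
        cfg = ScenarioConfig(
            "t", 0, {"duration": 100.0, "dt": 10.0, "amplitude": 0.0, "burst": 0.0,
                     "noise_sd": 0.0}
        )
        transport, baseline = synth.make_assay_traces("pyranine", cfg)
        np.testing.assert_allclose(transport.signal / transport.signal[0], 1.0)
        np.testing.assert_allclose(baseline.signal, transport.signal)

    def test_ssme_ground_truth_charge_is_analytic(self):
        cfg = synth.get_preset("wt_ssme")
        (trace,) = synth.make_assay_traces("ssme", cfg)
        gt = trace.metadata["ground_truth"]
        expected = gt["a1"] * gt["tau1"] * (1 - np.exp(-1.0 / gt["tau1"])) - gt["a2"] * gt[
            "tau2"
        ] * (1 - np.exp(-1.0 / gt["tau2"]))
        assert gt["charge_true"] == pytest.approx(expected, rel=1e-12)

    def test_unknown_kind_lists_valid_kinds(self):
        with pytest.raises(ValueError, match="pyranine, ssme"):
            synth.make_assay_traces("patch_clamp", synth.get_preset("wt_ssme"))


class TestDeterminism:
    @pytest.mark.parametrize("preset", ["zz_low_pH", "tpp_titration"])
    def test_identical_config_gives_identical_tables(self, preset):
        a = {
            "zz_low_pH": synth.make_zz_dataset,
            "tpp_titration": synth.make_titration_dataset,
        }[preset]
        df1 = a(synth.get_preset(preset))
        df2 = a(synth.get_preset(preset))
        assert df1.to_csv(index=False) == df2.to_csv(index=False)

    def test_umbrella_and_traces_reproduce(self):
        w1 = synth.make_umbrella_dataset(synth.get_preset("pmf_toy"))
        w2 = synth.make_umbrella_dataset(synth.get_preset("pmf_toy"))
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a.samples, b.samples)
        t1 = synth.make_assay_traces("pyranine", synth.get_preset("d107_leak"))
        t2 = synth.make_assay_traces("pyranine", synth.get_preset("d107_leak"))
        np.testing.assert_array_equal(t1[0].signal, t2[0].signal)

    def test_seed_override_changes_output(self):
        df1 = synth.make_zz_dataset(synth.get_preset("zz_low_pH"))
        df2 = synth.make_zz_dataset(synth.get_preset("zz_low_pH", seed=99))
        assert not np.allclose(df1["I_AA"], df2["I_AA"])
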