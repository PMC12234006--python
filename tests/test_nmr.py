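"""ZZ-exchange rate extraction and global titration fitting."""

import numpy as np
import pandas as pd
import pytest

from protongate import synth
from protongate.nmr import (
    ExchangeRateFitter,
    GlobalTitrationFitter,
    PeakQuartet,
    TitrationModel,
    classify_pka_sensitivity,
    exact_zz_ratio,
    fit_exchange_rate,
    fit_titration_global,
    model_select,
    titration_model_eval,
    zz_ratio,
)


class TestZZRatio:
    def test_zero_cross_peaks_give_zero(self):
        q = PeakQuartet("A", 0.1, 1.0, 1.0, 0.0, 0.0)
        assert zz_ratio(q) == 0.0

    def test_exact_quartet_matches_closed_form(self):
        # kt = 0.2: ratio = (1-e^-0.4)^2 / (4 e^-0.4) ≈ 0.040536 vs (kt)^2 = 0.04
        k, t = 2.0, 0.1
        auto, cross = synth.zz_quartet_model(k, np.array([t]), r1=2.0, i0=1.0)
        q = PeakQuartet("A", t, auto[0], auto[0], cross[0], cross[0])
        eps = np.exp(-0.4)
        assert zz_ratio(q) == pytest.approx((1 - eps) ** 2 / (4 * eps), rel=1e-12)
        assert zz_ratio(q) == pytest.approx(exact_zz_ratio(k, t), rel=1e-12)
        assert zz_ratio(q) == pytest.approx(0.040536, abs=5e-6)

    def test_scale_invariance(self):
        q1 = PeakQuartet("A", 0.05, 0.9, 0.8, 0.1, 0.12)
        q2 = PeakQuartet("A", 0.05, 0.9 * 7.3, 0.8 * 7.3, 0.1 * 7.3, 0.12 * 7.3)
        assert zz_ratio(q1) == pytest.approx(zz_ratio(q2), rel=1e-12)

    def test_relaxation_cancels_exactly(self):
        for r1 in (0.5, 2.0, 8.0):
            auto, cross = synth.zz_quartet_model(3.0, np.array([0.04]), r1=r1, i0=2.5)
            q = PeakQuartet("A", 0.04, auto[0], auto[0], cross[0], cross[0])
            assert zz_ratio(q) == pytest.approx(exact_zz_ratio(3.0, 0.04), rel=1e-12)

    def test_fast_exchange_denominator_rejected(self):
        with pytest.raises(ValueError, match="too fast"):
            zz_ratio(PeakQuartet("A", 0.5, 0.5, 0.5, 0.5, 0.5))


class TestSmallKtApproximation:
    def test_relative_error_bounds(self):
        kt = np.linspace(0.01, 0.1, 20)
        rel = np.abs(exact_zz_ratio(1.0, kt) - kt**2) / exact_zz_ratio(1.0, kt)
        assert rel.max() <= 0.015
        kt = np.linspace(0.1, 0.3, 20)
        rel = np.abs(exact_zz_ratio(1.0, kt) - kt**2) / exact_zz_ratio(1.0, kt)
        assert rel.max() <= 0.12


class TestExchangeRateFit:
    def test_noiseless_quadratic_ratios_recover_exactly(self):
        t = np.array([0.01, 0.02, 0.03, 0.04])
        rows = []
        for res in ("A", "B"):
            for ti in t:
                # quartet constructed so that the ratio is exactly (10 t)^2:
                # cross/auto = kt/sqrt(1+(kt)^2)
                kt = 10.0 * ti
                cross = kt / np.sqrt(1.0 + kt**2)
                rows.append(
                    {"residue": res, "t_s": ti, "I_AA": 1.0, "I_BB": 1.0,
                     "I_AB": cross, "I_BA": cross}
                )
        df = pd.DataFrame(rows)
        fit = fit_exchange_rate(df)
        assert fit.k_ == pytest.approx(10.0, rel=1e-6)

    def test_low_ph_preset_recovery(self):
        df = synth.make_zz_dataset(synth.get_preset("zz_low_pH"))
        fit = fit_exchange_rate(df)
        assert fit.k_ == pytest.approx(4.0, abs=1.0)
        assert fit.sigma_k_bootstrap_ is not None  # 5 residues → bootstrap runs

    def test_high_ph_preset_recovery_with_exclusions(self):
        df = synth.make_zz_dataset(synth.get_preset("zz_high_pH"))
        fit = fit_exchange_rate(df)
        assert fit.k_ == pytest.approx(17.0, abs=3.0)
        assert len(fit.excluded_) > 0  # long delays exceed the kt cap

    def test_per_residue_pooling_agrees(self):
        df = synth.make_zz_dataset(synth.get_preset("zz_low_pH"))
        composite = fit_exchange_rate(df, pooling="composite")
        per_res = fit_exchange_rate(df, pooling="per_residue")
        assert per_res.k_ == pytest.approx(composite.k_, rel=0.1)
        assert set(per_res.k_per_residue_) <= set(composite.residues_)

    def test_too_few_points_rejected_with_log(self):
        df = pd.DataFrame(
            [{"residue": "A", "t_s": 0.5, "I_AA": 0.5, "I_BB": 0.5, "I_AB": 0.5, "I_BA": 0.5}]
        )
        with pytest.raises(ValueError, match="exclusion log"):
            fit_exchange_rate(df)


class TestTitrationModel:
    def _model(self):
        return TitrationModel(
            n_pka=2,
            pka=[5.6, 7.1],
            pka_sd=[0.1, 0.1],
            curves={("R1", "H"): {"endpoint": 8.0, "amplitudes": [0.4, 0.3]}},
        )

    def test_midpoint_and_limit(self):
        m = TitrationModel(1, [7.0], [0.1], {("R1", "H"): {"endpoint": 8.0, "amplitudes": [1.0]}})
        assert titration_model_eval(m, "R1", "H", 7.0) == pytest.approx(8.5, rel=1e-12)
        assert titration_model_eval(m, "R1", "H", 13.0) == pytest.approx(8.0, abs=1e-5)

    def test_two_pka_curve_is_sum_of_single_pka_curves(self):
        m = self._model()
        ph = np.linspace(4.0, 9.5, 40)
        m1 = TitrationModel(1, [5.6], [0.1], {("R1", "H"): {"endpoint": 8.0, "amplitudes": [0.4]}})
        m2 = TitrationModel(1, [7.1], [0.1], {("R1", "H"): {"endpoint": 0.0, "amplitudes": [0.3]}})
        np.testing.assert_allclose(
            titration_model_eval(m, "R1", "H", ph),
            titration_model_eval(m1, "R1", "H", ph) + titration_model_eval(m2, "R1", "H", ph),
            rtol=1e-12,
        )

    def test_unknown_curve_rejected(self):
        with pytest.raises(KeyError, match="R9"):
            titration_model_eval(self._model(), "R9", "H", 7.0)


def _single_pka_table(pka=6.4, seed=0, noise=0.0, n_residues=3, ph_pts=8):
    cfg = synth.ScenarioConfig(
        "single",
        seed,
        {
            "pka_true": [pka],
            "ph_grid": np.linspace(4.5, 9.0, ph_pts).tolist(),
            "curves": {
                (f"R{i}", "H"): {"endpoint": 8.0 + 0.1 * i, "amplitudes": [0.5 + 0.1 * i]}
                for i in range(n_residues)
            },
            "noise_sd": {"H": noise},
        },
    )
    return synth.make_titration_dataset(cfg)


class TestGlobalTitrationFit:
    def test_noiseless_single_pka_recovered_sharply(self):
        model = fit_titration_global(_single_pka_table(), n_pka=1)
        assert model.pka[0] == pytest.approx(6.4, abs=0.01)

    def test_preset_recovers_both_pka(self):
        table = synth.make_titration_dataset(synth.get_preset("tpp_titration"))
        model = fit_titration_global(table, n_pka=2)
        assert model.pka[0] == pytest.approx(5.6, abs=0.2)
        assert model.pka[1] == pytest.approx(7.1, abs=0.2)
        assert model.pka[0] < model.pka[1]

    def test_agrees_with_grid_search_oracle(self):
        table = synth.make_titration_dataset(synth.get_preset("tpp_titration"))
        fitter = GlobalTitrationFitter(n_pka=2).fit(table)
        # independent coarse oracle: exhaustive 0.05-step pKa grid with
        # per-curve linear amplitudes solved exactly at each grid point
        curves = fitter._prepare(table)
        grid = np.arange(5.0, 8.0 + 1e-9, 0.05)
        best = (np.inf, None)
        for i, p1 in enumerate(grid):
            for p2 in grid[i + 1 :]:
                rss, _ = GlobalTitrationFitter._profiled_rss(np.array([p1, p2]), curves)
                if rss < best[0]:
                    best = (rss, (p1, p2))
        assert fitter.pka_[0] == pytest.approx(best[1][0], abs=0.05)
        assert fitter.pka_[1] == pytest.approx(best[1][1], abs=0.05)

    def test_constant_shift_offset_absorbed_by_endpoint(self):
        table = _single_pka_table()
        shifted = table.copy()
        mask = shifted["residue"] == "R1"
        shifted.loc[mask, "shift_ppm"] += 3.0
        m1 = fit_titration_global(table, n_pka=1)
        m2 = fit_titration_global(shifted, n_pka=1)
        assert m2.pka[0] == pytest.approx(m1.pka[0], abs=1e-6)
        assert m2.curves[("R1", "H")]["endpoint"] == pytest.approx(
            m1.curves[("R1", "H")]["endpoint"] + 3.0, abs=1e-6
        )

    def test_single_residue_rejected(self):
        table = _single_pka_table(n_residues=1)
        with pytest.raises(ValueError, match="2 residues"):
            fit_titration_global(table, n_pka=2)


class TestModelSelect:
    def test_identical_fits_give_f_zero(self):
        m = fit_titration_global(_single_pka_table(), n_pka=1)
        out = model_select(m, m)
        assert out["F"] == 0.0
        assert out["p"] == 1.0

    def test_mismatched_data_rejected(self):
        m1 = fit_titration_global(_single_pka_table(seed=1, noise=0.01), n_pka=1)
        m2 = fit_titration_global(_single_pka_table(seed=2, noise=0.01), n_pka=1)
        with pytest.raises(ValueError, match="identical data"):
            model_select(m1, m2)

    def test_null_and_alternative_selection_rates(self):
        # under a 1-pKa truth the F-test should rarely prefer 2 pKa
        # (nominal 5% false-positive rate); under a separated 2-pKa truth
        # it should essentially always prefer 2 pKa
        null_prefers_simple = 0
        for seed in range(100):
            table = _single_pka_table(seed=seed, noise=0.02)
            m1 = fit_titration_global(table, n_pka=1)
            m2 = fit_titration_global(table, n_pka=2)
            if model_select(m1, m2)["preferred_n_pka"] == 1:
                null_prefers_simple += 1
        assert null_prefers_simple >= 90

        alt_prefers_complex = 0
        for seed in range(10):
            table = synth.make_titration_dataset(synth.get_preset("tpp_titration", seed=seed))
            m1 = fit_titration_global(table, n_pka=1)
            m2 = fit_titration_global(table, n_pka=2)
            if model_select(m1, m2)["preferred_n_pka"] == 2:
                alt_prefers_complex += 1
        assert alt_prefers_complex >= 9


class TestSensitivityClassification:
    def test_designed_labels_recovered_from_preset_fit(self):
        table = synth.make_titration_dataset(synth.get_preset("tpp_titration"))
        model = fit_titration_global(table, n_pka=2)
        cls = classify_pka_sensitivity(model, min_amplitude=0.1)
        # preset design: R1–R4 low-only, R5–R8 high-only, R9–R12 both
        for res in ("R1", "R2", "R3", "R4"):
            assert cls.labels[res] == "low_only"
        for res in ("R5", "R6", "R7", "R8"):
            assert cls.labels[res] == "high_only"
        for res in ("R9", "R10", "R11", "R12"):
            assert cls.labels[res] == "both"

    def test_fraction_normalization_and_insensitive_label(self):
        model = TitrationModel(
            2,
            [5.6, 7.1],
            [0.1, 0.1],
            {
                ("R1", "H"): {"endpoint": 8.0, "amplitudes": [0.4, 0.0]},
                ("R2", "H"): {"endpoint": 8.0, "amplitudes": [0.001, 0.002]},
            },
        )
        cls = classify_pka_sensitivity(model, min_amplitude=0.05)
        assert cls.labels["R1"] == "low_only"
        assert cls.labels["R2"] == "insensitive"
        assert sum(cls.fractions["R1"]) == pytest.approx(1.0)
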