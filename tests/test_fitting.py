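"""Binned profiles, dose-response fits, rank-sum comparisons, onset times."""

import dataclasses

import numpy as np
import pytest

from notchcis.fitting import (
    binned_median_profile,
    compare_conditions,
    detect_t_on,
    fit_cis_inhibition,
    fit_saturation,
    half_inhibition_ratio,
    normalize_effective_ligand,
    normalize_to_uninduced,
)
from notchcis.synthetic import (
    DilutionTrace,
    generate_availability_dataset,
    generate_calibration_dataset,
    generator_params,
    half_inhibition_total_ligand,
)


class TestBinnedProfile:
    def test_constant_y_degenerate_ci(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 100, 400)
        p = binned_median_profile(x, np.full(400, 3.3), n_bins=5, n_boot=200)
        assert np.allclose(p.median[p.n > 0], 3.3)
        assert np.allclose(p.ci_low[p.n > 0], 3.3)
        assert np.allclose(p.ci_high[p.n > 0], 3.3)

    def test_single_point_bin(self):
        p = binned_median_profile([1.0, 100.0], [2.0, 9.0], n_bins=2, n_boot=100)
        assert p.n.tolist() == [1, 1]
        assert p.median.tolist() == [2.0, 9.0]
        assert p.ci_low.tolist() == [2.0, 9.0]

    def test_empty_bins_reported(self):
        x = np.array([1.0, 1.5, 900.0, 950.0])
        p = binned_median_profile(x, np.ones(4), n_bins=6, n_boot=100)
        assert (p.n == 0).any()
        assert np.isnan(p.median[p.n == 0]).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        x, y = rng.uniform(1, 50, 300), rng.normal(size=300)
        a = binned_median_profile(x, y, seed=4)
        b = binned_median_profile(x, y, seed=4)
        assert np.array_equal(a.ci_low, b.ci_low, equal_nan=True)

    def test_nonpositive_x_rejected(self):
        with pytest.raises(ValueError):
            binned_median_profile([0.0, 1.0], [1.0, 2.0])

    @pytest.mark.parametrize("n", [50, 200, 800])
    def test_ci_width_shrinks_like_sqrt_n(self, n):
        rng = np.random.default_rng(n)
        x = rng.uniform(1, 10, n)
        y = rng.normal(0, 1, n)
        p = binned_median_profile(x, y, n_bins=1, n_boot=500, seed=0)
        width = p.ci_high[0] - p.ci_low[0]
        # median CI width ~ 2*1.96*1.2533/sqrt(n) for a standard normal
        expected = 2 * 1.96 * 1.2533 / np.sqrt(n)
        assert width == pytest.approx(expected, rel=0.35)


class TestNormalization:
    def test_linear_data_recovers_slope_ratio(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(10, 100, 50)
        import pandas as pd
        tab = pd.concat([
            pd.DataFrame({"ligand": "Dll1", "total_ligand_fluor": x,
                          "availability_fluor": 0.7 * x}),
            pd.DataFrame({"ligand": "Jag1", "total_ligand_fluor": x,
                          "availability_fluor": 1.4 * x}),
        ])
        scale = normalize_effective_ligand(tab, reference="Dll1")
        assert scale["Dll1"] == pytest.approx(1.0)
        assert scale["Jag1"] == pytest.approx(2.0, rel=1e-9)

    def test_generator_round_trip_recovers_efficiency_ratio(self, gen_config):
        # ligand-only condition: no receptor production, ligand availability
        p = dataclasses.replace(generator_params(), beta_N=0.0)
        import pandas as pd
        tabs = []
        for lig in ("Dll1", "Jag1"):
            tabs.append(generate_availability_dataset(
                gen_config, p, ligand=lig, assay="ligand_availability",
                seed=7))
        tab = pd.concat(tabs)
        scale = normalize_effective_ligand(tab, reference="Dll1")
        true_ratio = (gen_config.surface_efficiency["Jag1"]
                      / gen_config.surface_efficiency["Dll1"])
        assert scale["Jag1"] == pytest.approx(true_ratio, rel=0.1)

    def test_too_few_points_rejected(self):
        import pandas as pd
        tab = pd.DataFrame({"ligand": ["Dll1"] * 2,
                            "total_ligand_fluor": [1.0, 2.0],
                            "availability_fluor": [1.0, 2.0]})
        with pytest.raises(ValueError):
            normalize_effective_ligand(tab)

    def test_uninduced_normalization_scales_everything(self):
        p = binned_median_profile(np.linspace(1, 100, 200),
                                  np.full(200, 8.0), n_bins=4, n_boot=100)
        q = normalize_to_uninduced(p, 8.0)
        assert np.allclose(q.median[q.n > 0], 1.0)
        # ratios between bins are preserved under scalar division
        r = normalize_to_uninduced(p, 2.0)
        np.testing.assert_allclose(r.median[r.n > 0] / q.median[q.n > 0], 4.0)
        with pytest.raises(ValueError):
            normalize_to_uninduced(p, 0.0)

    def test_detection_gain_cancels_after_normalization(self, gen_config):
        # doubling the detection gain must not change the normalized curve
        from notchcis.kinetics import FringeConfig
        cfg = dataclasses.replace(gen_config, noise_cv=0.0,
                                  background_mean=0.0, background_sd=0.0)
        curves = []
        for gain in (1.0, 2.0):
            fr = FringeConfig(identity="x", cis_factor={"Dll1": 1.0},
                              trans_factor={"Dll1": 1.0}, detection_gain=gain)
            tab = generate_availability_dataset(cfg, fringe=fr, seed=3)
            prof = binned_median_profile(tab.total_ligand_fluor,
                                         tab.availability_fluor,
                                         n_bins=6, n_boot=100, seed=0)
            uninduced = tab[tab.induction_ngml == 0].availability_fluor.median()
            curves.append(normalize_to_uninduced(prof, uninduced))
        np.testing.assert_allclose(curves[0].median, curves[1].median,
                                   rtol=1e-9)


class TestSaturationFit:
    def test_noise_free_exact_recovery(self):
        D = np.array([0.1, 0.3, 1, 2, 5, 10, 30])
        y = 1.0 * D / (D + 1.0)
        fit = fit_saturation(D, y)
        assert fit.a == pytest.approx(1.0, rel=1e-6)
        assert fit.K == pytest.approx(1.0, rel=1e-6)
        assert fit.identifiable

    def test_paper_scale_recovery_with_noise(self):
        tab = generate_calibration_dataset(2.1e4, 2.27,
                                           [0.1, 0.3, 1, 3, 5, 10, 20, 30],
                                           replicates=2, noise_cv=0.1, seed=0)
        fit = fit_saturation(tab.concentration_ugml, tab.signal)
        assert fit.K == pytest.approx(2.27, rel=0.25)
        assert fit.K_stderr is not None

    def test_all_zero_signal_flagged(self):
        fit = fit_saturation([1.0, 2.0, 4.0], [0.0, 0.0, 0.0])
        assert not fit.identifiable

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_saturation([1.0, 1.0, 2.0], [0.5, 0.5, 0.6])


class TestCisInhibitionFit:
    def test_noise_free_exact_recovery(self):
        L = np.logspace(0, 4, 60)
        y = 5.0 + 100.0 / (1 + L / 300.0)
        fit = fit_cis_inhibition(L, y)
        assert fit.amplitude == pytest.approx(100.0, rel=1e-4)
        assert fit.L50 == pytest.approx(300.0, rel=1e-4)
        assert fit.background == pytest.approx(5.0, rel=1e-3)
        assert fit.identifiable

    def test_generator_round_trip_within_ten_percent(self, gen_config):
        cfg = dataclasses.replace(gen_config, n_cells_per_level=500)
        tab = generate_availability_dataset(cfg, seed=21)
        t50 = half_inhibition_total_ligand(cfg)
        fit = fit_cis_inhibition(tab.total_ligand_fluor, tab.availability_fluor)
        assert fit.L50 == pytest.approx(t50, rel=0.10)

    def test_flat_data_flagged_unidentifiable(self):
        L = np.logspace(0, 3, 40)
        fit = fit_cis_inhibition(L, np.full(40, 50.0))
        assert not fit.identifiable


class TestHalfInhibitionRatio:
    def _fit(self, L50, stderr=10.0):
        from notchcis.fitting import CisFitResult
        return CisFitResult(amplitude=1.0, L50=L50, background=0.0,
                            amplitude_stderr=None, L50_stderr=stderr,
                            background_stderr=None, residual_norm=0.0)

    def test_identical_fits_ratio_one(self):
        r, err = half_inhibition_ratio(self._fit(200.0), self._fit(200.0))
        assert r == pytest.approx(1.0)
        assert err > 0

    def test_swap_inverts(self):
        a, b = self._fit(400.0), self._fit(100.0)
        r1, _ = half_inhibition_ratio(a, b)
        r2, _ = half_inhibition_ratio(b, a)
        assert r1 == pytest.approx(1 / r2)

    def test_unidentifiable_input_rejected(self):
        bad = self._fit(100.0)
        bad.identifiable = False
        with pytest.raises(ValueError):
            half_inhibition_ratio(bad, self._fit(100.0))

    def test_two_fold_cis_difference_recovered(self, gen_config):
        # Jag1 generated with half the cis strength (kc doubled) needs
        # twice the ligand for half-inhibition
        p = generator_params()
        p_weak = dataclasses.replace(p, kC_plus=p.kC_plus / 2)
        cfg = dataclasses.replace(
            gen_config, n_cells_per_level=500,
            surface_efficiency={"Dll1": 0.01, "Jag1": 0.01})
        td = generate_availability_dataset(cfg, p, ligand="Dll1", seed=31)
        tj = generate_availability_dataset(cfg, p_weak, ligand="Jag1", seed=32)
        fd = fit_cis_inhibition(td.total_ligand_fluor, td.availability_fluor)
        fj = fit_cis_inhibition(tj.total_ligand_fluor, tj.availability_fluor)
        r, _ = half_inhibition_ratio(fj, fd)
        assert r == pytest.approx(2.0, rel=0.15)


class TestCompareConditions:
    def test_table_against_itself_not_significant(self, gen_config):
        tab = generate_availability_dataset(gen_config)
        edges = np.logspace(1, 4.5, 7)
        res = compare_conditions(tab, tab, edges)
        assert not res.significant.any()
        assert np.allclose(res.p_value.dropna(), 1.0, atol=1e-9)

    def test_notch_absent_vs_present_significant_at_high_ligand(self, gen_config):
        # ligand availability rises when receptor is absent (no cis sink);
        # receptor production strong enough to visibly deplete surface ligand
        cfg = dataclasses.replace(gen_config, n_cells_per_level=400)
        p = dataclasses.replace(generator_params(), beta_N=2.0)
        with_n = generate_availability_dataset(cfg, p, seed=41,
                                               assay="ligand_availability")
        without = generate_availability_dataset(
            cfg, dataclasses.replace(p, beta_N=0.0), seed=42,
            assay="ligand_availability")
        edges = np.logspace(np.log10(5), np.log10(3e4), 7)
        res = compare_conditions(with_n, without, edges)
        tested = res[res.p_value.notna()]
        assert tested.significant.any()
        # depletion by the shared Notch pool persists into the upper bins
        upper = tested[tested.bin >= tested.bin.median()]
        assert upper.significant.any()

    def test_small_bins_excluded(self, gen_config):
        tab = generate_availability_dataset(gen_config)
        res = compare_conditions(tab, tab, [1e-3, 1e-2], n_min=10)
        assert res.p_value.isna().all()
        assert not res.significant.any()

    def test_bh_correction_is_conservative(self, gen_config):
        a = generate_availability_dataset(gen_config, seed=1)
        b = generate_availability_dataset(gen_config, seed=2)
        edges = np.logspace(1, 4.5, 9)
        raw = compare_conditions(a, b, edges)
        adj = compare_conditions(a, b, edges, correction="bh")
        assert adj.significant.sum() <= raw.significant.sum()


class TestDetectTOn:
    def _trace(self, t, reporter, ligand=None):
        return DilutionTrace(t=np.asarray(t, float),
                             ligand_fluor=(np.ones(len(t)) if ligand is None
                                           else np.asarray(ligand, float)),
                             reporter_fluor=np.asarray(reporter, float),
                             division_period=18.0)

    def test_piecewise_linear_onset_within_one_frame(self):
        dt = 1 / 3
        t = np.arange(0, 30, dt)
        r = detect_t_on(self._trace(t, np.maximum(0, t - 10) * 7.0))
        assert r.onset_detected
        assert abs(r.t_on - 10.0) <= dt + 1e-9

    def test_flat_reporter_flagged(self):
        t = np.arange(0, 10, 0.5)
        r = detect_t_on(self._trace(t, np.zeros_like(t)))
        assert not r.onset_detected and r.t_on is None

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 40, 1 / 3)
        y = np.maximum(0, t - 12) ** 1.5 + rng.normal(0, 0.3, t.size)
        r1 = detect_t_on(self._trace(t, y))
        r2 = detect_t_on(self._trace(t, 37.0 * y))
        assert r1.t_on == r2.t_on

    def test_reports_ligand_at_onset(self):
        t = np.arange(0, 30, 0.5)
        lig = 1000 * np.exp(-0.1 * t)
        r = detect_t_on(self._trace(t, np.maximum(0, t - 10), ligand=lig))
        assert r.ligand_at_t_on == pytest.approx(1000 * np.exp(-0.1 * r.t_on))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            detect_t_on(self._trace([0, 1, 2], [0, 0, 0]))
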