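"""Estimator tests: segmented mono-exponential vs full bi-exponential fitting."""

import numpy as np
import pytest

from ivim_grade import (
    BValueScheme,
    FitConfig,
    IVIMParams,
    SignalCurve,
    fit_bi_full,
    fit_dstar_fixed,
    fit_high_b_linear,
    fit_mono_segmented,
    ivim_signal,
    ivim_signal_curve,
    split_b,
)
from ivim_grade.fitting import FitInfeasibleError
from ivim_grade.simulate import add_rician_noise

from .conftest import MD_MONO, PD_MONO, WD_BI, WD_MONO


def _mono_curve(scheme, D, f=0.0):
    s = (1 - f) * np.exp(-scheme.b_array * D)
    s[0] = 1.0 if f == 0 else s[0]
    return SignalCurve(scheme, tuple((s / s[0]).tolist()))


def _noisy_curve(truth, scheme, snr, rng):
    clean = ivim_signal(truth, scheme.b_array)
    s = add_rician_noise(clean, 1.0 / snr, scheme.nex, rng)
    return SignalCurve(scheme, tuple((s / s[0]).tolist()))


class TestSplitB:
    def test_threshold_200_keeps_four_high_points(self, scheme):
        low, high = split_b(scheme, 200.0)
        assert scheme.b_array[low].tolist() == [0, 30, 50, 80, 150, 200]
        assert scheme.b_array[high].tolist() == [400, 600, 800, 1000]

    def test_threshold_80_partition(self, scheme):
        low, high = split_b(scheme, 80.0)
        assert scheme.b_array[low].tolist() == [0, 30, 50, 80]
        assert scheme.b_array[high].tolist() == [150, 200, 400, 600, 800, 1000]

    def test_union_covers_all_indices(self, scheme):
        low, high = split_b(scheme, 200.0)
        assert sorted(np.concatenate([low, high]).tolist()) == list(range(len(scheme)))

    @pytest.mark.parametrize("threshold", [1000.0, 799.0, 2000.0])
    def test_infeasible_thresholds_rejected(self, scheme, threshold):
        with pytest.raises(FitInfeasibleError):
            split_b(scheme, threshold)


class TestHighBLinear:
    def test_exact_on_pure_exponential(self, scheme):
        curve = _mono_curve(scheme, 1.0e-3)
        D, intercept, flags = fit_high_b_linear(curve)
        assert D == pytest.approx(1.0e-3, rel=1e-12)
        assert intercept == pytest.approx(1.0)

    def test_wd_means_recovered_with_negligible_contamination(self, wd_curve):
        D, intercept, _ = fit_high_b_linear(wd_curve)
        assert D == pytest.approx(1.48e-3, rel=1e-3)
        assert intercept == pytest.approx(0.84, abs=1e-3)

    def test_closed_form_slope_on_collinear_points(self):
        # 4 points exactly on ln s = ln 0.9 - 2e-3 b
        scheme = BValueScheme((0, 300, 500, 700, 900), (1, 1, 1, 1, 1))
        s = 0.9 * np.exp(-2e-3 * scheme.b_array)
        s[0] = 1.0  # b=0 point is not used by the high-b fit
        D, intercept, _ = fit_high_b_linear(SignalCurve(scheme, tuple(s)))
        assert D == pytest.approx(2e-3, rel=1e-12)
        assert intercept == pytest.approx(0.9, rel=1e-12)


class TestSegmentedFit:
    def test_pd_means_recovered_noise_free(self, pd_curve):
        res = fit_mono_segmented(pd_curve)
        assert res.model_tag == "mono"
        assert res.params.f == pytest.approx(PD_MONO.f, abs=0.01)
        assert res.params.D == pytest.approx(PD_MONO.D, rel=0.02)
        assert res.n_points_high == 4 and res.n_points_low == 6

    def test_pure_mono_exponential_flags_dstar(self, scheme):
        res = fit_mono_segmented(_mono_curve(scheme, 1.3e-3))
        assert res.params.f == pytest.approx(0.0, abs=1e-9)
        assert res.params.D == pytest.approx(1.3e-3, rel=1e-9)
        assert "D_star_nonidentifiable" in res.flags

    def test_median_f_unbiased_under_noise(self, scheme):
        # Monte-Carlo: ROI-level curves at SNR 50, truth = MD group means
        rng = np.random.default_rng(42)
        fs = [
            fit_mono_segmented(_noisy_curve(MD_MONO, scheme, 50.0, rng)).params.f
            for _ in range(200)
        ]
        assert np.median(fs) == pytest.approx(MD_MONO.f, abs=0.02)


class TestDstarFixed:
    def test_wd_means_recovered_noise_free(self, wd_curve):
        dstar, flags = fit_dstar_fixed(wd_curve, WD_MONO.D, WD_MONO.f)
        assert dstar == pytest.approx(WD_MONO.D_star, rel=0.005)
        assert flags == ()

    def test_zero_f_is_non_identifiable(self, wd_curve):
        with pytest.raises(FitInfeasibleError):
            fit_dstar_fixed(wd_curve, WD_MONO.D, 0.0)

    def test_optimizer_matches_grid_search_oracle(self, scheme):
        # brute-force 2000-point log grid over the D* bounds
        config = FitConfig()
        lo, hi = config.bounds["D_star"]
        grid = np.logspace(np.log10(lo), np.log10(hi), 2000)
        rng = np.random.default_rng(3)
        for _ in range(5):
            truth = IVIMParams(
                D=rng.uniform(0.5e-3, 2e-3),
                D_star=rng.uniform(5e-3, 8e-2),
                f=rng.uniform(0.1, 0.4),
            )
            curve = ivim_signal_curve(truth, scheme)
            b = scheme.b_array
            s = curve.signal_array
            sse = [
                np.sum(
                    (truth.f * np.exp(-b * d) + (1 - truth.f) * np.exp(-b * truth.D) - s)
                    ** 2
                )
                for d in grid
            ]
            oracle = grid[int(np.argmin(sse))]
            est, _ = fit_dstar_fixed(curve, truth.D, truth.f, config)
            step = np.log10(hi / lo) / 1999
            assert abs(np.log10(est) - np.log10(oracle)) <= step


class TestFullBiFit:
    def test_exact_recovery_noise_free_wd_bi_means(self, scheme):
        res = fit_bi_full(ivim_signal_curve(WD_BI, scheme))
        assert res.model_tag == "bi"
        assert res.converged
        assert res.params.D == pytest.approx(WD_BI.D, rel=1e-3)
        assert res.params.D_star == pytest.approx(WD_BI.D_star, rel=1e-3)
        assert res.params.f == pytest.approx(WD_BI.f, abs=1e-3)

    def test_pure_mono_exponential_flags_dstar(self, scheme):
        res = fit_bi_full(_mono_curve(scheme, 1.1e-3))
        assert res.params.f == pytest.approx(0.0, abs=1e-6)
        assert res.params.D == pytest.approx(1.1e-3, rel=1e-6)
        assert "D_star_nonidentifiable" in res.flags

    def test_init_strategies_agree_noise_free(self, scheme):
        rng = np.random.default_rng(5)
        for _ in range(10):
            truth = IVIMParams(
                D=rng.uniform(0.5e-3, 2.5e-3),
                D_star=rng.uniform(8e-3, 6e-2),
                f=rng.uniform(0.08, 0.45),
            )
            curve = ivim_signal_curve(truth, scheme)
            a = fit_bi_full(curve, FitConfig(init_strategy="segmented-init"))
            b = fit_bi_full(curve, FitConfig(init_strategy="fixed-init"))
            assert a.params.D == pytest.approx(b.params.D, rel=1e-3)
            assert a.params.D_star == pytest.approx(b.params.D_star, rel=1e-3)
            assert a.params.f == pytest.approx(b.params.f, abs=1e-3)

    def test_full_fit_rss_never_worse_than_segmented(self, scheme):
        rng = np.random.default_rng(9)
        for _ in range(10):
            curve = _noisy_curve(MD_MONO, scheme, 30.0, rng)
            seg = fit_mono_segmented(curve)
            bi = fit_bi_full(curve)
            assert bi.rss <= seg.rss + 1e-12

    def test_needs_five_distinct_b_values(self):
        scheme = BValueScheme((0, 200, 600, 1000), (1, 1, 1, 1))
        s = np.exp(-scheme.b_array * 1e-3)
        with pytest.raises(FitInfeasibleError):
            fit_bi_full(SignalCurve(scheme, tuple(s)))


def test_noise_free_identifiability_region(scheme):
    """Full fit exact; segmented D, f within 2% and D* within 5% wherever
    the perfusion pool is well separated (D* >= 5 D, 0.05 <= f <= 0.5)."""
    rng = np.random.default_rng(17)
    for _ in range(15):
        # D* restricted to the clinically observed pseudo-diffusion range
        # (>= 1.5e-2 mm^2/s), where the perfusion pool is fully decayed on
        # the high-b points the segmented fit uses
        D = rng.uniform(0.4e-3, 2.5e-3)
        truth = IVIMParams(
            D=D,
            D_star=rng.uniform(max(5.0 * D, 1.5e-2), 6e-2),
            f=rng.uniform(0.05, 0.5),
        )
        curve = ivim_signal_curve(truth, scheme)
        bi = fit_bi_full(curve)
        assert bi.params.D == pytest.approx(truth.D, rel=1e-3)
        assert bi.params.D_star == pytest.approx(truth.D_star, rel=1e-3)
        assert bi.params.f == pytest.approx(truth.f, abs=1e-3)
        seg = fit_mono_segmented(curve)
        assert seg.params.D == pytest.approx(truth.D, rel=0.02)
        assert seg.params.f == pytest.approx(truth.f, rel=0.02, abs=0.005)
        assert seg.params.D_star == pytest.approx(truth.D_star, rel=0.05)
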