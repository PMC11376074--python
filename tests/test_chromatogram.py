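"""Peak detection, series assignment, UCM index, and the 0-4 scoring rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oilbiodeg import (
    AlkaneCalibration,
    AlkaneProfile,
    Chromatogram,
    Peak,
    ScoringThresholds,
    assign_series,
    compute_ucm_index,
    detect_peaks,
    score_chromatogram,
    score_degradation,
    simulate_chromatogram,
)


def gauss(rt, center, sd):
    return np.exp(-0.5 * ((rt - center) / sd) ** 2)


class TestDetectPeaks:
    def test_flat_zero_trace_has_no_peaks(self, rt_grid):
        assert detect_peaks(Chromatogram(rt_grid, np.zeros_like(rt_grid))) == []

    def test_single_gaussian_found_at_apex(self, rt_grid):
        chrom = Chromatogram(rt_grid, 10.0 * gauss(rt_grid, 20.0, 0.1))
        peaks = detect_peaks(chrom)
        assert len(peaks) == 1
        assert peaks[0].apex_rt == pytest.approx(20.0, abs=0.05)
        assert peaks[0].area == pytest.approx(10.0 * 0.1 * np.sqrt(2 * np.pi), rel=0.15)

    def test_full_undegraded_series_yields_28_peaks(self):
        chrom, _ = simulate_chromatogram(0)
        assert len(detect_peaks(chrom)) == 28  # 26 n-alkanes + Pr + Ph

    def test_invalid_thresholds_rejected(self, rt_grid):
        chrom = Chromatogram(rt_grid, gauss(rt_grid, 20.0, 0.1))
        with pytest.raises(ValueError):
            detect_peaks(chrom, min_snr=0)


class TestChromatogramValidation:
    def test_decreasing_rt_rejected(self):
        with pytest.raises(ValueError):
            Chromatogram(np.array([2.0, 1.0]), np.array([0.0, 0.0]))

    def test_nonfinite_intensity_rejected(self, rt_grid):
        y = np.zeros_like(rt_grid)
        y[5] = np.inf
        with pytest.raises(ValueError):
            Chromatogram(rt_grid, y)


class TestAssignSeries:
    def make_peaks(self, heights):
        cal = AlkaneCalibration()
        pos = cal.positions()
        return [Peak(pos[name], h, h * 0.1) for name, h in heights.items()]

    def test_exact_positions_all_assigned(self):
        cal = AlkaneCalibration()
        heights = {name: 1.0 for name in cal.positions()}
        profile = assign_series(self.make_peaks(heights), cal)
        assert profile.n_alkanes_present == 26
        assert all(p.assignment != "unassigned" for p in profile.peaks)

    def test_ratio_arithmetic(self):
        profile = assign_series(self.make_peaks({"nC17": 200.0, "Pr": 100.0}))
        assert profile.c17_pr_ratio == pytest.approx(2.0)

    def test_missing_member_gives_undefined_ratio(self):
        profile = assign_series(self.make_peaks({"nC17": 200.0}))
        assert profile.c17_pr_ratio is None

    def test_far_peak_stays_unassigned(self):
        profile = assign_series([Peak(7.0, 1.0, 0.1)])  # 3 min before nC10
        assert profile.peaks[0].assignment == "unassigned"
        assert profile.n_alkanes_present == 0

    def test_dominance_infinite_without_surviving_alkanes(self):
        profile = assign_series(self.make_peaks({"Pr": 1.0, "Ph": 1.0}))
        assert profile.pr_ph_dominance == np.inf

    def test_nonmonotone_calibration_rejected(self):
        with pytest.raises(ValueError):
            AlkaneCalibration(slope=-1.0)


class TestUcmIndex:
    def test_narrow_peaks_only(self, rt_grid):
        y = sum(gauss(rt_grid, c, 0.1) for c in range(10, 60, 2))
        assert compute_ucm_index(Chromatogram(rt_grid, y)) < 0.02

    def test_broad_hump_only(self, rt_grid):
        # the rolling minimum shaves the flanks of the hump slightly, so a
        # pure hump lands just below 1
        y = gauss(rt_grid, 35.0, 10.0)
        assert compute_ucm_index(Chromatogram(rt_grid, y)) > 0.9

    def test_even_mixture_is_half(self, rt_grid):
        """50/50 resolved-vs-hump area split, areas fixed by construction
        and cross-checked by numerical integration."""
        peak_sd, hump_sd, n_peaks = 0.1, 9.0, 25
        hump_height = n_peaks * peak_sd / hump_sd  # equal total Gaussian areas
        resolved = sum(gauss(rt_grid, c, peak_sd) for c in np.linspace(12, 58, n_peaks))
        hump = hump_height * gauss(rt_grid, 33.0, hump_sd)
        assert np.trapezoid(hump, rt_grid) == pytest.approx(
            np.trapezoid(resolved, rt_grid), rel=0.02
        )
        index = compute_ucm_index(Chromatogram(rt_grid, resolved + hump))
        assert index == pytest.approx(0.5, abs=0.05)

    def test_all_zero_trace_is_zero(self, rt_grid):
        assert compute_ucm_index(Chromatogram(rt_grid, np.zeros_like(rt_grid))) == 0.0


def profile(n_alk, r17, r18, dominance):
    return AlkaneProfile(
        peaks=(), c17_pr_ratio=r17, c18_ph_ratio=r18,
        n_alkanes_present=n_alk, pr_ph_dominance=dominance,
    )


class TestScoringRules:
    @pytest.mark.parametrize(
        "prof,ucm,expected",
        [
            (profile(26, 2.0, 1.8, 0.8), 0.02, 0),    # straight trace, full series
            (profile(26, 1.3, 1.2, 1.0), 0.20, 1),    # slight UCM, mild loss
            (profile(10, 0.5, 0.4, 5.0), 0.60, 2),    # many residual alkanes
            (profile(2, 0.5, 0.4, 5.0), 0.60, 3),     # near-total loss
            (profile(0, None, None, np.inf), 0.70, 4),  # complete n-alkane removal
        ],
    )
    def test_rule_table(self, prof, ucm, expected):
        assert score_degradation(prof, ucm).degree == expected

    def test_degree_2_vs_3_boundary_at_residual_count(self):
        t = ScoringThresholds()
        at = score_degradation(profile(t.residual_count_threshold, 0.5, 0.5, 5.0), 0.6)
        above = score_degradation(profile(t.residual_count_threshold + 1, 0.5, 0.5, 5.0), 0.6)
        assert (at.degree, above.degree) == (3, 2)

    def test_undefined_ratios_fall_through_to_zero(self):
        # alkanes present but Pr/Ph missing: the ratio rules cannot apply
        assert score_degradation(profile(26, None, None, 0.0), 0.5).degree == 0

    def test_empty_profile_without_ucm_is_indeterminate(self):
        score = score_degradation(profile(0, None, None, 0.0), 0.05)
        assert score.indeterminate and score.degree is None

    def test_weak_dominance_blocks_moderate_rule(self):
        # ratios < 1 but Pr/Ph not dominant: neither 2/3 nor 1 applies
        assert score_degradation(profile(26, 0.5, 0.4, 1.0), 0.6).degree == 0


class TestEndToEnd:
    @pytest.mark.parametrize("degree", range(5))
    def test_noise_free_round_trip(self, degree):
        chrom, truth = simulate_chromatogram(degree)
        assert score_chromatogram(chrom).degree == truth.degradation_degree

    def test_degree_monotone_in_attenuation(self):
        degrees = [score_chromatogram(simulate_chromatogram(d)[0]).degree for d in range(5)]
        assert degrees == sorted(degrees)

    @pytest.mark.parametrize("scale", [0.01, 1.0, 1e6])
    def test_scale_invariance(self, scale):
        chrom, _ = simulate_chromatogram(2)
        scaled = Chromatogram(chrom.rt, chrom.intensity * scale)
        assert score_chromatogram(scaled).degree == 2
        assert compute_ucm_index(scaled) == pytest.approx(compute_ucm_index(chrom), rel=1e-9)

    @given(degree=st.integers(0, 4), seed=st.integers(0, 10_000))
    def test_total_function_on_simulated_traces(self, degree, seed):
        from dataclasses import replace
        from oilbiodeg import ChromatogramSimParams
        params = replace(ChromatogramSimParams(), noise_sd=0.02)
        chrom, _ = simulate_chromatogram(degree, params, seed=seed)
        score = score_chromatogram(chrom)
        assert score.degree in {0, 1, 2, 3, 4} or score.indeterminate
        assert 0.0 <= score.ucm_index <= 1.0
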