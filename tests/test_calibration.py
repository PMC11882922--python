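"""Staircases, logistic fitting, ISI design and trial allocation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from stdtlab.calibration import (
    DesignCollapse,
    ISIDesign,
    NonIdentifiableFit,
    PsychometricFit,
    allocate_trials,
    calibration_isis,
    design_isi_levels,
    fit_logistic,
    run_calibration_session,
    run_detection_staircase,
    run_stdt_staircase,
    stimulus_intensity,
)
from stdtlab.observers import LN99, Observer


def _step_observer(t50: float, det: float = 2.4) -> Observer:
    """Effectively deterministic observer (near-vertical psychometric slope)."""
    return Observer(t50=t50, scale=1e-9, det_threshold=det)


class TestDetectionStaircase:
    def test_hand_simulated_trace_2p33(self):
        # worked step-by-step by hand from the staircase rules
        est, trace = run_detection_staircase(_step_observer(40, det=2.33))
        assert trace.reversals == pytest.approx(
            [2.4, 2.30, 2.35, 2.325, 2.33125, 2.328125]
        )
        assert est == pytest.approx(2.3390625)

    def test_hand_simulated_estimate_1p05(self):
        est, _ = run_detection_staircase(_step_observer(40, det=1.05))
        assert est == pytest.approx(1.0473958333333333)

    def test_estimate_error_bound_over_threshold_grid(self):
        # brute-force sweep: estimate within 0.05 mA everywhere on [1.2, 5]
        for th in np.linspace(1.2, 5.0, 229):
            est, _ = run_detection_staircase(_step_observer(40, det=float(th)))
            assert abs(est - th) <= 0.05

    def test_reversal_containment_and_trace(self):
        est, trace = run_detection_staircase(_step_observer(40, det=3.1))
        visited = [v for v, _ in trace.steps]
        assert all(r in visited for r in trace.reversals)
        assert min(trace.reversals) <= est <= max(trace.reversals)
        assert len(trace.reversals) == 6

    def test_threshold_below_start_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            run_detection_staircase(_step_observer(40, det=0.9))


class TestStimulusIntensity:
    @pytest.mark.parametrize("est, expected", [(2.0, 4.0), (2.425, 4.85), (0.5, 1.0)])
    def test_doubles_threshold(self, est, expected):
        assert stimulus_intensity(est) == pytest.approx(expected)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            stimulus_intensity(0.0)


class TestStdtStaircase:
    def test_hand_simulated_step_observer(self, rng):
        # ascending from 2 in steps of 5 stops at 47; descending from 120 at 40
        est, traces = run_stdt_staircase(_step_observer(43.0), rng)
        assert est == pytest.approx(43.5)
        stops = [t.estimate for t in traces]
        assert stops == pytest.approx([47, 40, 47, 40, 47, 40])

    def test_threshold_below_start_stops_immediately(self, rng):
        est, traces = run_stdt_staircase(_step_observer(1.0), rng)
        assert traces[0].estimate == pytest.approx(2.0)  # first tested ISI

    def test_population_estimate_tracks_t50(self):
        rng = np.random.default_rng(8)
        errs = []
        for t50 in (20, 40, 60, 80):
            obs = Observer(t50=t50, scale=5)
            ests = [run_stdt_staircase(obs, rng)[0] for _ in range(20)]
            errs.append(abs(np.mean(ests) - t50))
        assert max(errs) <= 5.0  # within one staircase step


class TestCalibrationISIs:
    def test_closed_form_spacing(self):
        isis = calibration_isis(44.0)
        assert isis[0] == 2.0
        assert isis[7] == pytest.approx(44.0)
        assert isis[-1] == pytest.approx(86.0)
        assert np.diff(isis) == pytest.approx(np.full(14, 6.0))

    @settings(derandomize=True, max_examples=30)
    @given(stdt=st.floats(2.1, 200))
    def test_median_equals_initial_threshold(self, stdt):
        isis = calibration_isis(stdt)
        assert np.median(isis) == pytest.approx(stdt)
        assert len(isis) == 15

    def test_rejects_low_threshold(self):
        with pytest.raises(ValueError, match="staircase"):
            calibration_isis(2.0)


class TestCalibrationSession:
    def test_trial_total_is_300(self, rng):
        counts = run_calibration_session(
            Observer(t50=40, scale=8), calibration_isis(40.0), reps=20, rng=rng
        )
        assert counts.shape == (15,)
        assert 15 * 20 == 300  # design arithmetic
        assert np.all(counts >= 0) and np.all(counts <= 20)

    def test_step_observer_is_all_or_nothing(self, rng):
        counts = run_calibration_session(
            _step_observer(40.0), calibration_isis(40.0), reps=20, rng=rng
        )
        isis = calibration_isis(40.0)
        assert np.all(counts[isis < 40] == 0)
        assert np.all(counts[isis > 40] == 20)


class TestFitLogistic:
    def test_noiseless_recovery(self):
        isis = calibration_isis(40.0)
        p = expit((isis - 40.0) / 8.0)
        fit = fit_logistic(isis, p * 20, 20)
        assert fit.t50 == pytest.approx(40.0, abs=1e-4)
        assert fit.scale == pytest.approx(8.0, abs=1e-4)
        assert fit.mse == pytest.approx(0.0, abs=1e-10)
        assert fit.t01 == pytest.approx(40 - 8 * LN99, abs=1e-3)

    def test_threshold_identity(self, rng):
        isis = calibration_isis(35.0)
        obs = Observer(t50=35, scale=6)
        counts = run_calibration_session(obs, isis, rng=rng)
        fit = fit_logistic(isis, counts, 20)
        assert fit.t99 - fit.t50 == pytest.approx(fit.t50 - fit.t01, abs=1e-9)

    def test_group_mean_identity_of_printed_thresholds(self):
        # T99 implied by the printed group means: 2 * 40.51 - 2.45
        assert 2 * 40.51 - 2.45 == pytest.approx(78.56, abs=0.011)

    def test_all_identical_responses_rejected(self):
        with pytest.raises(NonIdentifiableFit):
            fit_logistic(np.arange(5.0), np.zeros(5), 20)

    def test_quick_parameter_recovery(self):
        # reduced-size version of the recovery study (full run in acceptance)
        rng = np.random.default_rng(42)
        obs = Observer(t50=40, scale=8)
        isis = calibration_isis(40.0)
        errs = [
            abs(fit_logistic(isis, run_calibration_session(obs, isis, 20, rng), 20).t50 - 40)
            for _ in range(50)
        ]
        assert np.median(errs) < 2.0

    def test_residual_mse_below_binomial_bound(self):
        rng = np.random.default_rng(7)
        obs = Observer(t50=40, scale=8)
        isis = calibration_isis(40.0)
        p = expit((isis - 40) / 8)
        bound = np.mean(p * (1 - p)) / 20
        mses = [
            fit_logistic(isis, run_calibration_session(obs, isis, 20, rng), 20).mse
            for _ in range(50)
        ]
        assert np.mean(mses) < bound


class TestDesignISILevels:
    def test_plain_branch_spans_t01_t99(self):
        fit = PsychometricFit(t50=40.505, scale=(78.56 - 2.45) / (2 * LN99), mse=0, n_trials=300)
        levels = design_isi_levels(fit)
        assert levels[0] == pytest.approx(fit.t01)
        assert levels[-1] == pytest.approx(fit.t99)
        assert np.diff(levels) == pytest.approx(np.full(9, (fit.t99 - fit.t01) / 9))

    def test_shifted_branch_preserves_midpoint(self):
        # t01 = -5, t50 = 20, t99 = 45 -> floor at 1, top reduced to 39
        fit = PsychometricFit(t50=20, scale=25 / LN99, mse=0, n_trials=300)
        levels = design_isi_levels(fit)
        assert levels[0] == pytest.approx(1.0)
        assert levels[-1] == pytest.approx(39.0)
        assert (levels[4] + levels[5]) / 2 == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=40)
    @given(t50=st.floats(5, 120), scale=st.floats(0.5, 25))
    def test_midpoint_identity_both_branches(self, t50, scale):
        fit = PsychometricFit(t50=t50, scale=scale, mse=0, n_trials=300)
        try:
            levels = design_isi_levels(fit)
        except DesignCollapse:
            assert fit.t99 - (1 - fit.t01) <= 1
            return
        assert (levels[4] + levels[5]) / 2 == pytest.approx(t50, rel=1e-9)

    def test_collapse_coincides_with_threshold_floor(self):
        # the shifted top is 2*t50 - floor, so a collapsed design implies
        # t50 <= floor, which the precondition already rejects; the dedicated
        # DesignCollapse guard is defensive for non-default floors
        fit = PsychometricFit(t50=0.9, scale=30 / LN99, mse=0, n_trials=300)
        with pytest.raises(ValueError):
            design_isi_levels(fit)


class TestAllocateTrials:
    def test_canonical_allocation(self):
        counts = allocate_trials()
        assert counts.tolist() == [8, 13, 20, 27, 32, 32, 27, 20, 13, 8]

    def test_structure_invariants(self):
        counts = allocate_trials()
        assert counts.sum() == 200
        assert np.array_equal(counts, counts[::-1])  # symmetric
        assert np.all(np.diff(counts[:5]) >= 0)  # unimodal rise to the center
        assert counts[[1, 2, 3]].sum() == (200 - 2 * 8 - 2 * 32) // 2

    def test_design_container_validates(self):
        levels = np.linspace(2.45, 78.56, 10)
        design = ISIDesign(levels=levels, counts_per_run=allocate_trials(levels))
        assert design.run_trials == 200
        with pytest.raises(ValueError):
            ISIDesign(levels=levels[::-1], counts_per_run=allocate_trials())
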