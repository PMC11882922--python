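"""Psychophysical calibration: staircases, logistic fitting, and ISI design.

The calibration chain mirrors a standard somatosensory temporal discrimination
session. A halving-step intensity staircase finds the single-pulse detection
threshold (stimulation intensity is then twice threshold). An interleaved
up/down ISI staircase provides an initial STDT estimate. A 15-ISI constant
stimuli session (20 repetitions per ISI, 300 trials) samples the psychometric
function, to which a two-parameter logistic is fitted by binomial maximum
likelihood. From the fitted T01/T99 span, 10 equally spaced ISI levels are
derived for the main experiment, with a floor rule shifting the span toward
the STDT when T01 falls below 1 ms, and trials are allocated to levels along a
discretized normal profile anchored at 8 trials/run at the extreme levels and
32 trials/run at the two central levels (200 trials per run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, xlogy

from .observers import LN99, Observer, psychometric_p, simulate_detection, simulate_discrimination

__all__ = [
    "StaircaseConfig",
    "StaircaseTrace",
    "PsychometricFit",
    "ISIDesign",
    "StaircaseFailure",
    "NonIdentifiableFit",
    "DesignCollapse",
    "run_detection_staircase",
    "stimulus_intensity",
    "run_stdt_staircase",
    "calibration_isis",
    "run_calibration_session",
    "fit_logistic",
    "design_isi_levels",
    "allocate_trials",
]


class StaircaseFailure(RuntimeError):
    """A staircase progression exhausted its safety cap without a reversal."""


class NonIdentifiableFit(RuntimeError):
    """All responses identical: the logistic parameters are not identifiable."""


class DesignCollapse(ValueError):
    """The shifted ISI design has no room between the 1 ms floor and its top."""


@dataclass(frozen=True)
class StaircaseConfig:
    """Intensity staircase parameters (start 1 mA, first step 0.1 mA)."""

    start_intensity: float = 1.0
    initial_step: float = 0.1
    n_up_progressions: int = 3
    n_down_progressions: int = 3
    max_steps: int = 200

    def __post_init__(self) -> None:
        if self.initial_step <= 0:
            raise ValueError("initial_step must be positive")
        if self.n_up_progressions < 1 or self.n_down_progressions < 1:
            raise ValueError("progression counts must be >= 1")


@dataclass
class StaircaseTrace:
    """Every visited (value, response) pair plus the reversal values."""

    steps: list[tuple[float, bool]] = field(default_factory=list)
    reversals: list[float] = field(default_factory=list)
    estimate: float = float("nan")


@dataclass(frozen=True)
class PsychometricFit:
    """Two-parameter logistic fit with derived 1%/99% thresholds.

    ``t01 = t50 - scale ln 99`` and ``t99 = t50 + scale ln 99``, so
    ``t99 - t50 == t50 - t01`` holds by construction. ``mse`` is the mean over
    ISIs of the squared difference between observed and fitted proportions,
    reported as a post-fit diagnostic (the fit itself maximizes the binomial
    likelihood).
    """

    t50: float
    scale: float
    mse: float
    n_trials: int

    @property
    def t01(self) -> float:
        return self.t50 - self.scale * LN99

    @property
    def t99(self) -> float:
        return self.t50 + self.scale * LN99


@dataclass(frozen=True)
class ISIDesign:
    """10 equally spaced ISI levels with per-run trial counts summing to 200."""

    levels: np.ndarray
    counts_per_run: np.ndarray

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        counts = np.asarray(self.counts_per_run, dtype=int)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "counts_per_run", counts)
        if levels.shape != (10,) or counts.shape != (10,):
            raise ValueError("design requires 10 levels and 10 counts")
        diffs = np.diff(levels)
        if not np.all(diffs > 0):
            raise ValueError("levels must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=1e-9):
            raise ValueError("levels must be equally spaced")
        if counts.sum() != 200:
            raise ValueError("counts_per_run must sum to 200")

    @property
    def run_trials(self) -> int:
        return int(self.counts_per_run.sum())


def run_detection_staircase(
    obs: Observer,
    cfg: StaircaseConfig = StaircaseConfig(),
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.0,
) -> tuple[float, StaircaseTrace]:
    """Halving-step intensity staircase for the detection threshold.

    Starting at ``start_intensity`` the intensity increases in ``initial_step``
    increments until the observer reports feeling the pulse; the step is then
    halved and the direction reversed, for three up- and three down-progressions
    in total. Each progression ends at its reversal value (the first intensity
    at which the response changes); the threshold estimate is the arithmetic
    mean of the six reversal values.
    """
    if obs.det_threshold <= cfg.start_intensity:
        warnings.warn(
            "detection threshold at or below the staircase start; "
            "first ascending progression is degenerate",
            stacklevel=2,
        )
    trace = StaircaseTrace()
    value = cfg.start_intensity
    step = cfg.initial_step
    ascending = True
    n_prog = cfg.n_up_progressions + cfg.n_down_progressions
    for _ in range(n_prog):
        target = ascending  # ascending runs end on "felt", descending on "not felt"
        for _ in range(cfg.max_steps):
            value = value + step if ascending else value - step
            felt = simulate_detection(value, obs, noise_sd=noise_sd, rng=rng)
            trace.steps.append((value, felt))
            if felt == target:
                trace.reversals.append(value)
                break
        else:
            raise StaircaseFailure(
                f"no reversal within {cfg.max_steps} steps "
                f"({'ascending' if ascending else 'descending'} progression)"
            )
        step /= 2.0
        ascending = not ascending
    trace.estimate = float(np.mean(trace.reversals))
    return trace.estimate, trace


def stimulus_intensity(det_threshold_estimate: float) -> float:
    """Main-experiment intensity: twice the detection threshold estimate."""
    if det_threshold_estimate <= 0:
        raise ValueError("threshold estimate must be positive")
    return 2.0 * det_threshold_estimate


def run_stdt_staircase(
    obs: Observer,
    rng: np.random.Generator,
    ascending_start: float = 2.0,
    descending_start: float = 120.0,
    step: float = 5.0,
    max_steps: int = 500,
) -> tuple[float, list[StaircaseTrace]]:
    """Initial STDT estimate from three ascending and three descending ISI series.

    Ascending series start at ``ascending_start`` and increase by ``step`` until
    the percept first switches to "two"; descending series start at
    ``descending_start`` and decrease until the percept first switches to "one".
    Series are interleaved A,D,A,D,A,D and the estimate is the mean of the six
    stopping ISIs.
    """
    if not ascending_start < descending_start:
        raise ValueError("ascending_start must be below descending_start")
    if step <= 0:
        raise ValueError("step must be positive")
    traces: list[StaircaseTrace] = []
    stops: list[float] = []
    for series in range(6):
        ascending = series % 2 == 0
        isi = ascending_start if ascending else descending_start
        trace = StaircaseTrace()
        for _ in range(max_steps):
            felt_two = simulate_discrimination(max(isi, 0.0), obs, rng)
            trace.steps.append((isi, felt_two))
            if felt_two == ascending:  # "two" stops ascending, "one" stops descending
                trace.reversals.append(isi)
                break
            isi = isi + step if ascending else isi - step
            if isi < 0:
                isi = 0.0
        else:
            raise StaircaseFailure("ISI series exhausted its safety cap without a switch")
        trace.estimate = trace.reversals[0]
        stops.append(trace.estimate)
        traces.append(trace)
    return float(np.mean(stops)), traces


def calibration_isis(initial_stdt: float) -> np.ndarray:
    """15 equally spaced ISIs from 2 ms with the initial STDT as the 8th value.

    Spacing is ``(initial_stdt - 2) / 7``; the top value is ``2*initial_stdt - 2``.
    """
    if not initial_stdt > 2:
        raise ValueError(
            "initial_stdt must exceed 2 ms; re-run the STDT staircase "
            "(the 15-ISI grid starts at 2 ms with the STDT as its median)"
        )
    spacing = (initial_stdt - 2.0) / 7.0
    return 2.0 + spacing * np.arange(15)


def run_calibration_session(
    obs: Observer,
    isis: np.ndarray,
    reps: int = 20,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Count of "felt as two" responses out of ``reps`` per ISI (method of
    constant stimuli; default 15 ISIs x 20 repetitions = 300 trials)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    isis = np.asarray(isis, dtype=float)
    counts = np.empty(isis.shape[0], dtype=int)
    for i, isi in enumerate(isis):
        counts[i] = int(np.sum(simulate_discrimination(np.full(reps, isi), obs, rng)))
    return counts


def _logistic_nll(params: np.ndarray, isis: np.ndarray, k: np.ndarray, n: np.ndarray) -> float:
    t50, log_scale = params
    p = expit((isis - t50) / np.exp(log_scale))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.sum(xlogy(k, p) + xlogy(n - k, 1 - p)))


def fit_logistic(isis: np.ndarray, successes: np.ndarray, trials) -> PsychometricFit:
    """Binomial maximum-likelihood fit of the two-parameter logistic.

    Parameters are the threshold ``t50`` and the scale; T01/T99 follow from the
    ln(99) offsets. Deterministic given the data (Nelder-Mead with fixed
    tolerances from a moment-based start, then a BFGS polish).
    """
    isis = np.asarray(isis, dtype=float)
    k = np.asarray(successes, dtype=float)
    n = np.broadcast_to(np.asarray(trials, dtype=float), k.shape).copy()
    if isis.shape != k.shape:
        raise ValueError("isis and successes must have the same shape")
    if np.unique(isis).size < 2:
        raise ValueError("need >= 2 distinct ISIs")
    if np.all(k == 0) or np.all(k == n):
        raise NonIdentifiableFit("all responses identical; logistic fit is not identifiable")

    prop = k / n
    # moment start: interpolate the 50% crossing; scale from the sampled span
    order = np.argsort(isis)
    xs, ps = isis[order], prop[order]
    above = np.nonzero(ps >= 0.5)[0]
    if above.size and above[0] > 0:
        j = above[0]
        x0, x1, p0, p1 = xs[j - 1], xs[j], ps[j - 1], ps[j]
        t50_0 = x0 + (0.5 - p0) / max(p1 - p0, 1e-9) * (x1 - x0)
    else:
        t50_0 = float(np.median(xs))
    scale_0 = max((xs[-1] - xs[0]) / (2 * LN99), 1e-3)

    res = minimize(
        _logistic_nll,
        x0=np.array([t50_0, np.log(scale_0)]),
        args=(isis, k, n),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
    )
    res = minimize(
        _logistic_nll, x0=res.x, args=(isis, k, n), method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    t50, scale = float(res.x[0]), float(np.exp(res.x[1]))
    fitted = expit((isis - t50) / scale)
    mse = float(np.mean((prop - fitted) ** 2))
    return PsychometricFit(t50=t50, scale=scale, mse=mse, n_trials=int(n.sum()))


def design_isi_levels(fit: PsychometricFit, floor_ms: float = 1.0) -> np.ndarray:
    """10 equally spaced main-experiment ISI levels spanning T01..T99.

    When the fitted T01 falls below the 1 ms floor, the whole span is shifted
    symmetrically toward the STDT: the minimum is set to the floor and the
    maximum reduced by the same amount ``delta = floor - t01``, preserving equal
    spacing and the STDT as the exact midpoint of the levels.
    """
    if not fit.t50 > floor_ms:
        raise ValueError("fitted t50 must exceed the ISI floor")
    t01, t99 = fit.t01, fit.t99
    if t01 >= floor_ms:
        lo, hi = t01, t99
    else:
        delta = floor_ms - t01
        lo, hi = floor_ms, t99 - delta
        if hi <= floor_ms:
            raise DesignCollapse(
                "shifted design collapses (t99 - delta <= floor); participant "
                "would be excluded"
            )
    return np.linspace(lo, hi, 10)


def allocate_trials(levels: np.ndarray | None = None, run_trials: int = 200) -> np.ndarray:
    """Per-run trial counts over the 10 ISI levels.

    Counts follow a normal-density profile over level index, anchored at the
    printed design values: 8 trials/run at the extreme levels (1 and 10) and 32
    at the central levels (5 and 6). The profile's width is the least-squares
    fit through the anchors (a Gaussian centered between levels 5 and 6), and
    the remaining 120 trials are distributed over levels 2-4 / 7-9
    proportionally to that density, rounded per side by largest remainder.
    Returns the canonical symmetric allocation [8, 13, 20, 27, 32, 32, 27, 20,
    13, 8].
    """
    if levels is not None and np.asarray(levels).shape != (10,):
        raise ValueError("expected 10 levels")
    anchor_outer, anchor_inner = 8.0, 32.0
    idx = np.arange(1, 11, dtype=float)
    center = 5.5
    # exact 2-point fit: ratio of anchors pins sigma, inner anchor pins amplitude
    d_outer, d_inner = 4.5, 0.5
    sigma2 = (d_outer**2 - d_inner**2) / (2.0 * np.log(anchor_inner / anchor_outer))
    amp = anchor_inner * np.exp(d_inner**2 / (2.0 * sigma2))
    density = amp * np.exp(-((idx - center) ** 2) / (2.0 * sigma2))

    counts = np.zeros(10, dtype=int)
    counts[[0, 9]] = int(anchor_outer)
    counts[[4, 5]] = int(anchor_inner)
    per_side = (run_trials - 2 * int(anchor_outer) - 2 * int(anchor_inner)) // 2
    side = density[1:4]  # levels 2-4; mirrored onto 7-9
    scaled = side / side.sum() * per_side
    floor = np.floor(scaled).astype(int)
    remainder = per_side - floor.sum()
    order = np.argsort(-(scaled - floor))
    floor[order[:remainder]] += 1
    counts[1:4] = floor
    counts[6:9] = floor[::-1]
    assert counts.sum() == run_trials
    return counts
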