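"""Synthetic 64-channel EEG with known somatosensory ERP components.

The generator produces epoched (512 Hz, -100..600 ms) or continuous (2048 Hz)
data containing four canonical somatosensory evoked components — P50 (CP4),
N140 (peaking at 120 ms at C6 in this paradigm), P170 (FC2) and P300 (CPz) —
each modeled as a separable Gaussian spatial profile around its peak channel
times a Gaussian temporal profile around its peak latency. Only the P170
carries a percept-dependent amplitude: "felt as two" trials receive a larger
amplitude than "felt as one" trials, which places the maximal condition
difference inside the 129-178 ms window targeted by the group analysis.
Colored (1/f plus alpha) spatially correlated noise and stereotyped blinks
complete the forward model; ground truth is retained for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.fft import irfft, rfft, rfftfreq

from .layout import ChannelLayout

__all__ = [
    "ComponentSpec",
    "EpochSet",
    "default_components",
    "component_field",
    "signal_field",
    "effect_field",
    "generate_noise",
    "spatial_mixing",
    "epoch_sample_indices",
    "simulate_subject_epochs",
    "inject_blinks",
    "simulate_subject_continuous",
]

#: Default percept-dependent P170 amplitude difference ("two" minus "one"), uV.
DEFAULT_EFFECT_UV = 2.5
#: Default single-trial channel noise standard deviation (analysis band), uV.
DEFAULT_NOISE_UV = 6.0


@dataclass(frozen=True)
class ComponentSpec:
    """One separable space-time ERP component.

    ``amp_one``/``amp_two`` are the peak amplitudes (uV) on "felt as one" and
    "felt as two" trials; unmodulated components have equal amplitudes.
    ``spatial_sigma`` is in unit-disk layout distance, ``temporal_sigma`` in ms.
    """

    name: str
    peak_ms: float
    peak_channel: str
    spatial_sigma: float
    temporal_sigma: float
    amp_one: float
    amp_two: float

    def __post_init__(self) -> None:
        if self.spatial_sigma <= 0 or self.temporal_sigma <= 0:
            raise ValueError("spatial_sigma and temporal_sigma must be positive")


def default_components(effect_uv: float = DEFAULT_EFFECT_UV) -> list[ComponentSpec]:
    """The four stock components; only the P170 is percept-modulated.

    ``effect_uv`` is the "two" minus "one" P170 amplitude difference; 0 yields
    identically distributed conditions (the null configuration).
    """
    return [
        ComponentSpec("P50", 50.0, "CP4", 0.20, 12.0, 2.0, 2.0),
        ComponentSpec("N140", 120.0, "C6", 0.25, 15.0, -4.0, -4.0),
        ComponentSpec("P170", 170.0, "FC2", 0.25, 14.0, 3.0, 3.0 + effect_uv),
        ComponentSpec("P300", 300.0, "CPz", 0.35, 45.0, 5.0, 5.0),
    ]


def component_field(
    spec: ComponentSpec,
    layout: ChannelLayout,
    times_ms: np.ndarray,
    amp: float | None = None,
) -> np.ndarray:
    """Channels x samples pattern of one component at amplitude ``amp``.

    ``field[c, t] = amp * exp(-d(c)^2 / (2 sp^2)) * exp(-(t - peak)^2 / (2 st^2))``
    with ``d(c)`` the layout distance to the peak channel; the maximum is
    ``amp`` at (peak_channel, peak_ms). ``amp`` defaults to ``amp_two``.
    """
    if amp is None:
        amp = spec.amp_two
    d = layout.distances_to(spec.peak_channel)
    spatial = np.exp(-(d**2) / (2.0 * spec.spatial_sigma**2))
    t = np.asarray(times_ms, dtype=float)
    temporal = np.exp(-((t - spec.peak_ms) ** 2) / (2.0 * spec.temporal_sigma**2))
    return amp * spatial[:, None] * temporal[None, :]


def signal_field(
    components: list[ComponentSpec],
    layout: ChannelLayout,
    times_ms: np.ndarray,
    percept: str,
) -> np.ndarray:
    """Sum of all component fields with percept-conditional amplitudes."""
    out = np.zeros((layout.n_scalp, len(times_ms)))
    for spec in components:
        amp = spec.amp_two if percept == "two" else spec.amp_one
        out += component_field(spec, layout, times_ms, amp=amp)
    return out


def effect_field(
    components: list[ComponentSpec], layout: ChannelLayout, times_ms: np.ndarray
) -> np.ndarray:
    """Ground-truth condition difference ("two" minus "one"), channels x samples."""
    return signal_field(components, layout, times_ms, "two") - signal_field(
        components, layout, times_ms, "one"
    )


def spatial_mixing(layout: ChannelLayout, length_scale: float = 0.6) -> np.ndarray:
    """Cholesky factor of a squared-exponential inter-channel correlation."""
    d = np.linalg.norm(layout.pos2d[:, None, :] - layout.pos2d[None, :, :], axis=-1)
    cov = np.exp(-(d**2) / (2.0 * length_scale**2))
    return np.linalg.cholesky(cov + 1e-6 * np.eye(layout.n_scalp))


def generate_noise(
    nchan: int,
    nsamp: int,
    sfreq: float,
    rng: np.random.Generator,
    exponent: float = 1.0,
    alpha_power: float = 1.0,
    spatial_mix: np.ndarray | None = None,
    sd: float = 1.0,
) -> np.ndarray:
    """Colored, optionally spatially mixed noise (channels x samples).

    The target power spectrum is ``f^-exponent`` (flattened below 0.5 Hz to
    keep the DC region finite) plus a Gaussian alpha bump at 10 Hz whose
    height is ``alpha_power`` times the 1/f power at 10 Hz. Each channel is
    normalized to standard deviation ``sd`` before mixing; ``exponent=0``,
    ``alpha_power=0`` and identity mixing give plain white noise. Fully
    reproducible from ``rng``.
    """
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    white = rng.standard_normal((nchan, nsamp))
    if exponent == 0 and alpha_power == 0:
        shaped = white
    else:
        spec = rfft(white, axis=1)
        freqs = rfftfreq(nsamp, 1.0 / sfreq)
        f = np.maximum(freqs, 0.5)
        power = f**-exponent
        if alpha_power > 0:
            power = power + alpha_power * (10.0**-exponent if exponent else 1.0) * np.exp(
                -((freqs - 10.0) ** 2) / (2.0 * 1.5**2)
            )
        spec *= np.sqrt(power)[None, :]
        shaped = irfft(spec, n=nsamp, axis=1)
        shaped /= shaped.std(axis=1, keepdims=True)
    out = sd * shaped
    if spatial_mix is not None:
        out = spatial_mix @ out
    return out


def epoch_sample_indices(sfreq: float, tmin: float = -0.1, tmax: float = 0.6) -> np.ndarray:
    """Integer sample indices n with tmin*sfreq <= n <= tmax*sfreq.

    At 512 Hz and the standard -100..600 ms window these are -51..307, i.e.
    359 samples.
    """
    lo = math.ceil(tmin * sfreq - 1e-9)
    hi = math.floor(tmax * sfreq + 1e-9)
    return np.arange(lo, hi + 1)


@dataclass
class EpochSet:
    """Epoched EEG: channels x samples x trials with per-trial metadata."""

    data: np.ndarray
    sfreq: float
    tmin: float
    tmax: float
    layout: ChannelLayout
    meta: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = epoch_sample_indices(self.sfreq, self.tmin, self.tmax).size
        if self.data.shape[1] != expected:
            raise ValueError(
                f"sample count {self.data.shape[1]} inconsistent with window "
                f"({expected} expected at {self.sfreq} Hz)"
            )
        if len(self.meta) != self.data.shape[2]:
            raise ValueError("metadata rows must match trial count")

    @property
    def times(self) -> np.ndarray:
        return epoch_sample_indices(self.sfreq, self.tmin, self.tmax) / self.sfreq

    @property
    def times_ms(self) -> np.ndarray:
        return self.times * 1000.0

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    def condition_mean(self, percept: str) -> np.ndarray:
        sel = (self.meta["percept"] == percept).to_numpy()
        if not sel.any():
            raise ValueError(f"no trials with percept {percept!r}")
        return self.data[:, :, sel].mean(axis=2)


def simulate_subject_epochs(
    trials: pd.DataFrame,
    components: list[ComponentSpec],
    layout: ChannelLayout,
    rng: np.random.Generator,
    sfreq: float = 512.0,
    tmin: float = -0.1,
    tmax: float = 0.6,
    noise_sd: float = DEFAULT_NOISE_UV,
    noise_exponent: float = 1.0,
    alpha_power: float = 1.0,
    spatial_mix: np.ndarray | None | str = "auto",
) -> EpochSet:
    """Epoched data for one subject: percept-conditional signal plus fresh noise.

    ``trials`` must carry a ``percept`` column. The ground-truth effect field
    is stored in ``ground_truth["effect_field"]`` for recovery tests.
    """
    if "percept" not in trials:
        raise ValueError("trials must carry a 'percept' column")
    times_ms = epoch_sample_indices(sfreq, tmin, tmax) / sfreq * 1000.0
    if isinstance(spatial_mix, str):
        spatial_mix = spatial_mixing(layout) if noise_sd > 0 else None
    sig = {p: signal_field(components, layout, times_ms, p) for p in ("one", "two")}
    n_trials = len(trials)
    data = np.empty((layout.n_scalp, times_ms.size, n_trials))
    percepts = trials["percept"].to_numpy()
    for i in range(n_trials):
        trial = sig[percepts[i]].copy()
        if noise_sd > 0:
            trial += generate_noise(
                layout.n_scalp,
                times_ms.size,
                sfreq,
                rng,
                exponent=noise_exponent,
                alpha_power=alpha_power,
                spatial_mix=spatial_mix,
                sd=noise_sd,
            )
        data[:, :, i] = trial
    return EpochSet(
        data=data,
        sfreq=sfreq,
        tmin=tmin,
        tmax=tmax,
        layout=layout,
        meta=trials.reset_index(drop=True),
        ground_truth={"effect_field": effect_field(components, layout, times_ms)},
    )


def _blink_template(sfreq: float, duration_s: float = 0.25) -> np.ndarray:
    n = int(round(duration_s * sfreq))
    return np.hanning(n) ** 2


def inject_blinks(
    data: np.ndarray,
    sfreq: float,
    layout: ChannelLayout,
    rng: np.random.Generator,
    rate_per_min: float = 8.0,
    veog_amp: float = 300.0,
    scalp_gain: float = 0.4,
    veog_row: int = -2,
) -> tuple[np.ndarray, np.ndarray]:
    """Add stereotyped blinks to continuous data (scalp rows + EOG rows).

    The vEOG row receives the full-amplitude template; scalp channels receive
    it scaled by a frontal-weighted topography (anterior channels strongest,
    decaying exponentially toward posterior sites). Returns the contaminated
    copy and the blink onset samples; the input is left untouched so the
    blink-free ground truth is retained.
    """
    out = data.copy()
    nsamp = data.shape[1]
    if rate_per_min <= 0:
        return out, np.array([], dtype=int)
    tpl = _blink_template(sfreq) * 1.0
    n_blinks = rng.poisson(rate_per_min * nsamp / sfreq / 60.0)
    if n_blinks == 0:
        return out, np.array([], dtype=int)
    onsets = np.sort(rng.integers(0, max(nsamp - tpl.size, 1), size=n_blinks))
    # enforce a refractory period of one template length
    keep = [onsets[0]]
    for o in onsets[1:]:
        if o - keep[-1] > tpl.size:
            keep.append(o)
    onsets = np.array(keep)
    y = layout.pos2d[:, 1]  # +y is anterior in the projected montage
    topo = scalp_gain * np.exp((y - y.max()) / 0.2)
    for o in onsets:
        seg = slice(o, o + tpl.size)
        out[:layout.n_scalp, seg] += veog_amp * topo[:, None] * tpl[None, :]
        out[veog_row, seg] += veog_amp * tpl
    return out, onsets


def simulate_subject_continuous(
    trials: pd.DataFrame,
    components: list[ComponentSpec],
    layout: ChannelLayout,
    rng: np.random.Generator,
    sfreq: float = 2048.0,
    gap_s: float = 1.5,
    noise_sd: float = DEFAULT_NOISE_UV,
    blink_rate_per_min: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Continuous recording (scalp + vEOG + hEOG rows) embedding the trials.

    Events are spaced ``gap_s`` apart with 1 s of padding at both ends; each
    event adds the percept-conditional component field over the 700 ms
    post/pre window used downstream. Returns (data, event_samples) where the
    channel order is ``layout.names + layout.eog_names``.
    """
    n_trials = len(trials)
    n_chan = layout.n_scalp + len(layout.eog_names)
    duration = 2.0 + gap_s * n_trials
    nsamp = int(duration * sfreq)
    data = np.zeros((n_chan, nsamp))
    if noise_sd > 0:
        data[: layout.n_scalp] = generate_noise(
            layout.n_scalp, nsamp, sfreq, rng,
            spatial_mix=spatial_mixing(layout), sd=noise_sd,
        )
        data[layout.n_scalp:] = generate_noise(
            len(layout.eog_names), nsamp, sfreq, rng, spatial_mix=None, sd=noise_sd
        )
    idx = epoch_sample_indices(sfreq, -0.1, 0.6)
    times_ms = idx / sfreq * 1000.0
    sig = {p: signal_field(components, layout, times_ms, p) for p in ("one", "two")}
    event_samples = (1.0 * sfreq + gap_s * sfreq * np.arange(n_trials)).astype(int)
    percepts = trials["percept"].to_numpy()
    for s, p in zip(event_samples, percepts):
        data[: layout.n_scalp, s + idx[0] : s + idx[-1] + 1] += sig[p]
    if blink_rate_per_min > 0:
        data, _ = inject_blinks(
            data, sfreq, layout, rng, rate_per_min=blink_rate_per_min
        )
    return data, event_samples
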