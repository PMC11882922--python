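"""Preprocessing chain: filters, reference, blinks, epochs, scalp volumes."""

import numpy as np
import pandas as pd
import pytest

from stdtlab.eegsim import (
    default_components,
    effect_field,
    epoch_sample_indices,
    inject_blinks,
    simulate_subject_continuous,
)
from stdtlab.layout import ChannelLayout
from stdtlab.preprocess import (
    PreprocConfig,
    VolumeGrid,
    baseline_correct,
    downsample,
    epoch,
    filter_chain,
    lowpass_epochs,
    preprocess_continuous,
    reject_artifacts,
    remove_blinks,
    rereference_average,
    scalp_interpolate,
)

CFG = PreprocConfig()


def _sine(freq, sfreq=2048.0, dur=20.0):
    t = np.arange(int(dur * sfreq)) / sfreq
    return np.sin(2 * np.pi * freq * t)[None, :], t


class TestFilterChain:
    def test_notch_attenuates_line_frequency(self):
        x, t = _sine(50.0)
        y = filter_chain(x, 2048, CFG)
        core = slice(2048, -2048)  # ignore filtfilt edges
        atten = 20 * np.log10(np.abs(y[0, core]).max() / np.abs(x[0, core]).max())
        assert atten <= -40

    def test_passband_tone_preserved(self):
        x, t = _sine(5.0)
        y = filter_chain(x, 2048, CFG)
        core = slice(2048, -2048)
        assert np.abs(y[0, core]).max() == pytest.approx(1.0, rel=0.02)

    def test_dc_offset_removed(self):
        x = np.full((1, 2048 * 30), 7.3)
        y = filter_chain(x, 2048, CFG)
        assert np.abs(y[0, 2048:-2048].mean()) < 0.5

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            filter_chain(np.zeros((1, 50)), 2048, CFG)


class TestDownsample:
    def test_length_and_event_remap(self):
        x = np.zeros((2, 8192))
        y, fs, ev = downsample(x, 2048, 512, event_samples=np.array([2048, 4096]))
        assert fs == 512
        assert y.shape[-1] == 2048
        assert ev.tolist() == [512, 1024]

    def test_passband_amplitude_preserved(self):
        x, _ = _sine(5.0, dur=10)
        y, _ = downsample(x, 2048, 512)
        assert np.abs(y[0, 512:-512]).max() == pytest.approx(1.0, rel=0.02)

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            downsample(np.zeros((1, 1000)), 2048, 500)


class TestRereference:
    def test_scalp_mean_exactly_zero(self, rng):
        data = rng.standard_normal((66, 500))
        out = rereference_average(data, scalp_idx=slice(0, 64))
        assert np.allclose(out[:64].mean(axis=0), 0.0, atol=1e-12)
        assert np.array_equal(out[64:], data[64:])  # EOG untouched

    def test_idempotent(self, rng):
        data = rng.standard_normal((8, 100))
        once = rereference_average(data)
        twice = rereference_average(once)
        assert np.allclose(once, twice, atol=1e-12)

    def test_channel_differences_invariant(self, rng):
        data = rng.standard_normal((8, 100))
        out = rereference_average(data)
        assert np.allclose(out[3] - out[5], data[3] - data[5], atol=1e-12)


class TestRemoveBlinks:
    def _blinky(self, layout, seed=0):
        rng = np.random.default_rng(seed)
        clean = rng.standard_normal((66, 60 * 512)) * 5
        dirty, onsets = inject_blinks(clean, 512, layout, rng, rate_per_min=15)
        return clean, dirty, onsets

    def test_frontal_blink_variance_removed(self, layout):
        clean, dirty, onsets = self._blinky(layout)
        cleaned, rep = remove_blinks(dirty[:64], dirty[64], 512, CFG)
        fp = layout.index("Fp1")
        win = np.zeros(dirty.shape[1], dtype=bool)
        for o in onsets:
            win[o : o + 128] = True
        var_before = dirty[fp, win].var()
        var_after = cleaned[fp, win].var()
        assert var_after < 0.2 * var_before
        assert rep["peaks"].size >= 3

    def test_blink_free_data_pass_through(self, layout, rng):
        data = rng.standard_normal((66, 20_000)) * 5
        with pytest.warns(UserWarning, match="blinks"):
            cleaned, _ = remove_blinks(data[:64], data[64], 512, CFG)
        assert np.array_equal(cleaned, data[:64])

    def test_effect_amplitude_survives_projection(self, layout):
        # rank-1 removal of the frontal blink pattern must not eat the P170
        clean, dirty, _ = self._blinky(layout, seed=3)
        times = epoch_sample_indices(512.0) / 512.0 * 1000.0
        eff = effect_field(default_components(), layout, times)
        cleaned, _ = remove_blinks(dirty[:64], dirty[64], 512, CFG)
        # project the effect field through the same rank-1 removal
        topo = dirty[:64, :].copy()
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(dirty[64], height=CFG.blink_threshold_uv, distance=256)
        v = topo[:, peaks].mean(axis=1)
        v /= np.linalg.norm(v)
        eff_proj = eff - np.outer(v, v @ eff)
        # the effect's amplitude lives at its peak channel and latency
        ch, ts = np.unravel_index(np.argmax(np.abs(eff)), eff.shape)
        assert abs(eff_proj[ch, ts] - eff[ch, ts]) < 0.05 * abs(eff[ch, ts])


class TestEpoch:
    def test_sample_count_at_512(self, rng):
        data = rng.standard_normal((4, 5120))
        ep, keep = epoch(data, 512, np.array([1000, 2000, 3000]))
        assert ep.shape == (4, 359, 3)
        assert keep.all()

    def test_edge_events_dropped_with_warning(self, rng):
        data = rng.standard_normal((2, 2000))
        with pytest.warns(UserWarning, match="edge"):
            ep, keep = epoch(data, 512, np.array([0, 1000]))
        assert keep.tolist() == [False, True]
        assert ep.shape[2] == 1

    def test_epochs_slice_correct_samples(self):
        data = np.arange(4000, dtype=float)[None, :]
        ep, _ = epoch(data, 512, np.array([1000]))
        assert ep[0, 0, 0] == 1000 - 51
        assert ep[0, -1, 0] == 1000 + 307


class TestRejectArtifacts:
    def test_clean_epochs_untouched(self, layout, rng):
        ep = rng.standard_normal((64, 359, 20)) * 10
        keep, out, rep = reject_artifacts(ep, layout, CFG)
        assert keep.all()
        assert len(rep) == 0
        assert np.array_equal(out, ep)

    def test_persistently_bad_channel_interpolated(self, layout, rng):
        ep = rng.standard_normal((64, 359, 20)) * 10
        bad = layout.index("Cz")
        ep[bad, :, :6] += 500 * np.sin(np.linspace(0, 20, 359))[:, None]  # 30% of trials
        keep, out, rep = reject_artifacts(ep, layout, CFG)
        assert rep["channel"].tolist() == ["Cz"]
        assert keep.all()  # interpolation repairs every trial

    def test_interpolation_is_weighted_neighbor_average(self, layout, rng):
        from stdtlab.preprocess import _neighbor_weights

        ep = rng.standard_normal((64, 359, 10)) * 10
        bad = layout.index("Pz")
        ep[bad] += 1e4 * np.sin(np.linspace(0, 30, 359))[:, None]
        _, out, _ = reject_artifacts(ep, layout, CFG)
        neighbors, w = _neighbor_weights(layout, bad)
        expected = np.tensordot(w, ep[neighbors], axes=(0, 0))
        assert np.allclose(out[bad], expected, atol=1e-12)

    def test_isolated_artifact_trial_removed(self, layout, rng):
        ep = rng.standard_normal((64, 359, 30)) * 10
        ep[5, 100:140, 7] += 400  # one transient in one trial/channel
        keep, out, _ = reject_artifacts(ep, layout, CFG)
        assert not keep[7]
        assert keep.sum() == 29

    def test_majority_bad_channels_abort(self, layout, rng):
        ep = rng.standard_normal((64, 359, 10)) * 10
        ep[:40, 100:200, :] += 500  # transient artifacts on most channels
        with pytest.raises(RuntimeError):
            reject_artifacts(ep, layout, CFG)


class TestBaseline:
    def test_baseline_mean_exactly_zero(self, rng):
        times = epoch_sample_indices(512.0) / 512.0
        ep = rng.standard_normal((4, 359, 5)) + 3.0
        out = baseline_correct(ep, times)
        sel = (times >= -0.1) & (times <= 0.0)
        assert np.allclose(out[:, sel].mean(axis=1), 0.0, atol=1e-12)

    def test_constant_offset_epoch_becomes_zero(self):
        times = epoch_sample_indices(512.0) / 512.0
        ep = np.full((2, 359, 3), 4.2)
        assert np.allclose(baseline_correct(ep, times), 0.0)


class TestVolumeGrid:
    def test_constant_field_constant_inside_hull(self, layout, grid):
        vol = grid.interpolate(np.full((64, 5), 3.7))
        inside = vol[grid.mask]
        assert np.allclose(inside, 3.7, atol=1e-9)
        assert np.isnan(vol[~grid.mask]).all()

    def test_affine_field_recovered_exactly(self, layout, grid):
        a, b, c = 1.3, -0.7, 0.2
        chan = (a * layout.pos2d[:, 0] + b * layout.pos2d[:, 1] + c)[:, None]
        vol = grid.interpolate(chan)
        axis = np.linspace(-1, 1, 32)
        gx, gy = np.meshgrid(axis, axis, indexing="ij")
        expected = a * gx + b * gy + c
        assert np.allclose(vol[grid.mask, 0], expected[grid.mask], atol=1e-9)

    def test_electrode_on_grid_node_reproduced(self):
        # custom layout with one electrode exactly on a grid node
        axis = np.linspace(-1, 1, 32)
        pos = np.array([[-0.9, -0.9], [0.9, -0.9], [0.0, 0.95], [axis[16], axis[14]]])
        lay = ChannelLayout(names=("a", "b", "c", "d"), pos2d=pos)
        grid = VolumeGrid(lay)
        vals = np.array([[0.0], [0.0], [0.0], [5.0]])
        vol = grid.interpolate(vals)
        assert vol[16, 14, 0] == pytest.approx(5.0, abs=1e-9)

    def test_degenerate_layout_rejected(self):
        pos = np.column_stack([np.linspace(0, 1, 5), np.linspace(0, 1, 5)])
        lay = ChannelLayout(names=tuple("abcde"), pos2d=pos)
        with pytest.raises(ValueError):
            VolumeGrid(lay)

    def test_per_trial_volumes_share_shape(self, layout, rng):
        ep = rng.standard_normal((64, 7, 3))
        vols = scalp_interpolate(ep, layout)
        assert vols.shape == (3, 32, 32, 7)
        assert np.array_equal(np.isnan(vols[0, :, :, 0]), np.isnan(vols[2, :, :, 6]))


class TestEndToEnd:
    def test_recovered_erps_correlate_with_injected_components(self, layout):
        # full-session trial count (~185 kept trials, as in a real recording)
        rng = np.random.default_rng(6)
        trials = pd.DataFrame({"percept": ["one", "two"] * 92})
        comps = default_components()
        data, events = simulate_subject_continuous(
            trials, comps, layout, rng, noise_sd=6.0, blink_rate_per_min=8.0
        )
        epochs, kept, rep = preprocess_continuous(data, 2048.0, events, layout, CFG)
        assert kept.sum() >= 170
        times = epoch_sample_indices(512.0) / 512.0 * 1000.0
        erp = epochs.mean(axis=2)
        # average-referenced injected signal (reference changes absolute values)
        from stdtlab.eegsim import signal_field

        sig = 0.5 * (
            signal_field(comps, layout, times, "one")
            + signal_field(comps, layout, times, "two")
        )
        sig = sig - sig.mean(axis=0, keepdims=True)
        for c in comps:
            ch = layout.index(c.peak_channel)
            win = (times >= c.peak_ms - 3 * c.temporal_sigma) & (
                times <= c.peak_ms + 3 * c.temporal_sigma
            )
            r = np.corrcoef(erp[ch, win], sig[ch, win])[0, 1]
            assert r > 0.95, c.name
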