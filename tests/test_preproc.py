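import numpy as np
import pytest
from scipy import signal

from musetrf.errors import ConfigError, DataQualityError, InterpolationError
from musetrf.preproc import (
    EEGRecording,
    bandpass_and_resample,
    detect_bad_channels,
    interpolate_bads,
    preprocess_recording,
    rereference,
)
from musetrf.simulate import make_layout


def _recording(data, fs=500.0, n_channels=None, bad=frozenset()):
    n_channels = n_channels or data.shape[0]
    names, pos = make_layout(n_channels)
    return EEGRecording(
        data=data, fs=fs, channel_names=names, positions=pos, bad_channels=bad
    )


def _grid_recording(data, spacing=10.0, bad=frozenset()):
    """Regular planar grid montage (symmetric interior neighborhoods)."""
    side = int(np.sqrt(data.shape[0]))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pos = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(side * side)]) * spacing
    names = tuple(f"G{i:02d}" for i in range(side * side))
    return EEGRecording(
        data=data, fs=100.0, channel_names=names, positions=pos, bad_channels=bad
    )


def test_bandpass_attenuates_out_of_band():
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    data = np.vstack(
        [np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 0.2 * t), np.sin(2 * np.pi * 45 * t)]
    )
    names, pos = make_layout(8)
    rec = EEGRecording(data=np.tile(data, (3, 1))[:8], fs=fs, channel_names=names, positions=pos)
    out = bandpass_and_resample(rec, fs_out=100.0)
    assert out.fs == 100.0
    assert out.data.shape[1] == 1000
    rms = np.sqrt(np.mean(out.data**2, axis=1))
    assert rms[0] > 0.6  # 10 Hz passes
    assert rms[1] < 0.15  # 0.2 Hz suppressed
    assert rms[2] < 0.15  # 45 Hz suppressed


def test_resample_rejects_upsampling():
    rec = _recording(np.zeros((8, 1000)), fs=90.0)
    with pytest.raises(ConfigError):
        bandpass_and_resample(rec, fs_out=100.0)


def test_planted_high_variance_channel_detected():
    rng = np.random.default_rng(0)
    data = rng.standard_normal((32, 2000))
    data[7] *= np.sqrt(20.0)
    rec = _recording(data, fs=100.0)
    bads = detect_bad_channels(rec, z=2.75)
    assert rec.channel_names[7] in bads


def test_flat_channel_detected():
    rng = np.random.default_rng(1)
    data = rng.standard_normal((32, 2000))
    data[3] = 0.0
    bads = detect_bad_channels(_recording(data, fs=100.0), z=2.75)
    assert _recording(data, fs=100.0).channel_names[3] in bads


def test_detection_needs_enough_channels():
    with pytest.raises(ConfigError):
        detect_bad_channels(_recording(np.zeros((4, 100)), fs=100.0, n_channels=4))


def test_rereference_zero_mean_at_refs():
    rng = np.random.default_rng(2)
    rec = _recording(rng.standard_normal((64, 500)), fs=100.0)
    out = rereference(rec)
    refs = [out.index(n) for n in ("F9", "F10", "P9", "P10", "Iz")]
    np.testing.assert_allclose(out.data[refs].mean(axis=0), 0.0, atol=1e-12)


def test_rereference_common_mode_removal():
    rec = _recording(np.full((64, 50), 3.7), fs=100.0)
    out = rereference(rec)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_rereference_rejects_bad_reference():
    rec = _recording(np.zeros((64, 50)), fs=100.0, bad=frozenset({"Iz"}))
    with pytest.raises(ConfigError):
        rereference(rec)


def test_interpolation_exact_on_grid_linear_field():
    # symmetric neighborhood: the neighbor mean reproduces a linear field
    side, spacing = 6, 10.0
    g = np.array([0.05, -0.03, 0.0])
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pos = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(side * side)]) * spacing
    field = (pos @ g)[:, None] * np.linspace(1.0, 2.0, 40)[None, :]
    center = 2 * side + 2  # interior electrode
    rec = _grid_recording(field.copy(), spacing=spacing,
                          bad=frozenset({f"G{center:02d}"}))
    out = interpolate_bads(rec, radius_mm=18.0)
    gradient_step = np.linalg.norm(g) * spacing
    err = np.abs(out.data[center] - field[center]).max()
    assert err < 0.1 * gradient_step
    assert not out.bad_channels


def test_interpolation_bounded_on_hemisphere():
    names, pos = make_layout(64)
    g = np.array([0.05, -0.03, 0.02])
    field = (pos @ g)[:, None] * np.ones((1, 20))
    nbr_dist = 14.0
    for ch in ("Cz", "Pz"):
        rec = EEGRecording(data=field.copy(), fs=100.0, channel_names=names,
                           positions=pos, bad_channels=frozenset({ch}))
        out = interpolate_bads(rec, radius_mm=18.0)
        i = rec.index(ch)
        assert np.abs(out.data[i] - field[i]).max() < 0.6 * np.linalg.norm(g) * nbr_dist


def test_isolated_bad_channel_errors():
    data = np.zeros((9, 30))
    rec = _grid_recording(data, spacing=100.0, bad=frozenset({"G04"}))
    with pytest.raises(InterpolationError):
        interpolate_bads(rec, radius_mm=18.0)


def test_preprocess_recording_full_run():
    rng = np.random.default_rng(5)
    data = rng.standard_normal((64, 4000))
    data[10] *= np.sqrt(25.0)
    rec = _recording(data, fs=200.0)
    calls = []

    def hook(r):
        calls.append(r.bad_channels)
        return r

    out = preprocess_recording(rec, fs_out=100.0, denoise_hook=hook)
    assert out.fs == 100.0
    assert calls and rec.channel_names[10] in calls[0]
    assert not out.bad_channels  # interpolated away
    # variance of the repaired channel is back in family
    assert out.data[10].std() < 3 * np.median(out.data.std(axis=1))
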