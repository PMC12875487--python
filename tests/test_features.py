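import numpy as np
import pytest

from musetrf.errors import AlignmentError, FormatError
from musetrf.features import (
    FeatureMatrix,
    acoustic_regressors,
    build_feature_matrix,
    event_regressors,
    synthesize_audio,
)
from musetrf.infodyn import InfoEstimates
from musetrf.midi import derive_viewpoints

from conftest import make_melody


def _info_for(mel, fill=1.5):
    n = len(mel)
    return InfoEstimates(
        melody_id=mel.id,
        onsets=mel.onsets,
        Sp=np.full(n, fill),
        Ep=np.full(n, fill + 1),
        St=np.concatenate([[np.nan, np.nan], np.full(n - 2, fill + 2)]),
        Et=np.concatenate([[np.nan, np.nan], np.full(n - 2, fill + 3)]),
    )


def test_event_regressors_impulse_placement(simple_melody):
    info = _info_for(simple_melody)
    intervals = derive_viewpoints(simple_melody)[2]
    fm = event_regressors(simple_melody, info, intervals, fs=100.0)
    on = fm.column("onset")
    expected = np.round(simple_melody.onsets * 100).astype(int)
    np.testing.assert_array_equal(np.flatnonzero(on), expected)
    np.testing.assert_array_equal(fm.onset_samples, expected)
    # everything else zero between onsets
    sp = fm.column("Sp")
    assert sp[expected].tolist() == [1.5] * len(simple_melody)
    assert np.count_nonzero(sp) == len(simple_melody)


def test_event_regressors_units_and_nan_handling(simple_melody):
    info = _info_for(simple_melody)
    intervals = derive_viewpoints(simple_melody)[2]
    fm = event_regressors(simple_melody, info, intervals, fs=100.0)
    ioi = fm.column("ioi")[fm.onset_samples]
    assert ioi[0] == 0.0  # undefined first note contributes nothing
    assert ioi[1] == pytest.approx(300.0)  # milliseconds
    st = fm.column("St")[fm.onset_samples]
    assert st[0] == 0.0 and st[1] == 0.0 and st[2] == 3.5


def test_event_regressors_length_mismatch(simple_melody):
    intervals = derive_viewpoints(simple_melody)[2]
    short = _info_for(make_melody([60, 62, 64], [0.3, 0.3], mid=simple_melody.id))
    with pytest.raises(AlignmentError):
        event_regressors(simple_melody, short, intervals)


def test_audio_support_and_normalization(simple_melody):
    sr = 8000.0
    wave = synthesize_audio(simple_melody, sr=sr)
    assert np.max(np.abs(wave)) == pytest.approx(1.0)
    first = simple_melody.notes[0]
    # exactly zero before the first onset
    assert np.all(wave[: int(first.onset * sr)] == 0)
    # silent in a gap between note end and next onset, if one exists
    n0_end = int((first.onset + first.duration) * sr) + 1
    n1_start = int(simple_melody.notes[1].onset * sr)
    if n1_start > n0_end + 10:
        assert np.max(np.abs(wave[n0_end + 5 : n1_start - 5])) < 1e-12


def test_acoustic_regressors_track_onsets(simple_melody):
    sr = 8000.0
    wave = synthesize_audio(simple_melody, sr=sr)
    fm = acoustic_regressors(wave, sr, fs_out=100.0, n_bands=8, fmax=3500.0)
    flux = fm.column("spectral_flux")
    assert np.all(flux >= 0)
    # flux peaks should sit near note onsets
    onset_samples = np.round(simple_melody.onsets * 100).astype(int)
    top = np.argsort(flux)[-len(onset_samples):]
    dist = np.abs(top[:, None] - onset_samples[None, :]).min(axis=1)
    assert np.median(dist) <= 3


def test_acoustic_regressors_rejects_stereo():
    with pytest.raises(FormatError):
        acoustic_regressors(np.zeros((2, 100)), 8000.0)


def test_normalize_unit_rms():
    values = np.zeros((100, 2))
    values[10, 0] = 4.0
    fm = FeatureMatrix(values=values, names=("a", "b"), fs=100.0)
    out = fm.normalize()
    assert np.sqrt(np.mean(out.column("a") ** 2)) == pytest.approx(1.0)
    assert np.all(out.column("b") == 0)  # all-zero column untouched


def test_build_feature_matrix_column_order(simple_melody):
    info = _info_for(simple_melody)
    intervals = derive_viewpoints(simple_melody)[2]
    fm = build_feature_matrix(
        simple_melody, info, intervals, audio_sr=8000.0, n_bands=8
    )
    assert fm.names == ("onset", "spectral_flux", "ioi", "ipi", "Sp", "St", "Ep", "Et")
    full = build_feature_matrix(
        simple_melody, info, intervals, audio_sr=8000.0, n_bands=8,
        include_envelope=True,
    )
    assert "envelope" in full.names and "env_derivative" in full.names


def test_hstack_shape_check(simple_melody):
    info = _info_for(simple_melody)
    intervals = derive_viewpoints(simple_melody)[2]
    fm = event_regressors(simple_melody, info, intervals)
    other = FeatureMatrix(values=np.zeros((fm.n_samples + 1, 1)), names=("x",), fs=100.0)
    with pytest.raises(AlignmentError):
        fm.hstack(other)
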