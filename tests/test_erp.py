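import numpy as np
import pytest

from musetrf.erp import (
    EpochSet,
    average_erp,
    channel_adjacency,
    cluster_permutation,
    concatenate,
    epoch,
    quantile_split,
    reject_trials,
)
from musetrf.errors import ConfigError, DataQualityWarning
from musetrf.simulate import make_layout

from conftest import make_melody


def _melody(n_notes=30, ioi=0.5):
    return make_melody([60 + (i % 5) for i in range(n_notes)], [ioi] * (n_notes - 1),
                       mid="erp_mel")


def test_epoch_extraction_and_baseline():
    fs = 100.0
    mel = _melody(10, ioi=0.8)
    T = int((mel.total_duration + 1.0) * fs)
    eeg = np.zeros((2, T))
    # constant offset must vanish after baseline correction
    eeg[0] = 5.0
    # a spike 100 ms after the 4th onset
    c = int(round(mel.onsets[3] * fs)) + 10
    eeg[1, c] = 3.0
    es = epoch(eeg, mel, fs=fs)
    assert es.epochs.shape[1:] == (2, 61)
    assert es.times[0] == pytest.approx(-0.1) and es.times[-1] == pytest.approx(0.5)
    np.testing.assert_allclose(es.epochs[:, 0, :], 0.0, atol=1e-12)
    trial3 = es.epochs[es.labels.index[es.labels["note_index"] == 3][0]]
    t_idx = np.argmin(np.abs(es.times - 0.1))
    assert trial3[1, t_idx] == pytest.approx(3.0)


def test_epoch_skips_boundary_notes():
    fs = 100.0
    mel = _melody(6, ioi=0.3)
    T = int(round(mel.onsets[-1] * fs)) + 10  # too short for the last epochs
    es = epoch(np.zeros((2, T)), mel, fs=fs)
    assert es.n_skipped >= 1
    assert len(es) + es.n_skipped == 6


def test_trim_window():
    mel = _melody(8, ioi=0.8)
    eeg = np.zeros((2, int((mel.total_duration + 1) * 100)))
    es = epoch(eeg, mel).trim()
    assert es.times[0] == pytest.approx(-0.05) and es.times[-1] == pytest.approx(0.4)
    assert es.epochs.shape[2] == 46


def test_reject_trials_drops_outliers():
    rng = np.random.default_rng(0)
    mel = _melody(40, ioi=0.7)
    eeg = rng.standard_normal((3, int((mel.total_duration + 1) * 100)))
    es = epoch(eeg, mel)
    bad_note = int(es.labels.loc[5, "note_index"])
    es.epochs[5] *= 20.0
    out = reject_trials(es, z=2.5)
    assert len(out) < len(es)
    assert bad_note not in out.labels["note_index"].tolist()


def test_reject_trials_needs_enough_trials():
    mel = _melody(5, ioi=0.8)
    es = epoch(np.zeros((2, int((mel.total_duration + 1) * 100))), mel)
    with pytest.raises(ConfigError):
        reject_trials(es)


def test_quantile_split_counts_and_ties():
    mel = _melody(20, ioi=0.6)
    eeg = np.zeros((2, int((mel.total_duration + 1) * 100)))
    es = epoch(eeg, mel)
    surprise = np.arange(20, dtype=float)
    present = es.labels["note_index"].tolist()  # boundary notes are skipped
    k = max(1, round(0.2 * len(present)))
    out = quantile_split(es, {"erp_mel": surprise}, q=0.2)
    counts = out.labels["quantile"].value_counts()
    assert counts["highS"] == k and counts["lowS"] == k
    assert set(out.labels.loc[out.labels["quantile"] == "highS", "note_index"]) == set(
        sorted(present)[-k:]
    )
    # all-equal surprises: stable sort labels earliest notes low, latest high
    tied = quantile_split(es, {"erp_mel": np.ones(20)}, q=0.2)
    assert set(tied.labels.loc[tied.labels["quantile"] == "lowS", "note_index"]) == set(
        sorted(present)[:k]
    )


def test_quantile_split_validates_q():
    mel = _melody(10, ioi=0.6)
    es = epoch(np.zeros((2, int((mel.total_duration + 1) * 100))), mel)
    with pytest.raises(ConfigError):
        quantile_split(es, {"erp_mel": np.ones(10)}, q=0.7)


def test_average_erp_selects_labels():
    mel = _melody(10, ioi=0.6)
    eeg = np.zeros((1, int((mel.total_duration + 1) * 100)))
    es = epoch(eeg, mel)
    es.epochs[:5] += 1.0
    es.labels.loc[:4, "quantile"] = "highS"
    avg = average_erp(es, "highS")
    np.testing.assert_allclose(avg, 1.0)
    with pytest.raises(ConfigError):
        average_erp(es, "absent")


def test_channel_adjacency_radius():
    _, pos = make_layout(32)
    adj = channel_adjacency(pos, radius_mm=30.0)
    assert adj.shape == (32, 32)
    assert (adj != adj.T).nnz == 0  # symmetric
    assert adj.diagonal().sum() == 0


def test_cluster_permutation_detects_planted_effect():
    rng = np.random.default_rng(1)
    _, pos = make_layout(16)
    adj = channel_adjacency(pos, 30.0)
    a = rng.standard_normal((12, 16, 46))
    b = rng.standard_normal((12, 16, 46))
    ch = np.argsort(np.linalg.norm(pos - pos[0], axis=1))[:5]
    a[:, ch[:, None], 20:35] += 1.5
    res = cluster_permutation(a, b, adj, n_perm=300, seed=0)
    assert res and res[0].p < 0.05 and res[0].polarity == 1
    assert set(np.unique(res[0].channels)) & set(ch.tolist())
    assert res[0].time_indices.min() >= 15 and res[0].time_indices.max() <= 40


def test_cluster_permutation_matches_mne_masses():
    """Observed cluster masses agree with the mne reference implementation."""
    mne = pytest.importorskip("mne")
    from scipy import stats

    rng = np.random.default_rng(2)
    _, pos = make_layout(12)
    adj = channel_adjacency(pos, 30.0)
    n = 10
    a = rng.standard_normal((n, 12, 30))
    b = rng.standard_normal((n, 12, 30))
    a[:, :4, 10:20] += 0.8
    res = cluster_permutation(a, b, adj, n_perm=200, min_channels=1, seed=0)

    d = np.transpose(a - b, (0, 2, 1))  # mne wants obs × time × space
    thr = stats.t.ppf(1 - 0.025, n - 1)
    t_obs, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
        d, threshold=thr, n_permutations=24, adjacency=adj.tocoo().tocsr(),
        tail=1, out_type="mask", seed=1, verbose=False,
    )
    mne_masses = sorted(float(t_obs[c].sum()) for c in clusters)
    ours = sorted(c.mass for c in res if c.polarity == 1)
    assert ours == pytest.approx(mne_masses, rel=1e-9)


def test_cluster_permutation_warns_small_n():
    rng = np.random.default_rng(3)
    _, pos = make_layout(8)
    adj = channel_adjacency(pos, 30.0)
    a = rng.standard_normal((4, 8, 20))
    with pytest.warns(DataQualityWarning):
        cluster_permutation(a, np.zeros_like(a), adj, n_perm=50, seed=0)


def test_cluster_permutation_shape_check():
    _, pos = make_layout(8)
    adj = channel_adjacency(pos, 30.0)
    with pytest.raises(ConfigError):
        cluster_permutation(np.zeros((5, 8, 10)), np.zeros((5, 8, 11)), adj)
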