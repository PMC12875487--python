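import numpy as np
import pandas as pd
import pytest

from musetrf.errors import AlignmentError, ConfigError, PowerWarning
from musetrf.features import FeatureMatrix
from musetrf.trf import AccuracyTable
from musetrf.vp import (
    REDUCED_MODELS,
    DeltaR,
    ReducedSpec,
    delta_r,
    group_stats,
    roi_mean,
    select_roi,
    shuffle_features,
)


def _feature_matrix(rng, T=300, n_notes=20):
    vals = np.zeros((T, 3))
    on = np.sort(rng.choice(np.arange(5, T - 5), n_notes, replace=False))
    vals[on, 0] = 1.0
    vals[on, 1] = rng.normal(2.0, 1.0, n_notes)
    vals[:, 2] = rng.standard_normal(T)  # continuous column
    return FeatureMatrix(
        values=vals, names=("onset", "St", "spectral_flux"), fs=100.0,
        melody_id="melA", onset_samples=on,
    )


def _table(r, tag="full"):
    S, M, C = r.shape
    return AccuracyTable(
        r=r, model_tag=tag,
        subjects=tuple(f"s{i}" for i in range(S)),
        melodies=tuple(f"m{i}" for i in range(M)),
        lambdas=np.ones(S),
    )


def test_standard_reduced_models():
    assert set(REDUCED_MODELS) == {"highlevel", "timing", "pitch", "ioi", "ipi"}
    assert ReducedSpec.standard("timing").features_to_shuffle == ("St", "Et")
    with pytest.raises(ConfigError):
        ReducedSpec.standard("nope")


def test_shuffle_permutes_amplitudes_in_place():
    rng = np.random.default_rng(0)
    fm = _feature_matrix(rng)
    spec = ReducedSpec(name="x", features_to_shuffle=("St",), seed=1)
    out = shuffle_features(fm, spec)
    on = fm.onset_samples
    assert sorted(out.values[on, 1]) == pytest.approx(sorted(fm.values[on, 1]))
    assert not np.array_equal(out.values[on, 1], fm.values[on, 1])
    # onset column and off-onset samples untouched
    np.testing.assert_array_equal(out.values[:, 0], fm.values[:, 0])
    mask = np.ones(fm.n_samples, bool)
    mask[on] = False
    np.testing.assert_array_equal(out.values[mask], fm.values[mask])


def test_shuffle_deterministic_per_randomization():
    rng = np.random.default_rng(0)
    fm = _feature_matrix(rng)
    spec = ReducedSpec(name="x", features_to_shuffle=("St",), seed=1)
    a = shuffle_features(fm, spec, randomization=0)
    b = shuffle_features(fm, spec, randomization=0)
    c = shuffle_features(fm, spec, randomization=1)
    np.testing.assert_array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_shuffle_rejects_continuous_columns():
    rng = np.random.default_rng(0)
    fm = _feature_matrix(rng)
    spec = ReducedSpec(name="x", features_to_shuffle=("spectral_flux",))
    with pytest.raises(ConfigError):
        shuffle_features(fm, spec)


def test_delta_r_algebra_and_averaging():
    rng = np.random.default_rng(1)
    full = _table(rng.uniform(0, 1, (3, 4, 5)))
    red1 = _table(full.r - 0.1, tag="timing")
    red2 = _table(full.r - 0.3, tag="timing")
    dr = delta_r(full, [red1, red2])
    np.testing.assert_allclose(dr.dr, 0.2)
    assert dr.model == "timing"


def test_delta_r_misalignment():
    rng = np.random.default_rng(2)
    full = _table(rng.uniform(0, 1, (3, 4, 5)))
    red = _table(rng.uniform(0, 1, (3, 3, 5)), tag="timing")
    with pytest.raises(AlignmentError):
        delta_r(full, red)


def test_select_roi_top_channels_and_ties():
    r = np.zeros((1, 2, 8))
    r[0, :, 3] = 0.9
    r[0, :, 6] = 0.5
    r[0, :, [0, 1]] = 0.5  # tie with channel 6: lower index wins
    roi = select_roi(_table(r), fraction=0.25)
    assert roi.shape == (1, 2)
    assert roi[0].tolist() == [0, 3]


def test_roi_mean_tidy_layout():
    rng = np.random.default_rng(3)
    dr = DeltaR(
        dr=rng.standard_normal((2, 2, 4)),
        model="timing",
        subjects=("s0", "s1"),
        melodies=("mA", "mB"),
    )
    roi = np.array([[0, 1], [2, 3]])
    df = roi_mean(dr, roi, {"mA": "real", "mB": "shuffled"})
    assert list(df.columns) == ["subject", "melody", "condition", "model", "dr"]
    assert len(df) == 4
    expected = dr.dr[1, 0, [2, 3]].mean()
    got = df.query("subject == 's1' and melody == 'mA'")["dr"].iloc[0]
    assert got == pytest.approx(expected)


def _tidy(effect_timing_real=0.2, n_subj=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        for m in range(6):
            cond = "real" if m < 4 else "shuffled"
            for model in ("timing", "pitch"):
                mu = effect_timing_real if (model == "timing" and cond == "real") else 0.0
                rows.append((f"s{s}", f"m{m}", cond, model, mu + 0.05 * rng.standard_normal()))
    return pd.DataFrame(rows, columns=["subject", "melody", "condition", "model", "dr"])


def test_group_stats_detects_planted_interaction():
    df = _tidy(effect_timing_real=0.2)
    report = group_stats(df)
    assert report["n_subjects"] == 12
    assert report["wilcoxon"]["real:timing>0"]["p"] < 0.01
    assert report["wilcoxon"]["shuffled:pitch>0"]["p"] > 0.05
    assert report["lmm"]["condition:model"]["p"] < 0.01
    # the real:timing vs real:pitch contrast should stand out in the Tukey set
    tuk = {(
        d["cell_a"], d["cell_b"]): d["p_tukey"] for d in report["tukey"]}
    key = [k for k in tuk if set(k) == {"real:timing", "real:pitch"}][0]
    assert tuk[key] < 0.05


def test_group_stats_null_is_calm():
    df = _tidy(effect_timing_real=0.0, seed=5)
    report = group_stats(df)
    assert report["lmm"]["condition:model"]["p"] > 0.05


def test_group_stats_warns_when_underpowered():
    df = _tidy(n_subj=3)
    with pytest.warns(PowerWarning):
        group_stats(df)


def test_group_stats_requires_columns():
    with pytest.raises(ConfigError):
        group_stats(pd.DataFrame({"dr": [1.0]}))
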