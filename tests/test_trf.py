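import numpy as np
import pytest
from sklearn.linear_model import Ridge

from musetrf.errors import ConfigError, DataError
from musetrf.features import FeatureMatrix
from musetrf.simulate import _convolve_lagged, make_kernels, make_layout
from musetrf.trf import (
    LagWindow,
    build_design,
    build_super_subject,
    cross_validate,
    cross_validate_subjects,
    default_lambda_grid,
    fit_ridge,
    fit_trf,
)


def _impulse_features(rng, T=1500, n_mel=4, names=("onset", "St"), n_notes=50):
    feats = {}
    for m in range(n_mel):
        vals = np.zeros((T, len(names)))
        on = np.sort(rng.choice(np.arange(10, T - 60), n_notes, replace=False))
        vals[on, 0] = 1.0
        for j in range(1, len(names)):
            vals[on, j] = rng.normal(1.0, 0.5, n_notes)
        feats[f"m{m}"] = FeatureMatrix(
            values=vals, names=names, fs=100.0, melody_id=f"m{m}", onset_samples=on
        )
    return feats


def _rank1(kernel):
    peak = int(np.argmax(np.abs(kernel).max(axis=1)))
    curve = kernel[peak]
    j = int(np.argmax(np.abs(curve)))
    topo = kernel[:, j] / curve[j]
    return topo[:, None] * curve[None, :]


def _noiseless_eeg(feats, kernels, window):
    eeg = {}
    names = feats[next(iter(feats))].names
    for m, fm in feats.items():
        y = np.zeros((kernels[names[0]].shape[0], fm.n_samples))
        for fi, f in enumerate(names):
            k = _rank1(kernels[f])
            peak = int(np.argmax(np.abs(k).max(axis=1)))
            curve = k[peak]
            topo = k[:, int(np.argmax(np.abs(curve)))] / curve[int(np.argmax(np.abs(curve)))]
            y += topo[:, None] * _convolve_lagged(fm.values[:, fi], curve, window.lags)[None, :]
        eeg[m] = y
    return eeg


def test_lag_window_sampling():
    w = LagWindow(-50.0, 400.0, 100.0)
    assert w.n_lags == 46
    assert w.lags[0] == -5 and w.lags[-1] == 40
    assert w.times_ms[0] == -50.0 and w.times_ms[-1] == 400.0


def test_default_lambda_grid():
    grid = default_lambda_grid()
    assert grid[0] == 1e-4 and grid[-1] == 1e8 and len(grid) == 13


def test_build_design_shift_semantics():
    vals = np.zeros((10, 1))
    vals[4, 0] = 1.0
    fm = FeatureMatrix(values=vals, names=("x",), fs=100.0)
    w = LagWindow(-20.0, 20.0, 100.0)  # lags -2..2
    X = build_design(fm, w)
    assert X.shape == (10, 5)
    # positive lag: response follows the impulse
    assert X[6, 4] == 1.0 and X[2, 0] == 1.0 and X[4, 2] == 1.0


def test_fit_ridge_matches_sklearn():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((200, 12))
    Y = rng.standard_normal((200, 3))
    lam = 5.0
    W, bias = fit_ridge(X, Y, lam)
    sk = Ridge(alpha=lam, fit_intercept=True).fit(X, Y)
    np.testing.assert_allclose(W, sk.coef_.T, atol=1e-8)
    np.testing.assert_allclose(bias, sk.intercept_, atol=1e-8)


def test_fit_ridge_validation():
    with pytest.raises(ConfigError):
        fit_ridge(np.zeros((5, 2)), np.zeros(5), 0.0)
    bad = np.zeros((5, 2))
    bad[0, 0] = np.nan
    with pytest.raises(DataError):
        fit_ridge(bad, np.zeros(5), 1.0)


def test_noiseless_recovery_matches_planted_kernels():
    rng = np.random.default_rng(1)
    window = LagWindow()
    _, pos = make_layout(16)
    feats = _impulse_features(rng, T=2500, n_mel=4)
    kernels = make_kernels(("onset", "St"), pos, window, seed=3)
    eeg = _noiseless_eeg(feats, kernels, window)
    model = fit_trf(feats, eeg, lam=1e-8, window=window)
    for fi, f in enumerate(("onset", "St")):
        truth = _rank1(kernels[f])
        err = np.linalg.norm(model.weights[:, fi, :] - truth) / np.linalg.norm(truth)
        assert err < 1e-4


def test_fit_trf_matches_exact_least_squares():
    rng = np.random.default_rng(2)
    window = LagWindow(-20.0, 100.0, 100.0)
    feats = _impulse_features(rng, T=800, n_mel=3)
    eeg = {m: rng.standard_normal((4, fm.n_samples)) for m, fm in feats.items()}
    model = fit_trf(feats, eeg, lam=1e-10, window=window)
    X = np.vstack([build_design(fm, window) for fm in feats.values()])
    Y = np.vstack([eeg[m].T for m in feats])
    Xc, Yc = X - X.mean(0), Y - Y.mean(0)
    W = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
    np.testing.assert_allclose(
        model.weights, W.T.reshape(4, 2, window.n_lags), atol=1e-6
    )


def test_cross_validate_subjects_matches_naive_loop():
    """The batched eigendecomposition CV must equal fit-and-predict per fold."""
    rng = np.random.default_rng(3)
    window = LagWindow(-20.0, 100.0, 100.0)
    feats = _impulse_features(rng, T=600, n_mel=3)
    subjects = {
        s: {m: rng.standard_normal((3, fm.n_samples)) for m, fm in feats.items()}
        for s in ("s0", "s1")
    }
    gt = build_super_subject(subjects)
    lambdas = [1.0, 100.0]
    table = cross_validate_subjects(feats, subjects, gt, lambdas, window)

    # naive reference: per-melody centering (each melody is its own epoch),
    # direct ridge solve, prediction correlated with the ground truth
    mels = sorted(feats)
    centered = {m: (lambda X: X - X.mean(0))(build_design(feats[m], window)) for m in mels}
    for si, s in enumerate(table.subjects):
        lam = table.lambdas[si]
        for mi, m in enumerate(mels):
            train = [x for x in mels if x != m]
            X = np.vstack([centered[x] for x in train])
            Y = np.vstack(
                [subjects[s][x].T - subjects[s][x].T.mean(0) for x in train]
            )
            W = np.linalg.solve(X.T @ X + lam * np.eye(X.shape[1]), X.T @ Y)
            pred = centered[m] @ W
            for c in range(3):
                r_ref = np.corrcoef(pred[:, c], gt[m][c])[0, 1]
                assert table.r[si, mi, c] == pytest.approx(r_ref, abs=1e-8)


def test_lambda_selection_prefers_regularization_in_noise():
    rng = np.random.default_rng(4)
    window = LagWindow(-20.0, 100.0, 100.0)
    feats = _impulse_features(rng, T=800, n_mel=4)
    _, pos = make_layout(8)
    kernels = make_kernels(("onset", "St"), pos, window, seed=1)
    clean = _noiseless_eeg(feats, kernels, window)
    noisy = {m: y + 5 * rng.standard_normal(y.shape) for m, y in clean.items()}
    table, lam = cross_validate(feats, noisy, clean, window=window)
    assert lam >= 1.0  # tiny ridge would overfit this noise level


def test_super_subject_mean():
    a = {"m": np.ones((2, 5))}
    b = {"m": 3 * np.ones((2, 5))}
    gt = build_super_subject({"s0": a, "s1": b})
    np.testing.assert_allclose(gt["m"], 2.0)


def test_missing_melody_raises():
    rng = np.random.default_rng(5)
    feats = _impulse_features(rng, T=400, n_mel=3)
    subj = {"s0": {m: rng.standard_normal((2, feats[m].n_samples)) for m in feats}}
    del subj["s0"]["m1"]
    gt = {m: rng.standard_normal((2, feats[m].n_samples)) for m in feats}
    with pytest.raises(ConfigError):
        cross_validate_subjects(feats, subj, gt)
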