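"""Forward (encoding) temporal response functions by lagged ridge regression.

The EEG at time t is modelled as a weighted sum of time-lagged copies of the
stimulus regressors, EEG_c(t) ≈ Σ_f Σ_ℓ w_c(f, ℓ) · s_f(t − ℓ), with lags
spanning −50..+400 ms.  Weights are estimated per subject by ridge regression
pooled over the training melodies; prediction accuracy is the per-channel
Pearson correlation between the predicted EEG of a held-out melody and a
group-average "super-subject" ground-truth EEG, under leave-one-melody-out
cross-validation.  The ridge parameter is chosen per subject as the value
maximizing mean accuracy over folds and channels on a decade grid.

Cross-validation over many subjects shares the per-fold eigendecomposition of
the pooled design Gram matrix, so the full lambda grid costs little more than
a single solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .features import FeatureMatrix

__all__ = [
    "LagWindow",
    "TRFModel",
    "AccuracyTable",
    "build_design",
    "fit_ridge",
    "fit_trf",
    "cross_validate",
    "cross_validate_subjects",
    "build_super_subject",
    "default_lambda_grid",
]


def default_lambda_grid() -> np.ndarray:
    """Ridge parameters 10^−4 .. 10^8 by decades."""
    return 10.0 ** np.arange(-4, 9, dtype=float)


@dataclass(frozen=True)
class LagWindow:
    """Lag range in milliseconds; negative lags let the EEG precede the feature."""

    t_min_ms: float = -50.0
    t_max_ms: float = 400.0
    fs: float = 100.0

    @property
    def lags(self) -> np.ndarray:
        """Lag offsets in samples (e.g. −5..40 at the defaults)."""
        lo = int(round(self.t_min_ms / 1000.0 * self.fs))
        hi = int(round(self.t_max_ms / 1000.0 * self.fs))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def times_ms(self) -> np.ndarray:
        return self.lags / self.fs * 1000.0


@dataclass
class TRFModel:
    """Fitted ridge weights, channels × features × lags."""

    weights: np.ndarray
    bias: np.ndarray
    lam: float
    lag_window: LagWindow
    feature_names: tuple[str, ...]


@dataclass
class AccuracyTable:
    """Pearson prediction accuracies, subjects × melodies × channels."""

    r: np.ndarray
    model_tag: str
    subjects: tuple[str, ...]
    melodies: tuple[str, ...]
    lambdas: np.ndarray  # chosen ridge parameter per subject

    def __post_init__(self) -> None:
        if np.any(np.abs(self.r[np.isfinite(self.r)]) > 1 + 1e-9):
            raise DataError("correlations outside [-1, 1]")


def build_design(features: FeatureMatrix, window: LagWindow) -> np.ndarray:
    """Time-lagged design matrix, one column per (feature, lag), zero-padded."""
    if features.fs != window.fs:
        raise ConfigError(
            f"feature rate {features.fs} does not match lag window rate {window.fs}"
        )
    T, F = features.values.shape
    lags = window.lags
    X = np.zeros((T, F * len(lags)))
    for f in range(F):
        col = features.values[:, f]
        for li, lag in enumerate(lags):
            j = f * len(lags) + li
            if lag >= 0:
                X[lag:, j] = col[: T - lag] if lag else col
            else:
                X[:lag, j] = col[-lag:]
    return X


def fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form ridge per output channel; the intercept is not penalized.

    Returns (weights (columns × channels), bias (channels,)).
    """
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise DataError("non-finite values in design or response")
    if lam <= 0:
        raise ConfigError("lambda must be positive")
    Y = Y if Y.ndim == 2 else Y[:, None]
    xm, ym = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xm, Y - ym
    G = Xc.T @ Xc + lam * np.eye(X.shape[1])
    W = np.linalg.solve(G, Xc.T @ Yc)
    bias = ym - xm @ W
    return W, bias


def fit_trf(
    features: Mapping[str, FeatureMatrix],
    eeg: Mapping[str, np.ndarray],
    lam: float,
    window: LagWindow,
) -> TRFModel:
    """Fit one TRF on all melodies pooled; ``eeg`` maps melody → channels × samples."""
    mels = sorted(features)
    names = features[mels[0]].names
    Xs, Ys = [], []
    for m in mels:
        X = build_design(features[m], window)
        Y = eeg[m].T
        if len(Y) != len(X):
            raise ConfigError(f"melody {m!r}: EEG/feature sample mismatch")
        Xs.append(X)
        Ys.append(Y)
    W, bias = fit_ridge(np.vstack(Xs), np.vstack(Ys), lam)
    C = W.shape[1]
    weights = W.T.reshape(C, len(names), window.n_lags)
    return TRFModel(weights=weights, bias=bias, lam=lam, lag_window=window, feature_names=names)


def build_super_subject(
    eeg_all_subjects: Mapping[str, Mapping[str, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Sample-wise mean EEG across subjects, per melody (the ground-truth signal)."""
    melodies: dict[str, list[np.ndarray]] = {}
    for per_mel in eeg_all_subjects.values():
        for mid, arr in per_mel.items():
            melodies.setdefault(mid, []).append(arr)
    if not melodies:
        raise DataError("no EEG data supplied")
    out = {}
    for mid, arrs in melodies.items():
        if not arrs:
            raise DataError(f"no subject has melody {mid!r}")
        out[mid] = np.mean(arrs, axis=0)
    return out


def cross_validate_subjects(
    features: Mapping[str, FeatureMatrix],
    eeg_by_subject: Mapping[str, Mapping[str, np.ndarray]],
    eeg_ground_truth: Mapping[str, np.ndarray],
    lambdas: Sequence[float] | None = None,
    window: LagWindow | None = None,
    model_tag: str = "full",
) -> AccuracyTable:
    """Leave-one-melody-out accuracies for every subject against the ground truth.

    For each held-out melody, each subject's TRF is trained on that subject's
    remaining melodies (real and shuffled pooled); the held-out prediction is
    correlated per channel with the super-subject EEG.  One lambda per subject
    is selected by mean accuracy over folds and channels; the returned table
    holds each subject's accuracies at their selected lambda.
    """
    window = window or LagWindow()
    lambdas = np.asarray(lambdas if lambdas is not None else default_lambda_grid(), float)
    mels = tuple(sorted(features))
    if len(mels) < 3:
        raise ConfigError("need at least 3 melodies for leave-one-out CV")
    subjects = tuple(sorted(eeg_by_subject))
    S = len(subjects)

    X: dict[str, np.ndarray] = {}
    G: dict[str, np.ndarray] = {}
    Y: dict[str, np.ndarray] = {}
    B: dict[str, np.ndarray] = {}
    gt: dict[str, np.ndarray] = {}
    gtn: dict[str, np.ndarray] = {}
    C = None
    for m in mels:
        Xm = build_design(features[m], window)
        Xm = Xm - Xm.mean(axis=0)
        X[m] = Xm
        G[m] = Xm.T @ Xm
        ys = []
        for s in subjects:
            if m not in eeg_by_subject[s]:
                raise ConfigError(f"subject {s!r} is missing melody {m!r}")
            y = eeg_by_subject[s][m].T.astype(float)
            if len(y) != len(Xm):
                raise ConfigError(f"melody {m!r}: EEG/feature sample mismatch")
            ys.append(y - y.mean(axis=0))
        if C is None:
            C = ys[0].shape[1]
        Y[m] = np.hstack(ys)  # T × (S·C)
        B[m] = Xm.T @ Y[m]
        g = eeg_ground_truth[m].T.astype(float)
        g = g - g.mean(axis=0)
        gt[m] = g
        gtn[m] = np.linalg.norm(g, axis=0)

    Gtot = sum(G.values())
    Btot = sum(B.values())
    D = Gtot.shape[0]
    r_all = np.zeros((len(lambdas), S, len(mels), C))
    for mi, m in enumerate(mels):
        s_eig, V = np.linalg.eigh(Gtot - G[m])
        s_eig = np.clip(s_eig, 0.0, None)
        U = V.T @ (Btot - B[m])
        P = X[m] @ V
        Gt = P.T @ P
        g = P.T @ gt[m]
        for li, lam in enumerate(lambdas):
            Z = U / (s_eig + lam)[:, None]
            sq = np.einsum("ds,ds->s", Z, Gt @ Z).reshape(S, C)
            num = np.einsum("dsc,dc->sc", Z.reshape(D, S, C), g)
            denom = np.sqrt(np.clip(sq, 0.0, None)) * gtn[m][None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            r_all[li, :, mi, :] = np.clip(r, -1.0, 1.0)

    mean_r = r_all.mean(axis=(2, 3))  # lambdas × subjects
    best = np.argmax(mean_r, axis=0)
    r = np.stack([r_all[best[si], si] for si in range(S)])
    return AccuracyTable(
        r=r,
        model_tag=model_tag,
        subjects=subjects,
        melodies=mels,
        lambdas=lambdas[best],
    )


def cross_validate(
    features: Mapping[str, FeatureMatrix],
    eeg_subject: Mapping[str, np.ndarray],
    eeg_ground_truth: Mapping[str, np.ndarray],
    lambdas: Sequence[float] | None = None,
    window: LagWindow | None = None,
    model_tag: str = "full",
) -> tuple[AccuracyTable, float]:
    """Single-subject convenience wrapper around :func:`cross_validate_subjects`."""
    table = cross_validate_subjects(
        features, {"s0": eeg_subject}, eeg_ground_truth, lambdas, window, model_tag
    )
    return table, float(table.lambdas[0])
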