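"""Variance partitioning of TRF prediction accuracy.

The unique contribution of a regressor (set) is measured by refitting the
encoding model with that regressor's impulse amplitudes permuted across the
melody's note onsets (onset times preserved, dimensionality unchanged) and
taking Δr = r_full − r_reduced.  Group statistics are computed on per-subject
Δr averaged over a region of interest: the top fraction of channels by
full-model accuracy, ranked independently of condition and regressor type.

Five standard reduced models are provided: all four information features
(``highlevel``), the timing pair St/Et, the pitch pair Sp/Ep, and the local
interval features IOI and IPI.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, ConfigError, PowerWarning
from .features import FeatureMatrix
from .trf import AccuracyTable

__all__ = [
    "ReducedSpec",
    "DeltaR",
    "REDUCED_MODELS",
    "shuffle_features",
    "delta_r",
    "select_roi",
    "roi_mean",
    "group_stats",
    "lmm_anova",
]

#: the five standard reduced models, by the features they randomize
REDUCED_MODELS: dict[str, tuple[str, ...]] = {
    "highlevel": ("St", "Et", "Sp", "Ep"),
    "timing": ("St", "Et"),
    "pitch": ("Sp", "Ep"),
    "ioi": ("ioi",),
    "ipi": ("ipi",),
}


@dataclass(frozen=True)
class ReducedSpec:
    """Which event columns to randomize, and how."""

    name: str
    features_to_shuffle: tuple[str, ...]
    n_randomizations: int = 1
    seed: int = 0

    @classmethod
    def standard(cls, name: str, seed: int = 0, n_randomizations: int = 1) -> "ReducedSpec":
        if name not in REDUCED_MODELS:
            raise ConfigError(f"unknown reduced model {name!r}")
        return cls(name, REDUCED_MODELS[name], n_randomizations, seed)


@dataclass
class DeltaR:
    """Δr = r_full − r_reduced, subjects × melodies × channels."""

    dr: np.ndarray
    model: str
    subjects: tuple[str, ...]
    melodies: tuple[str, ...]
    roi_channels: np.ndarray | None = None  # subjects × k channel indices
    roi_fraction: float = 0.25


def shuffle_features(
    features: FeatureMatrix, spec: ReducedSpec, randomization: int = 0
) -> FeatureMatrix:
    """Permute the impulse amplitudes of the named columns across note onsets.

    Onset sample positions and all other columns are untouched.  The
    permutation is deterministic in (spec.seed, randomization, melody id).
    """
    if not spec.features_to_shuffle:
        raise ConfigError("features_to_shuffle is empty")
    for name in spec.features_to_shuffle:
        if name not in features.names:
            raise ConfigError(f"feature {name!r} not in matrix")
        if not features.is_event_column(name):
            raise ConfigError(f"feature {name!r} is continuous; only event columns shuffle")
    onsets = features.onset_samples
    if len(onsets) == 0:
        raise ConfigError("feature matrix has no recorded onset samples")
    rng = np.random.default_rng(
        [spec.seed, randomization, zlib.crc32(features.melody_id.encode())]
    )
    values = features.values.copy()
    for name in spec.features_to_shuffle:
        j = features.names.index(name)
        amps = values[onsets, j]
        values[onsets, j] = rng.permutation(amps)
    return dc_replace(features, values=values)


def delta_r(full: AccuracyTable, reduced: AccuracyTable | Sequence[AccuracyTable]) -> DeltaR:
    """Elementwise r_full − r_reduced; several randomizations are averaged first."""
    tables = [reduced] if isinstance(reduced, AccuracyTable) else list(reduced)
    for t in tables:
        if t.r.shape != full.r.shape or t.melodies != full.melodies:
            raise AlignmentError("full and reduced accuracy tables are misaligned")
    red = np.mean([t.r for t in tables], axis=0)
    return DeltaR(
        dr=full.r - red,
        model=tables[0].model_tag,
        subjects=full.subjects,
        melodies=full.melodies,
    )


def select_roi(full: AccuracyTable, fraction: float = 0.25) -> np.ndarray:
    """Per-subject top channels by full-model accuracy (subjects × k indices).

    Ranking averages r over all melodies (both conditions pooled), so the ROI
    is independent of condition and of which regressor a later comparison
    randomizes.  Ties break toward lower channel index.
    """
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    mean_r = full.r.mean(axis=1)  # subjects × channels
    k = int(np.ceil(fraction * mean_r.shape[1]))
    order = np.argsort(-mean_r, axis=1, kind="stable")
    return np.sort(order[:, :k], axis=1)


def roi_mean(dr: DeltaR, roi: np.ndarray, conditions: Mapping[str, str]) -> pd.DataFrame:
    """Tidy per-subject, per-melody Δr averaged over each subject's ROI channels.

    ``conditions`` maps melody id → condition label.
    """
    rows = []
    for si, subj in enumerate(dr.subjects):
        ch = roi[si]
        for mi, mel in enumerate(dr.melodies):
            rows.append(
                (subj, mel, conditions[mel], dr.model, float(dr.dr[si, mi, ch].mean()))
            )
    return pd.DataFrame(rows, columns=["subject", "melody", "condition", "model", "dr"])


# --------------------------------------------------------------------------
# group-level statistics
# --------------------------------------------------------------------------

def _wilcoxon_vs_zero(values: np.ndarray) -> dict:
    values = np.asarray(values, float)
    if np.allclose(values, 0):
        return {"W": 0.0, "p": 1.0, "n": len(values)}
    res = stats.wilcoxon(values, alternative="greater")
    return {"W": float(res.statistic), "p": float(res.pvalue), "n": len(values)}


def _fit_lmm(df: pd.DataFrame, formula: str):
    import statsmodels.formula.api as smf

    vc = {"subject": "0 + C(subject)"}
    if df["melody"].nunique() > 1:
        vc["melody"] = "0 + C(melody)"
    md = smf.mixedlm(formula, df, groups=np.ones(len(df)), vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return md.fit(reml=False, method="lbfgs", maxiter=200)


def lmm_anova(df: pd.DataFrame) -> dict:
    """Sequential likelihood-ratio tests for Condition, Model and interaction.

    Mimics nested-model comparison with crossed infant and melody random
    intercepts (fitted as variance components by maximum likelihood).
    Factors with a single level are skipped.
    """
    out: dict = {}
    terms = []
    if df["condition"].nunique() > 1:
        terms.append(("condition", "C(condition)"))
    if df["model"].nunique() > 1:
        terms.append(("model", "C(model)"))
    base = "dr ~ 1"
    prev = _fit_lmm(df, base)
    rhs = "1"
    for label, term in terms:
        rhs = rhs + " + " + term
        fit = _fit_lmm(df, "dr ~ " + rhs)
        chi2 = 2 * (fit.llf - prev.llf)
        out[label] = {"chi2": float(max(chi2, 0.0)), "df": 1 if ":" not in term else 1,
                      "p": float(stats.chi2.sf(max(chi2, 0.0), 1))}
        prev = fit
    if len(terms) == 2:
        rhs_int = rhs + " + C(condition):C(model)"
        fit = _fit_lmm(df, "dr ~ " + rhs_int)
        chi2 = 2 * (fit.llf - prev.llf)
        out["condition:model"] = {
            "chi2": float(max(chi2, 0.0)),
            "df": 1,
            "p": float(stats.chi2.sf(max(chi2, 0.0), 1)),
        }
    return out


def _tukey_cells(df: pd.DataFrame) -> list[dict]:
    """Pairwise contrasts between condition×model cell means, Tukey-adjusted."""
    cells = (
        df.groupby(["condition", "model"], observed=True)["dr"]
        .agg(["mean", "count"])
        .reset_index()
    )
    # subject-level cell means for a paired error term
    subj = (
        df.groupby(["subject", "condition", "model"], observed=True)["dr"]
        .mean()
        .reset_index()
    )
    k = len(cells)
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            a = subj[
                (subj["condition"] == cells.loc[i, "condition"])
                & (subj["model"] == cells.loc[i, "model"])
            ].set_index("subject")["dr"]
            b = subj[
                (subj["condition"] == cells.loc[j, "condition"])
                & (subj["model"] == cells.loc[j, "model"])
            ].set_index("subject")["dr"]
            common = a.index.intersection(b.index)
            diff = a.loc[common] - b.loc[common]
            n = len(diff)
            se = diff.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            t = diff.mean() / se if se and se > 0 else 0.0
            dfree = max(n - 1, 1)
            p = float(stats.studentized_range.sf(np.abs(t) * np.sqrt(2), k, dfree))
            results.append(
                {
                    "cell_a": f"{cells.loc[i, 'condition']}:{cells.loc[i, 'model']}",
                    "cell_b": f"{cells.loc[j, 'condition']}:{cells.loc[j, 'model']}",
                    "estimate": float(diff.mean()),
                    "t": float(t),
                    "p_tukey": p,
                    "n": n,
                }
            )
    return results


def group_stats(df: pd.DataFrame) -> dict:
    """Group-level report for a tidy Δr table (subject, melody, condition, model, dr).

    Returns Wilcoxon signed-rank tests of each condition×model cell against
    zero (on per-subject means), the mixed-model likelihood-ratio tests, and
    Tukey-adjusted pairwise cell contrasts.
    """
    required = {"subject", "melody", "condition", "model", "dr"}
    if not required <= set(df.columns):
        raise ConfigError(f"tidy table must have columns {sorted(required)}")
    n_subjects = df["subject"].nunique()
    if n_subjects < 5:
        warnings.warn(
            f"only {n_subjects} subjects; group statistics are underpowered",
            PowerWarning,
        )
    report: dict = {"n_subjects": int(n_subjects), "wilcoxon": {}, "lmm": {}, "tukey": []}
    subj_means = (
        df.groupby(["subject", "condition", "model"], observed=True)["dr"].mean().reset_index()
    )
    for (cond, model), grp in subj_means.groupby(["condition", "model"], observed=True):
        report["wilcoxon"][f"{cond}:{model}>0"] = _wilcoxon_vs_zero(grp["dr"].to_numpy())
    report["lmm"] = lmm_anova(df)
    if df["condition"].nunique() * df["model"].nunique() > 1:
        report["tukey"] = _tukey_cells(df)
    return report
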