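"""Note-locked ERPs, surprise-quantile contrasts, and cluster permutation.

Epochs span −100..+500 ms around each note onset at 100 Hz and are baseline
corrected over −50..0 ms; statistics use the trimmed −50..+400 ms window.
Within each melody, notes in the top/bottom 20% of surprise are labelled
high/low; per-subject average ERPs for the two labels are contrasted with a
paired cluster-based permutation test: suprathreshold paired-t samples are
clustered by spatiotemporal adjacency, cluster mass is the summed t, and the
null distribution is the maximum |mass| over subject-level sign flips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, DataQualityWarning
from .midi import Melody

__all__ = [
    "EpochSet",
    "ClusterResult",
    "epoch",
    "reject_trials",
    "quantile_split",
    "average_erp",
    "channel_adjacency",
    "cluster_permutation",
]

RAW_WINDOW = (-0.1, 0.5)
TRIM_WINDOW = (-0.05, 0.4)
BASELINE = (-0.05, 0.0)


@dataclass
class EpochSet:
    """Trials × channels × samples with per-trial labels and the time axis."""

    epochs: np.ndarray
    times: np.ndarray
    labels: pd.DataFrame  # melody_id, note_index, condition, quantile
    fs: float
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.epochs)

    def trim(self, window: tuple[float, float] = TRIM_WINDOW) -> "EpochSet":
        keep = (self.times >= window[0] - 1e-9) & (self.times <= window[1] + 1e-9)
        return dc_replace(self, epochs=self.epochs[:, :, keep], times=self.times[keep])


@dataclass
class ClusterResult:
    """One spatiotemporal cluster: member (channel, time-index) pairs, mass, p."""

    channels: np.ndarray
    time_indices: np.ndarray
    mass: float
    p: float
    polarity: int


def epoch(
    eeg: np.ndarray,
    melody: Melody,
    fs: float = 100.0,
    window: tuple[float, float] = RAW_WINDOW,
    baseline: tuple[float, float] = BASELINE,
    condition: str | None = None,
) -> EpochSet:
    """Cut one baseline-corrected epoch per note; boundary notes are skipped."""
    n_samples = eeg.shape[1]
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    times = np.arange(-pre, post + 1) / fs
    b0 = int(round((baseline[0] - window[0]) * fs))
    b1 = int(round((baseline[1] - window[0]) * fs)) + 1

    epochs, rows = [], []
    skipped = 0
    for i, onset in enumerate(melody.onsets):
        c = int(round(onset * fs))
        if c - pre < 0 or c + post >= n_samples:
            skipped += 1
            continue
        seg = eeg[:, c - pre : c + post + 1].astype(float)
        seg = seg - seg[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(seg)
        rows.append((melody.id, i, condition or melody.condition, "mid"))
    labels = pd.DataFrame(rows, columns=["melody_id", "note_index", "condition", "quantile"])
    arr = np.stack(epochs) if epochs else np.empty((0, eeg.shape[0], len(times)))
    return EpochSet(epochs=arr, times=times, labels=labels, fs=fs, n_skipped=skipped)


def concatenate(sets: Sequence[EpochSet]) -> EpochSet:
    first = sets[0]
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        times=first.times,
        labels=pd.concat([s.labels for s in sets], ignore_index=True),
        fs=first.fs,
        n_skipped=sum(s.n_skipped for s in sets),
    )


def reject_trials(epochs: EpochSet, z: float = 2.5, iterations: int = 2) -> EpochSet:
    """Drop trials whose overall SD is an outlier of the per-trial SD distribution.

    A trial is rejected when its SD (across channels and samples) exceeds the
    mean plus ``z`` standard deviations of the per-trial SD distribution;
    applied twice (one repeat after removal).
    """
    if len(epochs) < 10:
        raise ConfigError("need at least 10 trials for rejection statistics")
    keep = np.ones(len(epochs), dtype=bool)
    for _ in range(iterations):
        sds = epochs.epochs[keep].std(axis=(1, 2))
        thr = sds.mean() + z * sds.std()
        bad = sds > thr
        if not bad.any():
            break
        idx = np.flatnonzero(keep)
        keep[idx[bad]] = False
    frac = 1.0 - keep.mean()
    if frac > 0.5:
        warnings.warn(f"{frac:.0%} of trials rejected", DataQualityWarning)
    return dc_replace(
        epochs,
        epochs=epochs.epochs[keep],
        labels=epochs.labels.loc[keep].reset_index(drop=True),
    )


def quantile_split(
    epochs: EpochSet,
    surprise: Mapping[str, np.ndarray],
    q: float = 0.20,
) -> EpochSet:
    """Label the top/bottom ``q`` of notes by surprise, within each melody.

    ``surprise`` maps melody id → per-note surprise (indexed by note_index).
    Ties break by note order (stable sort), so identical surprises label the
    earliest notes low and the latest high.
    """
    if not 0 < q <= 0.5:
        raise ConfigError("quantile fraction must be in (0, 0.5]")
    labels = epochs.labels.copy()
    labels["quantile"] = "mid"
    for mid, grp in labels.groupby("melody_id", observed=True):
        s = np.asarray([surprise[mid][i] for i in grp["note_index"]], dtype=float)
        ok = np.isfinite(s)
        idx = grp.index.to_numpy()[ok]
        if len(idx) == 0:
            continue
        k = max(1, int(round(q * len(idx))))
        order = np.argsort(s[ok], kind="stable")
        labels.loc[idx[order[:k]], "quantile"] = "lowS"
        labels.loc[idx[order[-k:]], "quantile"] = "highS"
    return dc_replace(epochs, labels=labels)


def average_erp(epochs: EpochSet, quantile: str, condition: str | None = None) -> np.ndarray:
    """Average ERP (channels × samples) over trials with the given labels."""
    mask = epochs.labels["quantile"] == quantile
    if condition is not None:
        mask &= epochs.labels["condition"] == condition
    if not mask.any():
        raise ConfigError(f"no trials labelled {quantile!r}/{condition!r}")
    return epochs.epochs[mask.to_numpy()].mean(axis=0)


# --------------------------------------------------------------------------
# cluster-based permutation test
# --------------------------------------------------------------------------

def channel_adjacency(positions: np.ndarray, radius_mm: float = 30.0) -> sparse.csr_matrix:
    """Boolean channel adjacency: electrodes within ``radius_mm`` of each other."""
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return sparse.csr_matrix(d <= radius_mm)


def _spatiotemporal_graph(adjacency: sparse.csr_matrix, n_times: int) -> sparse.csr_matrix:
    """Adjacency over (channel, time) nodes: time ±1 same channel, neighbors same time."""
    C = adjacency.shape[0]
    eye = sparse.identity(C, format="csr", dtype=bool)
    time_links = sparse.diags([True] * (n_times - 1), 1, shape=(n_times, n_times), dtype=bool)
    time_links = time_links + time_links.T
    graph = sparse.kron(eye, time_links) + sparse.kron(
        adjacency.astype(bool), sparse.identity(n_times, dtype=bool)
    )
    return graph.tocsr()


def _clusters_from_mask(
    mask: np.ndarray, graph: sparse.csr_matrix, n_times: int, min_channels: int
) -> list[tuple[np.ndarray, float]]:
    """Connected components of suprathreshold nodes with ≥ min_channels channels."""
    nodes = np.flatnonzero(mask)
    if len(nodes) == 0:
        return []
    sub = graph[nodes][:, nodes]
    n_comp, labels = connected_components(sub, directed=False)
    out = []
    for c in range(n_comp):
        members = nodes[labels == c]
        if len(np.unique(members // n_times)) >= min_channels:
            out.append((members, 0.0))
    return out


def cluster_permutation(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    adjacency: sparse.csr_matrix,
    n_perm: int = 1000,
    alpha_cluster: float = 0.025,
    min_channels: int = 3,
    seed: int = 0,
) -> list[ClusterResult]:
    """Paired spatiotemporal cluster permutation test.

    ``cond_a``/``cond_b`` are subjects × channels × times.  Paired t values
    exceeding the one-tailed ``alpha_cluster`` critical value form candidate
    samples; same-sign samples are clustered by spatiotemporal adjacency and
    clusters spanning fewer than ``min_channels`` distinct channels are
    discarded.  The null distribution is the maximum absolute cluster mass
    over ``n_perm`` subject-level sign flips; p-values use the add-one rule.
    """
    if cond_a.shape != cond_b.shape:
        raise ConfigError("condition arrays must have identical shape")
    n, C, T = cond_a.shape
    if n < 6:
        warnings.warn(f"only {n} subjects; permutation null is coarse", DataQualityWarning)
    d = (cond_a - cond_b).reshape(n, C * T)
    tcrit = stats.t.ppf(1 - alpha_cluster, n - 1)
    graph = _spatiotemporal_graph(adjacency, T)
    sumsq = np.sum(d**2, axis=0)

    def t_map(signs: np.ndarray) -> np.ndarray:
        mean = signs @ d / n
        var = (sumsq - n * mean**2) / (n - 1)
        return mean / np.sqrt(np.clip(var, 1e-300, None) / n)

    t_obs = t_map(np.ones(n))
    observed = []
    for sign in (1, -1):
        for members, _ in _clusters_from_mask(sign * t_obs > tcrit, graph, T, min_channels):
            observed.append((members, float(t_obs[members].sum()), sign))

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_p = t_map(signs[i])
        best = 0.0
        for sign in (1, -1):
            for members, _ in _clusters_from_mask(
                sign * t_p > tcrit, graph, T, min_channels
            ):
                best = max(best, abs(t_p[members].sum()))
        null_max[i] = best

    results = []
    for members, mass, sign in observed:
        p = (1 + np.sum(null_max >= abs(mass))) / (n_perm + 1)
        results.append(
            ClusterResult(
                channels=members // T,
                time_indices=members % T,
                mass=mass,
                p=float(p),
                polarity=sign,
            )
        )
    results.sort(key=lambda c: c.p)
    return results
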