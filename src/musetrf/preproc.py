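"""Deterministic continuous-EEG preprocessing.

Stages, in order: zero-phase order-3 Butterworth band-pass (1–30 Hz) with
anti-aliased resampling to 100 Hz; iterative bad-channel detection (per-trial
mean/SD/peak-to-peak deviating more than 2.75 cross-channel SDs); re-reference
to the average of a fixed electrode set with bad channels excluded first; a
pluggable hook where external denoising (e.g., artifact subspace
reconstruction, ICA-based ocular correction) would run; and neighbor-mean
interpolation of the bad channels (neighbors within 18 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import signal

from .errors import ConfigError, DataQualityError, InterpolationError

__all__ = [
    "EEGRecording",
    "bandpass_and_resample",
    "detect_bad_channels",
    "rereference",
    "interpolate_bads",
    "preprocess_recording",
    "DEFAULT_REFERENCE",
]

DEFAULT_REFERENCE = ("F9", "F10", "P9", "P10", "Iz")


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG: data in µV (channels × samples) plus montage metadata."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    positions: np.ndarray  # channels × 3, millimetres
    bad_channels: frozenset = frozenset()
    reference: str = "Cz"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigError("fs must be positive")
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigError("data rows must match channel_names")
        if self.positions.shape != (len(self.channel_names), 3):
            raise ConfigError("positions must be channels × 3")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


def bandpass_and_resample(
    rec: EEGRecording, low: float = 1.0, high: float = 30.0, fs_out: float = 100.0
) -> EEGRecording:
    """Zero-phase order-3 Butterworth band-pass, then polyphase resampling."""
    if fs_out > rec.fs:
        raise ConfigError(f"fs_out={fs_out} exceeds input rate {rec.fs}")
    if rec.fs < 2 * high:
        raise ConfigError(f"input rate {rec.fs} below Nyquist for high={high}")
    sos = signal.butter(3, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    if fs_out != rec.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        filtered = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=np.ascontiguousarray(filtered), fs=fs_out)


def _channel_metrics(data: np.ndarray, segments: Sequence[tuple[int, int]]) -> np.ndarray:
    """Per-channel mean, SD and peak-to-peak, averaged over trial segments."""
    metrics = np.zeros((data.shape[0], 3))
    for a, b in segments:
        seg = data[:, a:b]
        metrics[:, 0] += seg.mean(axis=1)
        metrics[:, 1] += seg.std(axis=1)
        metrics[:, 2] += np.ptp(seg, axis=1)
    return metrics / len(segments)


def detect_bad_channels(
    rec: EEGRecording,
    z: float = 2.75,
    segments: Sequence[tuple[int, int]] | None = None,
) -> frozenset:
    """Iteratively flag channels whose trial metrics are cross-channel outliers.

    A channel is flagged when its mean, SD or peak-to-peak (averaged over
    trial segments) deviates more than ``z`` standard deviations from the mean
    of the remaining channels; detection repeats on the surviving channels
    until no outliers remain.
    """
    if rec.n_channels < 8:
        raise ConfigError("need at least 8 channels for outlier statistics")
    if segments is None:
        segments = [(0, rec.data.shape[1])]
    metrics = _channel_metrics(rec.data, segments)
    good = np.ones(rec.n_channels, dtype=bool)
    while True:
        newly_bad = np.zeros(rec.n_channels, dtype=bool)
        for m in range(metrics.shape[1]):
            vals = metrics[:, m]
            mu, sd = vals[good].mean(), vals[good].std()
            if sd == 0:
                continue
            newly_bad |= good & (np.abs(vals - mu) > z * sd)
        if not newly_bad.any():
            break
        good &= ~newly_bad
        if not good.any():
            raise DataQualityError("all channels flagged as bad")
    return frozenset(
        name for name, g in zip(rec.channel_names, good) if not g
    ) | rec.bad_channels


def rereference(rec: EEGRecording, ref_labels: Iterable[str] = DEFAULT_REFERENCE) -> EEGRecording:
    """Subtract the average of the reference electrodes from every channel."""
    ref_labels = tuple(ref_labels)
    for name in ref_labels:
        if name not in rec.channel_names:
            raise ConfigError(f"reference electrode {name!r} not in montage")
        if name in rec.bad_channels:
            raise ConfigError(f"reference electrode {name!r} is marked bad")
    idx = [rec.index(name) for name in ref_labels]
    ref = rec.data[idx].mean(axis=0, keepdims=True)
    return replace(rec, data=rec.data - ref, reference="custom-average")


def _neighbor_map(positions: np.ndarray, radius_mm: float) -> list[np.ndarray]:
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    return [np.flatnonzero(d[i] <= radius_mm) for i in range(len(positions))]


def interpolate_bads(
    rec: EEGRecording,
    radius_mm: float = 18.0,
    redetect_z: float | None = None,
    max_iterations: int = 2,
) -> EEGRecording:
    """Replace each bad channel with the mean of its good neighbors.

    Neighbors are electrodes within ``radius_mm``.  If ``redetect_z`` is
    given, detection is re-run on the interpolated data and the step repeats
    (at most ``max_iterations`` times, then an error), mirroring the
    iterate-until-clean rule of the recording pipeline.
    """
    current = rec
    for _ in range(max_iterations):
        if not current.bad_channels:
            return current
        neighbors = _neighbor_map(current.positions, radius_mm)
        bad_idx = {current.index(name) for name in current.bad_channels}
        data = current.data.copy()
        for i in sorted(bad_idx):
            good_nb = [j for j in neighbors[i] if j not in bad_idx]
            if not good_nb:
                raise InterpolationError(
                    f"channel {current.channel_names[i]!r} has no good neighbor "
                    f"within {radius_mm} mm"
                )
            data[i] = current.data[good_nb].mean(axis=0)
        current = replace(current, data=data, bad_channels=frozenset())
        if redetect_z is None:
            return current
        still_bad = detect_bad_channels(current, z=redetect_z)
        if not still_bad:
            return current
        current = replace(current, bad_channels=still_bad)
    raise DataQualityError(
        f"bad channels persist after {max_iterations} interpolation passes: "
        f"{sorted(current.bad_channels)}"
    )


def preprocess_recording(
    rec: EEGRecording,
    low: float = 1.0,
    high: float = 30.0,
    fs_out: float = 100.0,
    bad_z: float = 2.75,
    ref_labels: Iterable[str] = DEFAULT_REFERENCE,
    radius_mm: float = 18.0,
    segments: Sequence[tuple[int, int]] | None = None,
    denoise_hook: Callable[[EEGRecording], EEGRecording] | None = None,
) -> EEGRecording:
    """Run the full deterministic pipeline on one continuous recording.

    ``segments`` are (start, stop) sample ranges at the *output* rate marking
    melody trials for the outlier statistics.  ``denoise_hook`` is the slot
    where external subspace/ICA denoising would plug in; default is identity.
    """
    rec = bandpass_and_resample(rec, low=low, high=high, fs_out=fs_out)
    bads = detect_bad_channels(rec, z=bad_z, segments=segments)
    rec = replace(rec, bad_channels=bads)
    # a flagged reference electrode is dropped from the average, not used
    usable_refs = [r for r in ref_labels if r not in bads]
    if not usable_refs:
        raise ConfigError("every reference electrode was flagged as bad")
    rec = rereference(rec, ref_labels=usable_refs)
    if denoise_hook is not None:
        rec = denoise_hook(rec)
    return interpolate_bads(rec, radius_mm=radius_mm)
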