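"""Time-sampled stimulus regressors at the EEG sampling rate.

Event-based columns (note onsets, local intervals, surprise/entropy) are
impulse trains: zero everywhere except at the sample nearest each note onset,
where the amplitude carries the feature value.  Acoustic columns (envelope,
its half-rectified derivative, spectral flux) are continuous and derived from
a synthesized waveform through a gammatone filterbank.

Each melody's matrix is normalized independently so that every non-zero
column has unit root-mean-square.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import AlignmentError, FormatError
from .infodyn import InfoEstimates
from .midi import LocalIntervals, Melody

__all__ = [
    "FeatureMatrix",
    "event_regressors",
    "acoustic_regressors",
    "synthesize_audio",
    "build_feature_matrix",
    "EVENT_COLUMNS",
    "ACOUSTIC_COLUMNS",
]

EVENT_COLUMNS = ("onset", "ioi", "ipi", "Sp", "St", "Ep", "Et", "ioi_next")
ACOUSTIC_COLUMNS = ("spectral_flux", "envelope", "env_derivative")

#: canonical column order of the full regressor bank
FULL_MODEL_COLUMNS = ("onset", "spectral_flux", "ioi", "ipi", "Sp", "St", "Ep", "Et")


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples × features regressor bank for one melody."""

    values: np.ndarray
    names: tuple[str, ...]
    fs: float
    melody_id: str = ""
    #: sample indices of the note onsets (impulse positions of event columns)
    onset_samples: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise AlignmentError(
                f"values shape {self.values.shape} does not match {len(self.names)} names"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def is_event_column(self, name: str) -> bool:
        return name in EVENT_COLUMNS

    def normalize(self) -> "FeatureMatrix":
        """Scale each column to unit RMS (all-zero columns left untouched)."""
        rms = np.sqrt(np.mean(self.values**2, axis=0))
        scale = np.where(rms > 0, 1.0 / np.where(rms > 0, rms, 1.0), 1.0)
        return replace(self, values=self.values * scale)

    def select(self, names: tuple[str, ...]) -> "FeatureMatrix":
        idx = [self.names.index(n) for n in names]
        return replace(self, values=self.values[:, idx], names=tuple(names))

    def hstack(self, other: "FeatureMatrix") -> "FeatureMatrix":
        if other.n_samples != self.n_samples or other.fs != self.fs:
            raise AlignmentError("cannot stack feature matrices of different shape/rate")
        return replace(
            self,
            values=np.hstack([self.values, other.values]),
            names=self.names + other.names,
        )


def _n_samples_for(melody: Melody, fs: float, tail: float = 0.5) -> int:
    return int(round((melody.total_duration + tail) * fs)) + 1


def event_regressors(
    melody: Melody,
    info: InfoEstimates,
    intervals: LocalIntervals,
    fs: float = 100.0,
    include_ioi_next: bool = False,
    n_samples: int | None = None,
) -> FeatureMatrix:
    """Impulse-train regressors at the sample nearest each note onset.

    Amplitudes: ``onset`` 1, ``ioi`` preceding IOI in ms, ``ipi`` absolute
    semitones, ``Sp``/``St``/``Ep``/``Et`` the information estimates.
    Undefined values (first notes, NaN estimates) contribute zero-amplitude
    impulses so the remaining notes are unaffected.
    """
    n_notes = len(melody)
    if len(info) != n_notes or len(intervals.ioi) != n_notes:
        raise AlignmentError(
            f"info/intervals length does not match melody {melody.id!r} ({n_notes} notes)"
        )
    if n_samples is None:
        n_samples = _n_samples_for(melody, fs)
    onset_samples = np.round(melody.onsets * fs).astype(int)
    if onset_samples[-1] >= n_samples:
        raise AlignmentError("melody extends beyond the requested sample count")

    names = ["onset", "ioi", "ipi", "Sp", "St", "Ep", "Et"]
    amps = [
        np.ones(n_notes),
        np.nan_to_num(intervals.ioi) * 1000.0,  # ms
        np.nan_to_num(intervals.ipi),
        np.nan_to_num(info.Sp),
        np.nan_to_num(info.St),
        np.nan_to_num(info.Ep),
        np.nan_to_num(info.Et),
    ]
    if include_ioi_next:
        names.append("ioi_next")
        amps.append(np.nan_to_num(intervals.ioi_next) * 1000.0)

    values = np.zeros((n_samples, len(names)))
    for j, a in enumerate(amps):
        values[onset_samples, j] = a
    return FeatureMatrix(
        values=values,
        names=tuple(names),
        fs=fs,
        melody_id=melody.id,
        onset_samples=onset_samples,
    )


def synthesize_audio(melody: Melody, sr: float = 44100.0, n_harmonics: int = 6) -> np.ndarray:
    """Render a melody as exponentially decaying harmonic tones.

    Each note is a sum of ``n_harmonics`` harmonics with 1/h amplitudes, an
    exponential decay (time constant 0.3 s) and 5 ms onset/offset ramps; the
    waveform is exactly zero outside [onset, onset + duration].  Loudness is
    constant across notes.
    """
    n = int(round(melody.total_duration * sr)) + 1
    wave = np.zeros(n)
    ramp = max(int(round(0.005 * sr)), 1)
    for note in melody.notes:
        f0 = 440.0 * 2.0 ** ((note.pitch - 69) / 12.0)
        length = int(round(note.duration * sr))
        if length < 2 * ramp:
            length = 2 * ramp
        t = np.arange(length) / sr
        tone = np.zeros(length)
        for h in range(1, n_harmonics + 1):
            if h * f0 < sr / 2:
                tone += np.sin(2 * np.pi * h * f0 * t) / h
        env = np.exp(-t / 0.3)
        env[:ramp] *= np.linspace(0, 1, ramp, endpoint=False)
        env[-ramp:] *= np.linspace(1, 0, ramp)
        start = int(round(note.onset * sr))
        stop = min(start + length, n)
        wave[start:stop] += (tone * env)[: stop - start]
    peak = np.max(np.abs(wave))
    return wave / peak if peak > 0 else wave


def acoustic_regressors(
    wave: np.ndarray,
    sr: float,
    fs_out: float = 100.0,
    n_bands: int = 128,
    fmin: float = 100.0,
    fmax: float = 8000.0,
    n_samples: int | None = None,
) -> FeatureMatrix:
    """Envelope, half-rectified envelope derivative, and spectral flux.

    The waveform is filtered into ``n_bands`` logarithmically spaced gammatone
    bands; band envelopes are Hilbert magnitudes, decimated to ``fs_out`` with
    polyphase anti-aliasing.  Spectral flux is the band-sum of half-wave
    rectified frame-to-frame envelope differences; the broadband envelope is
    the band sum, and its derivative is half-wave rectified as well.
    """
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise FormatError("audio must be mono (1-D)")
    if sr < 2 * fmax:
        raise FormatError(f"sample rate {sr} too low for fmax={fmax}")

    from scipy.fft import next_fast_len

    freqs = np.geomspace(fmin, fmax, n_bands)
    down = int(round(sr / fs_out))
    n_out = int(np.ceil(len(wave) / down))
    nfft = next_fast_len(len(wave))
    envs = np.empty((n_out, n_bands))
    for j, f in enumerate(freqs):
        b, a = signal.gammatone(f, "iir", fs=sr)
        band = signal.lfilter(b, a, wave)
        env = np.abs(signal.hilbert(band, N=nfft)[: len(wave)])
        envs[:, j] = signal.resample_poly(env, 1, down)[:n_out]
    envs = np.clip(envs, 0.0, None)

    flux = np.zeros(n_out)
    flux[1:] = np.sum(np.clip(np.diff(envs, axis=0), 0.0, None), axis=1)
    envelope = envs.sum(axis=1)
    deriv = np.zeros(n_out)
    deriv[1:] = np.clip(np.diff(envelope), 0.0, None)

    values = np.column_stack([flux, envelope, deriv])
    if n_samples is not None:
        if n_samples <= n_out:
            values = values[:n_samples]
        else:
            values = np.vstack([values, np.zeros((n_samples - n_out, values.shape[1]))])
    return FeatureMatrix(
        values=values, names=("spectral_flux", "envelope", "env_derivative"), fs=fs_out
    )


def build_feature_matrix(
    melody: Melody,
    info: InfoEstimates,
    intervals: LocalIntervals,
    fs: float = 100.0,
    include_flux: bool = True,
    include_envelope: bool = False,
    include_ioi_next: bool = False,
    audio_sr: float = 16000.0,
    n_bands: int = 32,
    normalize: bool = True,
) -> FeatureMatrix:
    """Assemble the full per-melody regressor bank (event + acoustic columns)."""
    fm = event_regressors(
        melody, info, intervals, fs=fs, include_ioi_next=include_ioi_next
    )
    if include_flux or include_envelope:
        wave = synthesize_audio(melody, sr=audio_sr)
        ac = acoustic_regressors(
            wave, audio_sr, fs_out=fs, n_bands=n_bands,
            fmax=min(8000.0, audio_sr / 2 - 1), n_samples=fm.n_samples,
        )
        cols = []
        if include_flux:
            cols.append("spectral_flux")
        if include_envelope:
            cols += ["envelope", "env_derivative"]
        fm = fm.hstack(ac.select(tuple(cols)))
    # canonical ordering: onset, acoustics, intervals, information features
    order = [n for n in ("onset", "spectral_flux", "envelope", "env_derivative",
                         "ioi", "ioi_next", "ipi", "Sp", "St", "Ep", "Et")
             if n in fm.names]
    fm = fm.select(tuple(order))
    return fm.normalize() if normalize else fm
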