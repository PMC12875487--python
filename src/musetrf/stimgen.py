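"""Control-stimulus and synthetic-corpus generation for monophonic melodies.

``shuffle_melody`` reproduces the construction of the study's control stimuli:
the pitch sequence is permuted (destroying melodic transition structure while
preserving pitch content) and the inter-onset intervals are redrawn from a
Gaussian centred on the original mean IOI, with standard deviation equal to
the difference between the mean and the minimum IOI, then snapped to the
16th-note grid so integer duration ratios are preserved.

``generate_corpus`` samples melodies from a seed-fixed Markov process: pitches
from a 15-symbol alphabet with temperature-controlled transition entropy, and
rhythms from an 8-symbol IOI-ratio alphabet on the 16th grid.  Low
temperatures give strongly patterned (predictable) melodies; high temperatures
approach uniform sampling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .midi import Melody, NoteEvent

__all__ = ["ShuffleSpec", "shuffle_melody", "generate_corpus", "PITCH_ALPHABET", "RATIO_ALPHABET"]

#: 15 pitches (MIDI numbers) spanning two diatonic octaves within the stimulus range
PITCH_ALPHABET = (55, 57, 59, 60, 62, 64, 65, 67, 69, 71, 72, 74, 76, 77, 79)

#: 8 IOI-ratio symbols; all map 16th-grid IOIs to 16th-grid IOIs for most states
RATIO_ALPHABET = (0.25, 1 / 3, 0.5, 2 / 3, 1.0, 1.5, 2.0, 3.0)

#: IOI bounds for the synthetic rhythm walk, in 16th notes
_IOI_MIN, _IOI_MAX = 2, 40


@dataclass(frozen=True)
class ShuffleSpec:
    """Parameters of the control-stimulus construction."""

    seed: int = 0
    sixteenth_duration: float = 0.06
    ioi_sd_rule: str = "mean_minus_min"

    def __post_init__(self) -> None:
        if self.sixteenth_duration <= 0:
            raise ConfigError("sixteenth_duration must be positive")


def shuffle_melody(melody: Melody, spec: ShuffleSpec) -> Melody:
    """Construct the shuffled control counterpart of a melody.

    The output pitch sequence is a seed-deterministic permutation of the input
    pitches; IOIs are i.i.d. Gaussian draws (mean = input mean IOI, sd per
    ``ioi_sd_rule``), redrawn while below half a 16th (rejection keeps the
    Gaussian shape, unlike clamping), rescaled to the input mean IOI (the
    rejection truncates the lower tail and would otherwise bias the mean
    upward), then snapped to the 16th grid with a floor of one 16th.
    Velocity is fixed at 100.
    """
    if len(melody) < 3:
        raise ConfigError("need at least 3 notes to shuffle")
    rng = np.random.default_rng(spec.seed)
    pitches = rng.permutation(melody.pitches)

    iois = np.diff(melody.onsets)
    mean_ioi = float(np.mean(iois))
    if spec.ioi_sd_rule == "mean_minus_min":
        sd = mean_ioi - float(np.min(iois))
    else:
        raise ConfigError(f"unknown ioi_sd_rule {spec.ioi_sd_rule!r}")
    sd = max(sd, 1e-9)

    grid = spec.sixteenth_duration
    new_iois = np.empty(len(iois))
    for i in range(len(iois)):
        draw = rng.normal(mean_ioi, sd)
        while draw < grid / 2:
            draw = rng.normal(mean_ioi, sd)
        new_iois[i] = draw
    new_iois *= mean_ioi / new_iois.mean()
    new_iois = np.maximum(1, np.round(new_iois / grid)) * grid

    onsets = np.concatenate([[0.0], np.cumsum(new_iois)])
    notes = tuple(
        NoteEvent(
            onset=float(t),
            pitch=int(p),
            duration=float(max(0.8 * ioi, grid / 2)),
            velocity=100,
        )
        for t, p, ioi in zip(onsets, pitches, np.append(new_iois, new_iois[-1]))
    )
    return Melody(
        id=melody.id + "_shuf",
        notes=notes,
        condition="shuffled",
        sixteenth_duration=grid,
    )


def _softmax_rows(logits: np.ndarray, temperature: float) -> np.ndarray:
    """Row-stochastic matrix; temperature 0 is argmax (deterministic rows)."""
    if temperature <= 0:
        out = np.zeros_like(logits)
        out[np.arange(len(logits)), np.argmax(logits, axis=1)] = 1.0
        return out
    z = logits / temperature
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    return p / p.sum(axis=1, keepdims=True)


def _markov_tables(n_symbols: int, order: int, temperature: float, rng: np.random.Generator):
    """Transition probabilities for every context of length ``order``."""
    n_ctx = n_symbols**order if order > 0 else 1
    logits = rng.normal(size=(n_ctx, n_symbols))
    probs = _softmax_rows(logits, temperature)

    def ctx_index(history: tuple[int, ...]) -> int:
        if order == 0:
            return 0
        idx = 0
        for s in history[-order:]:
            idx = idx * n_symbols + s
        return idx

    return probs, ctx_index


def generate_corpus(
    n_melodies: int,
    n_notes: int = 60,
    pitch_order: int = 1,
    rhythm_order: int = 1,
    temperature: float = 1.0,
    seed: int = 0,
    sixteenth_duration: float = 0.06,
) -> list[Melody]:
    """Sample a seed-deterministic corpus of structured synthetic melodies.

    Pitches follow an order-``pitch_order`` Markov chain over
    :data:`PITCH_ALPHABET`; IOI ratios follow an order-``rhythm_order`` chain
    over :data:`RATIO_ALPHABET`, renormalized at each step to the ratios that
    keep the IOI an integer number of 16ths within bounds.  ``temperature``
    scales transition entropy: 0 gives deterministic repeating patterns, large
    values approach uniform sampling.
    """
    if n_melodies < 1:
        raise ConfigError("n_melodies must be >= 1")
    if pitch_order < 0 or rhythm_order < 0:
        raise ConfigError("orders must be >= 0")
    rng = np.random.default_rng(seed)
    n_p, n_r = len(PITCH_ALPHABET), len(RATIO_ALPHABET)
    p_probs, p_ctx = _markov_tables(n_p, pitch_order, temperature, rng)
    r_probs, r_ctx = _markov_tables(n_r, rhythm_order, temperature, rng)

    melodies = []
    for m in range(n_melodies):
        # pitch sequence
        pitch_idx = [int(rng.integers(n_p))]
        for _ in range(n_notes - 1):
            p = p_probs[p_ctx(tuple(pitch_idx))]
            pitch_idx.append(int(rng.choice(n_p, p=p)))

        # rhythm: IOI walk in 16ths driven by ratio symbols
        ioi = 8  # start at a half note on the 16th grid
        ratio_idx: list[int] = []
        iois = []
        for _ in range(n_notes - 1):
            p = r_probs[r_ctx(tuple(ratio_idx))].copy()
            # keep only ratios that leave the IOI integer and in bounds
            for j, r in enumerate(RATIO_ALPHABET):
                nxt = ioi * r
                if abs(nxt - round(nxt)) > 1e-9 or not _IOI_MIN <= round(nxt) <= _IOI_MAX:
                    p[j] = 0.0
            if p.sum() == 0:  # dead end: reset to a neutral state
                ioi = 8
                continue_p = r_probs[r_ctx(tuple(ratio_idx))].copy()
                p = continue_p
                for j, r in enumerate(RATIO_ALPHABET):
                    nxt = ioi * r
                    if abs(nxt - round(nxt)) > 1e-9 or not _IOI_MIN <= round(nxt) <= _IOI_MAX:
                        p[j] = 0.0
            p = p / p.sum()
            j = int(rng.choice(n_r, p=p))
            ratio_idx.append(j)
            ioi = int(round(ioi * RATIO_ALPHABET[j]))
            iois.append(ioi * sixteenth_duration)

        onsets = np.concatenate([[0.0], np.cumsum(iois)])
        notes = tuple(
            NoteEvent(
                onset=float(t),
                pitch=PITCH_ALPHABET[k],
                duration=float(max(0.8 * d, sixteenth_duration / 2)),
                velocity=100,
            )
            for t, k, d in zip(onsets, pitch_idx, list(iois) + [iois[-1]])
        )
        melodies.append(
            Melody(
                id=f"syn{m:02d}",
                notes=notes,
                condition="synthetic",
                sixteenth_duration=sixteenth_duration,
            )
        )
    return melodies


def select_extremes(mean_timing_surprise: dict[str, float], k: int) -> list[str]:
    """Pick the k/2 highest- and k/2 lowest-surprise melodies (study rule)."""
    ordered = sorted(mean_timing_surprise, key=lambda mid: mean_timing_surprise[mid])
    lo = ordered[: k // 2]
    hi = ordered[len(ordered) - (k - k // 2):]
    return lo + hi
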