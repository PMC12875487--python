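"""Symbolic melodies: standard-MIDI I/O, plain-text melody tables, and viewpoint
derivation.

A :class:`Melody` is an onset-sorted sequence of monophonic :class:`NoteEvent`s
with times in seconds, onset of the first note at 0.  Two discrete "viewpoint"
sequences are derived from it for sequence modelling:

* ``cpitch`` — the raw MIDI pitch numbers (defined from the first note);
* ``ioi_ratio`` — the ratio of consecutive inter-onset intervals
  IOI(k)/IOI(k-1), defined from the third note, rounded to six decimals so
  that grid-quantized rhythms yield a small exact symbol alphabet.

Only the small subset of the standard-MIDI format needed for monophonic
type-0/1 files is implemented (note on/off, tempo map, ticks-per-quarter
division).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateMelodyError, FormatError, MonophonyError

__all__ = [
    "NoteEvent",
    "Melody",
    "ViewpointSequence",
    "LocalIntervals",
    "read_midi",
    "write_midi",
    "read_melody_table",
    "write_melody_table",
    "derive_viewpoints",
]

RATIO_DECIMALS = 6  # rounding grid for the ioi_ratio symbol alphabet


@dataclass(frozen=True)
class NoteEvent:
    """A single pitched note: ``onset``/``duration`` in seconds, MIDI pitch, velocity."""

    onset: float
    pitch: int
    duration: float
    velocity: int = 100

    def __post_init__(self) -> None:
        if not np.isfinite(self.onset) or self.onset < 0:
            raise ValueError(f"onset must be finite and non-negative, got {self.onset}")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch must be a MIDI number in 0..127, got {self.pitch}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not 0 <= self.velocity <= 127:
            raise ValueError(f"velocity must be in 0..127, got {self.velocity}")


@dataclass(frozen=True)
class Melody:
    """An onset-sorted monophonic note sequence.

    ``condition`` distinguishes real stimuli, their shuffled controls and
    synthetic corpus melodies.  Onsets are strictly increasing (no chords).
    """

    id: str
    notes: tuple[NoteEvent, ...]
    condition: str = "real"
    tempo_bpm: float | None = None
    sixteenth_duration: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("real", "shuffled", "synthetic"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.notes) < 2:
            raise DegenerateMelodyError(
                f"melody {self.id!r} has {len(self.notes)} notes; need at least 2"
            )
        onsets = np.array([n.onset for n in self.notes])
        if not np.all(np.diff(onsets) > 0):
            raise MonophonyError(
                f"melody {self.id!r}: onsets must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([n.onset for n in self.notes])

    @property
    def pitches(self) -> np.ndarray:
        return np.array([n.pitch for n in self.notes], dtype=int)

    @property
    def durations(self) -> np.ndarray:
        return np.array([n.duration for n in self.notes])

    @property
    def total_duration(self) -> float:
        last = self.notes[-1]
        return float(last.onset + last.duration)

    def with_condition(self, condition: str) -> "Melody":
        return replace(self, condition=condition)


@dataclass(frozen=True)
class ViewpointSequence:
    """A melody rendered as discrete symbols under one viewpoint.

    ``symbols`` has one entry per *defined* note; ``defined_from`` is the
    0-based index of the first note with a defined symbol (0 for cpitch,
    2 for ioi_ratio).
    """

    viewpoint: str
    symbols: tuple
    defined_from: int


@dataclass(frozen=True)
class LocalIntervals:
    """Per-note local interval features; NaN marks undefined boundary notes.

    ``ioi``/``ioi_next`` are the preceding/subsequent inter-onset intervals in
    seconds, ``ipi`` the absolute pitch interval in semitones.
    """

    ioi: np.ndarray
    ioi_next: np.ndarray
    ipi: np.ndarray


# --------------------------------------------------------------------------
# standard MIDI I/O (minimal SMF type 0/1 subset)
# --------------------------------------------------------------------------

_DEFAULT_TEMPO = 500_000  # µs per quarter note (120 bpm)
_PPQ = 480  # ticks per quarter used when writing


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes) -> list[tuple[int, int, int, int]]:
    """Return raw events as (tick, kind, a, b); kind: 0=note_off 1=note_on 2=tempo."""
    events = []
    pos = 0
    tick = 0
    status = 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        b = data[pos]
        if b & 0x80:
            status = b
            pos += 1
        if status == 0xFF:  # meta
            meta_type = data[pos]
            length, pos = _read_varlen(data, pos + 1)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x51:
                tempo = int.from_bytes(payload, "big")
                events.append((tick, 2, tempo, 0))
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            kind = status & 0xF0
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                a, b2 = data[pos], data[pos + 1]
                pos += 2
                if kind == 0x90:
                    events.append((tick, 1 if b2 > 0 else 0, a, b2))
                elif kind == 0x80:
                    events.append((tick, 0, a, b2))
            elif kind in (0xC0, 0xD0):
                pos += 1
            else:
                raise FormatError(f"unsupported MIDI status byte 0x{status:02x}")
    return events


def _ticks_to_seconds(ticks: np.ndarray, tempo_map: list[tuple[int, int]], ppq: int) -> np.ndarray:
    """Convert absolute ticks to seconds under a (tick, µs-per-quarter) tempo map."""
    out = np.empty(len(ticks), dtype=float)
    for i, t in enumerate(ticks):
        sec = 0.0
        prev_tick, tempo = 0, _DEFAULT_TEMPO
        for change_tick, new_tempo in tempo_map:
            if change_tick >= t:
                break
            sec += (change_tick - prev_tick) * tempo / (ppq * 1e6)
            prev_tick, tempo = change_tick, new_tempo
        sec += (t - prev_tick) * tempo / (ppq * 1e6)
        out[i] = sec
    return out


def read_midi(path: str | Path, melody_id: str | None = None, condition: str = "real") -> Melody:
    """Read a monophonic type-0/1 standard MIDI file into a :class:`Melody`.

    The tempo map is resolved to seconds and onsets are shifted so the first
    note starts at 0.  Simultaneous or overlapping notes raise
    :class:`MonophonyError`; unparseable input raises :class:`FormatError`.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 14 or data[:4] != b"MThd":
        raise FormatError(f"{path}: not a standard MIDI file")
    header_len = struct.unpack(">I", data[4:8])[0]
    fmt, ntrks, division = struct.unpack(">HHH", data[8:14])
    if fmt not in (0, 1):
        raise FormatError(f"{path}: unsupported SMF format {fmt}")
    if division & 0x8000:
        raise FormatError(f"{path}: SMPTE time division not supported")
    ppq = division
    pos = 8 + header_len
    events: list[tuple[int, int, int, int]] = []
    for _ in range(ntrks):
        if data[pos : pos + 4] != b"MTrk":
            raise FormatError(f"{path}: missing track chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        events.extend(_parse_track(data[pos + 8 : pos + 8 + length]))
        pos += 8 + length
    events.sort(key=lambda e: (e[0], e[1] != 2))  # tempo changes first at a tick

    tempo_map = [(t, a) for t, kind, a, _ in events if kind == 2]
    notes_raw: list[tuple[int, int, int, int]] = []  # (on_tick, off_tick, pitch, vel)
    open_note: tuple[int, int, int] | None = None  # (tick, pitch, vel)
    for tick, kind, a, b in events:
        if kind == 1:  # note on
            if open_note is not None:
                raise MonophonyError(
                    f"{path}: note {a} starts at tick {tick} while note "
                    f"{open_note[1]} is still sounding"
                )
            open_note = (tick, a, b)
        elif kind == 0:  # note off
            if open_note is None or open_note[1] != a:
                continue
            notes_raw.append((open_note[0], tick, open_note[1], open_note[2]))
            open_note = None
    if open_note is not None:
        raise FormatError(f"{path}: unterminated note {open_note[1]}")
    if len(notes_raw) < 2:
        raise DegenerateMelodyError(f"{path}: fewer than 2 notes")

    ticks = np.array([t for row in notes_raw for t in row[:2]])
    secs = _ticks_to_seconds(ticks, tempo_map, ppq).reshape(-1, 2)
    t0 = secs[0, 0]
    notes = tuple(
        NoteEvent(onset=float(on - t0), pitch=p, duration=float(max(off - on, 1e-6)), velocity=v)
        for (on, off), (_, _, p, v) in zip(secs, notes_raw)
    )
    return Melody(id=melody_id or path.stem, notes=notes, condition=condition)


def write_midi(melody: Melody, path: str | Path) -> None:
    """Write a melody as a type-0 standard MIDI file (480 PPQ, 120 bpm tempo)."""
    track = bytearray()
    track += _write_varlen(0) + bytes([0xFF, 0x51, 0x03]) + _DEFAULT_TEMPO.to_bytes(3, "big")

    def to_ticks(sec: float) -> int:
        return int(round(sec * 1e6 / _DEFAULT_TEMPO * _PPQ))

    events = []  # (tick, order, status, pitch, vel)
    for n in melody.notes:
        events.append((to_ticks(n.onset), 1, 0x90, n.pitch, n.velocity))
        events.append((to_ticks(n.onset + n.duration), 0, 0x80, n.pitch, 0))
    events.sort(key=lambda e: (e[0], e[1]))
    prev = 0
    for tick, _, status, pitch, vel in events:
        track += _write_varlen(tick - prev) + bytes([status, pitch, vel])
        prev = tick
    track += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])

    out = b"MThd" + struct.pack(">IHHH", 6, 0, 1, _PPQ)
    out += b"MTrk" + struct.pack(">I", len(track)) + bytes(track)
    Path(path).write_bytes(out)


# --------------------------------------------------------------------------
# plain-text melody tables
# --------------------------------------------------------------------------

def write_melody_table(melody: Melody, path: str | Path) -> None:
    """Write one row per note: onset_s, pitch, duration_s, velocity (TSV)."""
    lines = ["onset_s\tpitch\tduration_s\tvelocity"]
    for n in melody.notes:
        lines.append(f"{n.onset:.9f}\t{n.pitch}\t{n.duration:.9f}\t{n.velocity}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_melody_table(path: str | Path, melody_id: str | None = None, condition: str = "real") -> Melody:
    lines = Path(path).read_text().strip().splitlines()
    if not lines or lines[0].split("\t")[0] != "onset_s":
        raise FormatError(f"{path}: not a melody table")
    notes = []
    for line in lines[1:]:
        onset, pitch, dur, vel = line.split("\t")
        notes.append(NoteEvent(float(onset), int(pitch), float(dur), int(vel)))
    return Melody(id=melody_id or Path(path).stem, notes=tuple(notes), condition=condition)


# --------------------------------------------------------------------------
# viewpoints and local intervals
# --------------------------------------------------------------------------

def derive_viewpoints(melody: Melody) -> tuple[ViewpointSequence, ViewpointSequence, LocalIntervals]:
    """Derive the cpitch and ioi_ratio viewpoint sequences and local intervals.

    cpitch is defined for every note; ioi_ratio needs two preceding IOIs and is
    defined from the third note.  IOI ratios are rounded to six decimals so
    grid-quantized rhythms give an exact finite alphabet.
    """
    n = len(melody)
    onsets = melody.onsets
    pitches = melody.pitches

    cpitch = ViewpointSequence("cpitch", tuple(int(p) for p in pitches), defined_from=0)

    iois = np.diff(onsets)  # length n-1, IOI preceding notes 2..n
    ratios = tuple(
        round(float(iois[k] / iois[k - 1]), RATIO_DECIMALS) for k in range(1, n - 1)
    )
    ioi_ratio = ViewpointSequence("ioi_ratio", ratios, defined_from=2)

    ioi = np.full(n, np.nan)
    ioi[1:] = iois
    ioi_next = np.full(n, np.nan)
    ioi_next[:-1] = iois
    ipi = np.full(n, np.nan)
    ipi[1:] = np.abs(np.diff(pitches))
    return cpitch, ioi_ratio, LocalIntervals(ioi=ioi, ioi_next=ioi_next, ipi=ipi)
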