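"""Note-by-note surprise and entropy of melodies from a PPM sequence model.

For each melody, pitch (cpitch) and timing (ioi_ratio) viewpoints are modelled
independently.  Predictions combine a short-term model (STM), built
incrementally from the melody being analysed, with a long-term model (LTM)
trained on the remaining melodies of the corpus via k-fold resampling (plus an
optional pre-training corpus).  In the "plus" configuration the LTM also keeps
learning, note by note, from the melody under analysis.

Outputs per note:

* ``Sp``/``St`` — surprise, −log2 of the combined model's probability of the
  observed pitch / IOI-ratio symbol, in bits;
* ``Ep``/``Et`` — Shannon entropy of the combined predictive distribution
  before the note, in bits.

Timing estimates are undefined (NaN) for the first two notes, which have no
IOI ratio.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .midi import Melody, ViewpointSequence, derive_viewpoints
from .ppm import PPMModel, combine_stm_ltm, ppm_fit, shannon_entropy

__all__ = ["InfoEstimates", "estimate_information", "estimates_to_frame"]


@dataclass
class InfoEstimates:
    """Per-note surprise/entropy for one melody; NaN where undefined."""

    melody_id: str
    onsets: np.ndarray
    Sp: np.ndarray
    Ep: np.ndarray
    St: np.ndarray
    Et: np.ndarray

    def __len__(self) -> int:
        return len(self.onsets)


def _score_sequence(
    symbols: Sequence,
    ltm: PPMModel,
    alphabet: tuple,
    max_order: int,
    bias: float,
    ltm_online: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Surprise and entropy for each symbol under STM+LTM combination."""
    stm = PPMModel(viewpoint=ltm.viewpoint, alphabet=alphabet, max_order=max_order)
    surprise = np.empty(len(symbols))
    entropy = np.empty(len(symbols))
    history: list = []
    index = {s: i for i, s in enumerate(alphabet)}
    for j, sym in enumerate(symbols):
        p = combine_stm_ltm(stm.predict(history), ltm.predict(history), bias=bias)
        surprise[j] = -np.log2(p[index[sym]])
        entropy[j] = shannon_entropy(p)
        stm.update(history, sym)
        if ltm_online:
            ltm.update(history, sym)
        history.append(sym)
    return surprise, entropy


def _fold_assignment(n: int, folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[perm] = np.arange(n) % folds
    return assignment


def estimate_information(
    corpus: Sequence[Melody],
    folds: int = 10,
    max_order: int = 10,
    bias: float = 2.0,
    pretrain_corpus: Sequence[Melody] | None = None,
    seed: int = 0,
    ltm_online: bool = True,
) -> dict[str, InfoEstimates]:
    """Resampled surprise/entropy estimates for every melody of a corpus.

    Melodies are assigned to ``folds`` folds (seed-deterministic); each
    melody's LTM is trained on the melodies of the other folds plus
    ``pretrain_corpus`` if given.  ``ltm_online=False`` freezes the LTM during
    the analysed melody (the "minus" variant).
    """
    corpus = list(corpus)
    if folds < 2:
        raise ConfigError("folds must be >= 2")
    if folds > len(corpus):
        raise ConfigError(f"folds={folds} exceeds corpus size {len(corpus)}")

    views = {m.id: derive_viewpoints(m) for m in corpus}
    pre_views = [derive_viewpoints(m) for m in (pretrain_corpus or [])]

    results: dict[str, InfoEstimates] = {}
    for m in corpus:
        n = len(m)
        results[m.id] = InfoEstimates(
            melody_id=m.id,
            onsets=m.onsets,
            Sp=np.full(n, np.nan),
            Ep=np.full(n, np.nan),
            St=np.full(n, np.nan),
            Et=np.full(n, np.nan),
        )

    assignment = _fold_assignment(len(corpus), folds, seed)
    for vp_idx, vp_name in ((0, "cpitch"), (1, "ioi_ratio")):
        seqs = {m.id: list(views[m.id][vp_idx].symbols) for m in corpus}
        pre_seqs = [list(v[vp_idx].symbols) for v in pre_views]
        alphabet_seen: dict = {}
        for s in pre_seqs + list(seqs.values()):
            for sym in s:
                alphabet_seen.setdefault(sym, None)
        alphabet = tuple(alphabet_seen)

        for fold in range(folds):
            train = [
                seqs[m.id]
                for m, a in zip(corpus, assignment)
                if a != fold
            ] + pre_seqs
            ltm_base = ppm_fit(
                train, max_order=max_order, viewpoint=vp_name, alphabet=alphabet
            )
            for m, a in zip(corpus, assignment):
                if a != fold:
                    continue
                ltm = copy.deepcopy(ltm_base) if ltm_online else ltm_base
                surprise, entropy = _score_sequence(
                    seqs[m.id], ltm, alphabet, max_order, bias, ltm_online
                )
                est = results[m.id]
                start = views[m.id][vp_idx].defined_from
                sl = slice(start, start + len(surprise))
                if vp_name == "cpitch":
                    est.Sp[sl], est.Ep[sl] = surprise, entropy
                else:
                    est.St[sl], est.Et[sl] = surprise, entropy
    return results


def estimates_to_frame(estimates: Mapping[str, InfoEstimates]) -> pd.DataFrame:
    """Long-format table: melody_id, note_index, onset_s, Sp, Ep, St, Et."""
    rows = []
    for mid in sorted(estimates):
        est = estimates[mid]
        for i in range(len(est)):
            rows.append(
                (mid, i, est.onsets[i], est.Sp[i], est.Ep[i], est.St[i], est.Et[i])
            )
    return pd.DataFrame(
        rows, columns=["melody_id", "note_index", "onset_s", "Sp", "Ep", "St", "Et"]
    )
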