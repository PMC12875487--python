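"""Variable-order Markov sequence model with PPM escape-method-C smoothing.

The model keeps exhaustive n-gram counts up to ``max_order`` and predicts the
next symbol by interpolated smoothing: at each context length the probability
mass assigned to escaping, t/(n+t) with t the number of distinct continuation
types and n the total count, is redistributed over the prediction of the next
shorter context, terminating in a uniform order-(−1) distribution over the
alphabet.  Interpolation (rather than back-off) means every context length
contributes for every symbol.

Symbols are arbitrary hashables; distributions are returned as dense numpy
arrays ordered by the model's alphabet.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .errors import AlphabetError, EmptyModelError

__all__ = ["PPMModel", "ppm_fit", "ppm_predict", "combine_stm_ltm", "shannon_entropy"]

#: smallest relative entropy used in certainty weighting, to keep weights finite
_MIN_RELATIVE_ENTROPY = 1e-6


@dataclass
class PPMModel:
    """N-gram counts up to ``max_order`` over a fixed, ordered alphabet."""

    viewpoint: str
    alphabet: tuple
    max_order: int = 10
    escape: str = "C"
    counts: dict = field(default_factory=lambda: defaultdict(dict))
    #: index of each alphabet symbol, for dense output
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.escape != "C":
            raise ValueError("only escape method C is implemented")
        self._index = {s: i for i, s in enumerate(self.alphabet)}
        if len(self._index) != len(self.alphabet):
            raise ValueError("alphabet contains duplicate symbols")

    # -- training ----------------------------------------------------------
    def update(self, history: Sequence[Hashable], symbol: Hashable) -> None:
        """Record ``symbol`` following ``history`` for all orders 0..max_order.

        ``history`` is the full preceding sequence; only its tail is used.
        Symbols outside the alphabet extend it.
        """
        if symbol not in self._index:
            self._index[symbol] = len(self.alphabet)
            self.alphabet = self.alphabet + (symbol,)
        h = tuple(history[-self.max_order:]) if self.max_order else ()
        for k in range(len(h) + 1):
            ctx = h[len(h) - k:]
            node = self.counts[ctx]
            node[symbol] = node.get(symbol, 0) + 1

    def update_sequence(self, sequence: Sequence[Hashable]) -> None:
        seq = list(sequence)
        for i, s in enumerate(seq):
            self.update(seq[:i], s)

    # -- prediction --------------------------------------------------------
    def predict(self, context: Sequence[Hashable]) -> np.ndarray:
        """Predictive distribution over the alphabet given ``context``.

        Always a proper distribution with strictly positive entries.
        """
        m = len(self.alphabet)
        if m == 0:
            raise EmptyModelError("model has an empty alphabet and no training data")
        p = np.full(m, 1.0 / m)  # order -1: uniform
        ctx = tuple(context[-self.max_order:]) if self.max_order else ()
        # blend from shortest to longest context so escape mass nests correctly
        for k in range(len(ctx) + 1):
            sub = ctx[len(ctx) - k:]
            node = self.counts.get(sub)
            if not node:
                continue
            n = sum(node.values())
            t = len(node)
            q = np.zeros(m)
            for sym, c in node.items():
                q[self._index[sym]] = c / (n + t)
            p = q + (t / (n + t)) * p
        return p


def ppm_fit(
    sequences: Iterable[Sequence[Hashable]],
    max_order: int = 10,
    viewpoint: str = "",
    alphabet: Sequence[Hashable] | None = None,
) -> PPMModel:
    """Tally n-grams of ``sequences`` for all orders 0..max_order.

    ``alphabet``, if given, pre-declares symbols (so an untrained model still
    predicts uniformly over it); otherwise the alphabet is the union of
    observed symbols.
    """
    sequences = [list(s) for s in sequences]
    if alphabet is None:
        seen: dict = {}
        for seq in sequences:
            for s in seq:
                seen.setdefault(s, None)
        alphabet = tuple(seen)
    model = PPMModel(viewpoint=viewpoint, alphabet=tuple(alphabet), max_order=max_order)
    if not model.alphabet and not sequences:
        raise EmptyModelError("no training sequences and no declared alphabet")
    for seq in sequences:
        model.update_sequence(seq)
    return model


def ppm_predict(model: PPMModel, context: Sequence[Hashable]) -> np.ndarray:
    return model.predict(context)


def shannon_entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits of a probability vector."""
    p = np.asarray(p, dtype=float)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def combine_stm_ltm(p_stm: np.ndarray, p_ltm: np.ndarray, bias: float = 2.0) -> np.ndarray:
    """Certainty-weighted geometric combination of two predictive distributions.

    Each model m gets weight w_m ∝ (H(p_m)/log2|A|)^(−bias): the lower its
    normalized entropy (the more certain it is), the more it dominates.  The
    weighted geometric mean is renormalized to sum to one.
    """
    p_stm = np.asarray(p_stm, dtype=float)
    p_ltm = np.asarray(p_ltm, dtype=float)
    if p_stm.shape != p_ltm.shape:
        raise AlphabetError(
            f"distributions over different alphabets: {p_stm.shape} vs {p_ltm.shape}"
        )
    m = len(p_stm)
    if m == 1:
        return np.ones(1)
    h_max = np.log2(m)
    rel = np.array(
        [
            max(shannon_entropy(p) / h_max, _MIN_RELATIVE_ENTROPY)
            for p in (p_stm, p_ltm)
        ]
    )
    w = rel ** (-bias)
    a = w[0] / w.sum()
    log_p = a * np.log(np.clip(p_stm, 1e-300, None)) + (1 - a) * np.log(
        np.clip(p_ltm, 1e-300, None)
    )
    log_p -= log_p.max()
    p = np.exp(log_p)
    return p / p.sum()
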