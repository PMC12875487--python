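"""Brute-force reference implementation of the PPM escape-C predictor.

Deliberately structured differently from the library: counts come from a
direct n-gram scan over the finished training sequences, and the predictive
probability is computed by top-down recursion from the longest matching
context, instead of the library's incremental updates and bottom-up blending.
"""

from collections import Counter, defaultdict


def ngram_counts(sequences, max_order):
    """counts[context_tuple][symbol] over all orders 0..max_order."""
    counts = defaultdict(Counter)
    for seq in sequences:
        seq = list(seq)
        for i in range(len(seq)):
            for k in range(0, min(max_order, i) + 1):
                counts[tuple(seq[i - k : i])][seq[i]] += 1
    return counts


def reference_predict(sequences, alphabet, max_order, context):
    """Predictive distribution (list ordered by ``alphabet``) after training."""
    counts = ngram_counts(sequences, max_order)
    ctx = tuple(context)[-max_order:] if max_order else ()

    def prob(symbol, k):
        if k < 0:
            return 1.0 / len(alphabet)
        sub = ctx[len(ctx) - k :]
        node = counts.get(sub)
        if not node:
            return prob(symbol, k - 1)
        n = sum(node.values())
        t = len(node)
        return node.get(symbol, 0) / (n + t) + (t / (n + t)) * prob(symbol, k - 1)

    return [prob(s, len(ctx)) for s in alphabet]
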