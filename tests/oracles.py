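"""Independent reference computations for decoder tests.

The enumeration oracle walks *every* token sequence of bounded length under
a toy model and scores it by the exact product of conditional probabilities
(accumulated as a running log-sum along the path, the same arithmetic a
correct decoder must perform). It shares only the model's probability table
with the implementation under test, not any search code.
"""

from __future__ import annotations

import math

import numpy as np

from beamchem.tokenizer import BEGIN


def enumerate_ranking(model, max_length: int):
    """All END-terminated sequences of <= max_length emitted tokens, ranked.

    Returns a list of (token_tuple, log_score) sorted by descending score,
    ties broken lexicographically by token-index sequence — the same total
    order a correct k-best decoder must produce.
    """
    vocab = model.vocabulary
    end_id = vocab.end_id
    completed: list[tuple[float, tuple[int, ...], tuple[str, ...]]] = []

    def expand(tokens, indices, log_score, depth):
        if depth == max_length:
            return
        p = np.asarray(model.next_token_distribution(tokens), dtype=float)
        for tok_id in np.flatnonzero(p > 0.0):
            tok_id = int(tok_id)
            score = log_score + math.log(p[tok_id])
            new_tokens = tokens + (vocab.tokens[tok_id],)
            new_indices = indices + (tok_id,)
            if tok_id == end_id:
                completed.append((score, new_indices, new_tokens))
            else:
                expand(new_tokens, new_indices, score, depth + 1)

    expand((BEGIN,), (), 0.0, 0)
    completed.sort(key=lambda e: (-e[0], e[1]))
    return [(tokens, score) for score, _idx, tokens in completed]


def count_terminating_sequences(n_tokens: int, max_length: int) -> int:
    """Number of END-terminated sequences emitting <= max_length tokens."""
    return sum(n_tokens ** t for t in range(max_length))


def greedy_decode(model, max_length: int):
    """Argmax-at-every-step decoding; the k=1 beam must coincide with it."""
    vocab = model.vocabulary
    tokens = (BEGIN,)
    log_score = 0.0
    for _ in range(max_length):
        p = np.asarray(model.next_token_distribution(tokens), dtype=float)
        best = int(np.flatnonzero(p == p.max())[0])
        log_score += math.log(p[best])
        tokens = tokens + (vocab.tokens[best],)
        if best == vocab.end_id:
            return tokens, log_score, True
    return tokens, log_score, False
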