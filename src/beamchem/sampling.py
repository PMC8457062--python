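"""Decoding: beam search (generate + score) and temperature sampling.

Beam search is the deterministic k-best decoder: at every step each live
partial string is extended with every vocabulary token, the k highest-scoring
incomplete extensions survive, and extensions that emit the end-of-string
token are archived in a completed pool. The score of a sequence is the
product of its stepwise conditional token probabilities — accumulated in log
space — which is also the ranking criterion for the finished designs
("beam search score"). Completed hypotheses do not consume beam slots;
otherwise short high-probability strings would be silently lost.

Temperature sampling is the stochastic baseline: tokens are drawn one at a
time from the model distribution sharpened (T < 1) or flattened (T > 1) by a
temperature parameter.

Both decoders only require a model object exposing ``vocabulary`` and
``next_token_distribution(prefix_tokens) -> probabilities``; a trained
checkpoint and the closed-form :class:`ToyModel` both satisfy this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from beamchem.tokenizer import BEGIN, END, TokenSequence, Vocabulary, detokenize

_NORMALIZATION_TOL = 1e-4


@dataclass(frozen=True)
class Hypothesis:
    """A partial or finished token sequence with its cumulative log-probability."""

    tokens: tuple[str, ...]
    log_score: float
    completed: bool

    @property
    def smiles(self) -> str:
        return detokenize(self.tokens)

    @property
    def probability(self) -> float:
        return math.exp(self.log_score)


@dataclass(frozen=True)
class BeamConfig:
    """Beam-search settings.

    ``width_k`` live hypotheses survive each step; ``max_length`` bounds the
    number of decoding steps (tokens emitted after BEGIN, END included).
    Score ties are broken lexicographically by token-index sequence, which is
    deterministic across platforms. ``length_normalize`` divides scores by
    token count for ranking — OFF by default, since the raw product is the
    beam search score. ``keep_incomplete`` returns max-length-truncated
    hypotheses (flagged by ``completed=False``) instead of discarding them.
    """

    width_k: int = 64
    max_length: int = 140
    length_normalize: bool = False
    keep_incomplete: bool = False

    def __post_init__(self) -> None:
        if self.width_k < 1:
            raise ValueError("width_k must be >= 1")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")


@dataclass(frozen=True)
class SampleConfig:
    """Temperature-sampling settings: T > 0, number of draws, RNG seed."""

    temperature: float = 1.0
    num_samples: int = 100
    max_length: int = 140
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")


class ToyModel:
    """Explicit table of conditional token probabilities for oracle tests.

    Sequence probabilities are available in closed form, so exhaustive
    enumeration of all bounded-length sequences gives an exact reference
    ranking. Supports i.i.d. rows (one distribution regardless of context)
    and first-order Markov rows (distribution keyed by the previous token).
    Satisfies the same decoding interface as a trained checkpoint.
    """

    def __init__(self, vocabulary: Vocabulary,
                 table: dict[str, np.ndarray]):
        """``table`` maps a context token (BEGIN or a chemical token) to a
        probability vector over the vocabulary; PAD/BEGIN entries must be 0.
        An i.i.d. model is a table whose rows are identical (or a table with
        the single key BEGIN used as fallback for every context)."""
        self.vocabulary = vocabulary
        self.table = {}
        for ctx, row in table.items():
            row = np.asarray(row, dtype=float)
            if row.shape != (len(vocabulary),):
                raise ValueError("row length must equal vocabulary size")
            if (row < 0).any():
                raise ValueError(f"negative probability in row {ctx!r}")
            if row[vocabulary.pad_id] != 0 or row[vocabulary.begin_id] != 0:
                raise ValueError("PAD/BEGIN must have probability 0")
            s = row.sum()
            if s <= 0:
                raise ValueError(f"row {ctx!r} is not normalizable")
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"row {ctx!r} does not sum to 1")
            self.table[ctx] = row
        if BEGIN not in self.table:
            raise ValueError("table must contain a row for the BEGIN context")

    def next_token_distribution(self, prefix) -> np.ndarray:
        tokens = prefix.tokens if isinstance(prefix, TokenSequence) else tuple(prefix)
        if not tokens or tokens[0] != BEGIN:
            raise ValueError("prefix must start with BEGIN")
        last = tokens[-1]
        row = self.table.get(last)
        if row is None:
            row = self.table[BEGIN]  # i.i.d. fallback
        return row


def _distribution(model, prefix_tokens: tuple[str, ...]) -> np.ndarray:
    p = np.asarray(model.next_token_distribution(prefix_tokens), dtype=float)
    if abs(float(p.sum()) - 1.0) > _NORMALIZATION_TOL:
        raise ValueError(
            f"model emitted a non-normalized distribution (sum={p.sum():.6f})")
    return p


def beam_search(model, config: BeamConfig) -> list[Hypothesis]:
    """Deterministic k-best decoding; returns completed hypotheses, ranked.

    Each step expands every live hypothesis with every token of nonzero
    probability; END-extended hypotheses move to the completed pool (they do
    not occupy beam slots), the ``width_k`` highest-scoring incomplete
    hypotheses survive, and decoding stops when no incomplete hypothesis
    remains or ``max_length`` steps have been taken. The completed pool is
    returned sorted by log-score descending (ties: lexicographic by
    token-index sequence). Every returned score is re-verified against a
    fresh stepwise evaluation of the model.
    """
    vocab: Vocabulary = model.vocabulary
    end_id = vocab.end_id
    # live beams as (log_score, index_tuple, token_tuple)
    live: list[tuple[float, tuple[int, ...], tuple[str, ...]]] = [
        (0.0, (), (BEGIN,))
    ]
    completed: list[tuple[float, tuple[int, ...], tuple[str, ...]]] = []

    batch_fn = getattr(model, "next_token_distribution_batch", None)

    for _depth in range(config.max_length):
        candidates: list[tuple[float, tuple[int, ...], tuple[str, ...]]] = []
        if batch_fn is not None and len(live) > 1:
            rows = np.asarray(batch_fn([toks for _s, _i, toks in live]), dtype=float)
            bad = np.abs(rows.sum(axis=1) - 1.0) > _NORMALIZATION_TOL
            if bad.any():
                raise ValueError("model emitted a non-normalized distribution")
        else:
            rows = None
        for row_i, (log_score, idx, toks) in enumerate(live):
            p = rows[row_i] if rows is not None else _distribution(model, toks)
            for tok_id in np.flatnonzero(p > 0.0):
                tok_id = int(tok_id)
                score = log_score + math.log(p[tok_id])
                entry = (score, idx + (tok_id,), toks + (vocab.tokens[tok_id],))
                if tok_id == end_id:
                    completed.append(entry)
                else:
                    candidates.append(entry)
        if not candidates:
            live = []
            break
        candidates.sort(key=lambda e: (-e[0], e[1]))
        live = candidates[:config.width_k]

    results = [Hypothesis(tokens=t, log_score=s, completed=True)
               for s, _i, t in completed]
    if config.keep_incomplete:
        results += [Hypothesis(tokens=t, log_score=s, completed=False)
                    for s, _i, t in live]

    def rank_key(h: Hypothesis):
        score = h.log_score / len(h.tokens) if config.length_normalize else h.log_score
        return (-score, tuple(vocab.index[t] for t in h.tokens))

    results.sort(key=rank_key)
    verifier = getattr(model, "sequence_log_prob", None)
    for h in results:
        if h.completed:
            check = verifier(h.tokens) if verifier is not None \
                else beam_score(model, h.tokens)
            if abs(check - h.log_score) > 1e-9:
                raise AssertionError(
                    f"beam score {h.log_score} disagrees with stepwise "
                    f"re-evaluation {check} for {h.tokens}")
    return results


def beam_score(model, seq) -> float:
    """Log-probability of a complete BEGIN...END sequence under the model.

    The sum of log conditional token probabilities; ``exp`` of the result is
    the sequence probability (the product form of the beam search score).
    """
    tokens = seq.tokens if isinstance(seq, TokenSequence) else tuple(seq)
    if not tokens or tokens[0] != BEGIN or tokens[-1] != END:
        raise ValueError("sequence must be complete: BEGIN ... END")
    vocab: Vocabulary = model.vocabulary
    total = 0.0
    for t in range(1, len(tokens)):
        tok = tokens[t]
        if tok not in vocab:
            raise KeyError(f"token {tok!r} not in vocabulary")
        p = _distribution(model, tokens[:t])
        p_tok = float(p[vocab.index[tok]])
        if p_tok <= 0.0:
            return -math.inf
        total += math.log(p_tok)
    return total


@dataclass(frozen=True)
class SampledString:
    """One temperature-sampling draw; ``truncated`` marks max-length cutoff."""

    smiles: str
    log_score: float
    truncated: bool


def temperature_sample(model, config: SampleConfig) -> list[SampledString]:
    """Draw sequences token-by-token from p^(1/T), renormalised; seeded."""
    vocab: Vocabulary = model.vocabulary
    rng = np.random.default_rng(config.seed)
    out: list[SampledString] = []
    for _ in range(config.num_samples):
        toks: tuple[str, ...] = (BEGIN,)
        log_score = 0.0
        truncated = True
        for _step in range(config.max_length):
            p = _distribution(model, toks)
            logits = np.full_like(p, -np.inf)
            nz = p > 0.0
            logits[nz] = np.log(p[nz]) / config.temperature
            logits -= logits.max()
            q = np.exp(logits)
            q[p <= 0.0] = 0.0
            q /= q.sum()
            tok_id = int(rng.choice(len(vocab), p=q))
            log_score += math.log(float(p[tok_id]))
            toks = toks + (vocab.tokens[tok_id],)
            if tok_id == vocab.end_id:
                truncated = False
                break
        out.append(SampledString(smiles=detokenize(toks), log_score=log_score,
                                 truncated=truncated))
    return out
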