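"""Decoders: beam search vs exhaustive enumeration, temperature sampling."""

import math

import numpy as np
import pytest

from beamchem.fixtures import (
    MEMORIZATION_SET,
    ToyModelSpec,
    make_toy_model,
    random_toy_model,
)
from beamchem.sampling import (
    BeamConfig,
    SampleConfig,
    ToyModel,
    beam_score,
    beam_search,
    temperature_sample,
)
from beamchem.tokenizer import BEGIN, END, Vocabulary, tokenize

from oracles import count_terminating_sequences, enumerate_ranking, greedy_decode


def test_worked_example_ranking(toy_iid):
    """i.i.d. p(a)=0.5, p(b)=0.3, p(END)=0.2, k=2, depth 3: the completed
    ranking starts '' (0.2), 'a' (0.10), 'b' (0.06)."""
    res = beam_search(toy_iid, BeamConfig(width_k=2, max_length=3))
    top = [(h.smiles, h.probability) for h in res[:3]]
    assert top[0] == ("", pytest.approx(0.2))
    assert top[1] == ("a", pytest.approx(0.10))
    assert top[2] == ("b", pytest.approx(0.06))
    oracle = enumerate_ranking(toy_iid, 3)
    # width 2 prunes 'b'-prefixed depth-2 strings; everything returned must
    # match the oracle's ranking restricted to the returned set
    oracle_order = {tokens: i for i, (tokens, _s) in enumerate(oracle)}
    positions = [oracle_order[h.tokens] for h in res]
    assert positions == sorted(positions)


def test_beam_score_closed_form(toy_iid):
    assert beam_score(toy_iid, (BEGIN, "a", END)) == pytest.approx(
        math.log(0.5) + math.log(0.2), abs=1e-12)
    assert beam_score(toy_iid, (BEGIN, END)) == pytest.approx(
        math.log(0.2), abs=1e-12)
    with pytest.raises(ValueError):
        beam_score(toy_iid, (BEGIN, "a"))  # incomplete
    with pytest.raises(KeyError):
        beam_score(toy_iid, (BEGIN, "z", END))


@pytest.mark.parametrize("seed", range(8))
@pytest.mark.parametrize("order", ["iid", "markov"])
def test_full_width_beam_equals_enumeration(seed, order):
    model = random_toy_model(n_tokens=3, order=order, seed=seed)
    depth = 5
    k = count_terminating_sequences(3, depth)
    res = beam_search(model, BeamConfig(width_k=k, max_length=depth))
    oracle = enumerate_ranking(model, depth)
    assert [h.tokens for h in res] == [t for t, _ in oracle]
    for h, (_t, score) in zip(res, oracle):
        assert h.log_score == pytest.approx(score, abs=1e-9)


@pytest.mark.parametrize("k", [1, 2, 4])
def test_narrow_beam_is_prefix_consistent_subset(k):
    model = random_toy_model(n_tokens=3, order="markov", seed=42)
    res = beam_search(model, BeamConfig(width_k=k, max_length=5))
    oracle = enumerate_ranking(model, 5)
    order = {tokens: i for i, (tokens, _s) in enumerate(oracle)}
    scores = dict((tuple(t), s) for t, s in oracle)
    positions = [order[h.tokens] for h in res]
    assert positions == sorted(positions)  # never reorders
    for h in res:
        assert h.log_score == pytest.approx(scores[h.tokens], abs=1e-9)


def test_k1_beam_contains_greedy_string():
    """The argmax-at-every-step string always completes inside the width-1
    beam's archived pool with the exact product score. (It need not rank
    first: a still shorter END-completion can score higher.)"""
    for seed in range(5):
        model = random_toy_model(n_tokens=3, order="markov", seed=seed)
        res = beam_search(model, BeamConfig(width_k=1, max_length=8))
        tokens, log_score, completed = greedy_decode(model, 8)
        if completed:
            by_tokens = {h.tokens: h.log_score for h in res}
            assert tokens in by_tokens
            assert by_tokens[tokens] == pytest.approx(log_score, abs=1e-12)


def test_anytime_soundness():
    """Widening the beam only inserts designs; shared designs keep their
    relative order."""
    model = random_toy_model(n_tokens=3, order="markov", seed=7)
    wide = beam_search(model, BeamConfig(width_k=8, max_length=5))
    narrow = beam_search(model, BeamConfig(width_k=2, max_length=5))
    wide_order = {h.tokens: i for i, h in enumerate(wide)}
    shared = [wide_order[h.tokens] for h in narrow if h.tokens in wide_order]
    assert shared == sorted(shared)


def test_completed_pool_does_not_consume_beam_slots(toy_iid):
    """The empty string (END at step one) must survive even at width 1."""
    res = beam_search(toy_iid, BeamConfig(width_k=1, max_length=4))
    assert res[0].smiles == "" and res[0].probability == pytest.approx(0.2)


def test_results_sorted_and_scores_verified(toy_iid):
    res = beam_search(toy_iid, BeamConfig(width_k=4, max_length=5))
    scores = [h.log_score for h in res]
    assert scores == sorted(scores, reverse=True)
    for h in res:
        assert h.completed
        assert beam_score(toy_iid, h.tokens) == pytest.approx(
            h.log_score, abs=1e-9)


def test_keep_incomplete_flags_truncations(toy_iid):
    res = beam_search(toy_iid, BeamConfig(width_k=2, max_length=2,
                                          keep_incomplete=True))
    incomplete = [h for h in res if not h.completed]
    assert incomplete and all(h.tokens[-1] != END for h in incomplete)


def test_beam_rejects_bad_config_and_bad_model(toy_iid):
    with pytest.raises(ValueError):
        BeamConfig(width_k=0)
    vocab = Vocabulary.from_chemical_tokens(("a",))
    row = np.zeros(len(vocab))
    row[vocab.index["a"]] = 0.6
    row[vocab.end_id] = 0.6  # sums to 1.2
    broken = ToyModel.__new__(ToyModel)
    broken.vocabulary = vocab
    broken.table = {BEGIN: row}
    with pytest.raises(ValueError, match="non-normalized"):
        beam_search(broken, BeamConfig(width_k=2, max_length=3))


def test_memorization_recovery(memorized_model):
    """A model overfit on five molecules returns all five at the head of a
    width-5 beam."""
    res = beam_search(memorized_model, BeamConfig(width_k=5, max_length=15))
    top8 = {h.smiles for h in res[:8]}
    assert set(MEMORIZATION_SET) <= top8


def test_beam_scores_on_clm_verify(memorized_model):
    res = beam_search(memorized_model, BeamConfig(width_k=3, max_length=10))
    for h in res[:10]:
        assert beam_score(memorized_model, h.tokens) == pytest.approx(
            h.log_score, abs=1e-9)


def test_temperature_zero_limit_is_greedy(toy_iid, memorized_model):
    for model in (toy_iid, memorized_model):
        greedy_tokens, _s, completed = greedy_decode(model, 15)
        greedy = "".join(t for t in greedy_tokens if t not in (BEGIN, END))
        draws = temperature_sample(model, SampleConfig(
            temperature=1e-6, num_samples=10, max_length=15, seed=1))
        assert all(d.smiles == greedy for d in draws)
        assert all(d.truncated != completed for d in draws)


def test_temperature_sampling_frequencies(toy_iid):
    draws = temperature_sample(toy_iid, SampleConfig(
        temperature=1.0, num_samples=2000, max_length=10, seed=8))
    first = [d.smiles[0] if d.smiles else END for d in draws]
    freq_a = first.count("a") / len(first)
    se = math.sqrt(0.5 * 0.5 / len(first))
    assert abs(freq_a - 0.5) <= 3 * se


def test_temperature_sampling_is_seeded(toy_iid):
    a = temperature_sample(toy_iid, SampleConfig(num_samples=50, seed=4))
    b = temperature_sample(toy_iid, SampleConfig(num_samples=50, seed=4))
    assert [d.smiles for d in a] == [d.smiles for d in b]
    c = temperature_sample(toy_iid, SampleConfig(num_samples=50, seed=5))
    assert [d.smiles for d in a] != [d.smiles for d in c]


def test_sample_config_validation():
    with pytest.raises(ValueError):
        SampleConfig(temperature=0.0)
    with pytest.raises(ValueError):
        SampleConfig(num_samples=0)


def test_length_normalized_ranking_prefers_longer(toy_iid):
    raw = beam_search(toy_iid, BeamConfig(width_k=4, max_length=4))
    norm = beam_search(toy_iid, BeamConfig(width_k=4, max_length=4,
                                           length_normalize=True))
    assert {h.tokens for h in raw} == {h.tokens for h in norm}
    assert raw[0].smiles == ""          # raw product favors the shortest
    assert norm[0].smiles != ""         # normalization lifts longer strings
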