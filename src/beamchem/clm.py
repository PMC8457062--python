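"""Recurrent next-token language model over SMILES tokens.

A stacked LSTM trained by teacher forcing to minimise mean per-token
cross-entropy of next-token prediction, the standard chemical-language-model
objective: given the tokens emitted so far, predict a probability for every
token in the vocabulary. The implementation is a compact, fully seeded NumPy
LSTM (forward pass, backpropagation through time, Adam) sized for CPU-scale
corpora; architecture and optimiser settings are configurable.

Training is staged: a model pre-trained on a broad corpus can be fine-tuned
on a small task-specific corpus by passing its checkpoint as ``init``. The
vocabulary is frozen at pre-training time; fine-tuning corpora containing
novel tokens are rejected explicitly rather than silently extending it.
"""

from __future__ import annotations

import copy
import csv
import json
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from beamchem.tokenizer import (
    BEGIN,
    END,
    TokenSequence,
    Vocabulary,
    build_vocabulary,
    tokenize,
)


@dataclass(frozen=True)
class CLMConfig:
    """Hyperparameters of the chemical language model.

    Parameters
    ----------
    vocab_size
        Size of the token vocabulary; ``None`` means "set when the
        pre-training vocabulary is built".
    embedding_dim, hidden_units, num_recurrent_layers
        LSTM architecture. Defaults (64 / 256 / 2) are deliberately small
        enough for CPU training and can be raised for full-scale corpora.
    learning_rate, batch_size
        Adam step size and minibatch size.
    max_length
        Maximum token count (BEGIN/END included) accepted at training
        (longer molecules are skipped) and imposed at decoding.
    seed
        Fixes weight initialisation and epoch shuffling; identical seeds and
        corpora give bit-identical checkpoints.
    """

    vocab_size: int | None = None
    embedding_dim: int = 64
    hidden_units: int = 256
    num_recurrent_layers: int = 2
    learning_rate: float = 3e-3
    batch_size: int = 64
    max_length: int = 140
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_units", "num_recurrent_layers",
                     "batch_size", "max_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


# ---------------------------------------------------------------------------
# LSTM internals
# ---------------------------------------------------------------------------

def _init_weights(config: CLMConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    V, D, H = config.vocab_size, config.embedding_dim, config.hidden_units
    w: dict[str, np.ndarray] = {}
    w["emb"] = rng.uniform(-0.1, 0.1, size=(V, D))
    for layer in range(config.num_recurrent_layers):
        n_in = D if layer == 0 else H
        sx = 1.0 / np.sqrt(n_in)
        sh = 1.0 / np.sqrt(H)
        w[f"Wx{layer}"] = rng.uniform(-sx, sx, size=(n_in, 4 * H))
        w[f"Wh{layer}"] = rng.uniform(-sh, sh, size=(H, 4 * H))
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias: remember by default
        w[f"b{layer}"] = b
    so = 1.0 / np.sqrt(H)
    w["Wout"] = rng.uniform(-so, so, size=(H, V))
    w["bout"] = np.zeros(V)
    return w


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _forward(weights: dict, config: CLMConfig, X: np.ndarray):
    """Run the stacked LSTM over input token ids X (B, T).

    Returns logits (B, T, V) and the cache needed for BPTT.
    """
    B, T = X.shape
    H = config.hidden_units
    L = config.num_recurrent_layers
    x = weights["emb"][X]  # (B, T, D)
    cache_layers = []
    for layer in range(L):
        Wx, Wh, b = weights[f"Wx{layer}"], weights[f"Wh{layer}"], weights[f"b{layer}"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        steps = []
        # pre-compute the input contribution for all timesteps at once
        xz = x @ Wx  # (B, T, 4H)
        for t in range(T):
            z = xz[:, t, :] + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            steps.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[:, t, :] = h
        cache_layers.append({"x": x, "steps": steps, "hs": hs})
        x = hs
    logits = x @ weights["Wout"] + weights["bout"]
    return logits, {"layers": cache_layers, "X": X, "top": x}


def _loss_and_grads(weights: dict, config: CLMConfig, X: np.ndarray,
                    Y: np.ndarray, pad_id: int):
    """Mean per-token cross-entropy and its gradients (masked on PAD targets)."""
    B, T = X.shape
    H = config.hidden_units
    V = config.vocab_size
    logits, cache = _forward(weights, config, X)
    mask = (Y != pad_id)
    n_tok = int(mask.sum())
    m = logits.max(axis=2, keepdims=True)
    p = np.exp(logits - m)
    p /= p.sum(axis=2, keepdims=True)
    logp = np.log(np.take_along_axis(p, Y[..., None], axis=2)[..., 0] + 1e-300)
    loss = -(logp * mask).sum() / n_tok

    dlogits = p.copy()
    np.put_along_axis(
        dlogits, Y[..., None],
        np.take_along_axis(dlogits, Y[..., None], axis=2) - 1.0, axis=2,
    )
    dlogits *= mask[..., None] / n_tok

    grads = {k: np.zeros_like(v) for k, v in weights.items()}
    top = cache["top"]
    grads["Wout"] = top.reshape(-1, H).T @ dlogits.reshape(-1, V)
    grads["bout"] = dlogits.sum(axis=(0, 1))
    dh_above = dlogits @ weights["Wout"].T  # (B, T, H)

    for layer in reversed(range(config.num_recurrent_layers)):
        lc = cache["layers"][layer]
        Wx, Wh = weights[f"Wx{layer}"], weights[f"Wh{layer}"]
        dWx, dWh = grads[f"Wx{layer}"], grads[f"Wh{layer}"]
        db = grads[f"b{layer}"]
        dx_all = np.zeros_like(lc["x"])
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, tc = lc["steps"][t]
            dh = dh_above[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            x_t = lc["x"][:, t, :]
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_all[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        dh_above = dx_all  # becomes the "from above" gradient of the layer below
    # embedding: scatter-add the gradient of layer-0 inputs
    np.add.at(grads["emb"], cache["X"], dh_above)
    return loss, grads


class _Adam:
    def __init__(self, weights: dict, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict, grads: dict, clip: float) -> None:
        norm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = clip / norm if norm > clip else 1.0
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, w in weights.items():
            g = grads[k] * scale
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            w -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

@dataclass
class ModelCheckpoint:
    """The trained conditional next-token distribution at one epoch of a stage.

    Exposes the decoding interface used by the sampling module:
    :attr:`vocabulary` and :meth:`next_token_distribution`.
    """

    config: CLMConfig
    weights: dict[str, np.ndarray]
    stage_label: str
    epoch: int
    vocabulary: Vocabulary
    train_loss: float = float("nan")

    def _masked_softmax(self, logits: np.ndarray) -> np.ndarray:
        """Softmax over the last axis with PAD/BEGIN zeroed and renormalised
        (neither is ever emitted at decode time)."""
        z = logits - logits.max(axis=-1, keepdims=True)
        p = np.exp(z)
        p[..., self.vocabulary.pad_id] = 0.0
        p[..., self.vocabulary.begin_id] = 0.0
        p /= p.sum(axis=-1, keepdims=True)
        return p

    def next_token_distribution(self, prefix) -> np.ndarray:
        """p(. | prefix) over the vocabulary for a BEGIN-started prefix.

        PAD and BEGIN receive probability 0 (they are never emitted at decode
        time) and the remainder is renormalised. Deterministic for a fixed
        checkpoint.
        """
        tokens = prefix.tokens if isinstance(prefix, TokenSequence) else tuple(prefix)
        if not tokens or tokens[0] != BEGIN:
            raise ValueError("prefix must start with BEGIN")
        if END in tokens:
            raise ValueError("prefix must not contain END")
        if len(tokens) > self.config.max_length:
            raise ValueError(
                f"prefix of {len(tokens)} tokens exceeds max_length "
                f"{self.config.max_length}")
        ids = np.array([self.vocabulary.encode(tokens)], dtype=np.int64)
        logits, _ = _forward(self.weights, self.config, ids)
        return self._masked_softmax(logits[0, -1, :])

    def next_token_distribution_batch(self, prefixes) -> np.ndarray:
        """Vectorised :meth:`next_token_distribution` for equal-length
        prefixes; returns one probability row per prefix."""
        ids = np.array([self.vocabulary.encode(
            p.tokens if isinstance(p, TokenSequence) else tuple(p))
            for p in prefixes], dtype=np.int64)
        logits, _ = _forward(self.weights, self.config, ids)
        return self._masked_softmax(logits[:, -1, :])

    def sequence_log_prob(self, tokens) -> float:
        """Log-probability of a complete BEGIN...END sequence, recomputed
        from scratch in a single pass (stepwise conditionals of the RNN are
        exactly the per-position outputs of one forward run)."""
        toks = tokens.tokens if isinstance(tokens, TokenSequence) else tuple(tokens)
        if not toks or toks[0] != BEGIN or toks[-1] != END:
            raise ValueError("sequence must be complete: BEGIN ... END")
        ids = np.array(self.vocabulary.encode(toks), dtype=np.int64)
        logits, _ = _forward(self.weights, self.config, ids[None, :-1])
        p = self._masked_softmax(logits[0])
        stepwise = p[np.arange(len(ids) - 1), ids[1:]]
        if (stepwise <= 0.0).any():
            return -np.inf
        return float(np.log(stepwise).sum())

    def save(self, directory: str | os.PathLike) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.weights)
        meta = {
            "config": {k: v for k, v in self.config.__dict__.items()},
            "stage_label": self.stage_label,
            "epoch": self.epoch,
            "train_loss": self.train_loss,
            "vocabulary": list(self.vocabulary.tokens),
        }
        with open(os.path.join(directory, "meta.json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "ModelCheckpoint":
        with open(os.path.join(directory, "meta.json"), "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        with np.load(os.path.join(directory, "weights.npz")) as npz:
            weights = {k: npz[k].copy() for k in npz.files}
        return cls(
            config=CLMConfig(**meta["config"]),
            weights=weights,
            stage_label=meta["stage_label"],
            epoch=meta["epoch"],
            vocabulary=Vocabulary(tokens=tuple(meta["vocabulary"])),
            train_loss=meta["train_loss"],
        )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _encode_corpus(corpus: Sequence[str], vocab: Vocabulary,
                   max_length: int) -> tuple[list[list[int]], int]:
    """Encode BEGIN + tokens + END per molecule; skip over-length molecules."""
    encoded: list[list[int]] = []
    skipped = 0
    for smiles in corpus:
        seq = tokenize(smiles)
        if len(seq.tokens) + 1 > max_length:  # +1 for the END target position
            skipped += 1
            continue
        encoded.append(vocab.encode(seq.tokens) + [vocab.end_id])
    return encoded, skipped


def train(
    corpus: Sequence[str],
    config: CLMConfig,
    epochs: int,
    init: ModelCheckpoint | None = None,
    *,
    stage_label: str = "pretrain",
    checkpoint_dir: str | os.PathLike | None = None,
    log_path: str | os.PathLike | None = None,
) -> list[ModelCheckpoint]:
    """Train (or fine-tune) the model, returning one checkpoint per epoch.

    One epoch is one full pass over the corpus. Pre-training (``init=None``)
    builds a fresh vocabulary from the corpus; fine-tuning reuses the
    initial checkpoint's vocabulary verbatim and raises if the corpus
    contains tokens outside it (listing the novel tokens). With a fixed
    ``config.seed`` the run is bit-reproducible.

    Checkpoints are written to ``checkpoint_dir/<stage_label>/epoch_NNN`` when
    a directory is given, and per-epoch mean losses to ``log_path`` as CSV.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if init is not None:
        vocab = init.vocabulary
        novel: set[str] = set()
        for smiles in corpus:
            novel.update(t for t in tokenize(smiles).chemical_tokens if t not in vocab)
        if novel:
            raise ValueError(
                "fine-tuning corpus contains tokens absent from the "
                f"pre-training vocabulary: {sorted(novel)}")
        config = replace(config, vocab_size=len(vocab))
        weights = copy.deepcopy(init.weights)
    else:
        vocab = build_vocabulary(corpus)
        config = replace(config, vocab_size=len(vocab))
        weights = _init_weights(config, np.random.default_rng(config.seed))

    encoded, _ = _encode_corpus(corpus, vocab, config.max_length)
    if not encoded:
        raise ValueError("no trainable sequences (all skipped or empty corpus)")

    rng = np.random.default_rng(config.seed + 1)
    adam = _Adam(weights, config.learning_rate)
    pad = vocab.pad_id
    checkpoints: list[ModelCheckpoint] = []
    log_rows: list[tuple[int, float]] = []

    for epoch in range(1, epochs + 1):
        order = rng.permutation(len(encoded))
        total_loss = 0.0
        total_tok = 0
        for start in range(0, len(encoded), config.batch_size):
            batch = [encoded[i] for i in order[start:start + config.batch_size]]
            T = max(len(s) for s in batch) - 1
            X = np.full((len(batch), T), pad, dtype=np.int64)
            Y = np.full((len(batch), T), pad, dtype=np.int64)
            for r, s in enumerate(batch):
                n = len(s) - 1
                X[r, :n] = s[:-1]
                Y[r, :n] = s[1:]
            loss, grads = _loss_and_grads(weights, config, X, Y, pad)
            n_tok = int((Y != pad).sum())
            total_loss += loss * n_tok
            total_tok += n_tok
            adam.step(weights, grads, config.grad_clip)
        mean_loss = total_loss / total_tok
        ckpt = ModelCheckpoint(
            config=config,
            weights=copy.deepcopy(weights),
            stage_label=stage_label,
            epoch=epoch,
            vocabulary=vocab,
            train_loss=mean_loss,
        )
        checkpoints.append(ckpt)
        log_rows.append((epoch, mean_loss))
        if checkpoint_dir is not None:
            ckpt.save(os.path.join(checkpoint_dir, stage_label, f"epoch_{epoch:03d}"))

    if log_path is not None:
        with open(log_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "mean_loss"])
            writer.writerows(log_rows)
    return checkpoints


def mean_log_likelihood(model: ModelCheckpoint, corpus: Iterable[str]) -> float:
    """Mean per-molecule log-likelihood of complete SMILES under a checkpoint.

    Used to quantify the fine-tuning bias: after fine-tuning on a narrow
    structural family, held-out members of that family should become more
    likely.
    """
    from beamchem.sampling import beam_score  # local import to avoid a cycle

    scores = [beam_score(model, tokenize(s)) for s in corpus]
    if not scores:
        raise ValueError("empty corpus")
    return float(np.mean(scores))
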