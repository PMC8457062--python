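# Methods

## Model

The generative model is a stacked LSTM over SMILES tokens trained by
teacher forcing: given tokens x₁…xₜ₋₁ (prefixed by a begin-of-string
marker), it outputs a categorical distribution p(xₜ | x₁…xₜ₋₁) over the
vocabulary, and training minimizes the mean per-token cross-entropy of the
next-token prediction. The implementation is a compact double-precision
NumPy LSTM (forward pass, backpropagation through time, global-norm
gradient clipping, Adam) rather than a deep-learning-framework module; at
the corpus sizes this package targets (10²–10⁴ molecules, vocabularies of
20–60 tokens) this trains in seconds on one CPU and is bit-reproducible
from a single integer seed, which the decoding and pipeline guarantees
depend on.

Assumptions inherited from the SMILES-CLM family: molecules are adequately
represented as token strings; one canonical SMILES per molecule (no
randomized/augmented SMILES); chemistry is learned implicitly — the model
has no valence rules, so invalid strings are possible and are filtered
downstream, never repaired.

## Decoding

**Beam search** is deterministic k-best decoding. Each step expands every
live prefix with every nonzero-probability token; extensions ending in the
end-of-string token are moved to a completed pool, and the k
highest-scoring incomplete prefixes survive. The score is the running sum
of log conditional token probabilities (log-domain product; the raw product
underflows at realistic lengths). Key choices:

- *Completed pool semantics.* Finished strings never occupy beam slots.
  Otherwise a short high-probability completion (e.g. the empty string in
  the toy example) would evict live prefixes or be lost. A corollary worth
  knowing: the width-1 beam archives the END-completion of every step, so
  its top-ranked result can be shorter than the greedy trajectory's string;
  the greedy string itself is always in the pool.
- *No length normalization by default.* The score is the raw product, which
  favors short strings; `length_normalize` divides by token count for
  ranking only.
- *Tie-breaking* is lexicographic by token-index sequence — deterministic
  across platforms.
- *Truncation.* Prefixes still alive at `max_length` are discarded unless
  `keep_incomplete` is set, in which case they are returned flagged.
- Every returned score is re-verified against a fresh from-scratch
  evaluation of the model (tolerance 1e-9 in log space); a model emitting a
  distribution off normalization by more than 1e-4 is rejected.

**Temperature sampling**, the stochastic baseline, draws each token from
p^(1/T) renormalized (computed in log space for numerical stability at
small T). T → 0 recovers greedy decoding; T = 1 samples the model
distribution. Draws are seeded and reproducible.

## Staged fine-tuning pipeline

Transfer learning proceeds in stages: each stage continues training from
the previous stage's final checkpoint on a smaller, more focused corpus.
The vocabulary is frozen at pre-training; a fine-tuning corpus with novel
tokens is rejected explicitly (silently extending the embedding would make
checkpoints incompatible across stages). The optimizer state is reset at
each stage. Beam search runs on every final-stage checkpoint inside the
sampling window (the early epochs are skipped so the model has absorbed the
fine-tuning set before sampling begins); designs from all window epochs are
pooled and their scores compared directly. The reference full-scale
protocol (10 pre-training epochs on ~365k molecules; 20 epochs on 255
ligands; 16 epochs on 4 modulators; window 5–16) is recorded as
`pipeline.REFERENCE_PROTOCOL`.

Filtering: a design is *valid* iff RDKit parses and sanitizes it under
default valence rules. Valid designs are canonicalized; duplicates merge to
the maximum log-score (earlier epoch on exact ties) — a declared choice, as
is pooling scores across checkpoints. Designs reproducing a training
molecule are retained but flagged `is_novel=False`, so the memorization
rate is a reportable quantity; counts satisfy raw = valid + invalid and
valid = unique + merged by construction, and the test suite asserts it.
Pooled ranks break score ties by canonical SMILES string, the pooled-level
analogue of the decoder's token-index tie-break.

## Parameters

| Parameter | Default | Notes |
|---|---|---|
| embedding_dim / hidden_units / layers | 64 / 256 / 2 | architecture defaults; tests and the acceptance run use 16–24 / 64–96 / 1–2, which suffice at fixture scale |
| learning_rate | 3e-3 | Adam (β₁=0.9, β₂=0.999); gradient clip 5.0 (global norm) |
| batch_size | 64 | sequences, padded per batch; loss masked on padding |
| max_length | 140 tokens | over-length molecules skipped at training; decoding stops at this depth |
| beam width k | 64 (CLI) | a declared default; the toy schematic value is k=2 |
| fingerprint | radius 2 bonds, 1024 bits | Morgan/circular |

## Synthetic data

`fixtures.make_corpus` generates the study corpora: enumerable linear
families (alkanes, alcohols, ethers, amines), a narrow benzene-scaffold
family (monosubstituted aromatics — the "task-specific ligands" analogue,
with membership decidable by substructure match), and a seeded "mixed"
family of random acyclic C/N/O trees with ~10 % aromatics interleaved so
the pre-training vocabulary covers aromatic tokens. All corpora are valid,
canonical, unique, and deterministic given the spec.

What these fixtures emulate: corpus-scale statistics (a broad pre-training
distribution vs. a narrow fine-tuning family), exact enumerability for
oracle tests, and guaranteed tokenizer round-trips. What they do **not**
emulate: real medicinal-chemistry structure (rings beyond benzene,
stereochemistry, charged species), realistic vocabulary sizes, or any
bioactivity signal. Passing tests therefore demonstrate the correctness of
the machinery (decoding exactness, training dynamics, filtering
bookkeeping, transfer-learning bias), not prospective design performance on
real targets.

Toy probability models (`ToyModel`) are explicit conditional tables (i.i.d.
or first-order Markov) satisfying the decoding interface; all bounded-depth
sequence probabilities are available in closed form, so exhaustive
enumeration provides an exact reference ranking for the beam. Conservation
holds at every depth: terminated + live probability mass = 1 (the tests
check this to 1e-6), with live mass ≤ (1 − p_END)^depth under an END floor.

## Problem sizes

The default verification runs use: 500-molecule mixed pre-training corpus
(8 epochs) with 10 + 10 fine-tune/held-out family molecules for the
transfer-learning checks; a 120-molecule corpus with a two-stage schedule
(12 and 4 molecules, window epochs 2–5, k=8) for the pipeline determinism
checks; 300–500 epochs for the memorization experiments; 25 random toy
models (2–4 token vocabularies, depth 4–6) for decoder/enumeration
equivalence; 10,000 draws for sampling-frequency checks. The acceptance
script uses a 400-molecule corpus, 6 pre-training epochs, a 10-molecule
then 4-molecule schedule with window 3–8, and k=16. These sizes were
chosen so every experiment is exactly reproducible on a single CPU in
seconds while keeping each effect (memorization floor, family bias,
enumeration coverage) unambiguous.

## Numerical choices and degenerate inputs

- Scores accumulate in double-precision log space; `exp(log_score)` is also
  reported as a probability.
- PAD and BEGIN are masked to probability zero at decode time and the
  distribution renormalized; training masks the loss on padding targets.
- Softmax is computed with max-subtraction; sigmoid inputs are clipped at
  ±60 before exponentiation.
- Tanimoto of two all-zero fingerprints is defined as 0 (the set formula is
  0/0 there). Fsp³ raises on carbon-free molecules rather than returning an
  arbitrary value; the CLI reports NaN for them.
- Distance distributions require ≥ 2 molecules (≥ 1 pair); within-set mode
  excludes a record paired with itself but keeps pairs between duplicate
  entries.
- Empty corpora, unachievable fixture sizes, invalid sampling windows, and
  non-normalized model outputs all fail fast with explicit messages.

## Known limitations

- The LSTM is CPU-scale; pre-training on hundreds of thousands of
  molecules is out of intended scope (the architecture is configurable but
  the NumPy backend is not GPU-accelerated).
- Beam search archives an END-completion of every live prefix at every
  depth, so the raw completed pool is large and its validity fraction low;
  the ranked head of the pool is what matters.
- No SMILES augmentation, no attention/transformer architectures, no
  diverse/stochastic beam variants, no nucleus sampling.
- 3-D shape/electrostatics descriptors are not implemented; the
  `DescriptorSet` protocol in `chem_eval` is the plug-in point.
- Synthesizability, retrosynthesis, and bioactivity assessment are outside
  the package: the beam score ranks by model likelihood only.
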