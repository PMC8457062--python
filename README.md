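# beamchem

Chemical language modeling with beam-search design **and** scoring of
molecules.

## The problem

Generative SMILES language models (CLMs) can propose novel bioactive
molecules, but stochastic ("temperature") sampling produces large libraries
that still need an *external* scoring function to decide which designs are
worth making. `beamchem` implements the model-intrinsic alternative:
**beam-search decoding**, which simultaneously generates the *k* most likely
SMILES strings under the model and ranks them by the model's own sequence
probability. The probability of a design is

```
score(x₁ … x_T) = ∏ₜ p(xₜ | x₁ … xₜ₋₁)        (accumulated as Σₜ log p)
```

the product of the conditional probabilities of its tokens — the *beam
search score*. Under the working hypothesis that fine-tuning concentrates
probability mass on the design objective, the most probable strings are the
most promising designs, and no external ranking model is needed.

The package is aimed at method-oriented computational chemists: it provides
the complete workflow — tokenization, LSTM next-token training, staged
transfer learning, beam/temperature decoding, validity filtering and
ranking, and descriptor-based evaluation (Fsp³, Morgan/Tanimoto) — at a
scale that runs on one CPU, with synthetic corpus generators so every part
is testable offline.

## The method

1. **Tokenize** SMILES into lexical units. The tokenizer uses a
   longest-match regular grammar: bracket atoms (`[nH]`, `[C@@H]`) and the
   halogens `Cl`/`Br` are single tokens, `%NN` ring labels are kept whole,
   everything else is one character (see `beamchem/tokenizer.py` for the
   exact grammar).
2. **Pre-train** a stacked-LSTM next-token model by teacher forcing
   (mean per-token cross-entropy) on a broad corpus; **fine-tune** it in
   stages on small task-specific sets, reusing the frozen pre-training
   vocabulary. One checkpoint is written per epoch. The reference protocol
   this mirrors at full scale: 10 pre-training epochs on ~365k molecules,
   then 20 epochs on 255 target ligands, then 16 epochs on 4
   natural-product modulators.
3. **Decode** each checkpoint in an epoch window with beam search: at every
   step all live prefixes are extended with every token, END-terminated
   strings are archived (they never occupy beam slots), and the *k* best
   incomplete prefixes survive. Decoding is fully deterministic.
4. **Pool and rank**: all strings from the window are validity-filtered
   (RDKit sanitization), canonicalized, deduplicated (best score wins),
   flagged for novelty against the training corpora, and ranked by beam
   search score.
5. **Evaluate** with Fsp³ (fraction of sp³ carbons) and Morgan-fingerprint
   Tanimoto similarity to reference actives / pairwise distance
   distributions.

## Worked example

The decoders accept anything exposing `vocabulary` and
`next_token_distribution`, including an explicit probability table. With
i.i.d. token probabilities p(a) = 0.5, p(b) = 0.3, p(END) = 0.2, a width-2
beam with at most 3 decoding steps yields:

```python
from beamchem import BeamConfig, ToyModelSpec, beam_search, make_toy_model
from beamchem.tokenizer import END

model = make_toy_model(ToyModelSpec(tokens=("a", "b"), order="iid",
                                    table={"a": 0.5, "b": 0.3, END: 0.2}))
for h in beam_search(model, BeamConfig(width_k=2, max_length=3)):
    print(repr(h.smiles), round(h.probability, 4))
```

```
'' 0.2
'a' 0.1
'b' 0.06
'aa' 0.05
'ab' 0.03
```

The empty string scores 0.2 (END immediately), `"a"` scores
0.5 × 0.2 = 0.10, and so on — exactly the product of token probabilities.
Note the highest-probability string is the *shortest*: the raw product
score favors short strings (a `length_normalize` option exists but is off
by default, matching the score definition above).

A scaled-down transfer-learning run (`scripts/acceptance.py --seed 1`,
pre-training on 400 mixed synthetic molecules, then fine-tuning toward a
narrow benzene-scaffold family) prints, among other quantities:

```
family_fraction_top20_pretrained_pct: 0 (n=20)
family_fraction_top20_finetuned_pct: 80 (n=20)
heldout_mean_log_likelihood_pretrained: -18.6 (n=10)
heldout_mean_log_likelihood_finetuned: -5.067 (n=10)
```

i.e. fine-tuning raises the likelihood of unseen family members by ~13.5
nats per molecule and shifts the top-20 beam designs from 0 % to 80 %
family membership — the low-data design bias the workflow exists to exploit.

## Command line

```bash
beamchem fixtures --family mixed --size 400 --out corpus.smi   # synthetic corpus
beamchem train corpus.smi --epochs 10 --seed 1 --out run/      # pre-train
beamchem finetune ligands.smi --init run/pretrain/epoch_010 --out run/
beamchem beam --ckpt run/finetune/epoch_016 -k 64 --out designs.csv
beamchem sample --ckpt run/finetune/epoch_016 --temperature 0.7 -n 1000
beamchem design --config run.yaml                              # full pipeline
beamchem eval --designs d_ranked.csv --references actives.smi
```

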