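"""Shared fixtures: small corpora, toy models, and trained checkpoints.

The expensive fixtures (trained models, the pipeline run) are session-scoped
so each training run happens once per test session.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from beamchem.clm import CLMConfig, train
from beamchem.fixtures import (
    CorpusSpec,
    MEMORIZATION_SET,
    ToyModelSpec,
    make_corpus,
    make_toy_model,
)
from beamchem.pipeline import FineTuneSchedule, Stage, run_schedule
from beamchem.sampling import BeamConfig
from beamchem.tokenizer import END


@pytest.fixture(scope="session")
def toy_iid():
    """The worked i.i.d. example: p(a)=0.5, p(b)=0.3, p(END)=0.2."""
    return make_toy_model(ToyModelSpec(
        tokens=("a", "b"), order="iid", table={"a": 0.5, "b": 0.3, END: 0.2}))


@pytest.fixture(scope="session")
def mixed_corpus():
    return make_corpus(CorpusSpec(family="mixed", size=500,
                                  max_heavy_atoms=12, seed=11))


@pytest.fixture(scope="session")
def aromatic_corpus():
    return make_corpus(CorpusSpec(family="aromatics", size=20,
                                  max_heavy_atoms=14))


@pytest.fixture(scope="session")
def memorized_model():
    """Tiny 2-layer x 64-unit model overfit on five short distinct molecules."""
    cfg = CLMConfig(embedding_dim=16, hidden_units=64, num_recurrent_layers=2,
                    learning_rate=5e-3, batch_size=8, max_length=20, seed=3)
    return train(list(MEMORIZATION_SET), cfg, 300)[-1]


@pytest.fixture(scope="session")
def bias_experiment(mixed_corpus, aromatic_corpus):
    """Scaled-down transfer-learning run: broad pre-training, narrow-family
    fine-tuning, plus the held-out family molecules."""
    finetune_set, held_out = aromatic_corpus[0::2], aromatic_corpus[1::2]
    cfg = CLMConfig(embedding_dim=24, hidden_units=96, num_recurrent_layers=1,
                    learning_rate=5e-3, batch_size=32, max_length=60, seed=5)
    pretrained = train(mixed_corpus, cfg, 8, stage_label="pretrain")[-1]
    finetuned = train(finetune_set, cfg, 25, init=pretrained,
                      stage_label="finetune")[-1]
    return {
        "pretrained": pretrained,
        "finetuned": finetuned,
        "finetune_set": finetune_set,
        "held_out": held_out,
    }


def _pipeline_once(seed: int):
    pre_corpus = make_corpus(CorpusSpec(family="mixed", size=120,
                                        max_heavy_atoms=10, seed=23))
    arom = make_corpus(CorpusSpec(family="aromatics", size=16,
                                  max_heavy_atoms=13))
    cfg = CLMConfig(embedding_dim=16, hidden_units=64, num_recurrent_layers=1,
                    learning_rate=5e-3, batch_size=16, max_length=40, seed=seed)
    pretrained = train(pre_corpus, cfg, 4, stage_label="pretrain")[-1]
    schedule = FineTuneSchedule(
        stages=(Stage(corpus=tuple(arom[:12]), epochs=5, label="broad_family"),
                Stage(corpus=tuple(arom[12:16]), epochs=6, label="narrow_family")),
        sample_window=(2, 5),
    )
    beam = BeamConfig(width_k=8, max_length=30)
    return run_schedule(pretrained, schedule, beam)


@pytest.fixture(scope="session")
def pipeline_runs():
    """The same seeded two-stage design run executed twice, for determinism
    and conservation checks."""
    return _pipeline_once(17), _pipeline_once(17)
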