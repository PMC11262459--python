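"""Shared fixtures.

Heavy artifacts (trained tiny models, the curation-scale corpus) are
session-scoped so several tests can share one training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from thermadapt.encoder import TINY, AdapterConfig, EncoderModel, HeadConfig
from thermadapt.synthgen import (
    BenchmarkConfig,
    TmModel,
    make_benchmark,
    sample_sequences,
)
from thermadapt.training import TrainPlan, _class_labels, _tokenized, _train_loop


@pytest.fixture
def tiny_classifier_model() -> EncoderModel:
    """Untrained tiny encoder with adapters and a classifier head."""
    return EncoderModel(TINY, AdapterConfig(2), HeadConfig("classifier"), seed=0)


@pytest.fixture
def small_labeled_corpus():
    """120 short sequences, 60 per class, shuffled."""
    recs = sample_sequences(60, "thermophilic", (40, 60), seed=1) + sample_sequences(
        60, "non_thermophilic", (40, 60), seed=2, id_prefix="n"
    )
    rng = np.random.default_rng(0)
    order = rng.permutation(len(recs))
    return [recs[i] for i in order]


@pytest.fixture(scope="session")
def curation_benchmark():
    """~2,000-sequence family-structured corpus with Tm values and
    generator-known homolog pairs in the hard-negative identity range."""
    return make_benchmark(
        BenchmarkConfig(
            n_per_class=1000,
            n_families=70,
            length_range=(40, 80),
            homolog_identities=(0.85, 0.85, 0.88, 0.9, 0.9),
        ),
        seed=5,
    )


@pytest.fixture(scope="session")
def classification_run():
    """Tiny adapter classifier trained on the separable 2,000-sequence
    composition-shift corpus (fixed seeds); returns model, held-out
    records/labels and the training result."""
    recs = sample_sequences(1000, "thermophilic", (60, 160), seed=1) + sample_sequences(
        1000, "non_thermophilic", (60, 160), seed=2, id_prefix="n"
    )
    rng = np.random.default_rng(0)
    order = rng.permutation(len(recs))
    recs = [recs[i] for i in order]
    tokens = _tokenized(recs)
    labels = _class_labels(recs)
    model = EncoderModel(TINY, AdapterConfig(2), HeadConfig("classifier"), seed=0)
    result = _train_loop(
        model,
        tokens[:1600], labels[:1600],
        tokens[1600:1800], labels[1600:1800],
        "classifier",
        TrainPlan(max_epochs=12, lr=5e-3),
        seed=0,
        save_snapshots=True,
    )
    return {
        "model": model,
        "result": result,
        "test_records": recs[1800:],
        "test_tokens": tokens[1800:],
        "test_labels": labels[1800:],
    }


@pytest.fixture(scope="session")
def motif_run():
    """Tiny classifier trained to convergence on the motif-implanted
    corpus, for attention-recovery analyses."""
    bench = make_benchmark(
        BenchmarkConfig(n_per_class=500, motif="RRELV", motif_copies=2), seed=3
    )
    recs = [r for r in bench.records if not r.id.startswith("hom")]
    rng = np.random.default_rng(0)
    order = rng.permutation(len(recs))
    recs = [recs[i] for i in order]
    tokens = _tokenized(recs)
    labels = _class_labels(recs)
    model = EncoderModel(TINY, AdapterConfig(2), HeadConfig("classifier"), seed=0)
    result = _train_loop(
        model,
        tokens[:700], labels[:700],
        tokens[700:800], labels[700:800],
        "classifier",
        TrainPlan(max_epochs=25, lr=5e-3),
        seed=0,
        save_snapshots=False,
    )
    return {
        "benchmark": bench,
        "model": model,
        "result": result,
        "test_records": recs[800:1000],
        "test_labels": labels[800:1000],
    }


@pytest.fixture(scope="session")
def regression_run():
    """Tiny adapter regressor trained on noise-free two-regime Tm data."""
    from thermadapt.training import train_regressor

    bench = make_benchmark(
        BenchmarkConfig(n_per_class=400, tm=TmModel(sigma=0.0)), seed=7
    )
    recs = [r for r in bench.records if r.melting_temp is not None]
    rng = np.random.default_rng(0)
    order = rng.permutation(len(recs))
    recs = [recs[i] for i in order]
    model = EncoderModel(TINY, AdapterConfig(2), HeadConfig("regressor"), seed=0)
    result = train_regressor(
        recs[:600], recs[600:700], model, TrainPlan(max_epochs=60, lr=5e-3), seed=0
    )
    return {"model": model, "result": result, "test_records": recs[700:800]}
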