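# thermadapt

Protein thermostability prediction with adapter-tuned transformer encoders,
leakage-aware dataset curation, and attention-score interpretability.

## The problem

Whether a protein tolerates heat — summarized either as a binary thermal
class (from the source organism's growth temperature: thermophilic > 60 °C,
non-thermophilic < 30 °C) or as a melting temperature Tm in °C — is
expensive to measure and attractive to predict from sequence alone.  A
practical sequence-based pipeline needs four things beyond the model
itself, and this package implements all of them as a tested toolkit:

1. **Curation** — thermal labeling from growth temperature, removal of
   short (< 30 aa) and ambiguous sequences, greedy identity clustering
   (50 % threshold for thermophiles, 80 % for non-thermophiles),
   *hard-negative* mining (non-thermophilic sequences with 80–95 %
   identity to a thermophile), cluster-aware 80:10:10 train/val/test
   splits that put whole identity clusters in one split (no homology
   leakage; hard-negative pairs reserved for training), 10 °C Tm-bin
   balanced sampling for regression, and identity-binned test
   stratification.  Sequence identity is defined once: global alignment,
   BLOSUM62, affine gaps (open 10, extend 0.5), identical columns /
   alignment length.
2. **Model** — a BERT-style encoder in which only small bottleneck
   adapters (down-project, ReLU, up-project, residual: `h + U·relu(D·h)`)
   after each feed-forward block, plus a task head, are trained; the
   backbone stays frozen.  For the published full-size configuration
   (30 layers, 16 heads, hidden 1024) this reduces trainable parameters
   from ≈ 420 M to ≈ 5 M.  A closed-form parameter accountant reproduces
   both numbers exactly and is cross-checked against enumeration of an
   instantiated model.
3. **Training** — AdamW, batch size 16, up to 20 epochs (classification)
   or 200 (regression), lowest-validation-loss checkpointing, 3-seed
   replication, and classifier→regressor transfer initialization from
   adapter snapshots taken at 25/50/75/100 % of the first classification
   epoch or from the fully trained classifier.
4. **Interpretation and ensembling** — per-residue attention profiles; a
   residue is a *high attention score* (HAS) site when its score strictly
   exceeds Tukey's upper fence **Q3 + 1.5·IQR** of its own sequence's
   scores; amino-acid HAS enrichment vs background, pre-trained vs
   fine-tuned comparison, homolog conservation cross-tabs, per-column
   entropy, and attention-to-structure B-factor mapping.  Regression
   ensembles: oracle bound, greedy subset selection, inverse-MAE
   weighting, IQR/std trimmed combiners, and a class-gated ensemble that
   routes each sequence through a thermal classifier to a per-class
   member subset.

Everything runs at desk scale on synthetic corpora produced by the
built-in generator (`thermadapt.synthgen`), which emulates the structure
the method assumes: composition-shifted classes, a bimodal Tm
distribution with a gap between the ~50 °C and ~85 °C regimes, homolog
pairs at controlled identity, and ground-truth motif positions for
attention-recovery scoring.  Since no pre-trained protein language model
weights are bundled, trained models here are tiny from-scratch encoders
(2 layers, width 16); the full-size preset exists for parameter
accounting.

## Worked example

```python
import numpy as np
from thermadapt import ThermalClassifier, count_parameters, PROTBERT_BFD, AdapterConfig, HeadConfig
from thermadapt.synthgen import BenchmarkConfig, make_benchmark
from sklearn.metrics import accuracy_score, matthews_corrcoef

total = count_parameters(PROTBERT_BFD)
trainable = count_parameters(PROTBERT_BFD, AdapterConfig(16),
                             HeadConfig("classifier"), trainable_only=True)
print(f"full-size encoder: {total/1e6:.1f}M parameters, "
      f"{trainable/1e6:.2f}M trainable with adapters")

bench = make_benchmark(BenchmarkConfig(n_per_class=150), seed=0)
records = [r for r in bench.records if not r.id.startswith("hom")]
order = np.random.default_rng(0).permutation(len(records))
records = [records[i] for i in order]
X = [r.sequence for r in records]
y = [1 if r.thermal_class == "thermophilic" else 0 for r in records]

clf = ThermalClassifier(max_epochs=10, random_state=0)
clf.fit(X[:240], y[:240])
pred = clf.predict(X[240:])
print(f"held-out accuracy: {accuracy_score(y[240:], pred):.3f}")
print(f"held-out MCC:      {matthews_corrcoef(y[240:], pred):.3f}")
```

Output:

```
full-size encoder: 419.9M parameters, 5.02M trainable with adapters
held-out accuracy: 0.917
held-out MCC:      0.834
```

The first line is the closed-form parameter count of the full-size frozen
encoder and of its adapter + head trainable set.  The accuracy/MCC lines
evaluate a tiny adapter classifier fitted on 240 synthetic sequences whose
classes differ only in amino-acid composition (thermophile-like enrichment
of R/E/L/A/I/V, depletion of K/Q/N); with the larger corpora used in the
test suite (2,000 sequences) the same model exceeds 0.95 accuracy.

`ThermalClassifier` and `MeltingTempRegressor` are scikit-learn
estimators (`fit` / `predict` / `get_params`), so they compose with
sklearn pipelines and model selection.  A command-line interface wraps
the same library:

```bash
thermadapt synth --preset cls --n-per-class 200 --seed 7 --out corpus/
thermadapt curate --fasta corpus/corpus.fasta --out curated/
thermadapt split --fasta curated/curated.fasta --threshold 0.5 --seed 7 --out splits/
thermadapt train-cls --fasta curated/curated.fasta --epochs 10 --out run/
thermadapt predict-class --fasta curated/curated.fasta --checkpoint run/checkpoint --out scores.csv
```

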