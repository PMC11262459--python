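# Methods

This note documents the models, statistics and procedures the package
implements, the choices made where the design was genuinely open, and what
the synthetic benchmarks do and do not demonstrate.

## Thermal labeling and curation

Sequences are labeled from the source organism's growth temperature:
strictly above 60 °C → thermophilic, strictly below 30 °C →
non-thermophilic.  Temperatures in [30, 60] °C are left unlabeled and
excluded from class datasets — only the two tails are defined.  Sequences
shorter than 30 residues, or containing any ambiguity/non-standard symbol
(B, J, O, U, X, Z), are dropped before clustering, with a per-record
reason.

**Sequence identity** is defined once for the whole package: optimal
global alignment under BLOSUM62 with affine gap penalties (open 10,
extend 0.5; a gap of length *n* costs 10 + (*n*−1)·0.5, terminal gaps
penalized), identity = identical aligned columns / alignment length, gap
columns counted in the denominator.  Alignments are computed by biotite;
because its gap penalties are integral, the scoring is applied in the
score-equivalent integer form (doubled matrix, open 20, extend 1), which
leaves the set of optimal alignments — and hence identities — unchanged.
The test suite cross-checks alignment scores against an independent
Gotoh dynamic-programming implementation.

**Clustering** is greedy and incremental (CD-HIT-style): records sorted
by descending length (ties by id); each record joins the first existing
centroid with identity ≥ the threshold, else founds a new cluster.  The
thermophilic set is clustered at 50 % identity, the non-thermophilic set
at 80 %.  This is a deterministic, dependency-free approximation of the
cascading MMseqs workflow used at database scale; it does not reproduce
MMseqs' k-mer prefilter heuristics or its exact cluster boundaries.  An
exact composition bound (identical columns ≤ residue-multiset
intersection; alignment length ≥ longer sequence) skips alignments that
provably cannot reach the threshold; results are identical to the
unpruned loop.

**Hard negatives** are all cross-class pairs with 80 % < identity < 95 %
(strict bounds).  Candidate pairs must share at least one exact 5-mer
before being aligned — the one heuristic prefilter in the pipeline,
mirroring k-mer prefilters in standard clustering tools; at the
identities of interest (> 80 %) homologous pairs share many exact words,
so in practice nothing is lost.

**Splitting** assigns whole clusters to train/validation/test so that no
cluster spans two splits.  Quotas are measured in sequences (80:10:10 of
the total); clusters containing any hard-negative member are forced into
training first; the remaining clusters are shuffled with a seeded
generator and greedily fill the validation quota, then the test quota,
then train.  A cluster joins an evaluation split only if at least half of
it fits the remaining quota — a lone oversized cluster therefore stays in
train rather than emptying the training set.  Whether the published
80:10:10 ratio was counted in sequences or clusters is not determinable
from the text; sequences were chosen so that large clusters cannot starve
the evaluation sets.

**Tm-bin splits** for regression: melting temperatures are binned into
half-open 10 °C bins [10k, 10(k+1)).  Per non-empty bin, up to 10 records
are drawn (without replacement) for validation and up to 10 for test.
The remaining training records are rebalanced to a common per-bin target —
the median occupied-bin count by default, since the published protocol
states which bins were under/over-sampled but not the target —
undersampling without replacement and oversampling with replacement.

**Identity-binned evaluation**: each test record is assigned the maximum
identity to any training record and grouped into half-open bins with
default edges 0/0.2/0.4/0.6/0.8 (top bin closed at 1.0).

## Encoder, adapters, heads

The encoder is standard BERT: summed word/learned-position/token-type
embeddings with layer norm; per layer, multi-head self-attention and a
GELU feed-forward block, each with post-norm residuals; a pooler
(dense + tanh over the class token).  Tokenization is at the amino-acid
level with a 30-symbol vocabulary (PAD/UNK/CLS/SEP/MASK + 25 letters,
the protBERT convention: J has no token; B/J/O/U/Z are remapped to X at
encoding time).  Sequences are truncated to 512 residues keeping the
N-terminal prefix.

A bottleneck adapter `h + Up(relu(Down(h)))` follows each layer's
feed-forward block.  Up-projections are zero-initialized, so a freshly
adapted model computes exactly the frozen backbone's function; with
adapters enabled, only adapter and head parameters carry gradients
(asserted by parameter-hash tests).  Task heads read the class-token
hidden state through `dense(d→d) + tanh + dense(d→out)` with 2 outputs
(classifier, softmax) or 1 (regressor).  The head's internal shape is not
published; this two-layer form is the common convention and makes the
trainable count come out at the published ≈ 5 M for the full-size preset.
The pooler belongs to the published backbone and is counted in totals,
but heads bypass it; it stays frozen.

**Parameter accounting.**  The closed form sums embeddings
((V+P+T)·d + 2d), per-layer attention (4(d²+d) + 2d), feed-forward
(d·f+f + f·d+d + 2d), pooler (d²+d), adapters per layer
((d·b+b)+(b·d+d), b = d/r) and the head.  For the full-size preset
(30 layers, 16 heads, d = 1024, f = 4096, V = 30, P = 40000, T = 2) it
gives 419,931,136 total (≈ 420 M) and, with reduction-16 adapters plus
the classifier head, 5,016,450 trainable (≈ 5 M).  Reduction factor 16
with ReLU is the upstream adapter default; the published text defers the
exact value to its supplementary sweep.  The closed form equals the
enumerated parameter count of an instantiated model for every
configuration tested.

**Implementation.**  The model and its training run on NumPy (float64)
with a compact reverse-mode autodiff engine written for this package;
every primitive's gradient is verified against central finite differences
in the test suite.  Single-threaded NumPy makes same-seed runs bitwise
reproducible.

## Training protocol

Cross-entropy for classification, mean-squared error on z-normalized
targets for regression (the training-set mean/sd are stored with the
checkpoint and predictions de-normalize to °C; the published text does
not state the loss pairing or normalization — these are the standard
choices, and normalization stabilizes small-model training).  AdamW with
betas (0.9, 0.999), eps 1e-8, weight decay 0, constant learning rate (no
schedule); batch size 16; up to 20 epochs (classification) / 200
(regression); the lowest-validation-loss epoch is kept.  During the first
classification epoch, adapter snapshots are taken at
floor(f · steps-per-epoch) optimizer steps for f = 0.25/0.5/0.75/1.0;
together with the fully trained adapters they are the sources for
regressor transfer initialization.  Replication runs the same
configuration once per seed (three by default) and reports mean ± sd.

**Desk-scale model.**  Trained models in the test suite use a tiny preset:
2 layers, 2 heads, width 16, feed-forward 32, reduction-2 adapters,
initialization scale 0.3, learning rate 5e-3.  The BERT-conventional
0.02 initialization is tuned to wide pre-trained models; at width 16 it
leaves the class token carrying almost no sequence information through a
frozen random backbone, so the width-appropriate larger scale is the
package default (the full-size preset is never trained here).  The
learning rate and adapter width were selected by a small validation sweep,
mirroring the protocol's own per-dataset hyperparameter search.  Problem
sizes in the suite: classification on 2,000 sequences (1600/200/200) for
12 epochs reaches ≥ 0.95 held-out accuracy; regression on 800 noise-free
two-regime sequences for up to 60 epochs reaches R² ≥ 0.8.

## Attention interpretability

A per-residue profile reduces the (layers × heads × tokens × tokens)
attention stack to one non-negative score per residue, with special
tokens excised first.  Which layers/heads the original analysis
aggregated is not recoverable from the text, so the mode is an explicit,
recorded property of every profile:

* `received_mean` (package default) — mean attention received by the
  residue over all layers, heads and source positions;
* `received_last_layer` — last layer only;
* `cls_row_last_layer` — head-averaged attention paid by the class token
  to the residue in the last layer.

A residue is a **HAS** when its score strictly exceeds Q3 + 1.5·IQR of
its own profile (Tukey's upper fence; "exceeding" read as strict).
Quartiles use linear interpolation at position (n−1)p — conventions
differ and the source does not specify one; the same quantile definition
is used by the ensemble combiners.  A constant profile has zero IQR and
an empty HAS set.

Enrichment compares, per thermal class, the HAS residue composition with
the class background composition (both normalized to 1), reporting
difference and ratio per amino acid.  Homolog comparison globally aligns
the pair and labels each column conserved / non-conserved / insertion,
attaching both partners' HAS flags; per-column Shannon entropy (bits,
gaps ignored) quantifies variability.  Structure mapping writes min–max
scaled scores (0–100; a constant profile maps to 0) into the PDB B-factor
column after aligning the profile sequence to the chain's observed
residues; identity below 0.9 triggers a warning rather than an error.

For the *signal-recovery* analysis (fine-tune on a motif-implanted
corpus, then test whether HAS over-represents the implanted residue
types), the declared mode is `cls_row_last_layer`: in a from-scratch tiny
encoder the class token's attention row is where task-driven focusing
appears, while mean-received attention is dominated by the frozen
backbone's generic mixing.  Analyses that compare models are run on the
first replicate by convention.

## Ensembles

Given a members × samples prediction matrix with validation truth:

* **oracle** — per sample, the member prediction closest to the truth; a
  lower bound on member-selection error, reported as MAE and R²;
* **greedy** — forward selection minimizing combined-prediction MAE,
  stopping when no addition improves it strictly (ties by member id);
* **weighted** — weights ∝ 1/validation-MAE, normalized (a perfect member
  takes all weight); the published extended formulations live in
  supplementary material, so these are explicit stand-ins;
* **class-gated** — a thermal classifier routes each sequence to a
  per-class member subset (the published instance: five models for
  non-thermophilic, two for thermophilic), combined per sample.

Combiners: plain mean; IQR-trimmed mean (drop outside
[Q1−1.5·IQR, Q3+1.5·IQR]); sd-trimmed mean (drop beyond mean ± 2 sd).
If trimming removes everything the plain mean is returned.

## Synthetic data generator

The generator supplies corpora with the statistical structure the
pipeline assumes, and nothing more:

* **Classes** — i.i.d. residues from per-class compositions.  The
  non-thermophilic background is uniform over the 20 canonical residues;
  the thermophilic vector multiplies R/E/L/A/I/V by (1+shift) and K/Q/N
  by (1−shift), renormalized (default shift 0.75).  The signal direction
  follows the residue preferences reported for thermophiles (more
  arginine/glutamate/hydrophobics, less lysine/glutamine/asparagine);
  the magnitude is chosen so a desk-scale model can separate the classes.
* **Melting temperatures** — Tm = μ_class + β·(signal fraction −
  class mean) + N(0, σ), with μ = 50/85 °C (bimodal with an empty
  60–70 °C gap, matching the two-regime shape of real Tm data),
  β = 40 °C per unit signal fraction, σ = 3 °C.
* **Homologs** — exact-count substitutions to a target identity
  (optionally one indel block), so clustering, hard-negative mining and
  identity bins can be scored against ground truth.
* **Motifs** — non-overlapping implanted copies (default "RRELV") with
  recorded positions, the ground truth for HAS recovery.
* **Families** — optional family structure (founders plus members at
  55–90 % identity) giving the clustered shape real databases have.

What passing these benchmarks shows: the pipeline's rules, statistics and
training loop behave as specified on data with the assumed structure.
What it does not show: performance on real proteomes, whose positional
grammar, domain architecture, length distribution and organism-level
confounds the generator deliberately omits.  In particular, headline
real-data numbers (e.g. classification accuracy ≈ 0.89 or ensemble MAE
≈ 6.3 °C) require the original pre-trained weights and external corpora
and are out of scope here.

## Numerical and degenerate-case choices

* Quantiles: linear interpolation at (n−1)p everywhere.
* HAS fence: strict inequality; constant profiles → empty set.
* B-factor scaling of a constant profile → 0.
* Regression with zero-variance targets: sd clamped to 1.
* Tm bins with fewer than 20 records: validation is filled first (up to
  10), then test; a bin emptied by evaluation sampling contributes no
  training records.
* Empty trimmed sets fall back to the plain mean.
* Tokenizer truncation keeps the N-terminal prefix.

## Known limitations

* The greedy clustering approximates but does not replicate MMseqs;
  cluster boundaries differ and the cascading under-sampling workflow is
  not implemented.
* No pre-trained weights: attention analyses probe tiny from-scratch
  models, which is sufficient for testing the statistics but not a
  statement about what large pre-trained models attend to.
* The 5-mer prefilter in hard-negative mining is a heuristic; a pair
  above 80 % identity sharing no exact 5-mer would be missed (not
  observed in practice and essentially impossible for realistic lengths).
* Training is single-threaded NumPy: exact and reproducible, not fast;
  corpus sizes beyond a few thousand short sequences are out of its
  intended range.
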