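# Methods

## Problem setting

Given a binary miRNA–disease association matrix `A_md` (nm miRNAs ×
nd diseases) plus heterogeneous side data — a miRNA functional
similarity matrix `FS` covering a subset of miRNAs, miRNA–target
interactions `A_mt`, lncRNA–disease interactions `A_ld`, gene–disease
interactions `A_gd`, and MeSH category-C descriptors for the diseases —
the task is to score every (miRNA, disease) pair for association.  The
guiding assumption is the standard one in this field: miRNAs with
similar functions tend to associate with phenotypically similar
diseases, and vice versa.

## Similarity construction

**Gaussian interaction profile (GIP) kernels.**  For entities with
binary interaction profiles `IP(·)` (rows or columns of an association
matrix), similarity is

    K(i, j) = exp(−γ ‖IP(i) − IP(j)‖²),
    γ = γ′ / ( (1/n) Σ_k ‖IP(k)‖² ),

with γ′ = 1 by default.  Normalising the bandwidth by the mean squared
profile norm (the mean association count, for binary profiles) adapts
the kernel to data density.  Five kernels are built this way: `KM1`
(rows of `A_md`), `KM2` (rows of `A_mt`), `KD1` (columns of `A_md`),
`KD2` (columns of `A_ld`), `KD3` (columns of `A_gd`).  Entities with
empty profiles are handled by the formula as written; no special case.

**Disease semantic similarity.**  Each disease's MeSH tree numbers
induce a DAG whose term set `T(D)` contains the disease and all its
ancestors (prefix truncation of dot-delimited tree numbers).  A term's
information contribution is its negative log document frequency across
the disease set, `C(t) = −log(df(t)/N)`, so frequent (generic) terms
contribute little and universal terms contribute nothing.  Similarity
is the shared-information ratio

    SD(A, B) = Σ_{t ∈ T(A)∩T(B)} 2·C(t) / (C(A) + C(B)),

where `C(A) = Σ_{t∈T(A)} C(t)`.  The ratio is invariant to the
logarithm base; natural log is used so intermediate values are
reproducible.  Terms are identified by MeSH heading, not tree position:
a disease occupying several positions contributes one term whose
ancestor set is the union over positions, and `df` counts DAGs.  The
degenerate case `C(A)+C(B) = 0` (every term universal) is defined as
similarity 0 — the shared terms carry no discriminative information.
The denominator `N` defaults to the number of DAGs built (the analysis
set) and is exposed as a parameter.

**Fusion.**  Membership in a side source is decided per pair — both
endpoints must be covered.  miRNA similarity `SM`: pairs in both `FS`
and the target data get `(FS+KM2)/2`; in `FS` only, `FS`; in targets
only, `KM2`; otherwise `KM1`.  Disease kernel `KD`: pairs in the
lncRNA data get `KD2`; else pairs in the gene data get `KD3`; else
`KD1`.  Diagonals are forced to 1 after fusion.  The averaged branch
pairs `FS` with `KM2`: `KM1` exists for every miRNA by construction,
so conditioning that branch on `KM1` coverage would be vacuous, and the
averaged quantity is the one `KM2` contributes.  A `strict_average_km1`
switch restores the `KM1` pairing for comparison.

## Model

Every pair (i, j) is one sample: the miRNA half is row i of `SM`
(width nm), the disease half concatenates row j of `SD` and row j of
`KD` (width 2·nd).  Two stacked autoencoders compress the halves to
64-dimensional codes; the 128-dimensional concatenation feeds a
three-weight-layer classifier (ReLU hidden units, sigmoid output).

**Greedy pretraining.**  Each encoder layer is trained as a
one-hidden-layer autoencoder on the codes of the layers below it,
minimising reconstruction MSE with SGD while all other layers stay
frozen; training layer k leaves layers < k bit-identical.  The
reconstruction readout is linear: a ReLU readout unit that initialises
dead has exactly zero gradient and can never recover, whereas with a
linear readout a learnable bias alone can reconstruct any constant
input.  Hidden/code layers are ReLU throughout.

**Classifier.**  Binary cross-entropy, ADADELTA (ρ = 0.95, ε = 1e−6),
mini-batches of 200, dropout 0.5 after every hidden layer (inverted,
disabled at inference).  The output layer is computed as a linear
logit with the sigmoid applied at scoring time, giving the numerically
stable `a − y` gradient.  Early stopping monitors a 10% validation
split of the training pairs (patience 10, best weights restored).

**Initialisation.**  Weights are Gaussian with standard deviation
0.05 — appropriate for the model's layer widths (fan-in 128–495, where
it is close to He scaling) but deliberately configurable, since it
starves toy-sized networks.  Biases are uniform-negative on
(−0.05, 0).  Large negative bias ranges such as (−1, 0) silence every
ReLU unit at these weight scales — pre-activations of [0,1]-bounded
inputs never reach zero, gradients vanish identically, and the model
provably cannot train — so the convention is kept but at a scale that
leaves units active.

**Encoder freezing.**  After greedy pretraining the encoders are
frozen by default, keeping the feature extractor independent of the
labels; `fine_tune_encoders` lets classifier gradients flow into them
(`fine_tune_epochs`, default 10).

**Ablation and plug-in heads.**  `encoder="identity"` feeds the raw
concatenated similarity rows straight to the classifier (the RAW+DNN
variant).  `SklearnHead` adapts any scikit-learn classifier with
`predict_proba` (AdaBoost, random forest) onto the encoder codes; only
the DNN head is implemented natively.

**Defaults.**  Encoder stacks [input → 256 → 64] per side ("stacked"
⇒ at least two weight layers); classifier [128 → 64 → 32 → 1];
pretraining 20 epochs per layer with SGD learning rate 0.2; classifier
50 epochs.  All configurable through `TrainConfig`.

## Evaluation protocols

**Metrics.**  AUC is the rank (Mann–Whitney) probability that a random
positive outranks a random negative, ties counted ½; AUPR is the
step-wise area under precision–recall over descending-score
thresholds.  Both are checked in the test suite against brute-force
oracles (exhaustive pair enumeration; explicit threshold sweep).

**Five-fold CV.**  Known associations are split into five seeded folds
of near-equal size; unknown pairs are split the same way so train and
test pair sets are disjoint.  A `test_vs_all_unknown` mode reproduces
the alternative convention of ranking each fold's positives against
every unknown pair.

**Leakage guard.**  The association-derived kernels (`KM1`, `KD1`)
memorise `A_md`: if they are built once from the full matrix, each test
pair's label is partially encoded in its own features.  With the guard
(default on) those kernels are recomputed inside each fold from a copy
of `A_md` whose test positives are zeroed; the side-data kernels and
the semantic similarity are unaffected.  Guard-off reproduces the
common fixed-matrix convention.  The acceptance script reports both
numbers; their gap is a direct measure of how much of the unguarded
score is leakage rather than generalisation.

**Leave-one-disease-out CV.**  For each disease, its entire column is
zeroed before any similarity computation or training, and all nm pairs
of that disease form the test set — the held-out disease enters the
model with no known associations at all.  Diseases with no positives
(nothing to recover) or no negatives (AUC undefined) are skipped with a
note.  Significance against chance uses the null standard error of the
mean per-disease AUC derived from the Mann–Whitney null variance
`(n₊+n₋+1)/(12 n₊ n₋)` per disease.

**Robustness experiment.**  Encoders are pretrained once per fold;
zero-mean Gaussian noise with per-feature standard deviation
`sigma_scale ×` the training-code standard deviation is injected into
training and test codes; each classifier head is then trained and
scored on the same clean and noisy codes, and the per-head AUC drop is
reported.  Noise sits downstream of the fixed feature extractor, so
head comparisons are exact like-for-like.

**Seeds.**  Every stage derives its seed from one root via SHA-256
(`derive_seed`), so adding a stage never shifts the seeds of existing
ones and any stage can be replayed in isolation.  Full runs are
bit-reproducible; the CLI `run` command writes a manifest (config
hash, versions, root seed) sufficient for exact replay.

## Synthetic data generator

The generator emulates the statistical shape of the curated data the
model is designed for.  miRNAs and diseases receive latent factors
(dimension 8); the probability of a true association is a logistic
link on the scaled latent inner product, with the bias calibrated by
bisection so the expected density of `A_md` matches the target 3%
(the density of the curated association snapshot).  The link slope
defaults to 5.0, chosen so that the Bayes-optimal scorer (the true
probabilities) attains AUC ≥ 0.98 — the planted structure is then
clearly recoverable in principle and recovery failures are
attributable to the method, not the noise floor.

The same latents drive every side source: target/lncRNA/gene axes get
fresh latents and logistic-link tables at 5% density; `FS` is the
rescaled cosine of miRNA latents plus symmetric truncated Gaussian
noise (default sd 0.05); diseases are grouped by nearest latent
centroid into 8 clusters, and within each cluster every disease
attaches below its latent-nearest earlier member, so MeSH-like tree
distance tracks latent distance the way phenotypically similar
diseases nest together in real hierarchies.  Coverage fractions mirror
the real sources (FS 52%, targets 31%, lncRNA 58%, genes 90%) and are
sampled uniformly, which exercises every fusion branch by
construction.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: power-law degree distributions (real
association counts per miRNA are heavy-tailed; the logistic link gives
near-binomial degrees), the much richer per-entity association counts
of the real snapshot (~11 associations per miRNA versus ~3 at the
default 200×100 size with density pinned at 3%; GIP kernels on such
sparse profiles are substantially noisier), real MeSH depth statistics,
and any sequence-level miRNA features.

## Problem sizes

The default world is 200 miRNAs × 100 diseases (~600 positive pairs,
20 000 samples).  Leave-one-disease-out runs use a 150×60 world with
30 evaluated diseases and a width-scaled model (code 48, hidden 96);
robustness runs use 100×50 worlds over three seeds (code 32, hidden
64).  These sizes keep each protocol's training loops proportionate to
the world while exercising identical code paths to a full-size run.

## Known limitations

* Under the leakage guard the guarded 5-fold AUC on the default world
  sits well below the unguarded value — at the pinned density each
  entity has so few associations that masked kernels retain little
  signal, and what remains flows mainly through the side sources.
  This is a property of honest evaluation at this scale, not of the
  implementation: the unguarded protocol (which matches how headline
  numbers in this literature are usually produced) scores markedly
  higher on the same folds, and the acceptance script prints both.
* ADADELTA with near-zero accumulator bootstrap is slow on very small
  problems; toy experiments should raise `train_epochs` or use wider
  `weight_init_std` (see `TrainConfig`).
* MeSH descriptor names must already match disease identifiers in the
  association table (exact, case-insensitive); no synonym resolution.
* Dropout during encoder fine-tuning is applied inside each encoder's
  hidden layers and the classifier's hidden layers, not on the
  concatenated code itself.
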