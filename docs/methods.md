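# Methods notes

## Model and procedure

The package implements similarity-based virtual screening over reduced
molecular descriptors. A tied-weight sigmoid autoencoder compresses
nonnegative count fingerprints (min–max scaled per feature to [0,1])
through stacked layers h = σ(Wx + b) to a low-dimensional code; the
decoder mirrors the stack with transposed weights and free bias vectors
and reconstructs z. The training objective is the mean squared
reconstruction error ℒ = mean(x − z)², minimised by minibatch gradient
descent with exact backpropagation; tied weights receive the summed
gradient of their encoder and decoder uses. Training stops when the
epoch-mean ℒ falls below the tolerance α or at the epoch cap.

Screening follows the standard retrospective protocol: per activity
class, `n_references` query molecules are drawn without replacement from
a per-class seeded substream (so all methods are queried with identical
references); the database is ranked by decreasing similarity to each
query, ties broken by molecule id ascending; recall at cutoff p% counts
the class's actives inside the top k = round(p·N/100) (minimum 1)
positions. Concordance of the per-class method rankings uses Kendall's
W on within-class ranks (ascending with recall, average ranks for ties),
with the Friedman chi-square m(n−1)W on n−1 degrees of freedom for
significance.

## Design choices where the design was open

- **Input scaling.** Sigmoid outputs live in (0,1), so integer counts are
  min–max scaled per feature before training; the scaler is recorded on
  the dataset and exactly invertible. Constant features map to 0. A
  binarise-then-train route is available via `binarize`.
- **Learning rule.** The per-layer update is plain gradient descent on ℒ;
  the tolerance α = 0.01 acts purely as the stopping criterion (training
  continues "until the error is below α, at most 100 epochs"). The
  gradient step size is an independent hyperparameter (default 0.05).
- **Decoder biases** are free parameters initialised to zero: a transposed
  encoder bias has the wrong length for any asymmetric layer pair.
- **Dataset-level training.** The default trains whole-dataset epochs with
  minibatches (default 32) and stops on the epoch-mean loss. A
  per-molecule mode (each molecule descended to tolerance in turn) is
  retained behind `TrainConfig.per_molecule` for fidelity experiments,
  but it amounts to sequential memorisation and is not recommended.
- **Initialisation** defaults to Glorot-style scaled uniform weights with
  zero biases; the all-uniform-(0,1) mode is selectable but saturates
  sigmoids at realistic widths.
- **Tied decoder widths.** With tied weights the decoder necessarily
  mirrors the encoder widths; an untied mode with free decoder widths
  exists for architectures that deliberately break the mirror.
- **Continuous Tanimoto variant.** The default denominator is
  Σa² + Σb² − Σab (self-similarity 1). A variant with +Σab is selectable
  (`as_printed`); it is dominated by the standard form and has
  self-similarity 1/3, so results always record the variant used.
- **Class diversity** ("pairwise similarity" of a class) is the mean
  binary Tanimoto over all unordered member pairs of the binarised
  fingerprints; a continuous-variant flag exists. This is the homogeneity
  statistic the synthetic generator calibrates against.
- **Reference handling.** The query is excluded from both the ranked
  database and the active count (avoids a guaranteed self-hit);
  `exclude_reference=False` restores the self-inclusive protocol.
- **Rank offset.** Mean ranks are reported 0-based by default (the
  convention matching the published concordance summaries; with six
  methods the mean ranks then sum to 15). W itself is offset-invariant,
  which the tests assert exactly. No tie-correction term is applied to W
  by default; a corrected denominator is available behind
  `kendall_w(..., tie_correction=True)`.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `TrainConfig.tolerance` (α) | 0.01 | stop when epoch-mean MSE < α |
| `TrainConfig.max_epochs` | 100 | epoch cap |
| `TrainConfig.step_size` | 0.05 | gradient-descent step |
| `TrainConfig.batch_size` | 32 | minibatch size |
| `ScreeningConfig.n_references` | 10 | queries per class |
| `ScreeningConfig.cutoffs` | (1, 5) | recall cutoffs, % of database |
| `SyntheticSpec.density` (d) | 0.05 | expected fraction of prototype on-features |
| `SyntheticSpec.intensity` (λ) | 3 | mean count on an occurring feature |

## Synthetic data: what it emulates and what it does not

The generator fabricates MDDR-shaped screening sets: activity classes of
chosen sizes with controllable mean intra-class pairwise Tanimoto
similarity, plus unlabelled background decoys. Each class has a random
prototype support of ≈ d·F features; members keep each prototype feature
with probability θ and gain off-prototype features at the compensating
rate r = |S|(1−θ)/(F−|S|), so the expected on-feature count is
preserved while θ dials homogeneity (θ=1 gives identical supports,
diversity 1). Counts on occurring features are shifted Poisson
(1 + Poisson(λ−1), minimum 1 — a substructure that occurs has count at
least one). θ is found from a target similarity by bisection against a
simulated 500-member pilot class (tolerance 0.02, fixed calibration
seed); there is no convenient closed form once count noise and the
background rate interact, and the simulated inversion is exact for the
measure actually used.

The bundled example specs describe a homogeneous set (10 classes,
targets 0.23–0.36) and a heterogeneous set (targets 0.10–0.13), each
100 molecules per class plus 1000 background molecules at feature
dimension 64 with d = 0.1 — at F = 64 a 0.05 density would leave only ~3
prototype features, too coarse a support for similarity calibration.
The reduced scale keeps a full pipeline run (and its byte-identical
rerun) in the seconds range; the matching reduced autoencoder is
64→32→16.

What the generator does **not** emulate: real substructure statistics
(feature correlations from shared scaffolds, heavy-tailed feature
frequencies, hash collisions of folded fingerprints), class overlap
(molecules active in several classes), or class-size imbalance beyond
what a spec states. Consequently, passing screening tests demonstrate
the machinery (ranking, recall accounting, seeding, calibration) and the
qualitative homogeneity contrast — homogeneous classes screen better
than heterogeneous ones under the raw-Tanimoto baseline — not absolute
recall levels of any real database, and not the relative ordering of
descriptor methods on real chemistry.

## Numerical choices

- 64-bit floats throughout; the sigmoid is computed in a branch form that
  never exponentiates a large positive argument.
- Min–max scaling maps constant features to 0; inversion reconstructs
  them from the recorded parameters and rounds at 1e-12 to restore
  integer counts exactly.
- Similarity of two all-zero vectors is undefined and raises; the
  generator therefore guarantees at least one on-feature per molecule.
- Ranking ties break by molecule id ascending; rank ties within a judge
  take average ranks.
- The shortlist size is k = round(p·N/100) with a floor of 1 (round half
  up, so the convention is platform-independent).
- All randomness flows from a single seed through named substreams
  (CRC-32 of the stream name mixed into a `SeedSequence`), so synthetic
  generation, training and reference selection are independently
  reproducible and all derived seeds stay below 2³¹.

## Known limitations

- The autoencoder is a plain dense sigmoid stack: no denoising,
  variational or sparse variants, no GPU path; full-width presets
  (1024→…) train slowly on large databases in pure numpy.
- The published comparison columns (ASMTP, SQB) are consumed as printed
  recall values only; their scoring functions are not implemented, so new
  datasets can only be screened with the Tanimoto baseline and
  autoencoder descriptors.
- Recall tables for real MDDR data require the licensed database and a
  proprietary fingerprint pipeline; the shipped tables cover exactly the
  published benchmark subsets.
- The Friedman chi-square p-value attached to W is asymptotic and
  approximate for small numbers of classes.
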