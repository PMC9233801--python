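# Methods

`molgen` implements a de novo molecule-design pipeline built from four parts:
a SMILES sequence autoencoder, a Wasserstein GAN with gradient penalty
(WGAN-GP) over the autoencoder's latent space, a feedback loop that biases
the GAN toward multi-objective Pareto-optimal molecules, and a
distribution-learning evaluation suite.  This note records the model
assumptions, the parameters that matter, the numerical choices, and what the
desk-scale experiments do and do not demonstrate.

## Representation and tokenization

Molecules are handled as canonical SMILES (RDKit canonicalization
throughout; canonicalization is idempotent and stereo-preserving).  The
tokenizer treats every bracketed atom environment (`[C@@H]`, `[N+]`,
`[NH3+]`, ...) as a single token, so chirality and charge annotations cannot
be corrupted token-by-token; two-letter halogens (`Cl`, `Br`) and `%NN` ring
closures are also atomic tokens.  The token round trip
`join(tokenize(s)) == s` holds for every valid SMILES and is property-tested.

Vocabularies are built from the training corpus with specials first
(`pad=0`, start `G`=1, end `A`=2) and the body sorted lexicographically, so
encodings are reproducible across runs.  Sequences are encoded as
`[G, tokens..., A, pad...]`.  Over-length molecules are rejected rather than
truncated: a truncated SMILES is almost never the same molecule.  Duplicate
records are removed by canonical SMILES *including* stereo descriptors — two
enantiomers are distinct molecules here, by design.

## Autoencoder

Encoder: token embedding → two stacked bidirectional LSTM layers → the final
hidden and cell states of the top layer concatenated (fixed order
`[fwd h, bwd h, fwd c, bwd c]`) → dense projection to the context vector →
batch normalization → additive Gaussian noise (σ = 0.1, training mode only).
Decoder: four independent dense layers map the context vector to the initial
hidden/cell states of two stacked LSTM layers, followed by a dense softmax
over the vocabulary.  Batch normalization (momentum 0.9) sits between the
main layers of both halves.  Training minimizes categorical cross-entropy
with teacher forcing; a seeded random 10% molecule-level split is used for
validation and the best-validation checkpoint is kept.  Reference widths are
512 LSTM units and a 256-dimensional context vector; desk-scale runs shrink
these (64 units / 32 dims in the test suite).

Decoding is greedy argmax by default so that reconstruction metrics are
deterministic; multinomial sampling at a temperature is available
(temperature 0 falls back to greedy).  `reconstruction_report` returns the
correctly-reconstructed percentage (decoded canonical SMILES equals the
input) and the validity percentage; CR ≤ validity holds by construction.

Two implementation details matter for reconstruction quality and are easy to
get wrong.  First, the recurrent sweeps freeze their state on padded steps
(a 0/1 mask per timestep), which makes the context vector of a molecule
independent of how its batch happened to be padded; without this, training
and inference see systematically different latents and autoregressive
decoding collapses even when the teacher-forced loss is low.  Second,
encoding batches are grouped by token length so inference batches are
pad-free.

## Neural-network engine

No deep-learning framework is used: all models run on a compact reverse-mode
automatic-differentiation engine over numpy arrays (`molgen.autodiff`,
`molgen.nn`).  Two design points:

- Vector-Jacobian products are themselves expressed in engine primitives, so
  gradients can be differentiated again.  The WGAN-GP critic loss contains
  `∇_x̂ D(x̂)` inside the penalty term; training the critic therefore needs
  second derivatives, which the engine provides and the tests check against
  finite differences (≤ 1e-3, actual agreement ~1e-9).
- The LSTM layer sweep (forward and backward-through-time) is a single fused
  primitive with a hand-derived, first-order-only backward pass.  Sequence
  models never need second derivatives, and the fused sweep removes the
  per-timestep graph overhead that dominates runtime at desk scale.

Float64 is used throughout; Adam is the only optimizer.

## WGAN-GP

The critic loss is `E[D(G(z))] − E[D(x)] + λ·E[(‖∇_x̂D(x̂)‖₂ − 1)²]` with
`x̂ = ε·x̃ + (1−ε)·x`, ε ~ U(0,1) per sample; the generator loss is
`−E[D(G(z))]`.  Architectures: critic 256-256 dense with leaky-ReLU
(α = 0.3) and a final activation-free 256-unit layer; generator
128-256-256-256-256 dense with leaky-ReLU and batch normalization, input
z ∈ R⁶⁴ ~ U(0,1), Adam lr 1e-4, dropout 0.2.  Choices the architecture
description leaves open, fixed here: the critic's activation-free final
layer is reduced to the scalar the Wasserstein expectations require by an
unweighted mean; λ defaults to 10 and the critic takes 5 updates per
generator update (the standard WGAN-GP protocol); dropout follows each
hidden layer; z is uniform on the unit interval.  All of these are exposed
in `GANConfig`.

The penalty adds `1e-24` inside the square root of the gradient norm so the
derivative at an exactly-zero gradient is finite; the shift is below the
resolution of every quantity involved.

## Predictor

The QSAR regressor is an embedding (128) → two LSTM layers → dense (128) →
dense(1, linear) network on tokenized SMILES, trained with Adam
(β₁ = 0.9, β₂ = 0.999, lr 1e-4, batch 16), early stopping on validation MSE
(patience 10), and k = 5 validation splits with one model per split;
reported metrics are means ± sd across splits.  Metrics: MSE; CD, read as
the ordinary R² (a squared-Pearson reading is available via
`regression_metrics` directly); Lin's concordance correlation coefficient
with population moments; and MCC, which for a regression model is only
defined relative to an active/inactive cut — both vectors are binarized at a
configurable pIC50 threshold, defaulting to the median training label.

## Multi-objective selection

Score vectors put every objective in a maximization convention by sign
application — `(pIC50, −SAS)`, `(pIC50, −TPSA)`, `(−logP, −SAS)` are built
in, and arbitrary (property, sign) tuples are accepted.  `rank_population`
performs fast non-dominated sorting: each molecule's rank is its domination
count (how many population members dominate it, 0..P−1) and fronts are
peeled iteratively.  The implementation is vectorized over the P×P
comparison tensor and is tested for exact agreement with an O(n³)
brute-force oracle.

`select_best` takes molecules front by front; ties within a front break by
descending first objective then lexicographically (crowding distance is
deliberately not the default — only the domination-count ranking is part of
the selection scheme here).  An optional drug-likeness box filter
(QED ≥ 0.5, SAS ≤ 5, MW ≤ 600, logP ∈ [−2, 6]; all configurable) can be
applied before ranking.

## Feedback loop

The training pool (default capacity 5000; 300 at desk scale) is an
activity-stratified sample of the GAN's training data (equal-width activity
bins, largest-remainder proportional allocation), so the pool's pIC50
histogram tracks the source dataset.  Each feedback epoch: sample until
`sample_per_epoch` valid molecules are decoded (bounded attempts; a short
epoch is logged, never an infinite loop); deduplicate by canonical SMILES;
score; select the best `n = round(replace_fraction·sample_per_epoch)` by
Pareto rank; drop the n worst pool members (highest domination count, ties
by ascending first objective — the mirror of the selection tie-break);
insert the new molecules with latents obtained by *re-encoding their SMILES*
(not the raw generator output, which keeps pool latents exactly on the
encoder manifold); run one adversarial epoch on the updated pool.  Pool size
is conserved every epoch, and under a single-objective scorer the pool
minimum is non-decreasing.  The worst members are ranked within the pool
alone, not against the generated batch.  Property and activity evaluations
are cached by canonical SMILES.

`run_optimization` writes a trace row for the unbiased model (epoch 0) and
every `eval_interval` epochs: max/mean/min of the primary objective over
`eval_sample` freshly sampled valid molecules, % valid (of the attempt
stream), % unique, internal diversity, and external diversity against the
initial pool.

The sub-sampling strategies (`sample_by_diversity`) rank each molecule by
its mean Tanimoto distance to the rest of the set — its contribution to the
internal diversity — and take the top n (Tani-Inf), bottom n (Tani-Sup) or a
uniform draw (Random), stratified over activity bins.

## Evaluation metrics

Validity is the fraction of generated strings RDKit parses; uniqueness the
fraction of valid molecules with distinct canonical SMILES; novelty the
fraction of unique molecules absent from the reference set.  Tanimoto
similarity uses ECFP4 fingerprints (Morgan radius 2; 2048 bits — the bit
length is not dictated by the name and is fixed for reproducibility).
`Div(A,B)` is the mean Tanimoto distance over all |A|·|B| ordered pairs; the
internal diversity `Div(A,A)` includes self-pairs, matching the plain double
sum (excluding the diagonal is an option and shifts values by O(1/|A|)).

The KL score uses k = 10 features: NumRotatableBonds, MolLogP, MolWt,
BertzCT, TPSA, NumHAcceptors, NumHDonors, NumAliphaticRings,
NumAromaticRings, and the distribution of maximum nearest-neighbour ECFP4
similarities to the reference set.  (One published listing of this panel
fuses "MolWt" and "NumHDonors" into a single name; since MolWt already
appears, the ninth descriptor is read as NumHDonors.)  Each feature's
D_KL(reference ‖ generated) is estimated on shared supports — 50 equal bins
over the pooled range for continuous features, one bin per observed value
for integer features — with additive smoothing ε = 1e-10, and
`S = (1/k) Σ exp(−D_KL,i)`, so 0 < S ≤ 1 and S = 1 iff every feature
distribution matches.  The reference side of the nearest-neighbour feature
is computed leave-one-out (otherwise it is identically 1); when the
generated set is exactly the reference multiset the same rule is applied, so
perfect reproduction scores S = 1.

## Synthetic data and the surrogate oracle

The toy library generator assembles random small organic molecules atom by
atom (C/N/O/S/F/Cl by default; the element pool is configurable), with
occasional double bonds, up to two rings, optional protonated amines and
optional assigned tetrahedral stereocenters; every product is sanitized,
canonicalized and deduplicated, so validity and uniqueness are 100% by
construction and the whole library is reproducible from its seed.  It
emulates the *format* and token statistics of a drug-like corpus — short
branched/cyclic stereo-annotated SMILES — not its chemistry: no
pharmacophores, no synthetic-route realism, and molecular weights an order
of magnitude below lead-like space.  Passing desk-scale tests therefore
demonstrates that the machinery (representation learning, adversarial
training, Pareto feedback) functions and couples correctly, not that the
pipeline discovers potent chemistry.

The surrogate activity oracle stands in for a trained predictor where a
labeled corpus is unavailable: a fixed smooth function of computed
descriptors on a pIC50-like scale,

    4 + 2.5·exp(−((logP−2.5)/1.5)²) + 2·exp(−((TPSA−60)/30)²)
      + 0.5·min(rings, 2) + 0.5·exp(−((MW−300)/100)²),  clamped to [4, 10].

It is deterministic per canonical SMILES, cheap, and has a smooth optimum
inside the toy generator's reachable space, which is exactly what the
feedback loop needs to demonstrate distribution shift.  The clamp mirrors
the span of typical experimental pIC50 sets.

## Desk-scale study conditions

The reference experiments need 100k–500k molecules and thousands of epochs;
the test suite and `scripts/acceptance.py` run scaled-down analogues chosen
once:

- Reconstruction: 2000 training + 200 held-out toy molecules over a
  ring-free branched grammar (C/N/O/F; exactly 10 vocabulary tokens, ≤ 20
  tokens per molecule), 64 LSTM units, 32-dim context vector, batch 64,
  60 epochs, lr 4e-3 with 0.97 per-epoch decay.
- Latent GAN: trained on the 2000 context vectors; z_dim 16, reduced dense
  widths (critic 64-64-64, generator 32-64-64), 12 epochs at lr 2e-4.  One
  "epoch" is a pass over the data in batches with `n_critic` critic updates
  then one generator update per batch.
- Feedback loop: pool 300, 50 samples per epoch, 10% replacement, 30
  epochs, surrogate-activity objective paired with −SAS; during this phase
  the GAN steps with batch 30 at lr 5e-4 so the generator can track the
  drifting pool within 30 short epochs.

## Known limitations

- Runtime: the numpy engine is single-threaded and eager; it is sized for
  desk-scale corpora (10³ molecules), not for the 10⁵-molecule reference
  experiments.
- The autoencoder has no attention; reconstruction degrades with sequence
  length, which is why over-length inputs are rejected at encoding time.
- The generator's batch-normalization statistics differ slightly between
  training and inference early in training; sampled validity at epoch 0 of
  the feedback loop reflects the eval-mode network.
- KL-score histograms are sensitive to bin count for small samples; the
  default 50 bins assumes a few hundred molecules per side.
- The predictor is frozen during feedback optimization; co-training it on
  generated molecules is out of scope.
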