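# Methods

`socialpose` implements a feature-based encoding analysis of social scene
perception: compact 3D "social pose" descriptors of the people in a video
are compared, as predictors of human behavioral ratings, against the full
3D body-joint representation they are derived from, against their 2D
projections, and against embedding models of varying quality. Because the
original stimuli (videos, crowd-sourced ratings, pretrained-network
activations) are not shipped, the package includes a first-class synthetic
scene generator that reproduces the statistical structure the analysis
assumes, so every stage is testable end to end.

## Feature model

Each video contains two agents tracked as 45 3D joints (the 24 canonical
SMPL body joints plus 21 face/hand/foot landmarks) over 90 frames in camera
coordinates (meters, +z = depth). Three feature families are built per
video:

* **Full joints (270-dim).** Each agent's track is averaged over frames and
  the two 45x3 poses are flattened agent-major, joint-major,
  coordinate-minor.
* **3D social pose (12-dim).** Per agent: face position = midpoint of the
  two eye joints; facing direction = the unit normalization of the average
  of the head-center-to-nose and neck-to-nose vectors. The two raw vectors
  are averaged first and normalized once. Features are computed per frame
  and then averaged over time; the time-averaged direction is *not*
  re-normalized (plain mean).
* **2D social pose (8-dim).** The 3D vector with the depth components
  (z, dz) dropped — a raw projection, no 2D renormalization, so
  out-of-plane information is genuinely lost.

Agents are ordered left-to-right by mean x over valid frames (ties broken
by mean depth), giving a deterministic feature layout without identity
labels. Videos in which either agent has any invalid (failed) frame are
excluded entirely; all analyses run on the surviving set.

A depth-fusion helper (`fuse_depth`) implements the rule for combining a
pose estimator's camera translation with a separate metric depth estimate:
the translation's z component is replaced, x and y are untouched.

## Encoding framework

All predictive scores come from a ridge encoding pipeline:

* Features and targets are z-scored per column with statistics from the
  training rows only (population SD, ddof=0; constant columns map to
  zeros). No intercept is fit.
* The penalty is chosen from a log-spaced grid of 21 values spanning
  1e-10..1e10 by 5-fold cross-validation repeated twice (seeded shuffles,
  within-fold standardization, mean validation Pearson r; ties prefer the
  smaller alpha, then the lexicographically smaller candidate). For
  multi-layer embedding models, the layer and alpha are selected jointly
  the same way.
* The selected model is refit on the full training split and scored as the
  Pearson r between predicted and observed ratings on the held-out test
  split (nominally 200/50 videos before exclusions). Zero-variance
  predictions or targets score r = 0 with a warning rather than raising.
* Embedding matrices wider than the Johnson–Lindenstrauss minimum
  dimension, floor(4 ln n / (eps^2/2 - eps^3/3)) at eps = 0.1 (4732 for
  n = 250), are first reduced by Achlioptas-style sparse random projection
  (density 1/sqrt(d)); narrower matrices — including all pose feature
  tables — are never projected.
* Ridge solutions use the closed form via SVD; one decomposition serves
  the whole alpha path. Solutions satisfy their normal equations to 1e-8
  on random instances (tested).

**Grouped (banded) ridge.** To combine an embedding with the 3D pose
features, each standardized group g is scaled by sqrt(gamma_g) with the
group weights gamma drawn on the simplex: 200 Dirichlet samples, half at
concentration 0.1 (corner-seeking) and half at 1.0 (uniform), each
evaluated over the shared alpha grid with the same repeated 5-fold CV.
Internally the fit uses the dual form K(gamma) = sum_g gamma_g X_g X_g^T —
one n x n eigendecomposition per candidate instead of a d x d solve;
this is algebraically identical to the column-scaled primal.

No selection step (layer, alpha, gamma) ever sees test rows; this is
asserted by canary tests (shuffling the test ratings changes no selection).

## Permutation statistics

All inference is nonparametric, 5,000 permutations by default, with the
Monte-Carlo floor p = max(count, 1)/n_perm (minimum reportable p 0.0002):

1. *Model population vs a single model* (two-tailed): statistic = mean
   model r minus the single model's r; the null shuffles the held-out
   ratings against the fixed predictions and recomputes every correlation.
2. *Paired augmentation* (one-tailed): statistic = mean paired difference
   (combined minus alone); the null swaps each pair independently.
3. *Score correlation* (two-tailed): Pearson r between two per-model score
   vectors; the null shuffles one vector.
4. *Correlation difference* (one-tailed): delta r = r(3D scores, human) -
   r(2D scores, human); the null shuffles both score vectors
   independently.

Permutations rescore fixed predictions; models are not refit inside the
null (refitting thousands of models per permutation is neither stated nor
tractable). Tests 2 and 3 also offer exact enumeration for small inputs
(<= 20 pairs, <= 8 items), used as an oracle in the test suite. All four
tests hold their nominal 5% type-I rate within [0.03, 0.07] under their
own nulls (1,000 replicates; tested).

**Semi-partial analysis.** A multi-output ridge predicts the 270 joint
features from a smaller predictor set (positions only, directions only, or
the full 12-dim pose vector); the prediction is subtracted and the ratings
are re-encoded from the residuals. One alpha is shared across the 270
outputs so the residualizer stays a single linear map. Two numerical
safeguards matter here:

* Alpha is the *least* regularization whose mean validation r is within
  1e-3 of the best. A strictly score-maximizing alpha can leave ~1% of the
  predictor signal in the residual as shrinkage bias; because that bias is
  perfectly correlated with the removed signal, downstream standardization
  re-amplifies it and the "unique" variance estimate becomes spurious.
* Residual columns whose SD falls below 1e-8 of the original column SD are
  set to exactly zero: at that scale the residual is the rounding noise of
  the fit (self-residualization would otherwise "recover" the signal from
  float error).

## Synthetic scene generator

The generator emulates the study conditions, not the imagery: 250 videos,
two agents, 90 frames, an 80/20 train/test split, ratings on a 1–5 scale
averaged over 10 simulated raters with response noise SD 0.5.

* **Layout.** A midpoint is drawn in a box in front of the camera
  (x in [-1, 1], y in [-0.3, 0.3], depth in [3, 7] m); the agents are
  separated by a distance drawn uniformly from [0.5, 3] m along a
  direction in the x–z quadrant (azimuth phi uniform in [0, pi/2] from the
  lateral axis toward depth, vertical tilt uniform in [-0.15, 0.15] rad),
  so agent order by x is well defined and roughly half the displacement
  variance lies in depth. All positions are multiplied by a log-uniform
  scene scale in [0.7, 1.4]. Facing directions are uniform on the sphere by
  default; "mutual" and "noisy mutual" modes are available. The
  depth-dominant condition used by the parameter-recovery analyses narrows
  the azimuth to [pi/6, pi/2] (about 70% of displacement variance in
  depth).
* **Rendering.** The rest-pose skeleton is rigidly rotated (minimal
  rotation taking the canonical facing axis onto the latent direction —
  roll is left at zero) and translated so the eye midpoint sits at the
  latent position; isotropic per-frame jitter (SD 0.01 m) emulates
  estimator noise. Frames fail independently at 6e-4 per frame per track,
  which excludes roughly 10% of 250 videos — matching the scale of the
  exclusions a real pose estimator produces.
* **Ratings.** Raw scores per video: spatial expanse = log scene scale;
  inter-agent distance = |p1 - p2|; agents facing = mean cosine between
  each agent's facing and the direction to the other; communicative =
  facing minus 0.5 x distance; physical = max(0, 1 - distance / 2 m). Raw
  scores are affinely rescaled to [1, 5] over the batch (a constant batch
  maps to the midpoint 3), then per-rater Gaussian noise is added, clipped
  to [1, 5], and averaged. The rating model is a stand-in: it preserves
  which latent each dimension tracks, not any psychophysical law.
* **Embeddings.** A synthetic model layer is
  info x (F_std W) + (1 - info) x N, with W a seeded Gaussian map and N
  unit noise in the same columns: info = 0 is pure noise, info = 1 a
  noiseless linear image of the pose features, and intermediate levels give
  a smoothly increasing decodability — the knob behind the
  "models that encode pose better predict ratings better" analysis.
  Blending signal and noise in shared columns (rather than appending
  noiseless signal columns) is deliberate: appended noiseless columns would
  make any info > 0 perfectly decodable after standardization.

What passing tests on this generator do **not** show: anything about real
videos — articulated motion, occlusion structure, rater psychology,
nonlinear rating ceilings, or the actual correlation values of the original
study, which require the original stimuli and models.

Because facing is a *product* of latents (direction dotted with a
position-dependent unit vector), its best linear readout varies noticeably
across dataset draws (test r roughly 0.4–0.9 across seeds at n = 250); the
distance rating is the generator's most stably decodable social primitive.
The augmentation analysis in the acceptance suite is therefore scored on
the distance rating, while the decoding-vs-alignment correlation uses
facing.

## Problem sizes and determinism

Default analyses use 250 videos, 12 synthetic embedding models with two
layers each (embedding dim 100), 5,000 permutations; the acceptance script
adds a 10-replicate depth-dominant recovery study. The test suite scales
replicate counts to keep the full run in a few minutes (e.g. 50 recovery
replicates, calibration at 1,000 outer replicates x 500 permutations).
Every stochastic step takes an explicit integer seed; the pipeline fans a
single global seed into fixed per-stage seeds recorded in the run manifest,
and rerunning with the same configuration is byte-identical.

## Known limitations

* The rating model is linear-plus-rescale; no interaction between rater
  noise and scene content.
* Bodies are rigid (no articulation); joints beyond the five named
  landmarks carry only rigid-motion information.
* The grouped solver handles the two-group case the analysis needs; it is
  not a general banded-ridge package.
* Exact SMPL-X landmark indices are a convention of the template, chosen
  by name, not a reconstruction of any particular regressor's ordering.
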