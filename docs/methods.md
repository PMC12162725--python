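# Methods

## Model and procedure

The classifier is GMLVQ: one prototype per class, nearest-prototype
assignment under `d(w, x) = (x − w)ᵀ Λ (x − w)` with `Λ = ΩᵀΩ` and
`Tr(Λ) = 1` (`Ω` square, N×N).  The GLVQ cost is the sum over samples of
`(d₊ − d₋)/(d₊ + d₋)` with identity activation; each term lies in [−1, 1]
and the removable singularity at `d₊ = d₋ = 0` is defined as 0 (term and
gradients).

Center harmonization iterates: cross-validate the center classifier on
healthy controls under the current correction; stop when the mean CV
balanced accuracy is ≤ 1/C; otherwise train once on all controls, take the
leading eigenvector of Λ, re-orthogonalize it against the accumulated set
(a numerical guard — the restriction Ω → ΩΨ already forces new
eigenvectors into the complement), append, and rebuild
`Ψ = I − Σ v⁽ⁱ⁾v⁽ⁱ⁾ᵀ`.  The extracted directions define V; harmonization
is `x → xΨ`, and subsequently trained models apply Ψ to Ω after every
update, confining their relevances to U.

Key assumptions: age/sex-matched control cohorts share one distribution up
to a center effect; the center effect is a *linear* (mean-shift-like)
structure expressible as a low-dimensional subspace; and the signal of
clinical interest is not collinear with it.  The method places no
distributional requirements on the features (no Gaussianity or
independence); it removes the same subspace from every center, so it
cannot introduce center-specific distortions the way per-center
location/scale corrections can when their parameters are noisy.

## Training (waypoint gradient descent)

Batch steepest descent on the summed cost with gradients divided by the
sample count P, so the step sizes are per-sample quantities and one scale
works across cohort sizes.  Defaults: 30 epochs, initial step sizes 1
(prototypes) and 2 (Ω), rolling window of the last 10 parameter states.
Per epoch: take a raw step; form the window-average state; evaluate both;
keep whichever is cheaper, but only if it does not increase the cost —
otherwise reject the step and halve both step sizes (floor 1e-6).  This
makes the cost trace monotonically non-increasing by construction, which
is also asserted as a test invariant.  Prototypes initialize at the
class-conditional means and Ω at the (projected, trace-normalized)
identity, so training is fully deterministic given the data; the config
seed only feeds cross-validation fold assignment.  Convergence was checked
by comparing against 10× longer runs on the reference fixtures (no change
in the learned relevance span).

Numerical conventions: nearest-prototype ties resolve to the smallest
class index; eigenvector signs are fixed by making the largest-magnitude
entry positive; all-zero Ω (possible only for a rank-0 projector) is an
error.

## Cross-validation and stopping

10×10 repeated stratified k-fold CV; balanced accuracy (mean per-class
recall, chance = 1/C); 95% confidence intervals by the normal
approximation over the 100 fold scores.  The stopping rule compares the
*mean* CV BAC with 1/C (the CI lower bound is an alternative; the plain
mean gives a clean null: a dataset with no center signal can stop with an
empty V).  Two caveats, both visible in the
test suite: (i) under an exact null the mean CV BAC is centered on 1/C
with a dataset-level spread of ~0.03 at 120 samples (fold scores share
test samples across repeats), so roughly half of null datasets trigger one
spurious iteration before stopping — the loop self-corrects because the
next evaluation falls below chance; (ii) a trained-on-noise classifier
scores slightly *below* chance on held-out folds, which is why post-stop
BACs sit visibly under 1/C.

`max_iter` defaults to the feature count; hitting it flags the result as
non-converged instead of raising.

## Feature space and voxel reconstruction

The coordinate system comes from PCA on a mean-centered space-defining
reference cohort (SVD; centering is used because downstream z-scoring
presumes origin-free coordinates), keeping the smallest K whose cumulative
explained-variance fraction reaches the target (default 0.8).  `GᵀG = I`
holds exactly; `GGᵀ` is a rank-K projector, so back-projection is lossy
outside the span.  Features are z-scored (unbiased SD) with parameters
from the reference healthy controls.

Voxel maps: `reconstruct(x) = m + xGᵀ`, `X_rem = (x(I−Ψ))Gᵀ`,
`X_corr = m + (xΨ)Gᵀ`, so `X_corr + X_rem = reconstruct(x)` is an exact
algebraic identity (asserted at 1e-9).  The reference mean `m` is assigned
wholly to the corrected profile, keeping the removed map interpretable as
pure center signal.  For visualization the feature z-scoring is undone
*before* reconstruction and a voxel-wise z-score against the reference
controls is applied afterwards; zero-variance voxels map to 0 with a
logged warning.  The order of unscaling relative to the correction is a
declared convention (the operations do not commute exactly).

## Diagnostics

Principal angles between subspaces come from the singular values of
`AᵀB` (clipped to [0, 1]), reported ascending in degrees; the tests check
them against closed forms and an independent grid-search alignment oracle.
Per-feature group differences use the Kruskal–Wallis chi-square
approximation with tie correction (group sizes ≥ 20 in intended use;
constant features get p = 1 by convention), optionally Bonferroni-divided
thresholds.  The multiclass AUC is a macro average of one-vs-rest rank
AUCs on negated prototype distances — a convention chosen for prototype
classifiers, not a canonical definition.

## Synthetic data

`make_truth`/`generate_multicenter` emulate the study design: C control
cohorts sharing one distribution, each center displaced by a fixed vector
inside a planted subspace V\*, disease cohorts (one diagnosis per center,
mirroring retrospective pooling) shifted along directions at a controlled
angle to V\*, isotropic unit Gaussian noise (heavy-tailed t(5) option for
checking the no-Gaussianity claim).  Defaults: 4 centers, 31 features,
k = 3, offset norm 2 (in units of the within-class SD), 30 controls per
center, 3 diseases × 35 patients, 3-SD disease effects, orthogonal disease
directions.  The noise stream is independent of the offset values, so
zeroing the offsets yields an exactly paired center-free oracle dataset —
used to quantify signal preservation.

What the generator does **not** emulate: scanner point-spread functions,
reconstruction physics, nonlinear or multiplicative center effects,
center-specific covariance changes, or correlated voxel noise.  Passing
tests therefore certify the subspace-removal machinery and its
statistical behavior under the linear mean-shift model, not performance on
real PET cohorts.

## Known limitations

- **Finite-sample recovery.**  With 4 centers, only four cohort means pin
  down a 3-D subspace; at 30 controls per center the weakest recovered
  direction is far from the planted one (largest principal angles of tens
  of degrees), for the extraction and for the class-mean maximum-likelihood
  oracle alike.  The learned relevance span converges to V\* as cohorts
  grow (~39° → 12° → 5° at 30/300/2000 controls per center on the
  reference geometry).  Practically: harmonization still removes the
  center signal (post-stop BAC at chance) but the removed subspace also
  contains noise directions, and dim(V) typically exceeds the true
  dimension by one.
- Disease signal inside V is removed with the center signal; the method is
  unsuitable when the clinical contrast is correlated with center origin.
- The pipeline must be refitted when a new center is added.
- Problem sizes in the tests and acceptance script (31 features, 120
  controls, 105 patients, 10×10 CV) are the package's reference study
  conditions; runs complete in seconds to a couple of minutes on one CPU.
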