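# Methods

## Problem and model

Multi-voxel MR spectroscopic imaging (MRSI) of a brain volume yields a
grid of proton spectra, one per voxel. In a tumor-bearing brain, each
voxel spectrum is modeled as a linear mixture of a small number of
tissue-type signatures — in the two-class setting, a tumor source and a
normal-parenchyma source. Stacking the spectra column-wise into a data
matrix `X` (p spectral points × n voxels) the model is the low-rank
factorization

    X ≈ W H,    W: p × k sources,   H: k × n non-negative mixing matrix,

with `k = 2` throughout. Long-echo spectra contain genuinely negative
intensities (the J-modulated lactate/alanine methyl resonances appear
inverted), so a factorization that forces `X ≥ 0` and `W ≥ 0` can only
be applied to magnitude spectra. The convex variant instead constrains
the sources to non-negative combinations of the observed spectra,

    W = X G,    G: n × k,  G ≥ 0,

which accepts mixed-sign data and produces mixed-sign sources that look
like spectra. Because each source is a weighted average of data columns,
convex-NMF behaves like a soft clustering and its sources resemble
cluster centroids — this is what makes the extracted pair directly
interpretable as "tumor-like" and "normal-like" signatures.

## Preprocessing

Spectra are restricted to the 0–4.5 ppm window (closed interval, keyed
by ppm value so the axis may run in either direction) and then each
voxel spectrum is scaled to unit Euclidean length (UL2). Normalization
happens after windowing; the reverse order would normalize against
signal that is subsequently discarded. All-zero voxel columns are
rejected outright rather than passed through: a spectrum without a
direction cannot be correlated with anything and would silently poison
the labeling stage.

The four non-negative factorizers consume `|X|` (element-wise
magnitude); the convex factorizer consumes `X` as is.

## Factorization algorithms

All five methods minimize the Frobenius reconstruction error
`‖X − WH‖_F` and share one stopping rule: stop when the absolute change
in the error between successive iterations falls below `tol = 1e-5`, or
after `max_iter = 2000` iterations. Every ratio update carries a
denominator guard of `1e-12`.

* **euc** — multiplicative updates
  `H ← H ∘ (WᵀX)/(WᵀWH)`, `W ← W ∘ (XHᵀ)/(WHHᵀ)`, followed by rescaling
  each W column to unit sum with the inverse scale folded into H (the
  reconstruction is unchanged; sources get a fixed normalization).
  Monotone non-increase of the error is a theorem for these updates and
  is enforced as a property test — it is the tripwire for transcription
  errors in the formulas.
* **als** — alternating exact least squares with negatives clipped to
  zero. Rank-deficient normal systems fall back to the SVD
  (pseudoinverse) solution. Note that the *clipping* step carries no
  descent guarantee: the projected iterate can slightly increase the
  objective. This is inherent to clipped ALS, not an implementation
  artifact, and the tests assert only what the algebra guarantees
  (solve optimality before projection, non-negativity after it).
* **alspg** — each least-squares subproblem is solved by projected
  gradient descent with an Armijo backtracking line search
  (initial step 1, shrink ×0.1, sufficient-decrease constant 0.01, 20
  backtracks, 10 inner steps per outer iteration). The line search
  guarantees per-subproblem non-increase; accuracy near a subproblem
  optimum is limited to roughly the square root of machine epsilon by
  cancellation in the objective comparison.
* **alsobs** — ALS where the clipped (pruned) entries are compensated by
  an Optimal-Brain-Surgeon correction: for each factor column with
  pruned set P, the surviving entries move by
  `δ = −A⁻¹ E_P (E_Pᵀ A⁻¹ E_P)⁻¹ E_Pᵀ f`, the block form of the
  single-weight OBS rule, with `A` the λ-damped subproblem Hessian
  (`WᵀW + λI` or `HHᵀ + λI`, λ = 1e-3 by default). A singular damped
  system escalates λ tenfold up to a cap and then falls back to plain
  clipping with a warning. In the λ → ∞ limit the correction vanishes
  and the method reduces to plain ALS (tested). This module is a
  reconstruction from the published description of the approach, with
  the monotonicity and ALS-limit tests as its acceptance surface.
* **convex** — with `A = XᵀX` split into positive part `A⁺` and
  magnitude of negative part `A⁻`:

      H ← H ∘ √( (GᵀA⁺ + (GᵀA⁻G)H) / (GᵀA⁻ + (GᵀA⁺G)H) )
      G ← G ∘ √( (A⁺Hᵀ + A⁻G(HHᵀ)) / (A⁻Hᵀ + A⁺G(HHᵀ)) )

  with `W = XG` recomputed after each step. The square-root
  multiplicative form preserves `G, H ≥ 0` from non-negative starts;
  `W = XG` holds exactly at every iteration. Updates are applied H
  first, then G.

### A note on the stopping rule

"Change below 1e-5 between successive iterations" can fire on a saddle
plateau: rarely (under 1% of random starts on the default phantom — 0
of 300 sampled initializations, with one known case outside that
range), a convex restart's error sits at 4.6 with sub-tolerance changes
for ~16 consecutive iterations before escaping and converging to the
common solution near 0.03. The rule is
kept as stated because it is part of the protocol being implemented;
the multi-restart stability diagnostic is exactly the tool that exposes
such runs, which is why the stability report carries both the minimum
and the median of the matched correlations.

## Initialization

Six strategies produce starting factors; all are deterministic given a
seed, return `H0 ≥ 0`, and on the convex path return `G0 ≥ 0` with
`W0 = X G0` exact:

* **random** — all entries uniform in (0, 1).
* **k-means** — cluster the n voxel spectra; with `B` the binary k × n
  indicator and `D = diag(cluster sizes)`: `H0 = B + 0.2·E` and, on the
  convex path, `G0 = BᵀD⁻¹ + 0.2·E`. The 0.2 offset smooths the hard
  indicators so multiplicative updates can move every entry. On the
  non-convex path `W0` is the centroid matrix. Empty clusters trigger a
  bounded (5×) re-seed.
* **fcm** — fuzzy c-means (standard Bezdek alternating updates,
  fuzzifier m = 2 by default), implemented in-package; memberships play
  the role of the indicator, with the same 0.2 offset on the convex
  weights.
* **pca / ica** — principal axes / fastICA components over the spectral
  dimension. Components are mixed-sign, so feasibility is restored by
  taking absolute values and refitting: `H0` is the column-wise NNLS
  projection of `|X|` onto `W0`; on the convex path `G0` solves
  `W0 ≈ X G0` by NNLS and `W0` is reset to `X G0`. This rectification
  convention is a documented package choice; the rank-1 exactness test
  pins its behavior.
* **nmf** — a short warm run (20 iterations by default) of the euc
  updates from a random start on magnitude data.

## Voxel labeling and maps

Two labeling rules are implemented.

* **Contribution rule.** The contribution of source k to voxel v is the
  scalar product of the voxel spectrum with its rank-one reconstruction
  from that source: `C[k, v] = (x_v · w_k) h_kv`. Summed over sources
  this telescopes to `x_v · (WH)_v` exactly (tested to 1e-10). The
  voxel takes the argmax source; ties break toward the lower index and
  are logged.
* **Correlation rule** (the map-generating default). Each voxel is
  labeled by the source its spectrum has the highest Pearson
  correlation with; when every correlation is below the threshold
  (default 0.5) the voxel is left UNDECIDED — the method abstains
  rather than guesses. A value exactly at the threshold counts as
  decided; correlations are signed, so a strongly anti-correlated
  source never wins a label. Cosine similarity is available behind a
  flag for sensitivity analysis.

Sources are anonymous until assigned: the tumor source is the one most
correlated with the tumor-class mean spectrum (from a mask or explicit
reference files); the non-tumor source is chosen among the remainder.
If one source wins both classes the assignment is ambiguous and the
caller must assign explicitly.

The contribution map renders the tumor source's row of `C`, min-max
scaled per map to [0, 100] (the scaling is over that single row — the
map displays one source). Upsampled maps use separable linear
interpolation with `(n−1)·f + 1` samples per axis so every original
voxel center keeps its exact scaled value.

## Scoring

Gold masks label voxels TUMOR / NONTUMOR / EXCLUDED; EXCLUDED voxels
never enter any denominator (tested: adding them changes nothing).
A predicted UNDECIDED or wrong-source label is an error for its gold
class. Per-class accuracy is the percentage of gold-class voxels
labeled correctly, so accuracy_T/100 ≡ sensitivity and accuracy_N/100 ≡
specificity when computed from the same counts. Means across grids skip
absent entries (a grid with no usable non-tumor area contributes
nothing to the non-tumor columns); rounding to display precision
(accuracies one decimal, rates two) happens only at display time.

Uniqueness diagnostics: the stability analysis re-runs the
factorization from many random initializations and reports the
permutation-matched absolute Pearson correlations between the source
sets of every run pair (k = 2, so matching is an exhaustive
2-permutation search). The perturbation analysis multiplies H
element-wise by uniform (0, 1) noise (a Hadamard product, which
preserves the shape of a non-square H; an explicit `R` argument admits
other perturbation matrices), re-runs the factorization from the
perturbed factors, and reports the RMSE between original and
re-converged factor entries.

## Synthetic phantom

The phantom emulates a 10×10 MRSI grid over a 692-point, 0–4.5 ppm axis
with two tissue signatures rendered as sums of Gaussian kernels (FWHM
parametrization, 0.06 ppm default width; Lorentzian available):

* tumor, long echo: choline 3.21 ppm (+1.0), residual creatine 3.03 ppm
  (+0.3), inverted lactate 1.30 ppm (−1.0);
* tumor, short echo: choline, creatine, and mobile-lipid peaks at
  1.30/0.90 ppm (all positive);
* normal parenchyma (both echo times): NAA 2.02 ppm, creatine, choline
  at comparable heights (1.0 / 0.9 / 0.8).

Amplitudes are free parameters of the phantom with these documented
defaults; real acquisitions publish no SNR for comparison, so the
default noise level is likewise a choice (0 for the exact-recovery
phantom; tests and the acceptance script also use 10% of the smallest
normalized peak amplitude as a "moderate noise" condition).

Geometry: an elliptical tumor core (default radii 2.5 × 3.5 voxels at
the grid center) with a partial-volume ramp of one voxel measured along
the ray from the ellipse center. The per-voxel tumor fraction f is 1 in
the core, 0 outside the ramp, linear in between, and non-increasing
along any ray. Both templates are unit-normalized before mixing, so
`x_v = f·s_t + (1−f)·s_n` makes f a signal fraction and leaves the
f = 0.5 boundary symmetric between tissue types. I.i.d. Gaussian noise
is added before the final per-voxel UL2 normalization. The truth mask
is TUMOR for f > 0.5, NONTUMOR for f < 0.5, and EXCLUDED at exactly
0.5, mirroring the exclusion of borderline partial-volume voxels from
gold labels.

What the phantom does *not* emulate: J-coupling evolution and
multiplet structure, macromolecule baselines, field inhomogeneity and
lineshape distortion, chemical-shift displacement, spatially correlated
noise. Passing the recovery tests therefore demonstrates that the
algorithms and the pipeline are implemented correctly under the linear
mixing model, not that real acquisitions of any particular quality will
segment this well.

## Problem sizes used by tests and the acceptance script

Property sweeps over the update rules use 20×10 random instances with
k = 2 (100 instances in the test suite; 20 in the script) and 500
iterations for the multiplicative trajectories. Pipeline checks use the
default 692×100 phantom; the stability diagnostic uses 50 restarts.
IO and CLI round-trips use a reduced 200-point, 8×8 phantom.

## Known limitations

* `alsobs` is a reconstruction from a prose description; no reference
  implementation was available to diff against.
* The correlation-rule boundary between tissue types coincides with the
  f = 0.5 truth boundary only because the phantom mixes unit-norm
  templates; with unequal template norms the crossover shifts and
  borderline voxels can flip class.
* The change-based stopping rule can halt on saddle plateaus (see
  above); downstream analyses should inspect the stability report
  rather than trust a single restart.
* k is fixed by the caller (default 2); no rank-selection machinery is
  provided.
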