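# mrsisep

Unsupervised delimitation of brain-tumor tissue from multi-voxel MR
spectroscopic imaging (MRSI) grids by blind source separation.

An MRSI acquisition yields a grid of voxels (for example 10×10), each
carrying a proton MR spectrum. In a tumor-bearing brain every voxel
spectrum is, to good approximation, a linear mixture of a small number
of tissue-type signatures. `mrsisep` factorizes the data matrix
`X ∈ ℝ^{p×n}` (p spectral points × n voxels) as

    X ≈ W H,    H ≥ 0,  k = 2 sources,

and labels every voxel from the result — no tissue labels are used to
build the model. The method of record is **convex NMF**, which
constrains the sources to the column space of the data, `W = X G` with
`G ≥ 0`: it accepts the mixed-sign spectra of long-echo MRSI directly
(inverted lactate and all) and yields sources that behave like cluster
centroids, i.e. tumor-like and normal-like spectral signatures. Four
classical non-negative variants (multiplicative Euclidean updates,
alternating least squares, ALS with projected gradients, ALS with
Optimal-Brain-Surgeon pruning) run on magnitude spectra for
benchmarking, each combinable with six initialization strategies
(random, k-means, fuzzy c-means, PCA, ICA, warm-start NMF).

Voxels are then labeled by the source their spectrum correlates with
most strongly (abstaining as UNDECIDED below a 50% threshold), or by
the per-source contribution score `C[k,v] = (x_v·w_k) h_kv`; the tumor
source's contributions render a 0–100 "contribution map" over the
grid. When a gold-standard tissue mask is available, label maps are
scored by per-class accuracy, sensitivity and specificity.

Real pre-clinical acquisitions of this kind are not redistributable, so
the package ships a synthetic two-tissue phantom (choline/creatine/NAA/
lactate/lipid peaks, elliptical tumor with partial-volume border,
additive noise, unit-length normalization) with exact ground truth,
which drives the entire test suite.

## Worked example

```python
import numpy as np
from mrsisep import *
from mrsisep.initializers import init_kmeans

# a noisy 10x10 phantom with known ground truth
ph = generate_phantom(PhantomConfig(noise_sd=0.008, seed=42))
X = ph.dataset.X                      # 692 x 100, mixed sign

res = factorize(X, FactorizationConfig(method=Method.CONVEX, k=2),
                init_kmeans(X, 2, seed=0, convex=True))
print(f"converged: {res.converged} after {res.iterations} iterations; "
      f"final error {res.final_error:.4f}")

perm, score = match_sources(res.W, ph.true_sources)
print(f"matched |r| vs true sources: {score:.4f}")

ref = ReferenceSpectra(tumor_mean=ph.true_sources[:, 0],
                       nontumor_mean=ph.true_sources[:, 1])
asg = identify_tumor_source(res.W, ref)
lm = label_by_correlation(X, res.W, ph.dataset.grid)
m = classification_metrics(lm, ph.truth_mask, asg)
print(f"accuracy T: {m.accuracy_tumor:.1f}%  ({m.counts.tp}/{m.counts.tp+m.counts.fn})")
print(f"accuracy N: {m.accuracy_nontumor:.1f}%  ({m.counts.tn}/{m.counts.tn+m.counts.fp})")
```

Output:

```
converged: True after 310 iterations; final error 2.0833
matched |r| vs true sources: 0.9991
accuracy T: 100.0%  (36/36)
accuracy N: 100.0%  (64/64)
```

The extracted sources correlate above 0.999 with the two tissue
templates the phantom was mixed from (after permutation matching —
source order is arbitrary), and the correlation-rule labeling
reproduces the ground-truth mask on every voxel: 36 of 36 tumor voxels
and 64 of 64 non-tumor voxels. The final error is the Frobenius norm of
the residual `X − WH` over all 69 200 matrix entries of the
unit-normalized dataset.

## Command line

The same pipeline is scriptable from the shell:

```sh
mrsisep simulate --seed 1 --noise-sd 0.008 --out sim/
mrsisep run sim/dataset.csv --mask sim/truth_mask.csv \
        --method convex --init kmeans --seed 0 --out out/
```

`out/` then contains `W.csv`, `H.csv`, `G.csv`, the error trajectory,
the label grid (`labels.csv`, codes 1..k and `U` for undecided), the
0–100 contribution map (raw and bilinearly interpolated, CSV + PNG),
`metrics.json`, and a `manifest.json` from which the run is exactly
reproducible. Further subcommands: `factorize`, `label`, `map`,
`evaluate`, `benchmark` (all 5 methods × 6 initializations),
`stability`, `perturb`.

## Layout

- `src/mrsisep/spectra.py` — MRSI domain types and preprocessing
  (ppm windowing, unit-length normalization, magnitude transform)
- `src/mrsisep/phantom.py` — synthetic two-tissue phantom
- `src/mrsisep/initializers.py` — the six initialization strategies
- `src/mrsisep/nmf.py` — the five factorization algorithms
- `src/mrsisep/labeling.py` — voxel labeling and map rendering
- `src/mrsisep/evaluation.py` — scoring, stability, perturbation
- `src/mrsisep/io.py`, `src/mrsisep/cli.py` — file formats, pipeline,
  command line

`docs/methods.md` documents the model, the update rules, all tunable
parameters with their defaults, and known limitations.
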