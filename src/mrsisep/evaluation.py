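"""Quantitative scoring of sources and label maps.

Sources are scored against class mean spectra (Pearson correlation and
RMSE); label maps are scored against a gold-standard tissue mask
(per-class accuracy, sensitivity, specificity).  Solution-uniqueness
diagnostics mirror the standard protocol for multiplicative-update
factorizations: multi-restart agreement (permutation-matched source
correlations over many random initializations) and recovery after a
random perturbation of the mixing matrix.

Scoring conventions: voxels marked EXCLUDED in the gold mask never
enter any denominator; a predicted UNDECIDED (or wrong-source) label
counts as incorrect for its gold class; per-class accuracy is the
percentage of gold-class voxels labeled correctly, so accuracy_T/100
equals sensitivity and accuracy_N/100 equals specificity on the same
counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import permutations

import numpy as np

from .initializers import InitResult, init_random
from .labeling import SourceAssignment, SourceLabelMap, pearson
from .nmf import FactorizationConfig, FactorizationResult, Method, factorize
from .spectra import ReferenceSpectra, TissueClass, TissueMask


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-class accuracies (percent) and rates from one label map.

    Fields are None when the gold mask contains no voxel of the class
    (e.g. a grid with no usable non-tumor area).
    """

    counts: ConfusionCounts
    accuracy_tumor: float | None
    accuracy_nontumor: float | None
    sensitivity: float | None
    specificity: float | None

    @classmethod
    def from_counts(cls, counts: ConfusionCounts) -> "MetricsReport":
        n_t = counts.tp + counts.fn
        n_n = counts.tn + counts.fp
        sens = counts.tp / n_t if n_t else None
        spec = counts.tn / n_n if n_n else None
        return cls(
            counts=counts,
            accuracy_tumor=100.0 * sens if sens is not None else None,
            accuracy_nontumor=100.0 * spec if spec is not None else None,
            sensitivity=sens,
            specificity=spec,
        )


@dataclass
class SourceFitReport:
    """Source vs reference-mean agreement, per tissue class."""

    r_tumor: float
    rmse_tumor: float
    r_nontumor: float | None = None
    rmse_nontumor: float | None = None


@dataclass
class StabilityReport:
    n_restarts: int
    n_failed: int
    matched_correlations: np.ndarray  # one value per run pair, |Pearson r| after matching

    @property
    def min(self) -> float:
        return float(np.min(self.matched_correlations))

    @property
    def median(self) -> float:
        return float(np.median(self.matched_correlations))


@dataclass
class PerturbationReport:
    rmse: float
    rmse_w: float
    rmse_h: float
    seed: int
    converged: bool


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared difference between two equal-shape arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def source_fit(W: np.ndarray, assignment: SourceAssignment,
               reference: ReferenceSpectra) -> SourceFitReport:
    """Pearson r and RMSE of each assigned source against its class mean.

    The non-tumor class is omitted when no non-tumor reference exists or
    no source is assigned to it.
    """
    W = np.asarray(W, dtype=float)
    w_t = W[:, assignment.tumor_source]
    report = SourceFitReport(
        r_tumor=pearson(w_t, reference.tumor_mean),
        rmse_tumor=rmse(w_t, reference.tumor_mean),
    )
    if reference.nontumor_mean is not None and assignment.nontumor_source is not None:
        w_n = W[:, assignment.nontumor_source]
        report.r_nontumor = pearson(w_n, reference.nontumor_mean)
        report.rmse_nontumor = rmse(w_n, reference.nontumor_mean)
    return report


def classification_metrics(predicted: SourceLabelMap, gold: TissueMask,
                           assignment: SourceAssignment) -> MetricsReport:
    """Confusion counts of a label map against the gold mask.

    A gold-TUMOR voxel counts as TP iff its predicted label is the
    assigned tumor source; a gold-NONTUMOR voxel counts as TN iff its
    predicted label is the assigned non-tumor source (UNDECIDED and
    wrong-source predictions are errors for either class).
    """
    if predicted.grid.n != gold.grid.n:
        raise ValueError("label map and mask grids do not match")
    labels = predicted.labels
    tp = fn = tn = fp = 0
    for v in range(gold.grid.n):
        cls = gold.labels[v]
        if cls is TissueClass.EXCLUDED:
            continue
        if cls is TissueClass.TUMOR:
            if labels[v] == assignment.tumor_source:
                tp += 1
            else:
                fn += 1
        else:
            if assignment.nontumor_source is not None and labels[v] == assignment.nontumor_source:
                tn += 1
            else:
                fp += 1
    return MetricsReport.from_counts(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))


def summarize(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted arithmetic mean of each metric, skipping absent values
    (a grid with no gold non-tumor voxels contributes nothing to the
    non-tumor columns).  Counts are summed for reference."""
    if not reports:
        raise ValueError("summarize requires at least one report")

    def mean_of(attr: str) -> float | None:
        vals = [getattr(r, attr) for r in reports if getattr(r, attr) is not None]
        return float(np.mean(vals)) if vals else None

    total = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        fn=sum(r.counts.fn for r in reports),
        tn=sum(r.counts.tn for r in reports),
        fp=sum(r.counts.fp for r in reports),
    )
    return MetricsReport(
        counts=total,
        accuracy_tumor=mean_of("accuracy_tumor"),
        accuracy_nontumor=mean_of("accuracy_nontumor"),
        sensitivity=mean_of("sensitivity"),
        specificity=mean_of("specificity"),
    )


def match_sources(W_a: np.ndarray, W_b: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Best source-to-source matching between two factorizations.

    Searches all column permutations (trivial for k = 2) maximizing the
    minimum absolute Pearson correlation of matched pairs; returns the
    permutation and that minimum.
    """
    k = W_a.shape[1]
    best_perm: tuple[int, ...] = tuple(range(k))
    best_score = -np.inf
    for perm in permutations(range(k)):
        score = min(abs(pearson(W_a[:, j], W_b[:, perm[j]])) for j in range(k))
        if score > best_score:
            best_score = score
            best_perm = perm
    return best_perm, float(best_score)


def stability_analysis(X: np.ndarray, config: FactorizationConfig,
                       n_restarts: int = 50, base_seed: int = 0) -> StabilityReport:
    """Multi-restart uniqueness test.

    Runs the factorization from ``n_restarts`` random initializations
    (seeds base_seed .. base_seed + n - 1) and reports, for every pair of
    runs, the minimum permutation-matched absolute source correlation.
    Failed runs are excluded and counted.
    """
    if n_restarts < 2:
        raise ValueError("stability analysis needs at least 2 restarts")
    convex = Method(config.method) is Method.CONVEX
    sources = []
    n_failed = 0
    for i in range(n_restarts):
        init = init_random(X, config.k, base_seed + i, convex=convex)
        try:
            sources.append(factorize(X, config, init).W)
        except (FloatingPointError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    pair_scores = [
        match_sources(sources[i], sources[j])[1]
        for i in range(len(sources))
        for j in range(i + 1, len(sources))
    ]
    return StabilityReport(
        n_restarts=n_restarts,
        n_failed=n_failed,
        matched_correlations=np.asarray(pair_scores),
    )


def perturbation_analysis(X: np.ndarray, result: FactorizationResult,
                          config: FactorizationConfig, seed: int = 0,
                          R: np.ndarray | None = None) -> PerturbationReport:
    """Perturb the mixing matrix and test recovery.

    H is multiplied element-wise by a random matrix with entries uniform
    in (0, 1) (an explicit ``R`` overrides the draw, e.g. all-ones for a
    degenerate control); the factorization is re-run initialized from
    the perturbed factors, and the RMSE between original and
    re-converged factor entries is reported.
    """
    if R is None:
        rng = np.random.default_rng(seed)
        R = rng.uniform(size=result.H.shape)
    H_pert = result.H * R
    if Method(config.method) is Method.CONVEX:
        init = InitResult(W0=X @ result.G, H0=H_pert, G0=result.G.copy())
    else:
        init = InitResult(W0=result.W.copy(), H0=H_pert)
    rerun = factorize(X, config, init)
    return PerturbationReport(
        rmse=rmse(
            np.concatenate([result.W.ravel(), result.H.ravel()]),
            np.concatenate([rerun.W.ravel(), rerun.H.ravel()]),
        ),
        rmse_w=rmse(result.W, rerun.W),
        rmse_h=rmse(result.H, rerun.H),
        seed=seed,
        converged=rerun.converged,
    )
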