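"""Unsupervised voxel labeling from the factorization, and map rendering.

Two labeling rules are provided:

* contribution rule — the contribution of source k to voxel v is the
  scalar product of the voxel spectrum with the rank-one component
  reconstructed from that source, ``C[k, v] = (x_v . w_k) * h_kv``; the
  voxel takes the label of the source with the highest contribution.
* correlation rule (the map-generating default) — each voxel is labeled
  by the source its spectrum correlates with most strongly (Pearson);
  when every correlation falls below the threshold (default 0.5) the
  voxel is left UNDECIDED, i.e. the method abstains.

Maps: a label map colors each voxel by its winning source (black for
UNDECIDED), and a contribution map renders the tumor source's
contribution row min-max scaled to [0, 100], optionally upsampled by
bilinear interpolation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .spectra import ReferenceSpectra, VoxelGrid

logger = logging.getLogger(__name__)

UNDECIDED = -1  # sentinel label for abstained voxels


class CorrelationKind(str, Enum):
    PEARSON = "pearson"
    COSINE = "cosine"  # sensitivity-analysis alternative


@dataclass
class ContributionMatrix:
    """Per-source, per-voxel contribution scores (k x n, arbitrary units)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2:
            raise ValueError("C must be 2-D (sources x voxels)")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("C contains non-finite values")


@dataclass
class SourceLabelMap:
    """Per-voxel winning-source labels (0-based; UNDECIDED = -1) with the
    full voxel-by-source correlation table."""

    grid: VoxelGrid
    labels: np.ndarray        # length n, int
    corr: np.ndarray          # n x k
    threshold: float = 0.5

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.labels.size != self.grid.n:
            raise ValueError("label count does not match grid size")

    @property
    def n_undecided(self) -> int:
        return int(np.sum(self.labels == UNDECIDED))


class AssignmentBasis(str, Enum):
    REFERENCE_CORRELATION = "reference_correlation"
    USER = "user"


@dataclass(frozen=True)
class SourceAssignment:
    """Which extracted source plays the tumor (and non-tumor) role."""

    tumor_source: int
    nontumor_source: int | None = None
    basis: AssignmentBasis = AssignmentBasis.REFERENCE_CORRELATION

    def __post_init__(self) -> None:
        if self.nontumor_source is not None and self.nontumor_source == self.tumor_source:
            raise ValueError("tumor and non-tumor assignments must be distinct sources")


@dataclass
class ContributionMap:
    """Tumor-source contribution raster, min-max scaled to [0, 100]."""

    grid: VoxelGrid
    values: np.ndarray                 # n_rows x n_cols, in [0, 100]
    interpolated: np.ndarray | None = None


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of two vectors; NaN for a zero-variance input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    if denom == 0:
        return float("nan")
    return float(ac @ bc / denom)


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return float("nan")
    return float(a @ b / denom)


def contributions(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> ContributionMatrix:
    """Contribution of each source to each voxel:
    ``C[k, v] = (x_v . w_k) * h_kv``.

    Summed over sources this telescopes to the scalar product of each
    voxel spectrum with its full reconstruction, ``x_v . (W H)_v``.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if X.shape[0] != W.shape[0] or W.shape[1] != H.shape[0] or X.shape[1] != H.shape[1]:
        raise ValueError("inconsistent shapes for X, W, H")
    return ContributionMatrix(C=(W.T @ X) * H)


def label_by_contribution(C: ContributionMatrix | np.ndarray) -> np.ndarray:
    """Winning source per voxel (argmax over contributions); ties break
    toward the lower source index."""
    arr = C.C if isinstance(C, ContributionMatrix) else np.asarray(C, dtype=float)
    labels = np.argmax(arr, axis=0)  # np.argmax takes the first (lowest) index on ties
    ties = np.sum(arr == arr[labels, np.arange(arr.shape[1])], axis=0) > 1
    if np.any(ties):
        logger.info("contribution ties at voxels %s broken toward the lower source index",
                    np.flatnonzero(ties).tolist())
    return labels


def label_by_correlation(X: np.ndarray, W: np.ndarray, grid: VoxelGrid,
                         threshold: float = 0.5,
                         kind: CorrelationKind = CorrelationKind.PEARSON) -> SourceLabelMap:
    """Label each voxel by its most-correlated source; abstain when every
    correlation is below the threshold (a value exactly at the threshold
    counts as decided).  Signed correlations are used: a strongly
    negative correlation never decides a label.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError("W must contain at least one source")
    n = X.shape[1]
    k = W.shape[1]
    measure = pearson if CorrelationKind(kind) is CorrelationKind.PEARSON else _cosine
    corr = np.empty((n, k))
    labels = np.empty(n, dtype=int)
    for v in range(n):
        corr[v] = [measure(X[:, v], W[:, j]) for j in range(k)]
        if np.all(np.isnan(corr[v])):
            warnings.warn(f"constant spectrum at voxel {v}: labeled UNDECIDED", stacklevel=2)
            labels[v] = UNDECIDED
            continue
        row = np.nan_to_num(corr[v], nan=-np.inf)
        if np.max(row) < threshold:
            labels[v] = UNDECIDED
        else:
            labels[v] = int(np.argmax(row))
    return SourceLabelMap(grid=grid, labels=labels, corr=corr, threshold=threshold)


def identify_tumor_source(W: np.ndarray, reference: ReferenceSpectra) -> SourceAssignment:
    """Name the sources by correlating them with the class mean spectra.

    The tumor source is the one most correlated with the tumor mean; the
    non-tumor source is chosen among the remaining sources when a
    non-tumor reference exists.  If one source wins both classes
    outright the assignment is ambiguous and must be made by the user.
    """
    W = np.asarray(W, dtype=float)
    k = W.shape[1]
    r_tumor = np.array([pearson(W[:, j], reference.tumor_mean) for j in range(k)])
    tumor_source = int(np.nanargmax(r_tumor))
    nontumor_source = None
    if reference.nontumor_mean is not None:
        r_non = np.array([pearson(W[:, j], reference.nontumor_mean) for j in range(k)])
        if int(np.nanargmax(r_non)) == tumor_source and k > 1:
            raise ValueError(
                "the same source is most correlated with both class references; "
                "provide an explicit USER assignment"
            )
        rest = [j for j in range(k) if j != tumor_source]
        if rest:
            nontumor_source = int(rest[int(np.nanargmax(r_non[rest]))])
    return SourceAssignment(tumor_source=tumor_source, nontumor_source=nontumor_source)


def _bilinear_upsample(raster: np.ndarray, factor: int) -> np.ndarray:
    """Linear interpolation between voxel centers; output has
    ``(n-1)*factor + 1`` samples per axis so the original centers map to
    output indices that keep their exact values."""
    r, c = raster.shape
    out_r = (r - 1) * factor + 1 if r > 1 else 1
    out_c = (c - 1) * factor + 1 if c > 1 else 1
    rows = np.arange(out_r) / factor
    cols = np.arange(out_c) / factor
    # separable linear interpolation, rows then columns
    tmp = np.empty((out_r, c))
    for j in range(c):
        tmp[:, j] = np.interp(rows, np.arange(r), raster[:, j])
    out = np.empty((out_r, out_c))
    for i in range(out_r):
        out[i, :] = np.interp(cols, np.arange(c), tmp[i, :])
    return out


def contribution_map(C: ContributionMatrix | np.ndarray, assignment: SourceAssignment,
                     grid: VoxelGrid, interpolation_factor: int = 1) -> ContributionMap:
    """Render the tumor source's contribution row as a [0, 100] raster.

    Scaling is per-map min-max over the tumor-source row only.  An
    upsampling factor > 1 adds a bilinearly interpolated raster whose
    voxel-center samples keep their scaled values.
    """
    arr = C.C if isinstance(C, ContributionMatrix) else np.asarray(C, dtype=float)
    if not 0 <= assignment.tumor_source < arr.shape[0]:
        raise ValueError("assignment names a source outside the contribution matrix")
    if interpolation_factor < 1:
        raise ValueError("interpolation factor must be >= 1")
    row = arr[assignment.tumor_source, :]
    lo, hi = row.min(), row.max()
    if hi == lo:
        warnings.warn("constant contribution row: map set to a uniform 50", stacklevel=2)
        scaled = np.full_like(row, 50.0)
    else:
        scaled = 100.0 * (row - lo) / (hi - lo)
    raster = grid.reshape(scaled)
    interp = _bilinear_upsample(raster, interpolation_factor) if interpolation_factor > 1 else None
    return ContributionMap(grid=grid, values=raster, interpolated=interp)
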