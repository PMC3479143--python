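"""Core domain types for MRSI grids and spectral preprocessing.

An MRSI acquisition yields a grid of voxels, each carrying a proton MR
spectrum sampled on a chemical-shift (ppm) axis.  The data matrix ``X``
stacks these spectra column-wise (``p`` spectral points x ``n`` voxels);
intensities are mixed-sign real numbers in arbitrary units (long-echo
spectra contain inverted resonances such as the lactate methyl doublet).

Preprocessing before factorization follows the standard order: restrict
the axis to the window of interest (default 0-4.5 ppm), then scale every
voxel spectrum to unit Euclidean length (UL2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class EchoMode(str, Enum):
    """Echo time regime of the acquisition.

    Long echo (LTE, ~136 ms) inverts lactate/alanine methyl resonances
    through J-coupling; short echo (STE, ~12 ms) retains lipid and
    macromolecule signal.
    """

    LTE = "LTE"
    STE = "STE"


class TissueClass(str, Enum):
    """Gold-standard voxel classes; EXCLUDED voxels never enter metrics."""

    TUMOR = "T"
    NONTUMOR = "N"
    EXCLUDED = "X"


@dataclass(frozen=True)
class SpectralAxis:
    """Chemical-shift axis in ppm; strictly monotonic, stored as given.

    Spectroscopy display convention puts high ppm on the left, so the
    default axis runs 4.5 -> 0 ppm; every operation is keyed by ppm
    value, not index, and accepts either orientation.
    """

    ppm: np.ndarray

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        if ppm.ndim != 1 or ppm.size < 2:
            raise ValueError("ppm axis must be a 1-D array with >= 2 points")
        if not np.all(np.isfinite(ppm)):
            raise ValueError("ppm axis contains non-finite values")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotonic")

    def __len__(self) -> int:
        return int(self.ppm.size)

    @property
    def descending(self) -> bool:
        return bool(self.ppm[0] > self.ppm[-1])

    @classmethod
    def default(cls, lo: float = 0.0, hi: float = 4.5, n: int = 692) -> "SpectralAxis":
        """Default axis: ``n`` points covering [lo, hi] ppm, descending."""
        return cls(np.linspace(hi, lo, n))


@dataclass(frozen=True)
class VoxelGrid:
    """Rectangular voxel grid with a fixed row-major index <-> cell map."""

    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def n(self) -> int:
        return self.n_rows * self.n_cols

    def index_of(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        return row * self.n_cols + col

    def cell_of(self, index: int) -> tuple[int, int]:
        if not 0 <= index < self.n:
            raise IndexError(f"voxel index {index} outside grid of {self.n} voxels")
        return divmod(index, self.n_cols)

    def reshape(self, values: np.ndarray) -> np.ndarray:
        """Fold a length-n per-voxel vector into the (n_rows, n_cols) raster."""
        values = np.asarray(values)
        if values.shape[0] != self.n:
            raise ValueError(f"expected {self.n} per-voxel values, got {values.shape[0]}")
        return values.reshape(self.n_rows, self.n_cols)


@dataclass
class MRSIDataset:
    """One MRSI measurement: axis, grid geometry, and the p x n data matrix."""

    axis: SpectralAxis
    grid: VoxelGrid
    X: np.ndarray
    echo_mode: EchoMode = EchoMode.LTE

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.echo_mode = EchoMode(self.echo_mode)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D matrix (spectral points x voxels)")
        if self.X.shape[0] != len(self.axis):
            raise ValueError(
                f"X has {self.X.shape[0]} rows but the axis has {len(self.axis)} points"
            )
        if self.X.shape[1] != self.grid.n:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but the grid has {self.grid.n} voxels"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains NaN or Inf")

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class TissueMask:
    """Gold-standard per-voxel tissue labels on the dataset grid."""

    grid: VoxelGrid
    labels: np.ndarray  # length n, values from TissueClass

    def __post_init__(self) -> None:
        labels = np.asarray(
            [TissueClass(l) for l in np.asarray(self.labels).ravel()], dtype=object
        )
        if labels.size != self.grid.n:
            raise ValueError(
                f"mask has {labels.size} labels but the grid has {self.grid.n} voxels"
            )
        self.labels = labels

    def where(self, cls: TissueClass) -> np.ndarray:
        cls = TissueClass(cls)
        # element-wise identity: numpy's == broadcasts str-enums unreliably
        return np.flatnonzero([l is cls for l in self.labels])


@dataclass
class ReferenceSpectra:
    """Class mean spectra used to name the extracted sources."""

    tumor_mean: np.ndarray
    nontumor_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tumor_mean = np.asarray(self.tumor_mean, dtype=float)
        if not np.all(np.isfinite(self.tumor_mean)):
            raise ValueError("tumor reference spectrum contains non-finite values")
        if self.nontumor_mean is not None:
            self.nontumor_mean = np.asarray(self.nontumor_mean, dtype=float)
            if self.nontumor_mean.shape != self.tumor_mean.shape:
                raise ValueError("reference spectra have mismatched lengths")
            if not np.all(np.isfinite(self.nontumor_mean)):
                raise ValueError("non-tumor reference spectrum contains non-finite values")


def ul2_normalize(X: np.ndarray) -> np.ndarray:
    """Scale every column of ``X`` to unit Euclidean length (UL2).

    Directions are preserved: each output column is a positive scalar
    multiple of its input.  All-zero columns are rejected because a
    direction-free voxel would poison correlation-based labeling.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("cannot normalize a matrix with non-finite entries")
    norms = np.linalg.norm(X, axis=0)
    zero = np.flatnonzero(norms == 0.0)
    if zero.size:
        raise ValueError(f"all-zero spectrum at voxel index {int(zero[0])}")
    return X / norms


def ppm_window(dataset: MRSIDataset, lo: float, hi: float) -> MRSIDataset:
    """Restrict a dataset to the closed ppm interval [lo, hi].

    The voxel count is unchanged; only spectral rows are dropped.
    """
    if not lo < hi:
        raise ValueError(f"window requires lo < hi, got [{lo}, {hi}]")
    keep = (dataset.axis.ppm >= lo) & (dataset.axis.ppm <= hi)
    if not np.any(keep):
        raise ValueError(f"ppm window [{lo}, {hi}] does not overlap the axis")
    return MRSIDataset(
        axis=SpectralAxis(dataset.axis.ppm[keep]),
        grid=dataset.grid,
        X=dataset.X[keep, :],
        echo_mode=dataset.echo_mode,
    )


def magnitude_transform(X: np.ndarray) -> np.ndarray:
    """Element-wise absolute value; feeds the non-convex NMF variants,
    which require a non-negative data matrix."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("magnitude transform requires finite input")
    return np.abs(X)


def mean_spectrum(dataset: MRSIDataset, mask: TissueMask, cls: TissueClass) -> np.ndarray:
    """Arithmetic mean spectrum over the voxels whose mask label is ``cls``."""
    if mask.grid.n != dataset.grid.n:
        raise ValueError("mask grid does not match dataset grid")
    idx = mask.where(cls)
    if idx.size == 0:
        raise ValueError(f"mask contains no voxel of class {TissueClass(cls).name}")
    return dataset.X[:, idx].mean(axis=1)
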