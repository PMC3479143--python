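"""File formats and the end-to-end pipeline.

On-disk formats are deliberately plain: the dataset is one CSV matrix
(first column the ppm axis, remaining columns the voxels in row-major
grid order) with a JSON sidecar carrying the grid geometry and echo
mode; masks are a CSV grid of {T, N, X} codes; reference spectra are
two-column (ppm, intensity) CSVs.  CSV is the canonical numeric output;
PNG heatmaps are presentation-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import classification_metrics
from .initializers import InitStrategy, initialize
from .labeling import (
    UNDECIDED,
    AssignmentBasis,
    SourceAssignment,
    SourceLabelMap,
    contribution_map,
    contributions,
    identify_tumor_source,
    label_by_correlation,
)
from .nmf import FactorizationConfig, Method, factorize
from .spectra import (
    EchoMode,
    MRSIDataset,
    ReferenceSpectra,
    SpectralAxis,
    TissueClass,
    TissueMask,
    VoxelGrid,
    magnitude_transform,
    mean_spectrum,
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_dataset(dataset: MRSIDataset, path: str | Path) -> None:
    """Write the dataset CSV (header ``ppm,v000,v001,...``) and its JSON
    sidecar ``{n_rows, n_cols, echo_mode}``."""
    path = Path(path)
    cols = {"ppm": dataset.axis.ppm}
    for v in range(dataset.n):
        cols[f"v{v:03d}"] = dataset.X[:, v]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    _sidecar_path(path).write_text(json.dumps({
        "n_rows": dataset.grid.n_rows,
        "n_cols": dataset.grid.n_cols,
        "echo_mode": dataset.echo_mode.value,
    }, indent=2))


def read_dataset(path: str | Path) -> MRSIDataset:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar} for dataset {path}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    if df.columns[0] != "ppm":
        raise ValueError(f"first column of {path} must be 'ppm', got '{df.columns[0]}'")
    grid = VoxelGrid(int(meta["n_rows"]), int(meta["n_cols"]))
    X = df.iloc[:, 1:].to_numpy(dtype=float)
    if X.shape[1] != grid.n:
        raise ValueError(
            f"sidecar declares a {grid.n_rows}x{grid.n_cols} grid ({grid.n} voxels) "
            f"but {path} has {X.shape[1]} voxel columns"
        )
    return MRSIDataset(
        axis=SpectralAxis(df["ppm"].to_numpy(dtype=float)),
        grid=grid,
        X=X,
        echo_mode=EchoMode(meta["echo_mode"]),
    )


def write_mask(mask: TissueMask, path: str | Path) -> None:
    raster = mask.grid.reshape(np.array([l.value for l in mask.labels], dtype=object))
    pd.DataFrame(raster).to_csv(path, index=False, header=False)


def read_mask(path: str | Path, grid: VoxelGrid | None = None) -> TissueMask:
    raster = pd.read_csv(path, header=None, dtype=str).to_numpy()
    n_rows, n_cols = raster.shape
    if grid is not None and (grid.n_rows, grid.n_cols) != (n_rows, n_cols):
        raise ValueError(
            f"mask is {n_rows}x{n_cols} but the dataset grid is "
            f"{grid.n_rows}x{grid.n_cols}"
        )
    return TissueMask(
        grid=grid or VoxelGrid(n_rows, n_cols),
        labels=np.array([s.strip() for s in raster.ravel()], dtype=object),
    )


def write_reference(ppm: np.ndarray, intensity: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"ppm": ppm, "intensity": intensity}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_reference(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["intensity"].to_numpy(dtype=float)


def write_matrix(M: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(M)).to_csv(path, index=False, header=False,
                                       float_format="%.17g")


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)


def write_labels(label_map: SourceLabelMap, path: str | Path) -> None:
    """Label grid CSV with 1-based source codes and 'U' for undecided."""
    codes = np.array(
        ["U" if l == UNDECIDED else str(int(l) + 1) for l in label_map.labels],
        dtype=object,
    )
    pd.DataFrame(label_map.grid.reshape(codes)).to_csv(path, index=False, header=False)


# ------------------------------------------------------------- heatmaps


def save_label_png(label_map: SourceLabelMap, assignment: SourceAssignment,
                   path: str | Path) -> None:
    """Label-map heatmap: red = tumor source, blue = non-tumor source,
    magenta = any other source, black = undecided."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rgb = np.zeros((label_map.grid.n_rows, label_map.grid.n_cols, 3))
    raster = label_map.grid.reshape(label_map.labels)
    mag = label_map.grid.reshape(np.nan_to_num(np.abs(label_map.corr), nan=0.0).max(axis=1))
    for i in range(raster.shape[0]):
        for j in range(raster.shape[1]):
            l = raster[i, j]
            m = float(np.clip(mag[i, j], 0.0, 1.0))
            if l == UNDECIDED:
                rgb[i, j] = (0, 0, 0)
            elif l == assignment.tumor_source:
                rgb[i, j] = (m, 0, 0)
            elif assignment.nontumor_source is not None and l == assignment.nontumor_source:
                rgb[i, j] = (0, 0, m)
            else:
                rgb[i, j] = (m, 0, m)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgb, interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def save_contribution_png(values: np.ndarray, path: str | Path) -> None:
    """Contribution heatmap on a red (high) to blue (low) diverging scale."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values, cmap="RdBu_r", vmin=0, vmax=100, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="contribution (0-100)")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


# ------------------------------------------------------------- pipeline


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; the manifest reproduces it."""

    dataset_path: str
    out_dir: str
    mask_path: str | None = None
    reference_tumor_path: str | None = None
    reference_nontumor_path: str | None = None
    factorization: FactorizationConfig = field(default_factory=FactorizationConfig)
    init: InitStrategy = field(default_factory=InitStrategy)
    label_threshold: float = 0.5
    interpolation_factor: int = 4
    seed: int = 0
    write_png: bool = True

    def to_dict(self) -> dict:
        return {
            "dataset_path": str(self.dataset_path),
            "out_dir": str(self.out_dir),
            "mask_path": self.mask_path and str(self.mask_path),
            "reference_tumor_path": self.reference_tumor_path and str(self.reference_tumor_path),
            "reference_nontumor_path": (
                self.reference_nontumor_path and str(self.reference_nontumor_path)
            ),
            "factorization": {
                "method": self.factorization.method.value,
                "k": self.factorization.k,
                "max_iter": self.factorization.max_iter,
                "tol": self.factorization.tol,
                "lambda_w": self.factorization.lambda_w,
                "lambda_h": self.factorization.lambda_h,
            },
            "init": {
                "kind": self.init.kind.value,
                "seed": self.init.seed,
                "fcm_m": self.init.fcm_m,
                "nmf_warm_iters": self.init.nmf_warm_iters,
            },
            "label_threshold": self.label_threshold,
            "interpolation_factor": self.interpolation_factor,
            "seed": self.seed,
            "version": __version__,
        }


def _resolve_reference(config: RunConfig, dataset: MRSIDataset,
                       mask: TissueMask | None) -> ReferenceSpectra | None:
    if config.reference_tumor_path:
        return ReferenceSpectra(
            tumor_mean=read_reference(config.reference_tumor_path),
            nontumor_mean=(
                read_reference(config.reference_nontumor_path)
                if config.reference_nontumor_path else None
            ),
        )
    if mask is not None:
        tumor = mean_spectrum(dataset, mask, TissueClass.TUMOR)
        try:
            nontumor = mean_spectrum(dataset, mask, TissueClass.NONTUMOR)
        except ValueError:
            nontumor = None  # e.g. a grid without usable non-tumor area
        return ReferenceSpectra(tumor_mean=tumor, nontumor_mean=nontumor)
    return None


def run_pipeline(config: RunConfig) -> dict:
    """Factorize -> identify tumor source -> label -> maps -> evaluate.

    Writes all artifacts under ``config.out_dir`` and returns the
    manifest dict.  Identical config and seed give identical artifacts.
    On failure, partial outputs are left in place and the manifest
    carries a FAILED marker with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "status": "RUNNING"}
    stage = "read"
    try:
        dataset = read_dataset(config.dataset_path)
        mask = read_mask(config.mask_path, dataset.grid) if config.mask_path else None

        stage = "factorize"
        convex = Method(config.factorization.method) is Method.CONVEX
        X = dataset.X if convex else magnitude_transform(dataset.X)
        init = initialize(X, config.factorization.k, config.init, convex=convex)
        result = factorize(X, config.factorization, init)
        write_matrix(result.W, out / "W.csv")
        write_matrix(result.H, out / "H.csv")
        if result.G is not None:
            write_matrix(result.G, out / "G.csv")
        write_matrix(result.error_trajectory[:, None], out / "trajectory.csv")
        manifest["factorization"] = {
            "iterations": result.iterations,
            "converged": result.converged,
            "final_error": result.final_error,
        }

        stage = "assign"
        reference = _resolve_reference(config, dataset, mask)
        if reference is not None:
            assignment = identify_tumor_source(result.W, reference)
        else:
            assignment = SourceAssignment(
                tumor_source=0,
                nontumor_source=1 if config.factorization.k > 1 else None,
                basis=AssignmentBasis.USER,
            )
            manifest["note"] = "no mask or reference given: tumor source defaulted to 0"
        manifest["assignment"] = {
            "tumor_source": assignment.tumor_source,
            "nontumor_source": assignment.nontumor_source,
            "basis": assignment.basis.value,
        }

        stage = "label"
        label_map = label_by_correlation(
            dataset.X, result.W, dataset.grid, threshold=config.label_threshold
        )
        write_labels(label_map, out / "labels.csv")
        write_matrix(label_map.corr, out / "correlations.csv")
        manifest["n_undecided"] = label_map.n_undecided

        stage = "map"
        C = contributions(dataset.X, result.W, result.H)
        cmap = contribution_map(C, assignment, dataset.grid, config.interpolation_factor)
        write_matrix(cmap.values, out / "contribution_map.csv")
        if cmap.interpolated is not None:
            write_matrix(cmap.interpolated, out / "contribution_map_interp.csv")
        if config.write_png:
            save_label_png(label_map, assignment, out / "label_map.png")
            save_contribution_png(cmap.values, out / "contribution_map.png")
            if cmap.interpolated is not None:
                save_contribution_png(cmap.interpolated, out / "contribution_map_interp.png")

        stage = "evaluate"
        if mask is not None:
            metrics = classification_metrics(label_map, mask, assignment)
            manifest["metrics"] = {
                "accuracy_tumor": metrics.accuracy_tumor,
                "accuracy_nontumor": metrics.accuracy_nontumor,
                "sensitivity": metrics.sensitivity,
                "specificity": metrics.specificity,
                "counts": {
                    "tp": metrics.counts.tp, "fn": metrics.counts.fn,
                    "tn": metrics.counts.tn, "fp": metrics.counts.fp,
                },
            }
            (out / "metrics.json").write_text(json.dumps(manifest["metrics"], indent=2))
        else:
            manifest["metrics"] = None
            manifest.setdefault("notes", []).append("no mask: evaluation skipped")

        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
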