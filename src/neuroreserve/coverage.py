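"""Visual-field coverage maps from fitted pRFs ("neural perimetry").

Each retained voxel contributes its unit-peak Gaussian profile; the
coverage value at a visual-field point is the maximum profile value over
voxels.  The raster map is then downsampled to the Humphrey 30-2 grid by
taking, for each test location, the maximum coverage inside the 6x6
degree cell centred on it; location values are renormalised by their
global maximum and binarised at a detection threshold (default 0.5,
with 0.25/0.75 used for robustness checks).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .humphrey import PerimetricGrid, make_302_grid
from .prf import PRFEstimate
from .stimulus import VisualFieldRaster

DEFAULT_COVERAGE_THRESHOLD = 0.5


@dataclass
class CoverageMap:
    """Raster of per-pixel coverage values in [0, 1]."""

    raster: VisualFieldRaster
    values: np.ndarray          # (H, W)
    n_voxels: int
    ve_min: float | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.raster.shape:
            raise ValueError("coverage values must match the raster shape")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("coverage values must lie in [0, 1]")


@dataclass
class NeuralPerimetryMap:
    """Coverage resampled to the 30-2 grid, optionally binarised."""

    grid: PerimetricGrid
    values: np.ndarray                 # in [0, 1], max-normalised
    threshold: float | None = None
    covered: np.ndarray | None = None  # bool, values > threshold
    provenance: dict = field(default_factory=dict)


def coverage_from_estimates(estimates: list[PRFEstimate],
                            raster: VisualFieldRaster | None = None,
                            ve_min: float | None = None,
                            chunk: int = 64) -> CoverageMap:
    """Pixelwise max over unit-amplitude Gaussian pRF profiles.

    Profiles are evaluated at unit peak (no beta weighting), so a single
    responsive voxel saturates coverage at its centre.  An empty voxel
    set yields an all-zero map with a warning.
    """
    raster = raster or VisualFieldRaster()
    if not estimates:
        warnings.warn("no pRF estimates: coverage map is all zero", stacklevel=2)
        return CoverageMap(raster, np.zeros(raster.shape), 0, ve_min)
    xx, yy = raster.grids()
    xf, yf = xx.ravel(), yy.ravel()
    x0 = np.array([e.x0 for e in estimates])
    y0 = np.array([e.y0 for e in estimates])
    sg = np.array([e.sigma for e in estimates])
    best = np.zeros(xf.shape)
    for lo in range(0, len(estimates), chunk):
        hi = min(lo + chunk, len(estimates))
        d2 = ((xf[None, :] - x0[lo:hi, None]) ** 2
              + (yf[None, :] - y0[lo:hi, None]) ** 2)
        g = np.exp(-d2 / (2.0 * sg[lo:hi, None] ** 2))
        np.maximum(best, g.max(axis=0), out=best)
    return CoverageMap(raster, best.reshape(raster.shape),
                       len(estimates), ve_min)


def downsample_to_grid(coverage: CoverageMap,
                       grid: PerimetricGrid | None = None,
                       cell_deg: float = 6.0,
                       agg: str = "max") -> NeuralPerimetryMap:
    """Aggregate raster coverage into 6x6 degree Humphrey cells.

    Cells are half-open, [x - 3, x + 3) by [y - 3, y + 3), so adjacent
    cells partition the plane; per-cell aggregation is the maximum by
    default (mean available for sensitivity analysis).  All location
    values are then divided by their global maximum when positive.
    """
    grid = grid or make_302_grid()
    if agg not in ("max", "mean"):
        raise ValueError("agg must be 'max' or 'mean'")
    half = cell_deg / 2.0
    raster = coverage.raster
    if raster.half_extent < np.abs(np.concatenate([grid.x, grid.y])).max() + half:
        raise ValueError("raster does not cover every grid cell")
    xx, yy = raster.grids()
    xf, yf, vf = xx.ravel(), yy.ravel(), coverage.values.ravel()
    vals = np.empty(grid.n_locations)
    for i, (gx, gy) in enumerate(zip(grid.x, grid.y)):
        cell = ((xf >= gx - half) & (xf < gx + half)
                & (yf >= gy - half) & (yf < gy + half))
        if not cell.any():
            raise ValueError(f"grid cell at ({gx}, {gy}) contains no raster pixel")
        vals[i] = vf[cell].max() if agg == "max" else vf[cell].mean()
    m = vals.max()
    if m > 0:
        vals = vals / m
    return NeuralPerimetryMap(grid=grid, values=vals,
                              provenance={"n_voxels": coverage.n_voxels,
                                          "ve_min": coverage.ve_min,
                                          "agg": agg})


def binarize(npm: NeuralPerimetryMap,
             threshold: float = DEFAULT_COVERAGE_THRESHOLD) -> NeuralPerimetryMap:
    """Binarise location values with a strictly-greater comparison."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return replace(npm, threshold=threshold, covered=npm.values > threshold)


# --------------------------------------------------------------------------
# I/O


def write_neural_csv(npm: NeuralPerimetryMap, path: str | Path) -> None:
    path = Path(path)
    covered = (npm.covered.astype(int) if npm.covered is not None
               else np.full(npm.grid.n_locations, -1))
    pd.DataFrame({"x_deg": npm.grid.x, "y_deg": npm.grid.y,
                  "value": npm.values, "covered": covered}).to_csv(path, index=False)
    sidecar = {"eye": npm.grid.eye, "threshold": npm.threshold,
               **npm.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_neural_csv(path: str | Path) -> NeuralPerimetryMap:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = make_302_grid(meta.get("eye", "right"))
    covered = frame["covered"].to_numpy()
    npm = NeuralPerimetryMap(
        grid=grid, values=frame["value"].to_numpy(float),
        threshold=meta.get("threshold"),
        covered=None if (covered < 0).any() else covered.astype(bool),
        provenance={k: v for k, v in meta.items()
                    if k not in ("eye", "threshold")})
    return npm
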