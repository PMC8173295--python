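"""Wide-field retinotopic mapping stimulus apertures.

The pRF forward model only needs the *spatial envelope* of the mapping
stimulus: one binary mask per acquired volume marking which part of the
visual field carried contrast during that volume.  Two classic stimuli
are modelled, a rotating wedge (polar-angle mapping) and an expanding
ring (eccentricity mapping), both sweeping the field once per 64-second
cycle out to a maximum eccentricity of 45 degrees.  The checkerboard
texture and its 2 Hz contrast reversal are deliberately not rendered:
they are far faster than the volume acquisition and do not enter the
Gaussian-overlap forward model.

Ring width and (in the real stimulus) check size grow with eccentricity
following inverse-linear cortical magnification, ``width(e) ∝ e + e2``;
see :class:`MagnificationRule`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Sweep period of both mapping stimuli, seconds per cycle.
CYCLE_SECONDS = 64.0


class ApertureTimingError(ValueError):
    """Stimulus timing incompatible with the volume acquisition rate."""


@dataclass(frozen=True)
class VisualFieldRaster:
    """Square pixel raster over the visual field, centred on fixation.

    Pixel centres sit at integer multiples of ``step`` from the origin
    (so the raster always contains a pixel exactly at fixation), x
    positive rightward and y positive upward.  Rows are ordered with y
    descending (image convention).
    """

    half_extent: float = 45.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("raster step must be positive")
        if self.half_extent < self.step:
            raise ValueError("raster has zero size: half_extent < step")

    @property
    def axis(self) -> np.ndarray:
        n = int(round(self.half_extent / self.step))
        return np.arange(-n, n + 1) * self.step

    @property
    def shape(self) -> tuple[int, int]:
        n = len(self.axis)
        return (n, n)

    def grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcast (x, y) pixel-centre coordinate images."""
        ax = self.axis
        xx = np.broadcast_to(ax[None, :], (len(ax), len(ax)))
        yy = np.broadcast_to(ax[::-1, None], (len(ax), len(ax)))
        return xx, yy

    def eccentricity(self) -> np.ndarray:
        xx, yy = self.grids()
        return np.hypot(xx, yy)

    def polar_angle(self) -> np.ndarray:
        """Counterclockwise angle in degrees in [0, 360), 0 = rightward."""
        xx, yy = self.grids()
        return np.degrees(np.arctan2(yy, xx)) % 360.0


@dataclass(frozen=True)
class MagnificationRule:
    """Inverse-linear cortical magnification scaling.

    Ring width (and check size) are proportional to ``e + e2`` where
    ``e`` is eccentricity; ``e2`` is the eccentricity at which the
    scaling has doubled relative to the fovea.  ``e2 = inf`` degenerates
    to eccentricity-independent (constant) width.
    """

    e2: float = 0.75

    def __post_init__(self) -> None:
        if not (self.e2 > 0):
            raise ValueError("e2 must be positive (may be inf)")

    def ring_edges(self, half_extent: float, n_frames: int) -> np.ndarray:
        """Annulus edge radii for one cycle, frame k spans (edges[k], edges[k+1]].

        Edges are uniform in u = log(e + e2), so each annulus width is
        proportional to (e + e2): the magnification rule itself fixes the
        per-frame widths, the innermost frame is a central disc, the
        union of the annuli tiles the full disc exactly, and the sweep
        reaches ``half_extent`` at the end of the cycle.
        """
        k = np.arange(n_frames + 1) / n_frames
        if math.isinf(self.e2):
            return k * half_extent
        return self.e2 * np.expm1(k * math.log1p(half_extent / self.e2))


@dataclass
class StimulusAperture:
    """Binary visual-field occupancy movie of a mapping stimulus."""

    kind: str                      # "wedge", "ring" or "combined"
    frames: np.ndarray             # (n_frames, H, W) bool
    raster: VisualFieldRaster
    frame_period: float            # seconds per frame (= TR)
    n_cycles: int
    cycle_seconds: float = CYCLE_SECONDS
    wedge_width_deg: float | None = None
    start_angle: float | None = None
    e2: float | None = None
    direction: str = "ccw"
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.cycle_seconds / self.frame_period))

    def flat(self) -> np.ndarray:
        """Frames as a float (n_frames, n_pixels) matrix."""
        return self.frames.reshape(self.n_frames, -1).astype(float)

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Save as .npy with a JSON sidecar describing the geometry."""
        path = Path(path)
        np.save(path, self.frames.astype(np.uint8))
        sidecar = {
            "kind": self.kind,
            "half_extent": self.raster.half_extent,
            "step": self.raster.step,
            "frame_period": self.frame_period,
            "n_cycles": self.n_cycles,
            "cycle_seconds": self.cycle_seconds,
            "wedge_width_deg": self.wedge_width_deg,
            "start_angle": self.start_angle,
            "e2": self.e2,
            "direction": self.direction,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StimulusAperture":
        path = Path(path)
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        frames = np.load(path).astype(bool)
        meta = json.loads(path.with_suffix(".json").read_text())
        raster = VisualFieldRaster(meta.pop("half_extent"), meta.pop("step"))
        return cls(kind=meta.pop("kind"), frames=frames, raster=raster,
                   frame_period=meta.pop("frame_period"),
                   n_cycles=meta.pop("n_cycles"),
                   cycle_seconds=meta.pop("cycle_seconds"),
                   wedge_width_deg=meta.pop("wedge_width_deg"),
                   start_angle=meta.pop("start_angle"),
                   e2=meta.pop("e2"), direction=meta.pop("direction"))

    def to_nifti(self, path: str | Path) -> None:
        """Export frames as a NIfTI volume (x, y, 1, t) for visual inspection."""
        import nibabel as nib

        data = np.transpose(self.frames.astype(np.uint8), (2, 1, 0))[:, :, None, :]
        affine = np.diag([self.raster.step, self.raster.step, 1.0, 1.0])
        nib.Nifti1Image(data, affine).to_filename(str(path))


def _check_timing(frame_period: float, cycle_seconds: float) -> int:
    if frame_period <= 0:
        raise ApertureTimingError("frame_period must be positive")
    q = cycle_seconds / frame_period
    if abs(q - round(q)) > 1e-9 or round(q) < 1:
        raise ApertureTimingError(
            f"cycle of {cycle_seconds}s is not an integer number of "
            f"{frame_period}s frames")
    return int(round(q))


def make_wedge_aperture(raster: VisualFieldRaster,
                        frame_period: float = 2.0,
                        n_cycles: int = 1,
                        width_deg: float = 45.0,
                        start_angle: float = 0.0) -> StimulusAperture:
    """Rotating-wedge aperture, one counterclockwise revolution per cycle.

    Frame ``k`` activates pixels whose polar angle lies within the wedge
    sector ``(lead - width, lead]`` where the leading edge
    ``lead = start_angle + k * 360 * frame_period / 64`` advances
    counterclockwise, and whose eccentricity is positive and at most
    ``half_extent``.  The default start angle puts the leading edge on
    the positive horizontal meridian.
    """
    if not (0.0 < width_deg < 360.0):
        raise ValueError("wedge width must be in (0, 360) degrees")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    fpc = _check_timing(frame_period, CYCLE_SECONDS)
    rot_step = 360.0 / fpc
    ecc = raster.eccentricity()
    theta = raster.polar_angle()
    in_field = (ecc > 0) & (ecc <= raster.half_extent)
    cycle = np.empty((fpc,) + raster.shape, dtype=bool)
    for k in range(fpc):
        lead = start_angle + k * rot_step
        offset = (lead - theta) % 360.0
        cycle[k] = in_field & (offset < width_deg)
    frames = np.tile(cycle, (n_cycles, 1, 1))
    if not frames.any(axis=(1, 2)).all():
        raise ValueError("raster too coarse: a wedge frame has no active pixel")
    return StimulusAperture(kind="wedge", frames=frames, raster=raster,
                            frame_period=frame_period, n_cycles=n_cycles,
                            wedge_width_deg=width_deg, start_angle=start_angle)


def make_ring_aperture(raster: VisualFieldRaster,
                       frame_period: float = 2.0,
                       n_cycles: int = 1,
                       mag: MagnificationRule | None = None) -> StimulusAperture:
    """Expanding-ring aperture, one centre-to-periphery sweep per cycle.

    Frame ``k`` activates the annulus between consecutive ring edges
    (frame 0 is a central disc including fixation); edge radii follow
    the magnification rule so ring width grows with eccentricity.  A
    pixel is active when its footprint intersects the annulus, i.e. the
    annulus is dilated radially by half a pixel — foveal rings are
    thinner than a raster pixel and would otherwise vanish.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    mag = mag or MagnificationRule()
    fpc = _check_timing(frame_period, CYCLE_SECONDS)
    edges = mag.ring_edges(raster.half_extent, fpc)
    ecc = raster.eccentricity()
    half_px = raster.step / 2.0
    cycle = np.empty((fpc,) + raster.shape, dtype=bool)
    for k in range(fpc):
        lo, hi = edges[k] - half_px, edges[k + 1] + half_px
        inner = ecc >= 0 if k == 0 else ecc > lo
        cycle[k] = inner & (ecc <= hi)
    frames = np.tile(cycle, (n_cycles, 1, 1))
    if not frames.any(axis=(1, 2)).all():
        raise ValueError("raster too coarse: a ring frame has no active pixel")
    return StimulusAperture(kind="ring", frames=frames, raster=raster,
                            frame_period=frame_period, n_cycles=n_cycles,
                            e2=mag.e2)


def concatenate_apertures(*apertures: StimulusAperture) -> StimulusAperture:
    """Concatenate runs in time (e.g. wedge followed by ring) for joint fitting."""
    if not apertures:
        raise ValueError("need at least one aperture")
    first = apertures[0]
    for ap in apertures[1:]:
        if ap.raster != first.raster:
            raise ValueError("apertures must share a raster")
        if ap.frame_period != first.frame_period:
            raise ApertureTimingError("apertures must share a frame period")
    frames = np.concatenate([ap.frames for ap in apertures], axis=0)
    return replace(first, kind="combined", frames=frames,
                   metadata={"parts": [ap.kind for ap in apertures]})
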