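"""Humphrey SITA 30-2 perimetry: grid geometry, QC and change summaries.

The 30-2 program probes 76 visual-field locations (38 per hemifield) on
a 6-degree lattice offset 3 degrees from the meridians, reporting
sensitivity in dB (0 = brightest stimulus unseen, up to a subject
maximum of roughly 35 dB).  Reliability is gated on blind-spot probing:
sessions with more than 20% false detections during blind-spot stimuli
are excluded, following the perimeter's default clinical criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Half-coordinates of the 30-2 lattice (degrees).
_LATTICE = (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27)

#: Sanity cap on stored sensitivities (device max is ~35-40 dB).
DB_CAP = 50.0


class GridMismatchError(ValueError):
    """Operands are defined on different perimetric grids."""


@dataclass(frozen=True)
class PerimetricGrid:
    """Ordered 30-2 test locations with hemifield and blind-spot flags.

    Locations are stored in raster order (y descending, x ascending).
    The single blind-spot candidate sits at (15, -3) in the temporal
    field of the tested eye (mirrored in x for the left eye).
    """

    eye: str
    x: np.ndarray
    y: np.ndarray
    hemifield: np.ndarray   # "left" / "right" by sign of x
    blind_spot: np.ndarray  # bool

    @property
    def n_locations(self) -> int:
        return len(self.x)

    def eccentricity(self) -> np.ndarray:
        return np.hypot(self.x, self.y)

    def same_layout(self, other: "PerimetricGrid") -> bool:
        return (self.eye == other.eye
                and np.array_equal(self.x, other.x)
                and np.array_equal(self.y, other.y))


def _keep_302(x: float, y: float) -> bool:
    # Corner trimming that reduces the 10x10 lattice to the 76 tested points.
    return not (np.hypot(x, y) > 30.0 or (abs(x) >= 21 and abs(y) >= 21))


def make_302_grid(eye: str = "right") -> PerimetricGrid:
    """Construct the SITA 30-2 grid for the tested eye."""
    if eye not in ("left", "right"):
        raise ValueError("eye must be 'left' or 'right'")
    pts = [(x, y) for y in sorted(_LATTICE, reverse=True)
           for x in sorted(_LATTICE) if _keep_302(x, y)]
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    hemifield = np.where(x < 0, "left", "right")
    bs_x = 15.0 if eye == "right" else -15.0
    blind_spot = (x == bs_x) & (y == -3.0)
    return PerimetricGrid(eye=eye, x=x, y=y, hemifield=hemifield,
                          blind_spot=blind_spot)


@dataclass
class ReliabilityIndices:
    """Perimeter catch-trial fractions; any index may be missing (None)."""

    fixation_loss: float | None = None
    false_positive: float | None = None
    false_negative: float | None = None
    blind_spot_false_detection: float | None = None

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a fraction in [0, 1]")

    def as_dict(self) -> dict:
        return {"fixation_loss": self.fixation_loss,
                "false_positive": self.false_positive,
                "false_negative": self.false_negative,
                "blind_spot_false_detection": self.blind_spot_false_detection}


@dataclass
class PerimetryMap:
    """One Humphrey session: dB sensitivity per 30-2 location."""

    grid: PerimetricGrid
    sensitivity: np.ndarray
    session: str = "pre"
    reliability: ReliabilityIndices | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        sens = np.asarray(self.sensitivity, dtype=float)
        if sens.shape != (self.grid.n_locations,):
            raise ValueError("sensitivity length must match the grid")
        if np.any(sens < 0):
            # Devices print "<0 dB" for unseen max-intensity stimuli.
            import warnings
            warnings.warn("negative dB coerced to 0", stacklevel=2)
            sens = np.maximum(sens, 0.0)
        if np.any(sens > DB_CAP):
            raise ValueError(f"sensitivity above {DB_CAP} dB sanity cap")
        self.sensitivity = sens


@dataclass
class QCResult:
    """Reliability verdict: 'pass', 'fail' or 'indeterminate'."""

    status: str
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.status == "pass"


def qc_reliability(pmap: PerimetryMap,
                   max_blindspot_fp: float = 0.20) -> QCResult:
    """Gate a session on blind-spot false detection (> threshold fails).

    Other indices are reported in the reasons when elevated but do not
    gate inclusion; missing blind-spot data yields 'indeterminate'.
    """
    rel = pmap.reliability
    if rel is None or rel.blind_spot_false_detection is None:
        return QCResult("indeterminate", ["blind-spot false detection missing"])
    reasons = []
    for name in ("fixation_loss", "false_positive", "false_negative"):
        v = getattr(rel, name)
        if v is not None and v > 0.33:
            reasons.append(f"elevated {name} ({v:.0%}), not gating")
    if rel.blind_spot_false_detection > max_blindspot_fp:
        reasons.insert(0, (f"blind-spot false detection "
                           f"{rel.blind_spot_false_detection:.0%} > "
                           f"{max_blindspot_fp:.0%}"))
        return QCResult("fail", reasons)
    return QCResult("pass", reasons)


@dataclass
class ChangeMap:
    """Per-location dB change (post minus pre) with exclusion flags."""

    grid: PerimetricGrid
    change: np.ndarray
    excluded: np.ndarray  # bool; blind spot locations

    def included_changes(self) -> np.ndarray:
        return self.change[~self.excluded]


@dataclass
class ChangeSummary:
    """Training-effect summary: mean gain and count of improved locations."""

    mean_change: float
    n_improved: int
    improvement_threshold: float
    changes: np.ndarray


def change_map(pre: PerimetryMap, post: PerimetryMap) -> ChangeMap:
    """Post-minus-pre sensitivity change; the blind spot is excluded."""
    if not pre.grid.same_layout(post.grid):
        raise GridMismatchError("pre and post maps use different grids")
    change = post.sensitivity - pre.sensitivity
    return ChangeMap(grid=pre.grid, change=change,
                     excluded=pre.grid.blind_spot.copy())


def summarize_change(change, improvement_threshold: float = 1.0) -> ChangeSummary:
    """Mean dB change and count of locations improved by at least the threshold."""
    if isinstance(change, ChangeMap):
        vec = change.included_changes()
    else:
        vec = np.asarray(change, dtype=float)
    if vec.size == 0:
        raise ValueError("no included locations to summarise")
    return ChangeSummary(mean_change=float(vec.mean()),
                         n_improved=int((vec >= improvement_threshold).sum()),
                         improvement_threshold=improvement_threshold,
                         changes=vec)


# --------------------------------------------------------------------------
# I/O: CSV (x_deg, y_deg, db in raster order) + JSON sidecar


def write_perimetry_csv(pmap: PerimetryMap, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"x_deg": pmap.grid.x, "y_deg": pmap.grid.y,
                  "db": pmap.sensitivity}).to_csv(path, index=False)
    sidecar = {"eye": pmap.grid.eye, "session": pmap.session,
               "subject": pmap.subject,
               "reliability": (pmap.reliability.as_dict()
                               if pmap.reliability else None)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_perimetry_csv(path: str | Path) -> PerimetryMap:
    path = Path(path)
    frame = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = make_302_grid(meta["eye"])
    if (not np.array_equal(frame["x_deg"].to_numpy(float), grid.x)
            or not np.array_equal(frame["y_deg"].to_numpy(float), grid.y)):
        raise GridMismatchError(f"{path}: locations are not the 30-2 grid "
                                "in raster order")
    rel = ReliabilityIndices(**meta["reliability"]) if meta.get("reliability") else None
    return PerimetryMap(grid=grid, sensitivity=frame["db"].to_numpy(float),
                        session=meta.get("session", "pre"), reliability=rel,
                        subject=meta.get("subject"))
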