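"""Four-category Humphrey/retinotopy agreement classification.

Every 30-2 location is labelled by whether behavioral perimetry detects
vision there (Hum+, strictly > 0 dB) and whether the binarised neural
perimetry map shows cortical coverage (Ret+).  The Hum-/Ret+ category is
the "neural reserve": locations behaviorally blind but still driving
visual cortex.  The blind spot is excluded before classification, and
the rare Hum+/Ret- category can be dropped from downstream statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .coverage import NeuralPerimetryMap
from .humphrey import GridMismatchError, PerimetricGrid, PerimetryMap, make_302_grid

SEEN = "HumP_RetP"      # behavioral and neural coverage agree (seeing)
RARE = "HumP_RetM"      # behavioral only; infrequent, dropped from stats
RESERVE = "HumM_RetP"   # neural reserve: blind behaviorally, covered neurally
BLIND = "HumM_RetM"     # agree on absence
EXCLUDED = "excluded"

CATEGORIES = (SEEN, RARE, RESERVE, BLIND)


@dataclass
class MismatchClassification:
    """Per-location category labels with exclusion bookkeeping."""

    grid: PerimetricGrid
    category: np.ndarray           # str per location, CATEGORIES or EXCLUDED
    excluded_reason: np.ndarray    # str or "" per location
    original_category: np.ndarray  # label before any rare-category drop

    @property
    def included(self) -> np.ndarray:
        return self.category != EXCLUDED

    def counts(self) -> dict:
        return {c: int((self.category == c).sum()) for c in CATEGORIES}

    def fractions(self) -> dict:
        n = int(self.included.sum())
        if n == 0:
            return {c: float("nan") for c in CATEGORIES}
        return {c: cnt / n for c, cnt in self.counts().items()}


def classify_locations(humphrey_pre: PerimetryMap,
                       neural: NeuralPerimetryMap) -> MismatchClassification:
    """Assign each location to one of the four agreement categories.

    Hum+ means pre-training sensitivity strictly above 0 dB; Ret+ means
    the binarised neural map marks the location covered.  Blind-spot
    locations are excluded before classification.
    """
    if neural.covered is None:
        raise ValueError("neural map must be binarised first (see binarize)")
    if not humphrey_pre.grid.same_layout(neural.grid):
        raise GridMismatchError("Humphrey and neural maps use different grids")
    grid = humphrey_pre.grid
    hum = humphrey_pre.sensitivity > 0.0
    ret = neural.covered
    category = np.where(hum, np.where(ret, SEEN, RARE),
                        np.where(ret, RESERVE, BLIND)).astype(object)
    reason = np.full(grid.n_locations, "", dtype=object)
    category[grid.blind_spot] = EXCLUDED
    reason[grid.blind_spot] = "blind_spot"
    return MismatchClassification(grid=grid, category=category,
                                  excluded_reason=reason,
                                  original_category=category.copy())


def drop_rare_category(classification: MismatchClassification,
                       category: str = RARE) -> MismatchClassification:
    """Mark one (infrequent) category excluded; reversible via original_category."""
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    new_cat = classification.category.copy()
    new_reason = classification.excluded_reason.copy()
    mask = new_cat == category
    new_cat[mask] = EXCLUDED
    new_reason[mask] = "rare_category_drop"
    return replace(classification, category=new_cat, excluded_reason=new_reason)


def agreement_fraction(classification: MismatchClassification) -> float:
    """Fraction of included locations where the two maps agree (SEEN or BLIND)."""
    inc = classification.included
    n = int(inc.sum())
    if n == 0:
        raise ValueError("no included locations")
    agree = np.isin(classification.category[inc], (SEEN, BLIND))
    return float(agree.sum() / n)


# --------------------------------------------------------------------------
# I/O


def write_classification_csv(classification: MismatchClassification,
                             path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"x_deg": classification.grid.x,
                  "y_deg": classification.grid.y,
                  "category": classification.category,
                  "excluded_reason": classification.excluded_reason,
                  "original_category": classification.original_category,
                  }).to_csv(path, index=False)
    summary = {"eye": classification.grid.eye,
               "counts": classification.counts(),
               "fractions": classification.fractions(),
               "n_included": int(classification.included.sum())}
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def read_classification_csv(path: str | Path) -> MismatchClassification:
    path = Path(path)
    frame = pd.read_csv(path, keep_default_na=False)
    meta = json.loads(path.with_suffix(".json").read_text())
    grid = make_302_grid(meta.get("eye", "right"))
    if not np.array_equal(frame["x_deg"].to_numpy(float), grid.x):
        raise GridMismatchError(f"{path}: not the 30-2 grid in raster order")
    return MismatchClassification(
        grid=grid,
        category=frame["category"].to_numpy(object),
        excluded_reason=frame["excluded_reason"].to_numpy(object),
        original_category=frame["original_category"].to_numpy(object))
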