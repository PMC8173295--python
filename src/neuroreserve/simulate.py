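"""Synthetic hemianopia cohorts for end-to-end pipeline testing.

No patient data are distributed with this package, so every pipeline
stage is exercised on simulated patients: a lesioned retinotopic voxel
population (with optional BOLD time series), pre/post Humphrey maps
with category-dependent training effects, and goal-attainment scores
linked to the number of recovered reserve locations.

Neural reserve is created by two mechanisms, selectable per lesion:
spared islands of functional tissue inside the behavioral scotoma, and
a reserve margin by which the behavioral scotoma exceeds the neural
one.  Ground-truth categories are defined operationally as the
classification rule applied to the noiseless generator outputs
(noiseless perimetry + coverage of the true pRFs), so that with noise
disabled the pipeline reproduces them exactly and with noise enabled
they provide an exact confusion-matrix reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import classify as _classify
from .classify import BLIND, RESERVE, SEEN, MismatchClassification
from .coverage import binarize, coverage_from_estimates, downsample_to_grid
from .humphrey import (PerimetricGrid, PerimetryMap, ReliabilityIndices,
                       make_302_grid)
from .prf import HRFModel, PRFEstimate, VoxelTimeSeries, predict_timeseries
from .stats import GASRecord
from .stimulus import (StimulusAperture, VisualFieldRaster,
                       concatenate_apertures, make_ring_aperture,
                       make_wedge_aperture)

# ---------------------------------------------------------------------------
# visual-field regions


class Region:
    """A region of the visual field, composable and erodable."""

    def contains(self, x, y):
        raise NotImplementedError

    def erode(self, margin: float) -> "Region":
        raise NotImplementedError


@dataclass(frozen=True)
class HalfPlane(Region):
    """Half-plane nx*x + ny*y >= offset (unit normal)."""

    nx: float
    ny: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        norm = math.hypot(self.nx, self.ny)
        if norm == 0:
            raise ValueError("half-plane normal must be nonzero")
        object.__setattr__(self, "nx", self.nx / norm)
        object.__setattr__(self, "ny", self.ny / norm)

    def contains(self, x, y):
        return self.nx * np.asarray(x) + self.ny * np.asarray(y) >= self.offset

    def erode(self, margin: float) -> "HalfPlane":
        return HalfPlane(self.nx, self.ny, self.offset + margin)


@dataclass(frozen=True)
class Disc(Region):
    cx: float
    cy: float
    radius: float

    def contains(self, x, y):
        return np.hypot(np.asarray(x) - self.cx,
                        np.asarray(y) - self.cy) <= self.radius

    def erode(self, margin: float) -> "Disc":
        return Disc(self.cx, self.cy, max(self.radius - margin, 0.0))


@dataclass(frozen=True)
class Sector(Region):
    """Wedge-shaped sector of polar angles [start, start + span) degrees, CCW."""

    start_angle: float
    span: float

    def contains(self, x, y):
        theta = np.degrees(np.arctan2(np.asarray(y), np.asarray(x))) % 360.0
        return (theta - self.start_angle) % 360.0 < self.span

    def erode(self, margin: float) -> "Region":
        raise NotImplementedError(
            "sector erosion is ill-defined in degrees of visual angle; "
            "specify the neural scotoma explicitly instead")


@dataclass(frozen=True)
class Intersection(Region):
    regions: tuple

    def contains(self, x, y):
        out = np.ones(np.broadcast(np.asarray(x), np.asarray(y)).shape, bool)
        for r in self.regions:
            out &= r.contains(x, y)
        return out

    def erode(self, margin: float) -> "Intersection":
        return Intersection(tuple(r.erode(margin) for r in self.regions))


@dataclass(frozen=True)
class Union(Region):
    regions: tuple = ()

    def contains(self, x, y):
        out = np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, bool)
        for r in self.regions:
            out |= r.contains(x, y)
        return out

    def erode(self, margin: float) -> "Union":
        # Componentwise erosion under-erodes where components overlap;
        # conservative and sufficient for the disjoint lesions used here.
        return Union(tuple(r.erode(margin) for r in self.regions))


EMPTY_REGION = Union(())


def hemianopia(side: str) -> HalfPlane:
    """Complete hemifield loss, 'left' or 'right' visual field."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    return HalfPlane(-1.0 if side == "left" else 1.0, 0.0, 0.0)


def quadrantanopia(side: str, vertical: str) -> Intersection:
    """Quadrant loss, e.g. ('left', 'upper')."""
    if vertical not in ("upper", "lower"):
        raise ValueError("vertical must be 'upper' or 'lower'")
    return Intersection((hemianopia(side),
                         HalfPlane(0.0, 1.0 if vertical == "upper" else -1.0, 0.0)))


@dataclass(frozen=True)
class LesionSpec:
    """Behavioral scotoma plus the mechanisms generating neural reserve.

    ``scotoma`` is the behaviorally blind region.  The *neural* scotoma
    is the behavioral one eroded by ``reserve_margin`` degrees, minus
    any spared ``islands`` — voxels survive outside the neural scotoma.
    """

    scotoma: Region = EMPTY_REGION
    islands: tuple = ()
    reserve_margin: float = 0.0

    def __post_init__(self) -> None:
        if self.reserve_margin < 0:
            raise ValueError("reserve margin must be non-negative")
        for isl in self.islands:
            if not bool(np.asarray(self.scotoma.contains(isl.cx, isl.cy))):
                raise ValueError("island centres must lie inside the scotoma")

    def behavioral_contains(self, x, y):
        return self.scotoma.contains(x, y)

    def neural_contains(self, x, y):
        eroded = (self.scotoma.erode(self.reserve_margin)
                  if self.reserve_margin > 0 else self.scotoma)
        inside = np.asarray(eroded.contains(x, y))
        for isl in self.islands:
            inside = inside & ~np.asarray(isl.contains(x, y))
        return inside


# ---------------------------------------------------------------------------
# cohort specification


#: Category-mean training effects in dB (trained cohort).
DEFAULT_EFFECT_MEANS = {RESERVE: 1.34, SEEN: 0.76, BLIND: 0.22}

#: Mean gain among changed (>= 1 dB) locations per category, dB.
DEFAULT_CHANGED_MEANS = {RESERVE: 9.12, SEEN: 3.09, BLIND: 3.25}


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults emulate the trained-cohort conditions: 21 patients, wedge
    plus ring mapping runs of four 64-s cycles at a 2-s volume time,
    voxel populations tiling the field with magnification-weighted
    density, a hill of vision peaking at 33 dB and falling 0.3 dB/deg,
    1.5 dB perimetric test-retest noise, and category training effects
    of 1.34 / 0.76 / 0.22 dB (reserve / seen / blind) realised as a
    zero-inflated mixture whose changed locations average 9.12 / 3.09 /
    3.25 dB.
    """

    n_patients: int = 21
    seed: int = 0
    # neural side
    n_voxels: int = 300
    voxel_tiling: str = "random"
    snr: float = 3.0
    n_runs: int = 3
    sigma0: float = 0.75          # pRF size at fixation, deg
    sigma_slope: float = 0.1      # pRF size growth per deg eccentricity
    density_e2: float = 0.75      # magnification constant for voxel density
    raster_step: float = 0.5
    half_extent: float = 45.0
    frame_period: float = 2.0
    n_cycles: int = 4
    coverage_threshold: float = 0.5
    # behavioral side
    hill_peak_db: float = 33.0
    hill_slope: float = 0.30      # dB per degree eccentricity
    perimetry_noise_sd: float = 1.5
    effect_means: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MEANS))
    changed_means: dict = field(default_factory=lambda: dict(DEFAULT_CHANGED_MEANS))
    changed_sd: float = 1.0
    effect_mode: str = "mixture"  # or "gaussian"
    gaussian_sd: float = 1.5
    untrained: bool = False       # test-retest cohort: small uniform drift
    untrained_drift_db: float = 0.11
    # lesion geometry (reserve ~ a quarter of tested locations, near the
    # share reported for real hemianopic cohorts)
    reserve_margin: float = 9.0
    n_islands: tuple = (3, 5)     # inclusive range per patient
    island_radius: tuple = (3.5, 5.5)
    # GAS linkage
    gas_slope: float = 0.06
    gas_intercept: float = -1.0
    gas_noise_sd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        for name in ("perimetry_noise_sd", "changed_sd", "gaussian_sd",
                     "gas_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def raster(self) -> VisualFieldRaster:
        return VisualFieldRaster(self.half_extent, self.raster_step)


# ---------------------------------------------------------------------------
# voxel populations


def simulate_voxels(lesion: LesionSpec,
                    n_voxels: int = 300,
                    tiling: str = "random",
                    seed=None,
                    half_extent: float = 45.0,
                    sigma0: float = 0.75,
                    sigma_slope: float = 0.1,
                    density_e2: float = 0.75) -> pd.DataFrame:
    """Ground-truth pRF population with lesion survival flags.

    Centres tile the field with density following inverse-linear
    cortical magnification (uniform in log(e + e2) by angle), and pRF
    size grows linearly with eccentricity.  Voxels whose centres fall
    inside the neural scotoma (eroded behavioral scotoma minus spared
    islands) do not survive.  ``tiling='regular'`` places centres on a
    deterministic log-polar lattice instead of sampling them.
    """
    rng = np.random.default_rng(seed)
    if tiling == "random":
        u = rng.uniform(0.0, math.log1p(half_extent / density_e2), n_voxels)
        ecc = density_e2 * np.expm1(u)
        ang = rng.uniform(0.0, 2.0 * np.pi, n_voxels)
    elif tiling == "regular":
        n_u = max(3, int(round(math.sqrt(n_voxels / 4.0))))
        n_a = 4 * n_u
        u_edges = np.linspace(0.0, math.log1p(half_extent / density_e2), n_u + 1)
        u_mid = 0.5 * (u_edges[:-1] + u_edges[1:])
        ecc_levels = density_e2 * np.expm1(u_mid)
        ecc = np.concatenate([[0.0], np.repeat(ecc_levels, n_a)])
        ang = np.concatenate([[0.0],
                              np.tile(np.arange(n_a) * 2.0 * np.pi / n_a, n_u)])
    else:
        raise ValueError("tiling must be 'random' or 'regular'")
    x = ecc * np.cos(ang)
    y = ecc * np.sin(ang)
    sigma = sigma0 + sigma_slope * np.hypot(x, y)
    survives = ~np.asarray(lesion.neural_contains(x, y))
    return pd.DataFrame({"voxel_id": [f"v{i:04d}" for i in range(len(x))],
                         "x0": x, "y0": y, "sigma": sigma,
                         "survives": survives})


def truth_estimates(voxels: pd.DataFrame) -> list[PRFEstimate]:
    """Surviving ground-truth pRFs as perfect-fit estimates (VE = 1)."""
    out = []
    for row in voxels[voxels["survives"]].itertuples(index=False):
        out.append(PRFEstimate(row.voxel_id, row.x0, row.y0, row.sigma,
                               beta=1.0, baseline=0.0, variance_explained=1.0))
    return out


def simulate_timeseries(voxels: pd.DataFrame,
                        aperture: StimulusAperture,
                        hrf: HRFModel | None = None,
                        snr: float = 3.0,
                        n_runs: int = 3,
                        seed=None,
                        beta: float = 1.0,
                        baseline: float = 0.0) -> list[VoxelTimeSeries]:
    """Run-averaged BOLD series for surviving voxels.

    Each of ``n_runs`` acquisition runs is beta*prediction + baseline
    plus white Gaussian noise of SD beta/snr (the per-run SNR); runs
    are averaged sample-wise, mirroring the standard retinotopy
    preprocessing of averaging repeated runs per stimulus before
    fitting.  An infinite SNR gives the exact prediction; ``n_runs=1``
    yields a single raw run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    hrf = hrf or HRFModel()
    noise_sd = 0.0 if math.isinf(snr) else beta / snr
    avg_sd = noise_sd / math.sqrt(n_runs)
    out = []
    for row in voxels[voxels["survives"]].itertuples(index=False):
        pred = predict_timeseries(row.x0, row.y0, row.sigma, aperture, hrf)
        noise = rng.normal(0.0, avg_sd, len(pred)) if avg_sd else 0.0
        out.append(VoxelTimeSeries(row.voxel_id, beta * pred + baseline + noise,
                                   aperture.frame_period))
    return out


# ---------------------------------------------------------------------------
# perimetry


def choose_eye(lesion: LesionSpec) -> str:
    """Test the eye whose blind spot avoids the scotoma (right if both do)."""
    for eye, bs_x in (("right", 15.0), ("left", -15.0)):
        if not bool(np.asarray(lesion.behavioral_contains(bs_x, -3.0))):
            return eye
    return "right"


def simulate_perimetry(lesion: LesionSpec,
                       grid: PerimetricGrid | None = None,
                       peak_db: float = 33.0,
                       slope: float = 0.30,
                       noise_sd: float = 0.0,
                       seed=None,
                       subject: str | None = None) -> PerimetryMap:
    """Pre-training hill-of-vision map with the behavioral scotoma at 0 dB.

    Outside the scotoma, sensitivity is peak - slope*eccentricity plus
    optional measurement noise, floored at 0; scotoma and blind-spot
    locations read exactly 0 dB.
    """
    grid = grid or make_302_grid(choose_eye(lesion))
    rng = np.random.default_rng(seed)
    sens = peak_db - slope * grid.eccentricity()
    if noise_sd > 0:
        sens = sens + rng.normal(0.0, noise_sd, grid.n_locations)
    sens = np.maximum(sens, 0.0)
    blind = np.asarray(lesion.behavioral_contains(grid.x, grid.y)) | grid.blind_spot
    sens[blind] = 0.0
    rel = ReliabilityIndices(fixation_loss=0.05, false_positive=0.02,
                             false_negative=0.02, blind_spot_false_detection=0.05)
    return PerimetryMap(grid=grid, sensitivity=sens, session="pre",
                        reliability=rel, subject=subject)


def _draw_effects(categories: np.ndarray, rng: np.random.Generator,
                  effect_means: dict, mode: str, changed_means: dict,
                  changed_sd: float, gaussian_sd: float) -> np.ndarray:
    """Per-location training-effect draws by ground-truth category.

    'mixture' realises each category mean as a zero-inflated mixture: a
    location changes (by a >= 1 dB draw centred on the category's
    changed-location mean) with probability mean/changed_mean, else
    stays exactly at 0 dB change — matching how perimetric gains
    concentrate on a minority of locations.  'gaussian' adds a plain
    normal draw everywhere instead.
    """
    effects = np.zeros(len(categories))
    for cat, mean in effect_means.items():
        mask = categories == cat
        n = int(mask.sum())
        if n == 0:
            continue
        if mode == "gaussian":
            effects[mask] = rng.normal(mean, gaussian_sd, n)
        elif mode == "mixture":
            cm = changed_means[cat]
            if not (0.0 <= mean <= cm):
                raise ValueError(f"{cat}: category mean must lie in [0, "
                                 f"changed mean {cm}]")
            w = mean / cm
            changed = rng.random(n) < w
            if changed.any():
                a = (1.0 - cm) / changed_sd  # lower truncation at 1 dB
                draws = truncnorm.rvs(a, np.inf, loc=cm, scale=changed_sd,
                                      size=int(changed.sum()), random_state=rng)
                sub = np.zeros(n)
                sub[changed] = draws
                effects[mask] = sub
        else:
            raise ValueError("mode must be 'mixture' or 'gaussian'")
    return effects


def simulate_post_training(pre: PerimetryMap,
                           categories: np.ndarray,
                           effect_means: dict | None = None,
                           mode: str = "mixture",
                           changed_means: dict | None = None,
                           changed_sd: float = 1.0,
                           gaussian_sd: float = 1.5,
                           noise_sd: float = 0.0,
                           measurable_only: bool = False,
                           ceiling: float = 50.0,
                           seed=None) -> tuple[PerimetryMap, np.ndarray]:
    """Post-training map: pre + category effect (+ measurement noise).

    The post map is clipped to the physical [0, ceiling] dB range.  Note
    that the clip at 0 interacts with the scotoma (pre = 0 dB): a null
    cohort with exchangeable category labels therefore needs an effect
    distribution that is nonnegative by construction (e.g. the mixture
    mode with identical parameters for every category), so the clip
    never acts.  ``measurable_only`` restricts effect draws to
    locations with pre > 0 (deep-scotoma locations retest at a hard
    0 dB), the appropriate model for untrained test-retest drift.
    Returns the post map and the noiseless effect vector actually drawn.
    """
    effect_means = effect_means if effect_means is not None else DEFAULT_EFFECT_MEANS
    changed_means = changed_means if changed_means is not None else DEFAULT_CHANGED_MEANS
    rng = np.random.default_rng(seed)
    categories = np.asarray(categories, dtype=object)
    if len(categories) != pre.grid.n_locations:
        raise ValueError("category labels must match the grid")
    effects = _draw_effects(categories, rng, effect_means, mode,
                            changed_means, changed_sd, gaussian_sd)
    effects[pre.grid.blind_spot] = 0.0
    if measurable_only:
        effects[pre.sensitivity <= 0] = 0.0
    post = pre.sensitivity + effects
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, len(post))
        noise[pre.grid.blind_spot] = 0.0
        # scotoma locations read a hard 0 dB; measurement noise applies
        # only where there is something to measure
        noise[pre.sensitivity <= 0] = 0.0
        post = post + noise
    post = np.clip(post, 0.0, ceiling)
    pmap = PerimetryMap(grid=pre.grid, sensitivity=post, session="post",
                        reliability=pre.reliability, subject=pre.subject)
    return pmap, effects


def simulate_gas(counts, slope: float = 0.06, intercept: float = -1.0,
                 noise_sd: float = 0.6, n_goals: int = 3,
                 round_scores: bool = False, seed=None) -> list[GASRecord]:
    """GAS records linked linearly to per-patient improved-reserve counts.

    Goal scores are clipped to the 6-point scale [-3, +2].  By default
    they are kept continuous so that a zero-noise simulation is exactly
    collinear with the counts; ``round_scores=True`` yields the
    integer-valued scores a therapist would record.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, c in enumerate(np.asarray(counts, dtype=float)):
        latent = intercept + slope * c
        scores = np.full(n_goals, latent)
        if noise_sd > 0:
            scores = scores + rng.normal(0.0, noise_sd, n_goals)
        scores = np.clip(scores, -3.0, 2.0)
        if round_scores:
            scores = np.round(scores)
        out.append(GASRecord(patient=f"p{i:02d}", goal_scores=tuple(scores)))
    return out


# ---------------------------------------------------------------------------
# whole patients and cohorts


_LESION_TEMPLATES = ("hemianopia_left", "hemianopia_right",
                     "quadrant_left_upper", "quadrant_left_lower",
                     "quadrant_right_upper", "quadrant_right_lower",
                     "scotoma")


def random_lesion(rng: np.random.Generator,
                  reserve_margin: float = 9.0,
                  n_islands: tuple = (3, 5),
                  island_radius: tuple = (3.5, 5.5)) -> LesionSpec:
    """Draw a lesion from hemianopia/quadrantanopia/scotoma templates."""
    kind = _LESION_TEMPLATES[rng.integers(len(_LESION_TEMPLATES))]
    if kind == "scotoma":
        side = -1.0 if rng.random() < 0.5 else 1.0
        scotoma: Region = Disc(side * 15.0, float(rng.uniform(-9, 9)), 12.0)
    elif kind.startswith("hemianopia"):
        scotoma = hemianopia(kind.split("_")[1])
    else:
        _, side, vertical = kind.split("_")
        scotoma = quadrantanopia(side, vertical)
    k = int(rng.integers(n_islands[0], n_islands[1] + 1))
    islands = []
    for _ in range(200):
        if len(islands) >= k:
            break
        cx = float(rng.uniform(-27, 27))
        cy = float(rng.uniform(-27, 27))
        if bool(np.asarray(scotoma.contains(cx, cy))):
            islands.append(Disc(cx, cy, float(rng.uniform(*island_radius))))
    return LesionSpec(scotoma=scotoma, islands=tuple(islands),
                      reserve_margin=reserve_margin)


@dataclass
class SimulatedPatient:
    """One synthetic patient with ground truth and observed data."""

    patient_id: str
    lesion: LesionSpec
    eye: str
    voxels: pd.DataFrame
    pre_true: PerimetryMap
    pre_obs: PerimetryMap
    post_obs: PerimetryMap
    neural_map: "object"                    # binarised NeuralPerimetryMap
    truth: MismatchClassification
    true_effects: np.ndarray
    seed: int


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    patients: list
    gas: list
    table: pd.DataFrame          # tidy cohort table (see stats.build_cohort_table)
    reserve_improved: pd.Series  # per-patient truth counts feeding GAS


def default_apertures(spec: CohortSpec) -> StimulusAperture:
    """Wedge then ring runs, concatenated for joint fitting."""
    raster = spec.raster()
    wedge = make_wedge_aperture(raster, spec.frame_period, spec.n_cycles)
    ring = make_ring_aperture(raster, spec.frame_period, spec.n_cycles)
    return concatenate_apertures(wedge, ring)


def simulate_patient(spec: CohortSpec, patient_id: str, seed: int,
                     lesion: LesionSpec | None = None) -> SimulatedPatient:
    """Simulate one patient through the noiseless-truth pipeline.

    BOLD time series are not generated here (see simulate_timeseries);
    the neural map is built from the ground-truth pRFs, which is the
    noise-disabled reference the fitted pipeline is scored against.
    """
    rng = np.random.default_rng(seed)
    lesion = lesion if lesion is not None else random_lesion(
        rng, spec.reserve_margin, spec.n_islands, spec.island_radius)
    eye = choose_eye(lesion)
    grid = make_302_grid(eye)
    voxels = simulate_voxels(lesion, spec.n_voxels, spec.voxel_tiling, rng,
                             spec.half_extent, spec.sigma0, spec.sigma_slope,
                             spec.density_e2)
    cov = coverage_from_estimates(truth_estimates(voxels), spec.raster())
    neural = binarize(downsample_to_grid(cov, grid), spec.coverage_threshold)

    pre_true = simulate_perimetry(lesion, grid, spec.hill_peak_db,
                                  spec.hill_slope, 0.0, subject=patient_id)
    truth = _classify.drop_rare_category(
        _classify.classify_locations(pre_true, neural))

    pre_obs = simulate_perimetry(lesion, grid, spec.hill_peak_db,
                                 spec.hill_slope, spec.perimetry_noise_sd,
                                 rng, subject=patient_id)
    effect_means = (dict.fromkeys(spec.effect_means, spec.untrained_drift_db)
                    if spec.untrained else spec.effect_means)
    mode = "gaussian" if spec.untrained else spec.effect_mode
    post_obs, effects = simulate_post_training(
        pre_obs, truth.category, effect_means, mode, spec.changed_means,
        spec.changed_sd, spec.gaussian_sd, spec.perimetry_noise_sd,
        measurable_only=spec.untrained, seed=rng)
    return SimulatedPatient(patient_id=patient_id, lesion=lesion, eye=eye,
                            voxels=voxels, pre_true=pre_true, pre_obs=pre_obs,
                            post_obs=post_obs, neural_map=neural, truth=truth,
                            true_effects=effects, seed=seed)


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Simulate a full cohort with hierarchical per-patient seeds."""
    from .humphrey import change_map
    from .stats import build_cohort_table

    root = np.random.default_rng(spec.seed)
    patient_seeds = [int(s) for s in root.integers(0, 2**31 - 1, spec.n_patients)]
    patients = [simulate_patient(spec, f"p{i:02d}", s)
                for i, s in enumerate(patient_seeds)]
    triples = [(p.patient_id, p.truth, change_map(p.pre_obs, p.post_obs))
               for p in patients]
    table = build_cohort_table(triples)
    counts = pd.Series(
        {p.patient_id: int(((p.truth.category == RESERVE)
                            & (p.true_effects >= 1.0)).sum())
         for p in patients})
    gas = simulate_gas(counts.to_numpy(), spec.gas_slope, spec.gas_intercept,
                       spec.gas_noise_sd, seed=root)
    for rec, pid in zip(gas, counts.index):
        rec.patient = pid
    return SimulatedCohort(spec=spec, patients=patients, gas=gas,
                           table=table, reserve_improved=counts)


# ---------------------------------------------------------------------------
# on-disk cohort export


def write_cohort(cohort: SimulatedCohort, out_dir: str | Path,
                 with_timeseries: bool = False) -> Path:
    """Write per-patient CSVs plus a manifest JSON under ``out_dir``."""
    from .classify import write_classification_csv
    from .humphrey import write_perimetry_csv
    from .coverage import write_neural_csv
    from .prf import write_bold_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.spec.seed, "n_patients": cohort.spec.n_patients,
                "patients": []}
    for p, rec in zip(cohort.patients, cohort.gas):
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        write_perimetry_csv(p.pre_obs, pdir / "perimetry_pre.csv")
        write_perimetry_csv(p.post_obs, pdir / "perimetry_post.csv")
        write_neural_csv(p.neural_map, pdir / "neural.csv")
        write_classification_csv(p.truth, pdir / "truth_categories.csv")
        p.voxels.to_csv(pdir / "truth_prfs.csv", index=False)
        entry = {"id": p.patient_id, "eye": p.eye, "seed": p.seed,
                 "gas_scores": list(rec.goal_scores),
                 "files": {"pre": f"{p.patient_id}/perimetry_pre.csv",
                           "post": f"{p.patient_id}/perimetry_post.csv",
                           "neural": f"{p.patient_id}/neural.csv",
                           "truth": f"{p.patient_id}/truth_categories.csv"}}
        if with_timeseries:
            ap = default_apertures(cohort.spec)
            series = simulate_timeseries(p.voxels, ap, snr=cohort.spec.snr,
                                         seed=p.seed)
            write_bold_table(series, pdir / "bold.tsv")
            ap.save(pdir / "aperture.npy")
            entry["files"]["bold"] = f"{p.patient_id}/bold.tsv"
        manifest["patients"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"
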