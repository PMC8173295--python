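"""Training-effect statistics across mismatch categories.

The central inference is whether training-induced dB gains differ
between the agreement categories, above all whether neural-reserve
locations (Hum-/Ret+) gain more than the others.  Category means are
compared with a permutation test that shuffles category labels within
each patient (preserving per-patient category composition) and
recomputes the pooled category means, with the one-sided p-value
p = (1 + #{null >= observed}) / (1 + n_iterations).

Two analysis variants mirror the two ways of summarising training
effects: over all included locations, or over changed locations only
(gain of at least 1 dB, the perimeter's resolution).  Two pooling units
are supported: per-patient means averaged across patients (default) or
all locations pooled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import CATEGORIES, RESERVE
from .humphrey import ChangeMap, PerimetryMap

VARIANTS = ("all_locations", "changed_only")
POOLINGS = ("per_patient_then_mean", "pooled_locations")


# --------------------------------------------------------------------------
# cohort assembly


def build_cohort_table(per_patient: list[tuple]) -> pd.DataFrame:
    """Tidy cohort table from (patient_id, classification, change_map) triples.

    Excluded locations (blind spot, dropped rare category) are omitted.
    """
    rows = []
    for patient_id, classification, change in per_patient:
        cvec = change.change if isinstance(change, ChangeMap) else np.asarray(change)
        if len(cvec) != classification.grid.n_locations:
            raise ValueError(f"patient {patient_id}: change vector length "
                             "does not match the grid")
        inc = classification.included
        for x, y, cat, d in zip(classification.grid.x[inc],
                                classification.grid.y[inc],
                                classification.category[inc], cvec[inc]):
            rows.append((patient_id, x, y, cat, float(d)))
    return pd.DataFrame(rows, columns=["patient", "x_deg", "y_deg",
                                       "category", "change"])


def _apply_variant(table: pd.DataFrame, variant: str,
                   improvement_threshold: float, changed_rule: str) -> pd.DataFrame:
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "all_locations":
        return table
    if changed_rule == "at_least_threshold":
        return table[table["change"] >= improvement_threshold]
    if changed_rule == "nonzero":
        return table[table["change"] != 0.0]
    raise ValueError("changed_rule must be 'at_least_threshold' or 'nonzero'")


# --------------------------------------------------------------------------
# category effects


@dataclass
class CategoryEffect:
    category: str
    mean: float | None
    se: float | None
    n: int  # number of pooling units (patients or locations)


@dataclass
class CategoryEffectSummary:
    effects: dict
    variant: str
    pooling: str

    def mean(self, category: str) -> float | None:
        return self.effects[category].mean


def category_effects(table: pd.DataFrame,
                     variant: str = "all_locations",
                     pooling: str = "per_patient_then_mean",
                     improvement_threshold: float = 1.0,
                     changed_rule: str = "at_least_threshold") -> CategoryEffectSummary:
    """Mean dB change and standard error per category.

    Under the default pooling the unit is the patient: each patient
    contributes their within-patient category mean, and the SE is the
    between-patient SD over sqrt(n patients).  ``pooled_locations``
    treats every location as a unit instead.
    """
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    sub = _apply_variant(table, variant, improvement_threshold, changed_rule)
    effects = {}
    for cat in CATEGORIES:
        rows = sub[sub["category"] == cat]
        if rows.empty:
            effects[cat] = CategoryEffect(cat, None, None, 0)
            continue
        if pooling == "per_patient_then_mean":
            per_patient = rows.groupby("patient")["change"].mean()
            n = len(per_patient)
            mean = float(per_patient.mean())
            se = float(per_patient.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        else:
            vals = rows["change"].to_numpy()
            n = len(vals)
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else None
        effects[cat] = CategoryEffect(cat, mean, se, n)
    return CategoryEffectSummary(effects=effects, variant=variant, pooling=pooling)


# --------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationComparison:
    reference: str
    other: str
    observed: float        # reference mean minus other mean
    p: float
    null_mean: float
    null_sd: float


@dataclass
class PermutationResult:
    comparisons: dict      # (reference, other) -> PermutationComparison
    n_iterations: int
    seed: int | None
    pooling: str
    variant: str
    alternative: str

    def p(self, other: str, reference: str = RESERVE) -> float:
        return self.comparisons[(reference, other)].p


def permutation_test(table: pd.DataFrame,
                     n_iterations: int = 10_000,
                     seed: int | None = None,
                     reference: str = RESERVE,
                     others: tuple | None = None,
                     pooling: str = "per_patient_then_mean",
                     variant: str = "all_locations",
                     improvement_threshold: float = 1.0,
                     changed_rule: str = "at_least_threshold",
                     alternative: str = "greater") -> PermutationResult:
    """Permutation null for pairwise differences between category means.

    Labels are shuffled within each patient so category sizes per
    patient are preserved; pooled means are recomputed per iteration.
    The default alternative is one-sided (reference exceeds other);
    p = (1 + #{null >= observed}) / (1 + n_iterations).
    """
    if pooling not in POOLINGS:
        raise ValueError(f"pooling must be one of {POOLINGS}")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if n_iterations < 100:
        import warnings
        warnings.warn(f"{n_iterations} iterations gives a coarse p-value grid",
                      stacklevel=2)
    sub = _apply_variant(table, variant, improvement_threshold, changed_rule)
    present = [c for c in CATEGORIES if (sub["category"] == c).any()]
    if len(present) < 2:
        raise ValueError("permutation test needs at least two non-empty categories")
    if reference not in present:
        raise ValueError(f"reference category {reference!r} is empty")
    if others is None:
        others = tuple(c for c in present if c != reference)

    codes = {c: j for j, c in enumerate(present)}
    rng = np.random.default_rng(seed)

    # Null category means under the chosen pooling, all iterations at once.
    if pooling == "per_patient_then_mean":
        mean_sum = np.zeros((n_iterations, len(present)))
        n_pat = np.zeros(len(present))
    else:
        val_sum = np.zeros((n_iterations, len(present)))
        tot_cnt = np.zeros(len(present))
    for _, rows in sub.groupby("patient"):
        v = rows["change"].to_numpy()
        lab = rows["category"].map(codes).to_numpy()
        perm = np.argsort(rng.random((n_iterations, len(v))), axis=1)
        L = lab[perm]
        for j in range(len(present)):
            cnt = int((lab == j).sum())
            if cnt == 0:
                continue
            s = (L == j) @ v
            if pooling == "per_patient_then_mean":
                mean_sum[:, j] += s / cnt
                n_pat[j] += 1
            else:
                val_sum[:, j] += s
                tot_cnt[j] += cnt
    if pooling == "per_patient_then_mean":
        null_means = mean_sum / n_pat[None, :]
    else:
        null_means = val_sum / tot_cnt[None, :]

    observed = category_effects(sub, "all_locations", pooling)
    comparisons = {}
    for other in others:
        if other not in present:
            raise ValueError(f"category {other!r} is empty")
        d_obs = observed.mean(reference) - observed.mean(other)
        d_null = null_means[:, codes[reference]] - null_means[:, codes[other]]
        if alternative == "greater":
            hits = int((d_null >= d_obs).sum())
        else:
            hits = int((np.abs(d_null) >= abs(d_obs)).sum())
        p = (1 + hits) / (1 + n_iterations)
        comparisons[(reference, other)] = PermutationComparison(
            reference=reference, other=other, observed=float(d_obs), p=float(p),
            null_mean=float(d_null.mean()), null_sd=float(d_null.std(ddof=0)))
    return PermutationResult(comparisons=comparisons, n_iterations=n_iterations,
                             seed=seed, pooling=pooling, variant=variant,
                             alternative=alternative)


# --------------------------------------------------------------------------
# goal attainment scaling


@dataclass
class GASRecord:
    """Per-patient goal-attainment scores on the 6-point scale [-3, +2]."""

    patient: str | int
    goal_scores: tuple

    def __post_init__(self) -> None:
        if len(self.goal_scores) == 0:
            raise ValueError("at least one goal score required")
        for s in self.goal_scores:
            if not (-3.0 - 1e-9 <= s <= 2.0 + 1e-9):
                raise ValueError("GAS scores must lie within [-3, +2]")

    @property
    def aggregate(self) -> float:
        return float(np.mean(self.goal_scores))


@dataclass
class AssociationResult:
    predictor: str
    r: float
    p: float
    n: int
    slope: float
    intercept: float
    undefined: bool = False


def reserve_improved_counts(table: pd.DataFrame,
                            improvement_threshold: float = 1.0) -> pd.Series:
    """Per-patient count of neural-reserve locations improved by >= threshold."""
    mask = (table["category"] == RESERVE) & (table["change"] >= improvement_threshold)
    counts = table[mask].groupby("patient").size()
    return counts.reindex(table["patient"].unique(), fill_value=0)


def gas_association(counts, gas: list[GASRecord] | np.ndarray,
                    predictor: str = "n_reserve_improved") -> AssociationResult:
    """Linear association between an improvement predictor and GAS outcome.

    Ordinary least squares with Pearson r and its two-sided p-value.
    A zero-variance predictor is flagged undefined rather than raising.
    """
    x = np.asarray(counts, dtype=float)
    y = np.array([g.aggregate for g in gas]) if (len(gas) and
                                                 isinstance(gas[0], GASRecord)) \
        else np.asarray(gas, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictor and GAS vectors differ in length")
    if len(x) < 3:
        raise ValueError("need at least 3 patients for the association")
    if np.std(x) == 0 or np.std(y) == 0:
        return AssociationResult(predictor, float("nan"), float("nan"),
                                 len(x), float("nan"), float("nan"),
                                 undefined=True)
    fit = sps.linregress(x, y)
    return AssociationResult(predictor, float(fit.rvalue), float(fit.pvalue),
                             len(x), float(fit.slope), float(fit.intercept))


# --------------------------------------------------------------------------
# trained vs untrained cohorts and reliability QC report


@dataclass
class CohortComparison:
    difference: float      # trained mean minus untrained mean
    p: float
    n_trained: int
    n_untrained: int
    n_iterations: int
    seed: int | None


def pre_post_reliability_compare(trained_means, untrained_means,
                                 n_iterations: int = 10_000,
                                 seed: int | None = None,
                                 alternative: str = "greater") -> CohortComparison:
    """Two-sample permutation comparison of per-patient mean dB changes.

    Used to contrast a trained cohort against an untrained test-retest
    cohort; the default alternative is trained > untrained.
    """
    a = np.asarray(trained_means, dtype=float)
    b = np.asarray(untrained_means, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each cohort needs at least two patients")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    d_obs = a.mean() - b.mean()
    hits = 0
    for _ in range(n_iterations):
        perm = rng.permutation(pooled)
        d = perm[: len(a)].mean() - perm[len(a):].mean()
        if (d >= d_obs) if alternative == "greater" else (abs(d) >= abs(d_obs)):
            hits += 1
    return CohortComparison(difference=float(d_obs),
                            p=(1 + hits) / (1 + n_iterations),
                            n_trained=len(a), n_untrained=len(b),
                            n_iterations=n_iterations, seed=seed)


def reliability_ttests(pre_maps: list[PerimetryMap],
                       post_maps: list[PerimetryMap]) -> pd.DataFrame:
    """Paired t-tests of reliability indices across sessions (QC report only)."""
    if len(pre_maps) != len(post_maps):
        raise ValueError("cohorts differ in size")
    rows = []
    for name in ("fixation_loss", "false_positive", "false_negative",
                 "blind_spot_false_detection"):
        pre = [getattr(m.reliability, name) for m in pre_maps if m.reliability]
        post = [getattr(m.reliability, name) for m in post_maps if m.reliability]
        if (len(pre) == len(post) and len(pre) > 1
                and all(v is not None for v in pre + post)):
            t, p = sps.ttest_rel(pre, post)
            rows.append((name, float(np.mean(pre)), float(np.mean(post)),
                         float(t), float(p)))
    return pd.DataFrame(rows, columns=["index", "mean_pre", "mean_post",
                                       "t", "p"])
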