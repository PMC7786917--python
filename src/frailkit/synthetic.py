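"""Synthetic cohort generation.

The raw individual-level survey data behind the reference cohort are not
public, so the package generates cohorts with the statistical structure
the analysis assumes, in two modes:

* **table-faithful** — exactly 400 records whose every covariate-by-severity
  cross-tabulation reproduces the shipped reference tables EXACTLY, for any
  seed.  Only the margins of those tables are published, so covariates are
  drawn conditionally independent given the severity category (the minimal
  assumption preserving every printed table); the seed moves the joint
  covariate patterns, never the tables.  Each record's frailty index is
  drawn within its category's band, clipped to the observed range
  [0.05, 0.71].

* **parametric** — cohorts of configurable size from a known-truth logistic
  model: covariates drawn independently, the frail outcome Bernoulli with
  logit equal to the linear predictor, and FI drawn uniformly within the
  outcome class's band.  Used for parameter-recovery and CI-coverage
  studies.

An optional *deep* mode synthesizes the 30 item-level responses themselves
(so cohorts can be pushed through the full coding-and-scoring path); it
quantizes FI to the grid of values attainable as legal weight sums.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .instrument import CATEGORY_BANDS, FrailtyCategory, ItemRegistry, default_registry
from .reference_cohort import (
    AGE_MEAN_SD,
    AGE_RANGE,
    CATEGORIES,
    CATEGORY_TOTALS,
    FI_RANGE,
    REFERENCE_CROSSTABS,
)

__all__ = [
    "TableFaithfulSpec",
    "ParametricSpec",
    "generate_table_faithful",
    "generate_parametric",
    "calibration_report",
    "default_parametric_spec",
    "calibrate_intercept",
    "attainable_fi_grid",
]

_BANDS = {cat.value: band for cat, band in CATEGORY_BANDS.items()}


@dataclass
class TableFaithfulSpec:
    """Specification of a table-faithful cohort.

    ``crosstabs`` maps covariate name -> {level: (fit, mild, moderate,
    severe) counts}; every matrix must have column sums equal to
    ``category_totals``.
    """

    category_totals: dict[str, int] = field(default_factory=lambda: dict(CATEGORY_TOTALS))
    crosstabs: dict[str, dict[str, tuple[int, int, int, int]]] = field(
        default_factory=lambda: {
            cov: dict(levels) for cov, levels in REFERENCE_CROSSTABS.items()
        }
    )
    fi_sampler: str = "uniform"  # "uniform" | "grid"
    fi_clip: tuple[float, float] = FI_RANGE
    deep_items: bool = False
    continuous_age: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.fi_sampler not in ("uniform", "grid"):
            raise ValidationError(f"unknown fi_sampler {self.fi_sampler!r}")
        totals = np.array([self.category_totals[c] for c in CATEGORIES])
        if (totals < 0).any() or totals.sum() == 0:
            raise ValidationError("category totals must be non-negative and not all zero")
        for cov, levels in self.crosstabs.items():
            mat = np.array([levels[l] for l in levels])
            if mat.shape[1] != len(CATEGORIES) or (mat < 0).any():
                raise ValidationError(f"covariate {cov!r}: malformed count matrix")
            if not np.array_equal(mat.sum(axis=0), totals):
                raise ValidationError(
                    f"covariate {cov!r}: column sums {mat.sum(axis=0).tolist()} "
                    f"differ from category totals {totals.tolist()}"
                )


def attainable_fi_grid(registry: ItemRegistry | None = None) -> np.ndarray:
    """All FI values attainable as legal weight sums over the 30 items.

    Enumerates the distinct per-item weight multisets of the registry's
    schemes (no missing items) and returns the sorted set of sums / 30.
    """
    registry = registry or default_registry()
    sums = {0.0}
    for item in registry:
        sums = {s + w for s in sums for w in item.scheme.weights}
        sums = {round(s, 6) for s in sums}
    return np.array(sorted(s / len(registry) for s in sums))


def _draw_fi_uniform(category: str, clip: tuple[float, float], rng: np.random.Generator) -> float:
    lo, hi = _BANDS[category]
    lo = max(lo, clip[0]) if clip[0] > lo else np.nextafter(lo, 1.0)
    hi = min(hi, clip[1])
    return float(rng.uniform(lo, hi))


class _GridSampler:
    """Samples FI uniformly over the attainable weight-sum grid within a band."""

    def __init__(self, clip: tuple[float, float], registry: ItemRegistry | None = None):
        grid = attainable_fi_grid(registry)
        self.per_band: dict[str, np.ndarray] = {}
        for cat, (lo, hi) in _BANDS.items():
            if cat == "FIT":
                mask = grid >= clip[0] - 1e-12  # clip lower bound is inclusive
            else:
                mask = grid > lo + 1e-12  # bands are open below
            mask &= grid <= min(hi, clip[1]) + 1e-12
            self.per_band[cat] = grid[mask]

    def draw(self, category: str, rng: np.random.Generator) -> float:
        choices = self.per_band[category]
        if len(choices) == 0:
            raise ValidationError(f"no attainable FI value inside the {category} band")
        return float(rng.choice(choices))


def _synthesize_item_responses(
    category: str,
    clip: tuple[float, float],
    rng: np.random.Generator,
    registry: ItemRegistry,
) -> tuple[dict[str, str], float]:
    """Construct 30 raw responses whose computed FI lands in ``category``'s band.

    Builds a deficit sum on the half-integer grid (binary deficits plus at
    most one 0.5 grade), drawn uniformly over the grid points of the band.
    """
    lo, hi = _BANDS[category]
    n = len(registry)
    if category == "FIT":
        s_min = math.ceil(clip[0] * n * 2 - 1e-9) / 2  # clip lower bound, inclusive
    else:
        s_min = math.floor(lo * n * 2 + 1e-9) / 2 + 0.5  # band open below
    s_max = math.floor(min(hi, clip[1]) * n * 2 + 1e-9) / 2
    grid = np.arange(s_min, s_max + 1e-9, 0.5)
    s = float(rng.choice(grid))
    n_full = int(s)
    half = abs(s - n_full - 0.5) < 1e-9
    half_capable = [it for it in registry if 0.5 in it.scheme.weights]
    responses = {it.name: it.scheme.label_for(0.0) for it in registry}
    half_item = None
    if half:
        half_item = half_capable[rng.integers(len(half_capable))]
        responses[half_item.name] = half_item.scheme.label_for(0.5)
    pool = [it for it in registry if half_item is None or it.item_id != half_item.item_id]
    chosen = rng.choice(len(pool), size=n_full, replace=False)
    for idx in chosen:
        it = pool[idx]
        responses[it.name] = it.scheme.label_for(1.0)
    return responses, s / n


def generate_table_faithful(
    spec: TableFaithfulSpec | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Generate a cohort whose every cross-tab reproduces the spec matrices exactly.

    Records are assigned a severity category per ``category_totals``; within
    each category block each covariate's levels are distributed by a seeded
    permutation, so the covariate-by-category tables are exact for every
    seed while the joint covariate patterns vary with it.
    """
    spec = spec or TableFaithfulSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    registry = default_registry()

    categories = np.concatenate(
        [np.repeat(cat, spec.category_totals[cat]) for cat in CATEGORIES]
    )
    n = len(categories)
    data: dict[str, np.ndarray] = {"category": categories}

    block_slices: dict[str, slice] = {}
    start = 0
    for cat in CATEGORIES:
        block_slices[cat] = slice(start, start + spec.category_totals[cat])
        start += spec.category_totals[cat]

    for cov, level_counts in spec.crosstabs.items():
        col = np.empty(n, dtype=object)
        for j, cat in enumerate(CATEGORIES):
            labels = np.concatenate(
                [np.repeat(lvl, counts[j]) for lvl, counts in level_counts.items()]
            )
            rng.shuffle(labels)
            col[block_slices[cat]] = labels
        data[cov] = col

    grid_sampler = _GridSampler(spec.fi_clip, registry) if spec.fi_sampler == "grid" else None
    fis = np.empty(n)
    item_rows: list[dict[str, str]] | None = [] if spec.deep_items else None
    for i, cat in enumerate(categories):
        if spec.deep_items:
            responses, fi = _synthesize_item_responses(cat, spec.fi_clip, rng, registry)
            item_rows.append(responses)
            fis[i] = fi
        elif grid_sampler is not None:
            fis[i] = grid_sampler.draw(cat, rng)
        else:
            fis[i] = _draw_fi_uniform(cat, spec.fi_clip, rng)
    data["fi"] = fis

    if spec.continuous_age:
        mu, sd = AGE_MEAN_SD
        ages = np.empty(n)
        for i in range(n):
            a = rng.normal(mu, sd)
            while not AGE_RANGE[0] <= a <= AGE_RANGE[1]:
                a = rng.normal(mu, sd)
            ages[i] = a
        data["age_years"] = ages

    frame = pd.DataFrame(data)
    if item_rows is not None:
        frame = pd.concat([frame, pd.DataFrame(item_rows)], axis=1)
    frame["frail"] = frame["category"].isin(["MODERATE", "SEVERE"])
    perm = rng.permutation(n)
    frame = frame.iloc[perm].reset_index(drop=True)
    frame.insert(0, "subject_id", np.arange(1, n + 1))
    return frame


@dataclass
class ParametricSpec:
    """Specification of a known-truth parametric cohort.

    ``covariates`` maps covariate name -> {level: probability} (probabilities
    sum to 1; the FIRST level is the reference).  ``beta`` maps
    ``"covariate:level"`` to the true log-odds coefficient of that indicator.
    """

    n: int = 2000
    covariates: dict[str, dict[str, float]] = field(default_factory=dict)
    beta: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.0
    fi_fit: tuple[float, float] = (0.05, 0.24)
    fi_frail: tuple[float, float] = (0.24, 0.71)
    seed: int = 0

    def validate(self) -> None:
        if self.n <= 0:
            raise ValidationError("cohort size must be positive")
        for cov, probs in self.covariates.items():
            p = np.array(list(probs.values()))
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-8:
                raise ValidationError(f"covariate {cov!r}: probabilities must sum to 1")
        for key in self.beta:
            cov, _, lvl = key.partition(":")
            if cov not in self.covariates or lvl not in self.covariates[cov]:
                raise ValidationError(f"beta term {key!r} names no covariate level")

    def references(self) -> dict[str, str]:
        return {cov: next(iter(levels)) for cov, levels in self.covariates.items()}


def generate_parametric(spec: ParametricSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort from the spec's logistic model (seeded, reproducible)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    eta = np.full(n, spec.intercept)
    data: dict[str, np.ndarray] = {}
    for cov, probs in spec.covariates.items():
        levels = list(probs.keys())
        draw = rng.choice(len(levels), size=n, p=list(probs.values()))
        col = np.array(levels, dtype=object)[draw]
        data[cov] = col
        for j, lvl in enumerate(levels):
            b = spec.beta.get(f"{cov}:{lvl}", 0.0)
            if b:
                eta += b * (draw == j)
    frail = rng.random(n) < expit(eta)
    lo_fit, hi_fit = spec.fi_fit
    lo_fr, hi_fr = spec.fi_frail
    fi = np.where(
        frail,
        rng.uniform(np.nextafter(lo_fr, 1.0), hi_fr, size=n),
        rng.uniform(lo_fit, hi_fit, size=n),
    )
    data["frail"] = frail
    data["fi"] = fi
    frame = pd.DataFrame(data)
    frame["category"] = [
        "FIT" if v <= 0.12 else "MILD" if v <= 0.24 else "MODERATE" if v <= 0.36 else "SEVERE"
        for v in fi
    ]
    frame.insert(0, "subject_id", np.arange(1, n + 1))
    return frame


def calibrate_intercept(
    covariates: Mapping[str, Mapping[str, float]],
    beta: Mapping[str, float],
    target_prevalence: float,
) -> float:
    """Intercept giving the requested marginal frail prevalence.

    Enumerates the (independent) covariate cells and solves
    E[expit(b0 + x beta)] = target by bisection.
    """
    covs = list(covariates.items())
    cells = list(itertools.product(*(levels.items() for _, levels in covs)))

    def marginal(b0: float) -> float:
        total = 0.0
        for cell in cells:
            p = 1.0
            eta = b0
            for (cov, _), (lvl, prob) in zip(covs, cell):
                p *= prob
                eta += beta.get(f"{cov}:{lvl}", 0.0)
            total += p * expit(eta)
        return total - target_prevalence

    return float(brentq(marginal, -20.0, 20.0))


def default_parametric_spec(n: int = 2000, seed: int = 0) -> ParametricSpec:
    """A parametric spec emulating the reference cohort's structure.

    Age-group and gender frequencies follow the reference margins; the true
    log-odds coefficients are the reference cohort's adjusted odds ratios
    for those terms, and the intercept is calibrated so the marginal frail
    prevalence matches the observed 61.5%.
    """
    covariates = {
        "age_group": {"55-59": 0.3625, "60-64": 0.225, "65-69": 0.165, "70+": 0.2475},
        "gender": {"Male": 0.5725, "Female": 0.4275},
    }
    beta = {
        "age_group:60-64": math.log(2.910),
        "age_group:65-69": math.log(1.217),
        "age_group:70+": math.log(4.232),
        "gender:Female": math.log(1.487),
    }
    intercept = calibrate_intercept(covariates, beta, 246 / 400)
    return ParametricSpec(n=n, covariates=covariates, beta=beta, intercept=intercept, seed=seed)


def calibration_report(cohort: pd.DataFrame) -> dict:
    """Summary statistics for eyeball comparison against the reference cohort."""
    if len(cohort) == 0:
        raise ValidationError("empty cohort")
    fi = cohort["fi"].to_numpy(dtype=float)
    report = {
        "n": len(cohort),
        "fi_mean": float(fi.mean()),
        "fi_sd": float(fi.std(ddof=1)),
        "fi_min": float(fi.min()),
        "fi_max": float(fi.max()),
        "category_proportions": {
            cat: float((cohort["category"] == cat).mean()) for cat in CATEGORIES
        },
        "frail_prevalence": float(cohort["frail"].mean()),
    }
    if "age_years" in cohort.columns:
        report["age_mean"] = float(cohort["age_years"].mean())
        report["age_sd"] = float(cohort["age_years"].std(ddof=1))
    return report
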