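"""End-to-end analysis pipeline: read, grade, score, classify, associate, report.

``run_pipeline`` drives a full reproduction-style analysis from a delimited
cohort file to a report bundle: a scored subject table, covariate-by-severity
cross-tabs with Pearson chi-square, an odds/logistic risk-factor table
(within-level frailty odds alongside adjusted odds ratios from the joint
logistic model), category prevalence records with confidence intervals, and
a machine-readable run manifest.  Every number in the bundle is produced by
an operation from the instrument/measurements/association modules; the
pipeline itself only orchestrates.

Reports are deterministic for a fixed config and seed: no timestamps, fixed
column orders, fixed float formatting — re-running a config byte-identically
reproduces the bundle.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    CodingError,
    FrailkitError,
    IncomputableScoreError,
    RankDeficiencyError,
    SeparationError,
    ValidationError,
)
from .association import (
    chi_square,
    crosstab,
    fit_logistic,
    odds_ratio,
    prevalence_ci,
    subgroup_frailty_odds,
)
from .instrument import (
    ALLOWED_WEIGHTS,
    BINARY_CUT,
    CATEGORY_CUTS,
    ItemRegistry,
    categorize_fi,
    default_registry,
    dichotomize_fi,
    load_registry,
    score_responses,
)
from .measurements import (
    BMI_CUTS,
    BP_CUTS,
    GDS_CUTS,
    RBS_CUTS,
    compute_bmi,
    grade_bmi,
    grade_bp,
    grade_gds,
    grade_rbs,
)
from .reference_cohort import CATEGORIES, LEVEL_ORDER, REFERENCE_LEVELS

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "validate_registry"]

_NA_VALUES = ["", "NA"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (loadable from YAML)."""

    input_path: str
    output_dir: str
    seed: int = 0
    covariates: list[str] | None = None  # default: known covariates present in the input
    references: dict[str, str] = field(default_factory=dict)
    level_order: dict[str, list[str]] = field(default_factory=dict)
    registry_path: str | None = None
    min_items: int = 24
    ci_method: str = "wilson"  # prevalence intervals: "wilson" | "wald"
    odds_convention: str = "subgroup"  # unadjusted column: "subgroup" | "reference"
    precision: int = 3
    max_error_fraction: float = 0.0  # tolerated fraction of unscorable subjects

    def validate(self) -> None:
        if self.ci_method not in ("wilson", "wald"):
            raise ValidationError(f"unknown ci_method {self.ci_method!r}")
        if self.odds_convention not in ("subgroup", "reference"):
            raise ValidationError(f"unknown odds_convention {self.odds_convention!r}")
        if not 0 <= self.max_error_fraction < 1:
            raise ValidationError("max_error_fraction must be in [0, 1)")
        if self.min_items < 1:
            raise ValidationError("min_items must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ReportBundle:
    """Paths and tables of one pipeline run."""

    output_dir: Path
    scored: pd.DataFrame
    crosstabs: pd.DataFrame
    odds: pd.DataFrame
    prevalence: pd.DataFrame
    manifest: dict
    errors: pd.DataFrame
    status: str  # "success" | "partial"


_MEASUREMENT_GRADERS = {
    # target item column -> (required raw columns, grader)
    "bmi_grade": (("height_m", "weight_kg"), lambda r: grade_bmi(compute_bmi(r["height_m"], r["weight_kg"]))),
    "hbp_grade": (("sbp_mmhg", "dbp_mmhg"), lambda r: grade_bp(r["sbp_mmhg"], r["dbp_mmhg"])),
    "rbs_grade": (("rbs_mmol_l",), lambda r: grade_rbs(r["rbs_mmol_l"])),
    "gds_grade": (("gds_total",), lambda r: grade_gds(int(r["gds_total"]))),
}


def _grade_raw_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Fill graded item columns from raw measurement columns where present."""
    out = frame.copy()
    for target, (required, grader) in _MEASUREMENT_GRADERS.items():
        if target in out.columns:
            continue
        if all(c in out.columns for c in required):
            out[target] = [
                grader(row).label if not row[list(required)].isna().any() else None
                for _, row in out.iterrows()
            ]
    if "gds_grade" not in out.columns:
        qcols = [f"gds_q{i}" for i in range(1, 16)]
        if all(c in out.columns for c in qcols):
            out["gds_grade"] = [
                grade_gds(int(row[qcols].sum())).label for _, row in out.iterrows()
            ]
    return out


def _score_frame(
    frame: pd.DataFrame, registry: ItemRegistry, min_items: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each row; returns (scored rows, per-subject error records)."""
    colmap: dict[int, str] = {}
    for item in registry:
        for cand in (item.name, f"item_{item.item_id}"):
            if cand in frame.columns:
                colmap[item.item_id] = cand
                break
    has_items = bool(colmap)
    if not has_items and "fi" not in frame.columns:
        raise ValidationError(
            "input has neither instrument item columns nor a precomputed 'fi' column"
        )
    rows, errs = [], []
    for idx, row in frame.iterrows():
        sid = row.get("subject_id", idx)
        try:
            if has_items:
                res = score_responses(
                    {iid: row[col] for iid, col in colmap.items()},
                    registry=registry,
                    min_items=min_items,
                )
                fi, n_missing = res.score.fi, res.score.n_missing
            else:
                fi, n_missing = float(row["fi"]), 0
            rec = dict(row)
            rec["fi"] = fi
            rec["n_missing"] = n_missing
            rec["category"] = categorize_fi(fi).value
            rec["frail"] = dichotomize_fi(fi).value == "FRAIL"
            rows.append(rec)
        except (CodingError, IncomputableScoreError, ValidationError, ValueError) as exc:
            errs.append({"subject_id": sid, "error": str(exc)})
    return pd.DataFrame(rows), pd.DataFrame(errs, columns=["subject_id", "error"])


def _float_fmt(precision: int) -> str:
    return f"%.{precision}f"


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis on a cohort file and write the report bundle."""
    config.validate()
    registry = load_registry(config.registry_path) if config.registry_path else default_registry()

    frame = pd.read_csv(config.input_path, na_values=_NA_VALUES, keep_default_na=False)
    if len(frame) == 0 or len(frame.columns) == 0:
        raise ValidationError(f"input {config.input_path!r} contains no records")
    frame = _grade_raw_columns(frame)
    scored, errors = _score_frame(frame, registry, config.min_items)
    if len(frame) and len(errors) / len(frame) > config.max_error_fraction:
        raise ValidationError(
            f"{len(errors)}/{len(frame)} subjects unscorable, above the tolerated "
            f"fraction {config.max_error_fraction}; first error: {errors.iloc[0]['error']}"
        )
    status = "success" if len(errors) == 0 else "partial"

    covariates = config.covariates
    if covariates is None:
        covariates = [c for c in LEVEL_ORDER if c in scored.columns]
    references = {**REFERENCE_LEVELS, **config.references}
    level_order = {**LEVEL_ORDER, **{k: tuple(v) for k, v in config.level_order.items()}}

    # --- cross-tabs with chi-square -------------------------------------
    ct_rows = []
    tables = {}
    notes: list[str] = []
    for cov in covariates:
        table = crosstab(scored, cov, level_order=level_order.get(cov))
        tables[cov] = table
        try:
            chi = chi_square(table)
        except FrailkitError as exc:
            notes.append(f"chi-square for {cov}: {exc}")
            chi = None
        binary = table.binary_counts()
        for lvl, counts in zip(table.levels, table.counts):
            fit_n, frail_n = binary[lvl]
            ct_rows.append(
                {
                    "covariate": cov,
                    "level": lvl,
                    **{cat.lower(): int(c) for cat, c in zip(CATEGORIES, counts)},
                    "fit_binary": fit_n,
                    "frail_binary": frail_n,
                    "total": int(counts.sum()),
                    "chi2": chi.statistic if chi else None,
                    "df": chi.df if chi else None,
                    "p_value": chi.p_value if chi else None,
                    "low_expected": chi.low_expected if chi else None,
                }
            )
    crosstabs_frame = pd.DataFrame(ct_rows)

    # --- odds / logistic table ------------------------------------------
    adjusted = None
    multi_covs = [c for c in covariates if scored[c].nunique() > 1]
    if scored["frail"].nunique() == 2 and multi_covs:
        try:
            adjusted = fit_logistic(
                scored, multi_covs, references=references, level_order=level_order
            )
        except (SeparationError, RankDeficiencyError) as exc:
            notes.append(f"adjusted model not fitted: {exc}")
            status = "partial"
    else:
        notes.append("adjusted model not fitted: outcome or covariates degenerate")

    odds_rows = []
    for cov in covariates:
        table = tables[cov]
        ref = references.get(cov, table.levels[0])
        for lvl in table.levels:
            row = {"covariate": cov, "level": lvl, "reference": lvl == ref}
            if lvl == ref and config.odds_convention == "reference":
                row.update({"unadj_or": None, "unadj_low": None, "unadj_high": None, "unadj_p": None})
            else:
                try:
                    if config.odds_convention == "subgroup":
                        res = subgroup_frailty_odds(table, lvl)
                    else:
                        res = odds_ratio(table, lvl, ref)
                    row.update(
                        {
                            "unadj_or": res.estimate,
                            "unadj_low": res.ci_low,
                            "unadj_high": res.ci_high,
                            "unadj_p": res.p_value,
                        }
                    )
                except FrailkitError as exc:
                    notes.append(f"unadjusted odds for {cov}={lvl}: {exc}")
                    row.update({"unadj_or": None, "unadj_low": None, "unadj_high": None, "unadj_p": None})
            if adjusted is not None and lvl != ref and cov in multi_covs:
                t = adjusted.term(cov, lvl)
                row.update(
                    {"adj_or": t.odds_ratio, "adj_low": t.ci_low, "adj_high": t.ci_high, "adj_p": t.p_value}
                )
            else:
                row.update({"adj_or": None, "adj_low": None, "adj_high": None, "adj_p": None})
            odds_rows.append(row)
    odds_frame = pd.DataFrame(odds_rows)

    # --- prevalence records ---------------------------------------------
    n = len(scored)
    prev_rows = []
    for cat in CATEGORIES:
        k = int((scored["category"] == cat).sum())
        ci = prevalence_ci(k, n, method=config.ci_method)
        prev_rows.append(
            {"group": cat, "k": k, "n": n, "prevalence": ci.estimate, "ci_low": ci.ci_low, "ci_high": ci.ci_high}
        )
    k_frail = int(scored["frail"].sum())
    ci = prevalence_ci(k_frail, n, method=config.ci_method)
    prev_rows.append(
        {"group": "FRAIL", "k": k_frail, "n": n, "prevalence": ci.estimate, "ci_low": ci.ci_low, "ci_high": ci.ci_high}
    )
    prevalence_frame = pd.DataFrame(prev_rows)

    # --- manifest and writing -------------------------------------------
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "n_subjects": n,
        "n_score_errors": len(errors),
        "status": status,
        "notes": notes,
        "resolved_cut_points": {
            "category_cuts": list(CATEGORY_CUTS),
            "binary_cut": BINARY_CUT,
            "allowed_weights": list(ALLOWED_WEIGHTS),
            "bmi_cuts": list(BMI_CUTS),
            "bp_cuts": {k: list(v) for k, v in BP_CUTS.items()},
            "rbs_cuts": list(RBS_CUTS),
            "gds_cuts": list(GDS_CUTS),
        },
    }

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = _float_fmt(config.precision)
    scored.to_csv(out / "scored.csv", index=False)
    crosstabs_frame.to_csv(out / "crosstabs.csv", index=False, float_format=fmt)
    odds_frame.to_csv(out / "odds.csv", index=False, float_format=fmt)
    prevalence_frame.to_csv(out / "prevalence.csv", index=False, float_format=fmt)
    errors.to_csv(out / "errors.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ReportBundle(
        output_dir=out,
        scored=scored,
        crosstabs=crosstabs_frame,
        odds=odds_frame,
        prevalence=prevalence_frame,
        manifest=manifest,
        errors=errors,
        status=status,
    )


def validate_registry(path: str | Path) -> list[str]:
    """Check an item-registry file against the instrument invariants.

    Returns a list of human-readable findings; an empty list means the
    registry is valid.  An unparseable file raises :class:`ValidationError`.
    """
    from .instrument import CodingScheme, DeficitItem, ItemRegistry

    try:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    except (OSError, yaml.YAMLError) as exc:
        raise ValidationError(f"cannot parse registry file {path!r}: {exc}") from exc
    if not isinstance(raw, Mapping) or "items" not in raw:
        raise ValidationError("registry file must contain a top-level 'items' list")

    findings: list[str] = []
    items: list[DeficitItem] = []
    for entry in raw["items"]:
        iid = entry.get("item_id", "?") if isinstance(entry, Mapping) else "?"
        try:
            scheme = CodingScheme(tuple((str(l), float(w)) for l, w in entry["levels"]))
            items.append(
                DeficitItem(
                    item_id=int(entry["item_id"]),
                    name=str(entry["name"]),
                    scheme=scheme,
                    source=str(entry.get("source", "self-report")),
                )
            )
        except (ValidationError, KeyError, TypeError, ValueError) as exc:
            findings.append(f"item {iid}: {exc}")
    if not findings:
        try:
            ItemRegistry(items)
        except ValidationError as exc:
            findings.append(str(exc))
    else:
        ids = [it.item_id for it in items]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            findings.append(f"duplicate item_id: {sorted(dupes)}")
    return findings
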