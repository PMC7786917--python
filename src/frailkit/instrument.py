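"""The 30-item deficit-accumulation frailty instrument (FI-30).

A frailty index is the proportion of age-related health deficits an
individual carries out of the deficits measured.  Each of the 30 items is
coded on [0, 1] — 0 for deficit absent, 1 for fully present, with graded
intermediate weights for partial severity — and the index is

    FI = sum(deficit weights) / (30 - number of missing items),

so a participant missing a handful of items is scored on the deficits
actually observed.  Severity is read off the index with the conventional
cut points 0.12 / 0.24 / 0.36 (fit, mild, moderate, severe), and the
binary fit/frail outcome used for risk modelling splits at FI = 0.24.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import CodingError, DomainError, IncomputableScoreError, ValidationError

__all__ = [
    "ALLOWED_WEIGHTS",
    "MISSING",
    "N_ITEMS",
    "CodingScheme",
    "DeficitItem",
    "ItemRegistry",
    "FrailtyScore",
    "FrailtyCategory",
    "FrailtyBinary",
    "FrailtyResult",
    "code_item",
    "compute_fi",
    "categorize_fi",
    "dichotomize_fi",
    "default_registry",
    "load_registry",
    "score_responses",
    "score_table",
]

#: Deficit grades the instrument admits. 0/1 encode absence/presence of a
#: binary deficit; 0.25, 0.33, 0.5, 0.66 and 0.75 are the partial-severity
#: grades used by ordinal items.
ALLOWED_WEIGHTS: tuple[float, ...] = (0.0, 0.25, 0.33, 0.5, 0.66, 0.75, 1.0)

#: Sentinel for a missing item response.
MISSING = None

N_ITEMS = 30

#: Severity cut points: fit <= 0.12 < mild <= 0.24 < moderate <= 0.36 < severe.
CATEGORY_CUTS: tuple[float, float, float] = (0.12, 0.24, 0.36)

#: Binary fit/frail split.
BINARY_CUT: float = 0.24

_WEIGHT_TOL = 1e-9


def _is_allowed_weight(w: float) -> bool:
    return any(abs(w - a) <= _WEIGHT_TOL for a in ALLOWED_WEIGHTS)


@dataclass(frozen=True)
class CodingScheme:
    """Ordered mapping from response labels to deficit weights.

    Weights must be strictly increasing, start at 0, end at 1, and lie on
    the admitted grade set (0, 0.25, 0.33, 0.5, 0.66, 0.75, 1).
    """

    levels: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValidationError("a coding scheme needs at least two levels")
        weights = [w for _, w in self.levels]
        if any(b <= a for a, b in zip(weights, weights[1:])):
            raise ValidationError(f"weights must be strictly increasing: {weights}")
        if abs(weights[0]) > _WEIGHT_TOL:
            raise ValidationError("first weight must be 0 (deficit absent)")
        if abs(weights[-1] - 1.0) > _WEIGHT_TOL:
            raise ValidationError("last weight must be 1 (deficit fully present)")
        for w in weights:
            if not _is_allowed_weight(w):
                raise ValidationError(
                    f"weight {w} outside the admitted grade set {ALLOWED_WEIGHTS}"
                )
        labels = [lbl.strip().casefold() for lbl, _ in self.levels]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate labels in coding scheme")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.levels)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.levels)

    def weight_for(self, label: str) -> float:
        """Look up a label, case-insensitively and ignoring surrounding space."""
        key = label.strip().casefold()
        for lbl, w in self.levels:
            if lbl.strip().casefold() == key:
                return w
        raise KeyError(label)

    def label_for(self, weight: float) -> str:
        for lbl, w in self.levels:
            if abs(w - weight) <= _WEIGHT_TOL:
                return lbl
        raise KeyError(weight)


@dataclass(frozen=True)
class DeficitItem:
    """One instrument item: identifier, name, coding scheme and data source."""

    item_id: int
    name: str
    scheme: CodingScheme
    source: str = "self-report"

    _SOURCES = ("self-report", "biomarker", "performance")

    def __post_init__(self) -> None:
        if self.source not in self._SOURCES:
            raise ValidationError(
                f"item {self.item_id}: source {self.source!r} not in {self._SOURCES}"
            )


class ItemRegistry:
    """The ordered collection of the instrument's deficit items."""

    def __init__(self, items: Iterable[DeficitItem], n_items: int = N_ITEMS):
        self._items = tuple(items)
        self.n_items = n_items
        findings = self.validate()
        if findings:
            raise ValidationError("; ".join(findings))
        self._by_id = {it.item_id: it for it in self._items}
        self._by_name = {it.name: it for it in self._items}

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        findings: list[str] = []
        ids = [it.item_id for it in self._items]
        if sorted(ids) != list(range(1, self.n_items + 1)):
            findings.append(
                f"item_ids must be exactly 1..{self.n_items}; got {sorted(set(ids))}"
            )
        if len(set(ids)) != len(ids):
            findings.append("duplicate item_id in registry")
        names = [it.name for it in self._items]
        if len(set(names)) != len(names):
            findings.append("duplicate item name in registry")
        return findings

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)

    def __getitem__(self, key: int | str) -> DeficitItem:
        if isinstance(key, str):
            return self._by_name[key]
        return self._by_id[key]

    @property
    def items(self) -> tuple[DeficitItem, ...]:
        return self._items

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self._items)


def load_registry(path) -> ItemRegistry:
    """Load an item registry from a YAML file and validate its invariants."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _registry_from_mapping(raw)


def _registry_from_mapping(raw: Mapping) -> ItemRegistry:
    try:
        entries = raw["items"]
    except (TypeError, KeyError) as exc:
        raise ValidationError("registry file must contain a top-level 'items' list") from exc
    items = []
    for entry in entries:
        scheme = CodingScheme(tuple((str(l), float(w)) for l, w in entry["levels"]))
        items.append(
            DeficitItem(
                item_id=int(entry["item_id"]),
                name=str(entry["name"]),
                scheme=scheme,
                source=str(entry.get("source", "self-report")),
            )
        )
    return ItemRegistry(items)


_DEFAULT_REGISTRY: ItemRegistry | None = None


def default_registry() -> ItemRegistry:
    """The shipped 30-item registry (cached)."""
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        ref = resources.files("frailkit").joinpath("data/registry.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        _DEFAULT_REGISTRY = _registry_from_mapping(raw)
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# scoring


def _is_missing(value: object) -> bool:
    if value is MISSING:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().upper() in ("", "NA"):
        return True
    return False


def code_item(item: DeficitItem, response: object) -> float | None:
    """Map a raw response to its deficit weight.

    Accepts a response label (matched case-insensitively after trimming) or
    an already-graded numeric weight legal for the item's scheme.  Missing
    responses (None, NaN, "" or "NA") pass through as missing.
    """
    if _is_missing(response):
        return MISSING
    if isinstance(response, str):
        try:
            return item.scheme.weight_for(response)
        except KeyError:
            pass
        # a numeric weight arriving as text ("0.5")
        try:
            response = float(response)
        except ValueError:
            raise CodingError(item.item_id, response, item.scheme.labels) from None
    if isinstance(response, (int, float)) and not isinstance(response, bool):
        for w in item.scheme.weights:
            if abs(float(response) - w) <= _WEIGHT_TOL:
                return w
    raise CodingError(item.item_id, response, item.scheme.labels)


@dataclass(frozen=True)
class FrailtyScore:
    """A computed frailty index with its components."""

    fi: float
    deficit_sum: float
    n_missing: int


class FrailtyCategory(enum.Enum):
    """Four-band severity: fit, mild, moderate or severe frailty."""

    FIT = "FIT"
    MILD = "MILD"
    MODERATE = "MODERATE"
    SEVERE = "SEVERE"


class FrailtyBinary(enum.Enum):
    """Binary outcome for risk modelling: fit (FI <= 0.24) vs frail."""

    FIT = "FIT"
    FRAIL = "FRAIL"


#: Half-open severity bands (lower, upper]; FI = 0 belongs to FIT.
CATEGORY_BANDS: dict[FrailtyCategory, tuple[float, float]] = {
    FrailtyCategory.FIT: (0.0, CATEGORY_CUTS[0]),
    FrailtyCategory.MILD: (CATEGORY_CUTS[0], CATEGORY_CUTS[1]),
    FrailtyCategory.MODERATE: (CATEGORY_CUTS[1], CATEGORY_CUTS[2]),
    FrailtyCategory.SEVERE: (CATEGORY_CUTS[2], 1.0),
}


def compute_fi(
    vector: Mapping[int, float | None] | Sequence[float | None],
    min_items: int = 24,
) -> FrailtyScore:
    """Compute the frailty index from a 30-entry deficit vector.

    ``vector`` maps item_id (1..30) to a deficit weight or missing, or is a
    plain sequence of 30 weights.  Missing items shrink the denominator:
    FI = sum(weights) / (30 - n_missing).  Fewer than ``min_items``
    non-missing entries raises :class:`IncomputableScoreError`; the default
    (24, i.e. 80% completeness) guards against degenerate denominators.
    """
    if isinstance(vector, Mapping):
        values = [vector.get(i, MISSING) for i in range(1, N_ITEMS + 1)]
    else:
        values = list(vector)
        if len(values) != N_ITEMS:
            raise ValidationError(f"deficit vector must have {N_ITEMS} entries, got {len(values)}")
    present = [float(v) for v in values if not _is_missing(v)]
    for v in present:
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"deficit weight {v} outside [0, 1]")
    n_missing = N_ITEMS - len(present)
    if len(present) < min_items:
        raise IncomputableScoreError(
            f"only {len(present)} of {N_ITEMS} items answered; need at least {min_items}"
        )
    deficit_sum = float(sum(present))
    return FrailtyScore(fi=deficit_sum / (N_ITEMS - n_missing), deficit_sum=deficit_sum, n_missing=n_missing)


def categorize_fi(fi: float, cuts: tuple[float, float, float] = CATEGORY_CUTS) -> FrailtyCategory:
    """Assign the four-band severity category; cut points go to the less-severe band."""
    if not 0.0 <= fi <= 1.0:
        raise DomainError(f"frailty index {fi} outside [0, 1]")
    if fi <= cuts[0]:
        return FrailtyCategory.FIT
    if fi <= cuts[1]:
        return FrailtyCategory.MILD
    if fi <= cuts[2]:
        return FrailtyCategory.MODERATE
    return FrailtyCategory.SEVERE


def dichotomize_fi(fi: float, cut: float = BINARY_CUT) -> FrailtyBinary:
    """Collapse the index to the fit/frail binary; the cut point itself is fit."""
    if not 0.0 <= fi <= 1.0:
        raise DomainError(f"frailty index {fi} outside [0, 1]")
    return FrailtyBinary.FIT if fi <= cut else FrailtyBinary.FRAIL


@dataclass(frozen=True)
class FrailtyResult:
    """Full scoring output for one subject."""

    vector: dict[int, float | None]
    score: FrailtyScore
    category: FrailtyCategory
    binary: FrailtyBinary


def score_responses(
    responses: Mapping[int | str, object],
    registry: ItemRegistry | None = None,
    min_items: int = 24,
) -> FrailtyResult:
    """Code one subject's raw responses and score them.

    ``responses`` maps item id or item name to the raw response label (or an
    already-graded weight).  Items absent from the mapping count as missing.
    """
    registry = registry or default_registry()
    vector: dict[int, float | None] = {}
    for item in registry:
        raw = responses.get(item.item_id, responses.get(item.name, MISSING))
        vector[item.item_id] = code_item(item, raw)
    score = compute_fi(vector, min_items=min_items)
    return FrailtyResult(
        vector=vector,
        score=score,
        category=categorize_fi(score.fi),
        binary=dichotomize_fi(score.fi),
    )


def score_table(
    frame: pd.DataFrame,
    registry: ItemRegistry | None = None,
    min_items: int = 24,
) -> pd.DataFrame:
    """Score every row of a response table.

    Item columns are matched by registry name or ``item_<k>``.  Returns a
    copy of ``frame`` with ``fi``, ``deficit_sum``, ``n_missing``,
    ``category`` and ``frail`` columns appended.
    """
    registry = registry or default_registry()
    colmap: dict[int, str] = {}
    for item in registry:
        for cand in (item.name, f"item_{item.item_id}"):
            if cand in frame.columns:
                colmap[item.item_id] = cand
                break
    if not colmap:
        raise ValidationError("no instrument item columns found in the table")
    out = frame.copy()
    fis, sums, miss, cats, frls = [], [], [], [], []
    for _, row in frame.iterrows():
        responses = {iid: row[col] for iid, col in colmap.items()}
        res = score_responses(responses, registry=registry, min_items=min_items)
        fis.append(res.score.fi)
        sums.append(res.score.deficit_sum)
        miss.append(res.score.n_missing)
        cats.append(res.category.value)
        frls.append(res.binary is FrailtyBinary.FRAIL)
    out["fi"] = fis
    out["deficit_sum"] = sums
    out["n_missing"] = miss
    out["category"] = cats
    out["frail"] = frls
    return out
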