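"""Exception hierarchy shared across the package."""


class FrailkitError(Exception):
    """Base class for all package-specific errors."""


class CodingError(FrailkitError):
    """A raw response label could not be mapped to a deficit weight."""

    def __init__(self, item_id: int, label: object, known: tuple[str, ...] = ()):
        self.item_id = item_id
        self.label = label
        msg = f"item {item_id}: unknown response {label!r}"
        if known:
            msg += f" (expected one of {', '.join(known)})"
        super().__init__(msg)


class IncomputableScoreError(FrailkitError):
    """Too few non-missing items to compute a frailty index."""


class DomainError(FrailkitError, ValueError):
    """A numeric argument lies outside its admissible domain."""


class ValidationError(FrailkitError, ValueError):
    """A spec, registry or configuration violates its invariants."""


class DegenerateTableError(FrailkitError):
    """A contingency table has a zero marginal row or column."""


class InfiniteOddsError(FrailkitError):
    """Within-level odds are undefined because the fit cell is empty."""

    def __init__(self, level: str, frail: int, fit: int):
        self.level, self.frail, self.fit = level, frail, fit
        super().__init__(f"level {level!r}: odds undefined (frail={frail}, fit={fit})")


class SeparationError(FrailkitError):
    """The logistic likelihood is unbounded (complete/quasi separation)."""


class RankDeficiencyError(FrailkitError):
    """The logistic design matrix is rank deficient."""


class UndefinedAlphaError(FrailkitError):
    """Cronbach's alpha is undefined (zero total-score variance)."""
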