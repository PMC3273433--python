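"""Descriptive and inferential statistics on cross, fecundity and cytology counts.

Conventions: percentages are rounded half-up (one decimal for progeny-class
frequencies, integer for fertility); the excess-nullo chi-square test is a
Pearson test without continuity correction on the 2x2 table
``[[excess, rest], [excess_control, rest_control]]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

from scipy import stats as sps

from .errors import (
    NegativeExcessWarning,
    SmallExpectedCountWarning,
    UndefinedRateError,
    ValidationError,
)

__all__ = [
    "CrossCounts",
    "FecundityRecord",
    "ExcessNulloResult",
    "CytologyCounts",
    "round_half_up",
    "fertility_percent",
    "class_frequency_percent",
    "excess_nullo",
    "chi_square_excess",
    "chi_square_cytology",
    "fisher_exact_excess",
    "significance_tier",
    "binomial_ci",
]

CYTOLOGY_ENDPOINTS = ("dsb_signal", "karyosome_defect")


def _check_count(value: int, name: str) -> None:
    if not isinstance(value, (int,)) or isinstance(value, bool):
        raise ValidationError(f"{name} must be an integer count, got {value!r}")
    if value < 0:
        raise ValidationError(f"{name} must be non-negative, got {value}")


@dataclass(frozen=True)
class CrossCounts:
    """Scored progeny classes of one cross (one genotype/transgene row)."""

    label: str
    mothers: int
    total_progeny: int
    n_x0: int
    n_xxy: int
    n_other: int = field(default=-1)

    def __post_init__(self) -> None:
        for name in ("mothers", "total_progeny", "n_x0", "n_xxy"):
            _check_count(getattr(self, name), name)
        if self.n_other < 0:  # derive when not supplied
            object.__setattr__(
                self, "n_other", self.total_progeny - self.n_x0 - self.n_xxy
            )
        _check_count(self.n_other, "n_other")
        if self.n_x0 + self.n_xxy + self.n_other != self.total_progeny:
            raise ValidationError(
                f"{self.label}: n_x0 + n_xxy + n_other = "
                f"{self.n_x0 + self.n_xxy + self.n_other} != "
                f"total_progeny = {self.total_progeny}"
            )


@dataclass(frozen=True)
class FecundityRecord:
    """Eggs laid and pupae generated for one cross."""

    label: str
    mothers: int
    eggs: int
    pupae: int

    def __post_init__(self) -> None:
        for name in ("mothers", "eggs", "pupae"):
            _check_count(getattr(self, name), name)
        if self.pupae > self.eggs:
            raise ValidationError(
                f"{self.label}: pupae ({self.pupae}) exceed eggs ({self.eggs})"
            )


@dataclass(frozen=True)
class ExcessNulloResult:
    """Excess nullo-X statistic, optionally with a chi test against a control."""

    label: str
    excess_count: int
    excess_percent: float
    chi2: float | None = None
    p_value: float | None = None
    tier: str | None = None

    def with_test(self, chi2: float, p_value: float) -> "ExcessNulloResult":
        return replace(
            self, chi2=chi2, p_value=p_value, tier=significance_tier(p_value)
        )


@dataclass(frozen=True)
class CytologyCounts:
    """Oocyte nuclei positive for an endpoint out of the total observed."""

    label: str
    endpoint: str
    stage_range: str
    n_positive: int
    n_total: int
    ovaries: int

    def __post_init__(self) -> None:
        for name in ("n_positive", "n_total", "ovaries"):
            _check_count(getattr(self, name), name)
        if self.endpoint not in CYTOLOGY_ENDPOINTS:
            raise ValidationError(
                f"{self.label}: endpoint must be one of {CYTOLOGY_ENDPOINTS}, "
                f"got {self.endpoint!r}"
            )
        if self.n_positive > self.n_total:
            raise ValidationError(
                f"{self.label}: n_positive ({self.n_positive}) exceeds "
                f"n_total ({self.n_total})"
            )


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties away from zero (half-up), e.g. 2.5 -> 3, 0.25 -> 0.3."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def fertility_percent(rec: FecundityRecord) -> tuple[int, float]:
    """Percent of laid eggs that generated pupae.

    Returns ``(rounded, exact)`` where ``rounded`` is the integer half-up
    rounding reported in summary tables.
    """
    if rec.eggs == 0:
        raise UndefinedRateError(f"{rec.label}: fertility undefined for zero eggs")
    exact = 100.0 * rec.pupae / rec.eggs
    return int(round_half_up(exact, 0)), exact


def class_frequency_percent(count: int, total: int, decimals: int = 1) -> float:
    """Progeny-class frequency as a percentage, rounded half-up."""
    _check_count(count, "count")
    if total <= 0:
        raise UndefinedRateError("frequency undefined for zero total")
    if count > total:
        raise ValidationError(f"count ({count}) exceeds total ({total})")
    return round_half_up(100.0 * count / total, decimals)


def excess_nullo(counts: CrossCounts) -> ExcessNulloResult:
    """Nullo-X count minus diplo-X count, signed, with its percent of progeny.

    A surplus of X0 sons over XXY daughters indicates chromosome loss on top
    of (symmetric) nondisjunction.  Negative excess is reported signed with a
    warning.
    """
    if counts.total_progeny == 0:
        raise UndefinedRateError(f"{counts.label}: no progeny scored")
    excess = counts.n_x0 - counts.n_xxy
    if excess < 0:
        warnings.warn(
            f"{counts.label}: more XXY daughters ({counts.n_xxy}) than X0 sons "
            f"({counts.n_x0}); excess reported signed",
            NegativeExcessWarning,
            stacklevel=2,
        )
    percent = round_half_up(100.0 * excess / counts.total_progeny, 1)
    return ExcessNulloResult(
        label=counts.label, excess_count=excess, excess_percent=percent
    )


def _pearson_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on [[a, b], [c, d]]."""
    n = a + b + c + d
    if n == 0:
        raise UndefinedRateError("empty contingency table")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if row1 == 0 or row2 == 0:
        raise UndefinedRateError("a row of the contingency table is empty")
    if col1 == 0 or col2 == 0:
        # degenerate margin: both groups identical on this axis
        return 0.0, 1.0
    chi2 = 0.0
    small = False
    for obs, r, c_ in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        expected = r * c_ / n
        if expected < 5:
            small = True
        chi2 += (obs - expected) ** 2 / expected
    if small:
        warnings.warn(
            "chi-square table has an expected cell < 5; consider the Fisher "
            "exact p reported by fisher_exact_excess",
            SmallExpectedCountWarning,
            stacklevel=3,
        )
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def chi_square_excess(test: CrossCounts, control: CrossCounts) -> tuple[float, float]:
    """Chi test of the excess-nullo statistic of a cross against a control.

    The 2x2 table is ``[[excess, total - excess]]`` for each cross; Pearson,
    df = 1, no continuity correction.
    """
    rows = []
    for counts in (test, control):
        if counts.total_progeny == 0:
            raise UndefinedRateError(f"{counts.label}: no progeny scored")
        excess = counts.n_x0 - counts.n_xxy
        if excess < 0:
            warnings.warn(
                f"{counts.label}: negative excess ({excess}) entered into chi test",
                NegativeExcessWarning,
                stacklevel=2,
            )
        rows.append((excess, counts.total_progeny - excess))
    (a, b), (c, d) = rows
    return _pearson_2x2(a, b, c, d)


def fisher_exact_excess(test: CrossCounts, control: CrossCounts) -> float:
    """Fisher exact p on the same 2x2 table as :func:`chi_square_excess`.

    Reported alongside (never substituted for) the chi test when expected
    cells are small.
    """
    a = test.n_x0 - test.n_xxy
    c = control.n_x0 - control.n_xxy
    if a < 0 or c < 0:
        raise ValidationError("Fisher exact requires non-negative excess counts")
    table = [[a, test.total_progeny - a], [c, control.total_progeny - c]]
    return float(sps.fisher_exact(table)[1])


def chi_square_cytology(
    test: CytologyCounts, control: CytologyCounts
) -> tuple[float, float]:
    """Chi test of positive-nucleus proportions between two genotypes."""
    for counts in (test, control):
        if counts.n_total == 0:
            raise UndefinedRateError(f"{counts.label}: no nuclei observed")
    return _pearson_2x2(
        test.n_positive,
        test.n_total - test.n_positive,
        control.n_positive,
        control.n_total - control.n_positive,
    )


def significance_tier(p_value: float) -> str:
    """Map a p-value to the tier labels ***, **, * or ns.

    Boundaries: p < 1e-3 -> ``***``; 1e-3 <= p < 1e-2 -> ``**``;
    1e-2 <= p < 5e-2 -> ``*``; otherwise ``ns``.
    """
    if math.isnan(p_value) or not (0.0 <= p_value <= 1.0):
        raise ValidationError(f"p-value must lie in [0, 1], got {p_value!r}")
    if p_value < 1e-3:
        return "***"
    if p_value < 1e-2:
        return "**"
    if p_value < 5e-2:
        return "*"
    return "ns"


def binomial_ci(
    count: int, total: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    _check_count(count, "count")
    if total <= 0:
        raise UndefinedRateError("interval undefined for zero total")
    if count > total:
        raise ValidationError(f"count ({count}) exceeds total ({total})")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level must lie in (0, 1), got {level}")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    p_hat = count / total
    denom = 1.0 + z * z / total
    center = (p_hat + z * z / (2 * total)) / denom
    half = (
        z
        * math.sqrt(p_hat * (1.0 - p_hat) / total + z * z / (4.0 * total * total))
        / denom
    )
    # analytic boundary values, immune to float round-off
    lower = 0.0 if count == 0 else max(0.0, center - half)
    upper = 1.0 if count == total else min(1.0, center + half)
    return lower, upper
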