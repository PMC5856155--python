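"""GUM-style uncertainty budget with expanded uncertainty U.

Each uncertainty source carries a raw figure (mm, or percent of the
measurand length), a distribution type, and a conversion coefficient to a
standard deviation: ``1/sqrt(3)`` for rectangular full-width figures,
``1/sqrt(6)`` for triangular, 1 for normal.  Uncorrelated sources combine
by root sum of squares and the expanded uncertainty is

    U = k * sqrt(sum_i (t_i * s_i)^2)

with coverage factor ``k = 1.645`` for a 90% two-sided confidence level.
Averaging n repeated measurements divides random (non-systematic) source
figures by sqrt(n); alignment-type (Abbe) sources are systematic and exempt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import yaml
from scipy.stats import norm

__all__ = [
    "UncertaintySource", "UncertaintyBudget", "standard_uncertainty",
    "scale_for_repeats", "expanded_uncertainty", "coverage_factor",
    "load_budget", "available_budgets", "round_half_up",
]

_T_COEFF = {
    "rectangular": 1.0 / math.sqrt(3.0),
    "triangular": 1.0 / math.sqrt(6.0),
    "normal": 1.0,
}


def coverage_factor(confidence: float = 0.90) -> float:
    """Two-sided normal coverage factor for a confidence level (k = 1.645 at 90%)."""
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return float(norm.ppf(0.5 + confidence / 2.0))


@dataclass(frozen=True)
class UncertaintySource:
    """One budget row: raw figure, distribution and conversion behaviour."""

    name: str
    value: float                    # mm, or percent when ``percent`` is True
    distribution: str = "normal"
    percent: bool = False
    systematic: bool = False

    def __post_init__(self):
        if self.distribution not in _T_COEFF:
            raise ValueError(
                f"unknown distribution {self.distribution!r}; "
                f"expected one of {sorted(_T_COEFF)}"
            )
        if self.value < 0:
            raise ValueError("source value must be non-negative")

    @property
    def t(self) -> float:
        """Conversion coefficient to a standard deviation."""
        return _T_COEFF[self.distribution]


def standard_uncertainty(source: UncertaintySource, measurand_length: float | None = None,
                         ) -> float:
    """Standard uncertainty in mm: ``t * value``, percent sources resolved
    against the measurand length."""
    value = source.value
    if source.percent:
        if measurand_length is None or measurand_length <= 0:
            raise ValueError(
                f"percent source {source.name!r} needs a positive measurand length"
            )
        value = value / 100.0 * measurand_length
    return source.t * value


def scale_for_repeats(source: UncertaintySource, n: int) -> UncertaintySource:
    """Source figure after averaging n repeats: value / sqrt(n).

    Systematic sources (e.g. Abbe misalignment) do not average out and are
    returned unchanged.
    """
    if n < 1:
        raise ValueError("repeat count must be >= 1")
    if source.systematic or n == 1:
        return source
    return replace(source, value=source.value / math.sqrt(n))


@dataclass
class UncertaintyBudget:
    """A set of uncorrelated sources with coverage factor and measurand."""

    sources: list[UncertaintySource]
    k: float = 1.645
    measurand_length: float = 2000.0
    n_repeats: int = 1

    def __post_init__(self):
        if not self.sources:
            raise ValueError("budget needs at least one source")

    def standard_uncertainties(self) -> dict[str, float]:
        return {
            s.name: standard_uncertainty(s, self.measurand_length)
            for s in self.sources
        }

    @property
    def combined(self) -> float:
        """Combined standard uncertainty (root sum of squares), mm."""
        return math.sqrt(sum(v ** 2 for v in self.standard_uncertainties().values()))

    @property
    def U(self) -> float:
        """Expanded uncertainty, mm."""
        return self.k * self.combined

    def for_repeats(self, n: int) -> "UncertaintyBudget":
        return UncertaintyBudget(
            sources=[scale_for_repeats(s, n) for s in self.sources],
            k=self.k, measurand_length=self.measurand_length, n_repeats=n,
        )


def expanded_uncertainty(budget: UncertaintyBudget) -> float:
    """U = k * sqrt(sum (t_i s_i)^2) over the budget's sources, mm."""
    return budget.U


def _load_raw():
    with resources.files("bovimetry.data").joinpath("budgets.yaml").open() as fh:
        return yaml.safe_load(fh)


def available_budgets() -> list[str]:
    return sorted(_load_raw()["budgets"])


def load_budget(name: str, end: str = "upper", measurand_length: float = 2000.0,
                k: float | None = None) -> UncertaintyBudget:
    """Packaged default budget ("manual", "kinect-1", "kinect-10").

    ``end`` selects the lower or upper end of each source's range over the
    working-distance span; the default measurand length of 2000 mm is the
    worst-case body measurement.
    """
    raw = _load_raw()
    if name not in raw["budgets"]:
        raise KeyError(f"unknown budget {name!r}; available: {available_budgets()}")
    if end not in ("lower", "upper"):
        raise ValueError("end must be 'lower' or 'upper'")
    idx = 0 if end == "lower" else 1
    sources = [
        UncertaintySource(
            name=row["name"], value=float(row["value"][idx]),
            distribution=row["distribution"], percent=bool(row.get("percent", False)),
            systematic=bool(row.get("systematic", False)),
        )
        for row in raw["budgets"][name]
    ]
    return UncertaintyBudget(
        sources=sources, k=float(k if k is not None else raw["coverage_factor"]),
        measurand_length=measurand_length,
        n_repeats=10 if name.endswith("-10") else 1,
    )


def round_half_up(value: float, decimals: int = 1) -> float:
    """Report-table rounding (half away from zero), e.g. 0.759 -> 0.8."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5) / factor, value)
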