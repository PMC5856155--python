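"""Assessment of sensor-derived against reference (manual or ground-truth)
body measurements: per-parameter linear regression, deviations, and error
bars sized by the expanded uncertainty of the matching budget.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .uncertainty import UncertaintyBudget

__all__ = [
    "RegressionResult", "linear_regression", "deviation_percent",
    "assessment_report", "DegenerateRegressionError", "JoinError",
]


class DegenerateRegressionError(ValueError):
    pass


class JoinError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionResult:
    """OLS of measured on reference: slope, intercept (mm), R^2, residual sd."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float

    def as_dict(self) -> dict:
        return asdict(self)


def linear_regression(reference, measured) -> RegressionResult:
    """Ordinary least squares of measured (y) on reference (x).

    ``R^2 = 1 - SS_res / SS_tot``; a constant reference leaves the slope
    undetermined and raises.
    """
    x = np.asarray(reference, float)
    y = np.asarray(measured, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("reference and measured must be equal-length 1-D, n >= 2")
    if np.ptp(x) == 0:
        raise DegenerateRegressionError("constant reference: regression undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    dof = max(len(x) - 2, 1)
    return RegressionResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), n=len(x),
        residual_sd=float(np.sqrt(ss_res / dof)),
    )


def deviation_percent(reference: float, measured: float) -> float:
    """Absolute deviation of measured from reference, percent of reference."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * abs(measured - reference) / abs(reference)


def assessment_report(reference: pd.DataFrame, extracted: pd.DataFrame,
                      reference_budget: UncertaintyBudget | None = None,
                      extracted_budget: UncertaintyBudget | None = None,
                      ) -> dict:
    """Per-parameter comparison of two long-format measurement tables.

    Both tables need columns (animal_id, parameter, value); rows are joined
    on (animal_id, parameter).  Returns ``{"per_parameter": DataFrame,
    "per_animal": DataFrame}`` where the per-parameter table carries the
    regression statistics and mean absolute deviation, and the per-animal
    table each matched pair with its percent deviation and error bars (the
    expanded uncertainty of the corresponding budget, resolved against the
    reference value for percent sources).
    """
    need = {"animal_id", "parameter", "value"}
    for tag, tbl in (("reference", reference), ("extracted", extracted)):
        missing = need - set(tbl.columns)
        if missing:
            raise ValueError(f"{tag} table lacks columns {sorted(missing)}")
    merged = reference.merge(
        extracted, on=["animal_id", "parameter"], suffixes=("_ref", "_meas"),
        how="outer", indicator=True,
    )
    orphans = merged[merged["_merge"] != "both"]
    if len(orphans) == len(merged):
        raise JoinError("no matching (animal_id, parameter) pairs between tables")
    if len(orphans):
        raise JoinError(
            "unmatched rows: "
            + ", ".join(f"{r.animal_id}/{r.parameter}" for r in orphans.itertuples())
        )

    def bar(budget, length):
        if budget is None:
            return np.nan
        scaled = UncertaintyBudget(
            sources=budget.sources, k=budget.k,
            measurand_length=abs(float(length)) if length else budget.measurand_length,
            n_repeats=budget.n_repeats,
        )
        return scaled.U

    rows = []
    for r in merged.itertuples():
        rows.append({
            "animal_id": r.animal_id, "parameter": r.parameter,
            "reference": r.value_ref, "measured": r.value_meas,
            "deviation_percent": (
                deviation_percent(r.value_ref, r.value_meas)
                if r.value_ref != 0 else np.nan
            ),
            "U_reference": bar(reference_budget, r.value_ref),
            "U_measured": bar(extracted_budget, r.value_ref),
        })
    per_animal = pd.DataFrame(rows)

    stats_rows = []
    for param, grp in per_animal.groupby("parameter", sort=True):
        try:
            reg_dict = linear_regression(grp["reference"], grp["measured"]).as_dict()
        except DegenerateRegressionError:
            reg_dict = {"slope": np.nan, "intercept": np.nan,
                        "r_squared": np.nan, "n": len(grp),
                        "residual_sd": float(grp["measured"].std(ddof=1))}
        stats_rows.append({
            "parameter": param, **reg_dict,
            "mean_deviation_percent": float(grp["deviation_percent"].mean()),
            "max_deviation_percent": float(grp["deviation_percent"].max()),
        })
    return {"per_parameter": pd.DataFrame(stats_rows), "per_animal": per_animal}


def plot_assessment(report: dict, path_prefix: str) -> list[str]:
    """Scatter plots with error bars, one file per parameter (inspection only)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    files = []
    for param, grp in report["per_animal"].groupby("parameter"):
        fig, ax = plt.subplots(figsize=(4, 4))
        ax.errorbar(grp["reference"], grp["measured"],
                    xerr=grp["U_reference"], yerr=grp["U_measured"],
                    fmt="o", ms=3, lw=0.8, capsize=2)
        lims = [min(grp["reference"].min(), grp["measured"].min()),
                max(grp["reference"].max(), grp["measured"].max())]
        ax.plot(lims, lims, "k--", lw=0.7)
        ax.set_xlabel(f"reference {param}")
        ax.set_ylabel(f"measured {param}")
        row = report["per_parameter"].set_index("parameter").loc[param]
        ax.set_title(f"{param}: R²={row.r_squared:.3f}, m={row.slope:.3f}")
        fname = f"{path_prefix}_{param}.png"
        fig.tight_layout()
        fig.savefig(fname, dpi=120)
        plt.close(fig)
        files.append(fname)
    return files
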