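"""Cohort summaries and per-timepoint group comparisons of SUV series.

The comparison mirrors the study design: a one-way ANOVA across VOI
classes at each time point, followed by pairwise two-sample tests of
the affected joint against each other class, with Sidak adjustment over
the pairs tested at that time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "summarize",
    "anova_oneway",
    "sidak_adjust",
    "significance_stars",
    "compare_voi_classes",
    "load_cohort_table",
]


def summarize(values: Sequence[float]) -> dict[str, float]:
    """Mean, sample SD (n-1 denominator), min and max of a numeric list."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("summarize requires at least one value")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return {"mean": float(arr.mean()), "sd": sd,
            "min": float(arr.min()), "max": float(arr.max()),
            "n": int(arr.size)}


def anova_oneway(groups: Sequence[Sequence[float]]) -> dict[str, float]:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Requires >= 2 groups with >= 2 values each.  Identical groups give
    F = 0, p = 1.
    """
    if len(groups) < 2:
        raise InvalidInputError("ANOVA requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("every group needs at least 2 values")
    f, p = stats.f_oneway(*arrays)
    return {"F": float(f), "p": float(p)}


def sidak_adjust(p_values: Iterable[float], m: int) -> np.ndarray:
    """Sidak correction for m comparisons: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(list(p_values), dtype=float)
    if m < 1:
        raise InvalidInputError("m must be >= 1")
    if np.any((p < 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # log1p(-1) = -inf at p = 1 is fine
        return np.clip(-np.expm1(m * np.log1p(-p)), 0.0, 1.0)


def significance_stars(p: float) -> str:
    """Star rendering used in the uptake figures."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Omnibus + Sidak-adjusted pairwise results, one row per pair per
    time point."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_voi_classes(suv_table: pd.DataFrame,
                        value_col: str = "suv_max",
                        reference_class: str = "affected-joint") -> GroupComparison:
    """Per-timepoint ANOVA across VOI classes with pairwise follow-up.

    ``suv_table`` must have columns ``voi_class``, ``time_min`` and
    ``value_col``, with one row per subject per class per time point.
    At each time point the omnibus one-way ANOVA is computed across all
    classes, then the reference class is compared with every other class
    by a pooled-variance two-sample t test; those p-values are Sidak
    adjusted over the number of pairs at that time point.
    """
    need = {"voi_class", "time_min", value_col}
    if not need.issubset(suv_table.columns):
        raise InvalidInputError(f"suv_table must have columns {sorted(need)}")
    rows = []
    for t, sub in suv_table.groupby("time_min"):
        classes = sorted(sub["voi_class"].unique())
        if reference_class not in classes or len(classes) < 2:
            continue
        groups = {c: sub.loc[sub["voi_class"] == c, value_col].to_numpy()
                  for c in classes}
        omni = anova_oneway(list(groups.values()))
        others = [c for c in classes if c != reference_class]
        raw = []
        for c in others:
            tt = stats.ttest_ind(groups[reference_class], groups[c], equal_var=True)
            raw.append(float(tt.pvalue))
        adj = sidak_adjust(raw, m=len(others))
        for c, p_raw, p_adj in zip(others, raw, adj):
            rows.append({
                "time_min": t,
                "pair": f"{reference_class} vs {c}",
                "mean_diff": float(groups[reference_class].mean() - groups[c].mean()),
                "F_omnibus": omni["F"],
                "p_omnibus": omni["p"],
                "p_raw": p_raw,
                "p_sidak": float(p_adj),
                "stars": significance_stars(float(p_adj)),
            })
    return GroupComparison(table=pd.DataFrame(rows))


def load_cohort_table(group: str = "healthy") -> pd.DataFrame:
    """Bundled subject-characteristics tables: 'healthy' (6 volunteers)
    or 'suspected-infection' (5 patients)."""
    fname = {"healthy": "healthy_cohort.csv",
             "suspected-infection": "infection_cohort.csv"}.get(group)
    if fname is None:
        raise InvalidInputError(f"unknown cohort group {group!r}")
    path = resources.files("petquant.data").joinpath(fname)
    return pd.read_csv(path)
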