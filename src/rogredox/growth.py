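"""Root growth rates, treatment-relative growth and recovery assessment.

A growth rate is the per-seedling length increment over an interval divided
by the elapsed time in days, aggregated per treatment as mean +/- SEM.
Treated growth is expressed as a percentage of the control rate on the same
interval; "recovery to control levels" is operationalised as Tukey HSD
non-significance versus the control group at alpha = 0.01 on that interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import RootLengthTable
from .stats import TukeyResult, anova_tukey

__all__ = ["GrowthResult", "growth_rate", "relative_growth", "assess_recovery"]


@dataclass
class GrowthResult:
    """Per-seedling and per-treatment growth rates for one interval."""

    interval: tuple[float, float]
    per_seedling: pd.DataFrame   # treatment, seedling_id, rate_mm_d
    per_treatment: pd.DataFrame  # treatment, rate_mean, rate_sem, n
    tukey: TukeyResult | None = None

    def rate(self, treatment: str) -> float:
        row = self.per_treatment[self.per_treatment.treatment == treatment]
        if row.empty:
            raise InputError(f"no treatment {treatment!r} in growth result")
        return float(row["rate_mean"].iloc[0])


def _concat(tables: RootLengthTable | list[RootLengthTable]) -> pd.DataFrame:
    if isinstance(tables, RootLengthTable):
        return tables.df
    return pd.concat([t.df for t in tables], ignore_index=True)


def growth_rate(table: RootLengthTable | list[RootLengthTable],
                interval: tuple[float, float], *,
                compare: bool = False, alpha: float = 0.01) -> GrowthResult:
    """Per-treatment growth rate mean +/- SEM on one interval.

    Raises :class:`InputError` naming the seedlings for which either
    endpoint of the interval is missing.  With ``compare=True`` (and at
    least two treatments) an ANOVA + Tukey comparison across treatments is
    attached.
    """
    t0, t1 = interval
    if not t1 > t0:
        raise InputError(f"interval must satisfy t1 > t0, got {interval}")
    df = _concat(table)
    wide = df.pivot_table(index=["treatment", "seedling_id"], columns="time_h",
                          values="length_mm")
    for t in (t0, t1):
        if t not in wide.columns:
            raise InputError(f"no measurements at {t} h in the table")
    missing = wide.index[wide[[t0, t1]].isna().any(axis=1)].tolist()
    if missing:
        raise InputError(f"seedlings missing a {t0} or {t1} h measurement: {missing}")

    days = (t1 - t0) / 24.0
    per = wide.reset_index()
    per["rate_mm_d"] = (per[t1] - per[t0]) / days
    per = per[["treatment", "seedling_id", "rate_mm_d"]]

    agg = (per.groupby("treatment", as_index=False)
           .agg(rate_mean=("rate_mm_d", "mean"),
                rate_sem=("rate_mm_d", lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0),
                n=("rate_mm_d", "size")))

    tukey = None
    if compare and agg.shape[0] >= 2:
        groups = [grp["rate_mm_d"].to_numpy() for _, grp in per.groupby("treatment")]
        labels = sorted(per["treatment"].unique())
        tukey = anova_tukey(groups, labels=labels, alpha=alpha)
    return GrowthResult((t0, t1), per, agg, tukey)


def relative_growth(result: GrowthResult, control_label: str = "control") -> pd.DataFrame:
    """Add ``relative_to_control_pct`` = 100 * treated rate / control rate."""
    control = result.rate(control_label)
    if control <= 0:
        raise InputError(f"control rate is {control}; relative growth undefined")
    out = result.per_treatment.copy()
    out["relative_to_control_pct"] = 100.0 * out["rate_mean"] / control
    return out


def assess_recovery(result: GrowthResult, control_label: str = "control") -> pd.DataFrame:
    """Flag treatments whose rate is Tukey-indistinguishable from control.

    Requires the result to carry a Tukey comparison (``compare=True``).
    """
    if result.tukey is None:
        raise InputError("growth result has no Tukey comparison; rerun with compare=True")
    rel = relative_growth(result, control_label)
    rel["recovered"] = [
        t == control_label or not result.tukey.is_significant(t, control_label)
        for t in rel["treatment"]
    ]
    return rel
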