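"""Physiology utilities: specific growth rate and qPCR relative expression.

Small closed-form helpers that accompany the methylome pipeline: the
exponential specific growth rate mu = (ln OD2 - ln OD1) / (T2 - T1) from
optical-density endpoints, a Welch two-sample comparison of per-replicate
growth rates, and the 2^-ddCT relative-expression statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GrowthSeries:
    """Optical-density time course, one column of ODs per replicate.

    ``data`` is a long-format DataFrame(replicate, day, od) with strictly
    positive ODs and strictly increasing days within each replicate.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.data["od"] <= 0).any():
            raise ValueError("OD readings must be positive")
        for rep, grp in self.data.groupby("replicate"):
            days = grp["day"].to_numpy()
            if not (np.diff(days) > 0).all():
                raise ValueError(f"days must be strictly increasing (replicate {rep!r})")

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    def endpoint_rates(self) -> np.ndarray:
        """Per-replicate mu from the first and last time points."""
        rates = []
        for _, grp in self.data.sort_values("day").groupby("replicate"):
            first, last = grp.iloc[0], grp.iloc[-1]
            rates.append(
                specific_growth_rate(first["od"], last["od"], first["day"], last["day"])
            )
        return np.array(rates)


def specific_growth_rate(od1: float, od2: float, t1: float, t2: float) -> float:
    """mu = (ln OD2 - ln OD1) / (T2 - T1), per day."""
    if od1 <= 0 or od2 <= 0:
        raise ValueError("optical densities must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (math.log(od2) - math.log(od1)) / (t2 - t1)


def ddct_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    ddCT = (CT_target - CT_reference)_sample - (CT_target - CT_reference)_calibrator.
    """
    for ct in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not math.isfinite(ct):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_calibrator - ct_ref_calibrator)
    return 2.0 ** (-ddct)


def growth_rate_compare(series_a: GrowthSeries, series_b: GrowthSeries) -> dict:
    """Welch t-test comparison of endpoint growth rates between two cultures.

    Returns per-group mean and SD of mu plus the two-sided p-value.  With
    zero variance in both groups and equal means the t statistic is 0/0; the
    p-value is reported as NaN in that case.
    """
    mu_a, mu_b = series_a.endpoint_rates(), series_b.endpoint_rates()
    if len(mu_a) < 2 or len(mu_b) < 2:
        raise ValueError("need at least two replicates per group")
    t, p = stats.ttest_ind(mu_a, mu_b, equal_var=False)
    return {
        "mu_a_mean": float(np.mean(mu_a)),
        "mu_a_sd": float(np.std(mu_a, ddof=1)),
        "mu_b_mean": float(np.mean(mu_b)),
        "mu_b_sd": float(np.std(mu_b, ddof=1)),
        "t_statistic": float(t),
        "p_value": float(p),
    }


def read_growth_table(path) -> GrowthSeries:
    """Read a long-format TSV with columns replicate, day, od."""
    df = pd.read_csv(path, sep="\t")
    missing = {"replicate", "day", "od"} - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    return GrowthSeries(df)
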