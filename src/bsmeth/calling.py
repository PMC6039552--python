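"""Methylcytosine site calling from bisulfite read counts.

The null hypothesis at each cytosine is that every methylated-looking read is
a bisulfite non-conversion artifact: with non-conversion rate ``R`` the
methylated-read count at an unmethylated site is Binomial(n, R).  A site is
called methylated (an "mC site") when its one-sided upper-tail binomial
p-value survives Benjamini-Hochberg FDR control (q <= 0.05 by default) and
its coverage is at least 5 reads.

Methylation levels are the fraction of methylated reads, corrected for
non-conversion by inverting the error model:

    ML = (ML_uncorrected - R) / (1 - R),   clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_COVERAGE = 5
DEFAULT_Q_MAX = 0.05

#: columns appended to a counts table by :func:`call_sites`
CALL_COLUMNS = ["coverage", "p_value", "q_value", "ml_uncorrected", "ml_corrected", "is_mc"]


@dataclass(frozen=True)
class ConversionEstimate:
    """Pooled non-conversion rate from an unmethylated spike-in control."""

    r: float
    n_control: int
    k_control: int

    def __post_init__(self) -> None:
        if self.n_control <= 0:
            raise ValueError("control must contain at least one read observation")
        if not 0.0 <= self.r < 1.0:
            raise ValueError(f"non-conversion rate outside [0, 1): {self.r}")

    @property
    def conversion_rate_pct(self) -> float:
        """Bisulfite conversion rate in percent (100 * (1 - R))."""
        return 100.0 * (1.0 - self.r)


def estimate_nonconversion(control_counts: pd.DataFrame) -> ConversionEstimate:
    """Estimate R by pooling all reads of the unmethylated control.

    R = (methylated reads) / (total reads) over every control cytosine.
    """
    if len(control_counts) == 0:
        raise ValueError("empty control counts table")
    k = int(control_counts["count_methylated"].sum())
    n = k + int(control_counts["count_unmethylated"].sum())
    if n == 0:
        raise ValueError("control table has zero total coverage")
    return ConversionEstimate(r=k / n, n_control=n, k_control=k)


def binomial_pvalue(k: int, n: int, r: float) -> float:
    """Exact one-sided upper-tail binomial p-value P(X >= k | X ~ Bin(n, r))."""
    if not 0.0 <= r < 1.0:
        raise ValueError(f"rate must be in [0, 1), got {r}")
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, r))


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def methylation_level(k: int, n: int, r: float) -> tuple[float, float]:
    """(uncorrected, corrected) methylation level at a site.

    Uncorrected level is k/n; the corrected level subtracts the
    non-conversion background, (k/n - R)/(1 - R), clamped to [0, 1].
    """
    if n < 1:
        raise ValueError("coverage must be >= 1 to compute a level")
    ml_unc = k / n
    ml_cor = float(np.clip((ml_unc - r) / (1.0 - r), 0.0, 1.0))
    return ml_unc, ml_cor


def call_sites(
    counts: pd.DataFrame,
    r: float | ConversionEstimate,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    q_max: float = DEFAULT_Q_MAX,
    fdr_universe: str = "min_coverage",
) -> pd.DataFrame:
    """Call mC sites on a cytosine-report counts table.

    Adds p-values for every covered site, BH q-values over the testing
    universe, corrected levels, and the ``is_mc`` flag
    (coverage >= ``min_coverage`` AND q <= ``q_max``).

    ``fdr_universe`` selects which sites enter the BH correction:
    ``"min_coverage"`` (default) restricts it to sites already passing the
    coverage filter; ``"covered"`` uses every site with at least one read.
    Output rows are sorted by (replicon, pos, strand).
    """
    if isinstance(r, ConversionEstimate):
        r = r.r
    if not 0.0 <= r < 1.0:
        raise ValueError(f"non-conversion rate must be in [0, 1), got {r}")
    if fdr_universe not in ("min_coverage", "covered"):
        raise ValueError(f"unknown fdr_universe {fdr_universe!r}")

    calls = counts.sort_values(["replicon", "pos", "strand"], kind="mergesort").reset_index(
        drop=True
    )
    k = calls["count_methylated"].to_numpy()
    n = k + calls["count_unmethylated"].to_numpy()
    calls["coverage"] = n

    covered = n >= 1
    p = np.full(len(calls), np.nan)
    with np.errstate(divide="ignore"):
        p[covered] = stats.binom.sf(k[covered] - 1, n[covered], r)
    p[covered & (k == 0)] = 1.0
    calls["p_value"] = p

    universe = n >= min_coverage if fdr_universe == "min_coverage" else covered
    q = np.full(len(calls), np.nan)
    if universe.any():
        q[universe] = bh_qvalues(p[universe])
    calls["q_value"] = q

    ml_unc = np.full(len(calls), np.nan)
    ml_unc[covered] = k[covered] / n[covered]
    calls["ml_uncorrected"] = ml_unc
    calls["ml_corrected"] = np.clip((ml_unc - r) / (1.0 - r), 0.0, 1.0)

    calls["is_mc"] = (n >= min_coverage) & (q <= q_max)
    return calls


def call_summary(calls: pd.DataFrame) -> dict:
    """Per-context and per-replicon mC totals for reporting."""
    mc = calls[calls["is_mc"]]
    return {
        "n_sites": int(len(calls)),
        "n_mc": int(len(mc)),
        "per_context": mc.groupby("context", observed=True).size().to_dict(),
        "per_replicon": mc.groupby("replicon", observed=True).size().to_dict(),
    }
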