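"""Sliding-window detection of differentially methylated regions (DMRs).

Windows of 200 bp, stepped every 40 bp, pool methylated/unmethylated read
counts over the cytosines covered in both samples; each window's 2x2 table
(sample A vs B, methylated vs unmethylated reads) is tested with Fisher's
exact test, BH-corrected genome wide, and overlapping significant windows of
the same direction are merged into DMRs.  Direction (hyper/hypo) is defined
for the second sample relative to the first, so "hyper" means more
methylated after the treatment when calls are passed as (control, treated).

Genes whose body overlaps a DMR by at least 1 bp are the DMR-related
("differentially methylated") genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calling import DEFAULT_MIN_COVERAGE, DEFAULT_Q_MAX, bh_qvalues
from .genome_io import FeatureTable, Genome

DEFAULT_WINDOW = 200
DEFAULT_STEP = 40
DEFAULT_MIN_SITES = 5
DEFAULT_MIN_DIFF = 0.1

DMR_COLUMNS = [
    "replicon", "start", "end", "direction", "n_windows",
    "p_min", "q_min", "mean_diff", "genes",
]


def tile_windows(replicon_length: int, window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP):
    """(start, end) pairs of full-length sliding windows on one replicon.

    Starts at 0, window, ... with start + window <= length; a trailing
    partial window is never emitted.
    """
    if window < 1 or step < 1 or window < step:
        raise ValueError(f"need window >= step >= 1, got window={window}, step={step}")
    starts = range(0, replicon_length - window + 1, step)
    return [(s, s + window) for s in starts]


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Sums hypergeometric probabilities no larger than the observed table's.
    Degenerate tables (an all-zero margin) return 1 by convention.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass(frozen=True)
class WindowTest:
    """One tested sliding window with its pooled counts and test results."""

    replicon: str
    start: int
    end: int
    n_sites: int
    ka: int
    ua: int
    kb: int
    ub: int
    p_value: float

    @property
    def level_diff(self) -> float:
        """Pooled-level difference, sample B minus sample A."""
        la = self.ka / (self.ka + self.ua) if self.ka + self.ua else np.nan
        lb = self.kb / (self.kb + self.ub) if self.kb + self.ub else np.nan
        return lb - la


def _window_tables(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    genome: Genome,
    window: int,
    step: int,
    min_sites: int,
    min_coverage: int,
) -> pd.DataFrame:
    a = calls_a[calls_a["coverage"] >= min_coverage]
    b = calls_b[calls_b["coverage"] >= min_coverage]
    joined = a.merge(
        b,
        on=["replicon", "pos", "strand"],
        suffixes=("_a", "_b"),
    )
    rows = []
    for rep, length in genome.lengths.items():
        grp = joined[joined["replicon"] == rep].sort_values("pos")
        pos = grp["pos"].to_numpy()
        ka = np.concatenate([[0], np.cumsum(grp["count_methylated_a"].to_numpy())])
        ua = np.concatenate([[0], np.cumsum(grp["count_unmethylated_a"].to_numpy())])
        kb = np.concatenate([[0], np.cumsum(grp["count_methylated_b"].to_numpy())])
        ub = np.concatenate([[0], np.cumsum(grp["count_unmethylated_b"].to_numpy())])
        for start, end in tile_windows(length, window, step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            if hi - lo < min_sites:
                continue
            rows.append(
                {
                    "replicon": rep,
                    "start": start,
                    "end": end,
                    "n_sites": int(hi - lo),
                    "ka": int(ka[hi] - ka[lo]),
                    "ua": int(ua[hi] - ua[lo]),
                    "kb": int(kb[hi] - kb[lo]),
                    "ub": int(ub[hi] - ub[lo]),
                }
            )
    return pd.DataFrame(rows, columns=["replicon", "start", "end", "n_sites", "ka", "ua", "kb", "ub"])


def detect_dmrs(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    genome: Genome,
    features: FeatureTable | None = None,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    q_max: float = DEFAULT_Q_MAX,
    min_sites: int = DEFAULT_MIN_SITES,
    min_diff: float = DEFAULT_MIN_DIFF,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    return_windows: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Detect DMRs between two called samples on the same genome.

    Per window: pool read counts over cytosines covered >= ``min_coverage``
    in both samples; windows with fewer than ``min_sites`` such cytosines are
    not tested.  Fisher two-sided p-values are BH-corrected over all tested
    windows genome-wide; a window is significant when q <= ``q_max`` and its
    pooled-level difference reaches ``min_diff`` in absolute value.
    Overlapping or book-ended significant windows of the same direction merge
    into one DMR.  Returns a DataFrame with :data:`DMR_COLUMNS`; with
    ``return_windows=True`` also returns the full tested-window table
    (pooled counts, p, q, level diff per window).
    """
    for calls, label in ((calls_a, "A"), (calls_b, "B")):
        unknown = set(calls["replicon"]) - set(genome.names)
        if unknown:
            raise ValueError(f"sample {label} has replicons absent from the genome: {sorted(unknown)}")

    windows = _window_tables(calls_a, calls_b, genome, window, step, min_sites, min_coverage)
    if windows.empty:
        empty = pd.DataFrame(columns=DMR_COLUMNS)
        return (empty, windows) if return_windows else empty

    windows["p_value"] = [
        fisher_exact_2x2([[row.ka, row.ua], [row.kb, row.ub]])
        for row in windows.itertuples(index=False)
    ]
    windows["q_value"] = bh_qvalues(windows["p_value"].to_numpy())
    with np.errstate(invalid="ignore"):
        level_a = windows["ka"] / (windows["ka"] + windows["ua"])
        level_b = windows["kb"] / (windows["kb"] + windows["ub"])
    windows["diff"] = level_b - level_a

    sig = windows[
        (windows["q_value"] <= q_max) & (windows["diff"].abs() >= min_diff)
    ].copy()
    sig["direction"] = np.where(sig["diff"] > 0, "hyper", "hypo")

    dmrs = _merge_windows(sig)
    dmrs["genes"] = _overlapping_genes(dmrs, features)
    return (dmrs, windows) if return_windows else dmrs


def _merge_windows(sig: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/book-ended significant windows of equal direction."""
    rows = []
    for (rep, direction), grp in sig.groupby(["replicon", "direction"], sort=True):
        grp = grp.sort_values("start")
        current = None
        for w in grp.itertuples(index=False):
            if current is not None and w.start <= current["end"]:
                current["end"] = max(current["end"], w.end)
                current["n_windows"] += 1
                current["p_min"] = min(current["p_min"], w.p_value)
                current["q_min"] = min(current["q_min"], w.q_value)
                current["diffs"].append(w.diff)
            else:
                if current is not None:
                    rows.append(current)
                current = {
                    "replicon": rep,
                    "start": int(w.start),
                    "end": int(w.end),
                    "direction": direction,
                    "n_windows": 1,
                    "p_min": w.p_value,
                    "q_min": w.q_value,
                    "diffs": [w.diff],
                }
        if current is not None:
            rows.append(current)
    for row in rows:
        row["mean_diff"] = float(np.mean(row.pop("diffs")))
    out = pd.DataFrame(rows, columns=[c for c in DMR_COLUMNS if c != "genes"])
    return out.sort_values(["replicon", "start"]).reset_index(drop=True)


def _overlapping_genes(dmrs: pd.DataFrame, features: FeatureTable | None) -> list[list[str]]:
    if features is None or dmrs.empty:
        return [[] for _ in range(len(dmrs))]
    trees = features.gene_trees()
    out = []
    for row in dmrs.itertuples(index=False):
        tree = trees.get(row.replicon)
        hits = tree[row.start : row.end] if tree is not None else []
        out.append(sorted({iv.data for iv in hits}))
    return out


def dmr_genes(dmrs: pd.DataFrame, features: FeatureTable | None = None) -> tuple[set[str], set[str]]:
    """(hyper, hypo) sets of genes whose body overlaps a DMR by >= 1 bp.

    If the DMR table lacks attached gene lists, ``features`` must be given.
    A gene overlapping DMRs of both directions appears in both sets.
    """
    if dmrs.empty:
        return set(), set()
    table = dmrs
    if "genes" not in table.columns or features is not None:
        table = table.copy()
        table["genes"] = _overlapping_genes(table, features)
    hyper: set[str] = set()
    hypo: set[str] = set()
    for row in table.itertuples(index=False):
        target = hyper if row.direction == "hyper" else hypo
        target.update(row.genes)
    return hyper, hypo


def write_dmr_table(dmrs: pd.DataFrame, path) -> None:
    out = dmrs.copy()
    out["genes"] = [",".join(g) for g in out["genes"]] if len(out) else []
    out.to_csv(path, sep="\t", index=False)
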