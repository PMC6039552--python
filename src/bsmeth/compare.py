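"""Multi-condition methylome comparison.

Covers the set-level statistics behind a three-condition inheritance
analysis: the 7-cell Venn partition of per-condition mC-site (or mC-gene)
sets, loss/gain/retention fractions across a baseline -> stress -> recovery
ordering, methylation-level distribution summaries, per-context methylated
proportions, per-replicon site ratios, transposable-element site summaries,
and the cross-tabulation of DMR-related genes against an external
differential-expression table.

Site identity across conditions is the (replicon, position, strand) triple;
context is a property of the shared reference genome, never of a sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import CONTEXTS, FeatureTable, Genome, enumerate_cytosines

SiteId = tuple[str, int, str]

VENN_CELLS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


def mc_site_set(calls: pd.DataFrame) -> frozenset[SiteId]:
    """Identifier set of the called mC sites in one sample."""
    mc = calls[calls["is_mc"]]
    return frozenset(zip(mc["replicon"], mc["pos"].astype(int), mc["strand"]))


def methylated_gene_set(calls: pd.DataFrame, features: FeatureTable) -> frozenset[str]:
    """Genes with at least one mC site inside the gene body."""
    trees = features.gene_trees()
    mc = calls[calls["is_mc"]]
    genes: set[str] = set()
    for rep, pos in zip(mc["replicon"], mc["pos"].astype(int)):
        tree = trees.get(rep)
        if tree is not None:
            genes.update(iv.data for iv in tree[pos])
    return frozenset(genes)


@dataclass(frozen=True)
class VennPartition:
    """Exact 7-cell decomposition of three sets.

    ``cells`` maps "A", "B", "C", "AB", "AC", "BC", "ABC" to the *exclusive*
    member sets of each Venn region (e.g. "AB" = in A and B but not C).
    """

    labels: tuple[str, str, str]
    cells: dict[str, frozenset[Hashable]]

    @property
    def counts(self) -> dict[str, int]:
        return {cell: len(self.cells[cell]) for cell in VENN_CELLS}

    def total(self, which: str) -> int:
        """|A|, |B| or |C| reconstructed from the exclusive cells."""
        c = self.counts
        return sum(c[cell] for cell in VENN_CELLS if which in cell)

    def pairwise_overlap(self, pair: str) -> int:
        """|A ∩ B| etc.; ``pair`` is "AB", "AC" or "BC"."""
        c = self.counts
        return c[pair] + c["ABC"]

    @property
    def union_size(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "cells": self.counts,
            "totals": {w: self.total(w) for w in "ABC"},
            "pairwise_overlaps": {p: self.pairwise_overlap(p) for p in ("AB", "AC", "BC")},
            "union": self.union_size,
        }


def venn_partition(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    set_c: Iterable[Hashable],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> VennPartition:
    """Partition three sets into the 7 exclusive Venn cells."""
    a, b, c = frozenset(set_a), frozenset(set_b), frozenset(set_c)
    cells = {
        "A": a - b - c,
        "B": b - a - c,
        "C": c - a - b,
        "AB": (a & b) - c,
        "AC": (a & c) - b,
        "BC": (b & c) - a,
        "ABC": a & b & c,
    }
    return VennPartition(labels=tuple(labels), cells={k: frozenset(v) for k, v in cells.items()})


def venn_from_counts(counts: Mapping[str, int], labels=("A", "B", "C")) -> VennPartition:
    """Build a partition from published cell counts (opaque placeholder members).

    Useful when only a figure's printed per-cell counts are available: each
    cell is populated with distinct anonymous tokens so every derived total,
    overlap and retention statistic is computable exactly.
    """
    cells = {}
    token = 0
    for cell in VENN_CELLS:
        n = int(counts.get(cell, 0))
        cells[cell] = frozenset(range(token, token + n))
        token += n
    return VennPartition(labels=tuple(labels), cells=cells)


@dataclass(frozen=True)
class RetentionStats:
    """Loss/gain/retention statistics for a (base, stressed, recovered) triple.

    ``preserved_frac`` is the fraction of stress-gained sites still present
    after recovery; ``regained_frac`` the fraction of stress-lost sites that
    returned.  Fractions are NaN when their denominator is zero.
    """

    n_lost: int
    n_gained: int
    preserved_frac: float
    regained_frac: float

    def to_dict(self) -> dict:
        return {
            "n_lost": self.n_lost,
            "n_gained": self.n_gained,
            "preserved_frac": self.preserved_frac,
            "regained_frac": self.regained_frac,
        }


def retention_stats(partition: VennPartition) -> RetentionStats:
    """Retention statistics, reading the partition as (A=base, B=stressed, C=recovered).

    lost = A-only + AC (in base, absent under stress); gained = B-only + BC;
    preserved = BC / gained; regained = AC / lost.
    """
    c = partition.counts
    n_lost = c["A"] + c["AC"]
    n_gained = c["B"] + c["BC"]
    return RetentionStats(
        n_lost=n_lost,
        n_gained=n_gained,
        preserved_frac=c["BC"] / n_gained if n_gained else float("nan"),
        regained_frac=c["AC"] / n_lost if n_lost else float("nan"),
    )


# ---------------------------------------------------------------------------
# proportions and level summaries


def context_proportions(
    calls: pd.DataFrame,
    genome: Genome | None = None,
    denominator: str = "covered",
    min_coverage: int = 5,
) -> dict[str, float]:
    """Percent of cytosines called methylated, per context and overall.

    ``denominator="covered"`` divides by cytosines covered >= ``min_coverage``
    in this sample; ``"genomic"`` divides by all context-defined cytosines of
    the genome (requires ``genome``).
    """
    if denominator == "covered":
        denom = calls[calls["coverage"] >= min_coverage]
        denom_ctx = denom.groupby("context", observed=True).size()
    elif denominator == "genomic":
        if genome is None:
            raise ValueError("genomic denominator requires the genome")
        universe = enumerate_cytosines(genome)
        denom_ctx = universe.groupby("context", observed=True).size()
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    mc_ctx = calls[calls["is_mc"]].groupby("context", observed=True).size()
    out = {}
    for ctx in CONTEXTS:
        d = int(denom_ctx.get(ctx, 0))
        out[ctx] = 100.0 * int(mc_ctx.get(ctx, 0)) / d if d else float("nan")
    total_d = int(denom_ctx.sum())
    out["all"] = 100.0 * int(mc_ctx.sum()) / total_d if total_d else float("nan")
    return out


def replicon_site_ratio(
    calls: pd.DataFrame,
    genome: Genome,
    denominator: str = "covered",
    min_coverage: int = 5,
) -> pd.DataFrame:
    """Per-replicon, per-context percent of cytosines that are mC sites.

    The same computation as :func:`context_proportions`, grouped by replicon;
    replicons without calls report 0 (or NaN when the denominator is empty).
    """
    rows = []
    for rep in genome.names:
        sub = calls[calls["replicon"] == rep]
        if denominator == "genomic":
            sub_genome = Genome({rep: genome.replicons[rep]})
            props = context_proportions(sub, sub_genome, "genomic", min_coverage)
        else:
            props = context_proportions(sub, None, denominator, min_coverage)
        rows.append({"replicon": rep, **props})
    return pd.DataFrame(rows).set_index("replicon")


def level_summary(
    calls: pd.DataFrame,
    by: Iterable[str] = ("context",),
    level_col: str = "ml_corrected",
) -> pd.DataFrame:
    """Five-number summary of mC-site methylation levels per stratum.

    Strata come from the ``by`` columns (e.g. context, region, condition);
    quartiles use linear interpolation between order statistics.  Strata
    without mC sites are omitted.
    """
    mc = calls[calls["is_mc"]]
    by = list(by)
    if mc.empty:
        return pd.DataFrame(columns=by + ["min", "q1", "median", "q3", "max", "n"])
    rows = []
    for key, grp in mc.groupby(by, observed=True):
        levels = grp[level_col].to_numpy()
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key))
            | {
                "min": float(np.min(levels)),
                "q1": float(np.quantile(levels, 0.25)),
                "median": float(np.quantile(levels, 0.5)),
                "q3": float(np.quantile(levels, 0.75)),
                "max": float(np.max(levels)),
                "n": int(len(levels)),
            }
        )
    return pd.DataFrame(rows)


def te_site_summary(
    calls: pd.DataFrame, features: FeatureTable
) -> tuple[int, int, pd.DataFrame]:
    """mC sites lying exclusively within transposable elements.

    "Exclusively" means the site overlaps a TE interval and no gene body.
    Returns (number of TE-type mC sites, number of TEs containing at least
    one, per-context level summary of those sites).
    """
    te_trees = features.te_trees()
    gene_trees = features.gene_trees()
    mc = calls[calls["is_mc"]]
    keep = []
    te_hit: set[str] = set()
    for idx, rep, pos in zip(mc.index, mc["replicon"], mc["pos"].astype(int)):
        tes = te_trees.get(rep, IntervalTree())[pos]
        if not tes:
            continue
        if gene_trees.get(rep, IntervalTree())[pos]:
            continue
        keep.append(idx)
        te_hit.update(iv.data for iv in tes)
    te_calls = calls.loc[keep]
    return len(keep), len(te_hit), level_summary(te_calls)


def cross_tabulate_expression(
    hyper_genes: Iterable[str],
    hypo_genes: Iterable[str],
    de_table: pd.DataFrame | Mapping[str, str],
) -> pd.DataFrame:
    """Cross-tab of DMR-gene direction against differential-expression class.

    ``de_table`` maps gene -> class in {"up", "down", "unchanged"} (as a dict
    or a DataFrame with gene_id / de_class columns).  Returns a DataFrame
    indexed by hyper/hypo with columns down, up, unchanged, absent, total_expressed.
    """
    if isinstance(de_table, pd.DataFrame):
        mapping = dict(zip(de_table["gene_id"], de_table["de_class"]))
    else:
        mapping = dict(de_table)
    bad = set(mapping.values()) - {"up", "down", "unchanged"}
    if bad:
        raise ValueError(f"unknown DE classes: {sorted(bad)}")
    rows = {}
    for direction, genes in (("hyper", hyper_genes), ("hypo", hypo_genes)):
        counts = {"down": 0, "up": 0, "unchanged": 0, "absent": 0}
        for g in set(genes):
            counts[mapping.get(g, "absent")] += 1
        counts["total_expressed"] = counts["down"] + counts["up"] + counts["unchanged"]
        rows[direction] = counts
    return pd.DataFrame.from_dict(rows, orient="index")
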