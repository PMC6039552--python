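"""Hypergeometric over-representation analysis of gene lists.

Generic pathway enrichment over a user-supplied gene -> pathway mapping:
for each pathway of size K in a universe of N genes, the overlap k with a
selected list of n genes is tested against the upper-tail hypergeometric
distribution, and p-values are BH-corrected across pathways.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .calling import bh_qvalues

ENRICH_COLUMNS = ["pathway", "k", "K", "n", "N", "p_value", "q_value"]


def read_pathway_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene<TAB>pathway TSV into pathway -> gene sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "pathway"],
                     dtype=str, comment="#")
    out: dict[str, set[str]] = {}
    for gene, pathway in zip(df["gene_id"], df["pathway"]):
        out.setdefault(pathway, set()).add(gene)
    return out


def write_pathway_map(pathways: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pathway in sorted(pathways):
            for gene in sorted(pathways[pathway]):
                fh.write(f"{gene}\t{pathway}\n")


def hypergeom_pvalue(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for overlap k of (K, n) in N."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def hypergeom_enrich(
    selected: Iterable[str],
    pathways: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    q_max: float | None = None,
    min_pathway_size: int = 2,
) -> pd.DataFrame:
    """Pathway over-representation of a selected gene list.

    The universe defaults to the union of all mapped genes; selected genes
    outside the universe are dropped with a warning.  Pathways smaller than
    ``min_pathway_size`` or with zero overlap are skipped before BH
    correction.  Result sorted by (q, p, pathway); if ``q_max`` is given,
    rows above it are filtered out.
    """
    path_sets = {p: frozenset(g) for p, g in pathways.items()}
    if universe is None:
        uni = frozenset().union(*path_sets.values()) if path_sets else frozenset()
    else:
        uni = frozenset(universe)
    if not uni:
        raise ValueError("empty gene universe")
    sel = frozenset(selected)
    dropped = len(sel - uni)
    if dropped:
        warnings.warn(f"{dropped} selected gene(s) absent from the universe were dropped")
    sel &= uni

    rows = []
    for pathway in sorted(path_sets):
        members = path_sets[pathway] & uni
        if len(members) < min_pathway_size:
            continue
        k = len(sel & members)
        if k == 0:
            continue
        rows.append(
            {
                "pathway": pathway,
                "k": k,
                "K": len(members),
                "n": len(sel),
                "N": len(uni),
                "p_value": hypergeom_pvalue(k, len(members), len(sel), len(uni)),
            }
        )
    result = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:-1])
    if result.empty:
        return pd.DataFrame(columns=ENRICH_COLUMNS)
    result["q_value"] = bh_qvalues(result["p_value"].to_numpy())
    result = result.sort_values(["q_value", "p_value", "pathway"]).reset_index(drop=True)
    if q_max is not None:
        result = result[result["q_value"] <= q_max].reset_index(drop=True)
    return result
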