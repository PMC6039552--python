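"""Synthetic genomes, methylomes, condition shifts and bisulfite count tables.

The generator emulates a bacterial WGBS study of a nitrogen-stress time
course: a baseline methylome (condition "NC"), a stressed methylome ("N72")
in which a large fraction of methylated sites is lost while surviving sites
gain methylation level, and a recovered methylome ("NR") that preserves part
of the stress-induced sites and regains almost none of the lost ones.  Every
stochastic choice is recorded in a truth ledger so downstream estimates can
be checked against the exact generating values.

The read-count model is the standard WGBS error model: at a site with true
methylation level ``m`` and non-conversion rate ``R``, each of ``n`` reads
reports methylated with probability ``m + (1 - m) * R`` (methylated cytosines
fully protected; unmethylated ones fail to convert at rate R).  The
level-correction formula ``(ML - R) / (1 - R)`` used downstream inverts this
model exactly.

All operations take a seed and derive per-stage RNG streams from it, so a
fixed master seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CONTEXTS, COUNTS_COLUMNS, FeatureTable, Genome, enumerate_cytosines

SiteId = tuple[str, int, str]

#: default per-context fraction of cytosines that are methylated at baseline
DEFAULT_PREVALENCE: dict[str, float] = {"CG": 0.0305, "CHG": 0.0090, "CHH": 0.0103}

#: default Beta(alpha, beta) parameters of the true-level distribution per
#: context.  CG methylation (m5C) reads out near-completely; CHG/CHH sites
#: (largely m4C, only partially bisulfite-resistant) show lower apparent
#: levels, hence the low-mean Beta.
DEFAULT_LEVEL_BETA: dict[str, tuple[float, float]] = {
    "CG": (8.0, 2.0),
    "CHG": (2.5, 5.0),
    "CHH": (2.5, 5.0),
}

_STAGES = {"genome": 1, "methylome": 2, "shift": 3, "counts": 4, "control": 5,
           "features": 6, "pathways": 7, "de": 8}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STAGES[stage], extra])


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    length: int,
    gc_frac: float = 0.475,
    n_replicons: int = 1,
    seed: int = 0,
    lengths: Sequence[int] | None = None,
    names: Sequence[str] | None = None,
) -> Genome:
    """Random genome with the requested GC fraction.

    ``length`` is the total size; it is split equally over ``n_replicons``
    unless explicit per-replicon ``lengths`` are given.
    """
    if not 0.0 <= gc_frac <= 1.0:
        raise ValueError(f"gc_frac must be in [0, 1], got {gc_frac}")
    if lengths is None:
        if length < 1:
            raise ValueError("genome length must be >= 1")
        base = length // n_replicons
        lengths = [base + (1 if i < length % n_replicons else 0) for i in range(n_replicons)]
    if names is None:
        names = [f"replicon_{i + 1}" for i in range(len(lengths))]
    rng = _rng(seed, "genome")
    p = np.array([(1 - gc_frac) / 2, gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2])
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    replicons = {}
    for name, n in zip(names, lengths):
        draw = rng.choice(4, size=int(n), p=p)
        replicons[str(name)] = bases[draw].tobytes().decode("ascii")
    return Genome(replicons)


# ---------------------------------------------------------------------------
# methylomes


@dataclass
class TrueMethylome:
    """Ground-truth methylation levels over a genome's cytosine universe.

    ``sites`` has one row per strand-specific cytosine (columns: replicon,
    pos, strand, context, trinucleotide, true_m); ``true_m = 0`` means
    unmethylated.
    """

    sites: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.sites["true_m"].to_numpy()
        if len(m) and (m.min() < 0 or m.max() > 1):
            raise ValueError("true methylation levels must lie in [0, 1]")

    @property
    def methylated(self) -> pd.DataFrame:
        return self.sites[self.sites["true_m"] > 0]

    def methylated_set(self) -> frozenset[SiteId]:
        sub = self.methylated
        return frozenset(zip(sub["replicon"], sub["pos"].astype(int), sub["strand"]))

    def to_truth_table(self, path) -> None:
        out = self.sites.copy()
        out["pos"] = out["pos"] + 1
        out.to_csv(path, sep="\t", index=False)


def assign_methylome(
    genome: Genome,
    prevalence: Mapping[str, float] | None = None,
    level_beta: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> TrueMethylome:
    """Draw a baseline methylome over all cytosines of the genome.

    Each cytosine is methylated independently with its context's prevalence;
    methylated sites draw their level from the context's Beta distribution,
    all other sites have level 0.
    """
    prevalence = dict(DEFAULT_PREVALENCE if prevalence is None else prevalence)
    level_beta = dict(DEFAULT_LEVEL_BETA if level_beta is None else level_beta)
    for ctx, p in prevalence.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence for {ctx} outside [0, 1]: {p}")
    sites = enumerate_cytosines(genome).copy()
    rng = _rng(seed, "methylome")
    m = np.zeros(len(sites))
    ctx_arr = sites["context"].to_numpy()
    for ctx in CONTEXTS:
        mask = ctx_arr == ctx
        n_ctx = int(mask.sum())
        if n_ctx == 0:
            continue
        is_meth = rng.random(n_ctx) < prevalence.get(ctx, 0.0)
        levels = np.zeros(n_ctx)
        k = int(is_meth.sum())
        if k:
            a, b = level_beta[ctx]
            levels[is_meth] = rng.beta(a, b, size=k)
            # Beta draws of exactly 0 would silently demote a site to
            # "unmethylated"; nudge them to the smallest positive level.
            levels[is_meth] = np.maximum(levels[is_meth], 1e-9)
        m[mask] = levels
    sites["true_m"] = m
    return TrueMethylome(sites)


@dataclass
class ShiftSpec:
    """Parameters of the stress -> recovery methylome transformation.

    Defaults follow the nitrogen-starvation study design: ~41% of baseline
    methylated sites lose methylation under stress, surviving sites increase
    in level, stress-gained sites amount to ~12% of the baseline methylome
    (0.17% of the unmethylated universe at the default prevalences), 45% of
    gained sites persist after recovery and only 1% of lost sites return.
    """

    loss_frac: float = 0.41
    gain_frac: float = 0.0017
    level_delta: float = 0.10
    preserve_frac: float = 0.45
    regain_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_frac", "gain_frac", "preserve_frac", "regain_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ShiftLedger:
    """Exact record of which sites changed state across conditions."""

    lost: frozenset[SiteId]
    survived: frozenset[SiteId]
    gained: frozenset[SiteId]
    preserved_gained: frozenset[SiteId]
    regained_lost: frozenset[SiteId]

    @property
    def preserve_frac(self) -> float:
        return len(self.preserved_gained) / len(self.gained) if self.gained else float("nan")

    @property
    def regain_frac(self) -> float:
        return len(self.regained_lost) / len(self.lost) if self.lost else float("nan")


def apply_shift(
    base: TrueMethylome, spec: ShiftSpec
) -> tuple[TrueMethylome, TrueMethylome, ShiftLedger]:
    """Derive stressed and recovered methylomes from a baseline.

    Stressed: ``round(loss_frac * n_meth)`` baseline sites drop to level 0;
    survivors gain ``level_delta`` (clipped at 1); ``round(gain_frac *
    n_unmeth)`` previously unmethylated sites gain methylation at
    stress-typical levels.  Recovered: survivors and ``preserve_frac`` of the
    gained sites keep their stressed levels; ``regain_frac`` of the lost
    sites return at their baseline levels.  The returned ledger partitions
    are exact and mutually disjoint.
    """
    rng = _rng(spec.seed, "shift")
    sites = base.sites
    m0 = sites["true_m"].to_numpy()
    ids = list(zip(sites["replicon"], sites["pos"].astype(int), sites["strand"]))

    meth_idx = np.flatnonzero(m0 > 0)
    unmeth_idx = np.flatnonzero(m0 == 0)

    n_lost = int(round(spec.loss_frac * len(meth_idx)))
    lost_idx = rng.choice(meth_idx, size=n_lost, replace=False) if n_lost else np.array([], dtype=int)
    survived_idx = np.setdiff1d(meth_idx, lost_idx)

    n_gained = int(round(spec.gain_frac * len(unmeth_idx)))
    gained_idx = rng.choice(unmeth_idx, size=n_gained, replace=False) if n_gained else np.array([], dtype=int)

    m_stress = np.zeros_like(m0)
    m_stress[survived_idx] = np.clip(m0[survived_idx] + spec.level_delta, 0.0, 1.0)
    if len(gained_idx):
        ctx = sites["context"].to_numpy()[gained_idx]
        levels = np.empty(len(gained_idx))
        for c in CONTEXTS:
            mask = ctx == c
            if mask.any():
                a, b = DEFAULT_LEVEL_BETA[c]
                levels[mask] = rng.beta(a, b, size=int(mask.sum()))
        m_stress[gained_idx] = np.clip(np.maximum(levels, 1e-9) + spec.level_delta, 1e-9, 1.0)

    n_preserved = int(round(spec.preserve_frac * len(gained_idx)))
    preserved_idx = (
        rng.choice(gained_idx, size=n_preserved, replace=False) if n_preserved else np.array([], dtype=int)
    )
    n_regained = int(round(spec.regain_frac * len(lost_idx)))
    regained_idx = (
        rng.choice(lost_idx, size=n_regained, replace=False) if n_regained else np.array([], dtype=int)
    )

    m_rec = np.zeros_like(m0)
    m_rec[survived_idx] = m_stress[survived_idx]
    m_rec[preserved_idx] = m_stress[preserved_idx]
    m_rec[regained_idx] = m0[regained_idx]

    def _set(idx: np.ndarray) -> frozenset[SiteId]:
        return frozenset(ids[i] for i in idx)

    ledger = ShiftLedger(
        lost=_set(lost_idx),
        survived=_set(survived_idx),
        gained=_set(gained_idx),
        preserved_gained=_set(preserved_idx),
        regained_lost=_set(regained_idx),
    )
    stressed = TrueMethylome(sites.assign(true_m=m_stress))
    recovered = TrueMethylome(sites.assign(true_m=m_rec))
    return stressed, recovered, ledger


# ---------------------------------------------------------------------------
# read counts


@dataclass
class CoverageModel:
    """Per-site sequencing depth distribution.

    ``family`` is ``poisson`` or ``negative_binomial``; for the latter
    ``dispersion`` is the NB size parameter (smaller = more overdispersed).
    """

    family: str = "poisson"
    mean: float = 50.0
    dispersion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown coverage family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean coverage must be > 0")
        if self.family == "negative_binomial" and not (self.dispersion and self.dispersion > 0):
            raise ValueError("negative_binomial requires dispersion > 0")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "poisson":
            return rng.poisson(self.mean, size=size)
        r = self.dispersion
        p = r / (r + self.mean)
        return rng.negative_binomial(r, p, size=size)


def simulate_counts(
    methylome: TrueMethylome,
    coverage: CoverageModel | None = None,
    r_nonconversion: float = 0.003,
    seed: int = 0,
) -> pd.DataFrame:
    """Bisulfite read counts for every cytosine of a methylome.

    Per site: depth ``n`` from the coverage model, methylated-read count
    ``k ~ Binomial(n, m + (1 - m) * R)``.  Returns a cytosine-report style
    DataFrame (0-based positions) valid as input to
    :func:`bsmeth.genome_io.write_counts_table`.
    """
    if not 0.0 <= r_nonconversion < 1.0:
        raise ValueError("non-conversion rate must be in [0, 1)")
    coverage = coverage or CoverageModel()
    rng = _rng(seed, "counts")
    sites = methylome.sites
    n = coverage.sample(len(sites), rng)
    m = sites["true_m"].to_numpy()
    p_obs = m + (1.0 - m) * r_nonconversion
    k = rng.binomial(n, p_obs)
    return pd.DataFrame(
        {
            "replicon": sites["replicon"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "count_methylated": k,
            "count_unmethylated": n - k,
            "context": sites["context"].to_numpy(),
            "trinucleotide": sites["trinucleotide"].to_numpy(),
        }
    )[COUNTS_COLUMNS]


def simulate_control_counts(
    length: int = 20_000,
    coverage: CoverageModel | None = None,
    r_nonconversion: float = 0.003,
    seed: int = 0,
    replicon_name: str = "control_spikein",
) -> pd.DataFrame:
    """Counts for a fully unmethylated spike-in control genome.

    Emulates the unmethylated phage DNA spiked into a WGBS library to
    estimate the bisulfite non-conversion rate: every cytosine has true
    level 0, so pooled methylated/total read counts estimate R directly.
    """
    genome = simulate_genome(length, gc_frac=0.5, seed=seed + 7, names=[replicon_name])
    sites = enumerate_cytosines(genome).assign(true_m=0.0)
    control = TrueMethylome(sites)
    rng_seed_stage = _rng(seed, "control")
    counts = simulate_counts(
        control, coverage=coverage, r_nonconversion=r_nonconversion,
        seed=int(rng_seed_stage.integers(2**31)),
    )
    return counts


# ---------------------------------------------------------------------------
# annotation / auxiliary-table generators for fully synthetic runs


def simulate_features(
    genome: Genome,
    gene_length: int = 900,
    gene_gap: int = 300,
    te_frac: float = 0.05,
    te_length: int = 600,
    seed: int = 0,
) -> FeatureTable:
    """Regular gene tiling plus TE intervals placed in intergenic gaps.

    A deliberately simple annotation: genes of fixed length separated by
    fixed gaps on alternating strands (bacterial gene density is high), and
    TEs dropped into a fraction ``te_frac`` of the gaps.
    """
    rng = _rng(seed, "features")
    genes, tes = [], []
    g, t = 0, 0
    for name, length in genome.lengths.items():
        pos = gene_gap // 2
        while pos + gene_length <= length:
            g += 1
            genes.append(
                {
                    "replicon": name,
                    "start": pos,
                    "end": pos + gene_length,
                    "strand": "+" if g % 2 else "-",
                    "gene_id": f"gene_{g:05d}",
                }
            )
            gap_start = pos + gene_length
            if rng.random() < te_frac and gap_start + te_length <= length:
                t += 1
                tes.append(
                    {
                        "replicon": name,
                        "start": gap_start,
                        "end": min(gap_start + te_length, length),
                        "te_id": f"TE_{t:04d}",
                    }
                )
            pos += gene_length + gene_gap
    genes_df = pd.DataFrame(genes, columns=["replicon", "start", "end", "strand", "gene_id"])
    tes_df = pd.DataFrame(tes, columns=["replicon", "start", "end", "te_id"])
    return FeatureTable(
        genes=genes_df.astype({"start": int, "end": int}),
        tes=tes_df.astype({"start": int, "end": int}),
    )


def simulate_pathway_map(
    gene_ids: Iterable[str], n_pathways: int = 20, mean_size: int = 30, seed: int = 0
) -> dict[str, set[str]]:
    """Random gene -> pathway assignment for enrichment testing."""
    genes = list(gene_ids)
    rng = _rng(seed, "pathways")
    pathways: dict[str, set[str]] = {}
    for i in range(n_pathways):
        size = max(2, int(rng.poisson(mean_size)))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        pathways[f"path_{i + 1:03d}"] = {genes[j] for j in members}
    return pathways


def simulate_de_table(
    gene_ids: Iterable[str],
    frac_up: float = 0.3,
    frac_down: float = 0.3,
    frac_measured: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Random differential-expression classification of genes.

    Returns DataFrame(gene_id, de_class) with classes up / down / unchanged
    for a random ``frac_measured`` subset of genes (the rest are absent from
    the table, as in any real expression study).
    """
    genes = list(gene_ids)
    rng = _rng(seed, "de")
    measured = rng.random(len(genes)) < frac_measured
    u = rng.random(len(genes))
    de_class = np.where(u < frac_up, "up", np.where(u < frac_up + frac_down, "down", "unchanged"))
    df = pd.DataFrame({"gene_id": genes, "de_class": de_class})[measured]
    return df.reset_index(drop=True)
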