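"""End-to-end orchestration: simulate -> call -> compare -> dmr -> enrich.

A :class:`RunConfig` (built in code or loaded from a YAML file) either points
at existing input files (genome FASTA, per-condition cytosine-report TSVs, a
spike-in control table, optional GFF3/BED/pathway/DE tables) or carries a
``simulate`` block, in which case all inputs are generated synthetically
first and written alongside the results.  Outputs of a run are a pure
function of (inputs, parameters, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calling, compare, dmr as dmr_mod, enrichment, genome_io, synthetic

log = logging.getLogger("bsmeth")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Paths, parameters and seed of one pipeline run.

    ``conditions`` maps condition name -> counts TSV path in analysis order
    (baseline first, stressed second, optional recovered third).  When
    ``simulate`` is set (a dict of generator options, possibly empty), all
    inputs are generated under ``<out_dir>/inputs`` and the path fields are
    filled in automatically.
    """

    out_dir: str = "bsmeth_run"
    seed: int = 0
    genome: str | None = None
    conditions: dict[str, str] = field(default_factory=dict)
    control: str | None = None
    r_override: float | None = None
    genes_gff3: str | None = None
    te_bed: str | None = None
    pathway_map: str | None = None
    de_table: str | None = None
    simulate: dict | None = None
    min_coverage: int = 5
    q_max: float = 0.05
    window: int = 200
    step: int = 40
    upstream: int = 100
    downstream: int = 100
    min_sites: int = 5
    min_diff: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def demo_config(out_dir: str | Path, seed: int = 0) -> RunConfig:
    """Desk-scale fully synthetic three-condition run (200 kb genome)."""
    return RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        simulate={
            "genome_length": 200_000,
            "replicon_lengths": [180_000, 20_000],
            "replicon_names": ["chromosome", "plasmid_1"],
            "gc_frac": 0.475,
            "mean_coverage": 50.0,
            "r_nonconversion": 0.003,
        },
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _simulate_inputs(config: RunConfig, inputs_dir: Path) -> None:
    """Generate genome, annotation, methylomes and count tables in place."""
    opts = dict(config.simulate or {})
    seed = config.seed
    genome = synthetic.simulate_genome(
        length=opts.get("genome_length", 200_000),
        gc_frac=opts.get("gc_frac", 0.475),
        seed=seed,
        lengths=opts.get("replicon_lengths"),
        names=opts.get("replicon_names"),
    )
    genome_path = inputs_dir / "genome.fa"
    genome.to_fasta(genome_path)
    config.genome = str(genome_path)

    features = synthetic.simulate_features(genome, seed=seed)
    config.genes_gff3 = str(inputs_dir / "genes.gff3")
    config.te_bed = str(inputs_dir / "tes.bed")
    genome_io.write_genes_gff3(features.genes, config.genes_gff3)
    genome_io.write_te_bed(features.tes, config.te_bed)

    base = synthetic.assign_methylome(
        genome,
        prevalence=opts.get("prevalence"),
        seed=seed,
    )
    shift = synthetic.ShiftSpec(seed=seed, **opts.get("shift", {}))
    stressed, recovered, ledger = synthetic.apply_shift(base, shift)

    coverage = synthetic.CoverageModel(mean=opts.get("mean_coverage", 50.0))
    r = opts.get("r_nonconversion", 0.003)
    config.conditions = {}
    for i, (name, methylome) in enumerate(
        (("baseline", base), ("stressed", stressed), ("recovered", recovered))
    ):
        counts = synthetic.simulate_counts(methylome, coverage, r, seed=seed + 11 * (i + 1))
        path = inputs_dir / f"counts_{name}.tsv"
        genome_io.write_counts_table(counts, path)
        methylome.to_truth_table(inputs_dir / f"truth_{name}.tsv")
        config.conditions[name] = str(path)

    control = synthetic.simulate_control_counts(
        coverage=coverage, r_nonconversion=r, seed=seed
    )
    config.control = str(inputs_dir / "control.tsv")
    genome_io.write_counts_table(control, config.control)

    with open(inputs_dir / "truth_ledger.json", "w") as fh:
        json.dump(
            {
                "n_lost": len(ledger.lost),
                "n_survived": len(ledger.survived),
                "n_gained": len(ledger.gained),
                "n_preserved_gained": len(ledger.preserved_gained),
                "n_regained_lost": len(ledger.regained_lost),
                "preserve_frac": ledger.preserve_frac,
                "regain_frac": ledger.regain_frac,
            },
            fh,
            indent=2,
        )

    gene_ids = list(features.genes["gene_id"])
    pathways = synthetic.simulate_pathway_map(gene_ids, seed=seed)
    config.pathway_map = str(inputs_dir / "pathways.tsv")
    enrichment.write_pathway_map(pathways, config.pathway_map)
    de = synthetic.simulate_de_table(gene_ids, seed=seed)
    config.de_table = str(inputs_dir / "de_table.tsv")
    de.to_csv(config.de_table, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dict also written to summary.json.

    Stage outputs land in ``config.out_dir``; any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    param_keys = (
        "seed", "min_coverage", "q_max", "window", "step", "upstream",
        "downstream", "min_sites", "min_diff", "r_override",
    )
    summary: dict = {"parameters": {k: getattr(config, k) for k in param_keys}}
    try:
        if config.simulate is not None:
            inputs_dir = out / "inputs"
            inputs_dir.mkdir(exist_ok=True)
            log.info("stage simulate: begin (seed=%d)", config.seed)
            try:
                _simulate_inputs(config, inputs_dir)
            except Exception as exc:
                raise PipelineError(f"stage simulate failed: {exc}") from exc
            log.info("stage simulate: done")

        required = [config.genome, *config.conditions.values()]
        if config.r_override is None:
            required.append(config.control)
        for path in required:
            if path is None or not Path(path).exists():
                raise PipelineError(f"missing required input before any stage ran: {path}")
        if len(config.conditions) < 2:
            raise PipelineError("need at least two condition count tables")
        for path in [config.genome, *config.conditions.values()]:
            log.info("input %s sha256=%s", path, _sha256(Path(path)))

        genome = genome_io.read_genome(config.genome)
        features = None
        if config.genes_gff3:
            features = genome_io.FeatureTable.from_files(config.genes_gff3, config.te_bed)

        # ---- call ----------------------------------------------------
        log.info("stage call: begin")
        try:
            if config.r_override is not None:
                r = float(config.r_override)
                summary["conversion"] = {"r": r, "source": "override"}
            else:
                est = calling.estimate_nonconversion(
                    genome_io.read_counts_table(config.control)
                )
                r = est.r
                summary["conversion"] = {
                    "r": est.r,
                    "conversion_rate_pct": est.conversion_rate_pct,
                    "n_control": est.n_control,
                    "source": "control",
                }
            calls = {}
            summary["conditions"] = {}
            for name, path in config.conditions.items():
                counts = genome_io.read_counts_table(path)
                c = calling.call_sites(
                    counts, r, min_coverage=config.min_coverage, q_max=config.q_max
                )
                calls[name] = c
                c_out = c.copy()
                c_out["pos"] = c_out["pos"] + 1
                c_out.to_csv(out / f"calls_{name}.tsv", sep="\t", index=False)
                summary["conditions"][name] = calling.call_summary(c)
                summary["conditions"][name]["context_proportions_pct"] = (
                    compare.context_proportions(c, genome, min_coverage=config.min_coverage)
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage call failed: {exc}") from exc
        log.info("stage call: done")

        names = list(calls)

        # ---- compare -------------------------------------------------
        log.info("stage compare: begin")
        try:
            site_sets = [compare.mc_site_set(calls[n]) for n in names]
            if len(names) >= 3:
                venn = compare.venn_partition(*site_sets[:3], labels=tuple(names[:3]))
                summary["venn_sites"] = venn.to_dict()
                summary["retention"] = compare.retention_stats(venn).to_dict()
                if features is not None:
                    gene_sets = [
                        compare.methylated_gene_set(calls[n], features) for n in names[:3]
                    ]
                    summary["venn_genes"] = compare.venn_partition(
                        *gene_sets, labels=tuple(names[:3])
                    ).to_dict()
            levels = pd.concat(
                [
                    compare.level_summary(calls[n]).assign(condition=n)
                    for n in names
                ],
                ignore_index=True,
            )
            levels.to_csv(out / "level_summary.tsv", sep="\t", index=False)
            ratios = pd.concat(
                [
                    compare.replicon_site_ratio(
                        calls[n], genome, min_coverage=config.min_coverage
                    ).assign(condition=n)
                    for n in names
                ]
            )
            ratios.to_csv(out / "replicon_site_ratio.tsv", sep="\t")
            if features is not None and len(features.tes):
                te_rows = []
                for n in names:
                    n_sites, n_tes, _ = compare.te_site_summary(calls[n], features)
                    te_rows.append({"condition": n, "n_te_sites": n_sites, "n_tes": n_tes})
                pd.DataFrame(te_rows).to_csv(out / "te_summary.tsv", sep="\t", index=False)
                summary["te"] = te_rows
        except Exception as exc:
            raise PipelineError(f"stage compare failed: {exc}") from exc
        log.info("stage compare: done")

        # ---- dmr -----------------------------------------------------
        log.info("stage dmr: begin")
        try:
            a, b = names[0], names[1]
            dmrs = dmr_mod.detect_dmrs(
                calls[a],
                calls[b],
                genome,
                features=features,
                window=config.window,
                step=config.step,
                q_max=config.q_max,
                min_sites=config.min_sites,
                min_diff=config.min_diff,
                min_coverage=config.min_coverage,
            )
            dmr_mod.write_dmr_table(dmrs, out / f"dmrs_{a}_vs_{b}.tsv")
            hyper, hypo = dmr_mod.dmr_genes(dmrs)
            (out / "hyper_genes.txt").write_text("".join(f"{g}\n" for g in sorted(hyper)))
            (out / "hypo_genes.txt").write_text("".join(f"{g}\n" for g in sorted(hypo)))
            summary["dmr"] = {
                "comparison": [a, b],
                "n_dmrs": int(len(dmrs)),
                "n_hyper": int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0,
                "n_hypo": int((dmrs["direction"] == "hypo").sum()) if len(dmrs) else 0,
                "n_hyper_genes": len(hyper),
                "n_hypo_genes": len(hypo),
            }
            if config.de_table:
                de = pd.read_csv(config.de_table, sep="\t")
                xtab = compare.cross_tabulate_expression(hyper, hypo, de)
                xtab.to_csv(out / "expression_crosstab.tsv", sep="\t")
                summary["expression_crosstab"] = {
                    direction: {k: int(v) for k, v in row.items()}
                    for direction, row in xtab.to_dict("index").items()
                }
        except Exception as exc:
            raise PipelineError(f"stage dmr failed: {exc}") from exc
        log.info("stage dmr: done")

        # ---- enrich --------------------------------------------------
        if config.pathway_map:
            log.info("stage enrich: begin")
            try:
                pathways = enrichment.read_pathway_map(config.pathway_map)
                tables = {}
                for direction, genes in (("hyper", hyper), ("hypo", hypo)):
                    table = enrichment.hypergeom_enrich(genes, pathways)
                    table.to_csv(out / f"enrichment_{direction}.tsv", sep="\t", index=False)
                    tables[direction] = {
                        "n_tested": int(len(table)),
                        "n_significant": int((table["q_value"] <= config.q_max).sum())
                        if len(table)
                        else 0,
                    }
                summary["enrichment"] = tables
            except Exception as exc:
                raise PipelineError(f"stage enrich failed: {exc}") from exc
            log.info("stage enrich: done")

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        log.info("pipeline complete: %s", out / "summary.json")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
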