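"""Venn partition, retention statistics, proportions and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsmeth.compare import (
    context_proportions,
    cross_tabulate_expression,
    level_summary,
    mc_site_set,
    methylated_gene_set,
    replicon_site_ratio,
    retention_stats,
    te_site_summary,
    venn_from_counts,
    venn_partition,
)
from bsmeth.genome_io import FeatureTable, Genome, enumerate_cytosines
from bsmeth.synthetic import ShiftSpec, apply_shift
from conftest import make_calls_frame

# Printed per-cell counts of the three-condition mC-site Venn diagram
# (baseline NC, stressed N72, recovered NR).
STUDY_VENN_CELLS = {
    "A": 32_488, "B": 5_392, "C": 7_302,
    "AB": 197, "AC": 257, "BC": 4_466, "ABC": 46_859,
}


class TestVennPartition:
    def test_small_example(self):
        p = venn_partition({1, 2}, {2, 3}, {3, 4})
        assert p.counts == {"A": 1, "B": 0, "C": 1, "AB": 1, "AC": 0, "BC": 1, "ABC": 0}

    def test_identical_sets_only_abc(self):
        s = {1, 2, 3}
        p = venn_partition(s, s, s)
        assert p.counts == {"A": 0, "B": 0, "C": 0, "AB": 0, "AC": 0, "BC": 0, "ABC": 3}

    def test_study_cells_reproduce_totals_and_overlaps(self):
        """The published 7-cell partition implies the published totals."""
        p = venn_from_counts(STUDY_VENN_CELLS, labels=("NC", "N72", "NR"))
        assert p.total("A") == 79_801
        assert p.total("B") == 56_914
        assert p.total("C") == 58_884
        assert p.pairwise_overlap("AB") == 47_056
        assert p.pairwise_overlap("BC") == 51_325
        assert p.pairwise_overlap("AC") == 47_116

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_conservation_identities(self, a, b, c):
        p = venn_partition(a, b, c)
        assert p.total("A") == len(a)
        assert p.total("B") == len(b)
        assert p.total("C") == len(c)
        assert p.union_size == len(a | b | c)
        assert p.pairwise_overlap("AB") == len(a & b)


class TestRetentionStats:
    def test_study_cells_retention(self):
        """Lost/gained/preserved/regained from the published partition."""
        p = venn_from_counts(STUDY_VENN_CELLS)
        r = retention_stats(p)
        assert r.n_lost == 32_745
        assert r.n_gained == 9_858
        assert r.preserved_frac == pytest.approx(4_466 / 9_858)   # > 45%
        assert r.regained_frac == pytest.approx(257 / 32_745)     # ~ 1%
        assert r.preserved_frac > 0.45
        assert r.regained_frac < 0.01

    def test_identical_sets_undefined_fractions(self):
        p = venn_partition({1}, {1}, {1})
        r = retention_stats(p)
        assert r.n_lost == 0 and r.n_gained == 0
        assert np.isnan(r.preserved_frac) and np.isnan(r.regained_frac)

    def test_disjoint_then_fully_preserved(self):
        p = venn_partition({1, 2}, {3, 4}, {3, 4})
        assert retention_stats(p).preserved_frac == 1.0

    def test_exact_recovery_from_truth_ledger(self, methylome_small):
        """Venn of the true methylated sets reproduces the ledger fractions."""
        spec = ShiftSpec(seed=41)
        stressed, recovered, ledger = apply_shift(methylome_small, spec)
        p = venn_partition(
            methylome_small.methylated_set(),
            stressed.methylated_set(),
            recovered.methylated_set(),
        )
        r = retention_stats(p)
        assert r.n_lost == len(ledger.lost)
        assert r.n_gained == len(ledger.gained)
        assert r.preserved_frac == ledger.preserve_frac
        assert r.regained_frac == ledger.regain_frac


class TestContextProportions:
    def test_all_covered_called_gives_100(self, genome_small):
        sites = enumerate_cytosines(genome_small)
        calls = make_calls_frame(sites, coverage=10, k=10, is_mc=True)
        props = context_proportions(calls)
        assert all(props[c] == pytest.approx(100.0) for c in ("CG", "CHG", "CHH", "all"))

    def test_zero_calls_gives_0(self, genome_small):
        sites = enumerate_cytosines(genome_small)
        calls = make_calls_frame(sites, coverage=10, k=0, is_mc=False)
        assert context_proportions(calls)["all"] == 0.0

    def test_covered_equals_genomic_at_full_coverage(self, genome_small):
        sites = enumerate_cytosines(genome_small)
        is_mc = np.arange(len(sites)) % 7 == 0
        calls = make_calls_frame(sites, coverage=10, k=10, is_mc=is_mc)
        covered = context_proportions(calls, denominator="covered")
        genomic = context_proportions(calls, genome_small, denominator="genomic")
        for key in covered:
            assert covered[key] == pytest.approx(genomic[key])

    def test_unknown_mode_rejected(self, genome_small):
        sites = enumerate_cytosines(genome_small).head(5)
        calls = make_calls_frame(sites, coverage=10, k=0, is_mc=False)
        with pytest.raises(ValueError):
            context_proportions(calls, denominator="nope")


class TestRepliconSiteRatio:
    def test_replicon_without_calls_reports_zero(self, genome_small):
        sites = enumerate_cytosines(genome_small)
        is_mc = (sites["replicon"] == "chromosome") & (np.arange(len(sites)) % 5 == 0)
        calls = make_calls_frame(sites, coverage=10, k=10, is_mc=is_mc)
        ratios = replicon_site_ratio(calls, genome_small)
        assert ratios.loc["plasmid_1", "all"] == 0.0
        assert ratios.loc["chromosome", "all"] > 0.0

    def test_single_replicon_matches_genome_wide(self):
        from bsmeth.synthetic import simulate_genome

        g = simulate_genome(2_000, seed=42, names=["only"])
        sites = enumerate_cytosines(g)
        is_mc = np.arange(len(sites)) % 3 == 0
        calls = make_calls_frame(sites, coverage=10, k=10, is_mc=is_mc)
        ratios = replicon_site_ratio(calls, g)
        props = context_proportions(calls)
        for ctx in ("CG", "CHG", "CHH", "all"):
            assert ratios.loc["only", ctx] == pytest.approx(props[ctx])


class TestLevelSummary:
    def _calls(self, levels, context="CG"):
        n = len(levels)
        sites = pd.DataFrame(
            {"replicon": "r", "pos": range(n), "strand": "+", "context": context,
             "trinucleotide": "CGA"}
        )
        return make_calls_frame(sites, coverage=10, k=5, is_mc=True, ml=levels)

    def test_single_site_degenerate(self):
        s = level_summary(self._calls([0.5]))
        row = s.iloc[0]
        assert [row["min"], row.q1, row["median"], row.q3, row["max"]] == [0.5] * 5

    def test_decile_levels_linear_interpolation(self):
        levels = np.round(np.arange(0.1, 1.01, 0.1), 10)
        row = level_summary(self._calls(levels)).iloc[0]
        assert row["median"] == pytest.approx(0.55)
        assert row["q1"] == pytest.approx(0.325)
        assert row["q3"] == pytest.approx(0.775)
        assert row["n"] == 10

    def test_permutation_invariance(self):
        levels = [0.9, 0.1, 0.4, 0.7, 0.2]
        a = level_summary(self._calls(levels))
        b = level_summary(self._calls(levels[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_strata_omitted(self):
        calls = self._calls([0.5])
        calls["is_mc"] = False
        assert len(level_summary(calls)) == 0


class TestTeSiteSummary:
    def _setup(self, te_rows, gene_rows, mc_pos):
        genes = pd.DataFrame(gene_rows, columns=["replicon", "start", "end", "strand", "gene_id"])
        tes = pd.DataFrame(te_rows, columns=["replicon", "start", "end", "te_id"])
        features = FeatureTable(genes=genes, tes=tes)
        sites = pd.DataFrame(
            {"replicon": "r", "pos": mc_pos, "strand": "+", "context": "CHH",
             "trinucleotide": "CAT"}
        )
        calls = make_calls_frame(sites, coverage=10, k=8, is_mc=True)
        return features, calls

    def test_no_tes(self):
        features, calls = self._setup([], [], [5, 10])
        n_sites, n_tes, summary = te_site_summary(calls, features)
        assert (n_sites, n_tes) == (0, 0) and summary.empty

    def test_te_with_three_sites(self):
        features, calls = self._setup([("r", 0, 100, "te1")], [], [5, 10, 20])
        n_sites, n_tes, summary = te_site_summary(calls, features)
        assert (n_sites, n_tes) == (3, 1)
        assert summary["n"].sum() == 3

    def test_site_in_te_and_gene_excluded(self):
        """'Exclusively within TEs' drops sites also inside a gene body."""
        features, calls = self._setup(
            [("r", 0, 100, "te1")], [("r", 50, 150, "+", "g1")], [10, 60]
        )
        n_sites, n_tes, _ = te_site_summary(calls, features)
        assert n_sites == 1  # pos 60 overlaps gene g1, excluded


class TestCrossTabulate:
    def test_empty_de_table(self):
        xtab = cross_tabulate_expression({"g1"}, {"g2"}, {})
        assert xtab.loc["hyper", "absent"] == 1
        assert xtab.loc["hyper", "total_expressed"] == 0

    def test_simple_classification(self):
        xtab = cross_tabulate_expression({"g1", "g2"}, set(), {"g1": "down", "g2": "up"})
        assert xtab.loc["hyper", "down"] == 1
        assert xtab.loc["hyper", "up"] == 1
        assert xtab.loc["hyper", "unchanged"] == 0

    def test_study_marginals(self):
        """Cross-tab reproduces the published DMR-gene expression marginals:
        987 of 1,042 hyper genes expressed (488 down / 493 up / 6 unchanged),
        134 of 152 hypo genes expressed (64 down / 70 up)."""
        hyper = [f"h{i}" for i in range(1_042)]
        hypo = [f"l{i}" for i in range(152)]
        de = {}
        de.update({g: "down" for g in hyper[:488]})
        de.update({g: "up" for g in hyper[488:981]})
        de.update({g: "unchanged" for g in hyper[981:987]})
        de.update({g: "down" for g in hypo[:64]})
        de.update({g: "up" for g in hypo[64:134]})
        xtab = cross_tabulate_expression(hyper, hypo, de)
        assert xtab.loc["hyper"].to_dict() == {
            "down": 488, "up": 493, "unchanged": 6, "absent": 55, "total_expressed": 987,
        }
        assert xtab.loc["hypo"].to_dict() == {
            "down": 64, "up": 70, "unchanged": 0, "absent": 18, "total_expressed": 134,
        }

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate_expression({"g"}, set(), {"g": "sideways"})


class TestGeneSets:
    def test_methylated_gene_set(self, genome_small, features_small):
        gene = features_small.genes.iloc[0]
        inside = pd.DataFrame(
            {"replicon": [gene.replicon], "pos": [int(gene.start) + 1], "strand": ["+"],
             "context": ["CG"], "trinucleotide": ["CGA"]}
        )
        calls = make_calls_frame(inside, coverage=10, k=10, is_mc=True)
        assert methylated_gene_set(calls, features_small) == {gene.gene_id}

    def test_mc_site_set_identity_triples(self):
        sites = pd.DataFrame(
            {"replicon": ["r", "r"], "pos": [3, 4], "strand": ["+", "-"],
             "context": "CG", "trinucleotide": "CGA"}
        )
        calls = make_calls_frame(sites, coverage=10, k=10, is_mc=[True, False])
        assert mc_site_set(calls) == {("r", 3, "+")}
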