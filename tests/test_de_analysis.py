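import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senescan.de_analysis import (filter_de, overlap_sets,
                                  signature_concordance, summarize_categories)
from senescan.types import AnalysisConfig, DEGeneSet

from conftest import de


class TestFilterDE:
    @pytest.mark.parametrize("lfc, p, expected", [
        (0.9, 0.01, "up"),       # clears both thresholds
        (-0.7, 0.2, None),       # p fails
        (0.4, 0.04, "up"),       # inclusive boundary on |log2FC|
        (-0.4, 0.05, "down"),    # inclusive boundary on p too
        (0.39, 0.01, None),      # fold change too small
        (0.0, 0.0, None),        # zero change is neither direction
    ])
    def test_threshold_rules(self, config, lfc, p, expected):
        sets = filter_de([de("g", lfc=lfc, p=p)], config)
        s = sets[("thymus", "y-o")]
        direction = "up" if "g" in s.up else "down" if "g" in s.down else None
        assert direction == expected

    def test_adjusted_p_flag(self):
        record = de("g", lfc=1.0, p=0.01, adj=0.2)
        raw = AnalysisConfig(use_adjusted_p=False)
        adj = AnalysisConfig(use_adjusted_p=True)
        assert "g" in filter_de([record], raw)[("thymus", "y-o")].up
        assert "g" not in filter_de([record], adj)[("thymus", "y-o")].genes

    def test_partitions_by_tissue_and_comparison(self, config):
        records = [de("g1", tissue="thymus"), de("g1", tissue="spleen", lfc=-1.0),
                   de("g2", tissue="thymus", comparison="y-m")]
        sets = filter_de(records, config)
        assert sets[("thymus", "y-o")].up == {"g1"}
        assert sets[("spleen", "y-o")].down == {"g1"}
        assert sets[("thymus", "y-m")].up == {"g2"}

    @given(lfc=st.floats(-3, 3), p=st.floats(0, 1),
           p_lo=st.floats(0.001, 0.05), lfc_hi=st.floats(0.4, 2.0))
    @settings(deadline=None, max_examples=200)
    def test_monotone_in_thresholds(self, lfc, p, p_lo, lfc_hi):
        """Lowering p_cutoff or raising lfc_cutoff never adds a gene."""
        loose = AnalysisConfig(p_cutoff=0.05, lfc_cutoff=0.4)
        tight = AnalysisConfig(p_cutoff=p_lo, lfc_cutoff=lfc_hi)
        record = de("g", lfc=lfc, p=p)
        in_tight = filter_de([record], tight)[("thymus", "y-o")].genes
        in_loose = filter_de([record], loose)[("thymus", "y-o")].genes
        assert in_tight <= in_loose


class TestOverlap:
    def test_basic_partition(self):
        part = overlap_sets({"a", "b", "c"}, {"b", "c", "d"})
        assert part.a_only == {"a"}
        assert part.common == {"b", "c"}
        assert part.b_only == {"d"}

    def test_identity_case(self):
        part = overlap_sets({"x", "y"}, {"x", "y"})
        assert part.a_only == part.b_only == frozenset()
        assert part.common == {"x", "y"}

    def test_thymus_partition_worked_example(self):
        """1034 thymus y-o genes with 516 shared with spleen leave 518
        thymus-specific, reproducing the reported internally consistent
        partition."""
        thymus = {f"t{i}" for i in range(518)} | {f"c{i}" for i in range(516)}
        spleen = {f"s{i}" for i in range(1680)} | {f"c{i}" for i in range(516)}
        assert len(thymus) == 1034
        part = overlap_sets(thymus, spleen)
        assert len(part.common) == 516
        assert len(part.a_only) == 518
        assert len(part.a_only) + len(part.common) == len(thymus)

    @given(st.sets(st.integers(0, 60)), st.sets(st.integers(0, 60)))
    @settings(deadline=None, max_examples=200)
    def test_conservation_and_disjointness(self, a, b):
        part = overlap_sets(map(str, a), map(str, b))
        assert len(part.a_only) + len(part.common) == len(a)
        assert len(part.b_only) + len(part.common) == len(b)
        assert len(part.a_only | part.b_only | part.common) == len(a | b)
        assert not (part.a_only & part.b_only or part.a_only & part.common
                    or part.b_only & part.common)


class TestCategorySummary:
    def test_hand_counts(self):
        de_set = DEGeneSet("thymus", "y-o", up=frozenset({"g1"}),
                           down=frozenset({"g2", "g3"}))
        cats = {g: ("mitosis", "na") for g in ("g1", "g2", "g3")}
        (summary,) = summarize_categories(de_set, cats)
        assert (summary.n_up, summary.n_down) == (1, 2)
        assert summary.pct_down == pytest.approx(200 / 3)

    def test_empty_de_set(self):
        de_set = DEGeneSet("thymus", "y-o", frozenset(), frozenset())
        assert summarize_categories(de_set, {"g": ("mitosis", "na")}) == []

    def test_unassigned_bucket_and_roles(self):
        de_set = DEGeneSet("t", "y-o", up=frozenset({"inh", "x"}),
                           down=frozenset({"act"}))
        cats = {"inh": ("cc", "inhibitor"), "act": ("cc", "activator")}
        by_cat = {s.category: s for s in
                  summarize_categories(de_set, cats, split_roles=True)}
        assert by_cat["unassigned"].n_up == 1
        assert by_cat["cc"].n_up == 1 and by_cat["cc"].n_down == 1
        assert by_cat["cc [inhibitor]"].n_up == 1
        assert by_cat["cc [activator]"].n_down == 1

    def test_table_denominator_variant(self):
        de_set = DEGeneSet("t", "y-o", up=frozenset(), down=frozenset({"g1", "g2"}))
        cats = {g: ("S phase", "na") for g in ("g1", "g2", "g3", "g4")}
        (s,) = summarize_categories(de_set, cats, table_genes=["g1", "g2", "g3", "g4"])
        assert s.pct_down == 100.0            # of DE genes in the category
        assert s.pct_down_of_table == 50.0    # of category genes on the table

    def test_all_planted_down_gives_100_percent(self, config):
        """Ten planted-down genes in one category mirror an all-down row."""
        genes = [f"s{i}" for i in range(10)]
        records = [de(g, lfc=-1.0, p=0.001) for g in genes]
        sets = filter_de(records, config)
        cats = {g: ("S phase progression", "na") for g in genes}
        (s,) = summarize_categories(sets[("thymus", "y-o")], cats)
        assert s.n_down == 10 and s.pct_down == 100.0


class TestSignatureConcordance:
    def test_reported_direction_cases(self, config):
        # Ctgf: expected up, spleen y-o +1.9 -> consistent;
        # Gfap: expected up, spleen y-o -2.2 -> inconsistent
        records = [de("Ctgf", tissue="spleen", lfc=1.9, p=0.01),
                   de("Gfap", tissue="spleen", lfc=-2.2, p=0.01)]
        sig = {"Ctgf": "up", "Gfap": "up"}
        result = signature_concordance(records, sig, config)
        assert (result.n_consistent, result.n_evaluated) == (1, 2)

    def test_toy_hand_count(self, config):
        records = [de("a", lfc=1.0), de("b", lfc=-1.0), de("c", lfc=2.0),
                   de("d", lfc=0.5)]
        sig = {"a": "up", "b": "down", "c": "up", "d": "down"}
        result = signature_concordance(records, sig, config)
        assert (result.n_consistent, result.n_evaluated) == (3, 4)
        assert result.fraction == 0.75

    def test_na_and_unfiltered_excluded(self, config):
        records = [de("a", lfc=1.0), de("b", lfc=1.0, p=0.9), de("c", lfc=1.0)]
        sig = {"a": "up", "b": "up", "c": "na"}
        result = signature_concordance(records, sig, config)
        assert result.n_evaluated == 1

    def test_zero_lfc_inconsistent(self):
        config = AnalysisConfig(lfc_cutoff=0.0)
        records = [de("a", lfc=0.0, p=0.01)]
        result = signature_concordance(records, {"a": "up"}, config)
        assert (result.n_consistent, result.n_evaluated) == (0, 1)

    def test_row_order_invariance(self, config):
        rng = random.Random(7)
        records = [de(f"g{i}", lfc=rng.choice([-1.0, 1.0]), p=rng.random())
                   for i in range(40)]
        sig = {f"g{i}": rng.choice(["up", "down", "na"]) for i in range(40)}
        baseline = signature_concordance(records, sig, config)
        for _ in range(5):
            rng.shuffle(records)
            assert signature_concordance(records, sig, config) == baseline
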