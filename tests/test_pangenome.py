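import numpy as np
import pandas as pd
import pytest

from acetopan.clustering import OrthologGroup
from acetopan.io_formats import GenomePanel, ProteinRecord
from acetopan.pangenome import (
    annotation_summary,
    classify_product,
    load_genome_table,
    partition,
    presence_matrix,
    subtract_outgroups,
    table_stats,
)
from acetopan.synthetic import random_protein

from conftest import make_panel


def panel3():
    return make_panel(
        {
            "g1": {"g1a": "MKVLLA", "g1b": "MKVLLG"},
            "g2": {"g2a": "MKVLLA"},
            "g3": {"g3a": "MKVLLA"},
        }
    )


class TestPresenceMatrix:
    def test_paralogs_collapse_to_single_presence(self):
        groups = [OrthologGroup("OG1", ["g1a", "g1b", "g2a"], {"g1", "g2"})]
        m = presence_matrix(groups, panel3())
        assert list(m.loc["OG1"]) == [1, 1, 0]

    def test_singleton_group(self):
        groups = [OrthologGroup("OG1", ["g3a"], {"g3"})]
        m = presence_matrix(groups, panel3())
        assert list(m.loc["OG1"]) == [0, 0, 1]

    def test_row_sums_equal_occupancy_sizes(self, small_panel_truth):
        panel, truth = small_panel_truth
        groups = [
            OrthologGroup(fid, fam.member_ids, set(fam.occupancy))
            for fid, fam in truth.families.items()
        ]
        m = presence_matrix(groups, panel)
        for g in groups:
            assert m.loc[g.group_id].sum() == len(g.occupancy)

    def test_unknown_genome_is_error(self):
        groups = [OrthologGroup("OG1", ["x"], {"nope"})]
        with pytest.raises(ValueError, match="unknown genome"):
            presence_matrix(groups, panel3())


class TestPartition:
    def matrix(self, rows, genomes=("g1", "g2", "g3")):
        m = pd.DataFrame(rows, columns=list(genomes))
        m.index = [f"OG{i}" for i in range(len(rows))]
        m.index.name = "group_id"
        return m

    def test_three_genome_toy(self):
        part = partition(self.matrix([[1, 1, 1], [1, 1, 0], [0, 0, 1]]))
        assert part.group_counts == {"core": 1, "dispensable": 1, "specific": 1}

    def test_gene_counts_include_paralogs(self):
        # a full-occupancy group of 26 members contributes 26 core genes
        genomes = [f"g{i}" for i in range(14)]
        members = [f"g{i % 14}|p{i}" for i in range(26)]
        group = OrthologGroup("OG0", members, set(genomes))
        m = self.matrix([[1] * 14], genomes=genomes)
        part = partition(m, [group])
        assert part.group_counts["core"] == 1
        assert part.gene_counts["core"] == 26

    def test_all_core_means_no_other_classes(self):
        part = partition(self.matrix([[1, 1, 1], [1, 1, 1]]))
        assert part.group_counts == {"core": 2, "dispensable": 0, "specific": 0}

    def test_all_zero_row_is_error(self):
        with pytest.raises(ValueError, match="all-zero"):
            partition(self.matrix([[0, 0, 0]]))

    def test_fewer_than_three_genomes_rejected(self):
        m = pd.DataFrame([[1, 1]], columns=["g1", "g2"], index=["OG0"])
        with pytest.raises(ValueError):
            partition(m)

    def test_counts_sum_to_totals(self, small_panel_truth):
        panel, truth = small_panel_truth
        groups = [
            OrthologGroup(fid, fam.member_ids, set(fam.occupancy))
            for fid, fam in truth.families.items()
        ]
        m = presence_matrix(groups, panel)
        part = partition(m, groups)
        assert sum(part.group_counts.values()) == len(groups)
        assert sum(part.gene_counts.values()) == len(panel.proteins)


class TestAnnotationSummary:
    @pytest.mark.parametrize(
        "product,expected",
        [
            ("hypothetical protein", "hypothetical"),
            ("Hypothetical Protein", "hypothetical"),
            ("", "unknown"),
            ("unknown function", "unknown"),
            ("uncharacterized protein", "unknown"),
            ("acetate kinase", "annotated"),
        ],
    )
    def test_product_classification(self, product, expected):
        assert classify_product(product) == expected

    def test_fractions_sum_to_one_per_class(self):
        panel = make_panel({"g1": {"a": "MKVL", "b": "MKVA"},
                            "g2": {"c": "MKVL"}, "g3": {"d": "MKVL"}})
        panel.proteins[0] = ProteinRecord("a", "g1", "MKVL", "hypothetical protein")
        panel.proteins[1] = ProteinRecord("b", "g1", "MKVA", "acetate kinase")
        groups = [
            OrthologGroup("OG1", ["a", "b"], {"g1"}),
            OrthologGroup("OG2", ["c", "d"], {"g2", "g3"}),
        ]
        m = presence_matrix(groups, panel)
        part = partition(m, groups)
        summary = annotation_summary(part, groups, panel)
        assert summary["specific"]["hypothetical"] == pytest.approx(0.5)
        assert summary["specific"]["annotated"] == pytest.approx(0.5)
        assert summary["dispensable"]["unknown"] == pytest.approx(1.0)
        for cls in summary.values():
            assert sum(cls.values()) in (0.0, pytest.approx(1.0))


class TestSubtractOutgroups:
    def build(self, rng):
        core_seq_a = random_protein(120, rng)
        core_seq_b = random_protein(120, rng)
        panel = make_panel(
            {
                "g1": {"g1a": core_seq_a, "g1b": core_seq_b},
                "g2": {"g2a": core_seq_a, "g2b": core_seq_b},
                "g3": {"g3a": core_seq_a, "g3b": core_seq_b},
            }
        )
        groups = [
            OrthologGroup("OG1", ["g1a", "g2a", "g3a"], {"g1", "g2", "g3"}),
            OrthologGroup("OG2", ["g1b", "g2b", "g3b"], {"g1", "g2", "g3"}),
        ]
        return panel, groups, core_seq_a, core_seq_b

    def test_strong_outgroup_hit_removes_group(self, rng):
        panel, groups, seq_a, _ = self.build(rng)
        outgroup = [ProteinRecord("out1", "og", seq_a)]
        retained, removed = subtract_outgroups(groups, panel, outgroup)
        assert [g.group_id for g in removed] == ["OG1"]
        assert [g.group_id for g in retained] == ["OG2"]

    def test_subthreshold_hit_retains_group(self, rng):
        panel, groups, seq_a, _ = self.build(rng)
        # share only a short motif: a raw score well under 50
        outgroup = [ProteinRecord("out1", "og", seq_a[:8] + random_protein(100, rng))]
        retained, removed = subtract_outgroups(groups, panel, outgroup)
        assert removed == []
        assert len(retained) == 2

    def test_empty_outgroup_is_error(self, rng):
        panel, groups, _, _ = self.build(rng)
        with pytest.raises(ValueError, match="outgroup"):
            subtract_outgroups(groups, panel, [])

    def test_adding_outgroups_never_grows_core(self, rng):
        panel, groups, seq_a, seq_b = self.build(rng)
        one = [ProteinRecord("out1", "og", seq_a)]
        two = one + [ProteinRecord("out2", "og", seq_b)]
        r1, _ = subtract_outgroups(groups, panel, one)
        r2, _ = subtract_outgroups(groups, panel, two)
        assert {g.group_id for g in r2} <= {g.group_id for g in r1}


class TestTableStats:
    def test_single_genome(self):
        df = pd.DataFrame({"genome_size_bp": [2_500_000], "gc_percent": [41.0]})
        stats = table_stats(df)
        assert stats["mean_size_mb"] == 2.5
        assert stats["mean_gc_percent"] == 41.0
        assert stats["gc_min_percent"] == stats["gc_max_percent"] == 41.0

    def test_permutation_invariant(self):
        table = load_genome_table()
        shuffled = table.sample(frac=1.0, random_state=4)
        assert table_stats(table) == table_stats(shuffled)

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            table_stats(pd.DataFrame({"genome_size_bp": [], "gc_percent": []}))

    def test_packaged_table_has_23_rows_and_14_panel_strains(self):
        table = load_genome_table()
        assert len(table) == 23
        assert table.in_analysis_panel.sum() == 14
        assert table.accession.is_unique
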