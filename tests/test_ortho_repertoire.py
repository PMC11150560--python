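import numpy as np
import pandas as pd
import pytest

from cyanosym.ortho_repertoire import (
    OrthoError,
    OrthoMatrix,
    ancestral_retention,
    annotation_proportions,
    classify_groups,
    repertoire_size,
    retention_sets,
    select_phylo_markers,
)


def tiny_matrix():
    counts = pd.DataFrame(
        {
            "P1": [1, 1, 1, 0, 2, 1],
            "P2": [1, 1, 0, 0, 1, 1],
            "S1": [1, 1, 1, 0, 1, 1],
            "S2": [1, 0, 1, 0, 1, 1],
            "SymA": [1, 1, 0, 1, 0, 1],
            "SymB": [0, 1, 0, 1, 0, 1],
        },
        index=[f"OG{i}" for i in range(1, 7)],
    )
    labels = {
        "P1": {"free_living", "prochlorococcus_clade"},
        "P2": {"free_living", "prochlorococcus_clade"},
        "S1": {"free_living", "synechococcus_5_1"},
        "S2": {"free_living", "synechococcus_5_1"},
        "SymA": {"symbiont"},
        "SymB": {"symbiont"},
    }
    return OrthoMatrix(counts, labels, unassigned={"SymA": 2})


class TestRepertoireSize:
    def test_orthogroups_plus_unassigned(self):
        m = tiny_matrix()
        # SymA present in OG1, OG2, OG4, OG6 -> 4, plus 2 unassigned
        assert repertoire_size(m, "SymA") == 6

    def test_zero_for_empty_genome(self):
        counts = pd.DataFrame({"A": [1], "B": [0]}, index=["OG1"])
        m = OrthoMatrix(counts, {"A": {"free_living"}, "B": {"symbiont"}})
        assert repertoire_size(m, "B") == 0

    def test_extra_copies_do_not_count(self):
        m = tiny_matrix()
        base = repertoire_size(m, "P1")
        doubled = m.counts.copy()
        doubled.loc["OG1", "P1"] = 5
        m2 = OrthoMatrix(doubled, m.labels, m.unassigned)
        assert repertoire_size(m2, "P1") == base

    def test_unknown_genome_rejected(self):
        with pytest.raises(OrthoError):
            repertoire_size(tiny_matrix(), "nope")


class TestClassifyGroups:
    def test_three_way_partition(self):
        cats = classify_groups(tiny_matrix())
        assert cats["OG1"] == "core"  # in all four free-living genomes
        assert cats["OG2"] == "picocyanobacterial_ancestral"  # absent from S2
        assert cats["OG3"] == "picocyanobacterial_ancestral"  # absent from P2
        assert cats["OG4"] == "accessory"  # symbiont-only
        assert cats["OG5"] == "core"  # copy number 2 still counts as present
        assert cats["OG6"] == "core"
        assert cats.value_counts().sum() == 6  # total classification

    def test_missing_label_class_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["OG1"])
        m = OrthoMatrix(counts, {"A": {"free_living", "prochlorococcus_clade"}})
        with pytest.raises(OrthoError, match="synechococcus_5_1"):
            classify_groups(m)


class TestAncestralRetention:
    def test_printed_counts_reproduced(self, printed_fixture):
        matrix, _ = printed_fixture
        cats = classify_groups(matrix)
        report = ancestral_retention(matrix, cats, "CregCyn", "OmCyn")
        assert report.ancestral_size == 2369
        assert (report.retained_a, report.retained_b) == (1388, 1405)
        assert report.shared == 1259
        assert report.lost_both == 835
        assert round(report.retained_pct_a) == 59
        assert round(report.retained_pct_b) == 59
        assert round(report.shared_pct_a, 1) == 90.7
        assert round(report.shared_pct_b, 1) == 89.6

    def test_small_overlap_example(self):
        counts = pd.DataFrame(
            {
                "P1": [1, 1, 1], "P2": [1, 1, 1], "S1": [1, 1, 1], "S2": [1, 1, 1],
                "A": [1, 1, 0], "B": [0, 1, 1],
            },
            index=["x", "y", "z"],
        )
        labels = {
            "P1": {"free_living", "prochlorococcus_clade"},
            "P2": {"free_living", "prochlorococcus_clade"},
            "S1": {"free_living", "synechococcus_5_1"},
            "S2": {"free_living", "synechococcus_5_1"},
            "A": {"symbiont"}, "B": {"symbiont"},
        }
        m = OrthoMatrix(counts, labels)
        report = ancestral_retention(m, classify_groups(m), "A", "B")
        assert report.shared == 1
        assert report.shared_pct_a == pytest.approx(50.0)
        assert report.shared_pct_b == pytest.approx(50.0)

    def test_empty_symbiont_gives_missing_percentages(self):
        counts = pd.DataFrame(
            {"P1": [1], "S1": [1], "A": [0], "B": [1]}, index=["x"]
        )
        labels = {
            "P1": {"free_living", "prochlorococcus_clade"},
            "S1": {"free_living", "synechococcus_5_1"},
            "A": {"symbiont"}, "B": {"symbiont"},
        }
        m = OrthoMatrix(counts, labels)
        report = ancestral_retention(m, classify_groups(m), "A", "B")
        assert report.retained_a == 0 and report.shared == 0
        assert report.shared_pct_a is None

    def test_inclusion_exclusion_closes(self, printed_fixture):
        matrix, _ = printed_fixture
        report = ancestral_retention(
            matrix, classify_groups(matrix), "CregCyn", "OmCyn"
        )
        assert report.shared <= min(report.retained_a, report.retained_b)
        assert report.lost_both == (
            report.ancestral_size - report.retained_a - report.retained_b + report.shared
        )


class TestAnnotationProportions:
    def test_printed_annotation_percentages(self, printed_fixture):
        matrix, annotation = printed_fixture
        cats = classify_groups(matrix)
        sets = retention_sets(matrix, cats, "CregCyn", "OmCyn")
        fracs = annotation_proportions(sets, annotation)
        assert round(100 * fracs["ancestral"], 1) == 48.8
        assert round(100 * fracs["shared"], 1) == 67.5
        assert round(100 * fracs["a_only"], 1) == 45.0
        assert round(100 * fracs["b_only"], 1) == 36.3
        assert round(100 * fracs["lost_both"], 1) == 23.5
        # shared annotated groups as a share of each symbiont's annotated set
        ann_a = sum(1 for g in sets["retained_a"] if annotation.get(g, False))
        ann_b = sum(1 for g in sets["retained_b"] if annotation.get(g, False))
        ann_shared = sum(1 for g in sets["shared"] if annotation.get(g, False))
        assert ann_shared == 850
        assert round(100 * ann_shared / ann_a, 1) == 93.6
        assert round(100 * ann_shared / ann_b, 1) == 94.1

    def test_simple_fraction(self):
        fracs = annotation_proportions(
            {"s": {"a", "b", "c", "d"}}, {"a": True}
        )
        assert fracs["s"] == pytest.approx(0.25)

    def test_empty_set_missing(self):
        assert annotation_proportions({"s": set()}, {})["s"] is None


class TestSelectPhyloMarkers:
    def test_strictly_single_copy_everywhere_selected(self):
        m = tiny_matrix()
        markers = select_phylo_markers(m, conservation=0.99)
        assert markers == ["OG1", "OG6"]

    def test_conservation_fraction_enforced(self):
        m = tiny_matrix()
        # OG2 single-copy in 3/4 free-living genomes: passes at 0.75, not 0.99
        assert "OG2" in select_phylo_markers(m, conservation=0.75)
        assert "OG2" not in select_phylo_markers(m, conservation=0.99)

    def test_paralog_disqualifies(self):
        m = tiny_matrix()
        # OG5 present in all free-living genomes but duplicated in P1
        assert "OG5" not in select_phylo_markers(m, conservation=0.5)

    def test_empty_scope_rejected(self):
        counts = pd.DataFrame({"A": [1]}, index=["OG1"])
        m = OrthoMatrix(counts, {"A": {"symbiont"}})
        with pytest.raises(OrthoError):
            select_phylo_markers(m)
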