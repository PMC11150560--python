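import numpy as np
import pytest

from cyanosym.hit_frequency import (
    HitRecord,
    OrganismFrequencyTable,
    ScoreParams,
    organism_frequency,
    presence_track,
    protein_score,
    read_hit_table,
    score_proteins,
    window_score_track,
)
from cyanosym.sequence_io import Feature, FeatureTable
from cyanosym.tetra_windows import Window


def hits_of(query, organisms):
    return [
        HitRecord(query_id=query, subject_organism=o, rank=r + 1, bitscore=100 - r)
        for r, o in enumerate(organisms)
    ]


class TestOrganismFrequency:
    def test_minmax_arithmetic(self):
        # raw counts A:10, B:2, C:2 over two queries
        hbq = {
            "q1": hits_of("q1", ["A", "A", "A", "A", "B"]),
            "q2": hits_of("q2", ["A", "A", "A", "B", "C"]),
            "q3": hits_of("q3", ["A", "A", "A", "C"]),
        }
        table = organism_frequency(hbq)
        assert table.raw == {"A": 10, "B": 2, "C": 2}
        assert table.normalized == {"A": 1.0, "B": 0.0, "C": 0.0}

    def test_intermediate_normalization(self):
        raw = {"A": 8, "B": 6, "C": 2}
        hbq = {
            f"q{i}": hits_of(f"q{i}", orgs)
            for i, orgs in enumerate(
                [["A"] * 4, ["A"] * 4, ["B"] * 3, ["B"] * 3, ["C", "C"]]
            )
        }
        table = organism_frequency(hbq, ScoreParams(top_k=4))
        assert table.raw == raw
        assert table.normalized["A"] == 1.0
        assert table.normalized["B"] == pytest.approx(2 / 3, abs=1e-4)
        assert table.normalized["C"] == 0.0

    def test_single_organism_maps_to_one(self):
        table = organism_frequency({"q": hits_of("q", ["A"] * 5)})
        assert table.normalized == {"A": 1.0}

    def test_excluded_label_skipped_and_next_hit_takes_slot(self):
        params = ScoreParams(top_k=2, excluded_labels=frozenset({"bad"}))
        table = organism_frequency({"q": hits_of("q", ["bad", "A", "B", "C"])}, params)
        assert table.raw == {"A": 1, "B": 1}

    def test_empty_hits_give_empty_table(self):
        table = organism_frequency({})
        assert table.raw == {} and table.normalized == {}

    def test_query_order_invariance(self):
        queries = {f"q{i}": hits_of(f"q{i}", ["A", "B", "C", "A", "B"]) for i in range(5)}
        fwd = organism_frequency(dict(queries))
        rev = organism_frequency(dict(reversed(list(queries.items()))))
        assert fwd.raw == rev.raw

    def test_raising_top_k_only_adds_organisms(self):
        hbq = {"q": hits_of("q", ["A", "B", "C", "D", "E", "F", "G"])}
        seen = set()
        for k in range(1, 8):
            raw = organism_frequency(hbq, ScoreParams(top_k=k)).raw
            assert seen <= set(raw)
            seen = set(raw)


class TestProteinScore:
    freqs = OrganismFrequencyTable(
        raw={}, normalized={"A": 1.0, "B": 0.5, "C": 0.25, "D": 0.0}
    )

    def test_all_top_hits_most_common_scores_one(self):
        ps = protein_score("q", hits_of("q", ["A"] * 5), self.freqs)
        assert ps.score == 1.0 and ps.n_hits_used == 5

    def test_mean_of_five(self):
        ps = protein_score("q", hits_of("q", ["A", "B", "B", "D", "D"]), self.freqs)
        assert ps.score == pytest.approx(0.4)

    def test_fewer_than_k_hits_averages_available(self):
        ps = protein_score("q", hits_of("q", ["A", "C", "C"]), self.freqs)
        assert ps.score == pytest.approx(0.5) and ps.n_hits_used == 3

    def test_no_usable_hits_is_missing(self):
        params = ScoreParams(excluded_labels=frozenset({"X"}))
        freqs = OrganismFrequencyTable(raw={}, normalized={})
        ps = protein_score("q", hits_of("q", ["X", "X"]), freqs, params)
        assert ps.score is None and ps.n_hits_used == 0

    def test_scores_stay_in_unit_interval(self, rng):
        orgs = list("ABCD")
        hbq = {
            f"q{i}": hits_of(f"q{i}", rng.choice(orgs, size=5)) for i in range(30)
        }
        for ps in score_proteins(hbq).values():
            assert ps.score is not None and 0.0 <= ps.score <= 1.0


class TestWindowScoreTrack:
    windows = [Window(0, 0, 100), Window(1, 90, 190)]

    def _scores(self, mapping):
        hbq = {}
        freqs = OrganismFrequencyTable(raw={}, normalized={})
        from cyanosym.hit_frequency import ProteinScore

        return {
            pid: ProteinScore(pid, val, 5 if val is not None else 0)
            for pid, val in mapping.items()
        }

    def test_unweighted_mean(self):
        cds = FeatureTable(
            [Feature("a", "g", 0, 50, "+", "CDS"), Feature("b", "g", 50, 80, "+", "CDS")]
        )
        track = window_score_track(
            self._scores({"a": 0.2, "b": 0.8}), cds, self.windows[:1]
        )
        assert track.mean_score[0] == pytest.approx(0.5)

    def test_boundary_spanning_gene_counts_in_both_windows(self):
        cds = FeatureTable(
            [
                Feature("span", "g", 85, 120, "+", "CDS"),  # crosses both windows
                Feature("only0", "g", 0, 50, "+", "CDS"),
            ]
        )
        track = window_score_track(
            self._scores({"span": 0.0, "only0": 1.0}), cds, self.windows
        )
        assert track.mean_score[0] == pytest.approx(0.5)
        assert track.mean_score[1] == pytest.approx(0.0)

    def test_window_without_cds_is_missing(self):
        cds = FeatureTable([Feature("a", "g", 0, 50, "+", "CDS")])
        track = window_score_track(self._scores({"a": 0.7}), cds, self.windows)
        assert np.isnan(track.mean_score[1]) and track.n_genes[1] == 0

    def test_missing_scores_omitted_not_imputed(self):
        cds = FeatureTable(
            [Feature("a", "g", 0, 50, "+", "CDS"), Feature("b", "g", 10, 60, "+", "CDS")]
        )
        track = window_score_track(
            self._scores({"a": 0.6, "b": None}), cds, self.windows[:1]
        )
        assert track.mean_score[0] == pytest.approx(0.6)
        assert track.n_genes[0] == 1


class TestPresenceTrack:
    def test_focal_found_anywhere_in_top_k(self):
        hbq = {"q": hits_of("q", ["X", "Y", "Z", "Y", "Y"])}
        assert presence_track(hbq, {"X"}) == {"q": True}

    def test_focal_absent(self):
        hbq = {"q": hits_of("q", ["Y"] * 5)}
        assert presence_track(hbq, {"X"}) == {"q": False}

    def test_no_hits_is_false(self):
        assert presence_track({"q": []}, {"X"}) == {"q": False}

    def test_focal_beyond_top_k_not_counted(self):
        hbq = {"q": hits_of("q", ["Y", "Y", "Y", "Y", "Y", "X"])}
        assert presence_track(hbq, {"X"}, ScoreParams(top_k=5)) == {"q": False}


class TestReadHitTable:
    def test_thirteen_column_dialect(self, tmp_path):
        p = tmp_path / "hits.tsv"
        rows = [
            "q1\ts1\t98.0\t200\t4\t0\t1\t200\t1\t200\t1e-50\t500\tOrgA",
            "q1\ts2\t95.0\t180\t9\t0\t1\t180\t1\t180\t1e-40\t450\tOrgB",
        ]
        p.write_text("\n".join(rows) + "\n")
        hits = read_hit_table(p)
        assert [h.subject_organism for h in hits["q1"]] == ["OrgA", "OrgB"]
        assert [h.rank for h in hits["q1"]] == [1, 2]

    def test_separate_organism_map(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t98.0\t200\t4\t0\t1\t200\t1\t200\t1e-50\t500\n")
        m = tmp_path / "map.tsv"
        m.write_text("s1\tOrgA\n")
        hits = read_hit_table(p, organism_map=m)
        assert hits["q1"][0].subject_organism == "OrgA"

    def test_missing_map_entry_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q1\ts1\t98.0\t200\t4\t0\t1\t200\t1\t200\t1e-50\t500\n")
        with pytest.raises(ValueError, match="organism map"):
            read_hit_table(p, organism_map={"other": "OrgA"})
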