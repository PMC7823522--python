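"""Library ingestion, similarity search, extended MCS, Bray–Curtis, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from rdkit import Chem

from scaffoldmine.screening import (
    BenchmarkEntry,
    WeightConfig,
    _competition_ranks,
    bray_curtis_similarity,
    default_weights,
    extended_mcs_score,
    grid_search_weights,
    ingest,
    mixed_score,
    rank_benchmark,
    screen,
    tanimoto_topN,
)

from oracles import exhaustive_mcs


def _db(pairs):
    return ingest({"test": pairs})


class TestIngest:
    def test_same_molecule_two_notations_collapses(self):
        db = _db([("a", "OCC"), ("b", "CCO")])
        assert len(db) == 1

    def test_empty_library_is_an_error(self):
        with pytest.raises(ValueError):
            _db([])

    def test_invalid_records_are_skipped_and_counted(self):
        with pytest.warns(UserWarning, match="skipped"):
            db = _db([("a", "CCO"), ("bad", "xyz(((")])
        assert len(db) == 1 and db.skipped == 1

    def test_records_carry_seven_component_psm_vectors(self):
        rng = np.random.default_rng(0)
        pairs = [(f"m{i}", "C" * int(rng.integers(2, 8)) + "O") for i in range(20)]
        db = _db(pairs)
        for rec in db.records:
            assert len(rec.psm_vector) == 7

    def test_smiles_file_ingestion(self, tmp_path):
        f = tmp_path / "lib.smi"
        f.write_text("CCO\tethanol\nc1ccccc1\tbenzene\n")
        db = ingest([f])
        assert {r.id for r in db.records} == {"ethanol", "benzene"}


class TestTanimoto:
    def test_identical_molecule_ranks_first_with_similarity_one(self):
        db = _db([("target", "CC(=O)NC1=CC=C(O)C=C1"), ("other", "CCCCC")])
        top = tanimoto_topN(["CC(=O)Nc1ccc(O)cc1"], db, 2)
        assert top[0][0].id == "target" and top[0][1] == pytest.approx(1.0)

    def test_small_db_returns_everything(self):
        db = _db([("a", "CCO"), ("b", "CCC")])
        assert len(tanimoto_topN(["CCO"], db, 50)) == 2

    def test_no_shared_bits_scores_zero(self):
        db = _db([("a", "CCO"), ("b", "c1ccccc1")])
        scores = dict((r.id, s) for r, s in tanimoto_topN(["CCO"], db, 2))
        assert scores["b"] == 0.0

    def test_result_invariant_to_insertion_order(self):
        pairs = [("a", "CCO"), ("b", "CCN"), ("c", "CCC")]
        top1 = tanimoto_topN(["CCO"], _db(pairs), 3)
        top2 = tanimoto_topN(["CCO"], _db(list(reversed(pairs))), 3)
        assert [r.id for r, _ in top1] == [r.id for r, _ in top2]


class TestExtendedMCS:
    def test_identical_single_fragment_scores_one(self):
        assert extended_mcs_score(["CCO"], "CCO") == pytest.approx(1.0)

    def test_disjoint_fragment_scores_zero(self):
        assert extended_mcs_score(["CCCC"], "O=S=O") == pytest.approx(0.0)

    def test_exact_partition_of_disconnected_target_scores_one(self):
        assert extended_mcs_score(["CCO", "CN"], "CCO.CN") == pytest.approx(1.0)

    def test_partial_match_is_mean_of_query_and_target_fractions(self):
        # query CCO (3 atoms + 2 bonds) vs target CCOCC (5 atoms + 4 bonds):
        # common CCO -> matched 5; mean(5/5, 5/9)
        expected = 0.5 * (1.0 + 5 / 9)
        assert extended_mcs_score(["CCO"], "CCOCC") == pytest.approx(expected)

    def test_query_only_normalization(self):
        assert extended_mcs_score(["CCO"], "CCOCC", normalization="query") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "query,target",
        [("CCO", "CCO"), ("CCC", "CC"), ("CC(C)O", "CCO"), ("CCNCC", "CCN"),
         ("CC(N)C(=O)O", "CC(O)C(=O)O")],
    )
    def test_single_fragment_matches_exhaustive_oracle(self, query, target):
        atoms, bonds = exhaustive_mcs(query, target)
        matched = atoms + bonds
        qm = Chem.MolFromSmiles(query)
        tm = Chem.MolFromSmiles(target)
        qtot = qm.GetNumAtoms() + qm.GetNumBonds()
        ttot = tm.GetNumAtoms() + tm.GetNumBonds()
        expected = 0.5 * (matched / qtot + matched / ttot)
        assert extended_mcs_score([query], target) == pytest.approx(expected)

    def test_two_fragments_consume_the_target_sequentially(self):
        # dipeptide-like target: each fragment matches a different part
        target = "NCC(=O)NC(C)C(=O)O"
        score_both = extended_mcs_score(["NCC(=O)O", "NC(C)C(=O)O"], target)
        score_one = extended_mcs_score(["NCC(=O)O"], target)
        assert score_both > score_one

    def test_more_than_ten_fragments_rejected(self):
        with pytest.raises(ValueError):
            extended_mcs_score(["C"] * 11, "CCC")

    def test_unparseable_fragment_is_an_error(self):
        with pytest.raises(ValueError):
            extended_mcs_score(["((("], "CCC")


class TestBrayCurtis:
    def test_identical_vectors_score_one(self):
        assert bray_curtis_similarity([2, 1, 0], [2, 1, 0]) == 1.0

    def test_disjoint_support_scores_zero(self):
        assert bray_curtis_similarity([1, 0], [0, 1]) == 0.0

    def test_hand_computed_example(self):
        assert bray_curtis_similarity([2], [1]) == pytest.approx(2 / 3)

    def test_both_empty_vectors_are_identically_empty(self):
        assert bray_curtis_similarity([0, 0], [0, 0]) == 1.0

    def test_mapping_inputs_align_by_key(self):
        assert bray_curtis_similarity({"Cl": 2}, {"Cl": 2, "SS": 0}) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=7),
        st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=7),
    )
    def test_symmetric_and_bounded(self, u, v):
        n = min(len(u), len(v))
        u, v = u[:n], v[:n]
        s = bray_curtis_similarity(u, v)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(bray_curtis_similarity(v, u))
        if u == v:
            assert s == 1.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            bray_curtis_similarity([1], [1, 2])


class TestMixedScore:
    def test_similarity_passthrough(self):
        assert mixed_score(0.7, 0.1, 0.9, WeightConfig(1, 0, 0)) == pytest.approx(0.7)

    def test_unit_components_sum_the_weights(self):
        w = WeightConfig(0.3, 0.4, 0.1)
        assert mixed_score(1, 1, 1, w) == pytest.approx(0.8)

    def test_shipped_default_weights(self):
        w = default_weights()
        assert (w["All"].a, w["All"].b, w["All"].c) == (0.3, 0.4, 0.1)
        assert (w["PKS"].a, w["PKS"].b, w["PKS"].c) == (1, 1, 0.3)
        assert (w["NRPS"].a, w["NRPS"].b, w["NRPS"].c) == (1, 0.4, 0.5)
        assert (w["Mixed"].a, w["Mixed"].b, w["Mixed"].c) == (0.4, 0.6, 0.1)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(-0.1, 0.5, 0.5)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            WeightConfig(0, 0, 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_monotone_in_each_component(self, sim, mcs, psm, delta, b):
        w = WeightConfig(0.5, b, 0.2)
        base = mixed_score(sim, mcs, psm, w)
        assert mixed_score(min(1, sim + delta), mcs, psm, w) >= base - 1e-12


class TestRanking:
    def test_competition_ranks_share_best_rank_on_ties(self):
        ranks = _competition_ranks({"a": 0.9, "b": 0.9, "c": 0.5})
        assert ranks == {"a": 1, "b": 1, "c": 3}

    def test_identical_prediction_ranks_first(self):
        db = _db([("true", "NCC(=O)O"), ("d1", "c1ccccc1"), ("d2", "CCCCCC")])
        result = rank_benchmark(
            [BenchmarkEntry(["NCC(=O)O"], {}, "true")], db, WeightConfig(1, 1, 0)
        )
        assert result.ranks[0] == 1 and result.top10 == 1.0

    def test_missing_true_product_is_excluded_with_warning(self):
        db = _db([("a", "CCO")])
        entries = [
            BenchmarkEntry(["CCO"], {}, "a"),
            BenchmarkEntry(["CCO"], {}, "absent"),
        ]
        with pytest.warns(UserWarning, match="absent"):
            result = rank_benchmark(entries, db, WeightConfig(1, 0, 0))
        assert list(result.ranks) == [0]

    def test_constant_scoring_degenerates_to_all_rank_one(self):
        db = _db([("a", "CCO"), ("b", "CCN")])
        # psm-only scoring with empty vectors: every compound scores alike
        result = rank_benchmark(
            [BenchmarkEntry(["CCC"], {}, "a")], db, WeightConfig(0, 0, 1)
        )
        assert result.ranks[0] == 1

    def test_screen_returns_sorted_ranked_matches(self):
        db = _db([("true", "NCC(=O)O"), ("d1", "c1ccccc1")])
        matches = screen(["NCC(=O)O"], {}, db, top_n=10)
        assert matches[0].compound_id == "true" and matches[0].rank == 1
        assert matches[0].mixed_score >= matches[-1].mixed_score


class TestWeightGridSearch:
    def test_single_compound_db_ties_report_lexicographic_smallest(self):
        db = _db([("only", "CCO")])
        best, results = grid_search_weights(
            [BenchmarkEntry(["CCO"], {}, "only")], db, step=0.5
        )
        assert (best.a, best.b, best.c) == (0.0, 0.0, 0.5)
        top = max(v for _, v in results)
        assert all(v == top for _, v in results)

    def test_empty_benchmark_is_an_error(self):
        db = _db([("a", "CCO")])
        with pytest.raises(ValueError):
            grid_search_weights([], db)

    def test_mcs_separating_benchmark_prefers_mcs_weight(self):
        # true product shares an exact substructure with the query but few
        # fingerprint bits; a decoy shares fingerprint bits but no large MCS
        db = _db(
            [
                ("true", "CCCCCCCCCC(=O)O"),
                ("decoy", "CC(C)CC(C)(C)CC(=O)OC"),
            ]
        )
        entries = [BenchmarkEntry(["CCCCCCCCCC(=O)O"], {}, "true")]
        best, _ = grid_search_weights(entries, db, step=0.5)
        # any winning config must rank the true compound first
        scores = {
            r.compound_id: r.mixed_score
            for r in screen(["CCCCCCCCCC(=O)O"], {}, db, weights=best, top_n=10)
        }
        assert scores["true"] >= scores["decoy"]
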