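import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npmatch.lexicon import add_names
from npmatch.novelty import (
    GENUS_ONLY_RESULT,
    MEDICAL_TERM_COLLISION,
    CandidateMapping,
    adjudication_flags,
    build_query_set,
    capture_delta,
    filter_unmapped,
    merge_annotations,
    mine_candidates,
    overlap_summary,
    read_candidates,
    write_candidates,
)


class TestFilterUnmapped:
    def test_rule_application(self):
        res = filter_unmapped(["abc", "ABC.", "A" * 70])
        assert list(res.pool) == ["ABC"]
        assert res.n_removed_long == 1
        assert res.n_removed_dup == 1

    def test_empty_input(self):
        res = filter_unmapped([])
        assert res.n_input == res.n_removed_long == res.n_removed_dup == 0
        assert res.pool == ()

    def test_first_occurrence_kept_in_order(self):
        res = filter_unmapped(["b", "a", "B", "c", "a"])
        assert list(res.pool) == ["B", "A", "C"]

    @given(
        st.lists(
            st.text(
                alphabet=st.sampled_from("AB .x9"), max_size=80
            ),
            max_size=60,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_accounting_identity(self, strings):
        res = filter_unmapped(strings)
        assert res.n_input == res.n_removed_long + res.n_removed_dup + len(res.pool)


class TestQuerySet:
    def test_two_queries_per_group(self, small_lexicon):
        queries = build_query_set(small_lexicon, small_lexicon.group_ids)
        assert len(queries) == 2 * len(small_lexicon)
        kinds = [kind for _, _, kind in queries]
        assert kinds[:2] == ["latin_binomial", "preferred_term"]

    def test_seventy_groups_gives_140(self):
        from npmatch.pairgen import synth_lexicon

        corpus = synth_lexicon(70, 2, 0.2, seed=3)
        queries = build_query_set(corpus.lexicon, corpus.lexicon.group_ids)
        assert len(queries) == 140

    def test_unknown_group_is_error(self, small_lexicon):
        with pytest.raises(ValueError, match="nope"):
            build_query_set(small_lexicon, ["nope"])


class TestMining:
    def test_planted_variant_recovered(self, small_lexicon):
        pool = ["LIKVORICE", "XANADU", "QWERTY", "ZZZZ"]
        queries = build_query_set(small_lexicon, ["g1"])
        cands = mine_candidates(queries, pool, methods=("GPM",), k=3)
        pt_cands = [
            c.candidate for c in cands if c.query == "LIQUORICE"
        ]
        assert "LIKVORICE" in pt_cands

    def test_shape_bound_and_ranks(self, small_lexicon):
        pool = [f"POOL{i}" for i in range(30)]
        queries = build_query_set(small_lexicon, small_lexicon.group_ids)
        cands = mine_candidates(queries, pool, methods=("GPM",), k=20)
        assert len(cands) <= len(queries) * 20
        for q in {c.query for c in cands}:
            ranks = [c.rank for c in cands if c.query == q]
            assert sorted(ranks) == list(range(1, len(ranks) + 1))

    def test_pool_shuffle_invariance(self, small_lexicon, rng):
        pool = ["LIKVORICE", "GINGR", "CINAMON", "XANADU", "AAAA", "BBBB"]
        queries = build_query_set(small_lexicon, small_lexicon.group_ids)
        base = mine_candidates(queries, pool, methods=("GPM",), k=3)
        shuffled = list(pool)
        rng.shuffle(shuffled)
        again = mine_candidates(queries, shuffled, methods=("GPM",), k=3)
        assert [(c.query, c.candidate, c.rank) for c in base] == [
            (c.query, c.candidate, c.rank) for c in again
        ]

    def test_sm_requires_model(self, small_lexicon):
        queries = build_query_set(small_lexicon, ["g1"])
        with pytest.raises(ValueError):
            mine_candidates(queries, ["X"], methods=("SM",))

    def test_annotation_template_shape(self, small_lexicon, tmp_path):
        import csv as _csv

        from npmatch.novelty import write_annotation_template

        queries = build_query_set(small_lexicon, ["g1"])
        cands = mine_candidates(queries, ["LIKVORICE", "XYZ"], methods=("GPM",), k=2)
        path = tmp_path / "template.csv"
        write_annotation_template(cands, path)
        rows = list(_csv.DictReader(open(path)))
        assert len(rows) == len(cands)
        assert {"decision_annotator1", "decision_annotator2"} <= set(rows[0])
        assert all(r["decision_annotator1"] == "" for r in rows)

    def test_candidate_csv_round_trip(self, small_lexicon, tmp_path):
        queries = build_query_set(small_lexicon, ["g1"])
        cands = mine_candidates(queries, ["LIKVORICE", "XYZ"], methods=("GPM",), k=2)
        cands[0].flags = {GENUS_ONLY_RESULT}
        path = tmp_path / "cands.csv"
        write_candidates(cands, path)
        back = read_candidates(path)
        assert [(c.key(), c.rank, c.flags, c.decision) for c in back] == [
            (c.key(), c.rank, c.flags, c.decision) for c in cands
        ]


class TestOverlap:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y", "z"}, {"y", "w"}, (2, 1, 1, 4)),
            ({"x"}, {"x"}, (0, 0, 1, 1)),
            ({"x"}, {"y"}, (1, 1, 0, 2)),
            (set(), set(), (0, 0, 0, 0)),
        ],
    )
    def test_set_algebra(self, a, b, expected):
        out = overlap_summary(a, b)
        assert out == expected
        ua, ub, ov, union = out
        assert union == ua + ub + ov


class TestAdjudication:
    def _cand(self, query, kind, candidate):
        return CandidateMapping(
            query=query,
            query_kind=kind,
            candidate=candidate,
            candidate_norm=candidate,
            method="GPM",
            score=0.9,
            rank=1,
        )

    def test_genus_only_flag(self, small_lexicon):
        c = self._cand("GLYCYRRHIZA GLABRA", "latin_binomial", "GLYCYRRHIZA")
        assert adjudication_flags(c, small_lexicon) == {GENUS_ONLY_RESULT}

    def test_blocklist_flag(self, small_lexicon):
        c = self._cand("GINGER", "preferred_term", "ANGINA")
        flags = adjudication_flags(c, small_lexicon, blocklist={"Angina"})
        assert flags == {MEDICAL_TERM_COLLISION}

    def test_clean_candidate_unflagged(self, small_lexicon):
        c = self._cand("GINGER", "preferred_term", "GINGR")
        assert adjudication_flags(c, small_lexicon, blocklist={"ANGINA"}) == set()


class TestMergeAnnotations:
    def _cands(self, small_lexicon):
        queries = build_query_set(small_lexicon, ["g1", "g2"])
        return mine_candidates(
            queries, ["LIKVORICE", "GINGR", "XANADU"], methods=("GPM",), k=2
        )

    def test_full_agreement(self, small_lexicon):
        cands = self._cands(small_lexicon)
        ann = {c.key(): "accepted" if c.rank == 1 else "rejected" for c in cands}
        merged, disagreements, kappa = merge_annotations(cands, ann, dict(ann))
        assert disagreements == []
        assert kappa.kappa == 1.0
        assert all(c.decision != "pending" for c in merged)

    def test_single_disagreement_pending(self, small_lexicon):
        cands = self._cands(small_lexicon)
        ann1 = {c.key(): "accepted" for c in cands}
        ann2 = dict(ann1)
        ann2[cands[0].key()] = "rejected"
        merged, disagreements, kappa = merge_annotations(cands, ann1, ann2)
        assert [d.key() for d in disagreements] == [cands[0].key()]
        assert cands[0].decision == "pending"
        assert sum(c.decision == "pending" for c in merged) == 1

    def test_kappa_delegates_to_evalx(self, small_lexicon):
        from npmatch.evalx import cohens_kappa

        cands = self._cands(small_lexicon)
        ann1 = {c.key(): ("accepted" if i % 2 else "rejected") for i, c in enumerate(cands)}
        ann2 = {c.key(): ("accepted" if i % 3 else "rejected") for i, c in enumerate(cands)}
        _, _, kappa = merge_annotations(cands, ann1, ann2)
        v1 = [ann1[c.key()] for c in cands]
        v2 = [ann2[c.key()] for c in cands]
        assert kappa == cohens_kappa(v1, v2)

    def test_unknown_key_is_error(self, small_lexicon):
        cands = self._cands(small_lexicon)
        with pytest.raises(ValueError):
            merge_annotations(cands, {("ZZ", "ZZ", "GPM"): "accepted"}, {})


class TestCoverage:
    def test_accepted_candidates_counted_per_group(self, small_lexicon):
        from npmatch.novelty import coverage_summary

        queries = build_query_set(small_lexicon, ["g1", "g2"])
        cands = mine_candidates(queries, ["LIKVORICE", "GINGR"], methods=("GPM",), k=1)
        for c in cands:
            c.decision = "accepted"
        cov = coverage_summary(cands, small_lexicon)
        assert set(cov) <= {"g1", "g2"}
        assert sum(sum(v.values()) for v in cov.values()) == len(cands)

    def test_pending_candidates_ignored(self, small_lexicon):
        from npmatch.novelty import coverage_summary

        queries = build_query_set(small_lexicon, ["g1"])
        cands = mine_candidates(queries, ["LIKVORICE"], methods=("GPM",), k=1)
        assert coverage_summary(cands, small_lexicon) == {}


class TestCaptureDelta:
    def test_toy_capture(self, small_lexicon):
        reports = [
            ("r1", "Likorice"),
            ("r2", "Likvorice"),  # unknown before
            ("r3", "aspirin"),
        ]
        after = add_names(small_lexicon, "g1", ["LIKVORICE"])
        n_before, n_after, diff = capture_delta(reports, small_lexicon, after)
        assert (n_before, n_after, diff) == (1, 2, 1)

    def test_unchanged_lexicon_zero_delta(self, small_lexicon):
        reports = [("r1", "GINGER")]
        assert capture_delta(reports, small_lexicon, small_lexicon) == (1, 1, 0)

    def test_monotone_under_additions(self, small_lexicon, rng):
        reports = [(f"r{i}", name) for i, name in enumerate(
            ["GINGER", "GINGR", "CINAMON", "XYZ", "LIKVORICE"]
        )]
        lex = small_lexicon
        prev_after = capture_delta(reports, small_lexicon, lex)[1]
        for gid, name in [("g2", "GINGR"), ("g3", "CINAMON"), ("g1", "LIKVORICE")]:
            lex = add_names(lex, gid, [name])
            n_after = capture_delta(reports, small_lexicon, lex)[1]
            assert n_after >= prev_after
            prev_after = n_after

    def test_distinct_reports_counted_once(self, small_lexicon):
        reports = [("r1", "GINGER"), ("r1", "LIQUORICE")]
        assert capture_delta(reports, small_lexicon, small_lexicon)[0] == 1
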