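import numpy as np
import pytest

from npmatch.fuzzy import levenshtein
from npmatch.pairgen import (
    DISTANT,
    MATCHING,
    PairGenError,
    balance_labels,
    balance_targets,
    make_pairs,
    perturb,
    split,
    synth_lexicon,
)
from npmatch.textprep import MAX_LEN, decode, encode, normalize


class TestPerturb:
    def test_single_edit(self, rng):
        out = perturb("GINGER", 1, rng)
        assert out != "GINGER"
        assert levenshtein("GINGER", out) == 1

    def test_deterministic_under_seed(self):
        a = perturb("GINGER", 2, np.random.default_rng(7))
        b = perturb("GINGER", 2, np.random.default_rng(7))
        assert a == b

    def test_edit_budget_respected(self, rng):
        # LED bound checked against the DP implementation over many draws
        for _ in range(200):
            out = perturb("LIQUORICE", 2, rng)
            assert 1 <= levenshtein("LIQUORICE", out) <= 2
            assert out == normalize(out)
            assert len(out) <= MAX_LEN

    def test_empty_name_rejected(self, rng):
        with pytest.raises(PairGenError):
            perturb("", 1, rng)


class TestMakePairs:
    def test_labels_match_group_membership(self, small_lexicon, rng):
        pairs = make_pairs(small_lexicon, rng, aug_per_pair=1)
        assert pairs
        for p in pairs:
            same = (
                small_lexicon.lookup(p.a) is not None
                and small_lexicon.lookup(p.a) == small_lexicon.lookup(p.b)
            )
            if p.label == MATCHING:
                # side b may be a perturbed (unknown) variant of a group name
                gid_a = small_lexicon.lookup(p.a)
                gid_b = small_lexicon.lookup(p.b)
                assert gid_a is not None or gid_b is not None
                if gid_a is not None and gid_b is not None:
                    assert gid_a == gid_b
            else:
                assert not same

    def test_every_group_contributes_positive(self, small_lexicon, rng):
        pairs = make_pairs(small_lexicon, rng, aug_per_pair=0)
        covered = set()
        for p in pairs:
            if p.label == MATCHING:
                covered.add(small_lexicon.lookup(p.a))
        assert covered == set(small_lexicon.group_ids)

    def test_single_group_rejected(self, licorice_group, rng):
        from npmatch.lexicon import Lexicon

        with pytest.raises(PairGenError):
            make_pairs(Lexicon([licorice_group]), rng)

    def test_no_duplicate_pairs(self, small_lexicon, rng):
        pairs = make_pairs(small_lexicon, rng)
        keys = [p.key() for p in pairs]
        assert len(keys) == len(set(keys))


class TestBalancing:
    def test_targets_equalized_to_max(self, rng):
        corpus = synth_lexicon(8, 2, 0.2, seed=5)
        pairs = make_pairs(corpus.lexicon, rng, aug_per_pair=0)
        # skew representation: drop most pairs of the first group
        gid0 = corpus.lexicon.group_ids[0]
        skewed = [
            p
            for p in pairs
            if corpus.lexicon.lookup(p.a) != gid0 or rng.random() < 0.2
        ]
        out = balance_targets(skewed, corpus.lexicon, rng)
        counts = {}
        for p in out:
            gid = corpus.lexicon.lookup(p.a)
            if gid is not None:
                counts[gid] = counts.get(gid, 0) + 1
        assert max(counts.values()) - min(counts.values()) <= 1

    def test_targets_noop_when_equal(self, rng):
        corpus = synth_lexicon(4, 1, 0.2, seed=6)
        pairs = make_pairs(corpus.lexicon, rng, aug_per_pair=0)
        balanced = balance_targets(pairs, corpus.lexicon, rng)
        counts = {}
        for p in balanced:
            gid = corpus.lexicon.lookup(p.a)
            counts[gid] = counts.get(gid, 0) + 1
        assert max(counts.values()) - min(counts.values()) <= 1
        assert set(p.key() for p in pairs) <= set(p.key() for p in balanced)

    def test_balancing_only_adds(self, rng):
        corpus = synth_lexicon(6, 2, 0.2, seed=7)
        pairs = make_pairs(corpus.lexicon, rng)
        before = {p.key(): p.label for p in pairs}
        for fn in (
            lambda ps: balance_targets(ps, corpus.lexicon, rng),
            lambda ps: balance_labels(ps, rng, corpus.lexicon),
        ):
            out = fn(pairs)
            after = {p.key(): p.label for p in out}
            for k, lab in before.items():
                assert after[k] == lab

    def test_labels_balanced_within_tolerance(self, rng):
        corpus = synth_lexicon(10, 2, 0.2, seed=8)
        pairs = make_pairs(corpus.lexicon, rng, neg_per_pos=0.3)
        out = balance_labels(pairs, rng, corpus.lexicon)
        n0 = sum(p.label == MATCHING for p in out)
        n1 = len(out) - n0
        assert abs(n0 - n1) <= max(1, 0.01 * len(out))

    def test_labels_noop_when_balanced(self, rng):
        corpus = synth_lexicon(5, 1, 0.2, seed=9)
        pairs = make_pairs(corpus.lexicon, rng, neg_per_pos=1.0)
        n0 = sum(p.label == MATCHING for p in pairs)
        if abs(2 * n0 - len(pairs)) <= 0.01 * len(pairs):
            assert balance_labels(pairs, rng, corpus.lexicon) == pairs

    def test_requires_both_labels(self, rng):
        from npmatch.pairgen import LabeledPair

        with pytest.raises(PairGenError):
            balance_labels([LabeledPair("A", "B", MATCHING)], rng)


class TestSplit:
    def _pairs(self, n):
        from npmatch.pairgen import LabeledPair

        return [LabeledPair(f"A{i}", f"B{i}", i % 2) for i in range(n)]

    def test_70_30_split(self):
        ds = split(self._pairs(100), holdout_n=0, seed=1)
        assert len(ds.train) == 70
        assert len(ds.validation) == 30
        assert ds.holdout == []

    def test_holdout_exact_size(self):
        ds = split(self._pairs(10000), holdout_n=2500, seed=1)
        assert len(ds.holdout) == 2500
        assert len(ds.train) + len(ds.validation) == 7500

    def test_deterministic(self):
        a = split(self._pairs(100), holdout_n=10, seed=3)
        b = split(self._pairs(100), holdout_n=10, seed=3)
        assert a.train == b.train and a.validation == b.validation
        assert a.holdout == b.holdout

    def test_disjoint_splits(self):
        ds = split(self._pairs(100), holdout_n=20, seed=4)
        s = [set(p.key() for p in part) for part in (ds.train, ds.validation, ds.holdout)]
        assert not (s[0] & s[1]) and not (s[0] & s[2]) and not (s[1] & s[2])

    def test_oversized_holdout_rejected(self):
        with pytest.raises(ValueError):
            split(self._pairs(10), holdout_n=10, seed=1)

    def test_balance_stats_agree_with_recount(self):
        ds = split(self._pairs(100), holdout_n=10, seed=5)
        assert ds.balance_stats == ds.recount()


class TestSynthLexicon:
    def test_group_and_query_counts(self):
        corpus = synth_lexicon(70, 3, 0.2, seed=11)
        assert len(corpus.lexicon) == 70
        queries = [
            (g.latin_binomial, g.preferred_term) for g in corpus.lexicon
        ]
        assert len(queries) == 70
        assert all(lb and pt for lb, pt in queries)

    def test_names_encodable(self):
        corpus = synth_lexicon(20, 3, 0.2, seed=12)
        for name in sorted(corpus.lexicon.names()) + corpus.pool:
            assert decode(encode(name)) == name

    def test_pool_has_planted_variant_per_group(self):
        corpus = synth_lexicon(15, 2, 0.2, seed=13)
        planted_groups = set(corpus.truth.values())
        assert planted_groups == set(corpus.lexicon.group_ids)
        for name, gid in corpus.truth.items():
            assert name in corpus.pool

    def test_deterministic_under_seed(self):
        a = synth_lexicon(10, 2, 0.2, seed=14)
        b = synth_lexicon(10, 2, 0.2, seed=14)
        assert a.pool == b.pool
        assert a.truth == b.truth
        assert {g.group_id: g.names for g in a.lexicon} == {
            g.group_id: g.names for g in b.lexicon
        }

    def test_minimum_groups(self):
        with pytest.raises(PairGenError):
            synth_lexicon(1, 2, 0.2, seed=1)


def test_full_pipeline_determinism():
    def build():
        corpus = synth_lexicon(12, 2, 0.2, seed=21)
        rng = np.random.default_rng(22)
        pairs = make_pairs(corpus.lexicon, rng)
        pairs = balance_targets(pairs, corpus.lexicon, rng)
        pairs = balance_labels(pairs, rng, corpus.lexicon)
        return split(pairs, holdout_n=5, seed=23)

    a, b = build(), build()
    assert a.train == b.train
    assert a.validation == b.validation
    assert a.holdout == b.holdout
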