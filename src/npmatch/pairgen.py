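"""Labeled training-pair construction, augmentation, balancing and splitting.

The distance model learns from ``(name, name, label)`` triples where label
0 marks two names of the same natural product (a *matching* pair — e.g. a
misspelling and its canonical form, or a common name and its Latin
binomial) and label 1 marks names of different products (*distant*).

Raw within-group pairs are scarce, so the corpus is augmented by applying
random character edits (:func:`perturb`) to existing names, then balanced
in two rounds: first per-product representation is equalized
(:func:`balance_targets`), then the matching / non-matching totals are
evened out (:func:`balance_labels`).  Finally :func:`split` draws a
holdout set and divides the remainder 70/30 into train and validation.

:func:`synth_lexicon` generates a fully synthetic study corpus — a lexicon
of pseudo-Latin binomials, common names and typo variants, plus an
"unmapped" free-text pool with planted recoverable variants — so every
downstream stage is testable without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fuzzy import levenshtein
from .lexicon import Lexicon, SynonymGroup
from .textprep import MAX_LEN, normalize

__all__ = [
    "LabeledPair",
    "PairDataset",
    "SyntheticCorpus",
    "PairGenError",
    "BalanceShortfallWarning",
    "perturb",
    "make_pairs",
    "balance_targets",
    "balance_labels",
    "split",
    "synth_lexicon",
]

MATCHING = 0  #: label for same-group pairs
DISTANT = 1  #: label for cross-group pairs

_ALPHA = [chr(ord("A") + i) for i in range(26)]


class PairGenError(ValueError):
    """Unsatisfiable pair-generation request."""


class BalanceShortfallWarning(UserWarning):
    """Balancing could not synthesize enough unique pairs; counts attached."""


@dataclass(frozen=True)
class LabeledPair:
    a: str
    b: str
    label: int  # 0 = matching, 1 = distant

    def key(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass
class PairDataset:
    """Train / validation / holdout splits of labeled pairs."""

    train: list[LabeledPair]
    validation: list[LabeledPair]
    holdout: list[LabeledPair]
    seed: int
    balance_stats: dict[str, dict[str, int]] = field(default_factory=dict)

    def recount(self) -> dict[str, dict[str, int]]:
        stats = {}
        for name in ("train", "validation", "holdout"):
            pairs = getattr(self, name)
            n0 = sum(1 for p in pairs if p.label == MATCHING)
            stats[name] = {"matching": n0, "non_matching": len(pairs) - n0}
        return stats


@dataclass
class SyntheticCorpus:
    """A generated lexicon, an unmapped-string pool, and its ground truth.

    ``truth`` maps each planted pool string (normalized) to the group_id it
    belongs to; distractor strings are absent from the map.
    """

    lexicon: Lexicon
    pool: list[str]
    truth: dict[str, str]
    seed: int


# ---------------------------------------------------------------------------
# perturbation


def _one_edit(name: str, rng: np.random.Generator) -> str:
    ops = ["substitute", "insert", "delete", "transpose"]
    if len(name) < 2:
        ops.remove("transpose")
    op = ops[rng.integers(len(ops))]
    i = int(rng.integers(len(name)))
    if op == "substitute":
        return name[:i] + _ALPHA[rng.integers(26)] + name[i + 1 :]
    if op == "insert":
        i = int(rng.integers(len(name) + 1))
        return name[:i] + _ALPHA[rng.integers(26)] + name[i:]
    if op == "delete":
        return name[:i] + name[i + 1 :]
    j = min(i + 1, len(name) - 1)
    return name[:i] + name[j] + name[i] + name[j + 1 :]


def perturb(
    name: str, n_edits: int = 1, rng: np.random.Generator | None = None
) -> str:
    """Apply ``n_edits`` random character edits, keeping the result valid.

    Edit operators — substitution, insertion, deletion, adjacent
    transposition — are drawn uniformly.  The output is normalized, at most
    :data:`~npmatch.textprep.MAX_LEN` characters, differs from the input,
    and sits within ``n_edits`` Levenshtein distance of it.  Raises
    :class:`PairGenError` when no distinct valid output can be produced
    within the retry budget.
    """
    if not name:
        raise PairGenError("cannot perturb an empty name")
    if n_edits < 1:
        raise PairGenError("n_edits must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    for _ in range(64):
        out = name
        for _ in range(n_edits):
            out = _one_edit(out, rng)
        out = normalize(out)
        if (
            out
            and out != name
            and len(out) <= MAX_LEN
            and levenshtein(name, out) <= n_edits
        ):
            return out
    raise PairGenError(
        f"could not produce a distinct valid perturbation of {name!r} "
        f"with {n_edits} edit(s)"
    )


# ---------------------------------------------------------------------------
# pair construction


def _group_names(g: SynonymGroup) -> list[str]:
    return sorted(g.names)


def make_pairs(
    lex: Lexicon,
    rng: np.random.Generator,
    aug_per_pair: int = 4,
    neg_per_pos: float = 1.0,
    max_perturb_edits: int = 2,
) -> list[LabeledPair]:
    """Build labeled pairs from a lexicon.

    Matching (label 0) pairs are every unordered within-group name
    combination, plus ``aug_per_pair`` augmented copies of each in which one
    side is replaced by a random perturbation (1..``max_perturb_edits``
    edits).  Distant (label 1) pairs are sampled uniformly across groups,
    ``neg_per_pos`` per matching pair.  Every group with at least one name
    contributes at least one matching pair; a single-group lexicon is an
    error since no distant pair exists.
    """
    groups = sorted(lex, key=lambda g: g.group_id)
    if len(groups) < 2:
        raise PairGenError("need at least 2 groups to build distant pairs")

    seen: set[tuple[str, str]] = set()
    positives: list[LabeledPair] = []

    def emit(a: str, b: str, label: int, out: list[LabeledPair]) -> bool:
        if a == b:
            return False
        p = LabeledPair(a, b, label)
        if p.key() in seen:
            return False
        seen.add(p.key())
        out.append(p)
        return True

    for g in groups:
        names = _group_names(g)
        base: list[tuple[str, str]] = []
        if len(names) == 1:
            # pair the lone name with a perturbation of itself
            base.append((names[0], perturb(names[0], 1, rng)))
        else:
            for i in range(len(names)):
                for j in range(i + 1, len(names)):
                    base.append((names[i], names[j]))
        for a, b in base:
            emit(a, b, MATCHING, positives)
            for _ in range(aug_per_pair):
                side, keep = (a, b) if rng.random() < 0.5 else (b, a)
                n_edits = int(rng.integers(1, max_perturb_edits + 1))
                try:
                    emit(keep, perturb(side, n_edits, rng), MATCHING, positives)
                except PairGenError:
                    continue

    negatives: list[LabeledPair] = []
    n_neg = int(round(neg_per_pos * len(positives)))
    all_names = [(g.group_id, n) for g in groups for n in _group_names(g)]
    tries = 0
    while len(negatives) < n_neg and tries < 20 * n_neg:
        tries += 1
        ia, ib = rng.integers(len(all_names)), rng.integers(len(all_names))
        (ga, a), (gb, b) = all_names[ia], all_names[ib]
        if ga == gb:
            continue
        emit(a, b, DISTANT, negatives)
    return positives + negatives


def _synthesize_matching(
    g: SynonymGroup,
    rng: np.random.Generator,
    seen: set[tuple[str, str]],
    max_edits: int = 2,
) -> LabeledPair | None:
    names = _group_names(g)
    for _ in range(32):
        a = names[rng.integers(len(names))]
        b = names[rng.integers(len(names))]
        try:
            b = perturb(b, int(rng.integers(1, max_edits + 1)), rng)
        except PairGenError:
            continue
        if a == b:
            continue
        p = LabeledPair(a, b, MATCHING)
        if p.key() not in seen:
            seen.add(p.key())
            return p
    return None


def _synthesize_distant(
    lex: Lexicon,
    rng: np.random.Generator,
    seen: set[tuple[str, str]],
    group_id: str | None = None,
) -> LabeledPair | None:
    gids = lex.group_ids
    for _ in range(32):
        ga = group_id if group_id is not None else gids[rng.integers(len(gids))]
        gb = gids[rng.integers(len(gids))]
        if ga == gb:
            continue
        na = _group_names(lex.group(ga))
        nb = _group_names(lex.group(gb))
        a = na[rng.integers(len(na))]
        b = nb[rng.integers(len(nb))]
        if rng.random() < 0.5:  # perturbed negatives keep the pool unique
            try:
                b = perturb(b, 1, rng)
            except PairGenError:
                pass
            if normalize(b) in lex.names() and lex.lookup(b) == ga:
                continue
        p = LabeledPair(a, b, DISTANT)
        if p.key() not in seen:
            seen.add(p.key())
            return p
    return None


def balance_targets(
    pairs: list[LabeledPair], lex: Lexicon, rng: np.random.Generator
) -> list[LabeledPair]:
    """First balancing round: equalize per-product pair counts.

    Each pair is attributed to the group of its first member; every group's
    count is raised to the maximum observed (±1) by synthesizing new unique
    matching pairs from perturbed names of the under-represented group.
    Existing pairs are never altered or removed.  Emits
    :class:`BalanceShortfallWarning` when the retry budget cannot close the
    gap.
    """
    counts: dict[str, int] = {gid: 0 for gid in lex.group_ids}
    for p in pairs:
        gid = lex.lookup(p.a)
        if gid is not None:
            counts[gid] += 1
    if not counts:
        return list(pairs)
    target = max(counts.values())
    seen = {p.key() for p in pairs}
    out = list(pairs)
    shortfall: dict[str, int] = {}
    for gid in sorted(counts):
        deficit = target - counts[gid]
        for _ in range(deficit):
            p = _synthesize_matching(lex.group(gid), rng, seen)
            if p is None:
                shortfall[gid] = target - counts[gid]
                break
            out.append(p)
            counts[gid] += 1
    if shortfall:
        warnings.warn(
            f"per-group balancing shortfall, achieved counts {counts}",
            BalanceShortfallWarning,
        )
    return out


def balance_labels(
    pairs: list[LabeledPair],
    rng: np.random.Generator,
    lex: Lexicon | None = None,
    tolerance: float = 0.01,
) -> list[LabeledPair]:
    """Second balancing round: even out matching vs non-matching totals.

    Synthesizes pairs of the minority label until the absolute difference
    is within ``tolerance`` of the total (default 1%).  Requires ``lex``
    when synthesis is needed.
    """
    n0 = sum(1 for p in pairs if p.label == MATCHING)
    n1 = len(pairs) - n0
    if n0 == 0 or n1 == 0:
        raise PairGenError("both labels must be present before balancing")
    out = list(pairs)
    seen = {p.key() for p in pairs}
    stalled = 0
    while abs(n0 - n1) > tolerance * (n0 + n1) and stalled < 64:
        if lex is None:
            raise PairGenError("balance_labels needs a lexicon to synthesize pairs")
        if n0 < n1:
            p = _synthesize_matching(
                lex.group(lex.group_ids[rng.integers(len(lex))]), rng, seen
            )
        else:
            p = _synthesize_distant(lex, rng, seen)
        if p is None:
            stalled += 1
            continue
        stalled = 0
        out.append(p)
        n0 += p.label == MATCHING
        n1 += p.label == DISTANT
    if abs(n0 - n1) > tolerance * (n0 + n1):
        warnings.warn(
            f"label balancing shortfall: matching={n0} non-matching={n1}",
            BalanceShortfallWarning,
        )
    return out


def split(
    pairs: list[LabeledPair],
    train_frac: float = 0.70,
    holdout_n: int = 0,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> PairDataset:
    """Draw the holdout first, then split the remainder into train/validation.

    Drawing the holdout before the 70/30 split guarantees no leakage
    between holdout and the model-selection sets.  Deterministic under
    ``rng`` (or ``seed`` when no generator is given).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    if holdout_n >= len(pairs):
        raise ValueError(
            f"holdout_n={holdout_n} must be smaller than the corpus ({len(pairs)})"
        )
    rng = np.random.default_rng(seed) if rng is None else rng
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    holdout = shuffled[:holdout_n]
    rest = shuffled[holdout_n:]
    n_train = int(round(train_frac * len(rest)))
    ds = PairDataset(
        train=rest[:n_train],
        validation=rest[n_train:],
        holdout=holdout,
        seed=seed,
    )
    ds.balance_stats = ds.recount()
    return ds


# ---------------------------------------------------------------------------
# synthetic corpus generator

_SYLLABLES = [
    "BA", "CA", "DA", "FE", "GA", "HU", "KI", "LA", "LO", "MA",
    "NE", "NI", "PA", "PO", "RA", "RI", "RU", "SA", "SE", "SI",
    "TA", "TE", "TI", "TO", "VA", "VE", "VI", "ZA", "ZO", "XU",
]
_LATIN_SUFFIX = ["US", "A", "UM", "IS", "ENSIS", "OIDES", "ATA", "ALIS"]
_DESCRIPTORS = [
    "EXTRACT", "ROOT", "LEAF", "POWDER", "CAPSULE", "HERBAL", "SUPPLEMENT",
    "TEA", "OIL", "COMPLEX", "BLEND", "TABLET", "FORMULA", "CONCENTRATE",
]


def _word(rng: np.random.Generator, n_syll: int) -> str:
    return "".join(_SYLLABLES[rng.integers(len(_SYLLABLES))] for _ in range(n_syll))


def _binomial(rng: np.random.Generator) -> str:
    genus = _word(rng, int(rng.integers(3, 5)))
    species = _word(rng, int(rng.integers(3, 5))) + _LATIN_SUFFIX[
        rng.integers(len(_LATIN_SUFFIX))
    ]
    return f"{genus} {species}"


def _long_form(base: str, rng: np.random.Generator) -> str:
    # product-style strings give name lengths their heavy right tail
    n = int(rng.integers(3, 8))
    idx = rng.choice(len(_DESCRIPTORS), size=n, replace=False)
    name = base + " " + " ".join(_DESCRIPTORS[i] for i in idx)
    return name[:MAX_LEN].strip()


def _typo_edits(typo_rate: float, rng: np.random.Generator) -> int:
    return 1 + int(rng.binomial(2, min(max(typo_rate, 0.0), 1.0)))


def synth_lexicon(
    n_groups: int,
    variants_per_group: int = 3,
    typo_rate: float = 0.2,
    seed: int | np.random.Generator = 0,
    distractors_per_group: float = 1.0,
) -> SyntheticCorpus:
    """Generate a synthetic study corpus.

    Each of ``n_groups`` synonym groups receives a pseudo-Latin binomial
    ("Genus species" built from syllables), a distinct common name, and
    ``variants_per_group`` variants: misspellings of the common name or
    binomial (``typo_rate`` scales the edit intensity, 1–3 edits) and
    long-form product strings (common name plus descriptor words) that give
    the length distribution its mean near 30 characters and heavy right
    tail.  The unmapped pool mixes one or more planted perturbed group
    names per group (recoverable ground truth, recorded in ``truth``) with
    distractor strings belonging to no group.
    """
    if n_groups < 2:
        raise PairGenError("n_groups must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = -1 if isinstance(seed, np.random.Generator) else int(seed)

    taken: set[str] = set()

    def fresh(make) -> str:
        for _ in range(100):
            cand = normalize(make())
            if cand and cand not in taken:
                taken.add(cand)
                return cand
        raise PairGenError("could not generate a fresh unique name")

    groups: list[SynonymGroup] = []
    for gi in range(n_groups):
        common = fresh(
            lambda: " ".join(
                _word(rng, int(rng.integers(2, 5)))
                for _ in range(int(rng.integers(1, 3)))
            )
        )
        binomial = fresh(lambda: _binomial(rng))
        variants: set[str] = set()
        for vi in range(variants_per_group):
            if vi % 2 == 0:
                base = common if rng.random() < 0.5 else binomial
                v = fresh(lambda: perturb(base, _typo_edits(typo_rate, rng), rng))
            else:
                base = common if rng.random() < 0.7 else binomial
                v = fresh(lambda: _long_form(base, rng))
            variants.add(v)
        groups.append(
            SynonymGroup(
                group_id=f"g{gi:04d}",
                preferred_term=common,
                latin_binomial=binomial,
                variants=frozenset(variants),
            )
        )
    lex = Lexicon(groups)

    pool: list[str] = []
    truth: dict[str, str] = {}
    for g in groups:
        n_plant = 1 + int(rng.integers(0, 2))
        names = _group_names(g)
        for _ in range(n_plant):
            base = names[rng.integers(len(names))]
            for _ in range(20):
                planted = perturb(base, _typo_edits(typo_rate, rng), rng)
                if planted not in taken:
                    break
            taken.add(planted)
            pool.append(planted)
            truth[planted] = g.group_id
    n_distract = int(round(distractors_per_group * n_groups))
    for _ in range(n_distract):
        if rng.random() < 0.5:
            pool.append(fresh(lambda: _word(rng, int(rng.integers(3, 6)))))
        else:
            pool.append(
                fresh(lambda: _long_form(_word(rng, int(rng.integers(2, 5))), rng))
            )
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    return SyntheticCorpus(lexicon=lex, pool=pool, truth=truth, seed=seed_val)
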