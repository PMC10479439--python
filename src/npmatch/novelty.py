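"""Candidate mining over unmapped report strings, and its bookkeeping.

The novelty pipeline takes free-text drug-name strings that failed exact
lookup against the lexicon and searches them for new natural-product
names: the strings are normalized and filtered (over-length removed, then
exact duplicates), a query set of (Latin binomial, preferred term) pairs
is built for the products of interest, each query retrieves its top-20
most similar pool strings per method, and the resulting candidate
mappings go to two human annotators.  Agreement is scored with Cohen's
kappa; adjudication rules flag genus-only results for binomial queries
and known medical-term collisions for common-name queries.  Accepted
names are added to the lexicon and the report-capture delta is counted.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

from .evalx import KappaResult, cohens_kappa
from .fuzzy import top_k
from .lexicon import Lexicon
from .textprep import normalize

__all__ = [
    "CandidateMapping",
    "MiningReport",
    "FilterResult",
    "filter_unmapped",
    "build_query_set",
    "mine_candidates",
    "overlap_summary",
    "coverage_summary",
    "adjudication_flags",
    "merge_annotations",
    "capture_delta",
    "write_candidates",
    "read_candidates",
    "write_mining_report",
    "write_annotation_template",
]

GENUS_ONLY_RESULT = "GENUS_ONLY_RESULT"
MEDICAL_TERM_COLLISION = "MEDICAL_TERM_COLLISION"


@dataclass
class CandidateMapping:
    query: str  # normalized query name
    query_kind: str  # "latin_binomial" or "preferred_term"
    candidate: str  # raw unmapped string
    candidate_norm: str
    method: str  # "GPM" or "SM"
    score: float
    rank: int  # 1..k
    flags: set[str] = field(default_factory=set)
    decision: str = "pending"  # "accepted" / "rejected" / "pending"

    def key(self) -> tuple[str, str, str]:
        return (self.query, self.candidate_norm, self.method)


@dataclass(frozen=True)
class FilterResult:
    pool: tuple[str, ...]
    n_input: int
    n_removed_long: int
    n_removed_dup: int


@dataclass
class MiningReport:
    n_input: int
    n_removed_long: int
    n_removed_dup: int
    n_pool: int
    per_method_total: dict[str, int] = field(default_factory=dict)
    per_method_unique: dict[str, int] = field(default_factory=dict)
    per_np_coverage: dict[str, int] = field(default_factory=dict)

    def accounting_holds(self) -> bool:
        return self.n_input == self.n_removed_long + self.n_removed_dup + self.n_pool


def filter_unmapped(strings: list[str], max_len: int = 65) -> FilterResult:
    """Normalize, drop over-length strings, then drop exact duplicates.

    Over-length removal happens before deduplication, so the counts
    satisfy ``n_input = n_removed_long + n_removed_dup + n_pool``.  The
    first occurrence of each normalized form is kept, in input order.
    """
    n_long = 0
    n_dup = 0
    seen: set[str] = set()
    pool: list[str] = []
    for raw in strings:
        norm = normalize(raw)
        if len(norm) > max_len:
            n_long += 1
            continue
        if norm in seen:
            n_dup += 1
            continue
        seen.add(norm)
        pool.append(norm)
    return FilterResult(
        pool=tuple(pool),
        n_input=len(strings),
        n_removed_long=n_long,
        n_removed_dup=n_dup,
    )


def build_query_set(
    lex: Lexicon, np_ids: list[str]
) -> list[tuple[str, str, str]]:
    """Two queries per product of interest: its Latin binomial and its PT.

    Returns ``(group_id, name, query_kind)`` triples in stable order.
    """
    queries: list[tuple[str, str, str]] = []
    for gid in np_ids:
        try:
            g = lex.group(gid)
        except KeyError:
            raise ValueError(f"unknown group_id {gid!r} in query set") from None
        if not g.latin_binomial or not g.preferred_term:
            raise ValueError(
                f"group {gid!r} lacks a Latin binomial or preferred term"
            )
        queries.append((gid, g.latin_binomial, "latin_binomial"))
        queries.append((gid, g.preferred_term, "preferred_term"))
    return queries


def mine_candidates(
    queries: list[tuple[str, str, str]],
    pool: list[str],
    methods: tuple[str, ...] = ("GPM", "SM"),
    model=None,
    k: int = 20,
) -> list[CandidateMapping]:
    """Top-``k`` pool strings for every query × method.

    Deterministic under fixed inputs (ranking ties break lexicographically,
    so the output is invariant under pool shuffling).  ``model`` is
    required when "SM" is requested; an untrained model is usable but the
    mappings carry a ``flags`` entry via the ranking's trained marker.
    """
    from .siamese import model_top_k

    if "SM" in methods and model is None:
        raise ValueError("SM mining requires a model")
    out: list[CandidateMapping] = []
    for _gid, name, kind in queries:
        for method in methods:
            if method == "SM":
                ranking = model_top_k(model, name, list(pool), k=k)
            else:
                ranking = top_k(name, list(pool), method=method, k=k)
            for rank, (cand, score) in enumerate(ranking.entries, start=1):
                out.append(
                    CandidateMapping(
                        query=normalize(name),
                        query_kind=kind,
                        candidate=cand,
                        candidate_norm=normalize(cand),
                        method=method,
                        score=score,
                        rank=rank,
                    )
                )
    return out


def overlap_summary(
    accepted_a: set[str], accepted_b: set[str]
) -> tuple[int, int, int, int]:
    """(unique to A, unique to B, overlap, union) — union is additive."""
    overlap = accepted_a & accepted_b
    return (
        len(accepted_a - accepted_b),
        len(accepted_b - accepted_a),
        len(overlap),
        len(accepted_a | accepted_b),
    )


def adjudication_flags(
    c: CandidateMapping, lex: Lexicon, blocklist: set[str] | None = None
) -> set[str]:
    """Advisory adjudication-rule flags for one candidate mapping.

    Rule 1: a Latin-binomial query whose result is only a genus name is a
    non-match.  Rule 2: a common-name query whose result collides with
    another medical term (user-supplied blocklist) is a non-match.  Flags
    advise the adjudicators; they never auto-decide.
    """
    flags: set[str] = set()
    if c.query_kind == "latin_binomial" and c.candidate_norm in lex.genus_tokens():
        flags.add(GENUS_ONLY_RESULT)
    if (
        c.query_kind == "preferred_term"
        and blocklist
        and c.candidate_norm in {normalize(b) for b in blocklist}
    ):
        flags.add(MEDICAL_TERM_COLLISION)
    return flags


def merge_annotations(
    candidates: list[CandidateMapping],
    ann1: dict[tuple[str, str, str], str],
    ann2: dict[tuple[str, str, str], str],
) -> tuple[list[CandidateMapping], list[CandidateMapping], KappaResult]:
    """Apply two annotators' decisions; disagreements stay pending.

    Annotation tables are keyed by ``(query, candidate_norm, method)`` with
    values "accepted"/"rejected".  Kappa is computed on the
    doubly-annotated subset.  A key matching no candidate raises.
    """
    known = {c.key() for c in candidates}
    for tag, ann in (("annotator 1", ann1), ("annotator 2", ann2)):
        unknown = set(ann) - known
        if unknown:
            raise ValueError(
                f"{tag} annotated unknown candidate keys: {sorted(unknown)[:3]}"
            )
    disagreements: list[CandidateMapping] = []
    v1: list[str] = []
    v2: list[str] = []
    for c in candidates:
        d1, d2 = ann1.get(c.key()), ann2.get(c.key())
        if d1 is not None and d2 is not None:
            v1.append(d1)
            v2.append(d2)
            if d1 == d2:
                c.decision = d1
            else:
                c.decision = "pending"
                disagreements.append(c)
        elif d1 is not None or d2 is not None:
            c.decision = d1 if d1 is not None else d2
    if not v1:
        raise ValueError("no doubly-annotated candidates; cannot compute kappa")
    kappa = cohens_kappa(v1, v2)
    return candidates, disagreements, kappa


def coverage_summary(
    candidates: list[CandidateMapping], lex: Lexicon
) -> dict[str, dict[str, int]]:
    """Per-product counts of accepted candidate names, by query kind.

    A product counts as *covered* by a method when at least one accepted
    candidate was retrieved for either of its queries.  Queries are mapped
    back to their groups through the lexicon.
    """
    out: dict[str, dict[str, int]] = {}
    for c in candidates:
        if c.decision != "accepted":
            continue
        gid = lex.lookup(c.query)
        if gid is None:
            continue
        per = out.setdefault(gid, {})
        key = f"{c.method}:{c.query_kind}"
        per[key] = per.get(key, 0) + 1
    return out


def capture_delta(
    report_names: list[tuple[str, str]],
    lex_before: Lexicon,
    lex_after: Lexicon,
) -> tuple[int, int, int]:
    """Distinct reports captured before vs after a lexicon update.

    A report is captured when at least one of its name strings normalizes
    to a lexicon member.  Returns ``(n_before, n_after, difference)``;
    when the updated lexicon is a superset the difference is >= 0.
    """
    before: set[str] = set()
    after: set[str] = set()
    for report_id, raw in report_names:
        norm = normalize(raw)
        if lex_before.lookup(norm) is not None:
            before.add(report_id)
        if lex_after.lookup(norm) is not None:
            after.add(report_id)
    return len(before), len(after), len(after) - len(before)


# ---------------------------------------------------------------------------
# candidate-table IO (append-safe, keyed by (query, candidate_norm, method))

_CAND_COLUMNS = [
    "query",
    "query_kind",
    "candidate",
    "candidate_norm",
    "method",
    "score",
    "rank",
    "flags",
    "decision",
]


def write_candidates(
    candidates: list[CandidateMapping], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CAND_COLUMNS)
        for c in candidates:
            writer.writerow(
                [
                    c.query,
                    c.query_kind,
                    c.candidate,
                    c.candidate_norm,
                    c.method,
                    f"{c.score:.6f}",
                    c.rank,
                    "|".join(sorted(c.flags)),
                    c.decision,
                ]
            )


def read_candidates(path: str | Path) -> list[CandidateMapping]:
    out: list[CandidateMapping] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                CandidateMapping(
                    query=row["query"],
                    query_kind=row["query_kind"],
                    candidate=row["candidate"],
                    candidate_norm=row["candidate_norm"],
                    method=row["method"],
                    score=float(row["score"]),
                    rank=int(row["rank"]),
                    flags=set(filter(None, row["flags"].split("|"))),
                    decision=row["decision"],
                )
            )
    return out


def write_mining_report(report: MiningReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.__dict__, indent=2, sort_keys=True))


def write_annotation_template(
    candidates: list[CandidateMapping],
    path: str | Path,
    annotators: tuple[str, ...] = ("annotator1", "annotator2"),
) -> None:
    """Blank decision sheet: one row per candidate, one column per annotator."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["query", "query_kind", "candidate_norm", "method", "rank", "flags"]
            + [f"decision_{a}" for a in annotators]
        )
        for c in candidates:
            writer.writerow(
                [c.query, c.query_kind, c.candidate_norm, c.method, c.rank,
                 "|".join(sorted(c.flags))]
                + ["" for _ in annotators]
            )
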