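"""Classical string-similarity matchers and top-k retrieval.

Two matchers operate on normalized names:

* **Gestalt pattern-matching (GPM)** — the Ratcliff/Obershelp similarity:
  recursively locate the longest common substring (the *anchor*), match the
  regions left of the anchor against each other and likewise right of it,
  and score ``2·Km / (|s1| + |s2|)`` where ``Km`` is the total matched
  length.  Implemented from the pure recursive definition with no junk or
  popularity heuristic, so scores are independent of pool composition.

* **Levenshtein edit distance (LED)** — minimum number of single-character
  insertions, deletions and substitutions, unit costs, no transpositions.

:func:`top_k` ranks a candidate pool against a query under either method
with deterministic lexicographic tie-breaking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RankedCandidates",
    "gpm_similarity",
    "matching_blocks",
    "levenshtein",
    "top_k",
    "METHODS",
]

METHODS = ("GPM", "LED", "SM")


@dataclass(frozen=True)
class RankedCandidates:
    """Best-first ranked pool entries for one query under one method.

    ``entries`` are ``(candidate, score)`` pairs sorted best-first:
    similarity descending for GPM/SM-similarity, distance ascending for
    LED and SM-distance.  ``trained`` is False only when an SM ranking was
    produced by an untrained model.
    """

    query: str
    method: str
    entries: tuple[tuple[str, float], ...]
    trained: bool = True

    def candidates(self) -> list[str]:
        return [c for c, _ in self.entries]


def _longest_match(
    a: str, b: str, alo: int, ahi: int, blo: int, bhi: int
) -> tuple[int, int, int]:
    """Longest common substring of a[alo:ahi] and b[blo:bhi].

    Ties break to the earliest start in ``a``, then earliest in ``b``.
    Returns (i, j, size), size 0 when there is no common character.
    """
    b2j: dict[str, list[int]] = {}
    for j in range(blo, bhi):
        b2j.setdefault(b[j], []).append(j)
    besti, bestj, bestsize = alo, blo, 0
    # j2len[j] = length of the longest match ending at a[i], b[j]
    j2len: dict[int, int] = {}
    for i in range(alo, ahi):
        newj2len: dict[int, int] = {}
        for j in b2j.get(a[i], ()):
            k = j2len.get(j - 1, 0) + 1
            newj2len[j] = k
            if k > bestsize:
                besti, bestj, bestsize = i - k + 1, j - k + 1, k
        j2len = newj2len
    return besti, bestj, bestsize


def matching_blocks(s1: str, s2: str) -> list[tuple[int, int, int]]:
    """Ratcliff/Obershelp matching blocks as (i, j, size) triples, in order.

    The recursion anchors on the longest common substring and descends into
    the left and right flanks.
    """
    blocks: list[tuple[int, int, int]] = []
    stack = [(0, len(s1), 0, len(s2))]
    while stack:
        alo, ahi, blo, bhi = stack.pop()
        i, j, size = _longest_match(s1, s2, alo, ahi, blo, bhi)
        if size:
            blocks.append((i, j, size))
            stack.append((alo, i, blo, j))
            stack.append((i + size, ahi, j + size, bhi))
    return sorted(blocks)


def gpm_similarity(s1: str, s2: str) -> float:
    """Gestalt pattern-matching similarity in [0, 1].

    ``2·Km/(|s1|+|s2|)`` with ``Km`` the total length of the recursive
    matching blocks; 1.0 when both strings are empty.
    """
    total = len(s1) + len(s2)
    if total == 0:
        return 1.0
    km = sum(size for _, _, size in matching_blocks(s1, s2))
    return 2.0 * km / total


def levenshtein(s1: str, s2: str) -> int:
    """Classical edit distance (insert / delete / substitute, unit costs)."""
    if s1 == s2:
        return 0
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    b = np.frombuffer(s2.encode("utf-32-le"), dtype=np.uint32)
    prev = np.arange(len(s2) + 1)
    for i, ch in enumerate(s1):
        cur = np.empty_like(prev)
        cur[0] = i + 1
        # substitutions and insertions vectorize; deletions depend on the
        # previous cell in the same row and need the sequential pass
        np.minimum(prev[:-1] + (b != ord(ch)), prev[1:] + 1, out=cur[1:])
        run = cur[0]
        for j in range(1, len(cur)):
            run = min(run + 1, cur[j])
            cur[j] = run
        prev = cur
    return int(prev[-1])


def _score(query: str, candidate: str, method: str) -> float:
    if method == "GPM":
        return gpm_similarity(query, candidate)
    if method == "LED":
        return float(levenshtein(query, candidate))
    raise ValueError(f"unknown method {method!r} (expected GPM or LED)")


def top_k(
    query: str,
    pool: list[str],
    method: str = "GPM",
    k: int = 20,
    cutoff: float | None = None,
) -> RankedCandidates:
    """Best-``k`` pool members for ``query`` under ``method``.

    GPM sorts by similarity descending (optionally dropping entries below
    ``cutoff``); LED sorts by raw distance ascending (``cutoff`` is a
    maximum distance).  Ties break lexicographically on the candidate, so
    rankings are invariant under pool shuffling, and enlarging ``k`` only
    extends the list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    seen: set[str] = set()
    scored: list[tuple[str, float]] = []
    for cand in pool:
        if cand in seen:
            continue
        seen.add(cand)
        scored.append((cand, _score(query, cand, method)))
    if cutoff is not None:
        if method == "GPM":
            scored = [(c, s) for c, s in scored if s >= cutoff]
        else:
            scored = [(c, s) for c, s in scored if s <= cutoff]
    reverse = method == "GPM"
    scored.sort(key=lambda cs: ((-cs[1] if reverse else cs[1]), cs[0]))
    return RankedCandidates(query=query, method=method, entries=tuple(scored[:k]))
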