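"""Retrieval and agreement metrics.

Mean reciprocal rank (MRR) evaluates ranked candidate lists in two modes:
*exact* scores the rank of the first candidate string-equal to the target,
*equivalent* the rank of the first candidate in the target's synonym group,
so equivalent-mode MRR always dominates exact-mode on the same rankings.
A query whose target is absent from the top-k list contributes reciprocal
rank 0 (misses count, they are not skipped).

Cohen's kappa quantifies chance-corrected agreement between the two
annotators of the candidate-mapping review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fuzzy import RankedCandidates, top_k
from .lexicon import Lexicon, equivalents

__all__ = [
    "MRRResult",
    "KappaResult",
    "mrr",
    "compare_methods",
    "cohens_kappa",
    "recall_at_k",
]


@dataclass(frozen=True)
class MRRResult:
    mode: str  # "exact" or "equivalent"
    per_query: tuple[tuple[str, str, int | None, float], ...]
    mrr: float
    sd: float


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    n_items: int


def _first_hit_rank(
    ranking: RankedCandidates, target: str, accept: set[str]
) -> int | None:
    for rank, (cand, _score) in enumerate(ranking.entries, start=1):
        if cand in accept:
            return rank
    return None


def mrr(
    rankings: list[RankedCandidates],
    targets: list[str],
    mode: str = "exact",
    lex: Lexicon | None = None,
    k: int = 20,
    sample_sd: bool = False,
) -> MRRResult:
    """Mean reciprocal rank of the first qualifying hit within the top ``k``.

    ``rankings`` and ``targets`` are aligned 1:1.  ``mode="equivalent"``
    accepts any member of the target's synonym group and requires ``lex``.
    The reported ``sd`` is the population standard deviation over per-query
    reciprocal ranks (``sample_sd=True`` switches to the n-1 form).
    """
    if len(rankings) != len(targets):
        raise ValueError("rankings and targets must align 1:1")
    if mode not in ("exact", "equivalent"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "equivalent" and lex is None:
        raise ValueError("equivalent mode requires a lexicon")
    per_query = []
    rrs = []
    for ranking, target in zip(rankings, targets):
        if mode == "exact":
            accept = {target}
        else:
            accept = equivalents(lex, target) or {target}
        clipped = RankedCandidates(
            ranking.query, ranking.method, ranking.entries[:k], ranking.trained
        )
        rank = _first_hit_rank(clipped, target, accept)
        rr = 0.0 if rank is None else 1.0 / rank
        per_query.append((ranking.query, target, rank, rr))
        rrs.append(rr)
    arr = np.asarray(rrs, dtype=float)
    sd = float(arr.std(ddof=1 if sample_sd else 0)) if len(arr) > 1 else 0.0
    return MRRResult(
        mode=mode, per_query=tuple(per_query), mrr=float(arr.mean()), sd=sd
    )


def compare_methods(
    queries: list[str],
    pool: list[str],
    targets: list[str],
    lex: Lexicon,
    model=None,
    methods: tuple[str, ...] = ("GPM", "LED", "SM"),
    k: int = 20,
) -> pd.DataFrame:
    """MRR comparison table: one row per method × mode on identical inputs.

    ``model`` (a trained distance model) is required when "SM" is among the
    methods.  Returns columns (method, mode, mrr, sd, k, n_queries).
    """
    from .siamese import model_top_k  # local import avoids cycle

    if "SM" in methods and model is None:
        raise ValueError("SM comparison requires a trained model")
    rows = []
    for method in methods:
        if method == "SM":
            rankings = [model_top_k(model, q, pool, k=k) for q in queries]
        else:
            rankings = [top_k(q, pool, method=method, k=k) for q in queries]
        for mode in ("exact", "equivalent"):
            res = mrr(rankings, targets, mode=mode, lex=lex, k=k)
            rows.append(
                {
                    "method": method,
                    "mode": mode,
                    "mrr": res.mrr,
                    "sd": res.sd,
                    "k": k,
                    "n_queries": len(queries),
                }
            )
    return pd.DataFrame(rows)


def cohens_kappa(ann1: list, ann2: list) -> KappaResult:
    """Chance-corrected agreement between two aligned decision vectors.

    kappa = (po - pe) / (1 - pe) with pe from the marginal products.  The
    degenerate case po = pe = 1 (both raters constant and identical)
    returns kappa 1.0.
    """
    if len(ann1) != len(ann2):
        raise ValueError("annotation vectors must have equal length")
    n = len(ann1)
    if n == 0:
        raise ValueError("need at least one item")
    labels = sorted(set(ann1) | set(ann2), key=repr)
    po = sum(a == b for a, b in zip(ann1, ann2)) / n
    pe = sum(
        (sum(a == lab for a in ann1) / n) * (sum(b == lab for b in ann2) / n)
        for lab in labels
    )
    if math.isclose(pe, 1.0):
        kappa = 1.0 if math.isclose(po, 1.0) else 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
    return KappaResult(po=po, pe=pe, kappa=kappa, n_items=n)


def recall_at_k(
    rankings: list[RankedCandidates],
    targets: list[str],
    lex: Lexicon | None = None,
    mode: str = "exact",
    k: int = 20,
) -> float:
    """Fraction of queries whose target (or an equivalent) appears in top-k.

    A completeness companion to first-hit MRR; not part of the original
    evaluation design.
    """
    res = mrr(rankings, targets, mode=mode, lex=lex, k=k)
    return sum(1 for *_ , rank, _rr in res.per_query if rank is not None) / len(
        res.per_query
    )
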