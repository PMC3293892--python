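"""Ranked-list stability and selection-quality metrics.

The distance between two complete rankings T1, T2 of p features is the
Canberra distance of their rank vectors,

    d(T1, T2) = sum_i |tau1(i) - tau2(i)| / (tau1(i) + tau2(i)),

which weights disagreements near the top of the lists more heavily than the
same rank displacement near the bottom.  Partial (top-l) lists are compared
through the quotient-group extension: the *complete* distance is the mean of
the full distance over every pair of completions of the two lists (unlisted
features ordered in all possible ways in the tail), computed here in closed
form from per-feature expected contributions; the *core* distance drops the
term contributed by features unlisted in both lists, which depends only on
the list lengths and not on their content.

A set of lists is summarized by the stability indicator: the mean pairwise
distance normalized by its expectation over independent uniform random
permutations.  The indicator is 0 for identical lists, ~1 for random ones
and bounded by ~1.4 (the identity-vs-reversal extreme).

Classification quality uses the Matthews correlation coefficient; selection
quality uses precision/recall against the ground-truth biomarker set and
the area under the precision-recall curve of the full ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

__all__ = [
    "RankedList",
    "ConfusionCounts",
    "StabilityReport",
    "canberra_full",
    "canberra_partial_complete",
    "canberra_core",
    "canberra_enumerated",
    "expected_canberra",
    "stability_indicator",
    "mcc",
    "precision_recall",
    "aupr",
    "write_ranked_list",
    "read_ranked_list",
]

# exact O(p^2) expectation up to this size, asymptotic beyond
_EXACT_EXPECTATION_MAX_P = 30_000
_ASYMPTOTIC_SLOPE = 2.0 * math.log(2.0) - 1.0


@dataclass(frozen=True)
class RankedList:
    """An ordering of the top ``l`` of ``p`` features, best first.

    ``ids`` are hashable feature identifiers; rank of ``ids[k]`` is ``k+1``.
    """

    ids: tuple
    p: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list contains duplicate ids")
        if len(self.ids) > self.p:
            raise ValueError(f"list length {len(self.ids)} exceeds universe {self.p}")

    @property
    def l(self) -> int:
        return len(self.ids)

    def ranks(self) -> dict:
        return {f: k + 1 for k, f in enumerate(self.ids)}


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class StabilityReport:
    raw_mean_distance: float
    normalization: float
    value: float
    n_lists: int
    distance: str


def _as_list(obj, p: int | None = None) -> RankedList:
    if isinstance(obj, RankedList):
        return obj
    if p is None:
        p = len(obj)
    return RankedList(ids=tuple(obj), p=p)


# ---------------------------------------------------------------------------
# Full-list distance
# ---------------------------------------------------------------------------

def canberra_full(t1, t2) -> float:
    """Canberra distance between two complete rankings of the same universe."""
    t1, t2 = _as_list(t1), _as_list(t2)
    if t1.p != t2.p or t1.l != t1.p or t2.l != t2.p:
        raise ValueError("canberra_full requires two complete lists of equal size")
    p = t1.p
    a = np.arange(1, p + 1, dtype=float)
    ids1 = np.asarray(t1.ids)
    ids2 = np.asarray(t2.ids)
    if ids1.dtype.kind in "iu" and ids2.dtype.kind in "iu":
        # integer universe fast path: rank lookup via array indexing
        if ids1.min() < 0 or ids1.max() >= p or not np.array_equal(
            np.sort(ids1), np.sort(ids2)
        ):
            raise ValueError("lists rank different feature universes")
        r2 = np.empty(p)
        r2[ids2] = a
        b = r2[ids1]
    else:
        if set(t1.ids) != set(t2.ids):
            raise ValueError("lists rank different feature universes")
        ranks2 = t2.ranks()
        b = np.asarray([ranks2[f] for f in t1.ids], dtype=float)
    return float(np.sum(np.abs(a - b) / (a + b)))


# ---------------------------------------------------------------------------
# Partial-list distances (closed form over completions)
# ---------------------------------------------------------------------------

def _tail_term(t: float, lo: int, p: int) -> float:
    """Mean of |t - b| / (t + b) over b in {lo+1, ..., p}."""
    b = np.arange(lo + 1, p + 1, dtype=float)
    return float(np.mean(np.abs(t - b) / (t + b)))


@lru_cache(maxsize=256)
def _both_unlisted_term(l1: int, l2: int, p: int) -> float:
    """Mean of |a - b| / (a + b), a uniform in tail of T1, b in tail of T2."""
    a = np.arange(l1 + 1, p + 1, dtype=float)[:, None]
    total = 0.0
    chunk = max(1, int(2e6 / max(1, p - l1)))
    bs = np.arange(l2 + 1, p + 1, dtype=float)
    for s in range(0, bs.size, chunk):
        b = bs[s : s + chunk][None, :]
        total += float(np.sum(np.abs(a - b) / (a + b)))
    return total / ((p - l1) * (p - l2))


def _partial_terms(t1: RankedList, t2: RankedList, p: int) -> tuple[float, int]:
    """(sum of per-feature expected contributions, n features unlisted in both)."""
    if t1.p != p or t2.p != p:
        raise ValueError("lists declare a different universe size than p")
    r1, r2 = t1.ranks(), t2.ranks()
    total = 0.0
    listed_union = set(t1.ids) | set(t2.ids)
    for f in listed_union:
        in1, in2 = f in r1, f in r2
        if in1 and in2:
            a, b = r1[f], r2[f]
            total += abs(a - b) / (a + b)
        elif in1:
            total += _tail_term(r1[f], t2.l, p)
        else:
            total += _tail_term(r2[f], t1.l, p)
    n_both = p - len(listed_union)
    if n_both < 0:
        raise ValueError("listed features exceed the declared universe size")
    return total, n_both


def canberra_partial_complete(t1, t2, p: int) -> float:
    """Mean Canberra distance over all completion pairs of two partial lists."""
    t1, t2 = _as_list(t1, p), _as_list(t2, p)
    total, n_both = _partial_terms(t1, t2, p)
    if n_both:
        total += n_both * _both_unlisted_term(t1.l, t2.l, p)
    return total


def canberra_core(t1, t2, p: int) -> float:
    """Complete partial-list distance minus the both-unlisted contribution."""
    t1, t2 = _as_list(t1, p), _as_list(t2, p)
    total, _ = _partial_terms(t1, t2, p)
    return total


def canberra_enumerated(t1, t2, p: int, universe=None) -> float:
    """Brute-force mean over all completion pairs (oracle; p <= ~8 only).

    ``universe`` defaults to the integers 0..p-1; it must contain every
    listed id of both lists.
    """
    t1, t2 = _as_list(t1, p), _as_list(t2, p)
    universe = list(range(p)) if universe is None else list(universe)
    if len(universe) != p:
        raise ValueError("universe size must equal p")
    if not (set(t1.ids) | set(t2.ids)) <= set(universe):
        raise ValueError("listed ids fall outside the universe")
    rest1 = [f for f in universe if f not in set(t1.ids)]
    rest2 = [f for f in universe if f not in set(t2.ids)]
    total, count = 0.0, 0
    for c1 in permutations(rest1):
        full1 = RankedList(tuple(t1.ids) + c1, p)
        for c2 in permutations(rest2):
            full2 = RankedList(tuple(t2.ids) + c2, p)
            total += canberra_full(full1, full2)
            count += 1
    return total / count


# ---------------------------------------------------------------------------
# Normalization constant
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def expected_canberra(p: int) -> float:
    """Expected Canberra distance between two independent uniform rankings.

    Exactly (1/p) * sum_{a,b=1..p} |a-b| / (a+b); computed exactly up to
    p = 30000 and by the continuous-limit slope (2 ln 2 - 1) * p beyond.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if p > _EXACT_EXPECTATION_MAX_P:
        return _ASYMPTOTIC_SLOPE * p
    a = np.arange(1, p + 1, dtype=float)
    total = 0.0
    chunk = max(1, int(2e6 / p))
    for s in range(0, p, chunk):
        blk = a[s : s + chunk][:, None]
        total += float(np.sum(np.abs(blk - a[None, :]) / (blk + a[None, :])))
    return total / p


# ---------------------------------------------------------------------------
# Stability indicator
# ---------------------------------------------------------------------------

def stability_indicator(lists, p: int | None = None, distance: str = "full") -> StabilityReport:
    """Mean pairwise distance of a set of lists / random-permutation expectation.

    ``distance`` is "full" (complete rankings), "complete" or "core"
    (partial lists).  Values: 0 = identical lists, ~1 = independent random
    lists, ~1.4 = maximal instability.
    """
    lists = [(_as_list(t, p) if p is not None else _as_list(t)) for t in lists]
    if len(lists) < 2:
        raise ValueError("stability requires at least 2 lists")
    p = lists[0].p
    if any(t.p != p for t in lists):
        raise ValueError("lists declare different universe sizes")
    if distance == "full":
        dist = lambda a, b: canberra_full(a, b)
    elif distance == "complete":
        dist = lambda a, b: canberra_partial_complete(a, b, p)
    elif distance == "core":
        dist = lambda a, b: canberra_core(a, b, p)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    total, n_pairs = 0.0, 0
    for i in range(len(lists)):
        for j in range(i + 1, len(lists)):
            total += dist(lists[i], lists[j])
            n_pairs += 1
    raw = total / n_pairs
    norm = expected_canberra(p)
    return StabilityReport(
        raw_mean_distance=raw,
        normalization=norm,
        value=raw / norm if norm > 0 else 0.0,
        n_lists=len(lists),
        distance=distance,
    )


# ---------------------------------------------------------------------------
# Classification / selection quality
# ---------------------------------------------------------------------------

def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def precision_recall(selected, truth) -> tuple[float, float]:
    """(precision, recall) of a selected feature set against the truth set.

    Empty selection yields precision 0 (flagged upstream, not an error).
    """
    selected, truth = set(selected), set(truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    tp = len(selected & truth)
    precision = tp / len(selected) if selected else 0.0
    return precision, tp / len(truth)


def aupr(ranking, truth) -> float:
    """Area under the precision-recall curve of a full ranking.

    Steps through every cutoff 1..p; the area accumulates precision at each
    cutoff where recall increases, weighted by the recall increment 1/|truth|.
    """
    ranking = _as_list(ranking)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    hits = np.asarray([f in truth for f in ranking.ids], dtype=float)
    cum = np.cumsum(hits)
    k = np.arange(1, len(hits) + 1, dtype=float)
    precision_at = cum / k
    return float(np.sum(precision_at[hits > 0]) / len(truth))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_ranked_list(t: RankedList, path, weights=None) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tfeature_id\tweight\n")
        for k, f in enumerate(t.ids):
            w = "" if weights is None else f"{weights[k]:.12g}"
            fh.write(f"{k + 1}\t{f}\t{w}\n")


def read_ranked_list(path, p: int) -> RankedList:
    ids = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[1])
    return RankedList(ids=tuple(ids), p=p)
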