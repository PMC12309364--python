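"""Putative quadruplex-forming sequence (PQS) detection and propensity scoring.

A PQS hit is a chain of >= ``min_tracts`` all-G windows of a common tract
length, consecutive windows separated by 1..``max_loop`` nucleotides (the
loops; loops may themselves contain G when tracts are embedded in longer
G-runs).  The scanner reports every *maximal* chain — one that cannot be
extended by another valid tract window at either end — for every tract
length from ``min_tract`` up to the longest G-run present, so overlapping
hits are all reported; downstream consumers take the max-scoring hit.

The propensity score is a deliberately simple linear surrogate for
G-score-style metrics: it rises with tract length and tract number and
falls with mean loop length, which is the qualitative structure needed to
rank designed motifs by expected inhibitory strength.  Exact G-scores,
thermodynamic stability and folding topology are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

_VALID_BASES = frozenset("ACGTU")

#: Linear propensity weights: tract length dominates, tract count next,
#: mean loop length is a mild penalty.
SCORE_TRACT_LENGTH_WEIGHT = 2.0
SCORE_TRACT_COUNT_WEIGHT = 0.75
SCORE_LOOP_WEIGHT = 0.25


@dataclass(frozen=True)
class PQSHit:
    """One detected putative quadruplex-forming sequence.

    Coordinates are 0-based, ``start`` inclusive / ``end`` exclusive.
    ``tract_starts`` are the starts of the all-G tract windows, all of
    length ``tract_length``; ``loop_lengths`` are the gaps between
    consecutive windows.
    """

    start: int
    end: int
    tract_starts: tuple
    tract_length: int
    loop_lengths: tuple
    score: float = field(default=0.0, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "tract_starts", tuple(self.tract_starts))
        object.__setattr__(self, "loop_lengths", tuple(self.loop_lengths))
        n = len(self.tract_starts)
        span = n * self.tract_length + sum(self.loop_lengths)
        if self.end - self.start != span:
            raise ValueError("hit span inconsistent with tract/loop decomposition")

    @property
    def tract_count(self) -> int:
        return len(self.tract_starts)

    @property
    def mean_loop_length(self) -> float:
        return sum(self.loop_lengths) / len(self.loop_lengths)


def _validate_sequence(sequence: str) -> str:
    seq = sequence.upper()
    for i, b in enumerate(seq):
        if b not in _VALID_BASES:
            raise ValueError(f"invalid base {b!r} at position {i}")
    return seq


def propensity_score(hit: PQSHit) -> float:
    """Unitless quadruplex propensity of a hit.

    ``2.0 * tract_length + 0.75 * tract_count - 0.25 * mean_loop_length``:
    strictly increasing in tract length and tract count, strictly decreasing
    in mean loop length.
    """
    return (
        SCORE_TRACT_LENGTH_WEIGHT * hit.tract_length
        + SCORE_TRACT_COUNT_WEIGHT * hit.tract_count
        - SCORE_LOOP_WEIGHT * hit.mean_loop_length
    )


def _windows(seq: str, t: int) -> list:
    """Start positions of every all-G window of length t."""
    return [i for i in range(len(seq) - t + 1) if set(seq[i:i + t]) == {"G"}]


def _max_g_run(seq: str) -> int:
    best = run = 0
    for b in seq:
        run = run + 1 if b == "G" else 0
        best = max(best, run)
    return best


def find_pqs(
    sequence: str,
    min_tract: int = 2,
    max_loop: int = 7,
    min_tracts: int = 4,
) -> List[PQSHit]:
    """All maximal PQS hits in ``sequence``, ordered deterministically.

    For each tract length ``t`` in ``min_tract .. longest G-run``, tract
    windows are the all-G windows of length ``t``; window ``w2`` may follow
    ``w1`` when ``1 <= start(w2) - end(w1) <= max_loop``.  A hit is a
    followable chain of >= ``min_tracts`` windows that no window can extend
    at either end.  T- and U-alphabet renderings give identical results.
    """
    if min(min_tract, max_loop, min_tracts) < 1:
        raise ValueError("detector parameters must be positive")
    seq = _validate_sequence(sequence)
    hits = []
    for t in range(min_tract, _max_g_run(seq) + 1):
        ws = _windows(seq, t)
        index = {w: k for k, w in enumerate(ws)}
        succ = [[] for _ in ws]
        has_pred = [False] * len(ws)
        for k, w in enumerate(ws):
            lo, hi = w + t + 1, w + t + max_loop
            for w2 in ws:
                if lo <= w2 <= hi:
                    succ[k].append(index[w2])
                    has_pred[index[w2]] = True
        # depth-first enumeration of source->sink chains
        for k in range(len(ws)):
            if has_pred[k]:
                continue
            stack = [(k, (k,))]
            while stack:
                node, path = stack.pop()
                if not succ[node]:
                    if len(path) >= min_tracts:
                        starts = tuple(ws[i] for i in path)
                        loops = tuple(
                            starts[j + 1] - (starts[j] + t)
                            for j in range(len(starts) - 1)
                        )
                        hit = PQSHit(
                            start=starts[0],
                            end=starts[-1] + t,
                            tract_starts=starts,
                            tract_length=t,
                            loop_lengths=loops,
                        )
                        hits.append(
                            PQSHit(hit.start, hit.end, hit.tract_starts,
                                   hit.tract_length, hit.loop_lengths,
                                   score=propensity_score(hit))
                        )
                    continue
                for nxt in succ[node]:
                    stack.append((nxt, path + (nxt,)))
    hits.sort(key=lambda h: (h.start, h.end, h.tract_length, h.tract_starts))
    return hits


def is_pqs_positive(
    sequence: str,
    min_tract: int = 2,
    max_loop: int = 7,
    min_tracts: int = 4,
) -> bool:
    """True iff at least one PQS hit exists.

    Uses a longest-chain dynamic program over tract windows rather than
    enumerating maximal chains, so it stays fast on G-dense sequences; the
    answer is identical to ``len(find_pqs(...)) > 0``.
    """
    if min(min_tract, max_loop, min_tracts) < 1:
        raise ValueError("detector parameters must be positive")
    seq = _validate_sequence(sequence)
    for t in range(min_tract, _max_g_run(seq) + 1):
        ws = _windows(seq, t)
        if len(ws) < min_tracts:
            continue
        # longest chain ending at each window (windows are start-sorted)
        best = [1] * len(ws)
        for k, w in enumerate(ws):
            lo, hi = w - t - max_loop, w - t - 1
            for j in range(k):
                if lo <= ws[j] <= hi and best[j] + 1 > best[k]:
                    best[k] = best[j] + 1
            if best[k] >= min_tracts:
                return True
    return False


def best_hit(sequence: str, **params) -> PQSHit:
    """Max-scoring hit (ties broken by earliest start)."""
    hits = find_pqs(sequence, **params)
    if not hits:
        raise ValueError("no PQS hit in sequence")
    return max(hits, key=lambda h: (h.score, -h.start))
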