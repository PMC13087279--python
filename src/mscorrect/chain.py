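"""Minimizer-space alignment by seed-and-chaining.

Exact minimizer matches between two sketched reads are *anchors*.  A
banded dynamic program selects the maximum-score colinear chain of
anchors; the minimizers lying between consecutive chained anchors are
then classified as matches, mismatches, insertions or deletions of
minimizers.  No base-level alignment is ever performed.

Sequence divergence is estimated from the chain alone: if n of the m
query minimizers inside the aligned span match the target, the per-base
divergence is ``1 - (n/m)**(1/k)`` — the sketch analogue of the
k-mer-survival identity estimate used by sketching-based ANI tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .sketch import MRead, SketchParams

try:  # the DP hot loop benefits from JIT compilation when available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f

        return deco


SAME = "same"
OPPOSITE = "opposite"

MATCH = "match"
MISMATCH = "mismatch"
INSERTION = "insertion"
DELETION = "deletion"


class Anchor(NamedTuple):
    """An exact minimizer match between query and target hit lists."""

    q_index: int
    t_index: int
    q_offset: int
    t_offset: int
    relative_strand: str  # SAME or OPPOSITE


@dataclass(frozen=True)
class ChainParams:
    """Scoring of the banded colinear-chaining DP.

    Each chained anchor earns ``match_bonus``; a transition between
    anchors pays ``gap_scale`` per base of diagonal drift, capped at
    ``gap_cap`` so that long indels remain chainable.  Only the
    ``band_h`` closest predecessor anchors are examined.
    """

    match_bonus: float = 50.0
    gap_scale: float = 0.05
    gap_cap: float = 50.0
    band_h: int = 50

    def __post_init__(self) -> None:
        if self.match_bonus < 0 or self.gap_scale < 0 or self.gap_cap < 0:
            raise ValueError("chain scores must be non-negative")
        if self.band_h < 1:
            raise ValueError("band_h must be >= 1")


@dataclass
class Chain:
    anchors: list[Anchor]
    score: float


class AlignmentOp(NamedTuple):
    """One minimizer-level operation; indices point into the hit lists
    of the query/target MReads (None where not applicable)."""

    op: str
    q_index: int | None
    t_index: int | None


@dataclass
class MAlignment:
    """A minimizer-space alignment of a query read onto a target read.

    ``n`` counts matching seeds, ``m`` the query seeds within the
    aligned span; spans are half-open base intervals on each read's
    forward strand.  Overhangs are, at each alignment end, the smaller
    of the two unaligned flanks (a true dovetail overlap has overhang 0).
    """

    query_id: str
    target_id: str
    relative_strand: str
    ops: list[AlignmentOp]
    n: int
    m: int
    q_span: tuple[int, int]
    t_span: tuple[int, int]
    overhang_left: int
    overhang_right: int
    divergence: float
    score: float = 0.0

    @property
    def t_span_length(self) -> int:
        return self.t_span[1] - self.t_span[0]

    @property
    def t_cover_length(self) -> int:
        """Length of the projected overlap on the target: the anchored
        span extended by the dovetail flank (the overhang) at each end.
        A full overlap of identical reads covers the whole target."""
        return (
            self.t_span[1] - self.t_span[0] + self.overhang_left + self.overhang_right
        )

    @property
    def max_overhang(self) -> int:
        return max(self.overhang_left, self.overhang_right)

    @property
    def n_differences(self) -> int:
        return sum(1 for o in self.ops if o.op != MATCH)


def estimate_divergence(n: int, m: int, k: int) -> float:
    """Per-base divergence from seed-match counts: ``1 - (n/m)**(1/k)``.

    Identical sketches (n == m) give 0; no shared seeds give 1.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= n <= m):
        raise ValueError("require 0 <= n <= m")
    return 1.0 - (n / m) ** (1.0 / k)


# ---------------------------------------------------------------------------
# anchors


def find_anchors(
    query: MRead, target: MRead, blacklist: frozenset[int] = frozenset()
) -> list[Anchor]:
    """All (query, target) hit pairs sharing a non-blacklisted hash.

    Both strand phases are reported; an anchor is SAME-phase when the
    two hits have equal canonical orientation.  Ordered by
    (q_index, t_index) for determinism.
    """
    if query.density != target.density:
        raise ValueError(
            f"density mismatch: query={query.density} target={target.density}"
        )
    by_hash: dict[int, list[int]] = {}
    for j, h in enumerate(target.hashes):
        by_hash.setdefault(int(h), []).append(j)
    anchors: list[Anchor] = []
    for i, h in enumerate(query.hashes):
        h = int(h)
        if h in blacklist:
            continue
        for j in by_hash.get(h, ()):
            phase = SAME if query.orientations[i] == target.orientations[j] else OPPOSITE
            anchors.append(
                Anchor(i, j, int(query.offsets[i]), int(target.offsets[j]), phase)
            )
    return anchors


# ---------------------------------------------------------------------------
# chaining DP


@_njit(cache=True)
def _chain_dp(qi, ti, qo, to, match_bonus, gap_scale, gap_cap, band_h):
    n = qi.size
    score = np.empty(n, dtype=np.float64)
    parent = np.full(n, -1, dtype=np.int64)
    for j in range(n):
        best = match_bonus
        bp = -1
        i0 = j - band_h
        if i0 < 0:
            i0 = 0
        for i in range(i0, j):
            if qi[i] < qi[j] and ti[i] < ti[j]:
                drift = (qo[j] - qo[i]) - (to[j] - to[i])
                if drift < 0:
                    drift = -drift
                g = gap_scale * drift
                if g > gap_cap:
                    g = gap_cap
                cand = score[i] + match_bonus - g
                if cand > best:  # strict: ties keep the earlier predecessor
                    best = cand
                    bp = i
        score[j] = best
        parent[j] = bp
    return score, parent


def chain_anchors(anchors: list[Anchor], params: ChainParams) -> Chain:
    """Maximum-score colinear chain among one strand-phase anchor group.

    score(j) = max over the band_h previous anchors i (with strictly
    increasing q_index and t_index) of score(i) + match_bonus -
    min(gap_cap, gap_scale * |dq - dt|); ties prefer the smaller
    predecessor index.  Anchors of the OPPOSITE phase must be given in
    query-flipped coordinates (see :func:`align_mreads`).
    """
    if not anchors:
        return Chain([], 0.0)
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].q_index, anchors[i].t_index))
    srt = [anchors[i] for i in order]
    qi = np.array([a.q_index for a in srt], dtype=np.int64)
    ti = np.array([a.t_index for a in srt], dtype=np.int64)
    qo = np.array([a.q_offset for a in srt], dtype=np.int64)
    to = np.array([a.t_offset for a in srt], dtype=np.int64)
    score, parent = _chain_dp(
        qi, ti, qo, to,
        float(params.match_bonus), float(params.gap_scale),
        float(params.gap_cap), int(params.band_h),
    )
    best = int(np.argmax(score))  # argmax takes the earliest of tied maxima
    path = []
    j = best
    while j >= 0:
        path.append(srt[j])
        j = int(parent[j])
    path.reverse()
    return Chain(path, float(score[best]))


# ---------------------------------------------------------------------------
# expansion into a full minimizer-space alignment


def _flip_query_anchors(anchors: list[Anchor], query: MRead, k: int) -> list[Anchor]:
    """Re-express OPPOSITE-phase anchors on the query's reverse strand so
    that colinearity means jointly increasing indices."""
    nq = len(query)
    out = []
    for a in anchors:
        out.append(
            Anchor(
                q_index=nq - 1 - a.q_index,
                t_index=a.t_index,
                q_offset=int(query.read_length - k - a.q_offset),
                t_offset=a.t_offset,
                relative_strand=OPPOSITE,
            )
        )
    return out


def expand_alignment(
    chain: Chain, query: MRead, target: MRead, k: int
) -> MAlignment:
    """Classify every minimizer between chained anchors.

    Between consecutive anchors, the u unmatched query hits and v
    unmatched target hits become min(u, v) mismatches (paired in
    order) plus |u - v| insertions (extra query hits) or deletions
    (extra target hits).  For OPPOSITE-strand chains the anchors must be
    in query-flipped coordinates; reported query indices/spans are
    mapped back onto the query's forward strand.
    """
    if not chain.anchors:
        raise ValueError("cannot expand an empty chain")
    strand = chain.anchors[0].relative_strand
    flipped = strand == OPPOSITE
    nq = len(query)

    def raw_q(idx: int) -> int:
        return nq - 1 - idx if flipped else idx

    ops: list[AlignmentOp] = []
    a0 = chain.anchors[0]
    ops.append(AlignmentOp(MATCH, raw_q(a0.q_index), a0.t_index))
    for a, b in zip(chain.anchors, chain.anchors[1:]):
        qs = list(range(a.q_index + 1, b.q_index))
        ts = list(range(a.t_index + 1, b.t_index))
        u, v = len(qs), len(ts)
        for x in range(min(u, v)):
            ops.append(AlignmentOp(MISMATCH, raw_q(qs[x]), ts[x]))
        if u > v:
            for x in range(v, u):
                ops.append(AlignmentOp(INSERTION, raw_q(qs[x]), None))
        elif v > u:
            for x in range(u, v):
                ops.append(AlignmentOp(DELETION, None, ts[x]))
        ops.append(AlignmentOp(MATCH, raw_q(b.q_index), b.t_index))

    first, last = chain.anchors[0], chain.anchors[-1]
    n = len(chain.anchors)
    m = last.q_index - first.q_index + 1

    # spans/overhangs in the chaining coordinate frame (query possibly flipped)
    q_lo, q_hi = first.q_offset, last.q_offset + k
    t_lo, t_hi = first.t_offset, last.t_offset + k
    ovh_left = min(q_lo, t_lo)
    ovh_right = min(query.read_length - q_hi, target.read_length - t_hi)
    if flipped:
        q_span = (query.read_length - q_hi, query.read_length - q_lo)
    else:
        q_span = (q_lo, q_hi)

    return MAlignment(
        query_id=query.read_id,
        target_id=target.read_id,
        relative_strand=strand,
        ops=ops,
        n=n,
        m=m,
        q_span=q_span,
        t_span=(t_lo, t_hi),
        overhang_left=ovh_left,
        overhang_right=ovh_right,
        divergence=estimate_divergence(n, m, k),
        score=chain.score,
    )


def align_mreads(
    query: MRead,
    target: MRead,
    sketch_params: SketchParams,
    chain_params: ChainParams,
    blacklist: frozenset[int] = frozenset(),
    min_anchors: int = 2,
) -> MAlignment | None:
    """Best minimizer-space alignment of query onto target.

    Anchors are split by strand phase, each phase chained separately,
    and the higher-scoring chain expanded.  Returns None when no phase
    yields a chain of at least ``min_anchors`` anchors.  All reported
    coordinates are on the target's forward strand.
    """
    anchors = find_anchors(query, target, blacklist)
    same = [a for a in anchors if a.relative_strand == SAME]
    opp = _flip_query_anchors(
        [a for a in anchors if a.relative_strand == OPPOSITE], query, sketch_params.k
    )
    best: MAlignment | None = None
    for group in (same, opp):
        if len(group) < min_anchors:
            continue
        chain = chain_anchors(group, chain_params)
        if len(chain.anchors) < min_anchors:
            continue
        aln = expand_alignment(chain, query, target, sketch_params.k)
        if best is None or aln.score > best.score:
            best = aln
    return best
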