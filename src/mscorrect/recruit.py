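"""All-vs-all read recruitment in sparse minimizer space.

Every read's low-density sketch is placed in an inverted index
(hash -> occurrences).  For a target read, candidate reads sharing
minimizers are chained and scored with

    score = number of minimizer matches - number of differences

(differences = mismatches + insertions + deletions), and accepted in
descending score order until the accumulated aligned target span
reaches ``coverage_cap`` times the target length (20x by default).
Only the best similar reads therefore serve as correction evidence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .chain import MAlignment, ChainParams, align_mreads
from .sketch import LOW, MRead, SketchParams


@dataclass
class MinimizerIndex:
    """Inverted index over low-density sketches, post-blacklist."""

    postings: dict[int, list[tuple[str, int, bool]]] = field(default_factory=dict)
    read_ids: set[str] = field(default_factory=set)

    def lookup(self, h: int) -> list[tuple[str, int, bool]]:
        return self.postings.get(h, [])


@dataclass
class Candidate:
    """A recruited read: its id, ranking score and sparse alignment."""

    read_id: str
    score: int
    alignment: MAlignment


def build_index(
    mreads: Iterable[MRead], blacklist: frozenset[int] = frozenset()
) -> MinimizerIndex:
    """Index every retained low-density hit of every read.

    Postings for a hash are sorted by read_id.  Duplicate read ids are
    an error.
    """
    index = MinimizerIndex()
    for mr in mreads:
        if mr.density != LOW:
            raise ValueError(f"read {mr.read_id!r}: index requires low-density sketches")
        if mr.read_id in index.read_ids:
            raise ValueError(f"duplicate read_id {mr.read_id!r}")
        index.read_ids.add(mr.read_id)
        for i, h in enumerate(mr.hashes):
            h = int(h)
            if h in blacklist:
                continue
            index.postings.setdefault(h, []).append(
                (mr.read_id, i, bool(mr.orientations[i]))
            )
    for lst in index.postings.values():
        lst.sort(key=lambda p: (p[0], p[1]))
    return index


def candidate_score(alignment: MAlignment) -> int:
    """matches minus (mismatches + insertions + deletions)."""
    return alignment.n - alignment.n_differences


def recruit(
    target: MRead,
    index: MinimizerIndex,
    mreads: Mapping[str, MRead],
    sketch_params: SketchParams,
    chain_params: ChainParams,
    blacklist: frozenset[int] = frozenset(),
    coverage_cap: float = 20.0,
    min_shared: int = 2,
) -> list[Candidate]:
    """Best-scoring similar reads for ``target``, up to the coverage cap.

    Candidates sharing at least ``min_shared`` non-blacklisted
    minimizers with the target are chained (best strand only), ranked
    by descending score then ascending read_id, and accepted greedily
    by their projected target coverage; the candidate that first
    reaches ``coverage_cap * target_length`` cumulative coverage is
    still accepted, then recruitment stops.  The target never recruits
    itself.
    """
    shared: Counter[str] = Counter()
    for h in target.hashes:
        h = int(h)
        if h in blacklist:
            continue
        for read_id, _i, _o in index.lookup(h):
            if read_id != target.read_id:
                shared[read_id] += 1

    candidates: list[Candidate] = []
    for read_id in sorted(shared):
        if shared[read_id] < min_shared:
            continue
        aln = align_mreads(
            mreads[read_id], target, sketch_params, chain_params, blacklist
        )
        if aln is None:
            continue
        candidates.append(Candidate(read_id, candidate_score(aln), aln))

    candidates.sort(key=lambda c: (-c.score, c.read_id))
    accepted: list[Candidate] = []
    budget = coverage_cap * target.read_length
    covered = 0.0
    for cand in candidates:
        accepted.append(cand)
        covered += cand.alignment.t_cover_length
        if covered >= budget:
            break
    return accepted
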