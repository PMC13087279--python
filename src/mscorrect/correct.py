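"""High-density filtering and the end-to-end correction pipeline.

After sparse recruitment, each candidate is re-aligned against the
target with the dense sketch and filtered on three thresholds chosen to
keep same-species, same-locus evidence only: sketch-estimated divergence
at most 4% (tolerates the sequencing error rate while rejecting other
species), aligned target span at least 1000 bp, and overhang at most
2000 bp (rejects repeat-induced partial overlaps).  The survivors are
piled into a variation graph and the most supported path becomes the
corrected mRead.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .chain import ChainParams, MAlignment, align_mreads
from .graph import ConsensusResult, build_variation_graph, extract_consensus
from .recruit import Candidate, MinimizerIndex, build_index, recruit
from .reconstruct import reconstruct_bases
from .sketch import (
    HIGH,
    LOW,
    MRead,
    SketchParams,
    build_abundance_table,
    build_mread,
    repetitive_blacklist,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the high-density alignment filter."""

    max_divergence: float = 0.04
    min_span_bases: int = 1000
    max_overhang_bases: int = 2000

    def __post_init__(self) -> None:
        if self.max_divergence <= 0 or self.min_span_bases <= 0 or self.max_overhang_bases <= 0:
            raise ValueError("filter thresholds must be positive")

    def passes(self, aln: MAlignment) -> bool:
        return (
            aln.divergence <= self.max_divergence
            and aln.t_span_length >= self.min_span_bases
            and aln.max_overhang <= self.max_overhang_bases
        )


def filter_alignments(
    alignments: Iterable[MAlignment], params: FilterParams
) -> list[MAlignment]:
    return [a for a in alignments if params.passes(a)]


def filter_recruited(
    target: MRead, alignments: Iterable[MAlignment], params: FilterParams
) -> list[MAlignment]:
    """Keep high-density alignments onto ``target`` that satisfy the
    divergence, span and overhang thresholds."""
    kept = []
    for aln in alignments:
        if aln.target_id != target.read_id:
            raise ValueError(
                f"alignment targets {aln.target_id!r}, expected {target.read_id!r}"
            )
        if params.passes(aln):
            kept.append(aln)
    return kept


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str
    qualities: Sequence[int] | None


@dataclass
class CorrectedRead:
    """One read's correction outcome."""

    read_id: str
    mread: MRead
    corrected: bool
    trimmed: bool
    supporters_recruited: int
    supporters_retained: int
    s_max: float
    sequence: str | None = None
    gap_fallback: bool = False


@dataclass
class Corrector:
    """Holds the sketches and index of a read set and corrects reads.

    Build once from the full read set, then call :meth:`correct_read`
    per read or :meth:`correct_all` for the whole set.  Qualities are
    used for edge weighting whenever every read carries them.
    """

    reads: list[ReadRecord]
    sketch_params: SketchParams = field(default_factory=SketchParams)
    chain_params: ChainParams = field(default_factory=ChainParams)
    filter_params: FilterParams = field(default_factory=FilterParams)
    coverage_cap: float = 20.0
    min_shared: int = 2

    def __post_init__(self) -> None:
        sp = self.sketch_params
        self.sequences: dict[str, str] = {}
        self.low: dict[str, MRead] = {}
        self.high: dict[str, MRead] = {}
        order: list[str] = []
        for rec in self.reads:
            try:
                high = build_mread(rec.read_id, rec.sequence, rec.qualities, sp, HIGH)
                low = build_mread(rec.read_id, rec.sequence, rec.qualities, sp, LOW)
            except ValueError as exc:
                logger.warning("rejecting read: %s", exc)
                continue
            if rec.read_id in self.high:
                raise ValueError(f"duplicate read_id {rec.read_id!r}")
            self.sequences[rec.read_id] = rec.sequence
            self.high[rec.read_id] = high
            self.low[rec.read_id] = low
            order.append(rec.read_id)
        self.read_order = order
        self.use_quality = bool(order) and all(
            self.high[r].qualities is not None for r in order
        )
        # abundance is measured on the dense sketch (the sparse one is a
        # subset of it); one blacklist serves both densities
        table = build_abundance_table(self.high.values())
        self.blacklist = repetitive_blacklist(table, sp.repetitive_fraction)
        self.index: MinimizerIndex = build_index(self.low.values(), self.blacklist)

    # -- steps --------------------------------------------------------------

    def recruit_for(self, read_id: str) -> list[Candidate]:
        return recruit(
            self.low[read_id],
            self.index,
            self.low,
            self.sketch_params,
            self.chain_params,
            self.blacklist,
            self.coverage_cap,
            self.min_shared,
        )

    def realign_high(self, read_id: str, candidates: list[Candidate]) -> list[MAlignment]:
        target = self.high[read_id]
        out = []
        for cand in candidates:
            aln = align_mreads(
                self.high[cand.read_id],
                target,
                self.sketch_params,
                self.chain_params,
                self.blacklist,
            )
            if aln is not None:
                out.append(aln)
        return out

    def correct_read(self, read_id: str, reconstruct: bool = False) -> CorrectedRead:
        """Recruit (sparse), re-align and filter (dense), pile up,
        extract the consensus; an unsupported read is returned as-is."""
        if read_id not in self.high:
            raise KeyError(f"unknown read_id {read_id!r}")
        target = self.high[read_id]
        candidates = self.recruit_for(read_id)
        realigned = self.realign_high(read_id, candidates)
        retained = filter_recruited(target, realigned, self.filter_params)
        if not retained or len(target) == 0:
            return CorrectedRead(
                read_id=read_id,
                mread=target,
                corrected=False,
                trimmed=False,
                supporters_recruited=len(candidates),
                supporters_retained=len(retained),
                s_max=0.0,
                sequence=self.sequences[read_id] if reconstruct else None,
            )
        graph = build_variation_graph(
            target,
            retained,
            self.high,
            use_quality=self.use_quality,
            k=self.sketch_params.k,
        )
        result = extract_consensus(graph)
        sequence = None
        gap_fallback = False
        if reconstruct:
            sequence, gap_fallback = reconstruct_bases(
                result, graph, self.sequences
            )
        return CorrectedRead(
            read_id=read_id,
            mread=result.corrected,
            corrected=True,
            trimmed=result.trimmed,
            supporters_recruited=len(candidates),
            supporters_retained=len(retained),
            s_max=result.s_max,
            sequence=sequence,
            gap_fallback=gap_fallback,
        )

    def correct_all(
        self, threads: int = 1, reconstruct: bool = False
    ) -> list[CorrectedRead]:
        """Correct every read independently; output order equals input
        order and is identical for any thread count."""
        ids = self.read_order
        if threads <= 1:
            return [self.correct_read(r, reconstruct) for r in ids]
        with ThreadPoolExecutor(max_workers=threads) as pool:
            return list(pool.map(lambda r: self.correct_read(r, reconstruct), ids))


def correct_reads(
    reads: Iterable[ReadRecord],
    sketch_params: SketchParams | None = None,
    chain_params: ChainParams | None = None,
    filter_params: FilterParams | None = None,
    coverage_cap: float = 20.0,
    threads: int = 1,
    reconstruct: bool = False,
) -> list[CorrectedRead]:
    """One-shot convenience wrapper around :class:`Corrector`."""
    corrector = Corrector(
        reads=list(reads),
        sketch_params=sketch_params or SketchParams(),
        chain_params=chain_params or ChainParams(),
        filter_params=filter_params or FilterParams(),
        coverage_cap=coverage_cap,
    )
    return corrector.correct_all(threads=threads, reconstruct=reconstruct)
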