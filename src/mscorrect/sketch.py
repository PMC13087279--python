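"""Universal-minimizer sketching of long reads.

A k-mer is a *universal minimizer* when the hash of its canonical form
falls below a fixed fraction ``d`` (the density) of the hash range
``[0, H]``.  Because selection depends only on the k-mer itself, both
strands of a molecule — and every read covering the same locus — select
the same minimizers, which is what makes minimizer-space alignment of
reads possible.

Two nested densities are used downstream: a sparse sketch (``d_low``,
0.5% of k-mers by default) for fast all-vs-all read recruitment, and a
dense sketch (``d_high``, 2.5% by default) for accurate divergence
estimation and consensus.  Both use the same hash function with two
thresholds, so the sparse sketch is always a subset of the dense one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: maximum value of the 64-bit hash function
HASH_MAX = 2**64 - 1

LOW = "low"
HIGH = "high"

# base -> 2-bit code; anything that is not ACGT (case-insensitive) -> 4
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgtN", "TGCAtgcaN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SketchParams:
    """Parameters of the minimizer sketch.

    k : minimizer length in bases.
    seed : hash seed; fixing it makes every sketch reproducible.
    d_low / d_high : expected fractions of k-mers selected in the sparse
        and dense sketches.  ``d_low < d_high`` and the same hash is
        used for both, so low-density hits are nested in high-density hits.
    repetitive_fraction : fraction of distinct minimizers (the most
        abundant ones) blacklisted before alignment.
    hpc : homopolymer-compress the sequence before sketching.
    """

    k: int = 15
    seed: int = 0
    d_low: float = 0.005
    d_high: float = 0.025
    repetitive_fraction: float = 0.0001
    hpc: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0.0 < self.d_low < self.d_high <= 1.0):
            raise ValueError("require 0 < d_low < d_high <= 1")
        if not (0.0 <= self.repetitive_fraction < 1.0):
            raise ValueError("repetitive_fraction must be in [0, 1)")

    def threshold(self, density: str) -> int:
        d = self.d_low if density == LOW else self.d_high
        return min(int(d * HASH_MAX), HASH_MAX)


class MinimizerHit(NamedTuple):
    """One selected minimizer on a read.

    ``offset`` is the 0-based position of the k-mer's leftmost base on
    the read's forward strand.  ``is_reverse`` is True when the
    reverse-complement k-mer is the canonical (selected) representative.
    ``quality`` is the minimum Phred score over the k constituent bases,
    or -1 when the read carries no qualities.
    """

    hash: int
    offset: int
    is_reverse: bool
    quality: int


@dataclass
class MRead:
    """A read as its ordered list of minimizer hits at one density."""

    read_id: str
    read_length: int
    density: str
    hashes: np.ndarray      # uint64
    offsets: np.ndarray     # int64, strictly increasing
    orientations: np.ndarray  # bool, True = reverse canonical
    qualities: np.ndarray | None = None  # int16, min-over-k Phred

    def __post_init__(self) -> None:
        if len(self.offsets) > 1 and not np.all(np.diff(self.offsets) > 0):
            raise ValueError("minimizer offsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.hashes)

    @property
    def hits(self) -> list[MinimizerHit]:
        quals = (
            self.qualities
            if self.qualities is not None
            else np.full(len(self.hashes), -1, dtype=np.int16)
        )
        return [
            MinimizerHit(int(h), int(o), bool(r), int(q))
            for h, o, r, q in zip(self.hashes, self.offsets, self.orientations, quals)
        ]

    def copy_with(self, mask: np.ndarray) -> "MRead":
        return MRead(
            read_id=self.read_id,
            read_length=self.read_length,
            density=self.density,
            hashes=self.hashes[mask],
            offsets=self.offsets[mask],
            orientations=self.orientations[mask],
            qualities=None if self.qualities is None else self.qualities[mask],
        )

    def equals(self, other: "MRead") -> bool:
        if (
            self.read_id != other.read_id
            or self.read_length != other.read_length
            or self.density != other.density
            or len(self) != len(other)
        ):
            return False
        same = (
            np.array_equal(self.hashes, other.hashes)
            and np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.orientations, other.orientations)
        )
        if not same:
            return False
        if (self.qualities is None) != (other.qualities is None):
            return False
        if self.qualities is not None:
            return np.array_equal(self.qualities, other.qualities)
        return True


# ---------------------------------------------------------------------------
# hashing


def _mix64(x: np.ndarray) -> np.ndarray:
    """murmur3 64-bit finalizer; a uniform bijection on uint64."""
    z = x.copy()
    with np.errstate(over="ignore"):
        z ^= z >> np.uint64(33)
        z *= np.uint64(0xFF51AFD7ED558CCD)
        z ^= z >> np.uint64(33)
        z *= np.uint64(0xC4CEB9FE1A85EC53)
        z ^= z >> np.uint64(33)
    return z


def _seed_constant(seed: int) -> np.uint64:
    s = np.array([seed % (2**64)], dtype=np.uint64)
    with np.errstate(over="ignore"):
        s += np.uint64(0x9E3779B97F4A7C15)
    return _mix64(s)[0]


def _homopolymer_compress(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of identical bases; returns (codes, original offsets)."""
    if codes.size == 0:
        return codes, np.zeros(0, dtype=np.int64)
    keep = np.ones(codes.size, dtype=bool)
    keep[1:] = codes[1:] != codes[:-1]
    idx = np.nonzero(keep)[0]
    return codes[idx], idx.astype(np.int64)


def _scan(sequence: str, params: SketchParams):
    """Hash every k-mer of ``sequence``.

    Returns (positions, hashes, is_reverse) for all valid (N-free)
    k-mers, where positions are offsets on the original sequence.
    """
    k = params.k
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if params.hpc:
        codes, orig = _homopolymer_compress(codes)
    else:
        orig = None
    n = codes.size - k + 1
    if n <= 0:
        e = np.zeros(0, dtype=np.int64)
        return e, e.astype(np.uint64), np.zeros(0, dtype=bool)

    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | c64[j : j + n]
            # complement of code c is 3 - c; N (4) wraps but is masked out below
            rev |= (np.uint64(3) - c64[j : j + n]) << np.uint64(2 * j)

    # windows containing any non-ACGT base are never selected
    bad = (codes >= 4).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0

    canonical = np.minimum(fwd, rev)
    is_reverse = rev < fwd
    hashes = _mix64(canonical ^ _seed_constant(params.seed))

    pos = np.nonzero(valid)[0]
    if orig is not None:
        positions = orig[pos]
    else:
        positions = pos.astype(np.int64)
    return positions, hashes[pos], is_reverse[pos]


# ---------------------------------------------------------------------------
# public operations


def _select_mask(hashes: np.ndarray, params: SketchParams, density: str) -> np.ndarray:
    thr = params.threshold(density)
    if thr >= HASH_MAX:  # density 1: the whole hash range is admitted
        return np.ones(hashes.size, dtype=bool)
    return hashes < np.uint64(thr)



def select_minimizers(
    sequence: str, params: SketchParams, density: str = HIGH
) -> list[MinimizerHit]:
    """Select the k-mers whose canonical-hash falls below ``d * H``.

    Deterministic given ``params.seed``; on random sequence the selected
    fraction is ~``d``.  A sequence shorter than k yields an empty list.
    """
    positions, hashes, is_rev = _scan(sequence, params)
    sel = _select_mask(hashes, params, density)
    return [
        MinimizerHit(int(h), int(p), bool(r), -1)
        for h, p, r in zip(hashes[sel], positions[sel], is_rev[sel])
    ]


def build_mread(
    read_id: str,
    sequence: str,
    qualities: Sequence[int] | None,
    params: SketchParams,
    density: str = HIGH,
) -> MRead:
    """Sketch one read into an :class:`MRead`.

    ``qualities``, when given, must match the sequence length; each hit
    then carries the minimum Phred score over its k bases.  Raises
    ``ValueError`` on a length mismatch (callers reject the read).
    """
    if qualities is not None and len(qualities) != len(sequence):
        raise ValueError(
            f"read {read_id!r}: quality string length {len(qualities)} "
            f"!= sequence length {len(sequence)}"
        )
    positions, hashes, is_rev = _scan(sequence, params)
    sel = _select_mask(hashes, params, density)
    positions, hashes, is_rev = positions[sel], hashes[sel], is_rev[sel]

    quals = None
    if qualities is not None and len(sequence) >= params.k:
        qarr = np.asarray(qualities, dtype=np.int16)
        if positions.size:
            win = np.lib.stride_tricks.sliding_window_view(qarr, params.k)
            if params.hpc:
                # a compressed k-mer spans a variable base range; use the
                # window starting at its first original base
                quals = win[np.minimum(positions, len(sequence) - params.k)].min(axis=1)
            else:
                quals = win[positions].min(axis=1)
            quals = quals.astype(np.int16)
        else:
            quals = np.zeros(0, dtype=np.int16)

    return MRead(
        read_id=read_id,
        read_length=len(sequence),
        density=density,
        hashes=hashes,
        offsets=positions,
        orientations=is_rev,
        qualities=quals,
    )


@dataclass
class AbundanceTable:
    """Occurrence counts of distinct minimizer hashes across a read set."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total_distinct(self) -> int:
        return len(self.counts)

    def add_mread(self, mread: MRead) -> None:
        values, n = np.unique(mread.hashes, return_counts=True)
        for h, c in zip(values, n):
            self.counts[int(h)] += int(c)


def build_abundance_table(mreads: Iterable[MRead]) -> AbundanceTable:
    table = AbundanceTable()
    for mr in mreads:
        table.add_mread(mr)
    return table


def repetitive_blacklist(table: AbundanceTable, fraction: float) -> frozenset[int]:
    """The ``floor(fraction * total_distinct)`` most abundant hashes.

    Ties at the cutoff abundance are broken by ascending hash value so
    the blacklist is deterministic.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    n = int(fraction * table.total_distinct)
    if n == 0 or not table.counts:
        return frozenset()
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(h for h, _ in ranked[:n])


def apply_blacklist(mread: MRead, blacklist: frozenset[int]) -> MRead:
    """Remove blacklisted hashes from a sketch; the input is untouched."""
    if not blacklist:
        return mread.copy_with(np.ones(len(mread), dtype=bool))
    black = np.fromiter(blacklist, dtype=np.uint64, count=len(blacklist))
    keep = ~np.isin(mread.hashes, black)
    return mread.copy_with(keep)
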