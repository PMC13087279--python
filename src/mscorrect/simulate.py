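"""Synthetic metagenomes, error-laden long reads, and correction metrics.

The generator is the package's test bed: it draws one or more random
genomes (additional species are mutated copies at a stated pairwise
divergence, emulating the metagenomic risk of recruiting reads across
species), samples reads uniformly with random strand, corrupts them
with an i.i.d. substitution/insertion/deletion process at ONT-like
rates (~1% total by default), and records for every read the *ground
truth* — the minimizer sketch of its uncorrupted origin interval — so
that correction quality can be measured exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .sketch import HIGH, MRead, SketchParams, build_mread, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ErrorModel:
    """Per-base i.i.d. error process.

    Defaults give a 1% total error rate with an ONT-like mix of
    substitutions and indels; ``quality_mean`` is the constant Phred
    score assigned to simulated bases.
    """

    substitution_rate: float = 0.006
    insertion_rate: float = 0.002
    deletion_rate: float = 0.002
    quality_mean: int = 20

    def __post_init__(self) -> None:
        rates = (self.substitution_rate, self.insertion_rate, self.deletion_rate)
        if any(r < 0 or r >= 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("error rates must be in [0, 1) and sum below 1")

    @property
    def total_rate(self) -> float:
        return self.substitution_rate + self.insertion_rate + self.deletion_rate


@dataclass
class SimRead:
    sequence: str
    qualities: list[int]
    genome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class SimulatedDataset:
    genomes: dict[str, str]
    reads: dict[str, SimRead]
    truth_mreads: dict[str, MRead]
    params: SketchParams
    error_model: ErrorModel
    seed: int

    def read_records(self):
        from .correct import ReadRecord

        return [
            ReadRecord(rid, r.sequence, r.qualities) for rid, r in self.reads.items()
        ]

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_genomes": len(self.genomes),
            "genome_lengths": {g: len(s) for g, s in self.genomes.items()},
            "n_reads": len(self.reads),
            "error_model": {
                "substitution_rate": self.error_model.substitution_rate,
                "insertion_rate": self.error_model.insertion_rate,
                "deletion_rate": self.error_model.deletion_rate,
                "quality_mean": self.error_model.quality_mean,
            },
            "sketch": {"k": self.params.k, "seed": self.params.seed},
        }


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p)
    return _BASES[codes].tobytes().decode()


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    codes = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for b, c in _CODE_OF.items():
        lut[ord(b)] = c
    c = lut[codes]
    hit = rng.random(c.size) < rate
    shift = rng.integers(1, 4, size=c.size)
    c[hit] = (c[hit] + shift[hit]) % 4
    return _BASES[c].tobytes().decode()


def simulate_genome(
    length: int,
    gc: float = 0.5,
    seed: int = 0,
    n_species: int = 1,
    divergence_between_species: float = 0.0,
) -> dict[str, str]:
    """One random genome plus ``n_species - 1`` mutated copies at the
    stated pairwise substitution divergence."""
    if not (0.0 <= divergence_between_species <= 0.3):
        raise ValueError("divergence_between_species must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    base = _random_sequence(rng, length, gc)
    genomes = {"genome_0": base}
    for i in range(1, n_species):
        genomes[f"genome_{i}"] = _mutate(rng, base, divergence_between_species)
    return genomes


def apply_errors(
    sequence: str, model: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Corrupt a sequence with i.i.d. deletions, substitutions and
    (single-base, post-base) insertions; constant qualities."""
    lut = np.zeros(256, dtype=np.uint8)
    for b, c in _CODE_OF.items():
        lut[ord(b)] = c
    codes = lut[np.frombuffer(sequence.encode(), dtype=np.uint8)]
    n = codes.size
    keep = rng.random(n) >= model.deletion_rate
    kept = codes[keep]
    m = kept.size
    sub = rng.random(m) < model.substitution_rate
    shift = rng.integers(1, 4, size=m)
    kept = kept.copy()
    kept[sub] = (kept[sub] + shift[sub]) % 4
    ins = rng.random(m) < model.insertion_rate
    inserted = rng.integers(0, 4, size=m)
    reps = 1 + ins.astype(np.int64)
    out = np.empty(int(reps.sum()), dtype=np.uint8)
    starts = np.cumsum(reps) - reps
    out[starts] = kept
    out[starts[ins] + 1] = inserted[ins]
    seq = _BASES[out].tobytes().decode()
    return seq, [model.quality_mean] * len(seq)


def simulate_reads(
    genomes: Mapping[str, str],
    coverage: float,
    read_length_mean: int,
    error_model: ErrorModel | None = None,
    sketch_params: SketchParams | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Sample reads uniformly (random strand), corrupt them, and record
    the high-density ground-truth sketch of each origin interval.

    Read lengths vary uniformly within ±10% of the mean.  A requested
    length longer than the genome is truncated (no wrap-around).
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    model = error_model or ErrorModel()
    params = sketch_params or SketchParams()
    rng = np.random.default_rng(seed)
    reads: dict[str, SimRead] = {}
    truth: dict[str, MRead] = {}
    idx = 0
    for gid in sorted(genomes):
        genome = genomes[gid]
        L = len(genome)
        n_reads = int(round(coverage * L / read_length_mean))
        for _ in range(n_reads):
            rl = int(round(read_length_mean * rng.uniform(0.9, 1.1)))
            rl = min(rl, L)
            start = int(rng.integers(0, max(L - rl, 0) + 1))
            end = start + rl
            strand = "+" if rng.random() < 0.5 else "-"
            origin = genome[start:end]
            oriented = origin if strand == "+" else reverse_complement(origin)
            corrupted, quals = apply_errors(oriented, model, rng)
            rid = f"read_{idx:05d}"
            idx += 1
            reads[rid] = SimRead(corrupted, quals, gid, start, end, strand)
            truth[rid] = build_mread(rid, oriented, None, params, HIGH)
    return SimulatedDataset(
        genomes=dict(genomes),
        reads=reads,
        truth_mreads=truth,
        params=params,
        error_model=model,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# correction quality


def _lcs_length(a: np.ndarray, b: np.ndarray) -> int:
    """Longest common subsequence of two hash arrays (row-vectorized DP);
    the match count of the optimal edit-distance alignment."""
    if a.size == 0 or b.size == 0:
        return 0
    prev = np.zeros(b.size + 1, dtype=np.int32)
    for x in a:
        eq = (b == x).astype(np.int32)
        cand = np.maximum(prev[1:], prev[:-1] + eq)
        cur = np.empty_like(prev)
        cur[0] = 0
        cur[1:] = np.maximum.accumulate(cand)
        prev = cur
    return int(prev[-1])


@dataclass
class ReadMetrics:
    precision: float
    recall: float
    f1: float
    error: float


@dataclass
class CorrectionMetrics:
    per_read: dict[str, ReadMetrics]
    precision: float
    recall: float
    f1: float
    error: float


def eval_correction(
    corrected: Mapping[str, MRead], truth: Mapping[str, MRead]
) -> CorrectionMetrics:
    """Minimizer-level precision/recall of corrected sketches vs the
    ground-truth sketches of their origin intervals.

    Hit lists are aligned by an edit-distance DP over hash values; a
    matched pair is a recovered minimizer.  Error rate is 1 - F1,
    aggregated over all reads (micro average).
    """
    if set(corrected) != set(truth):
        raise ValueError("corrected and truth read_ids do not match")
    per_read: dict[str, ReadMetrics] = {}
    tot_match = tot_corr = tot_truth = 0
    for rid in sorted(corrected):
        c, t = corrected[rid], truth[rid]
        matches = _lcs_length(c.hashes, t.hashes)
        p = matches / len(c) if len(c) else (1.0 if len(t) == 0 else 0.0)
        r = matches / len(t) if len(t) else 1.0
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        per_read[rid] = ReadMetrics(p, r, f1, 1.0 - f1)
        tot_match += matches
        tot_corr += len(c)
        tot_truth += len(t)
    p = tot_match / tot_corr if tot_corr else 1.0
    r = tot_match / tot_truth if tot_truth else 1.0
    f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    return CorrectionMetrics(per_read, p, r, f1, 1.0 - f1)
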