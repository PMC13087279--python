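"""File formats: FASTA/FASTQ input, mRead/alignment/report dumps, config.

Sequence input goes through Bio.SeqIO; gzip is detected by magic bytes.
The mRead dump is a plain TSV, one hit per line, with a file header
carrying the sketch parameters and one ``@read`` line per read so that
hit-less reads round-trip too.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np
from Bio import SeqIO

from .chain import MAlignment, ChainParams, OPPOSITE
from .correct import CorrectedRead, FilterParams, ReadRecord
from .sketch import MRead, SketchParams

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sequence input


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _sniff_format(handle: TextIO) -> str | None:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    if first == "":
        return None
    raise ValueError(f"unrecognized sequence format (first character {first!r})")


def read_sequences(path: str | Path) -> list[ReadRecord]:
    """Read FASTA or FASTQ, plain or gzipped; record order preserved.

    FASTQ records carry per-base Phred qualities, FASTA records None.
    """
    with _open_text(path) as handle:
        fmt = _sniff_format(handle)
        if fmt is None:
            return []
        records = []
        for rec in SeqIO.parse(handle, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            records.append(ReadRecord(rec.id, str(rec.seq).upper(), quals))
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, Sequence[int]]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, quals in records:
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# mRead dump (TSV)


def write_mreads(
    path: str | Path, mreads: Iterable[MRead], params: SketchParams, density: str
) -> None:
    """One hit per line: read_id, read_length, offset, orientation (+/-),
    hash (hex), quality (int or '.')."""
    with open(path, "w") as fh:
        fh.write(f"#mscorrect-mreads\tk={params.k}\tseed={params.seed}\tdensity={density}\n")
        for mr in mreads:
            fh.write(f"@read\t{mr.read_id}\t{mr.read_length}\n")
            quals = mr.qualities
            for i in range(len(mr)):
                q = "." if quals is None else str(int(quals[i]))
                strand = "-" if mr.orientations[i] else "+"
                fh.write(
                    f"{mr.read_id}\t{mr.read_length}\t{int(mr.offsets[i])}\t"
                    f"{strand}\t{int(mr.hashes[i]):016x}\t{q}\n"
                )


def read_mreads(path: str | Path) -> tuple[list[MRead], dict]:
    """Inverse of :func:`write_mreads`; returns (mreads, header dict)."""
    mreads: list[MRead] = []
    header: dict = {}
    cur_id: str | None = None
    cur_len = 0
    hashes: list[int] = []
    offsets: list[int] = []
    orients: list[bool] = []
    quals: list[int] = []
    has_qual = True

    def flush():
        nonlocal hashes, offsets, orients, quals
        if cur_id is None:
            return
        mreads.append(
            MRead(
                read_id=cur_id,
                read_length=cur_len,
                density=header.get("density", "high"),
                hashes=np.array(hashes, dtype=np.uint64),
                offsets=np.array(offsets, dtype=np.int64),
                orientations=np.array(orients, dtype=bool),
                qualities=(
                    np.array(quals, dtype=np.int16)
                    if has_qual and hashes and len(quals) == len(hashes)
                    else None
                ),
            )
        )
        hashes, offsets, orients, quals = [], [], [], []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#mscorrect-mreads"):
                for part in line.split("\t")[1:]:
                    key, val = part.split("=")
                    header[key] = val if key == "density" else int(val)
                continue
            if line.startswith("@read\t"):
                flush()
                _, cur_id, slen = line.split("\t")
                cur_len = int(slen)
                has_qual = True
                continue
            rid, rlen, off, strand, hhex, q = line.split("\t")
            hashes.append(int(hhex, 16))
            offsets.append(int(off))
            orients.append(strand == "-")
            if q == ".":
                has_qual = False
            else:
                quals.append(int(q))
    flush()
    return mreads, header


# ---------------------------------------------------------------------------
# alignment / recruitment / report dumps


def write_alignments(path: str | Path, alignments: Iterable[MAlignment]) -> None:
    """PAF-like TSV: query_id, q_start, q_end, strand, target_id,
    t_start, t_end, n, m, divergence, score."""
    with open(path, "w") as fh:
        fh.write(
            "query_id\tq_start\tq_end\tstrand\ttarget_id\tt_start\tt_end\tn\tm\tdivergence\tscore\n"
        )
        for a in alignments:
            strand = "-" if a.relative_strand == OPPOSITE else "+"
            fh.write(
                f"{a.query_id}\t{a.q_span[0]}\t{a.q_span[1]}\t{strand}\t"
                f"{a.target_id}\t{a.t_span[0]}\t{a.t_span[1]}\t"
                f"{a.n}\t{a.m}\t{a.divergence:.6f}\t{a.score:.2f}\n"
            )


def write_report(path: str | Path, results: Iterable[CorrectedRead]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsupporters_recruited\tsupporters_retained\ts_max\tcorrected\ttrimmed\n"
        )
        for r in results:
            fh.write(
                f"{r.read_id}\t{r.supporters_recruited}\t{r.supporters_retained}\t"
                f"{r.s_max:.2f}\t{int(r.corrected)}\t{int(r.trimmed)}\n"
            )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Every knob of a correction run; JSON round-trippable.

    Defaults are the method's published operating point: k = 15,
    densities 0.5% / 2.5%, repetitive fraction 1e-4, 20x recruitment
    cap, 4% divergence / 1000 bp span / 2000 bp overhang filters.
    """

    k: int = 15
    seed: int = 0
    d_low: float = 0.005
    d_high: float = 0.025
    repetitive_fraction: float = 0.0001
    hpc: bool = False
    match_bonus: float = 50.0
    gap_scale: float = 0.05
    gap_cap: float = 50.0
    band_h: int = 50
    max_divergence: float = 0.04
    min_span_bases: int = 1000
    max_overhang_bases: int = 2000
    coverage_cap: float = 20.0
    threads: int = 1
    input_path: str = ""
    output_prefix: str = ""
    output_mode: str = "both"  # mreads | fasta | both

    def sketch_params(self) -> SketchParams:
        return SketchParams(
            k=self.k,
            seed=self.seed,
            d_low=self.d_low,
            d_high=self.d_high,
            repetitive_fraction=self.repetitive_fraction,
            hpc=self.hpc,
        )

    def chain_params(self) -> ChainParams:
        return ChainParams(
            match_bonus=self.match_bonus,
            gap_scale=self.gap_scale,
            gap_cap=self.gap_cap,
            band_h=self.band_h,
        )

    def filter_params(self) -> FilterParams:
        return FilterParams(
            max_divergence=self.max_divergence,
            min_span_bases=self.min_span_bases,
            max_overhang_bases=self.max_overhang_bases,
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))
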