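"""Estimate per-base divergence between two reads without aligning bases.

Two reads are sketched, their shared minimizers anchored and chained,
and the divergence inverted from the fraction of matching seeds:
if n of the m query minimizers in the aligned span match,
divergence = 1 - (n/m)^(1/k).
"""

import numpy as np

from mscorrect import ChainParams, HIGH, SketchParams, align_mreads, build_mread

rng = np.random.default_rng(1)
BASES = np.array(list("ACGT"))
genome = "".join(BASES[rng.integers(0, 4, size=100_000)])


def mutate(seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return "".join(out)


params = SketchParams()
target = build_mread("target", genome, None, params, HIGH)

print(f"{'true p':>8} {'estimate':>9} {'n/m':>12}")
for p in (0.00, 0.01, 0.02, 0.03):
    query = build_mread("query", mutate(genome, p), None, params, HIGH)
    aln = align_mreads(query, target, params, ChainParams())
    print(f"{p:8.3f} {aln.divergence:9.4f} {aln.n:5d}/{aln.m:<5d}")
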