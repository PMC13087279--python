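"""Sketch a sequence into an mRead and check the selected densities.

An mRead is the ordered list of *universal minimizers* of a read: a
k-mer is selected wherever it occurs iff its hash falls below a fixed
fraction d of the hash range.  The same hash function with two
thresholds gives two nested sketches — every low-density minimizer is
also a high-density one.
"""

import numpy as np

from mscorrect import HIGH, LOW, SketchParams, build_mread

rng = np.random.default_rng(0)
seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=200_000)])

params = SketchParams()  # k=15, d_low=0.5%, d_high=2.5%
low = build_mread("demo", seq, None, params, LOW)
high = build_mread("demo", seq, None, params, HIGH)

n_kmers = len(seq) - params.k + 1
print(f"sequence: {len(seq):,} bp, {n_kmers:,} k-mers (k={params.k})")
print(f"low-density sketch:  {len(low):5d} hits = {100*len(low)/n_kmers:.3f}% (target 0.5%)")
print(f"high-density sketch: {len(high):5d} hits = {100*len(high)/n_kmers:.3f}% (target 2.5%)")

nested = set(map(int, low.hashes)) <= set(map(int, high.hashes))
print(f"low sketch nested inside high sketch: {nested}")

# each hit records its hash, base offset, and canonical-strand flag
h = low.hits[0]
print(f"first low hit: offset={h.offset} strand={'-' if h.is_reverse else '+'} hash={h.hash:#018x}")
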