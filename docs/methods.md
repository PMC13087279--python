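# Methods

## Model

A read `R` of length `L` is represented as its **mRead**: the ordered
list of positions whose k-mer is a *universal minimizer*. A k-mer is
selected wherever it occurs iff

```
hash(canonical(kmer)) < d * H,        H = 2^64 - 1
```

so selection is a property of the k-mer alone (no windowing), the
expected selected fraction is `d`, and sketches at two densities with
the same hash are **nested**: every minimizer of the sparse sketch
(`d_low`) also appears in the dense sketch (`d_high`). Each hit stores
the 64-bit hash, the base offset, the canonical-strand flag, and (for
FASTQ input) the minimum Phred quality over its k bases. `canonical`
is the lexicographic minimum of the 2-bit-encoded k-mer and its
reverse complement, hashed with a murmur-style 64-bit finalizer; the
seed is folded into the hash so re-seeding permutes the selected set.

Correction of a target read proceeds in four stages.

**Recruitment (sparse sketch).** All sparse sketches go into an
inverted index `hash -> (read, hit index, strand)`. Reads sharing at
least 2 non-blacklisted minimizers with the target are aligned in
minimizer space: exact hash matches form *anchors*, and a banded DP
picks the maximum-score colinear chain,

```
score(j) = max over previous anchors i of
           score(i) + match_bonus - min(gap_cap, gap_scale * |dq - dt|)
```

with strictly increasing hit indices on both reads and only the
`band_h` nearest predecessors examined. Minimizers between consecutive
chained anchors are classified positionally: `u` unmatched query hits
against `v` unmatched target hits give `min(u, v)` mismatches plus
`|u - v|` insertions or deletions. Candidates are ranked by
`matches - differences` and accepted greedily until the accumulated
projected overlap length reaches `coverage_cap *` target length
(the crossing candidate is still accepted).

**Re-alignment and filtering (dense sketch).** Accepted candidates
are re-aligned on the dense sketches and kept only if

- divergence ≤ `max_divergence` (4%),
- aligned target span ≥ `min_span_bases` (1000 bp),
- overhang ≤ `max_overhang_bases` (2000 bp), where the overhang at
  each alignment end is the smaller of the two unaligned flanks (a
  true dovetail overlap has overhang 0).

Divergence is estimated from seed survival: if `n` of the `m` query
minimizers in the aligned span match the target, each k-mer survives
with probability `(1-p)^k ≈ n/m`, so `p ≈ 1 - (n/m)^(1/k)`.

**Pileup and consensus.** The variation graph is seeded with one node
per target minimizer. Threading a supporter's alignment along that
path, a run of consecutive mismatches/insertions becomes one *variant
node* keyed by its flanking target indices and minimizer content (so
identical variants from different supporters merge), and a deletion
becomes an edge skipping target nodes. Edge weights accumulate +1 per
supporting transition, or the sum of the two minimizer qualities when
qualities exist; the target supports its own path. Node identity is
positional, so the graph is a DAG by construction and its topological
order is a sort key, independent of insertion order. The consensus is
the maximum cumulative-weight path:

```
S[v] = max over incoming edges (u, v) of S[u] + w(u, v)
```

with backtracking from the global maximum; ties prefer the earlier
topological index. The corrected mRead is the path's minimizer list;
offsets of variant minimizers are interpolated between their flanking
target offsets.

**Base reconstruction (optional).** For each consecutive path pair,
the bases are copied from the supporting read with the heaviest
transition (ties: longest alignment, then read id), sliced between its
occurrences of the two minimizers in its aligned orientation. Flanks
outside the consensus span carry no pileup evidence and are kept from
the target's raw sequence; a target-to-target gap with no supporter
falls back to the raw sequence and flags the read.

## Parameters and defaults

| parameter | default | rationale |
|---|---|---|
| `k` | 15 | long enough to be near-unique in ~100 Mbp, short enough that a k-mer survives 1% errors with prob ~0.86 |
| `d_low` | 0.005 | sparse sketch for all-vs-all recruitment (~1 hit / 200 bp) |
| `d_high` | 0.025 | dense sketch for alignment/pileup (~1 hit / 40 bp); 5x ratio keeps the index 25x smaller than pileup resolution |
| `repetitive_fraction` | 1e-4 | blacklist of the most abundant distinct minimizers; suppresses repeat-driven anchor blowup |
| `match_bonus` / `gap_scale` / `gap_cap` / `band_h` | 50 / 0.05 / 50 / 50 | one anchor outweighs ≤ 1 kb of diagonal drift; the cap keeps long indels chainable; the band bounds the DP at O(band·n) |
| `max_divergence` | 0.04 | admits same-strain reads (~1%+1% errors plus estimator noise), rejects inter-species overlaps |
| `min_span_bases` | 1000 | overlaps shorter than this carry too few dense minimizers (~25) for a stable divergence estimate |
| `max_overhang_bases` | 2000 | large overhangs indicate chimeric/repeat-induced, not dovetail, overlaps |
| `coverage_cap` | 20 | diminishing returns beyond 20x evidence; bounds per-read work on deep datasets |

All knobs are carried by `RunConfig` (JSON round-trippable) and
exposed on the CLI.

## Simulator

`simulate_genome` draws uniform-random genomes (optional GC bias) and
derives "species" copies by i.i.d. substitution at a given divergence.
`simulate_reads` places reads uniformly, with length jitter of ±10%
around the mean, random strand, and i.i.d. substitution/insertion/
deletion errors (defaults 0.6%/0.2%/0.2% ≈ 1% total); qualities are
constant at `quality_mean` since the error model carries no positional
quality signal. For every read the **ground-truth mRead** is the dense
sketch of its error-free origin interval in read orientation.

Scope: the simulator tests the correction machinery, not sequencers.
It has no homopolymer-length error bias, no quality-correlated errors,
no chimeras, and species differ by substitutions only.

Evaluation aligns corrected to truth hash lists with a longest-common-
subsequence DP; matched hashes are true positives, extra corrected
hashes false positives, missed truth hashes false negatives. Reported
per read and micro-aggregated: precision, recall, F1, error = 1 − F1.

## Numerical and implementation choices

- Hashes are 64-bit; density thresholds computed as `d * (2^64 - 1)`
  clamped to the range, so `d = 1` selects every valid k-mer. k-mers
  overlapping `N` are never selected.
- Sketching is numpy-vectorized (rolling 2-bit encodings of both
  strands); per-hit qualities use a sliding-window minimum.
- The chaining DP inner loop is JIT-compiled with numba when
  available; the pure-Python fallback is semantically identical.
  Chaining ties prefer the earlier predecessor, making chains
  deterministic.
- Blacklist ties at the abundance cutoff break by ascending hash.
- The variation graph is a plain dict-keyed DAG; its canonical
  `signature()` (sorted nodes, edges, weights) is the order-
  independence contract tested in the acceptance suite.
- Multi-threaded correction shares only read-only state; per-read
  results are assembled in input order, so outputs are byte-identical
  for any thread count.

## Problem sizes

Development and acceptance runs use desk-scale data: 1 Mbp random
sequences for density calibration, 100 kb genomes at 30x / 1% errors
for parameter-recovery (~300 reads, ~20 s with 4 threads), 30-50 kb
genomes for determinism and reconstruction tests. On the 100 kb
benchmark the corrected minimizer error is ~0.003 against ~0.135
uncorrected (>50x reduction); base-space reconstruction halves the
base-level edit distance (gaps between minimizers are filled from a
single supporter and retain that supporter's errors, so base error
cannot approach zero by design).
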