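# mscorrect

Minimizer-space self-correction of noisy long reads.

Long-read sequencers (nanopore, PacBio) produce reads with ~1% errors.
Assembling large datasets in base space is expensive, so a family of
methods works in **minimizer space** instead: each read is reduced to
its ordered list of *universal minimizers* — k-mers selected wherever
they occur because their hash falls below a fixed fraction `d` of the
hash range — and all downstream work operates on those short hash
lists. Sequencing errors corrupt the minimizer lists (a single base
error can delete a true minimizer or create a spurious one), so the
lists must be corrected before assembly. `mscorrect` implements that
correction stage, plus a simulator and evaluation metrics to study it:

1. **Sketch** every read at two nested densities with the same hash
   function (defaults: k = 15, 0.5% sparse and 2.5% dense), and
   blacklist the most repetitive 0.01% of distinct minimizers.
2. **Recruit**, for each read, its most similar reads via an inverted
   index over the sparse sketches and banded colinear anchor chaining
   (score = minimizer matches − differences), up to 20× coverage.
3. **Re-align and filter** the recruited reads on the dense sketches:
   keep alignments with divergence ≤ 4%, span ≥ 1000 bp and overhang
   ≤ 2000 bp. Divergence is estimated without base alignment as
   `1 − (n/m)^(1/k)` from the fraction of matching seeds.
4. **Pile up** the surviving alignments into a variation graph seeded
   with the target's minimizer path (parallel nodes for mismatches,
   bridging nodes for insertions, skipping edges for deletions), and
   replace the read's minimizer list with the **maximum-weight
   consensus path** (topological-order dynamic program).
5. Optionally **reconstruct** a corrected base sequence by filling the
   gaps between consensus minimizers from the best-supporting read.

No base-level alignment is performed anywhere in the pipeline.

## Worked example

```python
from mscorrect import (Corrector, ErrorModel, SketchParams,
                       eval_correction, simulate_genome, simulate_reads)

params = SketchParams()                 # k=15, 0.5% / 2.5%
genomes = simulate_genome(100_000, seed=42)
ds = simulate_reads(genomes, coverage=30, read_length_mean=10_000,
                    error_model=ErrorModel(),   # 1% total errors
                    sketch_params=params, seed=42)

corrector = Corrector(reads=list(ds.read_records()), sketch_params=params)
results = corrector.correct_all(threads=4)

corrected = {r.read_id: r.mread for r in results}
uncorrected = {rid: corrector.high[rid] for rid in corrected}
print(eval_correction(uncorrected, ds.truth_mreads).error)  # 0.1352
print(eval_correction(corrected, ds.truth_mreads).error)    # 0.0026  (52.8x lower)
```

The same run from the shell:

```sh
mscorrect simulate -o sim --length 100000 --coverage 30 --seed 42
mscorrect correct sim.reads.fastq -o out --threads 4
mscorrect eval out.mreads.tsv sim.truth.tsv
```

The narrated scripts in `examples/` walk through each stage
(sketching/density, divergence estimation, end-to-end correction,
base-space reconstruction); each runs in seconds to ~1 minute.

## Layout

- `src/mscorrect/sketch.py` — universal-minimizer sketching, abundance
  blacklist, homopolymer compression
- `src/mscorrect/chain.py` — anchors, banded colinear chaining DP,
  minimizer-space alignment, divergence estimate
- `src/mscorrect/recruit.py` — inverted index and coverage-capped
  recruitment
- `src/mscorrect/graph.py` — variation graph and consensus extraction
- `src/mscorrect/correct.py` — filters and the end-to-end `Corrector`
- `src/mscorrect/reconstruct.py` — base-space reconstruction
- `src/mscorrect/simulate.py` — genome/read simulator and metrics
- `src/mscorrect/io.py`, `cli.py` — file formats and the `mscorrect` CLI
- `docs/methods.md` — model, parameter rationale, design decisions
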