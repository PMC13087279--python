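"""Alignment filtering, variation-graph pileup, consensus extraction,
and the end-to-end correction pipeline."""

import numpy as np
import pytest

from mscorrect import (
    HIGH,
    ChainParams,
    Corrector,
    FilterParams,
    MAlignment,
    MRead,
    ReadRecord,
    SketchParams,
    align_mreads,
    build_mread,
    build_variation_graph,
    extract_consensus,
    filter_recruited,
    max_weight_path,
    select_minimizers,
)
from mscorrect.chain import SAME

from conftest import mutate_substitutions, random_dna


def make_alignment(divergence=0.01, span=5000, overhang=0, target_id="t"):
    return MAlignment(
        query_id="q",
        target_id=target_id,
        relative_strand=SAME,
        ops=[],
        n=90,
        m=100,
        q_span=(0, span),
        t_span=(100, 100 + span),
        overhang_left=overhang,
        overhang_right=0,
        divergence=divergence,
        score=0.0,
    )


def target_mread(rng, params, length=20_000):
    return build_mread("t", random_dna(rng, length), None, params, HIGH)


class TestFilter:
    @pytest.mark.parametrize(
        "kwargs,kept",
        [
            (dict(divergence=0.05), False),   # above the 4% divergence cap
            (dict(span=900), False),          # shorter than 1000 bp
            (dict(overhang=2500), False),     # overhang beyond 2000 bp
            (dict(divergence=0.03, span=5000, overhang=0), True),
            (dict(divergence=0.04), True),    # boundary: exactly 4% passes
            (dict(span=1000), True),          # boundary: exactly 1000 bp passes
            (dict(overhang=2000), True),      # boundary: exactly 2000 bp passes
        ],
    )
    def test_threshold_cases(self, rng, params, kwargs, kept):
        t = target_mread(rng, params)
        out = filter_recruited(t, [make_alignment(**kwargs)], FilterParams())
        assert bool(out) == kept

    def test_foreign_target_rejected(self, rng, params):
        t = target_mread(rng, params)
        with pytest.raises(ValueError, match="target"):
            filter_recruited(t, [make_alignment(target_id="other")], FilterParams())


class TestVariationGraph:
    def _pipeline_graph(self, rng, params, supporters, target_seq=None, shuffle=None):
        seq = target_seq or random_dna(rng, 20_000)
        target = build_mread("t", seq, None, params, HIGH)
        mreads = {"t": target}
        alns = []
        for rid, s in supporters:
            mreads[rid] = build_mread(rid, s, None, params, HIGH)
            aln = align_mreads(mreads[rid], target, params, ChainParams())
            assert aln is not None
            alns.append(aln)
        if shuffle is not None:
            alns = [alns[i] for i in shuffle]
        return build_variation_graph(target, alns, mreads, k=params.k), target

    def test_target_only_graph_is_its_own_path(self, rng, params):
        graph, target = self._pipeline_graph(rng, params, [])
        res = extract_consensus(graph)
        assert res.corrected.equals(
            MRead("t", target.read_length, HIGH, target.hashes,
                  target.offsets, target.orientations)
        )
        assert not res.trimmed

    def test_single_mismatch_creates_one_parallel_node(self, rng, params):
        """A supporter disagreeing at one minimizer adds a variant node
        parallel to the target node, with one incoming and one outgoing edge."""
        from mscorrect import select_minimizers

        seq = random_dna(rng, 20_000)
        target = build_mread("t", seq, None, params, HIGH)
        mid = len(target) // 2
        off = int(target.offsets[mid])
        # replace the bases under one interior target minimizer with a
        # window that itself carries a selected minimizer, so the
        # supporter shows a mismatch (not a bare deletion) there
        sup_seq = None
        for trial in range(100):
            repl = random_dna(np.random.default_rng(trial), params.k)
            cand = seq[:off] + repl + seq[off + params.k :]
            win = [
                h
                for h in select_minimizers(cand, params, HIGH)
                if off - params.k < h.offset < off + params.k
            ]
            if win and int(target.hashes[mid]) not in {h.hash for h in win}:
                sup_seq = cand
                break
        assert sup_seq is not None
        graph, target = self._pipeline_graph(
            rng, params, [("s", sup_seq)], target_seq=seq
        )
        vnodes = {n for e in graph.edges for n in e if n[0] == "v"}
        assert any(n[1] < mid <= n[2] for n in vnodes)
        for v in vnodes:
            ins = [e for e in graph.edges if e[1] == v]
            outs = [e for e in graph.edges if e[0] == v]
            assert len(ins) == 1 and len(outs) == 1

    def test_graph_independent_of_supporter_order(self, rng, params):
        genome = random_dna(rng, 15_000)
        supporters = [
            (f"s{i}", mutate_substitutions(rng, genome, 0.01)) for i in range(6)
        ]
        g1, _ = self._pipeline_graph(rng, params, supporters, target_seq=genome)
        for trial in range(5):
            perm = list(np.random.default_rng(trial).permutation(6))
            g2, _ = self._pipeline_graph(
                rng, params, supporters, target_seq=genome, shuffle=perm
            )
            assert g1.signature() == g2.signature()

    def test_foreign_alignment_rejected(self, rng, params):
        t = target_mread(rng, params)
        graph = build_variation_graph(t, [], {}, k=params.k)
        with pytest.raises(ValueError, match="target"):
            graph.add_supporter(make_alignment(target_id="other"), t)


def random_dag(rng, n_nodes, p_edge=0.4):
    """Random DAG over positional nodes with positive edge weights."""
    edges = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                edges[(("t", i), ("t", j))] = float(rng.integers(1, 10))
    return edges


def brute_force_best_path(edges, nodes):
    """Maximum-weight path by exhaustive depth-first enumeration."""
    out = {}
    for (u, v), w in edges.items():
        out.setdefault(u, []).append((v, w))
    best = 0.0

    def walk(u, acc):
        nonlocal best
        best = max(best, acc)
        for v, w in out.get(u, ()):
            walk(v, acc + w)

    for n in nodes:
        walk(n, 0.0)
    return best


class TestConsensusDP:
    def test_linear_graph_sums_all_weights(self):
        edges = {(("t", i), ("t", i + 1)): float(i + 1) for i in range(5)}
        path, s_max = max_weight_path(edges)
        assert path == [("t", i) for i in range(6)]
        assert s_max == sum(range(1, 6))

    def test_bubble_takes_heavy_branch(self):
        v = ("v", 0, 2, ((123, False),))
        edges = {
            (("t", 0), ("t", 1)): 1.0,
            (("t", 1), ("t", 2)): 1.0,
            (("t", 0), v): 3.0,
            (v, ("t", 2)): 3.0,
        }
        path, s_max = max_weight_path(edges)
        assert path == [("t", 0), v, ("t", 2)]
        assert s_max == 6.0
        nodes = {n for e in edges for n in e}
        assert s_max == brute_force_best_path(edges, nodes)

    def test_dp_equals_exhaustive_enumeration_on_random_dags(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            n = int(rng.integers(2, 12))
            edges = random_dag(rng, n)
            nodes = {("t", i) for i in range(n)}
            path, s_max = max_weight_path(edges, nodes)
            assert s_max == brute_force_best_path(edges, nodes)
            # the returned path realizes its claimed weight
            assert s_max == sum(edges[(u, v)] for u, v in zip(path, path[1:]))

    def test_cycle_like_edge_rejected(self):
        with pytest.raises(ValueError):
            max_weight_path({(("t", 3), ("t", 1)): 1.0})


class TestCorrectRead:
    def test_isolated_read_returned_uncorrected(self, rng, params):
        reads = [
            ReadRecord("a", random_dna(rng, 10_000), None),
            ReadRecord("b", random_dna(rng, 10_000), None),
        ]
        corr = Corrector(reads=reads, sketch_params=params)
        res = corr.correct_read("a")
        assert not res.corrected
        assert res.mread.equals(corr.high["a"])

    def test_unknown_read_id_rejected(self, rng, params):
        corr = Corrector(
            reads=[ReadRecord("a", random_dna(rng, 5_000), None)],
            sketch_params=params,
        )
        with pytest.raises(KeyError):
            corr.correct_read("zzz")

    def test_identical_supporters_leave_target_unchanged(self, rng, params):
        seq = random_dna(rng, 10_000)
        reads = [ReadRecord(f"r{i:02d}", seq, None) for i in range(21)]
        corr = Corrector(reads=reads, sketch_params=params)
        res = corr.correct_read("r00")
        assert res.corrected
        assert res.mread.hashes.tolist() == corr.high["r00"].hashes.tolist()

    def test_spurious_minimizer_removed_by_majority(self, rng, params):
        """A target with inserted junk loses its spurious minimizers when
        the supporters lack them."""
        genome = random_dna(rng, 12_000)
        insert_rng = np.random.default_rng(4)
        pos = 6_000
        insert = random_dna(insert_rng, 300)
        target_seq = genome[:pos] + insert + genome[pos:]
        spurious = {
            h.hash
            for h in select_minimizers(target_seq, params, HIGH)
            if pos - params.k < h.offset < pos + len(insert)
        }
        assert spurious, "constructed insert must contain at least one minimizer"
        reads = [ReadRecord("t", target_seq, None)] + [
            ReadRecord(f"s{i:02d}", genome, None) for i in range(19)
        ]
        corr = Corrector(reads=reads, sketch_params=params)
        res = corr.correct_read("t")
        assert res.corrected
        assert not (spurious & set(map(int, res.mread.hashes)))


class TestCorrectAll:
    def test_empty_input(self, params):
        corr = Corrector(reads=[], sketch_params=params)
        assert corr.correct_all() == []

    def test_single_read_flagged_uncorrected(self, rng, params):
        corr = Corrector(
            reads=[ReadRecord("only", random_dna(rng, 8_000), None)],
            sketch_params=params,
        )
        out = corr.correct_all()
        assert len(out) == 1 and not out[0].corrected

    def test_thread_counts_agree(self, rng, params):
        genome = random_dna(rng, 15_000)
        reads = [
            ReadRecord(f"r{i:02d}", mutate_substitutions(rng, genome, 0.01), None)
            for i in range(10)
        ]
        one = Corrector(reads=reads, sketch_params=params).correct_all(threads=1)
        four = Corrector(reads=reads, sketch_params=params).correct_all(threads=4)
        assert [r.read_id for r in one] == [r.read_id for r in four]
        for a, b in zip(one, four):
            assert a.mread.equals(b.mread)
            assert a.s_max == b.s_max

    def test_quality_length_mismatch_skips_read(self, rng, params, caplog):
        reads = [
            ReadRecord("good", random_dna(rng, 8_000), None),
            ReadRecord("bad", random_dna(rng, 8_000), [30] * 10),
        ]
        corr = Corrector(reads=reads, sketch_params=params)
        assert corr.read_order == ["good"]


def test_idempotence_on_clean_reads(rng, params):
    """Error-free reads from a non-repetitive genome pass through
    correction essentially unchanged (>= 99% identical mReads)."""
    genome = random_dna(rng, 50_000)
    reads = []
    starts = rng.integers(0, 42_000, size=100)
    for i, s in enumerate(sorted(starts)):
        reads.append(ReadRecord(f"r{i:03d}", genome[s : s + 8_000], None))
    corr = Corrector(reads=reads, sketch_params=params)
    results = corr.correct_all()
    unchanged = sum(
        r.mread.hashes.tolist() == corr.high[r.read_id].hashes.tolist()
        for r in results
    )
    assert unchanged >= 0.99 * len(results)
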