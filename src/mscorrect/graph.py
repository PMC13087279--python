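"""Minimizer pileup via a variation graph, and consensus extraction.

The graph is seeded with the target read's minimizer path (one node per
target hit).  Each retained supporter alignment is threaded along that
path: a mismatch creates a node parallel to a target node, an insertion
a node bridging two target nodes, and a deletion a weight-bearing edge
that skips target nodes.  Runs of consecutive mismatches/insertions from
one supporter collapse into a single variant node keyed by its flanking
target indices and its minimizer content, so identical variants from
different supporters pile up on one node.  Edge weights accumulate the
support (+1 per supporting transition, or the sum of the source and
destination minimizer qualities when qualities are available), and the
final graph is independent of the order in which supporters are added.

The consensus is the maximum cumulative-weight path, found by a
topological-order dynamic program with backtracking from the
highest-scoring node.  Node identity is positional (anchored to target
indices), so the graph is structurally acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import numpy as np

from .chain import DELETION, INSERTION, MATCH, MISMATCH, MAlignment, OPPOSITE
from .sketch import HIGH, MRead

Node = tuple  # ('t', i) or ('v', left, right, ((hash, is_reverse), ...))


def _topo_key(node: Node):
    """Sort key that is a valid topological order by construction:
    a variant node (a, b, ...) sits strictly between its flanks."""
    if node[0] == "t":
        return (node[1], 0, 0, ())
    return (node[1], 1, node[2], node[3])


@dataclass
class EdgeSupport:
    """One supporter's contribution to an edge, with the coordinates
    needed to excise its spanning subsequence at reconstruction time.
    Offsets are in the supporter's aligned orientation (positions on the
    reverse complement for opposite-strand supporters)."""

    weight: float
    aln_span: int
    read_id: str
    flipped: bool
    src_offset: int      # start of the source node's last minimizer
    dst_offset: int      # start of the destination node's first minimizer
    dst_exit_offset: int  # start of the destination node's last minimizer


@dataclass
class VariationGraph:
    """DAG over minimizer occurrences of one target read."""

    target: MRead
    use_quality: bool = False
    edges: dict[tuple[Node, Node], float] = field(default_factory=dict)
    edge_support: dict[tuple[Node, Node], list[EdgeSupport]] = field(default_factory=dict)
    # per variant node, elementwise max supporter quality of its minimizers
    variant_quality: dict[Node, list[int]] = field(default_factory=dict)
    k: int = 15

    @property
    def target_path(self) -> list[Node]:
        return [("t", i) for i in range(len(self.target))]

    def nodes(self) -> list[Node]:
        seen = {n for e in self.edges for n in e}
        seen.update(self.target_path)
        return sorted(seen, key=_topo_key)

    def add_edge(
        self, u: Node, v: Node, weight: float, support: EdgeSupport | None = None
    ) -> None:
        if _topo_key(u) >= _topo_key(v):
            raise ValueError(f"edge {u}->{v} violates the topological order")
        self.edges[(u, v)] = self.edges.get((u, v), 0.0) + weight
        if support is not None:
            self.edge_support.setdefault((u, v), []).append(support)

    # -- threading supporters ------------------------------------------------

    def _hit_quality(self, mread: MRead, idx: int) -> int:
        if mread.qualities is None:
            return -1
        return int(mread.qualities[idx])

    def _edge_weight(self, src_qual: int, dst_qual: int) -> float:
        if self.use_quality and src_qual >= 0 and dst_qual >= 0:
            return float(src_qual + dst_qual)
        return 1.0

    def add_supporter(self, alignment: MAlignment, query: MRead) -> None:
        """Thread one filtered alignment through the graph."""
        if alignment.target_id != self.target.read_id:
            raise ValueError(
                f"alignment targets {alignment.target_id!r}, "
                f"graph is for {self.target.read_id!r}"
            )
        flipped = alignment.relative_strand == OPPOSITE
        k = self.k

        def aligned_offset(q_idx: int) -> int:
            off = int(query.offsets[q_idx])
            return query.read_length - k - off if flipped else off

        # walk the ops into path elements: (node, entry q_idx, exit q_idx)
        elems: list[tuple[Node, int, int]] = []
        pending: list[int] = []  # query indices of a mismatch/insertion run
        prev_t: int | None = None
        for op in alignment.ops:
            if op.op == MATCH:
                if prev_t is not None and pending:
                    variants = tuple(
                        (
                            int(query.hashes[q]),
                            (not bool(query.orientations[q]))
                            if flipped
                            else bool(query.orientations[q]),
                        )
                        for q in pending
                    )
                    vnode: Node = ("v", prev_t, op.t_index, variants)
                    elems.append((vnode, pending[0], pending[-1]))
                    quals = [self._hit_quality(query, q) for q in pending]
                    old = self.variant_quality.get(vnode)
                    if old is None:
                        self.variant_quality[vnode] = quals
                    else:
                        self.variant_quality[vnode] = [
                            max(a, b) for a, b in zip(old, quals)
                        ]
                elems.append((("t", op.t_index), op.q_index, op.q_index))
                prev_t = op.t_index
                pending = []
            elif op.op in (MISMATCH, INSERTION):
                pending.append(op.q_index)
            elif op.op == DELETION:
                pass  # skipped target node: realized as the skip edge below

        # ops advance along the target; for opposite-strand supporters the
        # raw query indices descend, but their positions on the reverse
        # complement ascend, so entry/exit order is already correct
        span = alignment.t_span_length
        for (node_a, _ea, xa), (node_b, eb, xb) in zip(elems, elems[1:]):
            w = self._edge_weight(
                self._hit_quality(query, xa), self._hit_quality(query, eb)
            )
            self.add_edge(
                node_a,
                node_b,
                w,
                EdgeSupport(
                    weight=w,
                    aln_span=span,
                    read_id=query.read_id,
                    flipped=flipped,
                    src_offset=aligned_offset(xa),
                    dst_offset=aligned_offset(eb),
                    dst_exit_offset=aligned_offset(xb),
                ),
            )

    def add_target_support(self) -> None:
        """The target supports its own path as one supporter."""
        t = self.target
        for i in range(len(t) - 1):
            w = self._edge_weight(self._hit_quality(t, i), self._hit_quality(t, i + 1))
            self.add_edge(
                ("t", i),
                ("t", i + 1),
                w,
                EdgeSupport(
                    weight=w,
                    aln_span=t.read_length,
                    read_id=t.read_id,
                    flipped=False,
                    src_offset=int(t.offsets[i]),
                    dst_offset=int(t.offsets[i + 1]),
                    dst_exit_offset=int(t.offsets[i + 1]),
                ),
            )

    def signature(self) -> tuple:
        """Canonical (order-independent) description of nodes, edges and
        weights — equal signatures mean equal graphs."""
        return (
            tuple(self.nodes()),
            tuple(sorted((u, v, w) for (u, v), w in self.edges.items())),
            tuple(sorted((n, tuple(q)) for n, q in self.variant_quality.items())),
        )


def build_variation_graph(
    target: MRead,
    alignments: Iterable[MAlignment],
    mreads: Mapping[str, MRead],
    use_quality: bool = False,
    k: int = 15,
    target_support: bool = True,
) -> VariationGraph:
    """Pile up filtered supporter alignments onto the target's path."""
    graph = VariationGraph(target=target, use_quality=use_quality, k=k)
    if target_support:
        graph.add_target_support()
    for aln in alignments:
        graph.add_supporter(aln, mreads[aln.query_id])
    return graph


# ---------------------------------------------------------------------------
# consensus


def max_weight_path(
    edges: Mapping[tuple[Node, Node], float],
    extra_nodes: Iterable[Node] = (),
) -> tuple[list[Node], float]:
    """Maximum cumulative-weight path in a DAG of positional nodes.

    Nodes are processed in topological order (their sort key); each node
    records as parent the predecessor maximizing S[u] + w_e, ties broken
    by the earliest topological index, and the path is recovered by
    backtracking from the highest-scoring node.  Raises on an edge that
    contradicts the topological order (a structural cycle).
    """
    nodes = {n for e in edges for n in e}
    nodes.update(extra_nodes)
    order = sorted(nodes, key=_topo_key)
    topo_index = {n: i for i, n in enumerate(order)}

    incoming: dict[Node, list[tuple[Node, float]]] = {}
    for (u, v), w in edges.items():
        if topo_index[u] >= topo_index[v]:
            raise ValueError(f"edge {u}->{v} is not topologically forward")
        incoming.setdefault(v, []).append((u, w))

    S: dict[Node, float] = {}
    parent: dict[Node, Node | None] = {}
    for v in order:
        best_s, best_u = 0.0, None
        for u, w in sorted(incoming.get(v, ()), key=lambda e: topo_index[e[0]]):
            cand = S[u] + w
            if best_u is None or cand > best_s:
                best_s, best_u = cand, u
        S[v] = best_s if best_u is not None else 0.0
        parent[v] = best_u

    v_max = max(order, key=lambda n: (S[n], -topo_index[n]))
    path = [v_max]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    path.reverse()
    return path, S[v_max]


@dataclass
class ConsensusResult:
    """The most supported path, as a corrected mRead."""

    corrected: MRead
    path: list[Node]
    support: list[float]  # edge weights along the path
    s_max: float
    trimmed: bool


def extract_consensus(graph: VariationGraph) -> ConsensusResult:
    """Extract the maximum-support path and express it as an mRead.

    Variant-node minimizers receive offsets interpolated between their
    flanking target offsets (then monotonized), the orientation observed
    by their supporters, and the maximum supporter quality seen.
    """
    path, s_max = max_weight_path(graph.edges, graph.target_path)
    t = graph.target

    hashes: list[int] = []
    offsets: list[int] = []
    orients: list[bool] = []
    quals: list[int] = []
    for node in path:
        if node[0] == "t":
            i = node[1]
            hashes.append(int(t.hashes[i]))
            offsets.append(int(t.offsets[i]))
            orients.append(bool(t.orientations[i]))
            quals.append(-1 if t.qualities is None else int(t.qualities[i]))
        else:
            _, a, b, variants = node
            left, right = int(t.offsets[a]), int(t.offsets[b])
            vq = graph.variant_quality.get(node, [-1] * len(variants))
            for j, (h, orient) in enumerate(variants):
                frac = (j + 1) / (len(variants) + 1)
                hashes.append(h)
                offsets.append(left + int(round(frac * (right - left))))
                orients.append(orient)
                quals.append(vq[j])

    # offsets must be strictly increasing; interpolation can collide when
    # many minimizers are inserted between close flanks
    for i in range(1, len(offsets)):
        if offsets[i] <= offsets[i - 1]:
            offsets[i] = offsets[i - 1] + 1

    has_qual = t.qualities is not None
    corrected = MRead(
        read_id=t.read_id,
        read_length=t.read_length,
        density=t.density,
        hashes=np.array(hashes, dtype=np.uint64),
        offsets=np.array(offsets, dtype=np.int64),
        orientations=np.array(orients, dtype=bool),
        qualities=np.array(quals, dtype=np.int16) if has_qual else None,
    )
    trimmed = bool(path) and (
        path[0] != ("t", 0) or path[-1] != ("t", len(t) - 1)
    )
    support = [graph.edges[(u, v)] for u, v in zip(path, path[1:])]
    return ConsensusResult(
        corrected=corrected, path=path, support=support, s_max=s_max, trimmed=trimmed
    )
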