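"""Base-space reconstruction of a corrected read.

The consensus path fixes the order of minimizers but not the bases
between them.  For every consecutive minimizer pair on the path, the
gap is filled with the spanning subsequence of the supporting read
whose transition carried the highest weight (ties: longest alignment,
then ascending read_id); the concatenation of these spans, plus the
final minimizer's bases, is the reconstructed read.  The flanks before
the first and after the last consensus minimizer carry no pileup
evidence, so they are kept verbatim from the target's own raw
sequence.  A gap with no supporter (possible only between two
target-path nodes) likewise falls back to the target's raw sequence
and is flagged.
"""

from __future__ import annotations

from typing import Mapping

from .graph import ConsensusResult, EdgeSupport, VariationGraph
from .sketch import reverse_complement


def _best_support(records: list[EdgeSupport]) -> EdgeSupport:
    return min(records, key=lambda r: (-r.weight, -r.aln_span, r.read_id))


class _OrientedSequences:
    """Raw sequences, reverse-complemented on demand and cached."""

    def __init__(self, sequences: Mapping[str, str]):
        self._fwd = sequences
        self._rc: dict[str, str] = {}

    def get(self, read_id: str, flipped: bool) -> str:
        if not flipped:
            return self._fwd[read_id]
        if read_id not in self._rc:
            self._rc[read_id] = reverse_complement(self._fwd[read_id])
        return self._rc[read_id]


def reconstruct_bases(
    result: ConsensusResult,
    graph: VariationGraph,
    sequences: Mapping[str, str],
) -> tuple[str, bool]:
    """Spell out the consensus path in bases.

    Returns (sequence, used_fallback): ``used_fallback`` is True when
    some gap had no supporting read and the target's own sequence was
    used instead.
    """
    t = graph.target
    k = graph.k
    oriented = _OrientedSequences(sequences)
    raw = sequences[t.read_id]
    path = result.path
    if not path:
        return "", False

    # uncorrected flanks outside the consensus span stay raw
    prefix = raw[: int(t.offsets[path[0][1]])] if path[0][0] == "t" else ""
    suffix = raw[int(t.offsets[path[-1][1]]) + k :] if path[-1][0] == "t" else ""

    if len(path) == 1:
        node = path[0]
        if node[0] != "t":
            raise ValueError("single-node consensus must lie on the target path")
        off = int(t.offsets[node[1]])
        return prefix + raw[off : off + k] + suffix, False

    parts: list[str] = [prefix]
    used_fallback = False
    last_support: EdgeSupport | None = None
    for u, v in zip(path, path[1:]):
        records = graph.edge_support.get((u, v), [])
        if records:
            best = _best_support(records)
            seq = oriented.get(best.read_id, best.flipped)
            # through the destination node's last minimizer start, so the
            # internal bases of multi-minimizer variant nodes are covered
            # and the next edge picks up at exactly that minimizer
            parts.append(seq[best.src_offset : best.dst_exit_offset])
            last_support = best
        else:
            # unspanned gap: only target-path nodes can lack support
            if u[0] != "t" or v[0] != "t":
                raise ValueError(f"variant edge {u}->{v} has no supporting read")
            a, b = int(t.offsets[u[1]]), int(t.offsets[v[1]])
            parts.append(sequences[t.read_id][a:b])
            used_fallback = True
            last_support = None

    # append the final minimizer's k bases from the last chosen supporter
    if last_support is not None:
        seq = oriented.get(last_support.read_id, last_support.flipped)
        parts.append(
            seq[last_support.dst_exit_offset : last_support.dst_exit_offset + k]
        )
    else:
        end_node = path[-1]
        off = int(t.offsets[end_node[1]])
        parts.append(raw[off : off + k])
    parts.append(suffix)
    return "".join(parts), used_fallback
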