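"""Partial-order alignment (POA) consensus for allele reads.

Repeat alleles extracted from noisy long reads are polished into a
single consensus by building a partial-order graph: the first sequence
seeds a linear chain, every further sequence is aligned to the graph
(global dynamic programming over the DAG, linear gap penalty) and fused
into it, with matched bases reusing existing nodes and mismatches
joining the node's aligned column.  Edge weights count how many
sequences traverse each edge; the consensus is the heaviest-bundle
path from the virtual source to the virtual sink (each node's incoming
edge of maximal weight, ties broken by accumulated score and then
toward the lexicographically smaller base), so the result is
deterministic for a given input order.

Sentinel source/sink nodes let fully empty sequences contribute weight
to the direct source->sink edge, so a read group dominated by 0 bp
alleles yields an empty consensus.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

_MATCH = 2.0
_MISMATCH = -1.0
_GAP = -2.0

# fixed base ordering for deterministic tie-breaks
_BASE_ORDER = {b: i for i, b in enumerate("ACGTN")}


class _POAGraph:
    """Partial-order graph over DNA bases with weighted edges."""

    def __init__(self) -> None:
        self.bases: list[str] = ["^", "$"]  # 0 = source, 1 = sink
        self.edges: dict[tuple[int, int], float] = {}
        self.preds: list[list[int]] = [[], []]
        self.succs: list[list[int]] = [[], []]
        self.aligned: list[set[int]] = [set(), set()]

    SOURCE = 0
    SINK = 1

    def add_node(self, base: str) -> int:
        self.bases.append(base)
        self.preds.append([])
        self.succs.append([])
        self.aligned.append(set())
        return len(self.bases) - 1

    def add_edge_weight(self, u: int, v: int, w: float = 1.0) -> None:
        if (u, v) not in self.edges:
            self.edges[(u, v)] = 0.0
            self.succs[u].append(v)
            self.preds[v].append(u)
        self.edges[(u, v)] += w

    def add_path(self, nodes: Sequence[int]) -> None:
        """Thread one sequence through the graph, incrementing edge weights."""
        prev = self.SOURCE
        for v in nodes:
            self.add_edge_weight(prev, v)
            prev = v
        self.add_edge_weight(prev, self.SINK)

    def topological_order(self) -> list[int]:
        """Kahn order over internal nodes (source and sink excluded)."""
        indeg = {
            v: sum(1 for p in self.preds[v] if p >= 2)
            for v in range(2, len(self.bases))
        }
        ready = sorted(v for v, d in indeg.items() if d == 0)
        order: list[int] = []
        while ready:
            v = ready.pop()
            order.append(v)
            for s in self.succs[v]:
                if s >= 2:
                    indeg[s] -= 1
                    if indeg[s] == 0:
                        ready.append(s)
        return order


def _align_to_graph(graph: _POAGraph, seq: str) -> list[tuple[Optional[int], Optional[int]]]:
    """Global alignment of ``seq`` to the graph.

    Returns a path of (node_id or None, seq_index or None): both set for
    a match/mismatch column, node-only for a node skipped by the
    sequence, index-only for a sequence base inserted between nodes.
    """
    order = graph.topological_order()
    n_rows = len(order)
    L = len(seq)
    row_of = {v: i for i, v in enumerate(order)}
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)

    # score[i+1] = DP row of node order[i]; score[0] = virtual source row
    score = np.empty((n_rows + 1, L + 1), dtype=np.float64)
    score[0] = _GAP * np.arange(L + 1)
    j_idx = np.arange(L + 1, dtype=np.float64)

    for i, v in enumerate(order):
        prows = [
            score[0] if p == graph.SOURCE else score[row_of[p] + 1]
            for p in graph.preds[v]
        ]
        pbest = np.max(prows, axis=0)
        sub = np.where(seq_arr == ord(graph.bases[v]), _MATCH, _MISMATCH)
        cand = np.full(L + 1, -np.inf)
        cand[1:] = pbest[:-1] + sub          # consume node + char
        np.maximum(cand, pbest + _GAP, out=cand)  # skip node
        # insertion (consume char only): prefix-max with linear gap
        shifted = cand - _GAP * j_idx
        np.maximum.accumulate(shifted, out=shifted)
        score[i + 1] = shifted + _GAP * j_idx

    # terminal: best over predecessors of sink at column L
    end_cands = [
        (score[0][L], graph.SOURCE) if p == graph.SOURCE
        else (score[row_of[p] + 1][L], p)
        for p in graph.preds[graph.SINK]
    ]
    best_score, v = max(end_cands, key=lambda t: (t[0], -t[1]))

    # backtrack by re-testing which move attains each cell
    path: list[tuple[Optional[int], Optional[int]]] = []
    j = L
    eps = 1e-9
    while not (v == graph.SOURCE and j == 0):
        if v == graph.SOURCE:
            path.append((None, j - 1))
            j -= 1
            continue
        cur = score[row_of[v] + 1][j]
        # insertion in current row
        if j > 0 and abs(score[row_of[v] + 1][j - 1] + _GAP - cur) < eps:
            path.append((None, j - 1))
            j -= 1
            continue
        moved = False
        for p in graph.preds[v]:
            prow = score[0] if p == graph.SOURCE else score[row_of[p] + 1]
            if j > 0:
                sub = _MATCH if seq[j - 1] == graph.bases[v] else _MISMATCH
                if abs(prow[j - 1] + sub - cur) < eps:
                    path.append((v, j - 1))
                    v, j = p, j - 1
                    moved = True
                    break
            if abs(prow[j] + _GAP - cur) < eps:
                path.append((v, None))
                v = p
                moved = True
                break
        if not moved:  # numeric safety net; should not happen
            raise RuntimeError("POA backtrack failed")
    path.reverse()
    return path


def _fuse(graph: _POAGraph, seq: str,
          path: list[tuple[Optional[int], Optional[int]]]) -> None:
    """Thread an aligned sequence into the graph, creating nodes as needed."""
    traversed: list[int] = []
    for node, j in path:
        if j is None:
            continue  # node skipped by this sequence
        base = seq[j]
        if node is not None and graph.bases[node] == base:
            traversed.append(node)
            continue
        target = None
        if node is not None:
            for m in graph.aligned[node]:
                if graph.bases[m] == base:
                    target = m
                    break
        if target is None:
            target = graph.add_node(base)
            if node is not None:
                group = graph.aligned[node] | {node}
                for m in group:
                    graph.aligned[m].add(target)
                graph.aligned[target] = group
        traversed.append(target)
    graph.add_path(traversed)


def _heaviest_bundle(graph: _POAGraph) -> str:
    """Max-weight source->sink traversal over per-node best incoming edges."""
    order = graph.topological_order()
    score: dict[int, float] = {graph.SOURCE: 0.0}
    best_pred: dict[int, int] = {}

    def pick(v: int) -> None:
        cands = []
        for p in graph.preds[v]:
            if p not in score:
                continue
            w = graph.edges[(p, v)]
            base_rank = -1 if p == graph.SOURCE else _BASE_ORDER.get(graph.bases[p], 5)
            cands.append((w, score[p], -base_rank, -p, p))
        w, s, _, _, p = max(cands)
        score[v] = w + s
        best_pred[v] = p

    for v in order:
        pick(v)
    pick(graph.SINK)

    out: list[str] = []
    v = best_pred[graph.SINK]
    while v != graph.SOURCE:
        out.append(graph.bases[v])
        v = best_pred[v]
    return "".join(reversed(out))


def poa_consensus(sequences: Sequence[str]) -> str:
    """Partial-order alignment consensus of one or more DNA sequences.

    A single sequence is returned unchanged; an empty input list is an
    error.  The result is deterministic for a given input order.
    """
    if len(sequences) == 0:
        raise ValueError("poa_consensus requires at least one sequence")
    sequences = [s.upper() for s in sequences]
    if len(sequences) == 1:
        return sequences[0]

    graph = _POAGraph()
    first = sequences[0]
    chain = [graph.add_node(b) for b in first]
    graph.add_path(chain)
    for seq in sequences[1:]:
        if not seq:
            graph.add_path([])
            continue
        path = _align_to_graph(graph, seq)
        _fuse(graph, seq, path)
    return _heaviest_bundle(graph)
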