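"""Max-product path inference through a layered weighted signalling network.

The optimal ligand-to-target route maximizes the product of edge weights over
paths of bounded length whose first hop is a ligand_receptor edge; found via
hop-bounded dynamic programming on edge costs -log(weight). Ties are broken
by fewer edges, then lexicographic node sequence, which also rules out
weight-1 cycles, so the returned path is simple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_model import SignallingNetwork, ValidationError


@dataclass
class SignallingPath:
    nodes: list  # ordered, ligand first, target last
    edge_weights: list
    score: float  # product of edge weights

    @property
    def n_edges(self) -> int:
        return len(self.edge_weights)


@dataclass
class NoPath:
    ligand: str
    target: str
    max_len: int
    reason: str = "no path within max_len"


def _adjacency(network: SignallingNetwork) -> dict:
    adj: dict = {}
    for row in network.data.itertuples(index=False):
        adj.setdefault(row.source, []).append((row.target, float(row.weight), row.layer))
    return adj


def infer_path(
    network: SignallingNetwork, ligand: str, target: str, max_len: int = 6
) -> SignallingPath | NoPath:
    """Best path from ligand to target with <= max_len edges, first edge in the
    ligand_receptor layer. Returns NoPath (not an exception) when unreachable."""
    adj = _adjacency(network)
    lr_edges = [e for e in adj.get(ligand, []) if e[2] == "ligand_receptor"]
    if not lr_edges:
        raise ValidationError(f"ligand {ligand!r} has no outgoing ligand_receptor edge")
    if target not in network.nodes:
        raise ValidationError(f"target {target!r} not present in network")
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")

    # label per (node, hop count): (cost, path tuple); labels kept per hop
    # level because the cheapest route to an intermediate node may spend hops
    # the remainder of the path then lacks. Lexicographic tuple comparison of
    # (cost, n_edges, path) implements the tie-breaking chain.
    level: dict = {}
    for nxt, w, _ in lr_edges:
        cand = (-math.log(w), (ligand, nxt))
        if nxt not in level or cand < level[nxt]:
            level[nxt] = cand

    best: dict = dict(level)
    for _ in range(max_len - 1):
        nxt_level: dict = {}
        for node, (cost, path) in level.items():
            for nxt, w, _ in adj.get(node, []):
                cand = (cost - math.log(w), path + (nxt,))
                if nxt not in nxt_level or cand < nxt_level[nxt]:
                    nxt_level[nxt] = cand
        for node, (cost, path) in nxt_level.items():
            cand = (cost, len(path) - 1, path)
            cur = best.get(node)
            cur_key = (cur[0], len(cur[1]) - 1, cur[1]) if cur else None
            if cur is None or cand < cur_key:
                best[node] = (cost, path)
        level = nxt_level
        if not level:
            break

    if target not in best:
        return NoPath(ligand=ligand, target=target, max_len=max_len)
    cost, path = best[target]
    weights = []
    for i, (a, b) in enumerate(zip(path, path[1:])):
        edges = adj[a]
        if i == 0:
            edges = [e for e in edges if e[2] == "ligand_receptor"]
        weights.append(max(wt for (t, wt, _) in edges if t == b))
    return SignallingPath(nodes=list(path), edge_weights=weights, score=math.exp(-cost))


def infer_paths_topk(
    network: SignallingNetwork, ligand: str, target: str, max_len: int = 6, k: int = 3
) -> list[SignallingPath]:
    """Top-k simple paths by weight product (exhaustive; intended for small nets)."""
    adj = _adjacency(network)
    if target not in network.nodes:
        raise ValidationError(f"target {target!r} not present in network")
    found: list[SignallingPath] = []

    def dfs(node, path, weights, score):
        if len(weights) > max_len:
            return
        if node == target and weights:
            found.append(SignallingPath(nodes=list(path), edge_weights=list(weights), score=score))
        if len(weights) == max_len:
            return
        for nxt, w, layer in adj.get(node, []):
            if nxt in path:
                continue
            first = not weights
            if first and layer != "ligand_receptor":
                continue
            path.append(nxt)
            weights.append(w)
            dfs(nxt, path, weights, score * w)
            path.pop()
            weights.pop()

    dfs(ligand, [ligand], [], 1.0)
    found.sort(key=lambda p: (-p.score, p.n_edges, tuple(p.nodes)))
    return found[:k]
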