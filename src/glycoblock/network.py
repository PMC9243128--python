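"""Relevance networks and circos-style correlation edges.

The relevance network follows the standard latent-component construction:
for a pair of blocks the similarity between variable p of block i and
variable q of block h is

    sim(p, q) = sum_d cor(x_p, z_d) * cor(x_q, z_d),

where z_d is the average of the two blocks' dimension-d component scores.
Edges with |sim| at or above a threshold (0.5 by default, a deliberately
interpretable cut) form a signed bipartite graph whose high-degree nodes
are the hub variables.  Circos-style edges are plain Spearman correlations
among selected variables, thresholded the same way, with within/between
block flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from glycoblock.errors import ComputationError, ValidationError
from glycoblock.sgcca import SgccaModel

__all__ = [
    "RelevanceNetwork",
    "similarity_matrix",
    "build_network",
    "circos_edges",
]


@dataclass
class RelevanceNetwork:
    """Thresholded signed bipartite graph over block variables."""

    nodes: tuple[tuple[str, str], ...]           # (variable id, block)
    edges: tuple[tuple[str, str, float], ...]    # (source, target, weight)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        ids = [v for v, _ in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate node ids in network")
        known = set(ids)
        for u, v, w in self.edges:
            if u == v:
                raise ValidationError(f"self-edge on {u!r}")
            if u not in known or v not in known:
                raise ValidationError(f"edge references unknown node: ({u}, {v})")
            if abs(w) < self.threshold:
                raise ValidationError(f"edge ({u}, {v}) below threshold {self.threshold}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def block_of(self, node: str) -> str:
        return dict(self.nodes)[node]

    def edge_records(self):
        blocks = dict(self.nodes)
        for u, v, w in self.edges:
            yield u, v, w, blocks[u], blocks[v]

    def degree_table(self) -> pd.DataFrame:
        g = self.to_graph()
        deg = dict(g.degree())
        try:
            eig = nx.eigenvector_centrality_numpy(g, weight=None) if g.number_of_edges() else {}
        except Exception:
            eig = {}
        rows = [{"node": v, "block": b, "degree": deg.get(v, 0),
                 "eigenvector_centrality": float(eig.get(v, 0.0))}
                for v, b in self.nodes]
        return pd.DataFrame(rows).sort_values(
            ["degree", "eigenvector_centrality"], ascending=False).reset_index(drop=True)

    def hubs(self, top: int = 3) -> list[str]:
        """Highest-degree nodes (connection count is the hub criterion)."""
        return self.degree_table()["node"].head(top).tolist()

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for v, b in self.nodes:
            g.add_node(v, block=b)
        for u, v, w in self.edges:
            g.add_edge(u, v, weight=float(w))
        return g

    @classmethod
    def from_graph(cls, g: nx.Graph, threshold: float = 0.0) -> "RelevanceNetwork":
        nodes = tuple((str(v), str(d.get("block", ""))) for v, d in g.nodes(data=True))
        edges = tuple((str(u), str(v), float(d["weight"])) for u, v, d in g.edges(data=True))
        return cls(nodes=nodes, edges=edges, threshold=threshold)


def similarity_matrix(model: SgccaModel, block_i: str, block_h: str,
                      n_dims_use: int = 1) -> pd.DataFrame:
    """Component-mediated variable similarity between two blocks.

    Correlations are computed against z_d, the mean of the two blocks'
    dimension-d training scores; entries are clipped to [-1, 1].
    """
    for b in (block_i, block_h):
        if b not in model.block_names:
            raise ValidationError(f"unknown block {b!r}")
    if model.train_blocks is None:
        raise ValidationError("similarity needs a model fitted with stored training blocks")
    if not 1 <= n_dims_use <= model.n_dims:
        raise ValidationError(f"n_dims_use must be in [1, {model.n_dims}]")
    Xi = model.train_blocks.blocks[block_i]
    Xh = model.train_blocks.blocks[block_h]
    sim = np.zeros((Xi.shape[1], Xh.shape[1]))
    for d in range(n_dims_use):
        z = 0.5 * (model.scores[block_i][:, d] + model.scores[block_h][:, d])
        if z.std() == 0:
            raise ComputationError(f"degenerate component {d + 1}: zero-variance scores")
        ci = _corr_with(Xi, z)
        ch = _corr_with(Xh, z)
        sim += np.outer(ci, ch)
    sim = np.clip(sim, -1.0, 1.0)
    return pd.DataFrame(sim, index=list(model.var_names[block_i]),
                        columns=list(model.var_names[block_h]))


def _corr_with(X: np.ndarray, z: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    zc = z - z.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (zc ** 2).sum())
    out = np.zeros(X.shape[1])
    nonzero = denom > 0
    out[nonzero] = (Xc.T @ zc)[nonzero] / denom[nonzero]
    return out


def build_network(similarities: pd.DataFrame | Mapping[tuple[str, str], pd.DataFrame],
                  threshold: float = 0.5,
                  blocks: tuple[str, str] = ("X", "Y")) -> RelevanceNetwork:
    """Keep edges with |similarity| >= threshold across block pairs.

    ``similarities`` is one DataFrame (rows = block_i variables, columns =
    block_h variables) or a mapping (block_i, block_h) -> DataFrame for a
    multi-block network.
    """
    if abs(threshold) > 1:
        # permitted: yields an empty network
        pass
    if isinstance(similarities, pd.DataFrame):
        similarities = {blocks: similarities}
    node_block: dict[str, str] = {}
    edges = []
    for (bi, bh), S in similarities.items():
        for v in S.index:
            node_block.setdefault(str(v), bi)
        for v in S.columns:
            node_block.setdefault(str(v), bh)
        vals = S.to_numpy(dtype=float)
        rows, cols = np.where(np.abs(vals) >= threshold)
        for r, c in zip(rows, cols):
            u, v = str(S.index[r]), str(S.columns[c])
            if u != v:
                edges.append((u, v, float(vals[r, c])))
    # deduplicate undirected edges
    seen = {}
    for u, v, w in edges:
        key = (min(u, v), max(u, v))
        seen.setdefault(key, (u, v, w))
    return RelevanceNetwork(nodes=tuple(node_block.items()),
                            edges=tuple(seen.values()), threshold=threshold)


def circos_edges(frames: Mapping[str, pd.DataFrame],
                 selected: Mapping[str, Sequence[str]] | None = None,
                 threshold: float = 0.5, method: str = "spearman",
                 groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise correlation edges among selected variables across blocks.

    Returns a table (source, target, weight, source_block, target_block,
    between_blocks) of correlations with |r| >= threshold; when per-sample
    ``groups`` are supplied each variable also gets a ``higher_in``
    annotation (the class with the larger mean).
    """
    cols: list[tuple[str, str]] = []
    data = []
    for b, df in frames.items():
        keep = list(selected.get(b, df.columns)) if selected else list(df.columns)
        missing = [v for v in keep if v not in df.columns]
        if missing:
            raise ValidationError(f"block {b!r} lacks selected variables: {missing}")
        for v in keep:
            col = df[v].to_numpy(dtype=float)
            if col.std() == 0:
                raise ComputationError(f"constant variable {v!r} in block {b!r}")
            cols.append((b, v))
            data.append(col)
    mat = np.column_stack(data)
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 0, mat)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.corrcoef(mat, rowvar=False)

    higher: dict[str, str] = {}
    if groups is not None:
        groups_arr = np.asarray(list(groups), dtype=object)
        for (b, v), col in zip(cols, data):
            means = {g: float(col[groups_arr == g].mean()) for g in pd.unique(groups_arr)}
            higher[v] = max(means, key=means.get)

    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            w = float(r[i, j])
            if abs(w) >= threshold:
                bi, vi = cols[i]
                bj, vj = cols[j]
                row = {"source": vi, "target": vj, "weight": w,
                       "source_block": bi, "target_block": bj,
                       "between_blocks": bi != bj}
                if groups is not None:
                    row["source_higher_in"] = higher[vi]
                    row["target_higher_in"] = higher[vj]
                rows.append(row)
    columns = ["source", "target", "weight", "source_block", "target_block",
               "between_blocks"]
    if groups is not None:
        columns += ["source_higher_in", "target_higher_in"]
    return pd.DataFrame(rows, columns=columns)
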