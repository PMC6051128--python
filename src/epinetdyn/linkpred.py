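"""Link-prediction similarity indices and the sampled-AUC evaluation harness.

Four local similarity indices on a simple undirected graph, with phi(x) the
neighbour set and k(x) the degree of node x:

* CN (common neighbours):        S_xy = |phi(x) ∩ phi(y)|
* RA (resource allocation):      S_xy = sum_{z in phi(x) ∩ phi(y)} 1 / k(z)
* AA (Adamic–Adar):              S_xy = sum_{z in phi(x) ∩ phi(y)} 1 / ln k(z)
* Sorenson:                      S_xy = 2 |phi(x) ∩ phi(y)| / (k(x) + k(y))

AA uses the natural logarithm: the worked value 1/log 2 + 1/log 2 = 2.8854
equals 2/ln 2, which pins the base. A common neighbour of two distinct nodes
necessarily has degree >= 2, so 1/ln k(z) is always finite; degree-1 nodes
are guarded out anyway.

Evaluation: the edge set is split uniformly at random into a train set E_t
and a probe set E_p; scores are computed on the train graph only, and the
sampled AUC is (n' + 0.5 n'') / n over n random (probe edge, non-edge)
comparisons, where n' counts strict wins for the probe edge and n'' ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "common_neighbors",
    "resource_allocation",
    "adamic_adar",
    "sorenson",
    "similarity_matrix",
    "EdgeSplit",
    "split_edges",
    "auc_score",
    "benchmark",
    "read_edge_list",
    "write_edge_list",
    "graph_from_adjacency",
]

INDEX_NAMES = ("CN", "RA", "AA", "Sorenson")


def _check_pair(g: nx.Graph, x, y) -> None:
    if x == y:
        raise ValueError(f"similarity undefined for identical nodes ({x})")
    for v in (x, y):
        if v not in g:
            raise KeyError(f"node {v!r} not in graph")


def common_neighbors(g: nx.Graph, x, y) -> int:
    """Number of shared neighbours of x and y."""
    _check_pair(g, x, y)
    return len(set(g[x]) & set(g[y]))


def resource_allocation(g: nx.Graph, x, y) -> float:
    """Degree-penalised common-neighbour sum, 1/k(z) per shared neighbour z."""
    _check_pair(g, x, y)
    return float(sum(1.0 / g.degree(z) for z in set(g[x]) & set(g[y])))


def adamic_adar(g: nx.Graph, x, y) -> float:
    """Log-degree-penalised sum, 1/ln k(z) per shared neighbour z."""
    _check_pair(g, x, y)
    total = 0.0
    for z in set(g[x]) & set(g[y]):
        kz = g.degree(z)
        if kz < 2:  # impossible for a common neighbour of distinct nodes
            raise RuntimeError(
                f"common neighbour {z!r} has degree {kz} < 2; graph is not "
                "simple"
            )
        total += 1.0 / np.log(kz)
    return float(total)


def sorenson(g: nx.Graph, x, y) -> float:
    """Shared-neighbour count normalised by the endpoints' degree sum.

    Returns 0.0 if both endpoints are isolated (undefined ratio).
    """
    _check_pair(g, x, y)
    ksum = g.degree(x) + g.degree(y)
    if ksum == 0:
        return 0.0
    return 2.0 * len(set(g[x]) & set(g[y])) / ksum


def weighted_resource_allocation(g: nx.Graph, x, y) -> float:
    """Weighted RA variant: sum over z of w(x,z) * w(z,y) / strength(z).

    Uses edge ``weight`` attributes (missing weights count as 1). Not the
    default anywhere — the standard indices operate on binary topology —
    but available for weighted PLV networks without thresholding.
    """
    _check_pair(g, x, y)
    total = 0.0
    for z in set(g[x]) & set(g[y]):
        sz = sum(d.get("weight", 1.0) for d in g[z].values())
        total += (g[x][z].get("weight", 1.0) * g[z][y].get("weight", 1.0)
                  / sz)
    return float(total)


_PAIR_FUNCS = {
    "CN": common_neighbors,
    "RA": resource_allocation,
    "AA": adamic_adar,
    "Sorenson": sorenson,
}


def similarity_matrix(
    g: nx.Graph,
    index_name: str,
    nodes: Sequence | None = None,
    weighted: bool = False,
) -> tuple[np.ndarray, list]:
    """Dense N×N similarity matrix for one index (diagonal zero).

    Computed from the graph's adjacency via matrix products; ``nodes`` fixes
    the row/column order (default: sorted node list). Returns the matrix and
    the node order. ``weighted=True`` is accepted only for RA and switches to
    the edge-weighted variant of :func:`weighted_resource_allocation`.
    """
    if index_name not in _PAIR_FUNCS:
        raise ValueError(
            f"unknown index {index_name!r}; choose from {INDEX_NAMES}"
        )
    node_list = list(nodes) if nodes is not None else sorted(g.nodes())
    if weighted:
        if index_name != "RA":
            raise ValueError("weighted similarity is defined for RA only")
        w = nx.to_numpy_array(g, nodelist=node_list, weight="weight")
        s = w.sum(axis=1)
        inv = np.where(s > 0, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        out = (w * inv[None, :]) @ w
        np.fill_diagonal(out, 0.0)
        return out, node_list
    a = nx.to_numpy_array(g, nodelist=node_list, weight=None)
    k = a.sum(axis=1)

    if index_name == "CN":
        s = a @ a
    elif index_name == "RA":
        inv = np.where(k > 0, 1.0 / np.where(k > 0, k, 1.0), 0.0)
        s = (a * inv[None, :]) @ a
    elif index_name == "AA":
        inv = np.where(k >= 2, 1.0 / np.log(np.where(k >= 2, k, 2.0)), 0.0)
        s = (a * inv[None, :]) @ a
    else:  # Sorenson
        cn = a @ a
        ksum = k[:, None] + k[None, :]
        s = np.where(ksum > 0, 2.0 * cn / np.where(ksum > 0, ksum, 1.0), 0.0)
    np.fill_diagonal(s, 0.0)
    return s, node_list


# ---------------------------------------------------------------------------
# Train/probe splits and AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeSplit:
    """Disjoint partition of a graph's edges into train and probe sets."""

    train: tuple[tuple, ...]
    probe: tuple[tuple, ...]
    train_ratio: float


def split_edges(g: nx.Graph, train_ratio: float, seed: int) -> EdgeSplit:
    """Uniform random edge partition; same seed gives the same split."""
    if not 0.0 < train_ratio < 1.0:
        raise ValueError(f"train_ratio must be in (0, 1), got {train_ratio}")
    edges = [tuple(sorted(e)) for e in g.edges()]
    edges.sort()
    m = len(edges)
    if m < 2:
        raise ValueError("graph must have at least 2 edges to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    n_train = int(round(train_ratio * m))
    n_train = min(max(n_train, 1), m - 1)
    train = tuple(edges[i] for i in sorted(order[:n_train]))
    probe = tuple(edges[i] for i in sorted(order[n_train:]))
    return EdgeSplit(train=train, probe=probe, train_ratio=train_ratio)


def _train_graph(g: nx.Graph, split: EdgeSplit) -> nx.Graph:
    t = nx.Graph()
    t.add_nodes_from(g.nodes())
    t.add_edges_from(split.train)
    return t


def _non_edges(g: nx.Graph, node_list: list) -> np.ndarray:
    """Index pairs (i < j) absent from g, in node_list coordinates."""
    n = len(node_list)
    a = nx.to_numpy_array(g, nodelist=node_list, weight=None).astype(bool)
    iu, ju = np.triu_indices(n, k=1)
    keep = ~a[iu, ju]
    return np.stack([iu[keep], ju[keep]], axis=1)


def auc_score(
    g: nx.Graph,
    split: EdgeSplit,
    index_name: str,
    n_comparisons: int | None = None,
    seed: int | None = None,
    score_transform=None,
) -> float:
    """Sampled AUC of one index on one edge split.

    Scores come from the train graph only; each comparison draws one probe
    edge and one non-edge (a pair absent from the full graph) uniformly with
    replacement. Ties (exact float equality) earn half credit.
    ``score_transform``, if given, is applied elementwise to the score matrix
    before comparison (a strictly decreasing transform flips the AUC to its
    complement).
    """
    if not split.probe:
        raise ValueError("probe set is empty")
    node_list = sorted(g.nodes())
    pos = {v: i for i, v in enumerate(node_list)}
    nonedges = _non_edges(g, node_list)
    if len(nonedges) == 0:
        raise ValueError("graph is complete: no non-edges to compare against")

    s, _ = similarity_matrix(_train_graph(g, split), index_name, node_list)
    if score_transform is not None:
        s = score_transform(s)
    probe_idx = np.array([[pos[u], pos[v]] for u, v in split.probe])
    n_max = len(split.probe) * len(nonedges)
    n = n_comparisons if n_comparisons is not None else min(10_000, n_max)
    rng = np.random.default_rng(seed)
    pi = rng.integers(len(probe_idx), size=n)
    ni = rng.integers(len(nonedges), size=n)
    ps = s[probe_idx[pi, 0], probe_idx[pi, 1]]
    ns = s[nonedges[ni, 0], nonedges[ni, 1]]
    n_win = int((ps > ns).sum())
    n_tie = int((ps == ns).sum())
    return (n_win + 0.5 * n_tie) / n


def benchmark(
    graphs: dict[str, nx.Graph],
    indices: Sequence[str] = INDEX_NAMES,
    ratios: Sequence[float] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
    n_repetitions: int = 100,
    n_comparisons: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± sd sampled AUC per (network, index, train ratio) cell.

    Each repetition draws a fresh edge split (shared across indices within a
    repetition, so the indices see identical splits); 100 repetitions by
    default. Train ratios above 0.95 are rejected.
    """
    for r in ratios:
        if not 0.0 < r <= 0.95:
            raise ValueError(f"train ratio {r} outside (0, 0.95]")
    rows = []
    ss = np.random.SeedSequence(seed)
    for gname, g in sorted(graphs.items()):
        for ratio in ratios:
            scores: dict[str, list[float]] = {ix: [] for ix in indices}
            n_used = None
            for rep_seed in ss.spawn(n_repetitions):
                child = rep_seed.generate_state(2) % (2**31)
                split = split_edges(g, ratio, seed=int(child[0]))
                for ix in indices:
                    scores[ix].append(
                        auc_score(g, split, ix, n_comparisons,
                                  seed=int(child[1]))
                    )
                if n_used is None:
                    nonedges = len(_non_edges(g, sorted(g.nodes())))
                    n_max = len(split.probe) * nonedges
                    n_used = (
                        n_comparisons if n_comparisons is not None
                        else min(10_000, n_max)
                    )
            for ix in indices:
                arr = np.asarray(scores[ix])
                rows.append({
                    "network": gname,
                    "index": ix,
                    "train_ratio": ratio,
                    "mean_auc": float(arr.mean()),
                    "sd_auc": float(arr.std(ddof=1)),
                    "n_reps": n_repetitions,
                    "n_comparisons": n_used,
                    "seed": seed,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a whitespace-delimited edge list ``u v [weight]`` (1-based labels,
    '#' comments); self-loops are dropped."""
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"malformed edge-list line: {line!r}")
        u, v = int(parts[0]), int(parts[1])
        if u == v:
            continue
        if len(parts) >= 3:
            g.add_edge(u, v, weight=float(parts[2]))
        else:
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """Write ``u v [weight]`` lines, sorted, 1-based labels as given."""
    lines = []
    for u, v, d in sorted(
        (min(u, v), max(u, v), d) for u, v, d in g.edges(data=True)
    ):
        w = d.get("weight") if isinstance(d, dict) else None
        lines.append(f"{u} {v} {w:.10g}" if w is not None else f"{u} {v}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def graph_from_adjacency(
    adjacency: np.ndarray, node_labels: Sequence[int] | None = None
) -> nx.Graph:
    """Graph from a symmetric nonnegative adjacency; positive entries become
    weighted edges. Default node labels are 1..N."""
    w = np.asarray(adjacency, dtype=float)
    n = w.shape[0]
    labels = list(node_labels) if node_labels is not None else list(
        range(1, n + 1)
    )
    g = nx.Graph()
    g.add_nodes_from(labels)
    iu, ju = np.triu_indices(n, k=1)
    for i, j in zip(iu, ju):
        if w[i, j] > 0:
            g.add_edge(labels[i], labels[j], weight=float(w[i, j]))
    return g
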