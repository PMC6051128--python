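"""Seizure tracking via node sequences from link-prediction similarity.

For each analysis window, every node is assigned its highest-similarity
partner (per-row argmax of the similarity matrix, self-similarity excluded);
the resulting length-N integer vector is the window's *node sequence*.
Sequence change over time is measured by cosine similarity and Euclidean
distance between sequence vectors, either between consecutive windows or
between all window pairs of two conditions.

Because intrafocus sites carry the lowest node labels (1..3 of 6 by
convention), the *node index summation* — the plain sum of a sequence — is a
focus-dominance score: lower values mean the network organises around the
epileptogenic focus, higher values mean more extrafocus involvement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity import WeightedNetworkSeries, binarize
from .linkpred import graph_from_adjacency, similarity_matrix

__all__ = [
    "node_sequence",
    "node_sequence_global_topk",
    "sequences_from_series",
    "cosine_similarity",
    "euclidean_distance",
    "variation_series",
    "cross_condition_variation",
    "node_index_summation",
]


def node_sequence(
    sim: np.ndarray, node_labels: Sequence[int] | None = None
) -> np.ndarray:
    """Highest-similarity partner of each node (1-based labels).

    partner(i) = argmax_{j != i} S_ij, ties broken toward the smallest node
    label; an all-zero row defaults to the smallest label != i (degenerate
    rows are tolerated, the choice is the same tie rule). Deterministic, and
    invariant to any strictly increasing transform of the scores.
    """
    s = np.asarray(sim, dtype=float)
    n = s.shape[0]
    if s.ndim != 2 or s.shape[1] != n:
        raise ValueError("similarity matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 nodes")
    labels = np.asarray(
        node_labels if node_labels is not None else range(1, n + 1)
    )
    masked = s.copy()
    np.fill_diagonal(masked, -np.inf)
    return labels[np.argmax(masked, axis=1)]


def node_sequence_global_topk(
    sim: np.ndarray, k: int, node_labels: Sequence[int] | None = None
) -> np.ndarray:
    """Alternative construction: the nodes touched by the k globally largest
    off-diagonal entries, largest first (each entry contributes its row node).
    Provided for comparison; the per-row argmax form is the default."""
    s = np.asarray(sim, dtype=float)
    n = s.shape[0]
    labels = np.asarray(
        node_labels if node_labels is not None else range(1, n + 1)
    )
    masked = s.copy()
    np.fill_diagonal(masked, -np.inf)
    flat = np.argsort(masked, axis=None)[::-1][:k]
    return labels[flat // n]


def sequences_from_series(
    series: WeightedNetworkSeries,
    index_name: str = "RA",
    threshold: float | None = 0.3,
) -> np.ndarray:
    """Node sequence per window of a network series.

    Each window's adjacency is binarized at ``threshold`` (``None`` keeps all
    nonzero weights as edges), the similarity matrix of ``index_name``
    (default RA) is computed on the full window graph — no edge split — and
    its per-row argmax gives the sequence. Returns (n_windows, N) ints.
    """
    work = binarize(series, threshold) if threshold is not None else series
    seqs = np.empty((work.n_windows, len(work.node_labels)), dtype=int)
    for w in range(work.n_windows):
        g = graph_from_adjacency(work.adjacency[w], work.node_labels)
        s, order = similarity_matrix(g, index_name, nodes=work.node_labels)
        seqs[w] = node_sequence(s, order)
    return seqs


def cosine_similarity(a: Sequence[int], b: Sequence[int]) -> float:
    """Cosine of the angle between two sequences as integer vectors.

    On positive integer sequences the value lies in (0, 1]; note it is
    scale-invariant, so e.g. the all-ones and all-sixes sequences compare
    as identical.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("sequences must have equal length")
    return float(av @ bv / (np.linalg.norm(av) * np.linalg.norm(bv)))


def euclidean_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Euclidean distance between two sequences as integer vectors."""
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape:
        raise ValueError("sequences must have equal length")
    return float(np.linalg.norm(av - bv))


def variation_series(
    sequences: np.ndarray,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Consecutive-window sequence variation.

    One row per window from the second onward: cosine similarity and
    Euclidean distance to the previous window's sequence, tagged with the
    window's condition when given.
    """
    seqs = np.asarray(sequences)
    if seqs.shape[0] < 2:
        raise ValueError("need at least 2 windows")
    rows = []
    for w in range(1, seqs.shape[0]):
        rows.append({
            "window": w,
            "condition": conditions[w] if conditions is not None else "unlabeled",
            "cosine_prev": cosine_similarity(seqs[w - 1], seqs[w]),
            "euclid_prev": euclidean_distance(seqs[w - 1], seqs[w]),
        })
    return pd.DataFrame(rows)


def cross_condition_variation(
    sequences: np.ndarray,
    conditions: Sequence[str],
    cond_a: str,
    cond_b: str,
) -> pd.DataFrame:
    """All-pairs sequence variation between two conditions.

    Returns the full |windows_a| × |windows_b| distribution, one row per
    window pair, rather than any scalar aggregate.
    """
    seqs = np.asarray(sequences)
    conds = np.asarray(conditions)
    idx_a = np.nonzero(conds == cond_a)[0]
    idx_b = np.nonzero(conds == cond_b)[0]
    rows = []
    for wa in idx_a:
        for wb in idx_b:
            rows.append({
                "cond_a": cond_a,
                "cond_b": cond_b,
                "window_a": int(wa),
                "window_b": int(wb),
                "cosine": cosine_similarity(seqs[wa], seqs[wb]),
                "euclid": euclidean_distance(seqs[wa], seqs[wb]),
            })
    return pd.DataFrame(
        rows,
        columns=["cond_a", "cond_b", "window_a", "window_b", "cosine",
                 "euclid"],
    )


def node_index_summation(
    sequences: np.ndarray,
    conditions: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum of the node sequence per window, summarised per condition.

    For N nodes the sum lies in [N, N*N]; lower values indicate
    intrafocus-dominated organisation. Returns (per-window frame with
    columns window/condition/index_sum, per-condition frame with
    mean/sd/n_windows).
    """
    seqs = np.asarray(sequences)
    sums = seqs.sum(axis=1)
    conds = (
        list(conditions) if conditions is not None
        else ["unlabeled"] * len(sums)
    )
    per_window = pd.DataFrame({
        "window": np.arange(len(sums)),
        "condition": conds,
        "index_sum": sums,
    })
    per_condition = (
        per_window.groupby("condition", sort=True)["index_sum"]
        .agg(mean="mean", sd="std", n_windows="count")
        .reset_index()
    )
    return per_window, per_condition
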