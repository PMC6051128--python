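"""Time-varying phase-locking-value (PLV) networks per subband.

The PLV between channels i and j over a window of T samples is the modulus of
the time-averaged unit phasor of their instantaneous phase difference,

    PLV_ij = | (1/T) sum_t exp(i (phi_i(t) - phi_j(t))) |,

with instantaneous phase taken from the analytic signal (Hilbert transform)
of the band-filtered trace. PLV is 1 for perfect phase locking and near 0
for independent phases; it is invariant to per-channel amplitude scaling and
to a global phase offset.

Windows are non-overlapping and frequency dependent: 6 cycles of the band's
lower edge frequency by default, the minimum commonly used for a stable PLV
estimate. Each window's adjacency is a symmetric N×N matrix with the diagonal
forced to zero (self-connections are eliminated). Weighted networks can be
binarized at a threshold (default 0.3) to keep only the strong ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _signal
from scipy.sparse.csgraph import shortest_path

from .preprocess import (
    BandDefinition,
    ConditionSegmentation,
    Recording,
)

logger = logging.getLogger("epinetdyn")

__all__ = [
    "WeightedNetworkSeries",
    "BinaryNetworkSeries",
    "instantaneous_phase",
    "plv_matrix",
    "window_plan",
    "build_network_series",
    "binarize",
    "weighted_metrics",
]


@dataclass
class WeightedNetworkSeries:
    """Per-band sequence of windowed PLV adjacency matrices.

    ``adjacency`` has shape (n_windows, N, N); each slice is symmetric with
    zero diagonal and entries in [0, 1]. ``conditions`` labels each window
    as preictal / ictal / postictal / unlabeled by its midpoint.
    """

    band: BandDefinition
    windows: list[tuple[int, int]]
    adjacency: np.ndarray
    node_labels: list[int]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n_w = len(self.windows)
        if self.adjacency.shape[0] != n_w or len(self.conditions) != n_w:
            raise ValueError("windows/adjacency/conditions length mismatch")

    @property
    def n_windows(self) -> int:
        return len(self.windows)


@dataclass
class BinaryNetworkSeries(WeightedNetworkSeries):
    threshold: float = 0.3


def instantaneous_phase(band_signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-pi, pi]) of each channel.

    Uses the analytic signal; valid only on band-limited input. An all-zero
    channel has no defined phase and raises.
    """
    x = np.asarray(band_signal, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    dead = np.all(x == 0.0, axis=-1)
    if dead.any():
        raise ValueError(
            f"channel(s) {np.nonzero(dead)[0].tolist()} are all-zero; "
            "phase undefined"
        )
    return np.angle(_signal.hilbert(x, axis=-1))


def plv_matrix(phases: np.ndarray, window: tuple[int, int] | None = None
               ) -> np.ndarray:
    """Pairwise PLV over one window of a channels × samples phase array.

    Symmetric, entries in [0, 1], diagonal forced to 0.
    """
    ph = np.asarray(phases, dtype=float)
    if window is not None:
        start, end = window
        ph = ph[:, start:end]
    t = ph.shape[-1]
    if t < 2:
        raise ValueError("window must contain at least 2 samples")
    z = np.exp(1j * ph)
    plv = np.abs(z @ z.conj().T) / t
    np.clip(plv, 0.0, 1.0, out=plv)
    np.fill_diagonal(plv, 0.0)
    return plv


def window_plan(
    band: BandDefinition,
    fs: float,
    n_samples: int,
    n_cycles: float = 6.0,
) -> list[tuple[int, int]]:
    """Non-overlapping contiguous windows of ``n_cycles`` of the band's lower
    edge frequency; the trailing partial window is dropped."""
    length = int(np.ceil(n_cycles * fs / band.low))
    if n_samples < length:
        raise ValueError(
            f"record of {n_samples} samples shorter than one {band.name} "
            f"window ({length} samples)"
        )
    n_win = n_samples // length
    return [(k * length, (k + 1) * length) for k in range(n_win)]


def _window_valid(mask: np.ndarray | None, window: tuple[int, int]) -> bool:
    if mask is None:
        return True
    start, end = window
    return bool(mask[:, start:end].all())


def build_network_series(
    banded: Mapping[str, Recording],
    segmentation: ConditionSegmentation | None = None,
    bands: Sequence[BandDefinition] | None = None,
    n_cycles: float = 6.0,
) -> dict[str, WeightedNetworkSeries]:
    """PLV network series for each band-filtered recording.

    Windows overlapping artifact-invalid samples (on any channel) are skipped
    with a log entry; each kept window is tagged with the condition at its
    midpoint.
    """
    from .preprocess import CANONICAL_BANDS

    band_defs = {b.name: b for b in (bands or CANONICAL_BANDS)}
    out: dict[str, WeightedNetworkSeries] = {}
    for name, rec in banded.items():
        if name not in band_defs:
            raise KeyError(f"no BandDefinition for band {name!r}")
        band = band_defs[name]
        plan = window_plan(band, rec.fs, rec.n_samples, n_cycles)
        phases = instantaneous_phase(rec.data)
        kept: list[tuple[int, int]] = []
        mats: list[np.ndarray] = []
        conds: list[str] = []
        n_skipped = 0
        for win in plan:
            if not _window_valid(rec.valid_mask, win):
                n_skipped += 1
                logger.info(
                    "band %s: skipping window [%d, %d) (artifact)",
                    name, win[0], win[1],
                )
                continue
            kept.append(win)
            mats.append(plv_matrix(phases, win))
            mid = (win[0] + win[1]) // 2
            conds.append(
                segmentation.condition_at(mid) if segmentation else "unlabeled"
            )
        if n_skipped:
            logger.info("band %s: %d window(s) skipped", name, n_skipped)
        adjacency = (
            np.stack(mats)
            if mats
            else np.empty((0, rec.n_channels, rec.n_channels))
        )
        out[name] = WeightedNetworkSeries(
            band=band,
            windows=kept,
            adjacency=adjacency,
            node_labels=list(range(1, rec.n_channels + 1)),
            conditions=conds,
        )
    return out


def binarize(
    series: WeightedNetworkSeries, threshold: float = 0.3
) -> BinaryNetworkSeries:
    """Keep edges with weight strictly greater than ``threshold``.

    Ties at exactly the threshold are excluded (strict >); node set
    unchanged.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")
    return BinaryNetworkSeries(
        band=series.band,
        windows=list(series.windows),
        adjacency=(series.adjacency > threshold).astype(float),
        node_labels=list(series.node_labels),
        conditions=list(series.conditions),
        threshold=threshold,
    )


def weighted_metrics(adjacency: np.ndarray) -> dict:
    """Node strength, weighted clustering and characteristic path length.

    * strength_i = sum_j w_ij
    * weighted clustering: geometric-mean (Onnela) form
      ``C_i = sum_{j,h} (w_ij w_ih w_jh)^{1/3} / (k_i (k_i - 1))`` with PLV
      weights already bounded by 1 (no renormalisation by the observed max)
    * characteristic path length: shortest paths with edge distance 1/w,
      averaged over connected node pairs; ``disconnected`` flags missing
      pairs.
    """
    w = np.asarray(adjacency, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("adjacency must be square")
    if (w < 0).any() or not np.allclose(w, w.T):
        raise ValueError("adjacency must be symmetric and nonnegative")
    if np.diagonal(w).any():
        raise ValueError("adjacency diagonal must be zero")

    n = w.shape[0]
    strength = w.sum(axis=1)

    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    w3 = np.cbrt(w)
    triples = np.diagonal(w3 @ w3 @ w3)  # 2x count of weighted triangles
    denom = k * (k - 1)
    clustering = np.where(denom > 0, triples / np.where(denom > 0, denom, 1), 0.0)

    with np.errstate(divide="ignore"):
        dist = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(dist, 0.0)
    sp = shortest_path(dist, method="D", directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    disconnected = bool((~np.isfinite(sp) & off).any())
    path_length = float(sp[finite].mean()) if finite.any() else np.nan
    return {
        "strength": strength,
        "clustering": clustering,
        "path_length": path_length,
        "disconnected": disconnected,
    }
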