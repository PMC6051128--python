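"""Synthetic inputs: a worked-example toy graph, random benchmark graphs, and
coupled phase-oscillator EEG with a controllable hypersynchronous (ictal) epoch.

The EEG simulator is a phase-level model: each channel carries one
band-limited oscillation per requested band, with an intrinsic phase that
diffuses and drifts independently of the other channels, plus a shared driver
phase per band. A coupling coefficient ``c`` blends each channel's phase
toward the driver, ``phi = psi + (1 - c) * (theta - psi)``, so ``c = 1`` means
perfect phase locking and ``c = 0`` means fully independent channels. During
ictal epochs the intrafocus channels (the first three by convention) are
coupled at ``ictal_coupling``; everywhere else the coupling is
``base_coupling``. Only phase-synchrony structure is modelled — no spike or
spike-wave morphology.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .preprocess import Recording, INTRAFOCUS, EXTRAFOCUS

__all__ = [
    "TOY_EDGES",
    "make_toy_network",
    "generate_random_graph",
    "SimulationConfig",
    "simulate_seizure_eeg",
]

#: Edge set of the six-node worked-example network: node 2 is the hub
#: (degree 4), nodes 2 and 5 share the two common neighbours {1, 4}.
TOY_EDGES = frozenset(
    frozenset(e) for e in [(1, 2), (1, 5), (2, 4), (4, 5), (2, 3), (2, 6)]
)


def make_toy_network() -> nx.Graph:
    """Return the six-node worked-example graph.

    Nodes are labelled 1..6; degrees are (2, 4, 1, 2, 2, 1). On this graph
    the similarity indices take the hand-checkable values CN(2,5)=2,
    RA(2,5)=1, RA(3,6)=1/4, AA(2,5)=2/ln 2, Sorenson(2,5)=2/3.
    """
    g = nx.Graph()
    g.add_nodes_from(range(1, 7))
    g.add_edges_from(tuple(sorted(e)) for e in TOY_EDGES)
    return g


def generate_random_graph(
    model: str,
    n_nodes: int,
    target_mean_degree: float,
    seed: int,
) -> nx.Graph:
    """Generate a connected simple undirected graph with 1-based node labels.

    Parameters
    ----------
    model
        One of ``"scale_free"`` (Barabási–Albert), ``"small_world"``
        (connected Watts–Strogatz, rewiring p=0.1) or ``"erdos_renyi"``.
    n_nodes
        Number of nodes (>= 4).
    target_mean_degree
        Desired mean degree; the realised mean degree is within 20% of it.
    seed
        RNG seed; same seed gives the same graph.
    """
    if n_nodes < 4:
        raise ValueError(f"n_nodes must be >= 4, got {n_nodes}")
    if not 0 < target_mean_degree < n_nodes - 1 + 1e-9:
        raise ValueError(
            f"target_mean_degree {target_mean_degree} unreachable on "
            f"{n_nodes} nodes (must be in (0, n_nodes - 1])"
        )

    if model == "small_world":
        k = max(2, 2 * int(round(target_mean_degree / 2)))
        if k >= n_nodes:
            raise ValueError("target_mean_degree too large for small_world")
        g = nx.connected_watts_strogatz_graph(n_nodes, k, p=0.1, seed=seed)
    elif model == "scale_free":
        m = max(1, int(round(target_mean_degree / 2)))
        if m >= n_nodes:
            raise ValueError("target_mean_degree too large for scale_free")
        g = nx.barabasi_albert_graph(n_nodes, m, seed=seed)
    elif model == "erdos_renyi":
        p = min(1.0, target_mean_degree / (n_nodes - 1))
        rng = np.random.default_rng(seed)
        for _ in range(500):
            g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
            realized = 2 * g.number_of_edges() / n_nodes
            if nx.is_connected(g) and (
                abs(realized - target_mean_degree)
                <= 0.2 * target_mean_degree
            ):
                break
        else:
            raise ValueError(
                "could not draw a connected Erdős–Rényi graph near the "
                "target mean degree; raise target_mean_degree"
            )
    else:
        raise ValueError(f"unknown model {model!r}")

    realized = 2 * g.number_of_edges() / n_nodes
    if abs(realized - target_mean_degree) > 0.2 * target_mean_degree:
        raise ValueError(
            f"{model}: realised mean degree {realized:.2f} misses target "
            f"{target_mean_degree} by more than 20%"
        )
    return nx.relabel_nodes(g, {i: i + 1 for i in range(n_nodes)})


# ---------------------------------------------------------------------------
# Coupled-oscillator EEG
# ---------------------------------------------------------------------------

#: Canonical carriers: one oscillation per clinical band.
DEFAULT_BAND_TARGETS: tuple[tuple[float, float], ...] = (
    (0.5, 4.0),
    (4.0, 8.0),
    (8.0, 13.0),
    (13.0, 30.0),
    (30.0, 45.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the coupled phase-oscillator EEG simulator.

    ``base_coupling``/``ictal_coupling`` are dimensionless in [0, 1];
    ``amplitude_uV`` is the per-band carrier amplitude; ``noise_sd`` the
    additive white-noise standard deviation (µV). ``linewidth_frac`` sets the
    per-band phase-diffusion rate so that each oscillation's spectral
    linewidth is that fraction of the band width; ``freq_jitter_frac``
    controls how far each channel's intrinsic frequency may sit from the band
    centre (as a fraction of half the band width).
    """

    n_channels: int = 6
    fs: float = 256.0
    base_coupling: float = 0.2
    ictal_coupling: float = 0.9
    band_targets: tuple[tuple[float, float], ...] = DEFAULT_BAND_TARGETS
    amplitude_uV: float = 40.0
    noise_sd: float = 5.0
    linewidth_frac: float = 0.25
    freq_jitter_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_coupling <= self.ictal_coupling <= 1.0:
            raise ValueError(
                "require 0 <= base_coupling <= ictal_coupling <= 1, got "
                f"{self.base_coupling}, {self.ictal_coupling}"
            )
        highest = max(hi for _, hi in self.band_targets)
        if self.fs <= 2.0 * highest:
            raise ValueError(
                f"fs={self.fs} Hz too low for band edge {highest} Hz "
                "(need fs > 2 * highest band edge)"
            )


DEFAULT_SEGMENT_PLAN: tuple[tuple[str, float], ...] = (
    ("preictal", 200.0),
    ("ictal", 60.0),
    ("postictal", 200.0),
)


def simulate_seizure_eeg(
    config: SimulationConfig,
    segment_plan: Sequence[tuple[str, float]] = DEFAULT_SEGMENT_PLAN,
) -> Recording:
    """Simulate a multichannel recording with hypersynchronous ictal epochs.

    ``segment_plan`` is an ordered list of ``(label, duration_s)`` with labels
    in {preictal, ictal, postictal}; it must contain at least one ictal
    segment. During ictal segments the intrafocus channels (1–3) are coupled
    at ``ictal_coupling``; all other channel/segment combinations use
    ``base_coupling``. Seizure onset/offset sample indices are recorded
    exactly in the returned :class:`Recording`.
    """
    if not segment_plan:
        raise ValueError("segment_plan must be nonempty")
    labels = {lab for lab, _ in segment_plan}
    bad = labels - {"preictal", "ictal", "postictal"}
    if bad:
        raise ValueError(f"unknown segment labels {sorted(bad)}")
    if "ictal" not in labels:
        raise ValueError("segment_plan must contain at least one ictal segment")

    fs = config.fs
    n_ch = config.n_channels
    n_intra = min(3, n_ch)
    rng = np.random.default_rng(config.seed)

    seg_samples = [int(round(d * fs)) for _, d in segment_plan]
    n_total = sum(seg_samples)

    # per-sample coupling per channel
    coupling = np.full((n_ch, n_total), config.base_coupling)
    seizures: list[tuple[int, int]] = []
    pos = 0
    for (lab, _), n_s in zip(segment_plan, seg_samples):
        if lab == "ictal":
            coupling[:n_intra, pos : pos + n_s] = config.ictal_coupling
            seizures.append((pos, pos + n_s))
        pos += n_s

    data = np.zeros((n_ch, n_total))
    for low, high in config.band_targets:
        bw = high - low
        f_c = 0.5 * (low + high)
        # phase diffusion giving a Lorentzian linewidth ~ linewidth_frac * bw
        sigma = np.sqrt(2.0 * np.pi * config.linewidth_frac * bw / fs)
        half = 0.5 * bw * config.freq_jitter_frac
        f_chan = f_c + rng.uniform(-half, half, size=n_ch)

        psi0 = rng.uniform(-np.pi, np.pi)
        psi = psi0 + 2.0 * np.pi * f_c / fs * np.arange(n_total)

        theta0 = rng.uniform(-np.pi, np.pi, size=n_ch)
        incr = (
            2.0 * np.pi * f_chan[:, None] / fs
            + sigma * rng.standard_normal((n_ch, n_total))
        )
        theta = theta0[:, None] + np.cumsum(incr, axis=1)

        phi = psi[None, :] + (1.0 - coupling) * (theta - psi[None, :])
        data += config.amplitude_uV * np.cos(phi)

    if config.noise_sd > 0:
        data += config.noise_sd * rng.standard_normal(data.shape)

    focus = [INTRAFOCUS] * n_intra + [EXTRAFOCUS] * (n_ch - n_intra)
    labels_ch = [f"ch{i}" for i in range(1, n_ch + 1)]
    return Recording(
        data=data,
        fs=fs,
        channel_labels=labels_ch,
        focus_class=focus,
        seizures=seizures,
    )
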