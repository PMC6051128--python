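import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_graph():
    from epinetdyn import make_toy_network

    return make_toy_network()


def brute_force_index(g: nx.Graph, x, y, index_name: str) -> float:
    """Independent set-enumeration implementation of the four indices.

    Builds neighbour sets by looping over the edge list, then evaluates the
    definitions term by term. Deliberately naive: the oracle for the
    adjacency-matrix implementations.
    """
    nbrs: dict = {v: set() for v in g.nodes()}
    for u, v in g.edges():
        nbrs[u].add(v)
        nbrs[v].add(u)
    common = nbrs[x] & nbrs[y]
    if index_name == "CN":
        return float(len(common))
    if index_name == "RA":
        return sum(1.0 / len(nbrs[z]) for z in common)
    if index_name == "AA":
        return sum(1.0 / np.log(len(nbrs[z])) for z in common)
    if index_name == "Sorenson":
        ksum = len(nbrs[x]) + len(nbrs[y])
        return 2.0 * len(common) / ksum if ksum else 0.0
    raise ValueError(index_name)


@pytest.fixture(scope="session")
def seizure_study():
    """Per-seed gamma-band dynamics summaries on simulated seizures.

    Twenty seeds of the coupled-oscillator simulator with ictal
    hypersynchrony confined to intrafocus channels; for each seed the mean
    consecutive Euclidean sequence variation and mean node index summation
    in the preictal vs ictal condition.
    """
    import epinetdyn as e

    plan = (("preictal", 60.0), ("ictal", 30.0), ("postictal", 60.0))
    gamma = [b for b in e.CANONICAL_BANDS if b.name == "gamma"]
    rows = []
    for seed in range(20):
        rec = e.simulate_seizure_eeg(e.SimulationConfig(seed=seed), plan)
        rec = e.remove_powerline(rec)
        rec = e.wavelet_denoise(rec)
        rec = e.reject_amplitude_artifacts(rec)
        seg = e.segment_conditions(rec, pre_s=60.0, post_s=60.0)
        banded = e.bandpass_decompose(rec, gamma)
        ser = e.build_network_series(banded, seg, gamma)["gamma"]
        seqs = e.sequences_from_series(ser)
        conds = np.asarray(ser.conditions)
        var = e.variation_series(seqs, ser.conditions)
        per_window, _ = e.node_index_summation(seqs, ser.conditions)
        rows.append({
            "euclid_pre": var.loc[var.condition == "preictal", "euclid_prev"].mean(),
            "euclid_ictal": var.loc[var.condition == "ictal", "euclid_prev"].mean(),
            "sum_pre": per_window.loc[conds == "preictal", "index_sum"].mean(),
            "sum_ictal": per_window.loc[conds == "ictal", "index_sum"].mean(),
        })
    return rows
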