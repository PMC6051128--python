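"""End-to-end orchestration: simulate/load → clean → PLV networks →
link-prediction benchmark → node-sequence dynamics, with a reproducibility
manifest.

Every default matches the workflow's stated operating point: 50 Hz notch,
8000 µV amplitude limit, the five canonical bands, 6-cycle windows, 0.3
binarization threshold, RA sequences, train ratios 0.70–0.95, 100
repetitions, 3-minute pre/postictal margins.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import build_network_series
from .dynamics import (
    cross_condition_variation,
    node_index_summation,
    sequences_from_series,
    variation_series,
)
from .fixtures import (
    DEFAULT_SEGMENT_PLAN,
    SimulationConfig,
    generate_random_graph,
    simulate_seizure_eeg,
)
from .linkpred import INDEX_NAMES, benchmark, write_edge_list
from .preprocess import (
    CANONICAL_BANDS,
    bandpass_decompose,
    load_recording,
    reject_amplitude_artifacts,
    remove_powerline,
    save_recording,
    segment_conditions,
    wavelet_denoise,
)

logger = logging.getLogger("epinetdyn")

_FLOAT_FMT = "%.10g"

CONDITIONS = ("preictal", "ictal", "postictal")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of one pipeline run."""

    recording: str | None = None          # basepath of CSV+JSON input
    simulate: bool = True                 # ignored if recording given
    seed: int = 0
    notch_hz: float = 50.0
    amplitude_limit_uV: float = 8000.0
    pre_s: float = 180.0
    post_s: float = 180.0
    n_cycles: float = 6.0
    threshold: float = 0.3
    index: str = "RA"
    ratios: tuple[float, ...] = (0.70, 0.75, 0.80, 0.85, 0.90, 0.95)
    n_repetitions: int = 100
    benchmark_nodes: int = 30
    benchmark_mean_degree: float = 4.0
    segment_plan: tuple[tuple[str, float], ...] = DEFAULT_SEGMENT_PLAN


def validate_config(raw: dict | None) -> PipelineConfig:
    """Fill defaults and reject out-of-range values with field-level messages.

    An empty/None input yields the full default configuration.
    """
    raw = dict(raw or {})
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    if "ratios" in raw:
        raw["ratios"] = tuple(float(r) for r in raw["ratios"])
    if "segment_plan" in raw:
        raw["segment_plan"] = tuple(
            (str(lab), float(d)) for lab, d in raw["segment_plan"]
        )
    cfg = PipelineConfig(**raw)

    if not 0.0 <= cfg.threshold < 1.0:
        raise ValueError(f"threshold: must be in [0, 1), got {cfg.threshold}")
    for r in cfg.ratios:
        if not 0.0 < r <= 0.95:
            raise ValueError(f"ratios: {r} outside (0, 0.95]")
    if cfg.index not in INDEX_NAMES:
        raise ValueError(f"index: {cfg.index!r} not one of {INDEX_NAMES}")
    if cfg.notch_hz <= 0:
        raise ValueError(f"notch_hz: must be positive, got {cfg.notch_hz}")
    if cfg.amplitude_limit_uV <= 0:
        raise ValueError(
            f"amplitude_limit_uV: must be positive, got "
            f"{cfg.amplitude_limit_uV}"
        )
    if cfg.n_cycles <= 0:
        raise ValueError(f"n_cycles: must be positive, got {cfg.n_cycles}")
    if cfg.n_repetitions < 1:
        raise ValueError(
            f"n_repetitions: must be >= 1, got {cfg.n_repetitions}"
        )
    if cfg.pre_s < 0 or cfg.post_s < 0:
        raise ValueError("pre_s/post_s: must be nonnegative")
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write the report bundle under ``out_dir``.

    Outputs: the (possibly simulated) recording, per-band network index and
    long-format PLV CSVs, a link-prediction benchmark CSV on generated
    30-node graphs, per-band sequence/variation/summation CSVs, and
    ``manifest.json``. Identical config + seed reproduce the outputs
    byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: input -----------------------------------------------------
    if config.recording is not None:
        logger.info("stage input: loading recording %s", config.recording)
        rec = load_recording(config.recording)
    elif config.simulate:
        logger.info("stage input: simulating recording (seed=%d)", config.seed)
        rec = simulate_seizure_eeg(
            SimulationConfig(seed=config.seed), config.segment_plan
        )
    else:
        raise ValueError("stage input: no recording given and simulate=False")
    save_recording(rec, out / "recording")

    # --- stage: preprocess ------------------------------------------------
    logger.info("stage preprocess: notch %.1f Hz, wavelet denoise, "
                "amplitude limit %.0f uV", config.notch_hz,
                config.amplitude_limit_uV)
    rec = remove_powerline(rec, config.notch_hz)
    rec = wavelet_denoise(rec)
    rec = reject_amplitude_artifacts(rec, config.amplitude_limit_uV)

    # --- stage: segmentation ----------------------------------------------
    if not rec.seizures:
        raise ValueError(
            "stage segmentation: recording has no seizure markers; supply "
            "onset/offset annotations or simulate an ictal segment"
        )
    segmentation = segment_conditions(rec, config.pre_s, config.post_s)

    # --- stage: connectivity ----------------------------------------------
    banded = bandpass_decompose(rec, CANONICAL_BANDS)
    series = build_network_series(
        banded, segmentation, CANONICAL_BANDS, config.n_cycles
    )
    index_rows, long_rows = [], []
    for bname in (b.name for b in CANONICAL_BANDS):
        ser = series[bname]
        logger.info("stage connectivity: band %s, %d windows", bname,
                    ser.n_windows)
        for w, (start, end) in enumerate(ser.windows):
            index_rows.append({
                "band": bname, "window": w,
                "start_s": start / rec.fs, "end_s": end / rec.fs,
                "condition": ser.conditions[w],
            })
            iu, ju = np.triu_indices(len(ser.node_labels), k=1)
            for i, j in zip(iu, ju):
                long_rows.append({
                    "band": bname, "window": w,
                    "i": ser.node_labels[i], "j": ser.node_labels[j],
                    "plv": ser.adjacency[w, i, j],
                })
    _write_csv(pd.DataFrame(index_rows), out / "windows.csv")
    _write_csv(pd.DataFrame(long_rows), out / "plv_long.csv")

    # --- stage: link-prediction benchmark ---------------------------------
    logger.info("stage linkpred: %d-node graphs, %d repetitions",
                config.benchmark_nodes, config.n_repetitions)
    graphs = {
        "scale_free": generate_random_graph(
            "scale_free", config.benchmark_nodes,
            config.benchmark_mean_degree, seed=config.seed,
        ),
        "small_world": generate_random_graph(
            "small_world", config.benchmark_nodes,
            config.benchmark_mean_degree, seed=config.seed + 1,
        ),
    }
    for name, g in graphs.items():
        write_edge_list(g, out / f"benchmark_{name}.edges")
    bench = benchmark(
        graphs, INDEX_NAMES, config.ratios,
        n_repetitions=config.n_repetitions, seed=config.seed,
    )
    _write_csv(bench, out / "benchmark.csv")

    # --- stage: dynamics ----------------------------------------------------
    seq_frames, var_frames, cross_frames, sum_frames = [], [], [], []
    for bname in (b.name for b in CANONICAL_BANDS):
        ser = series[bname]
        seqs = sequences_from_series(ser, config.index, config.threshold)
        n_nodes = seqs.shape[1]
        sf = pd.DataFrame(
            seqs, columns=[f"seq_{i + 1}" for i in range(n_nodes)]
        )
        sf.insert(0, "condition", ser.conditions)
        sf.insert(0, "window", np.arange(len(seqs)))
        sf.insert(0, "band", bname)
        per_window, _ = node_index_summation(seqs, ser.conditions)
        sf["index_sum"] = per_window["index_sum"]
        seq_frames.append(sf)

        vf = variation_series(seqs, ser.conditions)
        vf.insert(0, "band", bname)
        var_frames.append(vf)

        _, per_cond = node_index_summation(seqs, ser.conditions)
        per_cond.insert(0, "band", bname)
        sum_frames.append(per_cond)

        for ca, cb in (("preictal", "ictal"), ("ictal", "postictal")):
            cf = cross_condition_variation(seqs, ser.conditions, ca, cb)
            cf.insert(0, "band", bname)
            cross_frames.append(cf)
        logger.info("stage dynamics: band %s, %d sequences", bname, len(seqs))

    _write_csv(pd.concat(seq_frames, ignore_index=True),
               out / "sequences.csv")
    _write_csv(pd.concat(var_frames, ignore_index=True),
               out / "variation_consecutive.csv")
    _write_csv(pd.concat(cross_frames, ignore_index=True),
               out / "variation_cross_condition.csv")
    _write_csv(pd.concat(sum_frames, ignore_index=True),
               out / "index_summation.csv")

    # --- manifest -----------------------------------------------------------
    import networkx
    import scipy

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "epinetdyn": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
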