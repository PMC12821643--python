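"""End-to-end driver: simulate -> score -> sleep metrics -> statistics.

Everything is deterministic given the config seed; each run writes its
stage outputs plus a provenance record (config, package versions, seeds)
so a report can be regenerated bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .hypnogram import Hypnogram
from .metrics import compute_metrics
from .scoring import score_recording
from .synth import make_burst_plan, generate_hypnogram, synthesize_recording

log = logging.getLogger("rwahome")


def score_one_night(
    chin: np.ndarray,
    rate: float,
    hypnogram: Hypnogram,
    cfg: RunConfig,
):
    return score_recording(
        chin,
        rate,
        hypnogram,
        band=(cfg.band_low, cfg.band_high),
        smooth=cfg.smooth_s,
        envelope_method=cfg.envelope_method,
        background_scope=cfg.background_scope,
        trim_top=cfg.trim_top,
        ratio=cfg.amplitude_ratio,
        min_dur=cfg.min_burst_s,
        max_dur=cfg.max_burst_s,
        min_active=cfg.min_active_mini,
    )


def simulate_and_score_night(
    cfg: RunConfig, target_rwa_pct: float, seed: int, amplitude_ratio: float = 6.0
) -> dict:
    """One synthetic night with planted ground truth, scored end to end."""
    sim = cfg.simulation_config(seed=seed)
    t0 = time.perf_counter()
    hyp = generate_hypnogram(sim)
    plan = make_burst_plan(hyp, target_rwa_pct, amplitude_ratio=amplitude_ratio)
    rec = synthesize_recording(hyp, plan, sim)
    result = score_one_night(rec.chin, sim.sampling_rate, hyp, cfg)
    metrics = compute_metrics(hyp)
    log.info(
        "night seed=%d: %d REM epochs, planted %.1f%%, scored %.1f%% (%.2fs)",
        seed, hyp.n_rem_epochs, target_rwa_pct,
        result.rwa_pct, time.perf_counter() - t0,
    )
    return {
        "hypnogram": hyp,
        "plan": plan,
        "recording": rec,
        "rwa": result,
        "metrics": metrics,
    }


def _provenance(cfg: RunConfig) -> dict:
    cfg_json = json.dumps(asdict(cfg), sort_keys=True)
    return {
        "package": f"rwahome {__version__}",
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": asdict(cfg),
        "seed": cfg.seed,
    }


def run_pipeline(cfg: RunConfig, out_dir: str | Path, target_rwa_pct: float = 20.0) -> dict:
    """Simulate one night, score it, compute sleep metrics, and write
    every stage output with a provenance log. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    night = simulate_and_score_night(cfg, target_rwa_pct, cfg.seed)

    paths = {}
    hyp_path = out / "hypnogram.csv"
    night["hypnogram"].to_csv(hyp_path)
    paths["hypnogram"] = hyp_path

    rwa = night["rwa"]
    bursts = pd.DataFrame(
        [(b.onset, b.duration, b.peak_ratio) for b in rwa.bursts],
        columns=["onset_s", "duration_s", "peak_ratio"],
    )
    bursts.to_csv(out / "bursts.csv", index=False)
    paths["bursts"] = out / "bursts.csv"

    pd.DataFrame(
        [(m.index, m.occupancy, m.active) for m in rwa.mini_scores],
        columns=["mini_index", "occupancy", "active"],
    ).to_csv(out / "mini_epochs.csv", index=False)
    paths["mini_epochs"] = out / "mini_epochs.csv"

    pd.DataFrame(
        {"epoch_index": rwa.rem_epoch_indices, "rwa": rwa.rem_epoch_flags}
    ).to_csv(out / "rem_epoch_flags.csv", index=False)
    paths["rem_epoch_flags"] = out / "rem_epoch_flags.csv"

    summary = {
        "rwa_pct": rwa.rwa_pct,
        "n_rem_epochs": int(rwa.rem_epoch_indices.size),
        "n_bursts": len(rwa.bursts),
        "background": rwa.background,
        "planted_target_pct": target_rwa_pct,
        **{k: getattr(night["metrics"], k) for k in (
            "tst", "sleep_efficiency", "sol", "waso", "rem_min", "nrem_min", "n3_min",
        )},
    }
    pd.DataFrame([summary]).to_csv(out / "night_summary.csv", index=False)
    paths["night_summary"] = out / "night_summary.csv"

    (out / "provenance.json").write_text(json.dumps(_provenance(cfg), indent=2))
    paths["provenance"] = out / "provenance.json"
    return paths
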