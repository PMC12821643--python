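#!/usr/bin/env python
"""Simulate one home-recorded night and score it end to end.

Generates an 8-h hypnogram, plants phasic chin-EMG bursts so that 20% of
REM epochs should score as RWA, synthesizes the two-channel recording,
runs the full scoring chain and the sleep metrics, and writes every
stage output (hypnogram, bursts, mini-epochs, epoch flags, summary,
provenance) under results/night/.
"""

from pathlib import Path

from rwahome.config import RunConfig
from rwahome.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "night"

if __name__ == "__main__":
    cfg = RunConfig(seed=1)
    paths = run_pipeline(cfg, OUT, target_rwa_pct=20.0)
    import pandas as pd

    summary = pd.read_csv(paths["night_summary"]).iloc[0]
    print(f"night summary ({OUT}):")
    print(
        f"  planted target {summary.planted_target_pct:.1f}% of "
        f"{summary.n_rem_epochs:.0f} REM epochs -> scored RWA "
        f"{summary.rwa_pct:.1f}% ({summary.n_bursts:.0f} bursts, "
        f"background {summary.background:.2f})"
    )
    print(
        f"  TST {summary.tst:.1f} min, efficiency {summary.sleep_efficiency:.1f}%, "
        f"SOL {summary.sol:.1f} min, WASO {summary.waso:.1f} min, "
        f"REM {summary.rem_min:.1f} min"
    )
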