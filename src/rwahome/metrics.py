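"""Conventional objective sleep metrics computed from a hypnogram.

Definitions (AASM-style, on the 30-s epoch grid):

* time in bed (TIB): lights-off to lights-on span;
* sleep onset: first epoch of any sleep stage after lights off;
* SOL: minutes from lights off to sleep onset;
* TST: minutes in N1+N2+N3+REM within TIB;
* WASO: wake minutes between sleep onset and the final sleep epoch
  (terminal wake is excluded);
* sleep efficiency: 100 x TST / TIB.

Everything is quantized to half-minutes, so the identity
``TST + SOL + WASO + terminal wake = TIB`` holds exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .hypnogram import Hypnogram, SLEEP_STAGES


@dataclass(frozen=True)
class SleepMetrics:
    """One night's summary metrics, minutes unless noted.

    ``sol``/``waso`` are NaN and ``no_sleep`` is True for a night without
    any sleep epoch. ``log_rem`` (natural-log minutes) is NaN when the
    night has no REM sleep; such nights are excluded from log-scale
    analyses downstream.
    """

    tib: float
    tst: float
    sleep_efficiency: float  # percent
    sol: float
    waso: float
    terminal_wake: float
    rem_min: float
    nrem_min: float
    n1_min: float
    n2_min: float
    n3_min: float
    log_rem: float
    no_sleep: bool = False


def log_transform(x: float) -> float:
    """Natural log of a positive duration in minutes.

    Raises ``ValueError`` for non-positive input: a zero-REM night has no
    defined log-REM and must be excluded explicitly, never coerced.
    """
    if x <= 0:
        raise ValueError(f"log transform needs a positive value, got {x}")
    return math.log(x)


def compute_metrics(h: Hypnogram) -> SleepMetrics:
    """Compute the summary metrics of one night from its hypnogram."""
    epm = h.epoch_len / 60.0  # minutes per epoch
    tib_stages = h.stages[h.lights_off : h.lights_on]
    tib = tib_stages.size * epm

    sleep_mask = np.isin(tib_stages, SLEEP_STAGES)
    counts = {s: float(np.sum(tib_stages == s)) * epm for s in ("N1", "N2", "N3", "REM")}
    tst = float(sleep_mask.sum()) * epm

    if not sleep_mask.any():
        return SleepMetrics(
            tib=tib, tst=0.0, sleep_efficiency=0.0, sol=float("nan"),
            waso=float("nan"), terminal_wake=tib, rem_min=0.0, nrem_min=0.0,
            n1_min=0.0, n2_min=0.0, n3_min=0.0, log_rem=float("nan"),
            no_sleep=True,
        )

    onset = int(np.flatnonzero(sleep_mask)[0])
    last = int(np.flatnonzero(sleep_mask)[-1])
    sol = onset * epm
    waso = float(np.sum(~sleep_mask[onset : last + 1])) * epm
    terminal_wake = float(tib_stages.size - (last + 1)) * epm

    rem_min = counts["REM"]
    nrem_min = counts["N1"] + counts["N2"] + counts["N3"]
    if rem_min > 0:
        log_rem = log_transform(rem_min)
    else:
        warnings.warn("night has no REM sleep; log-REM undefined", stacklevel=2)
        log_rem = float("nan")

    return SleepMetrics(
        tib=tib,
        tst=tst,
        sleep_efficiency=100.0 * tst / tib,
        sol=sol,
        waso=waso,
        terminal_wake=terminal_wake,
        rem_min=rem_min,
        nrem_min=nrem_min,
        n1_min=counts["N1"],
        n2_min=counts["N2"],
        n3_min=counts["N3"],
        log_rem=log_rem,
    )


def mean_of_nights(nights: list[SleepMetrics]) -> SleepMetrics:
    """Average per-night metrics patient-wise (the default two-night summary).

    NaN fields (e.g. log-REM on a REM-free night) propagate via nanmean;
    ``no_sleep`` is True only if every night lacked sleep.
    """
    if not nights:
        raise ValueError("need at least one night")
    fields = [f for f in SleepMetrics.__dataclass_fields__ if f != "no_sleep"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        vals = {f: float(np.nanmean([getattr(n, f) for n in nights])) for f in fields}
    return SleepMetrics(**vals, no_sleep=all(n.no_sleep for n in nights))
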