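"""REM sleep without atonia (RWA) scoring for a two-channel home recording.

The detection rule operates on the chin/EOG channel and proceeds:

1. amplitude envelope of the raw signal;
2. background tone level estimated from REM sleep (trimmed median);
3. phasic bursts: maximal runs where the envelope reaches at least
   4x background, retained only if they last 0.1-5 s (longer runs are
   tonic elevation, not phasic activity, and are discarded);
4. 3-s mini-epochs: a mini-epoch is *active* when bursts cover strictly
   more than 50% of it;
5. a 30-s REM epoch is an RWA epoch when at least one of its ten
   mini-epochs is active (configurable k-of-10);
6. the patient-level RWA percentage is the share of REM epochs flagged,
   and a patient is RWA-positive when the night-aggregated percentage
   exceeds a cutoff (default 0: any RWA epoch).

All thresholds are relative to the background, so the scoring is invariant
to rescaling the raw signal by any positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .hypnogram import Hypnogram

MINI_LEN_S = 3.0
DEFAULT_RATIO = 4.0
DEFAULT_MIN_DUR = 0.1
DEFAULT_MAX_DUR = 5.0


@dataclass
class EnvelopeSeries:
    """Non-negative amplitude per sample, with the sample step in seconds."""

    values: np.ndarray
    step: float
    channel_id: str = "chin"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("envelope values must be non-negative")

    @property
    def duration_s(self) -> float:
        return self.values.size * self.step


@dataclass(frozen=True)
class Burst:
    """A phasic muscle-activity burst: onset/duration in seconds, peak
    amplitude as a multiple of the background level."""

    onset: float
    duration: float
    peak_ratio: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class MiniEpochScore:
    index: int
    occupancy: float  # fraction of the 3-s window covered by bursts
    active: bool  # occupancy strictly > 0.5


@dataclass
class RwaResult:
    """Scoring result for one night.

    ``rwa_pct`` is the percentage of REM epochs flagged RWA; it is NaN and
    ``no_rem`` is True for a night without REM sleep (explicitly not 0).
    """

    rem_epoch_indices: np.ndarray
    rem_epoch_flags: np.ndarray
    rwa_pct: float
    bursts: list[Burst]
    mini_scores: list[MiniEpochScore]
    background: float
    no_rem: bool = False

    def __post_init__(self) -> None:
        if self.rem_epoch_indices.size != self.rem_epoch_flags.size:
            raise ValueError("one flag per REM epoch required")


@dataclass
class PatientRwaStatus:
    night_pcts: list[float]
    aggregate_pct: float
    rwa_positive: bool
    aggregation: str = "mean"
    cutoff: float = 0.0


def compute_envelope(
    signal: np.ndarray,
    rate: float,
    band: tuple[float, float | None] = (10.0, None),
    smooth: float = 0.05,
    method: str = "hilbert",
) -> EnvelopeSeries:
    """Amplitude envelope of the chin/EOG channel.

    Band-pass (default 10 Hz to 90% of Nyquist; the upper edge is clipped
    to Nyquist), then the analytic-signal magnitude (``method="hilbert"``,
    exact for a pure tone) or full-wave rectification (``"rectify"``),
    smoothed with a moving window of ``smooth`` seconds (default 50 ms).
    """
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    nyq = rate / 2.0
    lo, hi = band
    hi = 0.9 * nyq if hi is None else min(hi, 0.98 * nyq)
    if not 0 < lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi}) at rate {rate}")
    sos = butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    filtered = sosfiltfilt(sos, x)
    if method == "hilbert":
        amp = np.abs(hilbert(filtered))
    elif method == "rectify":
        amp = np.abs(filtered)
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    win = max(1, int(round(smooth * rate)))
    env = uniform_filter1d(amp, size=win, mode="nearest")
    return EnvelopeSeries(values=np.maximum(env, 0.0), step=1.0 / rate)


def estimate_background(
    env: EnvelopeSeries,
    hypnogram: Hypnogram | None = None,
    scope: str = "rem",
    trim_top: float = 0.10,
) -> float:
    """Background muscle-tone level: trimmed median of the envelope.

    Default scope is REM sleep over the whole night (the epochs the 4x
    rule applies to), discarding the top ``trim_top`` fraction of samples
    first so that phasic bursts do not inflate the estimate.
    ``scope="whole_night"`` uses every sample instead.
    """
    values = env.values
    if scope == "rem":
        if hypnogram is None:
            raise ValueError("REM-scoped background needs a hypnogram")
        per_epoch = int(round(hypnogram.epoch_len / env.step))
        idx = [
            np.arange(i * per_epoch, min((i + 1) * per_epoch, values.size))
            for i in hypnogram.rem_indices
        ]
        if not idx:
            raise ValueError("no REM epochs to estimate background from")
        values = values[np.concatenate(idx)]
    elif scope != "whole_night":
        raise ValueError(f"unknown background scope {scope!r}")
    if values.size == 0:
        raise ValueError("no samples in background scope")
    if not np.any(values > 0):
        raise ValueError("all-zero envelope: background undefined")
    if not 0 <= trim_top < 1:
        raise ValueError("trim_top must be in [0, 1)")
    if trim_top > 0:
        cut = np.quantile(values, 1.0 - trim_top)
        kept = values[values <= cut]
        if kept.size:
            values = kept
    bg = float(np.median(values))
    if bg <= 0:
        raise ValueError("background estimate is not positive")
    return bg


def detect_bursts(
    env: EnvelopeSeries,
    background: float,
    min_dur: float = DEFAULT_MIN_DUR,
    max_dur: float = DEFAULT_MAX_DUR,
    ratio: float = DEFAULT_RATIO,
) -> list[Burst]:
    """Phasic bursts: maximal runs with envelope >= ratio x background.

    Runs shorter than ``min_dur`` are noise blips; runs longer than
    ``max_dur`` are sustained (tonic) elevation and are discarded entirely
    rather than truncated.
    """
    if background <= 0:
        raise ValueError("background must be positive")
    mask = env.values >= ratio * background
    if not mask.any():
        return []
    # run boundaries from the sign changes of the padded mask
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    bursts: list[Burst] = []
    for s, e in zip(starts, ends):
        dur = (e - s) * env.step
        if min_dur <= dur <= max_dur:
            peak = float(env.values[s:e].max()) / background
            bursts.append(Burst(onset=s * env.step, duration=dur, peak_ratio=peak))
    return bursts


def score_mini_epochs(
    bursts: list[Burst],
    night_len_s: float,
    mini_len: float = MINI_LEN_S,
    epoch_len: float = 30.0,
) -> list[MiniEpochScore]:
    """Occupancy scoring on the non-overlapping 3-s mini-epoch grid.

    The grid is anchored at recording start. A mini-epoch is active when
    bursts cover strictly more than half of it (exactly 50% is NOT
    active).
    """
    if night_len_s <= 0:
        raise ValueError("night length must be positive")
    n_per_epoch = epoch_len / mini_len
    if abs(n_per_epoch - round(n_per_epoch)) > 1e-9:
        raise ValueError(
            f"mini-epoch length {mini_len}s must divide the epoch length {epoch_len}s"
        )
    n_mini = int(np.ceil(night_len_s / mini_len - 1e-9))
    overlap = np.zeros(n_mini)
    edges = np.arange(n_mini + 1) * mini_len
    for b in bursts:
        if b.onset < -1e-9 or b.end > night_len_s + 1e-9:
            raise ValueError(f"burst {b} extends outside the recording")
        lo = np.maximum(edges[:-1], b.onset)
        hi = np.minimum(edges[1:], b.end)
        overlap += np.maximum(hi - lo, 0.0)
    occupancy = np.clip(overlap / mini_len, 0.0, 1.0)
    return [
        MiniEpochScore(index=i, occupancy=float(o), active=bool(o > 0.5))
        for i, o in enumerate(occupancy)
    ]


def score_epochs(
    mini: list[MiniEpochScore],
    hypnogram: Hypnogram,
    bursts: list[Burst] | None = None,
    background: float = float("nan"),
    min_active: int = 1,
    mini_len: float = MINI_LEN_S,
) -> RwaResult:
    """Classify each 30-s REM epoch and compute the night's RWA%.

    An epoch is RWA when at least ``min_active`` of its mini-epochs are
    active (default 1). Non-REM epochs never contribute; a night without
    REM epochs yields an explicit no-REM result (``rwa_pct`` NaN), not 0%.
    """
    per_epoch = int(round(hypnogram.epoch_len / mini_len))
    if not 1 <= min_active <= per_epoch:
        raise ValueError(f"min_active must be in 1..{per_epoch}")
    active = np.array([m.active for m in mini], dtype=bool)
    rem_idx = hypnogram.rem_indices
    if rem_idx.size == 0:
        return RwaResult(
            rem_epoch_indices=rem_idx,
            rem_epoch_flags=np.zeros(0, dtype=bool),
            rwa_pct=float("nan"),
            bursts=bursts or [],
            mini_scores=mini,
            background=background,
            no_rem=True,
        )
    if rem_idx.max() * per_epoch + per_epoch > active.size:
        raise ValueError("mini-epoch scores do not cover every REM epoch")
    flags = np.array(
        [active[i * per_epoch : (i + 1) * per_epoch].sum() >= min_active for i in rem_idx]
    )
    return RwaResult(
        rem_epoch_indices=rem_idx,
        rem_epoch_flags=flags,
        rwa_pct=100.0 * float(flags.sum()) / flags.size,
        bursts=bursts or [],
        mini_scores=mini,
        background=background,
    )


def classify_patient(
    nights: list[RwaResult],
    cutoff: float = 0.0,
    aggregation: str = "mean",
) -> PatientRwaStatus:
    """Aggregate per-night RWA% into a patient-level status.

    Nights without REM are excluded; the aggregate is the mean (default)
    or max of the remaining nights, and the patient is RWA-positive when
    it strictly exceeds ``cutoff`` (default 0%).
    """
    pcts = [n.rwa_pct for n in nights if not n.no_rem]
    if not pcts:
        raise ValueError("no night with REM sleep: patient RWA status undefined")
    if aggregation == "mean":
        agg = float(np.mean(pcts))
    elif aggregation == "max":
        agg = float(np.max(pcts))
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return PatientRwaStatus(
        night_pcts=[n.rwa_pct for n in nights],
        aggregate_pct=agg,
        rwa_positive=agg > cutoff,
        aggregation=aggregation,
        cutoff=cutoff,
    )


def score_recording(
    chin: np.ndarray,
    rate: float,
    hypnogram: Hypnogram,
    band: tuple[float, float | None] = (10.0, None),
    smooth: float = 0.05,
    envelope_method: str = "hilbert",
    background_scope: str = "rem",
    trim_top: float = 0.10,
    ratio: float = DEFAULT_RATIO,
    min_dur: float = DEFAULT_MIN_DUR,
    max_dur: float = DEFAULT_MAX_DUR,
    min_active: int = 1,
) -> RwaResult:
    """Full scoring chain for one night's chin channel."""
    env = compute_envelope(chin, rate, band=band, smooth=smooth, method=envelope_method)
    bg = estimate_background(env, hypnogram, scope=background_scope, trim_top=trim_top)
    bursts = detect_bursts(env, bg, min_dur=min_dur, max_dur=max_dur, ratio=ratio)
    night_len = hypnogram.n_epochs * hypnogram.epoch_len
    mini = score_mini_epochs(bursts, night_len, epoch_len=hypnogram.epoch_len)
    return score_epochs(mini, hypnogram, bursts=bursts, background=bg, min_active=min_active)
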