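"""Synthetic nights and cohorts with known ground truth.

Three generators:

* :func:`generate_hypnogram` — a first-order Markov chain over
  {W, N1, N2, N3, REM} on the 30-s epoch grid, with a REM-cycling bias
  (the propensity to enter REM from N2 ramps up with time since the last
  REM period, emulating the ~90-min ultradian cycle). Defaults are
  calibrated so that REM occupies roughly 20% of total sleep time and
  sleep efficiency is in the mid-80s.
* :func:`synthesize_recording` — band-limited Gaussian background noise
  on the chin channel whose envelope scale is the configured background
  amplitude, with planted bursts realised as raised-envelope noise
  segments (noise scaled by the amplitude ratio with short cosine ramps),
  plus the ground-truth mini-epoch activity flags implied by the plan
  geometry.
* :func:`simulate_cohort` — a patient table whose covariate marginals
  match a Parkinson's disease cohort and whose log-REM-duration group
  effect (RWA-positive vs negative) is configurable, for parameter-recovery
  and calibration studies of the downstream ANCOVA.

All randomness flows through one ``numpy.random.Generator`` seeded per
call, so identical seed + config gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .hypnogram import STAGES, Hypnogram
from .scoring import MINI_LEN_S

# -- configuration ------------------------------------------------------


def _default_stage_params() -> dict:
    """Markov-chain defaults (per 30-s epoch transition weights).

    Rows are unnormalised weights; the N2->REM weight is multiplied by the
    REM-cycling bias before normalisation. Dwell times implied by the
    self-weights: REM periods ~7 min, N3 runs ~5 min.
    """
    return {
        "transition": {
            "W": {"W": 0.88, "N1": 0.12},
            "N1": {"W": 0.04, "N1": 0.45, "N2": 0.51},
            "N2": {"W": 0.015, "N1": 0.02, "N2": 0.85, "N3": 0.055, "REM": 0.10},
            "N3": {"N2": 0.10, "N3": 0.90},
            "REM": {"W": 0.04, "N1": 0.02, "N2": 0.04, "REM": 0.93},
        },
        "rem_cycle_min": 40.0,  # time-since-REM at which REM entry reaches full weight
        "initial_stage": "W",
    }


@dataclass
class SimulationConfig:
    """Parameters of a simulated night.

    sampling_rate : Hz (device default 128)
    epoch_len : s, must be a multiple of the 3-s mini-epoch
    night_len_min : minutes of recording
    background_amp : envelope scale of the chin background tone
        (median analytic amplitude), arbitrary units
    stage_params : Markov-chain transition weights and REM-cycling bias
    seed : master seed for all randomness in the night
    """

    sampling_rate: float = 128.0
    epoch_len: float = 30.0
    night_len_min: float = 480.0
    background_amp: float = 10.0
    stage_params: dict = field(default_factory=_default_stage_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.night_len_min <= 0:
            raise ValueError("night_len_min must be positive")
        ratio = self.epoch_len / MINI_LEN_S
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"epoch_len {self.epoch_len}s must be a multiple of the "
                f"{MINI_LEN_S}s mini-epoch"
            )
        if self.background_amp <= 0:
            raise ValueError("background_amp must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.night_len_min * 60.0 // self.epoch_len)

    @property
    def n_samples(self) -> int:
        return int(round(self.n_epochs * self.epoch_len * self.sampling_rate))


@dataclass(frozen=True)
class PlannedBurst:
    onset: float  # s from recording start
    duration: float  # s
    amplitude_ratio: float  # multiple of background envelope


@dataclass
class BurstPlan:
    """Ground-truth burst layout for one night's chin channel."""

    bursts: list[PlannedBurst] = field(default_factory=list)
    target_epochs: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.bursts:
            if b.duration <= 0:
                raise ValueError(f"burst duration must be positive: {b}")
            if b.amplitude_ratio <= 0:
                raise ValueError(f"amplitude ratio must be positive: {b}")
        ordered = sorted(self.bursts, key=lambda b: b.onset)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.onset < prev.onset + prev.duration - 1e-12:
                raise ValueError(f"overlapping bursts: {prev} and {nxt}")

    def truth_mini_flags(self, night_len_s: float, mini_len: float = MINI_LEN_S) -> np.ndarray:
        """Expected per-mini-epoch activity from plan geometry alone.

        Independent interval arithmetic: a mini-epoch is expected active
        when planted bursts overlap strictly more than half of it.
        """
        n_mini = int(np.ceil(night_len_s / mini_len - 1e-9))
        edges = np.arange(n_mini + 1) * mini_len
        overlap = np.zeros(n_mini)
        for b in self.bursts:
            lo = np.maximum(edges[:-1], b.onset)
            hi = np.minimum(edges[1:], b.onset + b.duration)
            overlap += np.maximum(hi - lo, 0.0)
        return overlap / mini_len > 0.5


@dataclass
class SyntheticRecording:
    eeg: np.ndarray
    chin: np.ndarray
    sampling_rate: float
    truth: BurstPlan
    truth_mini_flags: np.ndarray

    def __post_init__(self) -> None:
        if self.eeg.shape != self.chin.shape:
            raise ValueError("EEG and chin channels must have equal length")


# -- hypnogram ----------------------------------------------------------


def generate_hypnogram(config: SimulationConfig, rng: np.random.Generator | None = None) -> Hypnogram:
    """Simulate one night's stage sequence.

    First-order Markov chain with a REM-cycling bias: the weight of
    entering REM ramps linearly from 0 just after a REM period back to
    its full value ``rem_cycle_min`` minutes later. For a night of at
    least 90 min the result is guaranteed to contain REM sleep: the chain
    is redrawn a few times if needed and, as a last resort, a late block
    of sleep is relabelled REM.
    """
    n_epochs = config.n_epochs
    if n_epochs < 1:
        raise ValueError(
            f"night_len_min={config.night_len_min} is shorter than one "
            f"{config.epoch_len}-s epoch"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = config.stage_params
    trans = params["transition"]
    cycle_epochs = max(1.0, params["rem_cycle_min"] * 60.0 / config.epoch_len)

    weights = {s: np.array([trans[s].get(t, 0.0) for t in STAGES]) for s in STAGES}
    rem_col = STAGES.index("REM")
    guarantee = config.night_len_min >= 90.0

    for _attempt in range(8):
        stages = np.empty(n_epochs, dtype=object)
        state = params.get("initial_stage", "W")
        since_rem = cycle_epochs  # start of night: full REM propensity
        for i in range(n_epochs):
            w = weights[state].copy()
            if state != "REM" and w[rem_col] > 0:
                w[rem_col] *= min(1.0, since_rem / cycle_epochs)
            p = w / w.sum()
            state = STAGES[rng.choice(len(STAGES), p=p)]
            stages[i] = state
            since_rem = 0.0 if state == "REM" else since_rem + 1.0
        if not guarantee or (stages == "REM").any():
            return Hypnogram(stages, epoch_len=config.epoch_len)

    # degenerate draw on a long night: relabel one late sleep block
    sleep_idx = np.flatnonzero(stages != "W")
    anchor = sleep_idx[int(0.75 * (sleep_idx.size - 1))] if sleep_idx.size else n_epochs - 10
    block = np.arange(anchor, min(anchor + 10, n_epochs))
    stages[block] = "REM"
    return Hypnogram(stages, epoch_len=config.epoch_len)


# -- burst planting -----------------------------------------------------


def make_burst_plan(
    hypnogram: Hypnogram,
    target_rwa_pct: float,
    occupancy: float = 0.8,
    amplitude_ratio: float = 6.0,
    bursts_per_epoch: int = 2,
) -> BurstPlan:
    """Plant bursts so that a known share of REM epochs scores RWA.

    Exactly ``ceil(target_rwa_pct/100 x n_REM)`` REM epochs (evenly spaced
    through the night's REM sequence) each receive ``bursts_per_epoch``
    bursts, one per mini-epoch from the epoch start, each covering
    ``occupancy`` of its 3-s mini-epoch (must exceed 0.5 to score) and
    centred in the window. The defaults (0.8 occupancy, two mini-epochs
    per target epoch) leave enough margin that the stochastic envelope of
    a realised burst — which dips below the detection threshold now and
    then, fragmenting it into shorter runs — still scores the epoch.
    """
    if not 0 <= target_rwa_pct <= 100:
        raise ValueError("target_rwa_pct must be in [0, 100]")
    if not 0.5 < occupancy <= 1.0:
        raise ValueError("occupancy must be in (0.5, 1] to produce scoreable epochs")
    dur = occupancy * MINI_LEN_S
    if dur > 5.0:
        raise ValueError("occupancy x 3 s exceeds the 5-s phasic maximum")
    if target_rwa_pct == 0:
        return BurstPlan()
    rem_idx = hypnogram.rem_indices
    if rem_idx.size == 0:
        raise ValueError("target RWA > 0 but the hypnogram has no REM epochs")
    n_target = math.ceil(target_rwa_pct / 100.0 * rem_idx.size)
    chosen = rem_idx[np.round(np.linspace(0, rem_idx.size - 1, n_target)).astype(int)]
    pad = (MINI_LEN_S - dur) / 2.0
    bursts = []
    for ep in np.unique(chosen):
        start, _ = hypnogram.epoch_bounds_s(int(ep))
        for k in range(bursts_per_epoch):
            bursts.append(
                PlannedBurst(
                    onset=start + k * MINI_LEN_S + pad,
                    duration=dur,
                    amplitude_ratio=amplitude_ratio,
                )
            )
    return BurstPlan(bursts=bursts, target_epochs=[int(e) for e in np.unique(chosen)])


# -- signal synthesis ---------------------------------------------------

# median of the analytic-signal magnitude of unit-variance Gaussian noise
# (Rayleigh distribution): sqrt(2 ln 2)
_RAYLEIGH_MEDIAN = math.sqrt(2.0 * math.log(2.0))
_RAMP_S = 0.02  # cosine ramp at burst edges


def _band_noise(n: int, rate: float, band: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, band, btype="band", fs=rate, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def synthesize_recording(
    hypnogram: Hypnogram,
    plan: BurstPlan,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticRecording:
    """Two-channel recording with planted phasic bursts.

    The chin channel is stationary band-limited (10-55 Hz) Gaussian noise
    scaled so its median analytic amplitude equals ``background_amp``;
    each planted burst multiplies the noise by its amplitude ratio with
    20-ms cosine edge ramps. The EEG channel is cosmetic slow-band noise.
    Ground-truth mini-epoch flags come from plan geometry.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if hypnogram.n_epochs != config.n_epochs:
        raise ValueError(
            f"hypnogram ({hypnogram.n_epochs} epochs) does not match the "
            f"configured night ({config.n_epochs} epochs)"
        )
    rate = config.sampling_rate
    n = config.n_samples
    night_len_s = n / rate

    sigma = config.background_amp / _RAYLEIGH_MEDIAN
    chin = _band_noise(n, rate, (10.0, min(55.0, 0.45 * rate)), rng) * sigma

    gain = np.ones(n)
    ramp = max(1, int(round(_RAMP_S * rate)))
    for b in plan.bursts:
        i0 = int(round(b.onset * rate))
        i1 = int(round((b.onset + b.duration) * rate))
        if i0 < 0 or i1 > n:
            raise ValueError(f"burst {b} lies outside the recording")
        gain[i0:i1] = b.amplitude_ratio
        up = np.linspace(1.0, b.amplitude_ratio, ramp, endpoint=False)
        down = np.linspace(b.amplitude_ratio, 1.0, ramp, endpoint=False)
        gain[max(0, i0 - ramp) : i0] = up[-(i0 - max(0, i0 - ramp)) or None :]
        gain[i1 : min(n, i1 + ramp)] = down[: min(n, i1 + ramp) - i1]
    chin = chin * gain

    eeg = _band_noise(n, rate, (0.5, 30.0), rng) * sigma
    return SyntheticRecording(
        eeg=eeg,
        chin=chin,
        sampling_rate=rate,
        truth=plan,
        truth_mini_flags=plan.truth_mini_flags(night_len_s),
    )


# -- cohort simulation --------------------------------------------------


def _default_marginals() -> dict:
    """Covariate marginals of a Parkinson's disease sleep-study cohort.

    Location/scale per variable on its instrument scale; the Parkinson's
    Fatigue Scale is drawn on the mean-per-item scale (1-5) so the
    fatigue cutoff (>= 3.3) applies directly.
    """
    return {
        "age": {"mean": 72.4, "sd": 6.6, "lo": 41.0, "hi": 95.0},
        "p_male": 0.61,
        "bmi": {"mean": 21.6, "sd": 3.3, "lo": 13.0, "hi": 40.0},
        "disease_duration": {"log_mean": math.log(109.0), "log_sd": 0.45},  # months
        "leed": {"log_mean": math.log(650.0), "log_sd": 0.55},  # mg/day
        "mmse": {"mean": 28.4, "sd": 1.4, "lo": 22, "hi": 30},
        "hoehn_yahr": {"mean": 2.4, "sd": 0.85, "lo": 1.0, "hi": 5.0},
        "updrs3": {"log_mean": 3.10, "log_sd": 0.45},
        "updrs4": {"mean": 4.9, "sd": 3.4, "lo": 0.0, "hi": 24.0},
        "pdss2_motor_night": {"mean": 6.3, "sd": 3.6, "lo": 0.0, "hi": 24.0},
        "pdss2_nocturnal": {"log_mean": 1.72, "log_sd": 0.64, "lo": 1.0},
        "pdss2_disturbed_sleep": {"mean": 10.7, "sd": 3.0, "lo": 0.0, "hi": 20.0},
        "rbdsq": {"mean": 5.9, "sd": 3.1, "lo": 0, "hi": 13},
        "bdi": {"mean": 13.7, "sd": 6.8, "lo": 0, "hi": 63},
        "pfs": {"mean": 3.1, "sd": 0.95, "lo": 1.0, "hi": 5.0},  # mean-item scale
        "anxiety": {"mean": 6.8, "sd": 5.5, "lo": 0.0, "hi": 24.0},
        "psychosis": {"mean": 1.4, "sd": 1.3, "lo": 0.0, "hi": 12.0},
        # sleep metrics other than REM
        "tst": {"mean": 331.0, "sd": 98.0, "lo": 60.0, "hi": 600.0},
        "sleep_efficiency": {"mean": 86.0, "sd": 8.0, "lo": 40.0, "hi": 100.0},
        "waso": {"log_mean": math.log(47.0), "log_sd": 0.6},
        "sol": {"log_mean": math.log(19.0), "log_sd": 0.6},
        "n3_min": {"mean": 70.5, "sd": 27.0, "lo": 0.0, "hi": 200.0},
        # log-REM outcome model
        "log_rem_baseline": 2.97,
        # small covariate effects on log-REM (standardised scales)
        "beta_age_per_sd": -0.10,
        "beta_male": 0.10,
        "beta_bmi_per_sd": 0.05,
    }


@dataclass
class CohortSpec:
    """Generating parameters of a synthetic patient cohort.

    ``log_rem_effect`` is the true RWA-group difference in mean log-REM
    minutes (default 0.93, the unadjusted group contrast in the emulated
    cohort); ``noise_sd`` the residual SD on the log scale.
    """

    n_patients: int = 41
    p_rwa: float = 27.0 / 41.0
    log_rem_effect: float = 0.93
    noise_sd: float = 1.0
    covariate_marginals: dict = field(default_factory=_default_marginals)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.p_rwa <= 1:
            raise ValueError("p_rwa must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _trunc_normal(rng, n, m):
    return np.clip(rng.normal(m["mean"], m["sd"], n), m.get("lo", -np.inf), m.get("hi", np.inf))


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per patient: covariates, sleep metrics, RWA status.

    log-REM minutes are generated as
    ``baseline + effect x RWA + covariate terms + N(0, noise_sd)``;
    RWA-positive patients additionally get a positive ``rwa_pct`` drawn
    on the observed scale (log-normal, median ~17%).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    m = spec.covariate_marginals

    rwa = rng.random(n) < spec.p_rwa
    age = _trunc_normal(rng, n, m["age"])
    male = rng.random(n) < m["p_male"]
    bmi = _trunc_normal(rng, n, m["bmi"])

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:03d}" for i in range(n)],
            "rwa_positive": rwa,
            "age": age,
            "sex": np.where(male, "M", "F"),
            "bmi": bmi,
            "disease_duration": rng.lognormal(
                m["disease_duration"]["log_mean"], m["disease_duration"]["log_sd"], n
            ),
            "leed": rng.lognormal(m["leed"]["log_mean"], m["leed"]["log_sd"], n),
            "mmse": np.round(_trunc_normal(rng, n, m["mmse"])),
            "hoehn_yahr": np.round(_trunc_normal(rng, n, m["hoehn_yahr"]) * 2) / 2,
            "updrs3": rng.lognormal(m["updrs3"]["log_mean"], m["updrs3"]["log_sd"], n),
            "updrs4": np.round(_trunc_normal(rng, n, m["updrs4"])),
            "pdss2_motor_night": np.round(_trunc_normal(rng, n, m["pdss2_motor_night"])),
            "pdss2_nocturnal": np.maximum(
                rng.lognormal(
                    m["pdss2_nocturnal"]["log_mean"], m["pdss2_nocturnal"]["log_sd"], n
                ),
                m["pdss2_nocturnal"]["lo"],
            ),
            "pdss2_disturbed_sleep": np.round(
                _trunc_normal(rng, n, m["pdss2_disturbed_sleep"])
            ),
            "rbdsq": np.round(_trunc_normal(rng, n, m["rbdsq"])).astype(int),
            "bdi": np.round(_trunc_normal(rng, n, m["bdi"])).astype(int),
            "pfs": _trunc_normal(rng, n, m["pfs"]),
            "anxiety": np.round(_trunc_normal(rng, n, m["anxiety"])),
            "psychosis": np.round(_trunc_normal(rng, n, m["psychosis"]) * 2) / 2,
            "tst": _trunc_normal(rng, n, m["tst"]),
            "sleep_efficiency": _trunc_normal(rng, n, m["sleep_efficiency"]),
            "waso": rng.lognormal(m["waso"]["log_mean"], m["waso"]["log_sd"], n),
            "sol": rng.lognormal(m["sol"]["log_mean"], m["sol"]["log_sd"], n),
            "n3_min": _trunc_normal(rng, n, m["n3_min"]),
        }
    )
    df["pdss2_total"] = (
        df["pdss2_motor_night"] + df["pdss2_nocturnal"] + df["pdss2_disturbed_sleep"]
    )

    z_age = (age - m["age"]["mean"]) / m["age"]["sd"]
    z_bmi = (bmi - m["bmi"]["mean"]) / m["bmi"]["sd"]
    log_rem = (
        m["log_rem_baseline"]
        + spec.log_rem_effect * rwa
        + m["beta_age_per_sd"] * z_age
        + m["beta_male"] * male
        + m["beta_bmi_per_sd"] * z_bmi
        + rng.normal(0.0, spec.noise_sd, n)
    )
    df["rem_min"] = np.exp(log_rem)
    df["log_rem"] = log_rem
    df["nrem_min"] = np.maximum(df["tst"] - df["rem_min"], df["n3_min"])
    # observed RWA% on the device scale: 0 for negatives, log-normal otherwise
    df["rwa_pct"] = np.where(
        rwa, np.clip(rng.lognormal(math.log(17.0), 0.8, n), 0.1, 100.0), 0.0
    )
    return df
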