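"""Hypnogram container: one sleep stage per 30-s epoch.

Stage labels follow AASM nomenclature: W, N1, N2, N3, REM. A hypnogram is
the staging of one night; with a portable home device the recording span
stands in for the lights-off/lights-on markers unless they are given
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")
EPOCH_LEN_S = 30.0


@dataclass
class Hypnogram:
    """Per-epoch stage sequence for one night.

    Parameters
    ----------
    stages
        Sequence of stage labels, one per 30-s epoch, drawn from
        ``{"W", "N1", "N2", "N3", "REM"}``.
    lights_off, lights_on
        Epoch ordinals delimiting time in bed. Default: the whole recording.
    """

    stages: np.ndarray
    lights_off: int = 0
    lights_on: int | None = None
    epoch_len: float = field(default=EPOCH_LEN_S)

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        if self.stages.ndim != 1 or self.stages.size == 0:
            raise ValueError("hypnogram needs a non-empty 1-D stage sequence")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        if self.lights_on is None:
            self.lights_on = self.stages.size
        if not (0 <= self.lights_off < self.lights_on <= self.stages.size):
            raise ValueError(
                f"lights_off/lights_on ({self.lights_off}, {self.lights_on}) "
                f"must satisfy 0 <= off < on <= {self.stages.size}"
            )
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.stages.size)

    @property
    def duration_min(self) -> float:
        return self.n_epochs * self.epoch_len / 60.0

    @property
    def rem_indices(self) -> np.ndarray:
        """Epoch ordinals staged REM, over the whole recording."""
        return np.flatnonzero(self.stages == "REM")

    @property
    def n_rem_epochs(self) -> int:
        return int(self.rem_indices.size)

    def epoch_bounds_s(self, index: int) -> tuple[float, float]:
        """(start, end) of an epoch in seconds from recording start."""
        return index * self.epoch_len, (index + 1) * self.epoch_len

    # -- CSV interchange: columns epoch_index (0-based), stage -----------

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"epoch_index": np.arange(self.n_epochs), "stage": self.stages}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "Hypnogram":
        df = pd.read_csv(path)
        if not {"epoch_index", "stage"} <= set(df.columns):
            raise ValueError("hypnogram CSV needs columns epoch_index, stage")
        df = df.sort_values("epoch_index")
        if not np.array_equal(df["epoch_index"].to_numpy(), np.arange(len(df))):
            raise ValueError("epoch_index must be contiguous starting at 0")
        return cls(df["stage"].to_numpy(dtype=object), **kwargs)
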