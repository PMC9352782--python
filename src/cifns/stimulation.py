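"""Stimulation protocol and current-level / charge-level arithmetic.

The device reports stimulation current in manufacturer current units (CU)
and charge in charge units (QU, 1 QU approximately 1 nC).  For biphasic
pulses the charge per phase is

    charge_qu = current_cu * phase_duration_us / 1000

a scaling verified empirically against every printed CU/QU pair of the
study protocol (it is not datasheet-sourced).  Display values are rounded
half-up to 3 decimals, matching the printed tables; raw values are kept
for computation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import NamedTuple, Sequence

import numpy as np

# Empirical CU*us -> QU scaling (1/1000); with the 150 us default phase this
# is the familiar x0.15 CU->QU factor.
QU_PER_CU_US = 1e-3

__all__ = [
    "QU_PER_CU_US",
    "StimulusSpec",
    "ChargeSummary",
    "charge_from_current",
    "display_round",
    "pulse_onsets",
    "summarize_charge_levels",
]


def display_round(value: float | Decimal, decimals: int = 3) -> float:
    """Half-up rounding in decimal arithmetic (matches the printed tables).

    Rounding the shortest decimal representation avoids float artefacts such
    as 311.85 * 0.15 = 46.77749999... rounding down instead of up.
    """
    d = value if isinstance(value, Decimal) else Decimal(repr(float(value)))
    q = Decimal(1).scaleb(-decimals)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def charge_from_current(current_level_cu: float, phase_duration_us: float = 150.0) -> float:
    """Charge per phase in QU for a given current level and phase duration.

    Returns the raw (unrounded) value; use :func:`display_round` for the
    3-decimal printed form.
    """
    if current_level_cu < 0:
        raise ValueError(f"current level must be non-negative, got {current_level_cu}")
    if phase_duration_us <= 0:
        raise ValueError(f"phase duration must be positive, got {phase_duration_us}")
    # exact in decimal for decimal inputs; float product only as fallback
    return float(
        Decimal(repr(float(current_level_cu)))
        * Decimal(repr(float(phase_duration_us)))
        / Decimal(1000)
    )


@dataclass(frozen=True)
class StimulusSpec:
    """Stimulation protocol: cathodic-leading biphasic pulses, monopolar mode.

    Defaults follow the intraoperative protocol: 150 us phases, 2.1 us
    interphase gap, trains of 2 pulses at 100 pulses per second.
    """

    current_level_cu: float = 378.0
    phase_duration_us: float = 150.0
    interphase_gap_us: float = 2.1
    pulses_per_train: int = 2
    rate_pps: float = 100.0
    polarity: str = "cathodic-leading-biphasic"
    mode: str = "monopolar"

    def __post_init__(self) -> None:
        if self.current_level_cu < 0:
            raise ValueError("current level must be non-negative")
        if self.phase_duration_us <= 0:
            raise ValueError("phase duration must be positive")
        if self.pulses_per_train < 1:
            raise ValueError("pulses_per_train must be >= 1")
        if self.rate_pps <= 0:
            raise ValueError("rate_pps must be positive")

    @property
    def charge_level_qu(self) -> float:
        return charge_from_current(self.current_level_cu, self.phase_duration_us)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["charge_level_qu"] = self.charge_level_qu
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpec":
        d = {k: v for k, v in d.items() if k != "charge_level_qu"}
        return cls(**d)


def pulse_onsets(spec: StimulusSpec) -> np.ndarray:
    """Protocol onset times in ms: k / rate_pps seconds for each pulse in the train."""
    return np.arange(spec.pulses_per_train) * 1000.0 / spec.rate_pps


class ChargeSummary(NamedTuple):
    min_qu: float
    max_qu: float
    mean_qu: float


def summarize_charge_levels(levels_qu: Sequence[float]) -> ChargeSummary:
    """Arithmetic min/max/mean of a set of charge levels (raw, unrounded)."""
    if len(levels_qu) == 0:
        raise ValueError("cannot summarize an empty list of charge levels")
    arr = [float(x) for x in levels_qu]
    return ChargeSummary(min(arr), max(arr), sum(arr) / len(arr))
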