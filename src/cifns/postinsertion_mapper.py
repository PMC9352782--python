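"""Per-contact EMG mapping after full insertion, peak detection at the 75%
normalized-amplitude threshold, and the concordance / rank-correlation
analysis against radiological EFND profiles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import EfndProfile
from .signal_processing import (
    average_repeats,
    extract_response_amplitude,
    normalize_profile,
)
from .synthetic_emg import EmgTrace

DEFAULT_PEAK_THRESHOLD = 0.75

__all__ = [
    "DEFAULT_PEAK_THRESHOLD",
    "ContactEmgProfile",
    "ConcordanceRecord",
    "PooledCorrelation",
    "build_contact_profile",
    "select_measurement_run",
    "detect_peak_contacts",
    "concordance_with_efnd",
    "spearman_rho",
    "pooled_efnd_emg_analysis",
]


@dataclass
class ContactEmgProfile:
    """Normalized per-contact EMG amplitudes of a fully inserted array.

    ``raw_uv`` / ``normalized`` map channel label to arrays aligned with
    ``contacts`` (ascending, apical to basal).  Exactly one contact per
    channel carries the normalized value 1.0 unless raw maxima tie, in
    which case all tied contacts are retained.
    """

    label: str
    contacts: list[int]
    raw_uv: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    current_cu: float | None = None
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, y in self.normalized.items():
            y = np.asarray(y, dtype=float)
            if y.min() != 0.0 or y.max() != 1.0:
                raise ValueError(f"channel {ch}: normalized profile must span [0, 1]")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.raw_uv)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ch in self.channels:
            for i, c in enumerate(self.contacts):
                rows.append(
                    {
                        "contact": int(c),
                        "channel": ch,
                        "amplitude_uv": float(self.raw_uv[ch][i]),
                        "normalized": float(self.normalized[ch][i]),
                    }
                )
        return pd.DataFrame(rows)


def build_contact_profile(
    sweep: Mapping[int, EmgTrace],
    label: str = "",
    blank_ms: tuple[float, float] | None = None,
    window_ms: tuple[float, float] | None = None,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD,
) -> ContactEmgProfile:
    """Extract and normalize a per-contact amplitude profile from a
    post-insertion sweep (contact number -> trace)."""
    contacts = sorted(sweep)
    kwargs = {}
    if blank_ms is not None:
        kwargs["blank_ms"] = blank_ms
    if window_ms is not None:
        kwargs["window_ms"] = window_ms
    raw: dict[str, list[float]] = {}
    current = None
    for c in contacts:
        trace = sweep[c]
        current = trace.stimulus.current_level_cu
        meas = extract_response_amplitude(
            average_repeats(trace.epochs()), sampling_rate_hz=trace.sampling_rate_hz, **kwargs
        )
        for ch, a in meas.amplitude_uv.items():
            raw.setdefault(ch, []).append(a)
    normalized = {ch: normalize_profile(v) for ch, v in raw.items()}
    return ContactEmgProfile(
        label=label,
        contacts=contacts,
        raw_uv={ch: np.asarray(v) for ch, v in raw.items()},
        normalized=normalized,
        current_cu=current,
        peak_threshold=peak_threshold,
    )


def select_measurement_run(
    sweeps_by_current: Mapping[float, Mapping[int, EmgTrace]],
    channel: str = "perioral",
    criterion: float = 8.0,
) -> float:
    """Pick the stimulation level to analyse from multiple measurement runs.

    Returns the lowest current level whose sweep has an above-noise
    response (peak-to-peak > ``criterion`` x noise-floor SD) on every
    contact — a documented proxy for choosing the run with the best
    spatial differentiation.  Falls back to the highest tested level if no
    run qualifies.
    """
    if not sweeps_by_current:
        raise ValueError("no measurement runs supplied")
    for current in sorted(sweeps_by_current):
        sweep = sweeps_by_current[current]
        ok = True
        for trace in sweep.values():
            meas = extract_response_amplitude(
                average_repeats(trace.epochs()), sampling_rate_hz=trace.sampling_rate_hz
            )
            if meas.amplitude_uv[channel] <= criterion * meas.noise_floor_uv[channel]:
                ok = False
                break
        if ok:
            return current
    return max(sweeps_by_current)


def detect_peak_contacts(
    profile: ContactEmgProfile, channel: str, threshold: float = DEFAULT_PEAK_THRESHOLD
) -> set[int]:
    """Contacts whose normalized amplitude reaches the threshold (default 75%).

    The argmax contact always qualifies (1.0 >= threshold for thresholds
    <= 1), so the set is never empty.
    """
    y = np.asarray(profile.normalized[channel], dtype=float)
    return {int(c) for c, v in zip(profile.contacts, y) if v >= threshold}


def _match_class(peaks: set[int], argmin_contact: int) -> str:
    if argmin_contact in peaks:
        return "exact"
    if (argmin_contact - 1) in peaks or (argmin_contact + 1) in peaks:
        return "neighbor"
    return "none"


def concordance_with_efnd(peaks: set[int], efnd: EfndProfile) -> str:
    """Grade a peak-contact set against the shortest-EFND contact.

    "exact" if the argmin contact is in the peak set, "neighbor" if an
    adjacent contact (+/- 1 in array topology) is, else "none".
    """
    if not peaks:
        raise ValueError("peak set cannot be empty (the argmax contact always qualifies)")
    return _match_class(peaks, efnd.argmin_contact())


@dataclass(frozen=True)
class ConcordanceRecord:
    """Per-subject agreement between EMG peak contacts and the shortest EFND."""

    subject: str
    shortest_efnd_contact: int
    peaks_per_channel: dict[str, frozenset[int]]
    match_per_channel: dict[str, str]

    @classmethod
    def build(
        cls,
        subject: str,
        profile: ContactEmgProfile,
        efnd: EfndProfile,
        threshold: float = DEFAULT_PEAK_THRESHOLD,
    ) -> "ConcordanceRecord":
        peaks = {
            ch: frozenset(detect_peak_contacts(profile, ch, threshold))
            for ch in profile.channels
        }
        return cls(
            subject=subject,
            shortest_efnd_contact=efnd.argmin_contact(),
            peaks_per_channel=peaks,
            match_per_channel={
                ch: concordance_with_efnd(set(p), efnd) for ch, p in peaks.items()
            },
        )


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    df: int  # n - 2, as reported alongside the correlation


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Two-sided p-value from the large-sample t approximation with n - 2
    degrees of freedom.  All-tied input has no defined rank order and
    raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 4:
        raise ValueError("need at least 4 pairs for a meaningful rank correlation")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("rank correlation undefined for an all-tied variable")
    rho, p = stats.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), df=int(x.size - 2))


class PooledCorrelation(NamedTuple):
    rho: float
    p_value: float
    n: int
    slope: float  # descriptive linear-fit slope (normalized amplitude per mm)


def pooled_efnd_emg_analysis(
    pairs: Sequence[tuple[ContactEmgProfile, EfndProfile]],
) -> dict[str, PooledCorrelation]:
    """Pool (EFND, normalized amplitude) points across subjects, per channel.

    Each subject contributes one point per contact and channel.  Returns
    the pooled Spearman correlation and a descriptive least-squares slope.
    """
    if not pairs:
        raise ValueError("no subject data to pool")
    channels = pairs[0][0].channels
    out: dict[str, PooledCorrelation] = {}
    for ch in channels:
        efnds: list[float] = []
        amps: list[float] = []
        for profile, efnd in pairs:
            for i, c in enumerate(profile.contacts):
                if c not in efnd.distances:
                    raise ValueError(
                        f"{profile.label}: contact {c} missing from EFND profile"
                    )
                efnds.append(efnd.distances[c])
                amps.append(float(profile.normalized[ch][i]))
        res = spearman_rho(efnds, amps)
        slope = float(np.polyfit(efnds, amps, 1)[0])
        out[ch] = PooledCorrelation(
            rho=res.rho, p_value=res.p_value, n=len(efnds), slope=slope
        )
    return out
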