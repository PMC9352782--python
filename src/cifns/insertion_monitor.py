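"""Real-time insertion tracking: amplitude vs number of inserted contacts.

During stepwise insertion the most apical contact stimulates at every
pause; the evoked amplitude rises as it approaches the facial nerve and
falls after passing it.  This module extracts that profile, locates the
passage peak, converts it to the estimated final tip position
P = 12 - N_inserted, flags a terminal amplitude re-rise (second approach
of the tip in the mid turn, a tip fold-over surrogate), and grades the
estimate against a radiological EFND profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .geometry import EfndProfile, apical_position_estimate
from .signal_processing import (
    average_repeats,
    extract_response_amplitude,
    normalize_profile,
)
from .synthetic_emg import EmgTrace

DEFAULT_RERISE_MARGIN = 0.2

__all__ = [
    "DEFAULT_RERISE_MARGIN",
    "InsertionTrack",
    "PassagePeak",
    "TerminalRise",
    "track_insertion",
    "locate_passage_peak",
    "detect_terminal_rise",
    "compare_P_to_efnd",
]


@dataclass
class InsertionTrack:
    """Per-step amplitudes of one stepwise-insertion run.

    ``raw_uv`` and ``normalized`` map channel label to arrays aligned with
    ``steps`` (numbers of inserted contacts, strictly increasing).
    Normalization is min-max per channel across the whole run.
    """

    steps: np.ndarray
    raw_uv: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    step_size: int
    current_cu: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=int)
        if not np.all(np.diff(self.steps) > 0):
            raise ValueError("n_inserted must be strictly increasing")
        if self.steps[-1] > 12:
            raise ValueError("final n_inserted cannot exceed 12")
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
            for i, n in enumerate(self.steps):
                rows.append(
                    {
                        "n_inserted": int(n),
                        "channel": ch,
                        "amplitude_uv": float(self.raw_uv[ch][i]),
                        "normalized": float(self.normalized[ch][i]),
                    }
                )
        return pd.DataFrame(rows)


def track_insertion(
    recording: Sequence[tuple[int, EmgTrace]],
    blank_ms: tuple[float, float] | None = None,
    window_ms: tuple[float, float] | None = None,
) -> InsertionTrack:
    """Extract and normalize per-step amplitudes from a stepwise recording.

    Epochs within each step's trace are averaged before the peak-to-peak
    measurement; normalization is per channel across the run.
    """
    if len(recording) < 2:
        raise ValueError("need at least two insertion steps to build a track")
    steps = [int(n) for n, _ in recording]
    kwargs = {}
    if blank_ms is not None:
        kwargs["blank_ms"] = blank_ms
    if window_ms is not None:
        kwargs["window_ms"] = window_ms
    raw: dict[str, list[float]] = {}
    for _, trace in recording:
        meas = extract_response_amplitude(
            average_repeats(trace.epochs()), sampling_rate_hz=trace.sampling_rate_hz, **kwargs
        )
        for ch, a in meas.amplitude_uv.items():
            raw.setdefault(ch, []).append(a)
    normalized = {ch: normalize_profile(v) for ch, v in raw.items()}
    diffs = np.diff(steps)
    step_size = int(diffs.min()) if len(diffs) else 0
    first_trace = recording[0][1]
    return InsertionTrack(
        steps=np.asarray(steps),
        raw_uv={ch: np.asarray(v) for ch, v in raw.items()},
        normalized=normalized,
        step_size=step_size,
        current_cu=first_trace.stimulus.current_level_cu,
    )


class TerminalRise(NamedTuple):
    detected: bool
    magnitude: float  # normalized rise of the final step above the post-peak minimum


def detect_terminal_rise(
    track: InsertionTrack, channel: str, margin: float = DEFAULT_RERISE_MARGIN
) -> TerminalRise:
    """Flag a renewed amplitude rise at the final insertion step.

    True iff, after the (pre-final) peak and a decline, the final step's
    normalized amplitude exceeds the post-peak minimum by at least
    ``margin`` normalized units.
    """
    y = np.asarray(track.normalized[channel], dtype=float)
    if len(y) < 3:
        raise ValueError("need at least three steps to assess a terminal rise")
    peak = int(np.argmax(y[:-1]))
    post = y[peak:-1]
    trough = float(post.min())
    magnitude = float(y[-1] - trough)
    declined = trough < y[peak]
    return TerminalRise(detected=bool(declined and magnitude >= margin), magnitude=magnitude)


class PassagePeak(NamedTuple):
    n_inserted: int
    position_estimate: int
    in_contact_range: bool
    terminal_rise_excluded: bool


def locate_passage_peak(
    track: InsertionTrack,
    channel: str,
    exclude_terminal_rise: bool = True,
    rerise_margin: float = DEFAULT_RERISE_MARGIN,
) -> PassagePeak:
    """Insertion step with maximal normalized amplitude, and P = 12 - n*.

    Ties take the earliest step (conservative depth estimate).  When the
    global maximum falls on the final step but the profile shows a terminal
    re-rise after an earlier peak-and-decline, the final step is excluded
    from the search: that re-rise marks the tip's second approach in the
    mid turn, not the passage peak.
    """
    y = np.asarray(track.normalized[channel], dtype=float)
    excluded = False
    search = y
    if exclude_terminal_rise and len(y) >= 3:
        rise = detect_terminal_rise(track, channel, margin=rerise_margin)
        if rise.detected and int(np.argmax(y)) == len(y) - 1:
            search = y[:-1]
            excluded = True
    idx = int(np.argmax(search))  # argmax takes the first occurrence on ties
    n_star = int(track.steps[idx])
    est = apical_position_estimate(n_star)
    return PassagePeak(
        n_inserted=n_star,
        position_estimate=est.position,
        in_contact_range=est.in_contact_range,
        terminal_rise_excluded=excluded,
    )


def _match_class(p: int, argmin_contact: int) -> str:
    if p == argmin_contact:
        return "exact"
    if abs(p - argmin_contact) == 1:
        return "neighbor"
    return "none"


def compare_P_to_efnd(
    p_per_channel: dict[str, int], efnd: EfndProfile
) -> dict[str, str]:
    """Grade the per-channel P estimates against the shortest-EFND contact.

    "exact" if P equals the argmin contact, "neighbor" if one contact off
    (step size 2 makes odd contact numbers unreachable by P), else "none".
    """
    argmin = efnd.argmin_contact()
    return {ch: _match_class(p, argmin) for ch, p in p_per_channel.items()}
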