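"""Scalar EMG response amplitudes from raw epochs, and profile normalization.

The response magnitude is the peak-to-peak voltage inside a response
window (default 1.5-15 ms after pulse onset) after discarding a blanking
window (default 0-1.5 ms) that contains the stimulation artifact.  The
noise floor is the sample SD of a quiet tail segment of the epoch.
Profiles (amplitude vs insertion step or vs contact) are min-max
normalized to [0, 1] per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic_emg import (
    CHANNELS,
    DEFAULT_SAMPLING_RATE_HZ,
    ForwardModelParams,
    synthesize_trace,
)
from .stimulation import StimulusSpec

DEFAULT_BLANK_MS = (0.0, 1.5)
DEFAULT_WINDOW_MS = (1.5, 15.0)
# Detection: response peak-to-peak > criterion x noise-floor SD.  The
# peak-to-peak of ~500 Gaussian noise samples concentrates near 6.2 SD, so a
# criterion must sit above that for the "just discernable" rule to have any
# rejection power; 8 SD keeps the false-positive rate low while detecting
# responses ~2 SD above the noise excursion.
DEFAULT_DETECTION_CRITERION = 8.0

__all__ = [
    "DEFAULT_BLANK_MS",
    "DEFAULT_WINDOW_MS",
    "DegenerateProfileError",
    "AmplitudeMeasurement",
    "average_repeats",
    "extract_response_amplitude",
    "normalize_profile",
    "detection_threshold_search",
]


class DegenerateProfileError(ValueError):
    """Raised when a profile carries no usable contrast (all values equal)."""


Epoch = Mapping[str, np.ndarray]


def average_repeats(epochs: Sequence[Epoch]) -> dict[str, np.ndarray]:
    """Pointwise mean of pulse-aligned epochs, per channel.

    All epochs must share channel labels and sample counts.
    """
    if len(epochs) == 0:
        raise ValueError("need at least one epoch to average")
    channels = tuple(epochs[0])
    out: dict[str, np.ndarray] = {}
    for ch in channels:
        arrays = []
        for i, ep in enumerate(epochs):
            if set(ep) != set(channels):
                raise ValueError(f"epoch {i} has channels {sorted(ep)} != {sorted(channels)}")
            x = np.asarray(ep[ch], dtype=float)
            if x.shape != np.asarray(epochs[0][ch]).shape:
                raise ValueError(f"epoch {i} channel {ch}: mismatched length")
            arrays.append(x)
        out[ch] = np.mean(arrays, axis=0)
    return out


@dataclass(frozen=True)
class AmplitudeMeasurement:
    """Peak-to-peak response amplitude per channel plus the analysis windows."""

    amplitude_uv: dict[str, float]
    noise_floor_uv: dict[str, float]
    blank_ms: tuple[float, float]
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if self.blank_ms[1] > self.window_ms[0]:
            raise ValueError("blanking window must precede the response window")
        for ch, a in self.amplitude_uv.items():
            if a < 0:
                raise ValueError(f"negative amplitude for {ch}")


def extract_response_amplitude(
    epoch: Epoch,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
    blank_ms: tuple[float, float] = DEFAULT_BLANK_MS,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
    noise_tail_fraction: float = 0.15,
) -> AmplitudeMeasurement:
    """Peak-to-peak amplitude inside the response window, per channel.

    Samples inside the blanking window are excluded (stimulation-artifact
    rejection); the noise floor is the SD of the trailing
    ``noise_tail_fraction`` of the epoch.
    """
    if blank_ms[1] > window_ms[0]:
        raise ValueError("blanking window must precede the response window")
    n = len(next(iter(epoch.values())))
    t = np.arange(n) * 1000.0 / sampling_rate_hz
    epoch_ms = n * 1000.0 / sampling_rate_hz
    if window_ms[1] > epoch_ms or window_ms[0] < 0:
        raise ValueError(
            f"response window {window_ms} ms outside epoch of {epoch_ms:.3f} ms"
        )
    in_window = (t >= window_ms[0]) & (t <= window_ms[1])
    tail = t >= (1.0 - noise_tail_fraction) * epoch_ms
    amplitude, noise = {}, {}
    for ch, x in epoch.items():
        x = np.asarray(x, dtype=float)
        seg = x[in_window]
        amplitude[ch] = float(seg.max() - seg.min())
        noise[ch] = float(np.std(x[tail]))
    return AmplitudeMeasurement(
        amplitude_uv=amplitude, noise_floor_uv=noise, blank_ms=blank_ms, window_ms=window_ms
    )


def normalize_profile(amplitudes: Sequence[float]) -> np.ndarray:
    """Min-max normalize: lowest response -> 0, highest -> 1, order preserved.

    Raises :class:`DegenerateProfileError` for all-equal input (no contrast
    to normalize; the analysis cannot proceed on such a profile).
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two values to normalize")
    lo, hi = a.min(), a.max()
    if hi == lo:
        raise DegenerateProfileError("all amplitudes equal; normalized profile undefined")
    return (a - lo) / (hi - lo)


def detection_threshold_search(
    distance_mm: float,
    params: ForwardModelParams,
    start_cu: float,
    step_cu: float,
    ceiling_cu: float = 2000.0,
    channel: str = "perioral",
    criterion: float = DEFAULT_DETECTION_CRITERION,
    rng: np.random.Generator | int | None = None,
    stim: StimulusSpec | None = None,
) -> float | None:
    """Smallest tested current whose extracted response clears the noise floor.

    Automated stand-in for the intraoperative rule of slowly raising the
    current until a response is just discernable from background noise:
    scans ``start_cu, start_cu + step_cu, ...`` up to ``ceiling_cu`` and
    returns the first current whose averaged-epoch peak-to-peak amplitude
    exceeds ``criterion`` times the noise-floor SD.  Returns ``None`` if no
    current up to the ceiling is detectable.
    """
    from .synthetic_emg import cmap_amplitude  # local to avoid cycle at import time

    if step_cu <= 0:
        raise ValueError("step_cu must be positive")
    rng = np.random.default_rng(rng)
    stim = stim or StimulusSpec()
    current = start_cu
    while current <= ceiling_cu + 1e-9:
        amps = {ch: cmap_amplitude(current, distance_mm, params, ch) for ch in CHANNELS}
        # per-current child stream: an exhaustive scan with the same base
        # seed reproduces each measurement exactly
        child = np.random.default_rng(int(rng.integers(2**31)))
        trace = synthesize_trace(stim, amps, params, rng=child)
        meas = extract_response_amplitude(
            average_repeats(trace.epochs()), sampling_rate_hz=trace.sampling_rate_hz
        )
        if meas.amplitude_uv[channel] > criterion * meas.noise_floor_uv[channel]:
            return current
        current += step_cu
    return None
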