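"""Synthetic stimulus-locked facial-muscle EMG.

Generates two-channel (periocular / perioral) evoked-EMG epochs with the
statistical structure the downstream analysis assumes:

* CMAP amplitude grows with stimulation current and shrinks with the
  distance between the stimulating contact and the facial nerve, via a
  quadratic strength--distance threshold law and a sigmoidal recruitment
  curve;
* each pulse leaves a decaying-exponential stimulation artifact at its
  onset, several times larger on the periocular channel;
* the perioral CMAP is a multiple of the periocular one;
* additive Gaussian noise, independent between channels.

Traces are sampled at 38.4 kHz by default.  Each pulse of a train gets its
own clean epoch (default 20 ms) and epochs are stored back-to-back in one
trace; the protocol pulse timing (e.g. 100 pps) lives in the attached
:class:`~cifns.stimulation.StimulusSpec`, the storage epoch onsets in
``epoch_onsets_ms``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .geometry import (
    CochlearSpiralModel,
    ElectrodeArraySpec,
    FacialNerveLocus,
    efnd_profile,
)
from .stimulation import StimulusSpec

CHANNELS = ("periocular", "perioral")
DEFAULT_SAMPLING_RATE_HZ = 38400.0

__all__ = [
    "CHANNELS",
    "DEFAULT_SAMPLING_RATE_HZ",
    "ForwardModelParams",
    "EmgTrace",
    "cmap_amplitude",
    "threshold_current",
    "synthesize_trace",
    "simulate_insertion_experiment",
    "simulate_postinsertion_sweep",
]


@dataclass(frozen=True)
class ForwardModelParams:
    """Parameters of the distance/current -> CMAP forward model.

    The facial-nerve stimulation threshold follows the classic quadratic
    strength--distance law ``I_th(d) = I0 * (1 + (d/d0)^2)`` and the evoked
    amplitude a sigmoidal recruitment curve around it::

        A(I, d) = A_max * sigmoid(k * (I - I_th(d)) / I_th(d))

    ``cmap_amplitude_uv`` and ``artifact_amplitude_uv`` are per-channel
    peak(-to-peak) scales; the default asymmetry (perioral CMAP x5,
    periocular artifact x10) mirrors the recorded channel asymmetry.
    CMAP latency/duration defaults are plausible placeholders for facial
    muscles, not literature-fitted values.
    """

    base_threshold_cu: float = 300.0        # I0: threshold at zero distance
    distance_scale_mm: float = 3.0          # d0: strength-distance curvature
    recruitment_steepness: float = 6.0      # k
    cmap_amplitude_uv: Mapping[str, float] = field(
        default_factory=lambda: {"periocular": 100.0, "perioral": 500.0}
    )
    artifact_amplitude_uv: Mapping[str, float] = field(
        default_factory=lambda: {"periocular": 2000.0, "perioral": 200.0}
    )
    artifact_decay_ms: float = 0.15
    cmap_latency_ms: float = 3.0
    cmap_duration_ms: float = 5.0
    noise_sd_uv: float = 5.0
    epoch_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in ("base_threshold_cu", "distance_scale_mm", "recruitment_steepness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be non-negative")
        for ch in CHANNELS:
            if self.cmap_amplitude_uv[ch] <= 0 or self.artifact_amplitude_uv[ch] < 0:
                raise ValueError(f"bad amplitude parameters for channel {ch}")
        # CMAP must start after the artifact has decayed (>= 5 time constants)
        if self.cmap_latency_ms <= 5 * self.artifact_decay_ms:
            raise ValueError("cmap_latency_ms must exceed the artifact decay window")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cmap_amplitude_uv"] = dict(self.cmap_amplitude_uv)
        d["artifact_amplitude_uv"] = dict(self.artifact_amplitude_uv)
        return d


def threshold_current(distance_mm: float, params: ForwardModelParams) -> float:
    """Strength-distance stimulation threshold I_th(d) = I0 (1 + (d/d0)^2), in CU."""
    if distance_mm <= 0:
        raise ValueError(f"distance must be positive, got {distance_mm}")
    ratio = distance_mm / params.distance_scale_mm
    return params.base_threshold_cu * (1.0 + ratio * ratio)


def cmap_amplitude(
    current_cu: float,
    distance_mm: float,
    params: ForwardModelParams,
    channel: str = "periocular",
) -> float:
    """Evoked CMAP peak-to-peak amplitude in uV for one channel.

    Strictly increasing in current, strictly decreasing in distance.
    At I = I_th(d) the amplitude is exactly A_max / 2.
    """
    if current_cu < 0:
        raise ValueError(f"current must be non-negative, got {current_cu}")
    i_th = threshold_current(distance_mm, params)
    a_max = params.cmap_amplitude_uv[channel]
    return float(a_max * expit(params.recruitment_steepness * (current_cu - i_th) / i_th))


@dataclass
class EmgTrace:
    """One stimulus-locked two-channel recording.

    ``samples_uv`` maps channel label to a float array; all channels have
    ``round(sampling_rate_hz * duration_ms / 1000)`` samples.  Pulse epochs
    of ``epoch_ms`` each start at ``epoch_onsets_ms``.
    """

    sampling_rate_hz: float
    duration_ms: float
    samples_uv: dict[str, np.ndarray]
    stimulus: StimulusSpec
    epoch_onsets_ms: list[float]
    epoch_ms: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = round(self.sampling_rate_hz * self.duration_ms / 1000.0)
        for ch, x in self.samples_uv.items():
            if len(x) != n:
                raise ValueError(
                    f"channel {ch}: {len(x)} samples, expected {n} "
                    f"({self.sampling_rate_hz} Hz x {self.duration_ms} ms)"
                )

    @property
    def n_samples(self) -> int:
        return round(self.sampling_rate_hz * self.duration_ms / 1000.0)

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.samples_uv)

    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz

    def epochs(self) -> list[dict[str, np.ndarray]]:
        """Split into per-pulse epochs (equal length, one per stored onset)."""
        n_ep = round(self.sampling_rate_hz * self.epoch_ms / 1000.0)
        out = []
        for onset in self.epoch_onsets_ms:
            i0 = round(onset * self.sampling_rate_hz / 1000.0)
            out.append({ch: x[i0 : i0 + n_ep] for ch, x in self.samples_uv.items()})
        return out

    def to_tsv(self, path: str | Path) -> None:
        """Write samples as TSV plus a JSON sidecar with the metadata."""
        path = Path(path)
        df = pd.DataFrame({"time_ms": self.time_ms()})
        for ch in self.channels:
            df[f"{ch}_uv"] = self.samples_uv[ch]
        df.to_csv(path, sep="\t", index=False)
        meta = {
            "sampling_rate_hz": self.sampling_rate_hz,
            "duration_ms": self.duration_ms,
            "epoch_onsets_ms": self.epoch_onsets_ms,
            "epoch_ms": self.epoch_ms,
            "stimulus": self.stimulus.to_dict(),
            "provenance": self.provenance,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmgTrace":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        df = pd.read_csv(path, sep="\t")
        samples = {
            col[: -len("_uv")]: df[col].to_numpy(dtype=float)
            for col in df.columns
            if col.endswith("_uv")
        }
        return cls(
            sampling_rate_hz=meta["sampling_rate_hz"],
            duration_ms=meta["duration_ms"],
            samples_uv=samples,
            stimulus=StimulusSpec.from_dict(meta["stimulus"]),
            epoch_onsets_ms=meta["epoch_onsets_ms"],
            epoch_ms=meta["epoch_ms"],
            provenance=meta.get("provenance", {}),
        )


def _cmap_wavelet(t_ms: np.ndarray, latency_ms: float, duration_ms: float) -> np.ndarray:
    """Zero-mean biphasic waveform (Gaussian first derivative), unit peak-to-peak."""
    sigma = duration_ms / 6.0
    u = (t_ms - latency_ms) / sigma
    w = -u * np.exp(-0.5 * u * u)
    pp = w.max() - w.min()
    return w / pp if pp > 0 else w


def synthesize_trace(
    stim: StimulusSpec,
    amplitude_per_channel: Mapping[str, float],
    params: ForwardModelParams,
    rng: np.random.Generator | int | None = None,
    sampling_rate_hz: float = DEFAULT_SAMPLING_RATE_HZ,
) -> EmgTrace:
    """Synthesize one stimulus-locked trace (one epoch per pulse in the train).

    Each epoch contains a decaying-exponential stimulation artifact at its
    onset and a biphasic CMAP scaled to the requested peak-to-peak amplitude
    at ``onset + latency``, plus white Gaussian noise.
    """
    for ch, a in amplitude_per_channel.items():
        if a < 0:
            raise ValueError(f"amplitude for channel {ch} must be non-negative, got {a}")
    rng = np.random.default_rng(rng)
    n_epoch = round(sampling_rate_hz * params.epoch_ms / 1000.0)
    n_total = n_epoch * stim.pulses_per_train
    duration_ms = n_total * 1000.0 / sampling_rate_hz
    t_epoch = np.arange(n_epoch) * 1000.0 / sampling_rate_hz
    artifact_shape = np.exp(-t_epoch / params.artifact_decay_ms)
    cmap_shape = _cmap_wavelet(t_epoch, params.cmap_latency_ms, params.cmap_duration_ms)

    samples: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        epoch = (
            params.artifact_amplitude_uv[ch] * artifact_shape
            + amplitude_per_channel.get(ch, 0.0) * cmap_shape
        )
        x = np.tile(epoch, stim.pulses_per_train)
        if params.noise_sd_uv > 0:
            x = x + rng.normal(0.0, params.noise_sd_uv, size=n_total)
        samples[ch] = x

    onsets = [k * params.epoch_ms for k in range(stim.pulses_per_train)]
    return EmgTrace(
        sampling_rate_hz=sampling_rate_hz,
        duration_ms=duration_ms,
        samples_uv=samples,
        stimulus=stim,
        epoch_onsets_ms=onsets,
        epoch_ms=params.epoch_ms,
        provenance={
            "generator": "cifns.synthetic_emg",
            "amplitude_per_channel": dict(amplitude_per_channel),
            "params": params.to_dict(),
        },
    )


def _amplitudes_at_distance(
    current_cu: float, distance_mm: float, params: ForwardModelParams
) -> dict[str, float]:
    return {ch: cmap_amplitude(current_cu, distance_mm, params, ch) for ch in CHANNELS}


def insertion_schedule(step: int, n_contacts: int = 12) -> list[int]:
    """Stepwise-insertion schedule: step, 2*step, ... plus the full insertion."""
    if step < 1:
        raise ValueError("step must be >= 1")
    ns = list(range(step, n_contacts + 1, step))
    if not ns or ns[-1] != n_contacts:
        ns.append(n_contacts)
    return ns


def simulate_insertion_experiment(
    spec: ElectrodeArraySpec,
    model: CochlearSpiralModel,
    fn: FacialNerveLocus,
    params: ForwardModelParams,
    current_cu: float,
    step: int = 2,
    rng: np.random.Generator | int | None = None,
    stim: StimulusSpec | None = None,
) -> list[tuple[int, EmgTrace]]:
    """Simulate the stepwise-insertion protocol.

    At every pause (``step``, ``2*step``, ... contacts inserted) the most
    apical contact stimulates at ``current_cu``; its EFND at that partial
    insertion sets the evoked amplitude.
    """
    rng = np.random.default_rng(rng)
    stim = stim or StimulusSpec(current_level_cu=current_cu)
    stim = replace(stim, current_level_cu=current_cu)
    out = []
    for n in insertion_schedule(step, spec.n_contacts):
        tip_efnd = efnd_profile(spec, model, fn, n_inserted=n).distances[1]
        amps = _amplitudes_at_distance(current_cu, tip_efnd, params)
        trace = synthesize_trace(stim, amps, params, rng=rng)
        trace.provenance.update({"n_inserted": n, "tip_efnd_mm": tip_efnd})
        out.append((n, trace))
    return out


def simulate_postinsertion_sweep(
    spec: ElectrodeArraySpec,
    model: CochlearSpiralModel,
    fn: FacialNerveLocus,
    params: ForwardModelParams,
    current_cu: float,
    rng: np.random.Generator | int | None = None,
    stim: StimulusSpec | None = None,
) -> dict[int, EmgTrace]:
    """Simulate the post-insertion sweep: one trace per contact 1..12 of the
    fully inserted array, amplitude set by that contact's EFND."""
    rng = np.random.default_rng(rng)
    stim = stim or StimulusSpec(current_level_cu=current_cu)
    stim = replace(stim, current_level_cu=current_cu)
    profile = efnd_profile(spec, model, fn, n_inserted=spec.n_contacts)
    out: dict[int, EmgTrace] = {}
    for contact in profile.contacts:
        amps = _amplitudes_at_distance(current_cu, profile.distances[contact], params)
        trace = synthesize_trace(stim, amps, params, rng=rng)
        trace.provenance.update(
            {"contact": contact, "efnd_mm": profile.distances[contact]}
        )
        out[contact] = trace
    return out
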