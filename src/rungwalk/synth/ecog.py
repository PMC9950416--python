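"""Synthetic multichannel ECoG with camera-strobe synchronization.

Step-contact events with the contralateral paw inject a condition-
dependent evoked-potential template on the anterior channels; the
default templates follow the observed responses: a −100 uV negativity
peaking 10 ms after contact on stable steps, and a much larger −300 uV
negativity peaking at 70 ms, followed by a slow positive rebound, on
unstable steps.  Ipsilateral contacts inject nothing (configurable
attenuation).  A square-wave strobe at the camera frame rate with
per-frame hardware counters, and per-step load-cell traces (half-sine
contact pulses), are generated alongside so the full synchronization
path can be exercised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Number of samples of waveform tail kept after the template window.
_TEMPLATE_SPAN_MS = 600.0


@dataclass(frozen=True)
class EpTemplate:
    """Evoked-potential template: a Gaussian negativity plus an optional
    delayed alpha-function rebound.

    The rebound begins ``3 * width_ms`` after the peak latency so that
    the noise-free waveform value at ``latency_ms`` equals
    ``amplitude_uv`` exactly.
    """

    amplitude_uv: float
    latency_ms: float
    width_ms: float
    rebound_uv: float = 0.0
    rebound_decay_ms: float = 200.0

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        v = self.amplitude_uv * np.exp(
            -((t_ms - self.latency_ms) ** 2) / (2.0 * self.width_ms ** 2))
        if self.rebound_uv:
            t0 = self.latency_ms + 3.0 * self.width_ms
            tr = np.maximum(t_ms - t0, 0.0) / self.rebound_decay_ms
            v = v + self.rebound_uv * tr * np.exp(1.0 - tr) * (t_ms > t0)
        return v


def default_templates() -> dict[str, EpTemplate]:
    return {
        "stable": EpTemplate(-100.0, 10.0, 5.0),
        "unstable": EpTemplate(-300.0, 70.0, 10.0,
                               rebound_uv=300.0, rebound_decay_ms=200.0),
    }


@dataclass(frozen=True)
class EcogSimSpec:
    n_channels: int = 16
    sample_rate: float = 1000.0
    ep_templates: dict[str, EpTemplate] = field(default_factory=default_templates)
    noise_white_sd: float = 50.0      # uV
    noise_pink_sd: float = 0.0        # uV (1/f-power component)
    strobe_rate: float = 120.0
    frame_counter_start: int = 0
    n_anterior: int | None = None     # defaults to n_channels // 2
    ipsi_attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate <= 100.0:
            raise ValueError("sample_rate must exceed 2 x 50 Hz")
        if self.strobe_rate > self.sample_rate:
            raise ValueError("strobe_rate cannot exceed sample_rate")
        for tpl in self.ep_templates.values():
            if not np.isfinite([tpl.amplitude_uv, tpl.latency_ms,
                                tpl.width_ms]).all():
                raise ValueError("template parameters must be finite")

    @property
    def anterior_channels(self) -> np.ndarray:
        n = self.n_anterior if self.n_anterior is not None else self.n_channels // 2
        return np.arange(n)


@dataclass(frozen=True)
class StepFieldEvent:
    time_s: float
    side: str                 # "contra" | "ipsi"
    state: str                # "stable" | "unstable"
    step_index: int = 3


@dataclass(frozen=True)
class SimulatedEcog:
    samples: np.ndarray       # (C, T) uV
    sample_rate: float
    strobe: np.ndarray        # (T,) 0/1
    frame_counters: np.ndarray
    load: np.ndarray          # (n_steps, T)
    events: tuple[tuple[int, dict], ...]   # (frame_index, metadata)
    spec: EcogSimSpec


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int],
                rate: float) -> np.ndarray:
    """Unit-variance noise with 1/f power spectrum."""
    c, t = shape
    white = rng.standard_normal((c, t))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(t, 1.0 / rate)
    f[0] = f[1] if t > 1 else 1.0
    spec /= np.sqrt(f)
    pink = np.fft.irfft(spec, n=t, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def synthesize_ecog(events: list[StepFieldEvent],
                    spec: EcogSimSpec,
                    seed: int,
                    duration_s: float,
                    n_steps: int = 8) -> SimulatedEcog:
    """Simulate a recording containing the given step-contact events."""
    rng = np.random.default_rng(seed)
    rate = spec.sample_rate
    T = int(round(duration_s * rate))
    t = np.arange(T) / rate

    # strobe: high for the first half of each frame period; the falling
    # edge of frame f occurs at (f + 0.5) / strobe_rate
    phase = np.floor(t * spec.strobe_rate * 2.0).astype(np.int64)
    strobe = (phase % 2 == 0).astype(np.int8)
    edges = np.flatnonzero((strobe[:-1] == 1) & (strobe[1:] == 0)) + 1
    counters = spec.frame_counter_start + np.arange(len(edges))

    samples = rng.normal(0.0, spec.noise_white_sd, (spec.n_channels, T)) \
        if spec.noise_white_sd > 0 else np.zeros((spec.n_channels, T))
    if spec.noise_pink_sd > 0:
        samples = samples + spec.noise_pink_sd * _pink_noise(
            rng, (spec.n_channels, T), rate)

    load = np.zeros((n_steps, T))
    span = int(round(_TEMPLATE_SPAN_MS / 1000.0 * rate))
    tail_ms = np.arange(span) / rate * 1000.0
    anterior = spec.anterior_channels

    ev_meta: list[tuple[int, dict]] = []
    for ev in events:
        frame = int(np.floor(ev.time_s * spec.strobe_rate))
        if not 0 <= frame < len(edges):
            raise ValueError(
                f"event at {ev.time_s:.3f}s beyond recording duration")
        s0 = int(edges[frame])
        tpl = spec.ep_templates.get(ev.state)
        if tpl is None:
            raise KeyError(f"no template for condition {ev.state!r}")
        gain = 1.0 if ev.side == "contra" else spec.ipsi_attenuation
        if gain != 0.0:
            wave = gain * tpl.waveform(tail_ms)
            end = min(T, s0 + span)
            samples[np.ix_(anterior, np.arange(s0, end))] += wave[:end - s0]
        # load-cell half-sine pulse, 100 ms
        lspan = int(round(0.1 * rate))
        lend = min(T, s0 + lspan)
        load[ev.step_index, s0:lend] += np.sin(
            np.pi * np.arange(lend - s0) / lspan)
        ev_meta.append((frame, {"side": ev.side, "state": ev.state,
                                "step_index": ev.step_index}))

    return SimulatedEcog(samples, rate, strobe, counters, load,
                         tuple(ev_meta), spec)
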