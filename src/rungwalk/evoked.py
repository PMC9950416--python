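"""Frame-synchronized evoked-potential analysis.

The camera strobe is digitized alongside the ECoG so that each video
frame can be matched to a voltage sample: falling edges of the strobe
are paired with the per-frame hardware counters, dropped frames leave
explicit holes in the map rather than being interpolated.  Step-aligned
epochs (250 ms pre / 500 ms post the contact frame) are low-pass
filtered at 50 Hz with a 4th-order two-pass (zero-phase) Butterworth
filter, baselined by subtracting the mean of the 250 ms before the
event, averaged per condition (paw side x trial state), and
characterized by peak amplitude and latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _signal


# ---------------------------------------------------------------------------
# types

@dataclass(frozen=True)
class EcogRecording:
    samples: np.ndarray           # (C, T) uV
    sample_rate: float
    strobe: np.ndarray | None = None
    frame_counters: np.ndarray | None = None
    impedances: np.ndarray | None = None  # per channel, optional

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.asarray(self.samples).ndim != 2:
            raise ValueError("samples must be (channels, time)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


class FrameSampleMap:
    """Strictly increasing frame-index -> sample-index mapping with
    explicit holes for dropped frames."""

    def __init__(self, frames: np.ndarray, samples: np.ndarray) -> None:
        frames = np.asarray(frames, dtype=np.int64)
        samples = np.asarray(samples, dtype=np.int64)
        if len(frames) != len(samples):
            raise ValueError("frames and samples differ in length")
        if len(frames) and (np.any(np.diff(frames) <= 0)
                            or np.any(np.diff(samples) <= 0)):
            raise ValueError("map must be strictly increasing")
        self.frames = frames
        self.samples = samples
        self._lookup = dict(zip(frames.tolist(), samples.tolist()))

    def __len__(self) -> int:
        return len(self.frames)

    def __contains__(self, frame: int) -> bool:
        return frame in self._lookup

    def __getitem__(self, frame: int) -> int:
        return self._lookup[frame]

    def frame_of(self, sample: int) -> int:
        """Inverse lookup (exact); raises KeyError for unmapped samples."""
        i = np.searchsorted(self.samples, sample)
        if i < len(self.samples) and self.samples[i] == sample:
            return int(self.frames[i])
        raise KeyError(sample)


@dataclass(frozen=True)
class Epoch:
    data: np.ndarray              # (C, L) uV
    sample_rate: float
    pre_ms: float
    metadata: dict = field(default_factory=dict)

    @property
    def times_ms(self) -> np.ndarray:
        L = self.data.shape[1]
        return np.arange(L) / self.sample_rate * 1000.0 - self.pre_ms


@dataclass(frozen=True)
class Erp:
    condition: tuple
    mean: np.ndarray              # (C, L)
    n: int
    band: np.ndarray              # 95% pointwise interval half-width
    sample_rate: float
    pre_ms: float

    @property
    def times_ms(self) -> np.ndarray:
        L = self.mean.shape[1]
        return np.arange(L) / self.sample_rate * 1000.0 - self.pre_ms


@dataclass(frozen=True)
class PeakMeasure:
    amplitude_uv: float
    latency_ms: float
    polarity_matched: bool = True


# ---------------------------------------------------------------------------
# synchronization

def detect_falling_edges(strobe: np.ndarray) -> np.ndarray:
    """Sample indices of falling edges, thresholded at half the strobe
    range with a one-sample debounce."""
    s = np.asarray(strobe, dtype=np.float64)
    if s.size < 2:
        return np.empty(0, dtype=np.int64)
    thr = (s.min() + s.max()) / 2.0
    high = s >= thr
    edges = np.flatnonzero(high[:-1] & ~high[1:]) + 1
    if len(edges) > 1:
        edges = edges[np.concatenate([[True], np.diff(edges) > 1])]
    return edges.astype(np.int64)


def build_frame_sample_map(strobe: np.ndarray,
                           frame_counters: np.ndarray,
                           sample_rate: float,
                           counter_wrap: int = 2 ** 16) -> FrameSampleMap:
    """Pair each detected falling edge with its hardware frame counter.

    Counter wraparound is resolved by monotone unwrapping; missing
    counters (dropped frames) leave holes in the map.
    """
    edges = detect_falling_edges(strobe)
    counters = np.asarray(frame_counters, dtype=np.int64)
    if len(counters) > len(edges):
        raise ValueError(
            f"more frame counters ({len(counters)}) than detected strobe "
            f"edges ({len(edges)})")
    if len(counters) < len(edges):
        raise ValueError(
            f"fewer frame counters ({len(counters)}) than detected strobe "
            f"edges ({len(edges)})")
    if len(counters) == 0:
        return FrameSampleMap(counters, edges)
    unwrapped = counters.copy()
    offset = 0
    for i in range(1, len(unwrapped)):
        if counters[i] < counters[i - 1]:
            offset += counter_wrap
        unwrapped[i] = counters[i] + offset
    return FrameSampleMap(unwrapped, edges)


# ---------------------------------------------------------------------------
# epoching

def extract_epochs(recording: EcogRecording,
                   events: list[tuple[int, dict]],
                   fmap: FrameSampleMap,
                   pre_ms: float = 250.0,
                   post_ms: float = 500.0) -> list[Epoch]:
    """One epoch per admissible event (frame, metadata) pair.

    Events whose frame is unmapped or whose window would extend past
    the recording edges are skipped with a warning.
    """
    rate = recording.sample_rate
    n_pre = int(round(pre_ms / 1000.0 * rate))
    n_post = int(round(post_ms / 1000.0 * rate))
    epochs = []
    skipped = 0
    for frame, meta in events:
        if frame not in fmap:
            skipped += 1
            continue
        s0 = fmap[frame]
        lo, hi = s0 - n_pre, s0 + n_post
        if lo < 0 or hi > recording.n_samples:
            skipped += 1
            continue
        epochs.append(Epoch(recording.samples[:, lo:hi].copy(), rate,
                            pre_ms, dict(meta)))
    if skipped:
        warnings.warn(f"skipped {skipped} events (unmapped frame or window "
                      "outside recording)", stacklevel=2)
    if not epochs:
        raise ValueError("no admissible events")
    return epochs


def filter_epoch(epoch: Epoch, cutoff_hz: float = 50.0,
                 order: int = 4) -> Epoch:
    """Zero-phase (forward-backward) Butterworth low-pass.

    The effective magnitude response is the squared single-pass
    response; reflective padding (three filter lengths) suppresses edge
    transients in short epochs.
    """
    nyq = epoch.sample_rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = _signal.butter(order, cutoff_hz / nyq, btype="low")
    # at least three filter lengths of reflective padding
    padlen = min(9 * max(len(a), len(b)), epoch.data.shape[1] - 1)
    data = _signal.filtfilt(b, a, epoch.data, axis=1, padlen=padlen)
    return replace(epoch, data=data)


def baseline_epoch(epoch: Epoch, baseline_ms: float = 250.0) -> Epoch:
    """Subtract the per-channel mean over the first ``baseline_ms``
    (the pre-event span).  Idempotent."""
    n_base = int(round(baseline_ms / 1000.0 * epoch.sample_rate))
    if baseline_ms > epoch.pre_ms or n_base < 1:
        raise ValueError("baseline window exceeds the pre-event span")
    base = epoch.data[:, :n_base].mean(axis=1, keepdims=True)
    return replace(epoch, data=epoch.data - base)


def exclude_bad_channels(samples: np.ndarray,
                         variance_factor: float = 10.0,
                         impedances: np.ndarray | None = None,
                         impedance_limit: float | None = None,
                         ) -> tuple[np.ndarray, list[str]]:
    """Channel mask flagging wide-amplitude (high-variance) or
    high-impedance channels.

    A channel is excluded when its broadband variance exceeds
    ``variance_factor`` times the median channel variance, or when its
    impedance exceeds ``impedance_limit``.  Returns (keep mask,
    per-channel reason strings).
    """
    samples = np.asarray(samples)
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    variances = samples.var(axis=1)
    med = np.median(variances)
    keep = np.ones(samples.shape[0], dtype=bool)
    reasons = ["ok"] * samples.shape[0]
    for i, v in enumerate(variances):
        if med > 0 and v > variance_factor * med:
            keep[i] = False
            reasons[i] = "variance"
        elif impedances is not None and impedance_limit is not None \
                and impedances[i] > impedance_limit:
            keep[i] = False
            reasons[i] = "impedance"
    if not keep.any():
        raise ValueError("all channels excluded")
    return keep, reasons


def average_evoked(epochs: list[Epoch],
                   grouping: tuple[str, ...] = ("side", "state"),
                   ) -> dict[tuple, Erp]:
    """Pointwise mean per condition (tuple of metadata values under the
    grouping keys), with n and a 95% pointwise normal interval of the
    mean."""
    if not epochs:
        raise ValueError("no epochs to average")
    by_cond: dict[tuple, list[Epoch]] = {}
    for e in epochs:
        cond = tuple(e.metadata.get(k) for k in grouping)
        by_cond.setdefault(cond, []).append(e)
    erps = {}
    for cond, group in by_cond.items():
        data = np.stack([e.data for e in group])
        mean = data.mean(axis=0)
        if len(group) > 1:
            band = 1.96 * data.std(axis=0, ddof=1) / np.sqrt(len(group))
        else:
            band = np.zeros_like(mean)
        e0 = group[0]
        erps[cond] = Erp(cond, mean, len(group), band, e0.sample_rate,
                         e0.pre_ms)
    return erps


def measure_peak(erp: Erp | np.ndarray, polarity: str = "negative",
                 window_ms: tuple[float, float] = (0.0, 200.0),
                 channel: int | None = None,
                 sample_rate: float | None = None,
                 pre_ms: float | None = None) -> PeakMeasure:
    """Extremum of the requested polarity within a post-event window.

    Operates on one channel or (default) the channel-pooled mean trace.
    When the trace contains no deflection of the requested polarity the
    extremum is still returned, flagged as polarity-mismatched.
    """
    if isinstance(erp, Erp):
        trace = erp.mean[channel] if channel is not None \
            else erp.mean.mean(axis=0)
        times = erp.times_ms
    else:
        if sample_rate is None or pre_ms is None:
            raise ValueError("sample_rate and pre_ms required for raw traces")
        trace = np.asarray(erp, dtype=np.float64)
        times = np.arange(len(trace)) / sample_rate * 1000.0 - pre_ms
    sel = (times >= window_ms[0]) & (times <= window_ms[1])
    if not sel.any():
        raise ValueError("empty search window")
    seg, seg_t = trace[sel], times[sel]
    idx = int(np.argmin(seg) if polarity == "negative" else np.argmax(seg))
    amp = float(seg[idx])
    matched = amp < 0 if polarity == "negative" else amp > 0
    return PeakMeasure(amp, float(seg_t[idx]), matched)
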