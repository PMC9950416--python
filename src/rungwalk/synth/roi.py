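"""ROI activation-trace synthesis.

A lightweight alternative to rendering full video: each paw contact
becomes a smoothed rectangular pulse on the corresponding step-surface
ROI trace, and each slip a pulse on the gap ROI trace, over a zero
baseline (plus optional noise).  Traces synthesized here are drop-in
inputs for :mod:`rungwalk.events`.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from rungwalk.geometry import CourseGeometry
from rungwalk.synth.crossing import CrossingGroundTruth
from rungwalk.tracking import ActivationTrace


def synthesize_roi_traces(gt: CrossingGroundTruth,
                          geometry: CourseGeometry,
                          pulse_width_s: float = 0.1,
                          amplitude: float = 1.0,
                          smooth_sigma_s: float = 0.012,
                          noise_sd: float = 0.0,
                          seed: int = 0,
                          n_frames: int | None = None,
                          ) -> list[ActivationTrace]:
    """Synthesize per-ROI activation traces from ground-truth events.

    Pulse onsets coincide with event times to within one frame; the
    smoothing sigma is kept well below the pulse width so the rising
    edge stays sharp for derivative-based event detection.
    """
    rate = geometry.frame_rate
    total = n_frames if n_frames is not None else len(gt.times)
    width = max(2, int(round(pulse_width_s * rate)))
    rng = np.random.default_rng(seed)

    labels = ([f"step_{k}_surface" for k in range(geometry.n_steps)]
              + [f"gap_{g}" for g in range(geometry.n_steps - 1)])
    roles = ["surface"] * geometry.n_steps + ["gap"] * (geometry.n_steps - 1)
    raw = {lab: np.zeros(total) for lab in labels}

    for ev in gt.contact_events:
        lab = f"step_{ev.step_index}_surface"
        if lab not in raw:
            raise ValueError(f"contact references nonexistent ROI {lab}")
        f0 = int(round(ev.time_s * rate))
        if not 0 <= f0 < total:
            raise ValueError(f"contact at {ev.time_s:.3f}s outside trace")
        raw[lab][f0:f0 + width] = np.maximum(raw[lab][f0:f0 + width],
                                             amplitude)
    for sl in gt.slip_events:
        lab = f"gap_{sl.gap_index}"
        if lab not in raw:
            raise ValueError(f"slip references nonexistent ROI {lab}")
        f0 = int(round(sl.time_s * rate))
        if not 0 <= f0 < total:
            raise ValueError(f"slip at {sl.time_s:.3f}s outside trace")
        raw[lab][f0:f0 + width] = np.maximum(raw[lab][f0:f0 + width],
                                             amplitude)

    sigma = smooth_sigma_s * rate
    traces = []
    for lab, role in zip(labels, roles):
        v = gaussian_filter1d(raw[lab], sigma) if sigma > 0 else raw[lab]
        if noise_sd > 0:
            v = np.abs(v + rng.normal(0.0, noise_sd, total))
        traces.append(ActivationTrace(lab, v, rate, role))
    return traces
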