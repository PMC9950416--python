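"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text except ECoG voltage data, which uses a flat
binary (channel-major float32 or int16) next to a JSON header; small
fixtures may use CSV instead via the generic pandas round trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rungwalk.ethogram import Ethogram, EthogramInterval
from rungwalk.lesion import LesionStack, SliceOutline
from rungwalk.synth.protocol import SessionSpec
from rungwalk.tracking import ActivationTrace, EllipseParams, PoseSample


# ---------------------------------------------------------------------------
# poses

def save_poses(path: str | Path, poses: list[PoseSample],
               frame_rate: float) -> None:
    rows = []
    for p in poses:
        e = p.ellipse
        rows.append({
            "frame": p.frame_index,
            "time_s": p.frame_index / frame_rate,
            "nose_x": p.nose[0] if p.nose else np.nan,
            "nose_y": p.nose[1] if p.nose else np.nan,
            "cx": e.cx if e else np.nan, "cy": e.cy if e else np.nan,
            "major": e.major if e else np.nan,
            "minor": e.minor if e else np.nan,
            "orientation": e.orientation if e else np.nan,
            "valid": int(p.valid),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_poses(path: str | Path) -> list[PoseSample]:
    df = pd.read_csv(path)
    poses = []
    for _, r in df.iterrows():
        valid = bool(r["valid"])
        nose = (float(r["nose_x"]), float(r["nose_y"])) if valid else None
        ellipse = EllipseParams(r["cx"], r["cy"], r["major"], r["minor"],
                                r["orientation"]) if valid else None
        poses.append(PoseSample(int(r["frame"]), nose, ellipse, valid))
    return poses


# ---------------------------------------------------------------------------
# activation traces

def save_traces(path: str | Path, traces: list[ActivationTrace]) -> None:
    path = Path(path)
    data = {t.label: t.values for t in traces}
    pd.DataFrame(data).to_csv(path, index_label="frame")
    meta = {"frame_rate": traces[0].frame_rate if traces else 0.0,
            "roles": {t.label: t.role for t in traces}}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def load_traces(path: str | Path) -> list[ActivationTrace]:
    path = Path(path)
    df = pd.read_csv(path, index_col="frame")
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return [ActivationTrace(label, df[label].to_numpy(),
                            meta["frame_rate"],
                            meta["roles"].get(label, "surface"))
            for label in df.columns]


# ---------------------------------------------------------------------------
# protocol

def save_protocol(path: str | Path, sessions: list[SessionSpec]) -> None:
    payload = [{"day_index": s.day_index,
                "condition_label": s.condition_label,
                "trial_states": list(s.trial_states)} for s in sessions]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_protocol(path: str | Path) -> list[SessionSpec]:
    payload = json.loads(Path(path).read_text())
    return [SessionSpec(d["day_index"], d["condition_label"],
                        tuple(d["trial_states"])) for d in payload]


# ---------------------------------------------------------------------------
# ethograms

def load_ethograms(path: str | Path) -> list[Ethogram]:
    """CSV columns: animal, group, category, onset_s, offset_s, and
    optionally crossed_at_s."""
    df = pd.read_csv(path)
    ethograms = []
    for (animal, group), g in df.groupby(["animal", "group"], sort=False):
        intervals = tuple(
            EthogramInterval(r["category"], float(r["onset_s"]),
                             float(r["offset_s"]))
            for _, r in g.iterrows())
        crossed = None
        if "crossed_at_s" in g.columns and g["crossed_at_s"].notna().any():
            crossed = float(g["crossed_at_s"].dropna().iloc[0])
        ethograms.append(Ethogram(str(animal), str(group), intervals,
                                  crossed))
    return ethograms


def save_ethograms(path: str | Path, ethograms: list[Ethogram]) -> None:
    rows = []
    for e in ethograms:
        for iv in e.intervals:
            rows.append({"animal": e.animal_id, "group": e.group,
                         "category": iv.category, "onset_s": iv.onset,
                         "offset_s": iv.offset,
                         "crossed_at_s": e.crossed_at})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# lesion outlines

def load_outlines(path: str | Path,
                  slice_thickness: float = 0.1) -> dict[str, LesionStack]:
    """CSV columns: animal, hemisphere, slice, kind, vertex_order, x_mm,
    y_mm (one row per vertex); returns one stack per animal."""
    df = pd.read_csv(path)
    stacks = {}
    for animal, g in df.groupby("animal", sort=False):
        outlines = []
        keys = ["hemisphere", "slice", "kind"]
        for (hemi, idx, kind), poly in g.groupby(keys, sort=False):
            poly = poly.sort_values("vertex_order")
            outlines.append(SliceOutline(
                int(idx), str(hemi),
                poly[["x_mm", "y_mm"]].to_numpy(float), str(kind)))
        stacks[str(animal)] = LesionStack(tuple(outlines), slice_thickness)
    return stacks


def save_outlines(path: str | Path, stacks: dict[str, LesionStack]) -> None:
    rows = []
    for animal, stack in stacks.items():
        for o in stack.outlines:
            for i, (x, y) in enumerate(o.polygon):
                rows.append({"animal": animal, "hemisphere": o.hemisphere,
                             "slice": o.slice_index, "kind": o.kind,
                             "vertex_order": i, "x_mm": x, "y_mm": y})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ECoG flat binary

def save_ecog(path: str | Path, samples: np.ndarray, sample_rate: float,
              dtype: str = "float32", uv_scale: float = 1.0) -> None:
    """Channel-major flat binary with a JSON header sidecar."""
    path = Path(path)
    arr = np.ascontiguousarray(samples / uv_scale).astype(dtype)
    arr.tofile(path)
    header = {"n_channels": int(samples.shape[0]),
              "n_samples": int(samples.shape[1]),
              "sample_rate": sample_rate, "dtype": dtype,
              "uv_scale": uv_scale, "order": "channel-major"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))


def load_ecog(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=header["dtype"])
    arr = arr.reshape(header["n_channels"], header["n_samples"])
    return arr.astype(np.float64) * header["uv_scale"], header["sample_rate"]
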