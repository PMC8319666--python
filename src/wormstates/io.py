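"""Plain-text serialization of tracks, speeds, states and model parameters.

Tracks and decoded states travel as CSV, group summaries and screen
tables as TSV, model parameters and manifests as JSON. All round trips
are lossless (JSON floats keep full precision; unknown CSV columns are
preserved). Image stacks are written as multi-page TIFF or numbered PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hmm import HMMParams, StateSequence, label_states
from .tracking import SpeedSeries, TrackSeries

TRACK_COLUMNS = ["frame", "time_s", "x_px", "y_px", "valid"]
STATES_COLUMNS = ["frame", "time_s", "label", "p_Q", "p_D", "p_R"]


def write_track_csv(track: TrackSeries, path) -> None:
    df = pd.DataFrame(
        {
            "frame": np.arange(track.times.size, dtype=int),
            "time_s": track.times,
            "x_px": track.positions[:, 0],
            "y_px": track.positions[:, 1],
            "valid": track.valid.astype(int),
        }
    )
    for name, col in track.extra.items():
        df[name] = col
    df.to_csv(path, index=False)


def read_track_csv(path, animal_id: str | None = None) -> TrackSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track columns {missing}")
    times = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        # +2: one for the diff offset, one for the header line
        raise ValueError(f"{path}: time_s not strictly increasing at row {bad[0] + 2}")
    valid = df["valid"].to_numpy().astype(bool)
    pos = df[["x_px", "y_px"]].to_numpy(dtype=float)
    pos[~valid] = np.nan
    extra = {
        c: df[c].to_numpy() for c in df.columns if c not in TRACK_COLUMNS
    }
    if animal_id is None:
        animal_id = Path(path).stem
    return TrackSeries(animal_id=animal_id, times=times, positions=pos, valid=valid, extra=extra)


def write_speeds_csv(segments: list[SpeedSeries], path) -> None:
    frames = []
    for seg in segments:
        frames.append(
            pd.DataFrame(
                {
                    "segment_id": seg.segment_id,
                    "time_s": seg.times,
                    "speed_px_s": seg.speeds,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["segment_id", "time_s", "speed_px_s"]
    )
    df.to_csv(path, index=False)


def read_speeds_csv(path, animal_id: str | None = None, window_s: float = float("nan")) -> list[SpeedSeries]:
    df = pd.read_csv(path, float_precision="round_trip")
    for c in ("segment_id", "time_s", "speed_px_s"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing speeds column {c!r}")
    if animal_id is None:
        animal_id = Path(path).stem
    out = []
    for seg_id, sub in df.groupby("segment_id", sort=True):
        out.append(
            SpeedSeries(
                animal_id=animal_id,
                segment_id=int(seg_id),
                times=sub["time_s"].to_numpy(dtype=float),
                speeds=sub["speed_px_s"].to_numpy(dtype=float),
                window_s=window_s,
            )
        )
    return out


def write_states_csv(sequences: list[StateSequence], path) -> None:
    frames = []
    offset = 0
    for seq in sequences:
        T = seq.labels.size
        times = seq.times if seq.times is not None else np.arange(T, dtype=float)
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(offset, offset + T, dtype=int),
                    "time_s": times,
                    "label": seq.labels,
                    "p_Q": seq.posteriors[:, 0],
                    "p_D": seq.posteriors[:, 1],
                    "p_R": seq.posteriors[:, 2],
                    "segment_id": seq.segment_id,
                }
            )
        )
        offset += T
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_states_csv(path, animal_id: str | None = None) -> list[StateSequence]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STATES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing states columns {missing}")
    if "segment_id" not in df.columns:
        df["segment_id"] = 0
    if animal_id is None:
        animal_id = Path(path).stem
    name_to_idx = {"Q": 0, "D": 1, "R": 2}
    out = []
    for seg_id, sub in df.groupby("segment_id", sort=True):
        labels = sub["label"].to_numpy(dtype="<U1")
        out.append(
            StateSequence(
                animal_id=animal_id,
                labels=labels,
                state_idx=np.array([name_to_idx[v] for v in labels]),
                posteriors=sub[["p_Q", "p_D", "p_R"]].to_numpy(dtype=float),
                log_likelihood=float("nan"),
                times=sub["time_s"].to_numpy(dtype=float),
                segment_id=int(seg_id),
            )
        )
    return out


def write_params_json(params: HMMParams, path) -> None:
    payload = {
        "pi": params.pi.tolist(),
        "A": params.A.tolist(),
        "means": params.means.tolist(),
        "sds": params.sds.tolist(),
        "epsilon": params.epsilon,
        "label_map": {str(k): v for k, v in label_states(params).items()}
        if params.n_states == 3
        else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_params_json(path) -> HMMParams:
    payload = json.loads(Path(path).read_text())
    params = HMMParams(
        pi=np.array(payload["pi"]),
        A=np.array(payload["A"]),
        means=np.array(payload["means"]),
        sds=np.array(payload["sds"]),
        epsilon=float(payload["epsilon"]),
    )
    params.validate()
    return params


def write_manifest_json(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2))


def read_manifest_json(path) -> dict:
    manifest = json.loads(Path(path).read_text())
    if "genes" not in manifest or not isinstance(manifest["genes"], list):
        raise ValueError(f"{path}: manifest must contain a 'genes' list")
    return manifest


def write_frames(stack: np.ndarray, path) -> None:
    """Write an image stack losslessly: .tif/.tiff multi-page, or a
    directory of numbered PNGs."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack)
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = len(str(len(stack) - 1))
        for t, frame in enumerate(stack):
            iio.imwrite(path / f"frame_{t:0{width}d}.png", frame)


def read_frames(path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(path.glob("*.png"))
        if not files:
            raise ValueError(f"{path}: no PNG frames found")
        return np.stack([iio.imread(f) for f in files])
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack
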