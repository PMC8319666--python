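"""Centroid tracking and speed computation.

A single worm per frame is located by thresholding (Otsu by default),
keeping the largest connected component above a minimum area, and taking
its intensity-weighted centroid. Movement is then the change in centroid
position between frames: the speed series is the per-frame Euclidean
displacement divided by the elapsed time, with short tracking dropouts
bridged by linear interpolation and longer ones splitting the series into
independent segments, followed by a centered moving-average smoother.

Coordinate convention: x = column, y = row, 0-based, origin at the
top-left pixel center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "TrackSeries",
    "SpeedSeries",
    "extract_centroid",
    "build_track",
    "compute_speed",
]


@dataclass
class TrackSeries:
    """One animal's timestamped centroid positions with validity flags.

    ``positions`` holds NaN where ``valid`` is False; extra columns read
    from disk (e.g. a synthetic track's true_state) are carried along in
    ``extra`` and preserved on write.
    """

    animal_id: str
    times: np.ndarray        # (T,) seconds
    positions: np.ndarray    # (T, 2) float, NaN where invalid
    valid: np.ndarray        # (T,) bool
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        T = self.times.size
        if self.positions.shape != (T, 2) or self.valid.shape != (T,):
            raise ValueError("times, positions and valid must align")
        if T > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        has_pos = ~np.isnan(self.positions).any(axis=1)
        if np.any(has_pos != self.valid):
            raise ValueError("missing positions must coincide with valid=False")


@dataclass
class SpeedSeries:
    """Smoothed speeds (px/s) for one contiguous segment of a track."""

    animal_id: str
    segment_id: int
    times: np.ndarray    # (N,) seconds, time of the first frame of each step
    speeds: np.ndarray   # (N,) px/s, >= 0
    window_s: float


def extract_centroid(
    frame: np.ndarray,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: int = 5,
) -> tuple[float, float] | None:
    """Locate the worm in one grayscale frame.

    Binarizes the image (Otsu threshold by default, or a fixed intensity),
    keeps the largest connected component of at least ``min_area`` pixels,
    and returns its intensity-weighted centroid as (x, y). Returns None
    when no component passes (e.g. an all-dark frame).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    if threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required with threshold_method='fixed'")
        thr = fixed_threshold
    elif threshold_method == "otsu":
        if frame.min() == frame.max():
            return None
        thr = threshold_otsu(frame)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = frame > thr
    if not mask.any():
        return None
    labels, n = cc_label(mask, return_num=True)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(areas)) + 1
    if areas[best - 1] < max(min_area, 1):
        return None
    rows, cols = np.nonzero(labels == best)
    wts = frame[rows, cols].astype(float)
    total = wts.sum()
    if total <= 0:
        return None
    x = float((cols * wts).sum() / total)
    y = float((rows * wts).sum() / total)
    return (x, y)


def build_track(
    frames: np.ndarray,
    frame_rate_hz: float,
    animal_id: str = "",
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
    min_area: int = 5,
) -> TrackSeries:
    """Run centroid extraction over an image stack.

    Frames with no detection are flagged invalid; times are
    frame_index / frame_rate_hz.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("frames must be a (T, H, W) stack with T >= 2")
    T = frames.shape[0]
    pos = np.full((T, 2), np.nan)
    valid = np.zeros(T, dtype=bool)
    for t in range(T):
        c = extract_centroid(
            frames[t],
            threshold_method=threshold_method,
            fixed_threshold=fixed_threshold,
            min_area=min_area,
        )
        if c is not None:
            pos[t] = c
            valid[t] = True
    times = np.arange(T) / frame_rate_hz
    return TrackSeries(animal_id=animal_id, times=times, positions=pos, valid=valid)


def compute_speed(
    track: TrackSeries,
    window_s: float = 0.0,
    max_gap_frames: int = 5,
) -> list[SpeedSeries]:
    """Convert a centroid track into speed segments.

    Raw speed per consecutive frame pair is the Euclidean displacement
    divided by the elapsed time. Runs of at most ``max_gap_frames``
    invalid frames are bridged by linear position interpolation (which by
    construction spreads the bridged displacement evenly, so interpolated
    speeds never exceed displacement / gap duration); longer dropouts
    split the track into independent segments. An optional centered
    moving average of width ``window_s`` is then applied within each
    segment; it is off by default (``window_s=0``) because the HMM's
    quiescence component models the centroid jitter floor directly, and
    averaging across state boundaries manufactures intermediate speeds
    that do not belong to any one state. Each speed sample is stamped
    with the time of the first frame of its step, so it aligns with the
    behavioral state occupied during the step.
    """
    vidx = np.nonzero(track.valid)[0]
    if vidx.size < 2:
        warnings.warn(
            f"track {track.animal_id!r}: fewer than 2 valid frames, no speeds",
            stacklevel=2,
        )
        return []
    # split where more than max_gap_frames invalid frames separate valid ones
    gaps = np.diff(vidx) - 1
    breaks = np.nonzero(gaps > max_gap_frames)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [vidx.size - 1]])

    segments: list[SpeedSeries] = []
    seg_id = 0
    for s, e in zip(starts, ends):
        idx = vidx[s], vidx[e]
        if idx[1] - idx[0] < 1:
            continue
        frames = np.arange(idx[0], idx[1] + 1)
        seg_valid = vidx[s : e + 1]
        # linear interpolation over frame index for bridged frames
        x = np.interp(frames, seg_valid, track.positions[seg_valid, 0])
        y = np.interp(frames, seg_valid, track.positions[seg_valid, 1])
        t = track.times[frames]
        disp = np.hypot(np.diff(x), np.diff(y))
        dt = np.diff(t)
        speeds = disp / dt
        w = int(round(window_s * _segment_rate(dt)))
        if w > 1:
            speeds = uniform_filter1d(speeds, size=w, mode="nearest")
        segments.append(
            SpeedSeries(
                animal_id=track.animal_id,
                segment_id=seg_id,
                times=t[:-1],
                speeds=speeds,
                window_s=window_s,
            )
        )
        seg_id += 1
    return segments


def _segment_rate(dt: np.ndarray) -> float:
    return 1.0 / float(np.median(dt))
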