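"""Per-animal behavioral readouts from decoded state sequences.

Three summaries are computed from the per-frame labels of one animal:

* percent time -- the fraction of valid frames spent in each of roaming,
  dwelling and quiescence;
* transition rates -- first-order hazards of switching between states,
  analogous to rate constants of first-order chemical reactions,
  estimated as rate[i][j] = (# decoded i->j steps) / (time spent in state
  i with a decoded successor frame). With the linear rate-to-probability
  convention used by the synthetic generator this estimator is the exact
  maximum-likelihood inverse of the generating chain;
* bout durations -- lengths of maximal single-state runs, with runs
  truncated by the session ends or tracking gaps flagged as censored.

Sequences split by tracking gaps are handled as independent segments:
counts and occupancy never bridge a gap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

STATE_NAMES = ("Q", "D", "R")
_NAME_TO_IDX = {"Q": 0, "D": 1, "R": 2}
N_STATES = 3


def _as_segments(states) -> list[np.ndarray]:
    """Normalize input to a list of int index arrays (0=Q, 1=D, 2=R).

    Accepts a StateSequence, a label/index array, or a list of either
    (one entry per contiguous segment).
    """
    if hasattr(states, "state_idx"):
        return [np.asarray(states.state_idx, dtype=np.int64)]
    if isinstance(states, (list, tuple)) and len(states) and (
        hasattr(states[0], "state_idx") or isinstance(states[0], (list, tuple, np.ndarray))
    ):
        out = []
        for s in states:
            out.extend(_as_segments(s))
        return out
    arr = np.asarray(states)
    if arr.dtype.kind in "US":
        idx = np.array([_NAME_TO_IDX[str(v)] for v in arr], dtype=np.int64)
    else:
        idx = arr.astype(np.int64)
        if idx.size and (idx.min() < 0 or idx.max() >= N_STATES):
            raise ValueError("state indices must be in {0, 1, 2}")
    return [idx]


@dataclass
class Bout:
    state: str
    duration_s: float
    censored: bool


@dataclass
class BehaviorSummary:
    """One animal's percent times, transition rates and bout statistics."""

    animal_id: str
    frac: np.ndarray            # (3,) fraction of valid frames in Q, D, R
    rates: np.ndarray           # (3, 3) s^-1; NaN rows for never-occupied states
    n_transitions: np.ndarray   # (3, 3) int counts
    occupancy_s: np.ndarray     # (3,) seconds in state with a decoded successor
    bouts: dict[str, list[Bout]]
    n_valid_frames: int
    frame_rate_hz: float = 1.0

    @property
    def pct(self) -> np.ndarray:
        return 100.0 * self.frac

    def metric_dict(self) -> dict[str, float]:
        """Flat metric vector used by the screen statistics."""
        d = {
            "pct_Q": float(self.pct[0]),
            "pct_D": float(self.pct[1]),
            "pct_R": float(self.pct[2]),
        }
        for i, a in enumerate(STATE_NAMES):
            for j, b in enumerate(STATE_NAMES):
                if i != j:
                    d[f"rate_{a}{b}"] = float(self.rates[i, j])
        return d


def percent_time(states) -> np.ndarray:
    """Fraction of valid frames in each state, ordered (Q, D, R).

    Invariant to how the sequence is cut into segments and sums to 1.
    """
    segs = _as_segments(states)
    total = sum(s.size for s in segs)
    if total == 0:
        raise ValueError("no labeled frames")
    counts = np.zeros(N_STATES)
    for s in segs:
        counts += np.bincount(s, minlength=N_STATES)
    return counts / total


def transition_counts(states) -> tuple[np.ndarray, np.ndarray]:
    """(3x3 transition counts, per-state frames-with-successor counts).

    Only consecutive frames within one segment count; the last frame of
    each segment has no decoded successor and contributes to neither.
    """
    segs = _as_segments(states)
    n = np.zeros((N_STATES, N_STATES), dtype=np.int64)
    occ = np.zeros(N_STATES, dtype=np.int64)
    for s in segs:
        if s.size < 2:
            continue
        a, b = s[:-1], s[1:]
        np.add.at(n, (a, b), 1)
        occ += np.bincount(a, minlength=N_STATES)
    return n, occ


def transition_rates(states, frame_rate_hz: float = 1.0) -> np.ndarray:
    """First-order transition-rate matrix in s^-1.

    rate[i][j] = n_transitions[i][j] / occupancy_s[i], with occupancy
    counting only frames that have a decoded successor (the exact MLE of
    the discrete chain, times the frame rate). Rows of states never
    occupied are NaN (missing, not zero); the diagonal is 0 by convention.
    """
    n, occ = transition_counts(states)
    occ_s = occ / frame_rate_hz
    rates = np.full((N_STATES, N_STATES), np.nan)
    for i in range(N_STATES):
        if occ[i] > 0:
            rates[i] = n[i] / occ_s[i]
            rates[i, i] = 0.0
    return rates


def bout_durations(states, frame_rate_hz: float = 1.0) -> dict[str, list[Bout]]:
    """Maximal single-state runs per state, with censoring flags.

    A bout's duration is its run length divided by the frame rate. Runs
    touching a segment boundary (session start/end or a tracking gap) are
    flagged censored: their true duration is unknown. The durations sum
    back to the total number of labeled frames.
    """
    segs = _as_segments(states)
    out: dict[str, list[Bout]] = {name: [] for name in STATE_NAMES}
    for s in segs:
        if s.size == 0:
            continue
        change = np.nonzero(np.diff(s))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [s.size - 1]])
        for k, (b, e) in enumerate(zip(starts, ends)):
            censored = (b == 0) or (e == s.size - 1)
            out[STATE_NAMES[s[b]]].append(
                Bout(
                    state=STATE_NAMES[s[b]],
                    duration_s=(e - b + 1) / frame_rate_hz,
                    censored=censored,
                )
            )
    return out


def mean_bout_duration(
    bouts: dict[str, list[Bout]], include_censored: bool = False
) -> dict[str, float]:
    """Mean bout duration per state; censored bouts excluded by default."""
    out = {}
    for name, lst in bouts.items():
        durs = [b.duration_s for b in lst if include_censored or not b.censored]
        out[name] = float(np.mean(durs)) if durs else float("nan")
    return out


def summarize(states, frame_rate_hz: float = 1.0, animal_id: str = "") -> BehaviorSummary:
    """All per-animal readouts in one object."""
    segs = _as_segments(states)
    frac = percent_time(segs)
    n, occ = transition_counts(segs)
    rates = transition_rates(segs, frame_rate_hz)
    bouts = bout_durations(segs, frame_rate_hz)
    return BehaviorSummary(
        animal_id=animal_id,
        frac=frac,
        rates=rates,
        n_transitions=n,
        occupancy_s=occ / frame_rate_hz,
        bouts=bouts,
        n_valid_frames=int(sum(s.size for s in segs)),
        frame_rate_hz=frame_rate_hz,
    )
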