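"""Three-state hidden Markov model over log-speed observations.

The observable is y_t = log(speed_t + epsilon); each hidden state emits
from a univariate Gaussian on y, so quiescence, dwelling and roaming are
identified purely by how fast the animal moves. Fitting is multi-sequence
Baum-Welch (expected counts pooled across animals), decoding is Viterbi,
and posteriors come from the forward-backward recursion. All recursions
use per-step scaling (equivalently, log-space likelihoods), so sessions of
tens of thousands of frames pose no underflow risk.

The recommended protocol for a screen is to fit one model on the
concurrent control group's sequences, freeze it, and decode every animal
of that experiment with the frozen model, which guarantees that treated
and control animals are scored on the same footing.

After fitting, states are relabeled by ascending emission mean, so index
0 = Q (slowest), 1 = D, 2 = R (fastest), matching the package convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_LOG2PI = float(np.log(2.0 * np.pi))
STATE_NAMES = ("Q", "D", "R")


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and Gaussian emissions.

    ``epsilon`` is the speed floor (px/s) used when mapping speeds to
    observations, kept with the parameters so a serialized model can be
    applied to raw speed series unambiguously.
    """

    pi: np.ndarray       # (K,)
    A: np.ndarray        # (K, K) per-frame transition probabilities
    means: np.ndarray    # (K,) emission means on log(speed + epsilon)
    sds: np.ndarray      # (K,) emission sds, > 0
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)

    @property
    def n_states(self) -> int:
        return self.pi.size

    def validate(self) -> None:
        k = self.n_states
        if self.A.shape != (k, k) or self.means.shape != (k,) or self.sds.shape != (k,):
            raise ValueError("inconsistent parameter shapes")
        if np.any(self.pi < -1e-12) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")
        if np.any(self.A < -1e-12) or np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-8):
            raise ValueError("rows of A must be probability vectors")
        if np.any(self.sds <= 0):
            raise ValueError("emission sds must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def relabeled_by_mean(self) -> "HMMParams":
        """Permute states so emission means are ascending (Q < D < R)."""
        order = np.argsort(self.means, kind="stable")
        return HMMParams(
            pi=self.pi[order],
            A=self.A[np.ix_(order, order)],
            means=self.means[order],
            sds=self.sds[order],
            epsilon=self.epsilon,
        )


@dataclass
class StateSequence:
    """Decoded per-frame states with posterior probabilities."""

    animal_id: str
    labels: np.ndarray        # (T,) unicode in {"Q","D","R"}
    state_idx: np.ndarray     # (T,) int, package state order (0=Q,1=D,2=R)
    posteriors: np.ndarray    # (T, K) in package state order, rows sum to 1
    log_likelihood: float
    times: np.ndarray | None = None
    segment_id: int = 0


def speeds_to_obs(speeds: np.ndarray, epsilon: float = 0.01) -> np.ndarray:
    """Map speeds (px/s) to the HMM observation space log(speed + epsilon)."""
    speeds = np.asarray(speeds, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("speeds must be non-negative")
    return np.log(speeds + epsilon)


def _log_emissions(params: HMMParams, Y: np.ndarray) -> np.ndarray:
    """Log N(y; mu_k, sd_k) for every observation; shape Y.shape + (K,)."""
    z = (Y[..., None] - params.means) / params.sds
    return -0.5 * z * z - np.log(params.sds) - 0.5 * _LOG2PI


def _forward_scaled(params: HMMParams, logB: np.ndarray):
    """Scaled forward pass on a batch.

    logB: (B, T, K) log emission densities. Returns (alpha, log_c) with
    alpha (B, T, K) the scaled forward variables (rows sum to 1) and
    log_c (B, T) the per-step log normalizers; the per-sequence
    log-likelihood is log_c.sum(axis=1).
    """
    B, T, K = logB.shape
    alpha = np.empty((B, T, K))
    log_c = np.empty((B, T))
    # factor out the per-frame max emission for numerical stability
    m = logB.max(axis=2)
    Bmat = np.exp(logB - m[..., None])
    a = params.pi * Bmat[:, 0]
    c = a.sum(axis=1)
    alpha[:, 0] = a / c[:, None]
    log_c[:, 0] = np.log(c) + m[:, 0]
    At = params.A
    for t in range(1, T):
        a = (alpha[:, t - 1] @ At) * Bmat[:, t]
        c = a.sum(axis=1)
        alpha[:, t] = a / c[:, None]
        log_c[:, t] = np.log(c) + m[:, t]
    return alpha, log_c


def _backward_scaled(params: HMMParams, logB: np.ndarray, log_c: np.ndarray) -> np.ndarray:
    """Scaled backward pass matching the forward normalizers."""
    B, T, K = logB.shape
    m = logB.max(axis=2)
    Bmat = np.exp(logB - m[..., None])
    beta = np.empty((B, T, K))
    beta[:, -1] = 1.0
    A = params.A
    # forward used c_t = exp(log_c_t - m_t) as its normalizer in scaled space
    c_scaled = np.exp(log_c - m)
    for t in range(T - 2, -1, -1):
        b = (Bmat[:, t + 1] * beta[:, t + 1]) @ A.T
        beta[:, t] = b / c_scaled[:, t + 1][:, None]
    return beta


def forward_log_likelihood(params: HMMParams, obs: np.ndarray) -> float:
    """Total observation log-likelihood log P(y_1..T | params).

    Computed with the scaled forward recursion; finite for any valid
    parameters and non-empty sequence.
    """
    params.validate()
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observations must be a non-empty 1-D sequence")
    logB = _log_emissions(params, obs[None, :])
    _, log_c = _forward_scaled(params, logB)
    return float(log_c.sum())


def posterior_probs(params: HMMParams, obs: np.ndarray) -> tuple[np.ndarray, float]:
    """Forward-backward smoothing: per-frame state posteriors and loglik."""
    params.validate()
    obs = np.asarray(obs, dtype=float)
    logB = _log_emissions(params, obs[None, :])
    alpha, log_c = _forward_scaled(params, logB)
    beta = _backward_scaled(params, logB, log_c)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma[0], float(log_c.sum())


def quantile_init(sequences: list[np.ndarray], n_states: int = 3, epsilon: float = 0.01) -> HMMParams:
    """Deterministic initialization from pooled observation terciles.

    Pooled log-speeds are split at the (100/K)-percentile grid; each bin's
    mean and sd initialize one emission component. A starts at 0.95
    self-transition, pi uniform.
    """
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in sequences])
    edges = np.quantile(pooled, np.linspace(0, 1, n_states + 1))
    means = np.empty(n_states)
    sds = np.empty(n_states)
    for k in range(n_states):
        lo, hi = edges[k], edges[k + 1]
        sel = (pooled >= lo) & (pooled <= hi) if k == n_states - 1 else (pooled >= lo) & (pooled < hi)
        chunk = pooled[sel] if sel.any() else pooled
        means[k] = chunk.mean()
        sds[k] = max(chunk.std(), 1e-2)
    A = np.full((n_states, n_states), 0.05 / max(n_states - 1, 1))
    np.fill_diagonal(A, 0.95)
    pi = np.full(n_states, 1.0 / n_states)
    return HMMParams(pi=pi, A=A, means=means, sds=sds, epsilon=epsilon)


def fit_baum_welch(
    sequences: list[np.ndarray],
    init: HMMParams | str = "quantile",
    max_iter: int = 500,
    tol: float = 1e-6,
    n_states: int = 3,
    min_sigma: float = 1e-3,
    n_restarts: int = 0,
    seed: int | None = None,
    epsilon: float = 0.01,
) -> tuple[HMMParams, np.ndarray]:
    """Fit the HMM by multi-sequence Baum-Welch (EM).

    Expected counts are pooled across all sequences; sequences of equal
    length are processed as one batched recursion. Iteration stops when
    the relative total log-likelihood improvement falls below ``tol`` or
    after ``max_iter`` iterations. The returned parameters are relabeled
    by ascending emission mean; the second return value is the iteration
    trace of total log-likelihoods, which is non-decreasing up to
    numerical slack (the EM guarantee).

    ``n_restarts`` > 0 adds randomly perturbed re-runs of the
    deterministic initialization (seeded) and keeps the best final fit.
    """
    seqs = []
    for s in sequences:
        s = np.asarray(s, dtype=float).ravel()
        if s.size < 2:
            warnings.warn("sequence shorter than 2 frames excluded from fit", stacklevel=2)
            continue
        seqs.append(s)
    if not seqs:
        raise ValueError("no usable sequences (all shorter than 2 frames)")

    total_obs = sum(s.size for s in seqs)
    n_free = n_states - 1 + n_states * (n_states - 1) + 2 * n_states
    if total_obs < 30 * n_free:
        warnings.warn(
            f"only {total_obs} observations for {n_free} free parameters; "
            "estimates may be unstable",
            stacklevel=2,
        )

    if isinstance(init, str):
        if init != "quantile":
            raise ValueError(f"unknown init {init!r}")
        base = quantile_init(seqs, n_states=n_states, epsilon=epsilon)
    else:
        base = init
        base.validate()
        n_states = base.n_states

    inits = [base]
    if n_restarts > 0:
        rng = np.random.default_rng(seed)
        spread = np.std(np.concatenate(seqs))
        for _ in range(n_restarts):
            pert = HMMParams(
                pi=base.pi.copy(),
                A=base.A.copy(),
                means=base.means + rng.normal(0, 0.25 * spread, n_states),
                sds=base.sds.copy(),
                epsilon=epsilon,
            )
            inits.append(pert)

    best: tuple[HMMParams, np.ndarray] | None = None
    for p0 in inits:
        fitted, trace = _em_run(seqs, p0, max_iter, tol, min_sigma)
        if best is None or trace[-1] > best[1][-1]:
            best = (fitted, trace)
    assert best is not None
    params, trace = best
    return params.relabeled_by_mean(), trace


def _em_run(
    seqs: list[np.ndarray],
    params: HMMParams,
    max_iter: int,
    tol: float,
    min_sigma: float,
) -> tuple[HMMParams, np.ndarray]:
    # group sequences by length so each group runs as one batched recursion
    by_len: dict[int, list[np.ndarray]] = {}
    for s in seqs:
        by_len.setdefault(s.size, []).append(s)
    batches = [np.stack(group) for group in by_len.values()]

    K = params.n_states
    trace = []
    prev_ll = -np.inf
    params = HMMParams(
        pi=params.pi.copy(), A=params.A.copy(),
        means=params.means.copy(), sds=params.sds.copy(), epsilon=params.epsilon,
    )
    for _ in range(max_iter):
        ll = 0.0
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        g_sum = np.zeros(K)
        gy_sum = np.zeros(K)
        gyy_sum = np.zeros(K)
        for Y in batches:
            logB = _log_emissions(params, Y)
            alpha, log_c = _forward_scaled(params, logB)
            beta = _backward_scaled(params, logB, log_c)
            gamma = alpha * beta
            gamma /= gamma.sum(axis=2, keepdims=True)
            ll += float(log_c.sum())
            pi_acc += gamma[:, 0].sum(axis=0)
            m = logB.max(axis=2)
            Bmat = np.exp(logB - m[..., None])
            w = Bmat[:, 1:] * beta[:, 1:]                       # (B, T-1, K)
            # xi_t(i,j) ∝ alpha_t(i) A(i,j) b_{t+1}(j) beta_{t+1}(j); each
            # per-t slice sums to 1 after normalization
            xi_un = np.einsum("bti,ij,btj->btij", alpha[:, :-1], params.A, w)
            xi_un /= xi_un.sum(axis=(2, 3), keepdims=True)
            xi_acc += xi_un.sum(axis=(0, 1))
            g_sum += gamma.sum(axis=(0, 1))
            gy_sum += np.einsum("btk,bt->k", gamma, Y)
            gyy_sum += np.einsum("btk,bt->k", gamma, Y * Y)
        trace.append(ll)

        # M step
        params.pi = pi_acc / pi_acc.sum()
        row = xi_acc.sum(axis=1, keepdims=True)
        params.A = np.where(row > 0, xi_acc / np.where(row > 0, row, 1.0), params.A)
        params.means = gy_sum / g_sum
        var = gyy_sum / g_sum - params.means**2
        params.sds = np.sqrt(np.maximum(var, min_sigma**2))

        if np.isfinite(prev_ll):
            rel = (ll - prev_ll) / (abs(prev_ll) + 1e-12)
            if rel < tol:
                break
        prev_ll = ll
    return params, np.asarray(trace)


def label_states(params: HMMParams):
    """Map state indices to behavioral labels by ascending emission mean.

    The slowest state is quiescence, the middle dwelling, the fastest
    roaming. Exactly tied means are rejected as unidentifiable.
    """
    if params.n_states != 3:
        raise ValueError("behavioral labeling requires a 3-state model")
    means = params.means
    if len(np.unique(means)) != 3:
        raise ValueError("emission means are exactly equal: states unidentifiable")
    order = np.argsort(means, kind="stable")
    mapping = {}
    for rank, idx in enumerate(order):
        mapping[int(idx)] = STATE_NAMES[rank]
    return mapping


def _viterbi_batch(params: HMMParams, logB: np.ndarray) -> np.ndarray:
    """Max-product decoding on a batch; ties broken toward the lowest index."""
    B, T, K = logB.shape
    logA = np.log(np.maximum(params.A, 1e-300))
    logpi = np.log(np.maximum(params.pi, 1e-300))
    delta = logpi + logB[:, 0]                       # (B, K)
    back = np.empty((B, T, K), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None]        # (B, K_prev, K_next)
        back[:, t] = cand.argmax(axis=1)             # argmax -> first (lowest) index on ties
        delta = cand.max(axis=1) + logB[:, t]
    path = np.empty((B, T), dtype=np.int8)
    path[:, -1] = delta.argmax(axis=1)
    for t in range(T - 2, -1, -1):
        path[:, t] = back[np.arange(B), t + 1, path[:, t + 1]]
    return path


def viterbi_decode(
    params: HMMParams,
    obs: np.ndarray,
    animal_id: str = "",
    times: np.ndarray | None = None,
    segment_id: int = 0,
) -> StateSequence:
    """Most probable state path plus forward-backward posteriors.

    Labels and posterior columns are reported in package state order
    (Q, D, R) regardless of the internal ordering of ``params``; the
    mapping comes from :func:`label_states`. Ties in the max-product
    recursion break toward the lowest state index.
    """
    params.validate()
    obs = np.asarray(obs, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observations must be a non-empty 1-D sequence")
    mapping = label_states(params)
    logB = _log_emissions(params, obs[None, :])
    raw_path = _viterbi_batch(params, logB)[0]
    gamma, ll = posterior_probs(params, obs)

    # reorder everything into Q, D, R
    order = np.argsort(params.means, kind="stable")   # order[rank] = internal idx
    inv = np.empty(3, dtype=int)
    inv[order] = np.arange(3)                          # internal idx -> rank
    state_idx = inv[raw_path]
    labels = np.array(STATE_NAMES, dtype="<U1")[state_idx]
    posteriors = gamma[:, order]
    assert all(mapping[int(i)] == STATE_NAMES[inv[int(i)]] for i in range(3))
    return StateSequence(
        animal_id=animal_id,
        labels=labels,
        state_idx=state_idx,
        posteriors=posteriors,
        log_likelihood=ll,
        times=times,
        segment_id=segment_id,
    )


def viterbi_paths_batch(params: HMMParams, Y: np.ndarray) -> np.ndarray:
    """Decode many equal-length sequences at once; returns (B, T) ranks in
    package state order (0=Q, 1=D, 2=R)."""
    params.validate()
    Y = np.asarray(Y, dtype=float)
    logB = _log_emissions(params, Y)
    raw = _viterbi_batch(params, logB)
    order = np.argsort(params.means, kind="stable")
    inv = np.empty(params.n_states, dtype=int)
    inv[order] = np.arange(params.n_states)
    return inv[raw]
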