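import numpy as np
import pytest

import wormstates as ws


@pytest.fixture
def control_config():
    """Study-condition control regime: 1 fps, 30 min, printed control rates."""
    return ws.SimulationConfig()


@pytest.fixture
def short_config():
    """Control regime but a short session, for fast end-to-end tests."""
    return ws.SimulationConfig(duration_s=300.0, arena_px=(128, 128))


def random_valid_params(rng: np.random.Generator, n_states: int = 3) -> ws.HMMParams:
    """A random well-formed HMM with distinct emission means."""
    pi = rng.dirichlet(np.ones(n_states))
    A = rng.dirichlet(np.ones(n_states), size=n_states)
    means = np.sort(rng.normal(0.0, 2.0, n_states))
    while np.any(np.diff(means) < 0.1):
        means = np.sort(rng.normal(0.0, 2.0, n_states))
    sds = rng.uniform(0.3, 1.5, n_states)
    return ws.HMMParams(pi=pi, A=A, means=means, sds=sds)


def brute_force_forward(params: ws.HMMParams, obs: np.ndarray) -> float:
    """Log-likelihood by exhaustive summation over all state paths."""
    from itertools import product
    from scipy.stats import norm

    K = params.n_states
    T = len(obs)
    total = -np.inf
    for path in product(range(K), repeat=T):
        lp = np.log(params.pi[path[0]])
        for t in range(1, T):
            lp += np.log(params.A[path[t - 1], path[t]])
        for t in range(T):
            lp += norm.logpdf(obs[t], params.means[path[t]], params.sds[path[t]])
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_viterbi(params: ws.HMMParams, obs: np.ndarray) -> tuple[tuple, float]:
    """Best path by enumeration; ties resolved to the lexicographically
    smallest path (matching per-step lowest-index tie-breaking when the
    optimum is unique)."""
    from itertools import product
    from scipy.stats import norm

    K = params.n_states
    T = len(obs)
    best_path, best_lp = None, -np.inf
    for path in product(range(K), repeat=T):
        lp = np.log(params.pi[path[0]])
        for t in range(1, T):
            lp += np.log(params.A[path[t - 1], path[t]])
        for t in range(T):
            lp += norm.logpdf(obs[t], params.means[path[t]], params.sds[path[t]])
        if lp > best_lp:
            best_path, best_lp = path, lp
    return best_path, float(best_lp)
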