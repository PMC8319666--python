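"""Synthetic single-worm sessions with known ground truth.

Locomotor behavior is modeled as a discrete-time Markov chain over the
three states quiescence (Q), dwelling (D) and roaming (R), observed at a
fixed frame rate. Per-second transition rates are converted to per-frame
probabilities linearly, ``p[i][j] = r[i][j] / frame_rate_hz``, which at
1 fps and the rate scale of the satiety-quiescence assay (1e-4 .. 5e-2
per second) is indistinguishable from the matrix exponential and makes
the downstream count-based rate estimator the exact inverse of the
generator.

On top of the state sequence the module generates centroid kinematics
(state-dependent log-normal speeds, persistent headings while roaming,
back-and-forth reversals while dwelling, a Gaussian jitter floor while
quiescent), renders image stacks of a single bright disk per frame, and
assembles whole mock RNAi screens in which knockdown effects are
expressed as multiplicative changes to the control transition rates.

State index convention throughout the package: 0 = Q, 1 = D, 2 = R
(ascending typical speed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

STATE_NAMES = ("Q", "D", "R")
N_STATES = 3
IDX_Q, IDX_D, IDX_R = 0, 1, 2

# Control-regime per-second rates r[i][j], rows/cols ordered Q, D, R.
# D->R = 0.001 and Q->R = 0.0002 are the printed control values of the
# assay; D<->Q are balanced at 0.02 (the control groups switch between
# dwelling and quiescence with roughly equal tendency, about every 50 s);
# exits from roaming are fast enough to keep roaming rare (~1% occupancy).
DEFAULT_CONTROL_RATES = np.array(
    [
        [0.0, 0.02, 0.0002],  # Q -> (Q, D, R)
        [0.02, 0.0, 0.001],   # D -> (Q, D, R)
        [0.005, 0.05, 0.0],   # R -> (Q, D, R)
    ]
)


@dataclass(frozen=True)
class EmissionModel:
    """Log-normal speed model for one state: speed = exp(N(mu, sigma)) px/s."""

    mu: float
    sigma: float


# Defaults chosen for identifiability: the three log-speed distributions are
# separated by >3 pooled standard deviations. Q's entry is the effective
# log-speed floor set by centroid jitter, not a locomotion speed.
DEFAULT_EMISSIONS = (
    EmissionModel(mu=-1.9, sigma=0.5),            # Q: jitter floor ~0.15 px/s
    EmissionModel(mu=float(np.log(2.0)), sigma=0.35),   # D: ~2 px/s
    EmissionModel(mu=float(np.log(10.0)), sigma=0.30),  # R: ~10 px/s
)


@dataclass
class SimulationConfig:
    """Parameters of one simulated recording session.

    Attributes
    ----------
    frame_rate_hz : frames per second (assay default 1.0).
    duration_s : session length in seconds (assay default 1800 = 30 min).
    rates : 3x3 per-second transition rates r[i][j], diagonal ignored.
    emissions : per-state log-speed model (Q, D, R order).
    jitter_px : sd of the isotropic centroid jitter while quiescent.
    heading_diffusion_rad : per-frame angular diffusion sd while roaming.
    seed : default RNG seed for operations that are not passed one.
    arena_px : (width, height) of the rendered arena in pixels.
    worm_radius_px : radius of the rendered worm blob.
    """

    frame_rate_hz: float = 1.0
    duration_s: float = 1800.0
    rates: np.ndarray = field(default_factory=lambda: DEFAULT_CONTROL_RATES.copy())
    emissions: tuple[EmissionModel, EmissionModel, EmissionModel] = DEFAULT_EMISSIONS
    jitter_px: float = 0.15
    heading_diffusion_rad: float = 0.15
    seed: int = 0
    arena_px: tuple[int, int] = (256, 256)
    worm_radius_px: float = 4.0

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.validate()

    @property
    def n_frames(self) -> int:
        n = self.duration_s * self.frame_rate_hz
        return int(round(n))

    def validate(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        n = self.duration_s * self.frame_rate_hz
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration_s * frame_rate_hz must be a positive integer, got {n}"
            )
        r = self.rates
        if r.shape != (N_STATES, N_STATES):
            raise ValueError("rates must be a 3x3 matrix")
        off = r.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("transition rates must be non-negative")
        row_exit = off.sum(axis=1) / self.frame_rate_hz
        bad = np.nonzero(row_exit >= 1.0)[0]
        if bad.size:
            names = ", ".join(STATE_NAMES[i] for i in bad)
            raise ValueError(
                f"per-frame exit probability >= 1 for state(s) {names}: "
                f"sum of outgoing rates must be < frame_rate_hz"
            )
        mus = [e.mu for e in self.emissions]
        if not (mus[IDX_Q] < mus[IDX_D] < mus[IDX_R]):
            raise ValueError(
                "emission means must satisfy mu_Q < mu_D < mu_R "
                "(states are identified by speed)"
            )
        if any(e.sigma < 0 for e in self.emissions):
            raise ValueError("emission sigmas must be non-negative")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruthTrack:
    """A simulated animal: timestamps, centroid positions, true states."""

    times: np.ndarray           # (T,) seconds
    positions: np.ndarray       # (T, 2) x_px, y_px
    true_states: np.ndarray     # (T,) int in {0=Q, 1=D, 2=R}
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.positions) == len(self.true_states)):
            raise ValueError("times, positions and true_states must align")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class EffectSpec:
    """A simulated knockdown: multiplicative changes to control rates."""

    gene_label: str
    rate_multipliers: np.ndarray = field(
        default_factory=lambda: np.ones((N_STATES, N_STATES))
    )
    n_treated: int = 16
    n_control: int = 8

    def __post_init__(self) -> None:
        self.rate_multipliers = np.asarray(self.rate_multipliers, dtype=float)
        if self.rate_multipliers.shape != (N_STATES, N_STATES):
            raise ValueError("rate_multipliers must be 3x3")
        if np.any(self.rate_multipliers <= 0):
            raise ValueError("rate multipliers must be positive")
        if self.n_treated < 1 or self.n_control < 1:
            raise ValueError("group sizes must be >= 1")


def transition_matrix(config: SimulationConfig) -> np.ndarray:
    """Per-frame transition probability matrix P with p[i][j] = r[i][j]/f."""
    off = config.rates.copy()
    np.fill_diagonal(off, 0.0)
    P = off / config.frame_rate_hz
    np.fill_diagonal(P, 1.0 - P.sum(axis=1))
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (pi P = pi)."""
    P = np.asarray(P, dtype=float)
    k = P.shape[0]
    # Solve (P^T - I) pi = 0 with the normalization row appended.
    a = np.vstack([P.T - np.eye(k), np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _simulate_states_batch(
    P: np.ndarray, pi0: np.ndarray, n_frames: int, n_animals: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate (n_animals, n_frames) independent chains with shared P."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    out = np.empty((n_animals, n_frames), dtype=np.int8)
    state = np.searchsorted(np.cumsum(pi0), rng.random(n_animals), side="right")
    state = np.clip(state, 0, P.shape[0] - 1).astype(np.int8)
    out[:, 0] = state
    u = rng.random((n_frames - 1, n_animals))
    for t in range(1, n_frames):
        # next state = first column where cumulative prob exceeds u
        state = (u[t - 1][:, None] > cum[state][:, :-1]).sum(axis=1).astype(np.int8)
        out[:, t] = state
    return out


def simulate_state_sequence(
    config: SimulationConfig, seed: int | None = None, n_frames: int | None = None
) -> np.ndarray:
    """Simulate one per-frame state sequence from the configured chain.

    The initial state is drawn from the chain's stationary distribution,
    so short sessions need no burn-in. Returns an int array in {0,1,2}
    (Q, D, R); reproducible given the seed.
    """
    config.validate()
    if n_frames is None:
        n_frames = config.n_frames
    rng = np.random.default_rng(config.seed if seed is None else seed)
    P = transition_matrix(config)
    pi0 = stationary_distribution(P)
    return _simulate_states_batch(P, pi0, n_frames, 1, rng)[0]


def simulate_log_speeds(
    states: np.ndarray, config: SimulationConfig, seed: int | None = None
) -> np.ndarray:
    """Draw the HMM's observation sequence directly: y_t ~ N(mu_s, sigma_s).

    These are log-speeds in log(px/s); ``exp`` of them gives the speeds a
    tracker would measure. Useful for testing the model-fitting stages
    without going through rendering and centroid extraction.
    """
    states = np.asarray(states)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mus = np.array([e.mu for e in config.emissions])
    sds = np.array([e.sigma for e in config.emissions])
    return rng.normal(mus[states], sds[states])


def simulate_track(
    states: np.ndarray, config: SimulationConfig, seed: int | None = None
) -> GroundTruthTrack:
    """Generate centroid kinematics for a given state sequence.

    Per frame, the displacement to the next frame depends on the current
    state: roaming moves at a log-normal speed along a persistent heading
    with small angular diffusion; dwelling moves at a (lower) log-normal
    speed and reverses heading with probability 1/2 each frame; quiescence
    displaces only by isotropic Gaussian jitter of sd ``jitter_px``.
    Positions reflect off the arena walls (inset by the worm radius so
    rendered disks always fit).
    """
    states = np.asarray(states)
    if states.size == 0:
        raise ValueError("state sequence must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = states.size
    dt = 1.0 / config.frame_rate_hz
    w, h = config.arena_px
    r = config.worm_radius_px
    lo = np.array([r, r])
    hi = np.array([w - 1 - r, h - 1 - r])
    if np.any(hi <= lo):
        raise ValueError("worm radius too large for the arena")

    mus = np.array([e.mu for e in config.emissions])
    sds = np.array([e.sigma for e in config.emissions])

    pos = np.empty((T, 2))
    pos[0] = rng.uniform(lo, hi)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    for t in range(T - 1):
        s = states[t]
        if s == IDX_Q:
            step = rng.normal(0.0, config.jitter_px, size=2)
        else:
            speed = np.exp(rng.normal(mus[s], sds[s]))
            if s == IDX_D:
                if rng.random() < 0.5:
                    heading += np.pi
            else:  # roaming: persistent heading with angular diffusion
                heading += rng.normal(0.0, config.heading_diffusion_rad)
            step = speed * dt * np.array([np.cos(heading), np.sin(heading)])
        nxt = pos[t] + step
        # reflect into [lo, hi] (repeat in case of large excursions)
        for _ in range(8):
            over = nxt > hi
            under = nxt < lo
            if not (over.any() or under.any()):
                break
            nxt = np.where(over, 2 * hi - nxt, nxt)
            nxt = np.where(under, 2 * lo - nxt, nxt)
        pos[t + 1] = nxt

    times = np.arange(T) * dt
    return GroundTruthTrack(times=times, positions=pos, true_states=states, config=config)


def render_frames(
    track: GroundTruthTrack,
    config: SimulationConfig | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    foreground: int = 200,
    background: int = 0,
) -> np.ndarray:
    """Render a (T, H, W) uint8 stack: one bright disk per frame.

    Each frame is a dark background with a single filled disk of the
    configured radius centered at the true centroid (a pixel belongs to
    the disk if its center lies within the radius; radius 0 lights the
    single nearest pixel). Optional additive Gaussian pixel noise.
    """
    if config is None:
        config = track.config
    w, h = config.arena_px
    r = config.worm_radius_px
    if 2 * r >= min(w, h):
        raise ValueError("worm radius must be smaller than the arena")
    pos = track.positions
    if np.any(pos < -0.5) or np.any(pos[:, 0] > w - 0.5) or np.any(pos[:, 1] > h - 0.5):
        raise ValueError("positions outside the arena")
    T = len(pos)
    stack = np.full((T, h, w), background, dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    rng = np.random.default_rng(seed) if noise_sd > 0 else None
    for t in range(T):
        x, y = pos[t]
        if r == 0:
            stack[t, int(round(y)), int(round(x))] = foreground
        else:
            mask = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
            stack[t][mask] = foreground
        if rng is not None:
            noisy = stack[t].astype(float) + rng.normal(0.0, noise_sd, size=(h, w))
            stack[t] = np.clip(noisy, 0, 255).astype(np.uint8)
    return stack


@dataclass
class ScreenGroup:
    gene_label: str
    role: str  # "control" | "treated"
    tracks: list[GroundTruthTrack]
    rates: np.ndarray
    seeds: list[int]


@dataclass
class ScreenBundle:
    """Tracks plus a manifest for one simulated RNAi screen."""

    groups: list[ScreenGroup]
    manifest: dict

    def group(self, gene_label: str, role: str) -> ScreenGroup:
        for g in self.groups:
            if g.gene_label == gene_label and g.role == role:
                return g
        raise KeyError(f"no {role} group for {gene_label}")


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def make_screen_dataset(
    control_config: SimulationConfig,
    effects: list[EffectSpec],
    seed: int,
    with_kinematics: bool = True,
) -> ScreenBundle:
    """Simulate a whole screen: per gene, a concurrent control group and a
    treated group whose transition rates are the control rates multiplied
    elementwise by the effect's ``rate_multipliers``.

    All animals are statistically independent given the master seed. With
    ``with_kinematics=False`` only state sequences are generated (positions
    are omitted), which is much faster for statistics-level studies.
    """
    if not effects:
        raise ValueError("at least one effect is required")
    groups: list[ScreenGroup] = []
    manifest: dict = {"seed": seed, "genes": []}
    gene_seeds = _spawn_seeds(seed, len(effects))
    for eff, gseed in zip(effects, gene_seeds):
        treated_rates = control_config.rates * eff.rate_multipliers
        try:
            treated_config = control_config.replace(rates=treated_rates)
        except ValueError as exc:
            raise ValueError(
                f"gene {eff.gene_label!r}: multiplied rates invalid ({exc})"
            ) from exc
        animal_seeds = _spawn_seeds(gseed, eff.n_control + eff.n_treated)
        ctrl_seeds = animal_seeds[: eff.n_control]
        trt_seeds = animal_seeds[eff.n_control:]
        ctrl_tracks = [
            _simulate_animal(control_config, s, with_kinematics) for s in ctrl_seeds
        ]
        trt_tracks = [
            _simulate_animal(treated_config, s, with_kinematics) for s in trt_seeds
        ]
        groups.append(
            ScreenGroup(eff.gene_label, "control", ctrl_tracks, control_config.rates, ctrl_seeds)
        )
        groups.append(
            ScreenGroup(eff.gene_label, "treated", trt_tracks, treated_rates, trt_seeds)
        )
        manifest["genes"].append(
            {
                "gene_label": eff.gene_label,
                "n_control": eff.n_control,
                "n_treated": eff.n_treated,
                "control_rates": control_config.rates.tolist(),
                "treated_rates": treated_rates.tolist(),
                "control_seeds": ctrl_seeds,
                "treated_seeds": trt_seeds,
            }
        )
    return ScreenBundle(groups=groups, manifest=manifest)


def _simulate_animal(
    config: SimulationConfig, seed: int, with_kinematics: bool
) -> GroundTruthTrack:
    states = simulate_state_sequence(config, seed=seed)
    if with_kinematics:
        return simulate_track(states, config, seed=seed + 1)
    times = np.arange(states.size) / config.frame_rate_hz
    pos = np.full((states.size, 2), np.nan)
    return GroundTruthTrack(times=times, positions=pos, true_states=states, config=config)
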