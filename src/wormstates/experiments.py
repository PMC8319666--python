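"""Replicate simulation studies: calibration and power of the screen stats.

These routines run the package's own machinery over many replicate
synthetic screens to answer two questions a screener cares about:

* calibration -- under a null effect (treated and control animals drawn
  from the same law), how often does the Bonferroni-corrected family
  produce any false positive, and does the normalized quiescence value
  center on 1?
* power -- for a knockdown of known size (multiplicative changes to the
  dwelling<->quiescence rates), how often is the gene detected and
  classified "reduced" at paper-scale group sizes?

The calibration study operates on ground-truth state sequences (the
statistics under test are the screen-level ones; state inference is
exercised and validated separately), while the power study runs the full
inference chain: simulate log-speed observations, fit the HMM on the
concurrent controls, freeze it, decode everyone, summarize, normalize
and classify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import fit_baum_welch, viterbi_paths_batch
from .metrics import summarize
from .screen import (
    bonferroni_threshold,
    classify_quiescence,
    group_summary,
    normalize_to_control,
    two_sample_t_test,
)
from .simulate import (
    IDX_D,
    IDX_Q,
    SimulationConfig,
    _simulate_states_batch,
    stationary_distribution,
    transition_matrix,
)


@dataclass
class NullCalibration:
    n_families: int
    n_genes: int
    alpha: float
    family_size: int
    familywise_fp_rate: float
    median_norm_q_per_gene: np.ndarray   # (n_genes,)
    all_norm_q: np.ndarray               # (n_families, n_genes)


def null_screen_calibration(
    config: SimulationConfig,
    n_families: int = 200,
    n_genes: int = 28,
    n_control: int = 8,
    n_treated: int = 16,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullCalibration:
    """Replicate whole null screens and measure family-wise calibration.

    Each family simulates, for every gene, an independent concurrent
    control group and a treated group from the identical chain, computes
    per-animal percent times, tests dwelling and quiescence with the
    pooled-variance t-test, and records whether any of the
    n_genes x 2 comparisons clears the Bonferroni threshold.
    """
    rng = np.random.default_rng(seed)
    P = transition_matrix(config)
    pi0 = stationary_distribution(P)
    T = config.n_frames
    m = 2 * n_genes
    thr = bonferroni_threshold(alpha, m)
    per_gene = n_control + n_treated

    fp_families = 0
    norm_q = np.empty((n_families, n_genes))
    for fam in range(n_families):
        batch = _simulate_states_batch(P, pi0, T, n_genes * per_gene, rng)
        frac_q = 100.0 * (batch == IDX_Q).mean(axis=1)
        frac_d = 100.0 * (batch == IDX_D).mean(axis=1)
        any_fp = False
        for g in range(n_genes):
            block = slice(g * per_gene, (g + 1) * per_gene)
            cq, tq = frac_q[block][:n_control], frac_q[block][n_control:]
            cd, td = frac_d[block][:n_control], frac_d[block][n_control:]
            p_q = two_sample_t_test(tq, cq).p
            p_d = two_sample_t_test(td, cd).p
            if p_q < thr.exact or p_d < thr.exact:
                any_fp = True
            norm_q[fam, g] = tq.mean() / cq.mean()
        fp_families += any_fp
    return NullCalibration(
        n_families=n_families,
        n_genes=n_genes,
        alpha=alpha,
        family_size=m,
        familywise_fp_rate=fp_families / n_families,
        median_norm_q_per_gene=np.median(norm_q, axis=0),
        all_norm_q=norm_q,
    )


@dataclass
class EffectDetection:
    n_replicates: int
    detection_rate: float        # fraction with norm Q < 0.8 AND class "reduced"
    norm_q_values: np.ndarray    # (n_replicates,)
    expected_norm_q: float       # stationary-ratio prediction for the effect


def effect_detection_study(
    config: SimulationConfig,
    rate_multipliers: np.ndarray | None = None,
    n_replicates: int = 50,
    n_control: int = 8,
    n_treated: int = 16,
    seed: int = 0,
) -> EffectDetection:
    """Replicate end-to-end screens of one knockdown gene.

    Default effect: quiescence-to-dwelling rate doubled and
    dwelling-to-quiescence rate halved (a quiescence-reducing knockdown).
    Per replicate: simulate state chains and log-speed observations for
    both groups, fit the HMM on the control group, decode every animal
    with the frozen model, summarize, normalize to the concurrent
    control, and classify with the +/-20% band rule.
    """
    if rate_multipliers is None:
        rate_multipliers = np.ones((3, 3))
        rate_multipliers[IDX_Q, IDX_D] = 2.0
        rate_multipliers[IDX_D, IDX_Q] = 0.5
    treated_config = config.replace(rates=config.rates * rate_multipliers)
    P_c = transition_matrix(config)
    P_t = transition_matrix(treated_config)
    pi_c = stationary_distribution(P_c)
    pi_t = stationary_distribution(P_t)
    expected = pi_t[IDX_Q] / pi_c[IDX_Q]
    T = config.n_frames
    mus = np.array([e.mu for e in config.emissions])
    sds = np.array([e.sigma for e in config.emissions])

    rng = np.random.default_rng(seed)
    norm_q = np.empty(n_replicates)
    detected = 0
    for rep in range(n_replicates):
        ctrl_states = _simulate_states_batch(P_c, pi_c, T, n_control, rng)
        trt_states = _simulate_states_batch(P_t, pi_t, T, n_treated, rng)
        ctrl_obs = rng.normal(mus[ctrl_states], sds[ctrl_states])
        trt_obs = rng.normal(mus[trt_states], sds[trt_states])
        params, _ = fit_baum_welch(list(ctrl_obs), max_iter=200)
        groups = {}
        for role, obs in (("control", ctrl_obs), ("treated", trt_obs)):
            paths = viterbi_paths_batch(params, obs)
            summaries = [
                summarize(paths[k], config.frame_rate_hz, f"{role}_{k}")
                for k in range(paths.shape[0])
            ]
            groups[role] = group_summary("gene", role, summaries)
        norm = normalize_to_control(groups["treated"], groups["control"])
        q = norm["pct_Q"].value
        norm_q[rep] = q
        cls = classify_quiescence(q, rule="ratio_band", band=0.20)
        if np.isfinite(q) and q < 0.8 and cls == "reduced":
            detected += 1
    return EffectDetection(
        n_replicates=n_replicates,
        detection_rate=detected / n_replicates,
        norm_q_values=norm_q,
        expected_norm_q=float(expected),
    )


@dataclass
class ParameterRecovery:
    fitted_params: "object"
    max_abs_err_A: float
    max_abs_err_means: float
    decode_accuracy: float


def parameter_recovery_study(
    config: SimulationConfig,
    n_animals: int = 20,
    seed: int = 0,
) -> ParameterRecovery:
    """Fit the HMM on simulated sessions and compare with the generator.

    Reports the largest absolute error of the per-frame transition
    probabilities and emission means, and the frame-wise Viterbi accuracy
    against the ground-truth states.
    """
    rng = np.random.default_rng(seed)
    P = transition_matrix(config)
    pi0 = stationary_distribution(P)
    T = config.n_frames
    mus = np.array([e.mu for e in config.emissions])
    sds = np.array([e.sigma for e in config.emissions])
    states = _simulate_states_batch(P, pi0, T, n_animals, rng)
    obs = rng.normal(mus[states], sds[states])
    params, trace = fit_baum_welch(list(obs))
    assert np.all(np.diff(trace) >= -1e-8)
    paths = viterbi_paths_batch(params, obs)
    return ParameterRecovery(
        fitted_params=params,
        max_abs_err_A=float(np.abs(params.A - P).max()),
        max_abs_err_means=float(np.abs(params.means - mus).max()),
        decode_accuracy=float((paths == states).mean()),
    )
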