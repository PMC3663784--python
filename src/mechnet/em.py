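"""Heuristic-EM engine for active-subnetwork recovery.

The algorithm alternates:

* **E-step** — for each interaction, the active posterior is proportional to
  the H1 noise likelihood times ``exp(psi_1)`` and the inactive posterior to
  the H0 likelihood times ``exp(psi_0)``, with the MRF potentials evaluated
  at the *expected* opposite-state neighbor counts computed from the
  incoming posteriors (heuristic belief propagation).  All interactions are
  updated synchronously; optional damping blends old and new posteriors.
* **M-step** — ``r_alpha`` via the posterior- (or rank-) weighted Fisher-z
  mean, and the MRF parameters by bounded pseudo-likelihood maximization.

States are initialized from a one-sided correlation t-test.  Iteration
stops when the thresholded state assignment repeats (or the posteriors move
less than a tolerance), or at ``max_iter``.  Runaway reinforcement — the
coupling driving every interaction into one state — is detected and
reported, not silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .mrf import (
    DEFAULT_MIN_PAIRS,
    DEFAULT_PSI_BOUNDS,
    FullParamPsi,
    LineGraphIndex,
    PsiFit,
    SingleParamPsi,
    _pl_and_conditionals,
    _potential_arrays,
    fit_psi,
)
from .network import CorrelationData, InteractionNetwork, StateVector
from .noise import (
    NoiseParams,
    estimate_r_alpha,
    fisher_z,
    likelihood_active,
    likelihood_inactive,
)

__all__ = [
    "EmConfig",
    "EmResult",
    "initialize_states",
    "e_step",
    "m_step",
    "complete_data_loglik",
    "run_em",
]

logger = logging.getLogger(__name__)

#: Small-network cutoff below which the full model defaults to a single
#: pair of global bias parameters (overfitting guard).
GLOBAL_BIAS_CUTOFF = 500


@dataclass
class EmConfig:
    """Configuration for :func:`run_em`.

    ``bias_mode='auto'`` resolves to ``global`` for networks with fewer than
    500 interactions and ``per_mechanism`` otherwise.  ``psi_init=None``
    uses the standard initialization: single model (gamma_0=1, gamma_1=1,
    beta=2); full model all gammas 1, beta 2 on same-mechanism pairs, 0
    elsewhere.  ``r_alpha_init=None`` estimates r_alpha once from the
    t-test-initialized states.
    """

    model: str = "single"  # single | full
    bias_mode: str = "auto"  # auto | global | per_mechanism
    max_iter: int = 50
    init_alpha: float = 0.05
    psi_init: SingleParamPsi | FullParamPsi | None = None
    r_alpha_init: float | None = None
    weighting: str = "posterior"  # posterior | rank
    negative_mode: str = "signed"  # signed | absolute
    damping: float = 0.0
    psi_bounds: tuple[float, float] = DEFAULT_PSI_BOUNDS
    min_pairs: int = DEFAULT_MIN_PAIRS
    #: pin every coupling at its initial value; fit bias terms only
    freeze_beta: bool = False
    #: skip the Psi M-step entirely (Psi stays at its initialization);
    #: with beta = 0 and tied gammas this collapses EM onto the ML baseline
    freeze_psi: bool = False
    posterior_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("single", "full"):
            raise ValueError(f"model must be single|full, got {self.model}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0.0 <= self.damping < 1.0:
            raise ValueError("damping must be in [0, 1)")

    def resolved_bias_mode(self, n_interactions: int) -> str:
        if self.bias_mode != "auto":
            return self.bias_mode
        return "global" if n_interactions < GLOBAL_BIAS_CUTOFF else "per_mechanism"


@dataclass
class EmResult:
    """Posteriors, thresholded states, fitted parameters and the run trace."""

    posteriors: dict[str, float]
    states: StateVector
    theta: NoiseParams
    psi: SingleParamPsi | FullParamPsi
    psi_fit: PsiFit | None
    iterations: int
    converged: bool
    runaway: bool
    trace: list[dict]
    excluded: tuple[str, ...] = ()
    #: 0 for a fixed point; > 1 when the synchronous dynamics entered an
    #: exact limit cycle of that period (the assignment has stabilized up
    #: to a small recurring flip set).
    cycle_length: int = 0


def _threshold(posteriors: np.ndarray) -> np.ndarray:
    # ties at exactly 0.5 go inactive, favoring the null
    return (posteriors > 0.5).astype(int)


def initialize_states(
    corr: CorrelationData, alpha: float = 0.05, negative_mode: str = "signed"
) -> StateVector:
    """Active iff the one-sided correlation t-test rejects at level ``alpha``.

    The p-value is the survival probability of ``t = r*sqrt((n-2)/(1-r^2))``
    under Student t with ``n-2`` degrees of freedom (computed on ``|r|`` in
    absolute mode) — i.e. exactly the H0 noise likelihood.
    """
    states = {}
    for i, r in corr.values.items():
        p = likelihood_inactive(r, corr.n, negative_mode=negative_mode)
        states[i] = int(p < alpha)
    return StateVector(states=states)


def _noise_loglik_arrays(
    r: np.ndarray, theta: NoiseParams
) -> tuple[np.ndarray, np.ndarray]:
    l1 = np.asarray(likelihood_active(r, theta), dtype=float)
    l0 = np.asarray(
        likelihood_inactive(r, theta.n, negative_mode=theta.negative_mode), dtype=float
    )
    tiny = np.finfo(float).tiny
    return np.log(np.maximum(l1, tiny)), np.log(np.maximum(l0, tiny))


def _e_step_arrays(
    idx: LineGraphIndex,
    p: np.ndarray,
    logl1: np.ndarray,
    logl0: np.ndarray,
    psi: SingleParamPsi | FullParamPsi,
    damping: float = 0.0,
) -> np.ndarray:
    exps = idx.opposite_expectations(p)
    psi1, psi0 = _potential_arrays(idx, exps, psi)
    # posterior log-odds = noise log-LR + prior log-odds
    log_odds = (logl1 - logl0) + (psi1 - psi0)
    new_p = 1.0 / (1.0 + np.exp(np.clip(-log_odds, -700.0, 700.0)))
    if damping > 0.0:
        new_p = damping * p + (1.0 - damping) * new_p
    return new_p


def e_step(
    posteriors: Mapping[str, float],
    corr: CorrelationData,
    theta: NoiseParams,
    psi: SingleParamPsi | FullParamPsi,
    net: InteractionNetwork,
    damping: float = 0.0,
    index: LineGraphIndex | None = None,
) -> dict[str, float]:
    """One synchronous posterior update over all interactions."""
    idx = index if index is not None else LineGraphIndex(net)
    p = idx.vector(posteriors)
    r = idx.vector(corr.values)
    logl1, logl0 = _noise_loglik_arrays(r, theta)
    new_p = _e_step_arrays(idx, p, logl1, logl0, psi, damping=damping)
    return {i: float(v) for i, v in zip(idx.ids, new_p)}


def m_step(
    posteriors: Mapping[str, float],
    corr: CorrelationData,
    net: InteractionNetwork,
    config: EmConfig,
    psi_current: SingleParamPsi | FullParamPsi | None = None,
    index: LineGraphIndex | None = None,
) -> tuple[NoiseParams, PsiFit]:
    """Re-estimate Theta (r_alpha) and Psi (pseudo-likelihood fit)."""
    idx = index if index is not None else LineGraphIndex(net)
    p = idx.vector(posteriors)
    r = idx.vector(corr.values)
    z = fisher_z(r)
    if config.negative_mode == "absolute":
        z = np.abs(z)
    r_alpha = estimate_r_alpha(z, p, weighting=config.weighting)
    theta = NoiseParams(
        r_alpha=r_alpha,
        n=corr.n,
        negative_mode=config.negative_mode,
        weighting=config.weighting,
    )
    if config.freeze_psi:
        psi = psi_current if psi_current is not None else _default_psi(config, idx)
        from .mrf import pseudo_likelihood

        fit = PsiFit(
            psi=psi,
            pseudo_loglik=pseudo_likelihood(psi, posteriors, net, index=idx),
            converged=True,
            message="psi frozen by config",
            frozen=frozenset({"*"}),
        )
        return theta, fit
    bias_mode = config.resolved_bias_mode(len(idx.ids))
    fit = fit_psi(
        posteriors,
        net,
        model=config.model,
        bias_mode=bias_mode,
        bounds=config.psi_bounds,
        init=psi_current,
        min_pairs=config.min_pairs,
        freeze_beta=config.freeze_beta,
        index=idx,
    )
    return theta, fit


def complete_data_loglik(
    posteriors: Mapping[str, float],
    corr: CorrelationData,
    theta: NoiseParams,
    psi: SingleParamPsi | FullParamPsi,
    net: InteractionNetwork,
    index: LineGraphIndex | None = None,
) -> float:
    """Expected complete-data log-likelihood F.

    Sum over interactions and states of ``[log noise-likelihood + log
    normalized MRF conditional] * posterior``; the MRF conditional uses
    expected neighbor counts from the same posteriors.
    """
    idx = index if index is not None else LineGraphIndex(net)
    p = idx.vector(posteriors)
    r = idx.vector(corr.values)
    logl1, logl0 = _noise_loglik_arrays(r, theta)
    exps = idx.opposite_expectations(p)
    pl, cond = _pl_and_conditionals(idx, p, exps, psi)
    noise_term = float(np.dot(p, logl1) + np.dot(1.0 - p, logl0))
    return noise_term + pl


def _default_psi(config: EmConfig, idx: LineGraphIndex) -> SingleParamPsi | FullParamPsi:
    if config.psi_init is not None:
        return config.psi_init
    if config.model == "single":
        return SingleParamPsi(gamma0=1.0, gamma1=1.0, beta=2.0)
    return FullParamPsi.initial(
        idx.mechs, bias_mode=config.resolved_bias_mode(len(idx.ids))
    )


def run_em(
    net: InteractionNetwork,
    corr: CorrelationData,
    config: EmConfig | None = None,
) -> EmResult:
    """Run the full EM loop; deterministic for fixed inputs and config.

    Interactions without a correlation value are excluded (with a warning)
    and the model runs on the induced subnetwork.  Convergence is exact
    equality of successive thresholded state vectors, with a small maximum
    posterior change as a secondary stop.
    """
    config = config if config is not None else EmConfig()
    missing = [i for i in net.interactions if i not in corr.values]
    if missing:
        logger.warning(
            "excluding %d interaction(s) without correlation values", len(missing)
        )
        kept = [ia for i, ia in net.interactions.items() if i not in set(missing)]
        net = InteractionNetwork(kept)
    corr.require_network(net)

    idx = LineGraphIndex(net)
    states0 = initialize_states(corr, config.init_alpha, config.negative_mode)
    p = idx.vector({i: float(s) for i, s in states0.states.items()})
    r = idx.vector(corr.values)
    z = fisher_z(r)
    if config.negative_mode == "absolute":
        z = np.abs(z)

    if config.r_alpha_init is not None:
        r_alpha = config.r_alpha_init
    elif p.sum() > 0:
        r_alpha = estimate_r_alpha(z, p, weighting="posterior")
    else:  # nothing initially significant: fall back to a mid-scale default
        r_alpha = 0.5
    theta = NoiseParams(
        r_alpha=r_alpha,
        n=corr.n,
        negative_mode=config.negative_mode,
        weighting=config.weighting,
    )
    psi: SingleParamPsi | FullParamPsi = _default_psi(config, idx)
    psi_fit: PsiFit | None = None

    logl1, logl0 = _noise_loglik_arrays(r, theta)
    prev_states = _threshold(p)
    converged = False
    cycle_length = 0
    iterations = 0
    trace: list[dict] = []
    seen_states: dict[bytes, int] = {prev_states.tobytes(): 0}

    for it in range(1, config.max_iter + 1):
        iterations = it
        new_p = _e_step_arrays(idx, p, logl1, logl0, psi, damping=config.damping)
        new_states = _threshold(new_p)
        changes = int(np.sum(new_states != prev_states))
        posteriors_map = {i: float(v) for i, v in zip(idx.ids, new_p)}
        f_value = complete_data_loglik(posteriors_map, corr, theta, psi, net, index=idx)
        trace.append(
            {
                "iteration": it,
                "state_changes": changes,
                "F": f_value,
                "r_alpha": theta.r_alpha,
            }
        )
        logger.info(
            "iter %d: %d state change(s), F=%.4f, r_alpha=%.4f",
            it,
            changes,
            f_value,
            theta.r_alpha,
        )
        max_delta = float(np.max(np.abs(new_p - p))) if len(p) else 0.0
        if changes == 0 or max_delta < config.posterior_tol:
            p = new_p
            prev_states = new_states
            converged = True
            break
        key = new_states.tobytes()
        if key in seen_states:
            # the synchronous update has entered an exact limit cycle: the
            # state assignment is stable up to a recurring flip set
            cycle_length = it - seen_states[key]
            logger.info("state assignment cycles with period %d; stopping", cycle_length)
            p = new_p
            prev_states = new_states
            converged = True
            break
        seen_states[key] = it
        theta, psi_fit = m_step(
            posteriors_map, corr, net, config, psi_current=psi, index=idx
        )
        psi = psi_fit.psi
        logl1, logl0 = _noise_loglik_arrays(r, theta)
        p = new_p
        prev_states = new_states

    states = StateVector(states={i: int(s) for i, s in zip(idx.ids, prev_states)})
    runaway = bool(len(prev_states) > 0 and prev_states.min() == prev_states.max())
    return EmResult(
        posteriors={i: float(v) for i, v in zip(idx.ids, p)},
        states=states,
        theta=theta,
        psi=psi,
        psi_fit=psi_fit,
        iterations=iterations,
        converged=converged,
        runaway=runaway,
        trace=trace,
        excluded=tuple(missing),
        cycle_length=cycle_length,
    )
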