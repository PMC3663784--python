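"""Markov random field over interaction activity states.

Two parameterizations of the Gibbs distribution on the line graph:

* **single** — the 2-color Ising form.  Energy ``gamma_0*n_0 + gamma_1*n_1
  - beta*n_{0,1}`` with ``n_k`` the number of interactions in state ``k``
  and ``n_{0,1}`` the number of neighbor pairs in opposite states; every
  neighbor is equally influential.
* **full** — mechanism-dependent couplings.  Each interaction is biased by
  ``gamma_s^a`` (mechanism ``s``, activity ``a``; or a mechanism-free
  ``gamma^a`` in ``global`` bias mode) and each opposite-state neighbor pair
  with mechanisms ``(s, t)`` is penalized by a symmetric ``beta_{s,t}``.
  This is the reduced parameterization of the 2*|IM|-color model: couplings
  across activity levels are structural zeros, so only mechanism-pair
  disagreement penalties remain.

The conditional probability of a state given its neighborhood is the
softmax of the potentials ``psi_a = gamma(s, a) - sum_t beta_{s,t} *
(#neighbors of mechanism t not in state a)``.  During EM the observed
neighbor counts are replaced by their expectations under the current
posteriors (heuristic belief propagation).  Parameters are fitted by
maximizing the posterior-weighted pseudo-likelihood under box bounds;
mechanism pairs with too few interaction-interaction pairs in the network
are frozen at zero to avoid overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, sparse

from .network import InteractionNetwork, StateVector

__all__ = [
    "SingleParamPsi",
    "FullParamPsi",
    "PsiFit",
    "NeighborExpectation",
    "LineGraphIndex",
    "mechanism_pair",
    "potential_single",
    "potential_full",
    "conditional_state_prob",
    "expected_neighbor_counts",
    "gibbs_energy",
    "pseudo_likelihood",
    "fit_psi",
    "psi_table",
    "DEFAULT_PSI_BOUNDS",
    "DEFAULT_MIN_PAIRS",
]

#: Box bounds for every gamma/beta during fitting; prevents runaway
#: reinforcement from diverging the optimizer.
DEFAULT_PSI_BOUNDS: tuple[float, float] = (-10.0, 10.0)

#: Mechanism pairs with fewer I-I pairs than this in the network have their
#: coupling frozen at 0 (overfitting mitigation).
DEFAULT_MIN_PAIRS: int = 5


def mechanism_pair(s: str, t: str) -> tuple[str, str]:
    """Canonical unordered mechanism-pair key."""
    return (s, t) if s <= t else (t, s)


@dataclass
class SingleParamPsi:
    """Ising-form parameters (gamma_0, gamma_1, beta)."""

    gamma0: float = 1.0
    gamma1: float = 1.0
    beta: float = 2.0

    def gamma(self, state: int) -> float:
        return self.gamma1 if state == 1 else self.gamma0


@dataclass
class FullParamPsi:
    """Mechanism-dependent parameters {gamma_s^a, beta_{s,t}}.

    ``gamma`` maps ``(mechanism, activity) -> bias`` in ``per_mechanism``
    bias mode, or ``activity -> bias`` in ``global`` mode.  ``beta`` maps
    canonical mechanism pairs to the (symmetric) disagreement penalty.
    """

    gamma: dict
    beta: dict[tuple[str, str], float]
    bias_mode: str = "per_mechanism"
    frozen: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if self.bias_mode not in ("per_mechanism", "global"):
            raise ValueError(f"bias_mode must be per_mechanism|global, got {self.bias_mode}")
        self.beta = {mechanism_pair(*k): float(v) for k, v in self.beta.items()}

    @classmethod
    def initial(
        cls,
        mechanisms: Iterable[str],
        bias_mode: str = "per_mechanism",
        gamma_init: float = 1.0,
        beta_same: float = 2.0,
        beta_diff: float = 0.0,
    ) -> "FullParamPsi":
        """Default initialization: all biases 1; beta 2 on same-mechanism pairs
        (slight encouragement for same-mechanism neighbors to share a state),
        0 on cross-mechanism pairs."""
        mechs = sorted(set(mechanisms))
        if bias_mode == "global":
            gamma: dict = {0: gamma_init, 1: gamma_init}
        else:
            gamma = {(s, a): gamma_init for s in mechs for a in (0, 1)}
        beta = {
            mechanism_pair(s, t): (beta_same if s == t else beta_diff)
            for i, s in enumerate(mechs)
            for t in mechs[i:]
        }
        return cls(gamma=gamma, beta=beta, bias_mode=bias_mode)

    def gamma_value(self, mechanism: str, state: int) -> float:
        if self.bias_mode == "global":
            return float(self.gamma[state])
        return float(self.gamma[(mechanism, state)])

    def beta_value(self, s: str, t: str) -> float:
        return float(self.beta.get(mechanism_pair(s, t), 0.0))


@dataclass
class PsiFit:
    """Fitted parameters plus optimizer diagnostics."""

    psi: SingleParamPsi | FullParamPsi
    pseudo_loglik: float
    converged: bool
    message: str
    at_bound: frozenset[str] = frozenset()
    frozen: frozenset[str] = frozenset()


@dataclass
class NeighborExpectation:
    """Expected number of neighbors *not* in the target state, per interaction.

    ``by_mechanism`` (full model) splits the total by the neighbor's
    mechanism; the per-mechanism counts sum to ``total``.
    """

    target_state: int
    total: dict[str, float]
    by_mechanism: dict[str, dict[str, float]] | None = None


# ---------------------------------------------------------------------------
# Vectorized line-graph view


class LineGraphIndex:
    """Array/sparse view of a network's interaction adjacency.

    Caches the 0/1 line-graph adjacency ``A`` (interaction x interaction),
    its per-neighbor-mechanism slices, and I-I pair counts per mechanism
    pair.  Used by the EM engine and the pseudo-likelihood fitter; the
    dict-based public operations delegate here.
    """

    def __init__(self, net: InteractionNetwork) -> None:
        self.net = net
        self.ids: list[str] = list(net.interactions)
        self.pos: dict[str, int] = {i: k for k, i in enumerate(self.ids)}
        self.mechs: list[str] = sorted({ia.mechanism for ia in net.interactions.values()})
        mech_of = {i: net.interactions[i].mechanism for i in self.ids}
        self.mech_idx = np.array([self.mechs.index(mech_of[i]) for i in self.ids], dtype=int)
        n = len(self.ids)
        row_list, col_list = [], []
        for i in self.ids:
            for j in net.adjacency[i]:
                row_list.append(self.pos[i])
                col_list.append(self.pos[j])
        rows = np.asarray(row_list, dtype=int)
        cols = np.asarray(col_list, dtype=int)
        data = np.ones(len(rows))
        self.A = sparse.csr_matrix((data, (rows, cols)), shape=(n, n))
        self.A_mech = []
        for t in range(len(self.mechs)):
            mask = self.mech_idx[cols] == t
            self.A_mech.append(
                sparse.csr_matrix((data[mask], (rows[mask], cols[mask])), shape=(n, n))
            )
        # I-I pair counts per canonical mechanism pair
        self.pair_counts: dict[tuple[str, str], int] = {}
        deg_by_mech = np.stack([np.asarray(At.sum(axis=1)).ravel() for At in self.A_mech], axis=1)
        for ti, t in enumerate(self.mechs):
            for ui in range(ti, len(self.mechs)):
                u = self.mechs[ui]
                if ti == ui:
                    count = deg_by_mech[self.mech_idx == ti, ti].sum() / 2.0
                else:
                    count = deg_by_mech[self.mech_idx == ti, ui].sum()
                self.pair_counts[mechanism_pair(t, u)] = int(round(count))

    def vector(self, mapping: Mapping[str, float]) -> np.ndarray:
        return np.array([mapping[i] for i in self.ids], dtype=float)

    def opposite_expectations(self, p: np.ndarray) -> dict:
        """Expected opposite-state neighbor counts from active posteriors ``p``.

        Returns totals and per-mechanism (n x T) matrices for both target
        states: for target 1 a neighbor contributes its inactive probability,
        for target 0 its active probability.
        """
        return {
            "total1": self.A @ (1.0 - p),
            "total0": self.A @ p,
            "mech1": np.stack([At @ (1.0 - p) for At in self.A_mech], axis=1),
            "mech0": np.stack([At @ p for At in self.A_mech], axis=1),
        }


# ---------------------------------------------------------------------------
# Potentials and conditionals


def potential_single(state: int, opp_count: float, psi: SingleParamPsi) -> float:
    """Ising potential ``gamma_k - beta * (#opposite-state neighbors)``."""
    if opp_count < 0:
        raise ValueError("opp_count must be >= 0")
    return psi.gamma(state) - psi.beta * opp_count


def potential_full(
    mechanism: str,
    state: int,
    opp_counts: Mapping[str, float],
    psi: FullParamPsi,
) -> float:
    """Mechanism-dependent potential ``gamma_s^a - sum_t beta_{s,t} * opp[t]``."""
    penalty = sum(psi.beta_value(mechanism, t) * c for t, c in opp_counts.items())
    return psi.gamma_value(mechanism, state) - penalty


def conditional_state_prob(psi_active, psi_inactive):
    """P(active) = exp(psi_1) / (exp(psi_1) + exp(psi_0)), overflow-safe."""
    diff = np.clip(np.asarray(psi_inactive, dtype=float) - np.asarray(psi_active, dtype=float),
                   -700.0, 700.0)
    out = 1.0 / (1.0 + np.exp(diff))
    return float(out) if np.ndim(out) == 0 else out


def expected_neighbor_counts(
    posteriors: Mapping[str, float],
    net: InteractionNetwork,
    target_state: int,
    per_mechanism: bool = False,
) -> NeighborExpectation:
    """Expected number of neighbors *not* in ``target_state`` per interaction.

    For target state 1 each neighbor contributes ``1 - posterior``, for
    target 0 it contributes ``posterior``.  With ``per_mechanism=True`` the
    sums are additionally split by the neighbor's mechanism.
    """
    if target_state not in (0, 1):
        raise ValueError("target_state must be 0 or 1")
    total: dict[str, float] = {}
    by_mech: dict[str, dict[str, float]] | None = {} if per_mechanism else None
    for i in net.interactions:
        contribs = {}
        tot = 0.0
        for j in net.adjacency[i]:
            p = posteriors[j]
            c = (1.0 - p) if target_state == 1 else p
            tot += c
            mech = net.interactions[j].mechanism
            contribs[mech] = contribs.get(mech, 0.0) + c
        total[i] = tot
        if by_mech is not None:
            by_mech[i] = contribs
    return NeighborExpectation(target_state=target_state, total=total, by_mechanism=by_mech)


# ---------------------------------------------------------------------------
# Gibbs energy and pseudo-likelihood


def gibbs_energy(
    states: StateVector,
    net: InteractionNetwork,
    psi: SingleParamPsi | FullParamPsi,
) -> float:
    """Unnormalized log-probability of a full state configuration.

    Bias terms sum over interactions; each unordered neighbor pair in
    opposite activity states contributes ``-beta`` once (with ``beta``
    looked up by the pair's mechanisms in the full model).
    """
    ids = list(net.interactions)
    energy = 0.0
    for i in ids:
        a = states[i]
        if isinstance(psi, SingleParamPsi):
            energy += psi.gamma(a)
        else:
            energy += psi.gamma_value(net.interactions[i].mechanism, a)
    seen = set()
    for i in ids:
        for j in net.adjacency[i]:
            key = (i, j) if i <= j else (j, i)
            if key in seen:
                continue
            seen.add(key)
            if states[i] != states[j]:
                if isinstance(psi, SingleParamPsi):
                    energy -= psi.beta
                else:
                    energy -= psi.beta_value(
                        net.interactions[i].mechanism, net.interactions[j].mechanism
                    )
    return energy


def _potential_arrays(
    idx: LineGraphIndex,
    exps: dict,
    psi: SingleParamPsi | FullParamPsi,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interaction potentials (psi_1, psi_0) at expected neighbor counts."""
    if isinstance(psi, SingleParamPsi):
        psi1 = psi.gamma1 - psi.beta * exps["total1"]
        psi0 = psi.gamma0 - psi.beta * exps["total0"]
        return psi1, psi0
    T = len(idx.mechs)
    B = np.zeros((T, T))
    for (s, t), v in psi.beta.items():
        if s in idx.mechs and t in idx.mechs:
            si, ti = idx.mechs.index(s), idx.mechs.index(t)
            B[si, ti] = B[ti, si] = v
    rows = np.arange(len(idx.ids))
    pen1 = (exps["mech1"] @ B)[rows, idx.mech_idx]
    pen0 = (exps["mech0"] @ B)[rows, idx.mech_idx]
    if psi.bias_mode == "global":
        g1 = np.full(len(idx.ids), psi.gamma[1], dtype=float)
        g0 = np.full(len(idx.ids), psi.gamma[0], dtype=float)
    else:
        g1 = np.array([psi.gamma[(idx.mechs[k], 1)] for k in idx.mech_idx])
        g0 = np.array([psi.gamma[(idx.mechs[k], 0)] for k in idx.mech_idx])
    return g1 - pen1, g0 - pen0


def _pl_and_conditionals(
    idx: LineGraphIndex,
    p: np.ndarray,
    exps: dict,
    psi: SingleParamPsi | FullParamPsi,
) -> tuple[float, np.ndarray]:
    """Posterior-weighted pseudo-log-likelihood and P(active) per interaction."""
    psi1, psi0 = _potential_arrays(idx, exps, psi)
    logp1 = -np.logaddexp(0.0, psi0 - psi1)
    logp0 = -np.logaddexp(0.0, psi1 - psi0)
    pl = float(np.dot(p, logp1) + np.dot(1.0 - p, logp0))
    return pl, np.exp(logp1)


def pseudo_likelihood(
    psi: SingleParamPsi | FullParamPsi,
    posteriors: Mapping[str, float],
    net: InteractionNetwork,
    index: LineGraphIndex | None = None,
) -> float:
    """Sum over interactions and states of posterior-weighted log conditional.

    The conditional of each state uses the expected opposite-state neighbor
    counts computed from the same posteriors, normalized over the two
    admissible states of the interaction.
    """
    idx = index if index is not None else LineGraphIndex(net)
    p = idx.vector(posteriors)
    exps = idx.opposite_expectations(p)
    pl, _ = _pl_and_conditionals(idx, p, exps, psi)
    return pl


# ---------------------------------------------------------------------------
# Psi fitting (M-step)


def _pack_full(psi: FullParamPsi, mechs: list[str], free_pairs: list[tuple[str, str]]) -> np.ndarray:
    if psi.bias_mode == "global":
        gammas = [psi.gamma[0], psi.gamma[1]]
    else:
        gammas = [psi.gamma[(s, a)] for s in mechs for a in (0, 1)]
    betas = [psi.beta.get(pr, 0.0) for pr in free_pairs]
    return np.array(gammas + betas, dtype=float)


def _unpack_full(
    x: np.ndarray,
    mechs: list[str],
    free_pairs: list[tuple[str, str]],
    bias_mode: str,
    frozen_values: Mapping[tuple[str, str], float],
) -> FullParamPsi:
    if bias_mode == "global":
        gamma: dict = {0: float(x[0]), 1: float(x[1])}
        k = 2
    else:
        gamma = {}
        k = 0
        for s in mechs:
            for a in (0, 1):
                gamma[(s, a)] = float(x[k])
                k += 1
    beta = {pr: float(v) for pr, v in frozen_values.items()}
    for pr, v in zip(free_pairs, x[k:]):
        beta[pr] = float(v)
    return FullParamPsi(
        gamma=gamma, beta=beta, bias_mode=bias_mode, frozen=frozenset(frozen_values)
    )


def fit_psi(
    posteriors: Mapping[str, float],
    net: InteractionNetwork,
    model: str = "single",
    bias_mode: str = "per_mechanism",
    bounds: tuple[float, float] = DEFAULT_PSI_BOUNDS,
    init: SingleParamPsi | FullParamPsi | None = None,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    freeze_beta: bool = False,
    index: LineGraphIndex | None = None,
) -> PsiFit:
    """Maximize the pseudo-likelihood over the box-bounded parameter set.

    Deterministic given ``init`` (bounded L-BFGS-B with finite-difference
    gradients).  In the full model, mechanism pairs with fewer than
    ``min_pairs`` I-I pairs in the network are frozen at beta = 0; the
    symmetric/structural-zero constraints are built into the
    parameterization.  ``freeze_beta=True`` pins every coupling at its
    initial value and fits the bias terms only.  Non-convergence is
    reported on the result, which still carries the best parameters found.
    """
    idx = index if index is not None else LineGraphIndex(net)
    p = idx.vector(posteriors)
    exps = idx.opposite_expectations(p)
    lo, hi = bounds

    if model == "single":
        psi0 = init if init is not None else SingleParamPsi()
        if freeze_beta:
            beta_fixed = psi0.beta

            def negpl_bias(x: np.ndarray) -> float:
                pl, _ = _pl_and_conditionals(
                    idx, p, exps, SingleParamPsi(gamma0=x[0], gamma1=x[1], beta=beta_fixed)
                )
                return -pl

            res = optimize.minimize(
                negpl_bias,
                np.clip([psi0.gamma0, psi0.gamma1], lo, hi),
                method="L-BFGS-B",
                bounds=[(lo, hi)] * 2,
            )
            fitted = SingleParamPsi(gamma0=res.x[0], gamma1=res.x[1], beta=beta_fixed)
            at_bound = frozenset(
                nm for nm, v in zip(["gamma0", "gamma1"], res.x)
                if abs(v - lo) < 1e-8 or abs(v - hi) < 1e-8
            )
            return PsiFit(
                psi=fitted,
                pseudo_loglik=-float(res.fun),
                converged=bool(res.success),
                message=str(res.message),
                at_bound=at_bound,
                frozen=frozenset({"beta"}),
            )
        x0 = np.array([psi0.gamma0, psi0.gamma1, psi0.beta], dtype=float)
        names = ["gamma0", "gamma1", "beta"]

        def negpl(x: np.ndarray) -> float:
            pl, _ = _pl_and_conditionals(
                idx, p, exps, SingleParamPsi(gamma0=x[0], gamma1=x[1], beta=x[2])
            )
            return -pl

        res = optimize.minimize(
            negpl, np.clip(x0, lo, hi), method="L-BFGS-B", bounds=[(lo, hi)] * 3
        )
        fitted = SingleParamPsi(gamma0=res.x[0], gamma1=res.x[1], beta=res.x[2])
        at_bound = frozenset(
            nm for nm, v in zip(names, res.x) if abs(v - lo) < 1e-8 or abs(v - hi) < 1e-8
        )
        return PsiFit(
            psi=fitted,
            pseudo_loglik=-float(res.fun),
            converged=bool(res.success),
            message=str(res.message),
            at_bound=at_bound,
            frozen=frozenset(),
        )

    if model != "full":
        raise ValueError(f"model must be single|full, got {model}")

    mechs = idx.mechs
    all_pairs = [
        mechanism_pair(s, t) for i, s in enumerate(mechs) for t in mechs[i:]
    ]
    psi0 = (
        init
        if isinstance(init, FullParamPsi)
        else FullParamPsi.initial(mechs, bias_mode=bias_mode)
    )
    if psi0.bias_mode != bias_mode:
        raise ValueError("init psi bias_mode does not match requested bias_mode")
    if freeze_beta:
        frozen = frozenset(all_pairs)
        frozen_values = {pr: psi0.beta.get(pr, 0.0) for pr in all_pairs}
    else:
        frozen = frozenset(pr for pr in all_pairs if idx.pair_counts.get(pr, 0) < min_pairs)
        frozen_values = {pr: 0.0 for pr in frozen}
    free_pairs = [pr for pr in all_pairs if pr not in frozen]
    x0 = _pack_full(psi0, mechs, free_pairs)

    def negpl_full(x: np.ndarray) -> float:
        pl, _ = _pl_and_conditionals(
            idx, p, exps, _unpack_full(x, mechs, free_pairs, bias_mode, frozen_values)
        )
        return -pl

    res = optimize.minimize(
        negpl_full,
        np.clip(x0, lo, hi),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * len(x0),
    )
    fitted_full = _unpack_full(res.x, mechs, free_pairs, bias_mode, frozen_values)
    if bias_mode == "global":
        names = ["gamma[0]", "gamma[1]"]
    else:
        names = [f"gamma[{s},{a}]" for s in mechs for a in (0, 1)]
    names += [f"beta[{s},{t}]" for s, t in free_pairs]
    at_bound = frozenset(
        nm for nm, v in zip(names, res.x) if abs(v - lo) < 1e-8 or abs(v - hi) < 1e-8
    )
    return PsiFit(
        psi=fitted_full,
        pseudo_loglik=-float(res.fun),
        converged=bool(res.success),
        message=str(res.message),
        at_bound=at_bound,
        frozen=frozenset(f"beta[{s},{t}]" for s, t in frozen),
    )


def psi_table(fit: PsiFit | SingleParamPsi | FullParamPsi) -> pd.DataFrame:
    """Flat serialization: rows (param_name, value, frozen, at_bound)."""
    if isinstance(fit, PsiFit):
        psi, at_bound, frozen = fit.psi, fit.at_bound, fit.frozen
    else:
        psi, at_bound, frozen = fit, frozenset(), frozenset()
    rows = []
    if isinstance(psi, SingleParamPsi):
        items = [("gamma0", psi.gamma0), ("gamma1", psi.gamma1), ("beta", psi.beta)]
    else:
        if psi.bias_mode == "global":
            items = [("gamma[0]", psi.gamma[0]), ("gamma[1]", psi.gamma[1])]
        else:
            items = [(f"gamma[{s},{a}]", v) for (s, a), v in sorted(psi.gamma.items())]
        items += [(f"beta[{s},{t}]", v) for (s, t), v in sorted(psi.beta.items())]
    for name, value in items:
        rows.append(
            {
                "param_name": name,
                "value": float(value),
                "frozen": name in frozen,
                "at_bound": name in at_bound,
            }
        )
    return pd.DataFrame(rows, columns=["param_name", "value", "frozen", "at_bound"])
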