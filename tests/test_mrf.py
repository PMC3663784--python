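"""MRF potentials, conditionals, Gibbs energy, pseudo-likelihood, Psi fitting.

The exactness checks pit the heuristic machinery against independent
re-implementations: brute-force enumeration of the joint Gibbs distribution
for conditionals, and an exhaustive grid search for the pseudo-likelihood
maximizer.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mechnet import (
    FullParamPsi,
    SingleParamPsi,
    StateVector,
    conditional_state_prob,
    expected_neighbor_counts,
    fit_psi,
    gibbs_energy,
    potential_full,
    potential_single,
    pseudo_likelihood,
    psi_table,
)
from mechnet.mrf import mechanism_pair
from conftest import make_network


# ---------------------------------------------------------------------------
# potentials


@pytest.mark.parametrize(
    "state,opp,psi,expected",
    [
        (1, 0.0, SingleParamPsi(1, 1, 2), 1.0),
        (1, 3.0, SingleParamPsi(1, 1, 2), -5.0),
        (0, 2.5, SingleParamPsi(gamma0=0.5, gamma1=1, beta=0.0), 0.5),
    ],
)
def test_potential_single(state, opp, psi, expected):
    assert potential_single(state, opp, psi) == pytest.approx(expected)


def test_potential_full_substitution():
    psi = FullParamPsi(
        gamma={("B", 1): 1.0, ("B", 0): 0.0, ("TR", 1): 0.0, ("TR", 0): 0.0},
        beta={("B", "B"): 2.0, ("B", "TR"): 0.0, ("TR", "TR"): 0.0},
    )
    assert potential_full("B", 1, {"B": 2.0, "TR": 1.0}, psi) == pytest.approx(-3.0)
    assert potential_full("B", 1, {}, psi) == pytest.approx(1.0)


def test_full_reduces_to_single_with_tied_parameters():
    rng = np.random.default_rng(3)
    mechs = ["B", "M", "TR"]
    for _ in range(20):
        g0, g1, b = rng.normal(size=3)
        full = FullParamPsi(
            gamma={(s, a): (g1 if a else g0) for s in mechs for a in (0, 1)},
            beta={mechanism_pair(s, t): b for s in mechs for t in mechs},
        )
        opp = {m: float(rng.uniform(0, 4)) for m in mechs}
        s = rng.choice(mechs)
        a = int(rng.integers(2))
        tied = potential_single(a, sum(opp.values()), SingleParamPsi(g0, g1, b))
        assert potential_full(s, a, opp, full) == pytest.approx(tied, abs=1e-12)


def test_conditional_state_prob():
    assert conditional_state_prob(1.3, 1.3) == pytest.approx(0.5)
    assert conditional_state_prob(1.0, -1.0) == pytest.approx(0.88080, abs=1e-5)
    with np.errstate(over="raise"):  # saturation without overflow
        assert conditional_state_prob(50.0, -50.0) == pytest.approx(1.0, abs=1e-40)
        assert conditional_state_prob(-50.0, 50.0) == pytest.approx(0.0, abs=1e-40)


def test_conditional_probs_normalize():
    rng = np.random.default_rng(0)
    for _ in range(100):
        p1, p0 = rng.normal(scale=20, size=2)
        total = conditional_state_prob(p1, p0) + conditional_state_prob(p0, p1)
        assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# expected neighbor counts


def test_expected_counts_example(star_net):
    ids = star_net.interaction_ids
    posts = dict(zip(ids, [0.5, 0.9, 0.2, 0.5]))
    exp1 = expected_neighbor_counts(posts, star_net, target_state=1)
    exp0 = expected_neighbor_counts(posts, star_net, target_state=0)
    # neighbors of ids[0] have posteriors {0.9, 0.2, 0.5}
    assert exp1.total[ids[0]] == pytest.approx(0.1 + 0.8 + 0.5)
    assert exp0.total[ids[0]] == pytest.approx(1.6)
    # complement conservation: totals sum to the neighbor count
    for i in ids:
        assert exp1.total[i] + exp0.total[i] == pytest.approx(len(star_net.neighbors(i)))


def test_expected_counts_per_mechanism(chain_net):
    ids = chain_net.interaction_ids  # mechanisms TR, M, B along the chain
    posts = dict(zip(ids, [0.9, 0.5, 0.2]))
    exp = expected_neighbor_counts(posts, chain_net, target_state=1, per_mechanism=True)
    mid = ids[1]
    assert exp.by_mechanism[mid] == pytest.approx({"TR": 0.1, "B": 0.8})
    assert sum(exp.by_mechanism[mid].values()) == pytest.approx(exp.total[mid])


# ---------------------------------------------------------------------------
# Gibbs energy and the enumeration oracle


def test_gibbs_energy_pair_examples():
    net = make_network([("a", "B", "b"), ("b", "B", "c")])
    ids = net.interaction_ids
    psi = SingleParamPsi(gamma0=1.0, gamma1=1.0, beta=2.0)
    both = StateVector(states={ids[0]: 1, ids[1]: 1})
    assert gibbs_energy(both, net, psi) == pytest.approx(2.0)
    # opposite states: gamma_0 + gamma_1 - beta = 1 + 1 - 2
    opposite = StateVector(states={ids[0]: 1, ids[1]: 0})
    assert gibbs_energy(opposite, net, psi) == pytest.approx(0.0)


def _oracle_energy(states, net, psi):
    """Independent re-implementation: bias sum minus coupling per
    opposite-state unordered neighbor pair."""
    e = 0.0
    for i, ia in net.interactions.items():
        if isinstance(psi, SingleParamPsi):
            e += psi.gamma1 if states[i] else psi.gamma0
        else:
            e += psi.gamma_value(ia.mechanism, states[i])
    done = set()
    for i in net.interactions:
        for j in net.adjacency[i]:
            key = frozenset((i, j))
            if key in done or states[i] == states[j]:
                done.add(key)
                continue
            done.add(key)
            if isinstance(psi, SingleParamPsi):
                e -= psi.beta
            else:
                e -= psi.beta_value(
                    net.interactions[i].mechanism, net.interactions[j].mechanism
                )
    return e


def _exact_conditional(net, fixed_states, target, psi):
    """P(target active | all other states) by enumerating the joint."""
    ids = list(net.interactions)
    weights = {0: 0.0, 1: 0.0}
    for a in (0, 1):
        states = dict(fixed_states)
        states[target] = a
        weights[a] = np.exp(_oracle_energy(states, net, psi))
    return weights[1] / (weights[0] + weights[1])


TINY_NETS = [
    make_network([("a", "B", "b"), ("b", "M", "c"), ("c", "TR", "d")]),
    make_network([("h", "B", f"s{i}") for i in range(4)]),
    make_network(
        [("a", "B", "b"), ("b", "M", "c"), ("c", "TR", "a"), ("a", "TR", "d")]
    ),
    make_network([("a", "B", "b"), ("a", "TR", "b"), ("b", "M", "c"), ("x", "B", "y")]),
    make_network(
        [
            ("a", "B", "b"), ("a", "M", "c"), ("a", "TR", "d"),
            ("b", "B", "c"), ("c", "M", "d"), ("d", "TR", "b"),
            ("b", "M", "e"), ("e", "B", "f"),
        ]
    ),
]


@pytest.mark.parametrize("net", TINY_NETS, ids=lambda n: f"net{len(n)}")
@pytest.mark.parametrize("model", ["single", "full"])
def test_heuristic_conditional_matches_exact_gibbs(net, model):
    """With degenerate posteriors, the normalized heuristic conditional at
    observed neighbor counts equals the exact conditional of the joint Gibbs
    distribution, for every interaction and every 0/1 configuration."""
    rng = np.random.default_rng(17)
    if model == "single":
        psi = SingleParamPsi(*rng.normal(scale=1.0, size=3))
    else:
        mechs = sorted({ia.mechanism for ia in net.interactions.values()})
        psi = FullParamPsi(
            gamma={(s, a): float(rng.normal()) for s in mechs for a in (0, 1)},
            beta={
                mechanism_pair(s, t): float(rng.normal())
                for s in mechs
                for t in mechs
            },
        )
    ids = list(net.interactions)
    for config_bits in itertools.islice(itertools.product((0, 1), repeat=len(ids)), 64):
        states = dict(zip(ids, config_bits))
        posts = {i: float(s) for i, s in states.items()}
        for target in ids:
            exact = _exact_conditional(net, states, target, psi)
            if isinstance(psi, SingleParamPsi):
                e1 = expected_neighbor_counts(posts, net, 1).total[target]
                e0 = expected_neighbor_counts(posts, net, 0).total[target]
                p1 = potential_single(1, e1, psi)
                p0 = potential_single(0, e0, psi)
            else:
                mech = net.interactions[target].mechanism
                e1 = expected_neighbor_counts(posts, net, 1, per_mechanism=True)
                e0 = expected_neighbor_counts(posts, net, 0, per_mechanism=True)
                p1 = potential_full(mech, 1, e1.by_mechanism[target], psi)
                p0 = potential_full(mech, 0, e0.by_mechanism[target], psi)
            heuristic = conditional_state_prob(p1, p0)
            assert heuristic == pytest.approx(exact, abs=1e-10)


# ---------------------------------------------------------------------------
# pseudo-likelihood


def test_pl_isolated_interaction_symmetric():
    net = make_network([("a", "B", "b")])
    psi = SingleParamPsi(gamma0=0.7, gamma1=0.7, beta=3.0)
    pl = pseudo_likelihood(psi, {net.interaction_ids[0]: 0.42}, net)
    assert pl == pytest.approx(np.log(0.5))


def test_pl_beta_zero_ignores_adjacency(chain_net, disconnected_net):
    # same posterior multiset, beta = 0: adjacency cannot matter
    psi = SingleParamPsi(gamma0=0.2, gamma1=1.1, beta=0.0)
    posts_chain = dict(zip(chain_net.interaction_ids, [0.9, 0.4, 0.9]))
    net2 = make_network([("a", "B", "b"), ("c", "TR", "d"), ("e", "M", "f")])
    posts_far = dict(zip(net2.interaction_ids, [0.9, 0.4, 0.9]))
    assert pseudo_likelihood(psi, posts_chain, chain_net) == pytest.approx(
        pseudo_likelihood(psi, posts_far, net2)
    )


def test_pl_three_chain_hand_computed(chain_net):
    ids = chain_net.interaction_ids
    posts = dict(zip(ids, [0.9, 0.6, 0.3]))
    psi = SingleParamPsi(gamma0=0.5, gamma1=1.0, beta=1.5)
    expected = 0.0
    for i in ids:
        nbrs = chain_net.adjacency[i]
        e1 = sum(1 - posts[j] for j in nbrs)
        e0 = sum(posts[j] for j in nbrs)
        d = (psi.gamma1 - psi.beta * e1) - (psi.gamma0 - psi.beta * e0)
        logp1 = -np.log1p(np.exp(-d))
        logp0 = -np.log1p(np.exp(d))
        expected += posts[i] * logp1 + (1 - posts[i]) * logp0
    assert pseudo_likelihood(psi, posts, chain_net) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# Psi fitting


@pytest.fixture
def six_net():
    return make_network(
        [
            ("a", "B", "b"), ("b", "TR", "c"), ("c", "B", "d"),
            ("d", "TR", "e"), ("b", "B", "e"), ("e", "TR", "f"),
        ]
    )


def test_fit_psi_matches_grid_search(six_net):
    """Bounded quasi-Newton fit attains the pseudo-likelihood of an
    exhaustive 0.05-step grid search over the box (within 1e-4)."""
    posts = dict(zip(six_net.interaction_ids, [0.95, 0.8, 0.7, 0.15, 0.6, 0.1]))
    box = (-2.0, 2.0)
    fit = fit_psi(posts, six_net, model="single", bounds=box,
                  init=SingleParamPsi(0.0, 0.0, 0.0))
    # independent grid oracle: PL depends on (gamma1 - gamma0, beta) only
    p = np.array([posts[i] for i in six_net.interaction_ids])
    e1 = np.array([
        sum(1 - posts[j] for j in six_net.adjacency[i]) for i in six_net.interaction_ids
    ])
    e0 = np.array([
        sum(posts[j] for j in six_net.adjacency[i]) for i in six_net.interaction_ids
    ])
    gammas = np.arange(box[0], box[1] + 1e-9, 0.05)
    diffs = np.unique(np.round(gammas[:, None] - gammas[None, :], 10).ravel())
    betas = gammas
    best = -np.inf
    for b in betas:
        delta = diffs[:, None] - b * (e1 - e0)[None, :]
        logp1 = -np.logaddexp(0.0, -delta)
        logp0 = -np.logaddexp(0.0, delta)
        pl = (p * logp1 + (1 - p) * logp0).sum(axis=1)
        best = max(best, pl.max())
    assert fit.pseudo_loglik >= best - 1e-4


def test_fit_psi_deterministic(six_net):
    posts = dict(zip(six_net.interaction_ids, [0.95, 0.8, 0.7, 0.15, 0.6, 0.1]))
    f1 = fit_psi(posts, six_net, model="single")
    f2 = fit_psi(posts, six_net, model="single")
    assert f1.psi == f2.psi


def test_fit_psi_all_active_hits_beta_bound(six_net):
    """Every interaction active: coupling is unidentifiable upward and the
    estimate is reported boundary-clipped."""
    posts = {i: 1.0 for i in six_net.interactions}
    fit = fit_psi(posts, six_net, model="single", bounds=(-4, 4))
    assert fit.psi.beta == pytest.approx(4.0)
    assert "beta" in fit.at_bound


def _chain_states(n_inter, agreement):
    """0/1 state sequence along a chain with the requested fraction of
    agreeing neighbor pairs (boundaries spread evenly)."""
    n_pairs = n_inter - 1
    n_boundaries = int(round((1 - agreement) * n_pairs))
    positions = np.linspace(1, n_inter - 1, n_boundaries, dtype=int) if n_boundaries else []
    states = np.zeros(n_inter, dtype=int)
    current = 1
    bset = set(int(x) for x in positions)
    for k in range(n_inter):
        if k in bset:
            current = 1 - current
        states[k] = current
    return states


def test_fitted_beta_increases_with_agreement():
    net = make_network([(f"n{k}", "B", f"n{k+1}") for k in range(41)])
    ids = net.interaction_ids
    betas = []
    for p_agree in (0.5, 0.7, 0.9):
        states = _chain_states(len(ids), p_agree)
        posts = {i: float(s) for i, s in zip(ids, states)}
        fit = fit_psi(posts, net, model="single")
        betas.append(fit.psi.beta)
    assert betas[0] < betas[1] < betas[2]


def test_full_fit_symmetry_and_frozen_zeros():
    # mechanism M appears once: every pair involving M has < 5 I-I pairs
    edges = [(f"n{k}", "B", f"n{k+1}") for k in range(8)] + [("n0", "M", "x")]
    net = make_network(edges)
    rng = np.random.default_rng(5)
    posts = {i: float(rng.uniform()) for i in net.interactions}
    fit = fit_psi(posts, net, model="full", bias_mode="global", min_pairs=5)
    psi = fit.psi
    for (s, t), v in psi.beta.items():
        assert psi.beta_value(t, s) == v  # canonical-key symmetry
    assert psi.beta[mechanism_pair("B", "M")] == 0.0
    assert psi.beta[mechanism_pair("M", "M")] == 0.0
    assert "beta[B,M]" in fit.frozen
    assert psi.beta[mechanism_pair("B", "B")] != 0.0


def test_freeze_beta_fits_bias_only(six_net):
    posts = dict(zip(six_net.interaction_ids, [0.9, 0.8, 0.7, 0.2, 0.6, 0.1]))
    fit = fit_psi(posts, six_net, model="single", init=SingleParamPsi(beta=0.0),
                  freeze_beta=True)
    assert fit.psi.beta == 0.0
    assert "beta" in fit.frozen


def test_psi_table_schema(six_net):
    posts = {i: 0.5 for i in six_net.interactions}
    fit = fit_psi(posts, six_net, model="full", bias_mode="global")
    table = psi_table(fit)
    assert list(table.columns) == ["param_name", "value", "frozen", "at_bound"]
    assert {"gamma[0]", "gamma[1]"} <= set(table.param_name)
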