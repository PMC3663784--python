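"""Noise model: likelihood of an observed edge correlation under each state.

An interaction's observed Spearman correlation ``r`` (over ``n`` time
points) is treated as a noisy readout of its latent activity.  Under the
active hypothesis H1 the Fisher transform ``z = artanh(r)`` is modelled as
Gaussian around ``z_alpha = artanh(r_alpha)`` with standard error
``1/sqrt(n-3)``, and the likelihood is the CDF value ``Pr(Z < z)`` — 0.5
exactly at ``r = r_alpha``, increasing in ``r``.  Under the null H0 the
correlation is converted to the usual one-sample t statistic
``t = r*sqrt((n-2)/(1-r^2))`` and the likelihood is the one-tailed survival
probability ``Pr(T > t)`` with ``n-2`` degrees of freedom — 0.5 at ``r = 0``,
decreasing in ``r``.

The single free parameter ``r_alpha`` (the active-class population
correlation) is re-estimated during EM as a posterior-weighted mean in
Fisher-z space, optionally weighting by posterior *ranks* for stability when
many posteriors saturate near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NoiseParams",
    "fisher_z",
    "inverse_fisher_z",
    "likelihood_active",
    "likelihood_inactive",
    "estimate_r_alpha",
    "R_ALPHA_BOUNDS",
]

#: Clamp for the r_alpha estimate: keeps H1 distinguishable from H0 even if
#: early EM iterations put most posterior mass on one class.
R_ALPHA_BOUNDS: tuple[float, float] = (0.05, 0.99)


@dataclass
class NoiseParams:
    """Noise-model parameter set Theta = {r_alpha} plus behavioural flags.

    negative_mode
        ``signed`` uses correlations as observed; ``absolute`` replaces the
        Fisher-z observation by its magnitude (appropriate when inhibitory
        interactions make strong negative correlation equally informative).
    weighting
        ``posterior`` or ``rank`` — how :func:`estimate_r_alpha` weights
        observations in the M-step.
    """

    r_alpha: float
    n: int
    negative_mode: str = "signed"
    weighting: str = "posterior"

    def __post_init__(self) -> None:
        if not 0.0 < self.r_alpha < 1.0:
            raise ValueError(f"r_alpha must be in (0, 1), got {self.r_alpha}")
        if self.n < 4:
            raise ValueError(f"sample size n must be >= 4, got {self.n}")
        if self.negative_mode not in ("signed", "absolute"):
            raise ValueError(f"negative_mode must be signed|absolute, got {self.negative_mode}")
        if self.weighting not in ("posterior", "rank"):
            raise ValueError(f"weighting must be posterior|rank, got {self.weighting}")

    @property
    def z_alpha(self) -> float:
        return float(np.arctanh(self.r_alpha))

    @property
    def fisher_se(self) -> float:
        return 1.0 / np.sqrt(self.n - 3)


def fisher_z(r):
    """Fisher z-transform ``artanh(r) = 0.5*log((1+r)/(1-r))``; requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse transform tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def likelihood_active(r, params: NoiseParams):
    """Pr(Z < z_obs) under Z ~ Normal(z_alpha, 1/sqrt(n-3)) — the H1 likelihood."""
    z = fisher_z(r)
    if params.negative_mode == "absolute":
        z = np.abs(z)
    out = stats.norm.cdf(z, loc=params.z_alpha, scale=params.fisher_se)
    return float(out) if np.ndim(out) == 0 else out


def likelihood_inactive(r, n: int, negative_mode: str = "signed"):
    """Pr(T > t_obs) under Student t with df=n-2 — the one-tailed H0 likelihood."""
    if n < 4:
        raise ValueError(f"sample size n must be >= 4, got {n}")
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("likelihood_inactive requires |r| < 1")
    if negative_mode == "absolute":
        r = np.abs(r)
    t_obs = r * np.sqrt((n - 2) / (1.0 - r**2))
    out = stats.t.sf(t_obs, df=n - 2)
    return float(out) if np.ndim(out) == 0 else out


def estimate_r_alpha(z_values, active_posteriors, weighting: str = "posterior") -> float:
    """M-step estimate of the active-class correlation parameter.

    A weighted mean of Fisher-z observations mapped back through tanh:
    ``r_alpha = tanh(sum(w*z)/sum(w))`` with ``w`` the active posteriors, or
    their (average-tie) ranks in ``rank`` mode.  The result is clamped to
    ``R_ALPHA_BOUNDS``.
    """
    z = np.asarray(z_values, dtype=float)
    w = np.asarray(active_posteriors, dtype=float)
    if z.shape != w.shape:
        raise ValueError("z_values and active_posteriors differ in shape")
    if np.any((w < 0) | (w > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    if weighting == "rank":
        w = stats.rankdata(w, method="average")
    elif weighting != "posterior":
        raise ValueError(f"weighting must be posterior|rank, got {weighting}")
    total = w.sum()
    if total <= 0:
        raise ValueError("all posteriors are zero; r_alpha is undefined")
    r = float(np.tanh(np.dot(w, z) / total))
    lo, hi = R_ALPHA_BOUNDS
    return min(max(r, lo), hi)
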