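"""Maximum-likelihood-only classifier: the no-prior comparator.

Each interaction is classified independently by comparing the active (H1)
and inactive (H0) noise-model likelihoods of its observed correlation.  No
network information enters — permuting the topology leaves the result
unchanged — which makes this baseline a topology-free yardstick for the
MRF-coupled methods.
"""

from __future__ import annotations

import numpy as np

from .network import CorrelationData, StateVector
from .noise import NoiseParams, likelihood_active, likelihood_inactive

__all__ = ["ml_classify", "ml_posteriors"]


def ml_classify(
    corr: CorrelationData,
    r_alpha: float,
    n: int | None = None,
    negative_mode: str = "signed",
) -> StateVector:
    """Assign active iff the H1 likelihood strictly exceeds the H0 likelihood.

    Ties go to inactive (favoring the null).  In signed mode this is a single
    threshold on the Fisher-z scale.
    """
    n = corr.n if n is None else n
    params = NoiseParams(r_alpha=r_alpha, n=n, negative_mode=negative_mode)
    ids = list(corr.values)
    r = np.array([corr.values[i] for i in ids], dtype=float)
    l1 = np.asarray(likelihood_active(r, params))
    l0 = np.asarray(likelihood_inactive(r, n, negative_mode=negative_mode))
    active = l1 > l0
    return StateVector(states={i: int(a) for i, a in zip(ids, active)})


def ml_posteriors(
    corr: CorrelationData,
    r_alpha: float,
    n: int | None = None,
    negative_mode: str = "signed",
) -> dict[str, float]:
    """Normalized likelihood ratio l1/(l1+l0) per interaction (report column)."""
    n = corr.n if n is None else n
    params = NoiseParams(r_alpha=r_alpha, n=n, negative_mode=negative_mode)
    ids = list(corr.values)
    r = np.array([corr.values[i] for i in ids], dtype=float)
    l1 = np.asarray(likelihood_active(r, params), dtype=float)
    l0 = np.asarray(likelihood_inactive(r, n, negative_mode=negative_mode), dtype=float)
    post = l1 / (l1 + l0)
    return {i: float(p) for i, p in zip(ids, post)}
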