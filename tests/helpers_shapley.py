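"""Shared Shapley test helpers: toy mixture models and the enumeration oracle."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

from strainpheno.cluster import GmmModel, posterior_matrix
from strainpheno.io import FEATURE_COLUMNS


def toy_model(means, weights=None, covs=None) -> GmmModel:
    """A hand-built mixture on the raw feature scale (no standardization)."""
    means = np.asarray(means, dtype=float)
    k, d = means.shape
    weights = np.full(k, 1 / k) if weights is None else np.asarray(weights)
    covs = np.stack([np.eye(d)] * k) if covs is None else np.asarray(covs)
    return GmmModel(
        k=k, weights=weights, means=means, covariances=covs,
        scale_center=np.zeros(d), scale_scale=np.ones(d),
        log_likelihood=0.0, bic=0.0,
        feature_names=list(FEATURE_COLUMNS[:d]),
    )


def exact_shapley(model: GmmModel, x: np.ndarray, B: np.ndarray, cluster: int):
    """Subset-enumeration Shapley oracle for v(S) = mean_b f(x_S, b_-S).

    Brute force over all coalitions with the classical weight
    |S|! (d-|S|-1)! / d!; independent of the permutation sampler it checks.
    """
    d = x.size

    def value(S):
        rows = B.copy()
        if S:
            rows[:, list(S)] = x[list(S)]
        return posterior_matrix(model, rows)[:, cluster].mean()

    phi = np.zeros(d)
    for j in range(d):
        rest = [i for i in range(d) if i != j]
        for r in range(d):
            for S in combinations(rest, r):
                w = (math.factorial(len(S)) * math.factorial(d - len(S) - 1)
                     / math.factorial(d))
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi
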