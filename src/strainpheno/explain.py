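"""Feature-importance analysis of the fitted mixture.

Two complementary views of which features drive cluster membership:

* **Shapley values** of the explained function f_c(x) = posterior
  probability of cluster c under the mixture, estimated by permutation
  sampling with background imputation — for each sampled feature ordering,
  features of a background draw are switched one by one to the explained
  subject's values and the change in f_c is credited to the switched
  feature.  Averaged over orderings and the background set this converges
  to the Shapley value of the game v(S) = E_b[f_c(x_S, b_{-S})], and
  satisfies the efficiency property sum_j phi_j = f_c(x) - E_b[f_c(b)]
  exactly for every sampled ordering.

* **Random-forest mean-decrease-impurity importance** of a forest trained
  to predict the hard cluster labels from the six features.

A radar-chart normalization (per-feature cluster means divided by the
maximum cluster mean of that feature) summarizes the cluster profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cluster import GmmModel, posterior_matrix
from .io import FEATURE_COLUMNS

__all__ = [
    "ShapleyReport",
    "ForestImportance",
    "shapley_values",
    "forest_importance",
    "radar_profile",
]


@dataclass
class ShapleyReport:
    """Per-subject, per-cluster, per-feature Shapley contributions.

    ``values[i, c, j]`` is feature j's contribution to subject i's posterior
    probability of cluster c, relative to the background average
    ``baseline[c]``.  Efficiency: ``values[i, c].sum() == f_x[i, c] -
    baseline[c]`` (exact up to float roundoff for exhaustive orderings,
    Monte-Carlo tolerance otherwise).
    """

    values: np.ndarray  # (n_subjects, k, d)
    baseline: np.ndarray  # (k,)
    f_x: np.ndarray  # (n_subjects, k)
    subject_ids: list[str]
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    n_permutations: int = 0
    background_size: int = 0
    seed: int = 0

    def per_cluster(self, c: int) -> pd.DataFrame:
        """Subjects x features contribution matrix for 1-based cluster c."""
        return pd.DataFrame(
            self.values[:, c - 1, :], columns=self.feature_names, index=self.subject_ids
        )


def _feature_array(features, names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        ids = (
            features["subject_id"].astype(str).tolist()
            if "subject_id" in features
            else [str(i) for i in range(len(features))]
        )
        if names is None:
            names = [c for c in FEATURE_COLUMNS if c in features.columns]
            if not names:
                names = [c for c in features.columns if c != "subject_id"]
        return features[list(names)].to_numpy(dtype=float), ids
    X = np.atleast_2d(np.asarray(features, dtype=float))
    return X, [str(i) for i in range(X.shape[0])]


def shapley_values(
    model: GmmModel,
    features,
    background_size: int = 100,
    n_permutations: int = 200,
    seed: int = 0,
    exhaustive: bool = False,
    background=None,
) -> ShapleyReport:
    """Monte-Carlo permutation-sampling Shapley values of cluster posteriors.

    The background set is a seeded subsample of ``background`` (default:
    ``features`` itself), at most ``background_size`` rows.  With
    ``exhaustive=True`` all d! feature orderings are used instead of
    sampling (exact Shapley values with respect to the empirical
    background), feasible for small d.
    """
    X, ids = _feature_array(features, names=model.feature_names)
    n, d = X.shape
    rng = np.random.default_rng(seed)
    Xbg, _ = _feature_array(
        features if background is None else background, names=model.feature_names
    )
    bg_idx = (
        np.arange(Xbg.shape[0])
        if Xbg.shape[0] <= background_size
        else rng.choice(Xbg.shape[0], size=background_size, replace=False)
    )
    B = Xbg[bg_idx]
    if B.shape[0] < 10:
        raise ValueError("background set must contain at least 10 subjects")

    if exhaustive:
        orderings = [np.array(p) for p in permutations(range(d))]
    else:
        orderings = [rng.permutation(d) for _ in range(n_permutations)]

    f_bg = posterior_matrix(model, B)  # (B, k)
    baseline = f_bg.mean(axis=0)
    k = model.k
    values = np.zeros((n, k, d))
    f_x = posterior_matrix(model, X)
    for i in range(n):
        x = X[i]
        acc = np.zeros((k, d))
        for order in orderings:
            cur = B.copy()
            f_prev = f_bg
            # evaluate all d switch steps in one posterior batch
            batch = np.empty((d, B.shape[0], d))
            for step, j in enumerate(order):
                cur[:, j] = x[j]
                batch[step] = cur
            f_steps = posterior_matrix(model, batch.reshape(-1, d)).reshape(
                d, B.shape[0], k
            )
            for step, j in enumerate(order):
                f_new = f_steps[step]
                acc[:, j] += (f_new - f_prev).mean(axis=0)
                f_prev = f_new
        values[i] = acc / len(orderings)
    return ShapleyReport(
        values=values,
        baseline=baseline,
        f_x=f_x,
        subject_ids=ids,
        feature_names=list(model.feature_names),
        n_permutations=len(orderings),
        background_size=int(B.shape[0]),
        seed=seed,
    )


@dataclass
class ForestImportance:
    """Gini mean-decrease-impurity importances (nonnegative, sum to 1)."""

    importances: np.ndarray
    feature_names: list[str]
    oob_agreement: float
    n_trees: int
    seed: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.importances, index=self.feature_names)


def forest_importance(
    features,
    labels: Sequence[int],
    n_trees: int = 500,
    seed: int = 0,
) -> ForestImportance:
    """Random-forest impurity importance of the features for the cluster labels.

    CART trees on bootstrap samples with Gini impurity splits; importance is
    the forest-averaged decrease in impurity, normalized to sum to 1.  The
    out-of-bag label-agreement rate is reported as a sanity check on how
    well the features determine the labels.
    """
    X, _ = _feature_array(features)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("forest importance requires at least 2 distinct labels")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    imp = forest.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    names = (
        list(features[FEATURE_COLUMNS].columns)
        if isinstance(features, pd.DataFrame)
        else list(FEATURE_COLUMNS)[: X.shape[1]]
    )
    if len(names) != X.shape[1]:
        names = [f"f{j}" for j in range(X.shape[1])]
    return ForestImportance(
        importances=imp,
        feature_names=names,
        oob_agreement=float(forest.oob_score_),
        n_trees=n_trees,
        seed=seed,
    )


def radar_profile(model: GmmModel) -> pd.DataFrame:
    """Cluster feature-mean profiles normalized per feature to (0, 1].

    Each cluster's mean (original units, magnitudes) is divided by the
    maximum cluster mean of that feature, so the largest cluster scores 1
    on every axis it dominates.
    """
    means = np.abs(model.means_original())
    maxima = means.max(axis=0)
    if np.any(maxima == 0):
        bad = [model.feature_names[j] for j in np.flatnonzero(maxima == 0)]
        raise ValueError(f"zero maximum cluster mean for features: {bad}")
    profile = means / maxima
    return pd.DataFrame(
        profile,
        index=[f"cluster_{c + 1}" for c in range(model.k)],
        columns=model.feature_names,
    )
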