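"""Gaussian-mixture phenogrouping of the six-feature matrix.

The mixture is fitted by expectation–maximization with full covariances,
k-means++ multi-start initialization, and z-score standardization of the
features using training-cohort statistics that are stored in the model so a
frozen model can later be applied unchanged to an external cohort.  The
number of phenogroups is chosen from the Bayesian information criterion
(BIC) curve with an explicit elbow rule: the smallest k at which the BIC
decrease drops below a set fraction of the previous decrease.

The log-likelihood is asserted non-decreasing at every EM iteration, and
BIC = -2 log L + p ln n with p = (k-1) + k d + k d(d+1)/2 free parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .io import FEATURE_COLUMNS

__all__ = [
    "GmmModel",
    "ClusterAssignment",
    "fit_gmm",
    "select_k",
    "assign",
    "relabel_canonical",
    "save_model",
    "load_model",
]

_JITTER = 1e-6


@dataclass
class GmmModel:
    """A fitted Gaussian mixture on standardized features.

    ``scale_center``/``scale_scale`` are the training-cohort feature means
    and SDs applied before fitting; ``means``/``covariances`` live on the
    standardized scale.  ``means_original`` returns component means mapped
    back to physical units.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray  # (k, d), standardized scale
    covariances: np.ndarray  # (k, d, d)
    scale_center: np.ndarray
    scale_scale: np.ndarray
    log_likelihood: float
    bic: float
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    n_train: int = 0
    metadata: dict = field(default_factory=dict)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def n_parameters(self) -> int:
        d = self.d
        return (self.k - 1) + self.k * d + self.k * d * (d + 1) // 2

    def means_original(self) -> np.ndarray:
        return self.means * self.scale_scale + self.scale_center


@dataclass
class ClusterAssignment:
    subject_id: str
    label: int  # 1-based
    posteriors: np.ndarray


def _as_matrix(features: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(features, pd.DataFrame):
        X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
        ids = (
            features["subject_id"].astype(str).tolist()
            if "subject_id" in features
            else [str(i) for i in range(len(features))]
        )
        return X, ids
    X = np.asarray(features, dtype=float)
    return X, [str(i) for i in range(X.shape[0])]


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = mean.size
    L = np.linalg.cholesky(cov)
    sol = solve_triangular(L, (X - mean).T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _component_logpdf(X: np.ndarray, model_means, model_covs, weights) -> np.ndarray:
    """(n, k) weighted log densities log(pi_c N(x | mu_c, Sigma_c))."""
    k = len(weights)
    out = np.empty((X.shape[0], k))
    for c in range(k):
        out[:, c] = np.log(weights[c]) + _log_gauss(X, model_means[c], model_covs[c])
    return out


def _regularize(cov: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    cov[np.diag_indices_from(cov)] += _JITTER
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov[np.diag_indices_from(cov)] += 1e-3
        np.linalg.cholesky(cov)  # raises if still singular
    return cov


def fit_gmm(
    features: pd.DataFrame | np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    standardize: bool = True,
) -> GmmModel:
    """Fit a k-component full-covariance Gaussian mixture by EM.

    Runs ``n_init`` k-means++ initializations and keeps the best final
    log-likelihood.  Features are z-scored with training statistics stored
    in the model (disable with ``standardize=False``).  Non-convergence
    within ``max_iter`` sets ``metadata['converged'] = False``.
    """
    X_raw, _ = _as_matrix(features)
    n, d = X_raw.shape
    if n <= k * (d + 1):
        raise ValueError(f"need more than k*(d+1)={k * (d + 1)} subjects, got {n}")
    if not np.all(np.isfinite(X_raw)):
        raise ValueError("features contain missing or non-finite values")

    if standardize:
        center = X_raw.mean(axis=0)
        scale = X_raw.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        center = np.zeros(d)
        scale = np.ones(d)
    X = (X_raw - center) / scale

    rng = np.random.default_rng(seed)
    best: dict | None = None
    for init in range(n_init):
        centers, _ = kmeans_plusplus(
            X, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
        )
        # hard assignment to the nearest seed center -> initial M step
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        resp = np.zeros((n, k))
        resp[np.arange(n), np.argmin(dist, axis=1)] = 1.0
        resp += 1e-6  # avoid empty components
        resp /= resp.sum(axis=1, keepdims=True)

        weights, means, covs = _m_step(X, resp)
        prev_ll = -np.inf
        converged = False
        collapsed = False
        iters = 0
        for iters in range(1, max_iter + 1):
            log_wpdf = _component_logpdf(X, means, covs, weights)
            log_norm = logsumexp(log_wpdf, axis=1)
            ll = float(log_norm.sum())
            resp = np.exp(log_wpdf - log_norm[:, None])
            if resp.sum(axis=0).min() < d + 1 or any(
                np.linalg.eigvalsh(c)[0] < 10 * _JITTER for c in covs
            ):
                # a component collapsed onto fewer points than its covariance
                # has parameters, or onto a hyperplane (covariance eigenvalue
                # at the regularization floor); abandon this init
                collapsed = True
                break
            # EM guarantees a non-decreasing log-likelihood; the covariance
            # jitter perturbs the exact M step, so allow small numerical slack
            assert ll >= prev_ll - 1e-6 * max(1.0, abs(prev_ll)), (
                f"EM log-likelihood decreased: {prev_ll} -> {ll}"
            )
            weights, means, covs = _m_step(X, resp)
            if ll - prev_ll < tol * max(1.0, abs(ll)) and iters > 1:
                converged = True
                prev_ll = ll
                break
            prev_ll = ll
        if collapsed:
            continue
        if best is None or prev_ll > best["ll"]:
            best = dict(
                ll=prev_ll, weights=weights, means=means, covs=covs,
                converged=converged, iters=iters,
            )

    if best is None:
        raise RuntimeError(
            f"all {n_init} EM initializations collapsed for k={k}; "
            "the mixture is over-parameterized for these data"
        )
    p = (k - 1) + k * d + k * d * (d + 1) // 2
    bic = -2.0 * best["ll"] + p * np.log(n)
    return GmmModel(
        k=k,
        weights=best["weights"],
        means=best["means"],
        covariances=best["covs"],
        scale_center=center,
        scale_scale=scale,
        log_likelihood=best["ll"],
        bic=float(bic),
        n_train=n,
        metadata=dict(
            n_init=n_init, seed=seed, tol=tol, max_iter=max_iter,
            converged=bool(best["converged"]), iterations=int(best["iters"]),
            standardize=standardize,
        ),
    )


def _m_step(X: np.ndarray, resp: np.ndarray):
    n, d = X.shape
    nk = resp.sum(axis=0)
    weights = nk / n
    means = (resp.T @ X) / nk[:, None]
    covs = np.empty((resp.shape[1], d, d))
    for c in range(resp.shape[1]):
        diff = X - means[c]
        covs[c] = _regularize((resp[:, c, None] * diff).T @ diff / nk[c])
    return weights, means, covs


def select_k(
    features: pd.DataFrame | np.ndarray,
    k_range: Sequence[int] = range(1, 9),
    seed: int = 0,
    elbow_fraction: float = 0.25,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame, dict[int, GmmModel]]:
    """Choose the number of phenogroups from the BIC curve.

    The chosen k is the smallest k whose BIC decrease toward k+1 falls below
    ``elbow_fraction`` of the preceding decrease (ties toward smaller k);
    with ``elbow_fraction = 0`` the global BIC minimum is returned.  If BIC
    does not decrease from k=1 to k=2 at all, k=1 is returned with a warning
    flag in the curve.  Returns ``(k, bic_curve, fitted_models)``.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain positive integers")
    models: dict[int, GmmModel] = {}
    skipped: list[int] = []
    for k in ks:
        try:
            models[k] = fit_gmm(features, k, seed=seed, **fit_kwargs)
        except RuntimeError:
            # every initialization degenerated: k is over-parameterized for
            # these data and is not a candidate
            skipped.append(k)
    ks = [k for k in ks if k in models]
    if not ks:
        raise RuntimeError("no mixture size in k_range could be fitted")
    bics = np.array([models[k].bic for k in ks])
    curve = pd.DataFrame(
        {"k": ks, "bic": bics, "log_likelihood": [models[k].log_likelihood for k in ks]}
    )
    if skipped:
        curve.attrs["skipped_k"] = skipped
    if len(ks) == 1:
        return ks[0], curve, models

    if elbow_fraction <= 0:
        return ks[int(np.argmin(bics))], curve, models
    drops = -np.diff(bics)  # drops[i] = BIC(k_i) - BIC(k_{i+1})
    if drops[0] <= 0:
        curve.attrs["warning"] = "BIC non-decreasing at k=2"
        return ks[0], curve, models
    for i in range(1, len(drops)):
        if drops[i] < elbow_fraction * drops[i - 1]:
            return ks[i], curve, models
    return ks[int(np.argmin(bics))], curve, models


def assign(
    model: GmmModel, features: pd.DataFrame | np.ndarray
) -> list[ClusterAssignment]:
    """Posterior responsibilities and hard labels under a (frozen) model.

    The model's stored training center/scale are reused — the external
    cohort is never re-standardized with its own statistics.
    """
    X_raw, ids = _as_matrix(features)
    if X_raw.shape[1] != model.d:
        raise ValueError(
            f"feature count mismatch: model has {model.d}, got {X_raw.shape[1]}"
        )
    post = posterior_matrix(model, X_raw)
    labels = np.argmax(post, axis=1) + 1
    return [
        ClusterAssignment(subject_id=s, label=int(lab), posteriors=p)
        for s, lab, p in zip(ids, labels, post)
    ]


def posterior_matrix(model: GmmModel, X_raw: np.ndarray) -> np.ndarray:
    """(n, k) posterior cluster probabilities for raw-scale feature rows."""
    X = (np.atleast_2d(X_raw) - model.scale_center) / model.scale_scale
    log_wpdf = _component_logpdf(X, model.means, model.covariances, model.weights)
    return np.exp(log_wpdf - logsumexp(log_wpdf, axis=1)[:, None])


def relabel_canonical(
    model: GmmModel, assignments: Sequence[ClusterAssignment] | None = None
) -> tuple[GmmModel, list[ClusterAssignment] | None]:
    """Permute component order into the package's canonical label order.

    Components are ordered by descending early-diastolic release rate
    (ascending signed ``slope_ed`` component mean on the original feature
    scale), so cluster 1 is the fastest-relaxing, lowest-risk phenotype and
    the last cluster the stiffest.  Purely a deterministic relabeling; the
    mixture itself is unchanged.
    """
    means_orig = model.means_original()
    j = model.feature_names.index("slope_ed")
    order = np.argsort(means_orig[:, j], kind="stable")
    relabeled = GmmModel(
        k=model.k,
        weights=model.weights[order],
        means=model.means[order],
        covariances=model.covariances[order],
        scale_center=model.scale_center,
        scale_scale=model.scale_scale,
        log_likelihood=model.log_likelihood,
        bic=model.bic,
        feature_names=list(model.feature_names),
        n_train=model.n_train,
        metadata={**model.metadata, "canonical_order": order.tolist()},
    )
    new_assignments = None
    if assignments is not None:
        inv = np.empty(model.k, dtype=int)
        inv[order] = np.arange(model.k)
        new_assignments = [
            ClusterAssignment(
                subject_id=a.subject_id,
                label=int(inv[a.label - 1]) + 1,
                posteriors=a.posteriors[order],
            )
            for a in assignments
        ]
    return relabeled, new_assignments


def save_model(model: GmmModel, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "k": model.k,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
        "scale_center": model.scale_center.tolist(),
        "scale_scale": model.scale_scale.tolist(),
        "log_likelihood": model.log_likelihood,
        "bic": model.bic,
        "feature_names": model.feature_names,
        "n_train": model.n_train,
        "metadata": model.metadata,
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: str | Path) -> GmmModel:
    data = json.loads(Path(path).read_text())
    return GmmModel(
        k=int(data["k"]),
        weights=np.array(data["weights"]),
        means=np.array(data["means"]),
        covariances=np.array(data["covariances"]),
        scale_center=np.array(data["scale_center"]),
        scale_scale=np.array(data["scale_scale"]),
        log_likelihood=float(data["log_likelihood"]),
        bic=float(data["bic"]),
        feature_names=list(data["feature_names"]),
        n_train=int(data["n_train"]),
        metadata=dict(data["metadata"]),
    )


def assignments_to_frame(assignments: Sequence[ClusterAssignment]) -> pd.DataFrame:
    k = assignments[0].posteriors.size
    rows = [
        {
            "subject_id": a.subject_id,
            "label": a.label,
            **{f"p{c + 1}": a.posteriors[c] for c in range(k)},
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)
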