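"""MFCC-GMM baseline branch.

One diagonal-covariance Gaussian mixture per class (and gender) models the
pooled cepstral-frame distribution of its training group.  A test subject's
kept frames are scored against both models; the sigmoid of the difference of
frame-averaged log-likelihoods (the log-likelihood ratio) is the subject
score, with 1 leaning to the patient class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.mixture import GaussianMixture

from pdvoice.frontend import FeatureMatrix

#: mixture sizes used in the study conditions
N_COMPONENTS_HIGH_QUALITY = 20
N_COMPONENTS_TELEPHONE = 50


@dataclass
class GmmModel:
    weights: np.ndarray           # (n_components,) on the simplex
    means: np.ndarray             # (n_components, dim)
    variances: np.ndarray         # (n_components, dim) diagonal
    training_log: list = field(default_factory=list)  # per-iteration mean LLH

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")


@dataclass
class GmmPair:
    pd_model: GmmModel
    hc_model: GmmModel
    gender: str = "M"

    def __post_init__(self) -> None:
        if (self.pd_model.dim != self.hc_model.dim
                or self.pd_model.n_components != self.hc_model.n_components):
            raise ValueError("paired models must share dim and n_components")


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.values
    return np.asarray(features, dtype=float)


def train_gmm(
    features,
    n_components: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    variance_floor_frac: float = 1e-3,
) -> GmmModel:
    """EM-fit a diagonal GMM from k-means initialization.

    The per-iteration mean log-likelihood is recorded and must be
    non-decreasing; components are floored at ``variance_floor_frac`` of the
    global variance.  Raises if fewer than ``10 * n_components`` frames are
    provided.
    """
    X = _as_array(features)
    if len(X) < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} frames to fit {n_components} components,"
            f" got {len(X)}"
        )
    # per-dimension floor at variance_floor_frac of each dimension's global
    # variance; cepstral dimensions span orders of magnitude, so a scalar
    # floor either distorts the quiet dimensions or protects nothing
    floor = np.maximum(variance_floor_frac * np.var(X, axis=0), 1e-12)
    gm = GaussianMixture(
        n_components=n_components,
        covariance_type="diag",
        max_iter=1,
        warm_start=True,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-10,
        tol=0.0,
    )
    log: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-step fits never "converge"
        for _ in range(max_iter):
            gm.fit(X)
            if np.any(gm.covariances_ < floor):
                gm.covariances_ = np.maximum(gm.covariances_, floor)
                gm.precisions_cholesky_ = 1.0 / np.sqrt(gm.covariances_)
            ll = float(gm.score(X))
            if log and ll < log[-1] - 1e-4:
                raise RuntimeError("EM log-likelihood decreased")
            if log and ll <= log[-1]:
                # float-precision wobble at convergence (the variance floor
                # makes exact monotonicity hold only to ~1e-7): stop here
                break
            improved = not log or ll - log[-1] > tol
            log.append(ll)
            if not improved:
                break
    model = GmmModel(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        variances=np.maximum(gm.covariances_.copy(), floor),
        training_log=log,
    )
    return model


def mean_loglik(model: GmmModel, features) -> float:
    """Frame-averaged mixture log-likelihood (independent of frame count)."""
    X = _as_array(features)
    if X.shape[1] != model.dim:
        raise ValueError(f"feature dim {X.shape[1]} != model dim {model.dim}")
    # (frames, components) log N(x | mu_c, diag var_c) + log w_c
    inv_var = 1.0 / model.variances
    log_det = np.sum(np.log(model.variances), axis=1)
    quad = (
        np.einsum("nd,cd->nc", X**2, inv_var)
        - 2.0 * np.einsum("nd,cd->nc", X, model.means * inv_var)
        + np.sum(model.means**2 * inv_var, axis=1)
    )
    log_p = (
        np.log(model.weights)
        - 0.5 * (model.dim * np.log(2 * np.pi) + log_det + quad)
    )
    return float(np.mean(logsumexp(log_p, axis=1)))


def score_subject_gmm(pair: GmmPair, features, sigmoid_scale: float = 1.0) -> float:
    """Sigmoid of the scaled log-likelihood ratio; > 0.5 leans patient-class."""
    llr = mean_loglik(pair.pd_model, features) - mean_loglik(pair.hc_model, features)
    return float(expit(sigmoid_scale * llr))
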