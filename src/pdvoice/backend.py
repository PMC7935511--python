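"""Back-end classification of x-vectors.

Test embeddings are compared against per-class mean reference x-vectors with
one of three similarity measures — cosine, cosine in an LDA subspace, or a
PLDA log-likelihood ratio — and the sigmoid of the similarity difference is
the segment score; a subject's score is the mean over their segments.

The PLDA here is the factor-analysis model ``x = mu + F h + G w + eps`` with
class latent ``h`` (shared by all vectors of a class), per-vector latent
``w`` and diagonal-Gaussian residual.  Training is exact EM over the joint
posterior of (h, w); verification uses the closed-form two-covariance
marginals (across-class covariance F F', within-class covariance G G' +
Sigma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import expit

from pdvoice.tdnn import XVector


def _as_matrix(xvectors) -> np.ndarray:
    rows = [x.values if isinstance(x, XVector) else np.asarray(x, float) for x in xvectors]
    return np.vstack([r[None, :] if r.ndim == 1 else r for r in rows])


@dataclass
class ClassReferences:
    xvec_pd: np.ndarray
    xvec_hc: np.ndarray
    gender: str = "M"
    degenerate: bool = False


@dataclass
class LdaTransform:
    projection: np.ndarray        # (dim_in, dim_out)
    mean: np.ndarray              # training mean, removed before projecting
    class_means: dict = field(default_factory=dict)  # label -> projected mean
    eigenvalues: np.ndarray | None = None

    @property
    def dim_out(self) -> int:
        return self.projection.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, float) - self.mean) @ self.projection


@dataclass
class PldaModel:
    mu: np.ndarray
    F: np.ndarray                 # (dim, rank_F) across-class loadings
    G: np.ndarray                 # (dim, rank_G) within-class loadings
    Sigma: np.ndarray             # (dim,) diagonal residual covariance
    training_log: list = field(default_factory=list)  # per-iteration loglik

    @property
    def dim(self) -> int:
        return len(self.mu)

    @property
    def between_cov(self) -> np.ndarray:
        return self.F @ self.F.T

    @property
    def within_cov(self) -> np.ndarray:
        return self.G @ self.G.T + np.diag(self.Sigma)


# ---------------------------------------------------------------------------
# references and cosine
# ---------------------------------------------------------------------------


def compute_references(xvectors, labels, gender: str = "M") -> ClassReferences:
    """Arithmetic per-class mean of training x-vectors."""
    X = _as_matrix(xvectors)
    labels = np.asarray(labels)
    out = {}
    for cls in ("PD", "HC"):
        rows = X[labels == cls]
        if len(rows) == 0:
            raise ValueError(f"no training x-vectors for class {cls}")
        out[cls] = rows.mean(axis=0)
    degenerate = min(np.linalg.norm(out["PD"]), np.linalg.norm(out["HC"])) < 1e-9
    return ClassReferences(xvec_pd=out["PD"], xvec_hc=out["HC"],
                           gender=gender, degenerate=degenerate)


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


def fit_lda(xvectors, labels, dim_out: int = 2, ridge: float = 1e-6) -> LdaTransform:
    """Generalized-eigenproblem LDA: maximize between- over within-class scatter.

    The within-class scatter is ridge-regularized by ``ridge * trace/dim``
    before the simultaneous diagonalization; the top ``dim_out`` directions
    are kept.  With two classes the leading direction is the Fisher
    direction; further directions arise from the within-class whitening.
    """
    X = _as_matrix(xvectors)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("LDA needs at least 2 classes")
    n, d = X.shape
    mean = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for cls in classes:
        rows = X[labels == cls]
        if len(rows) < 2:
            raise ValueError(f"class {cls!r} needs at least 2 vectors")
        mu_c = rows.mean(axis=0)
        diff = rows - mu_c
        Sw += diff.T @ diff
        delta = (mu_c - mean)[:, None]
        Sb += len(rows) * (delta @ delta.T)
    Sw += ridge * (np.trace(Sw) / d + 1e-12) * np.eye(d)
    evals, evecs = linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:dim_out]
    proj = evecs[:, order]
    lda = LdaTransform(projection=proj, mean=mean,
                       eigenvalues=evals[order])
    for cls in classes:
        lda.class_means[cls] = lda.transform(X[labels == cls].mean(axis=0))
    return lda


# ---------------------------------------------------------------------------
# PLDA
# ---------------------------------------------------------------------------


def _plda_loglik(X: np.ndarray, groups: list[np.ndarray], mu, F, G, Sigma) -> float:
    """Exact marginal log-likelihood of grouped data under the PLDA model.

    Per class the joint covariance is I (x) W + 11' (x) FF' with
    W = GG' + Sigma, so the determinant and quadratic form reduce via the
    matrix determinant lemma and Woodbury to per-class d x d / r x r solves.
    """
    d = X.shape[1]
    W = G @ G.T + np.diag(Sigma)
    Wi = linalg.inv(W)
    sign, logdet_W = np.linalg.slogdet(W)
    ll = 0.0
    for idx in groups:
        n = len(idx)
        Xc = X[idx] - mu
        r = F.shape[1]
        if r:
            A = np.eye(r) + n * (F.T @ Wi @ F)
            sign_a, logdet_A = np.linalg.slogdet(A)
            t = Xc.sum(axis=0)
            WiF = Wi @ F
            corr = (t @ WiF) @ linalg.solve(A, WiF.T @ t)
        else:
            logdet_A, corr = 0.0, 0.0
        quad = float(np.einsum("ij,jk,ik->", Xc, Wi, Xc)) - corr
        ll += -0.5 * (n * d * np.log(2 * np.pi) + n * logdet_W + logdet_A + quad)
    return ll


def fit_plda(
    xvectors,
    labels,
    rank_F: int = 1,
    rank_G: int | None = None,
    iters: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
) -> PldaModel:
    """EM estimation of (mu, F, G, Sigma) from labeled vectors.

    The E-step computes the exact joint posterior moments of the class latent
    ``h`` and per-vector latents ``w`` (w's are conditionally independent
    given h); the M-step jointly updates [F G] and the diagonal Sigma.  The
    training marginal likelihood is recorded and must be non-decreasing.
    """
    X = _as_matrix(xvectors)
    labels = np.asarray(labels)
    n, d = X.shape
    if rank_G is None:
        rank_G = max(d - max(rank_F, 1), 1)
    if rank_F + rank_G > d:
        raise ValueError("rank_F + rank_G must not exceed dim")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("PLDA training needs >= 2 classes")
    groups = [np.where(labels == c)[0] for c in classes]

    rng = np.random.default_rng(seed)
    mu = X.mean(axis=0)
    total_sd = X.std(axis=0).mean() + 1e-12
    F = 0.5 * total_sd * rng.standard_normal((d, rank_F)) if rank_F else np.zeros((d, 0))
    G = 0.5 * total_sd * rng.standard_normal((d, rank_G)) if rank_G else np.zeros((d, 0))
    Sigma = np.maximum(X.var(axis=0), 1e-6)
    Xc_all = X - mu
    S_xx = Xc_all.T @ Xc_all

    log: list[float] = []
    for _ in range(iters):
        rF, rG = F.shape[1], G.shape[1]
        W = G @ G.T + np.diag(Sigma)
        Wi = linalg.inv(W)
        Si = 1.0 / Sigma
        M = np.eye(rG) + (G.T * Si) @ G if rG else np.zeros((0, 0))
        Mi = linalg.inv(M) if rG else M
        K = Mi @ (G.T * Si) if rG else np.zeros((0, d))  # E[w|x,h] map
        KF = K @ F if rG else np.zeros((0, rF))

        R = np.zeros((rF + rG, rF + rG))
        C = np.zeros((d, rF + rG))
        Th = np.zeros((rF, rF))  # mean posterior second moment of h (per class)
        for idx in groups:
            ni = len(idx)
            Xc = X[idx] - mu
            t = Xc.sum(axis=0)
            if rF:
                A = np.eye(rF) + ni * (F.T @ Wi @ F)
                cov_h = linalg.inv(A)
                Eh = cov_h @ (F.T @ (Wi @ t))
                Ehh = cov_h + np.outer(Eh, Eh)
            else:
                Eh = np.zeros(0)
                cov_h = np.zeros((0, 0))
                Ehh = cov_h
            # per-vector w moments given the h posterior
            Ew = (K @ Xc.T).T - Eh @ KF.T if rG else np.zeros((ni, 0))
            cov_wh = -KF @ cov_h if rG and rF else np.zeros((rG, rF))
            sum_Eww = np.zeros((rG, rG))
            if rG:
                sum_Eww = (
                    ni * (Mi + KF @ cov_h @ KF.T) + Ew.T @ Ew
                )
            # accumulate sufficient statistics
            if rF:
                Th += Ehh / len(groups)
            R[:rF, :rF] += ni * Ehh
            if rF and rG:
                sum_Ewh = Ew.sum(axis=0)[:, None] @ Eh[None, :] + ni * cov_wh
                R[rF:, :rF] += sum_Ewh
                R[:rF, rF:] += sum_Ewh.T
            R[rF:, rF:] += sum_Eww
            if rF:
                C[:, :rF] += np.outer(t, Eh)
            if rG:
                C[:, rF:] += Xc.T @ Ew

        B = linalg.solve(R + 1e-10 * np.eye(rF + rG), C.T).T if rF + rG else C
        Sigma = np.maximum(np.diag(S_xx - B @ C.T) / n, 1e-9)
        F = B[:, :rF]
        G = B[:, rF:]
        # minimum-divergence step: renormalize the latent priors to N(0, I).
        # EM alone crawls along a near-flat ridge in the scale of F; folding
        # the posterior latent covariance back into the loadings fixes the
        # scale and accelerates convergence without decreasing the likelihood.
        if rF:
            F = F @ np.linalg.cholesky(Th + 1e-12 * np.eye(rF))
        if rG:
            Tw = R[rF:, rF:] / n
            G = G @ np.linalg.cholesky(Tw + 1e-12 * np.eye(rG))

        ll = _plda_loglik(X, groups, mu, F, G, Sigma) / n
        if log and ll < log[-1] - 1e-6:
            raise RuntimeError("PLDA EM log-likelihood decreased")
        improved = not log or ll - log[-1] > tol
        log.append(ll)
        if not improved:
            break

    return PldaModel(mu=mu, F=F, G=G, Sigma=Sigma, training_log=log)


def plda_llr(model: PldaModel, x1: np.ndarray, x2: np.ndarray) -> float:
    """Log-likelihood ratio that two vectors share the class latent ``h``.

    Two-covariance form: under H_same the pair is jointly Gaussian with
    cross-covariance F F'; under H_diff the two vectors are independent with
    total covariance F F' + G G' + Sigma.
    """
    x1 = np.asarray(x1, float).ravel()
    x2 = np.asarray(x2, float).ravel()
    if len(x1) != model.dim or len(x2) != model.dim:
        raise ValueError("vector dimension does not match the PLDA model")
    Phi_b = model.between_cov
    Phi_t = Phi_b + model.within_cov
    d = model.dim
    top = np.hstack([Phi_t, Phi_b])
    bottom = np.hstack([Phi_b, Phi_t])
    joint = np.vstack([top, bottom])
    z = np.concatenate([x1 - model.mu, x2 - model.mu])

    def _logpdf(v: np.ndarray, cov: np.ndarray) -> float:
        sign, logdet = np.linalg.slogdet(cov)
        sol = linalg.solve(cov, v, assume_a="pos")
        return -0.5 * (len(v) * np.log(2 * np.pi) + logdet + v @ sol)

    ll_same = _logpdf(z, joint)
    ll_diff = _logpdf(x1 - model.mu, Phi_t) + _logpdf(x2 - model.mu, Phi_t)
    return float(ll_same - ll_diff)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_xvector(
    references: ClassReferences,
    x,
    method: str = "cosine",
    transforms: dict | None = None,
    sigmoid_scale: float = 1.0,
) -> float:
    """Sigmoid of the similarity difference to the two class references."""
    v = x.values if isinstance(x, XVector) else np.asarray(x, float)
    transforms = transforms or {}
    if method == "cosine":
        sim_pd = cosine_similarity(v, references.xvec_pd)
        sim_hc = cosine_similarity(v, references.xvec_hc)
    elif method == "lda_cosine":
        lda: LdaTransform | None = transforms.get("lda")
        if lda is None:
            raise ValueError("lda_cosine scoring requires an 'lda' transform")
        sim_pd = cosine_similarity(lda.transform(v), lda.transform(references.xvec_pd))
        sim_hc = cosine_similarity(lda.transform(v), lda.transform(references.xvec_hc))
    elif method == "plda":
        plda: PldaModel | None = transforms.get("plda")
        if plda is None:
            raise ValueError("plda scoring requires a 'plda' model")
        pre = transforms.get("plda_lda")
        vp = pre.transform(v) if pre is not None else v
        ref_pd = pre.transform(references.xvec_pd) if pre is not None else references.xvec_pd
        ref_hc = pre.transform(references.xvec_hc) if pre is not None else references.xvec_hc
        sim_pd = plda_llr(plda, vp, ref_pd)
        sim_hc = plda_llr(plda, vp, ref_hc)
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return float(expit(sigmoid_scale * (sim_pd - sim_hc)))


def score_subject(segment_scores) -> float:
    """Arithmetic mean of a subject's per-segment scores."""
    scores = np.asarray(list(segment_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("subject has no segment scores")
    return float(scores.mean())
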