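"""Factor mixture model core: likelihood, estimation, posteriors, entropy.

The model ties a latent-class model to a one-factor measurement model.  For
subject i in class k with factor score eta ~ Normal(alpha_k, psi_k), the
continuous items follow

    y_ic = I_kc + F_kc * eta + e_ic,     e_ic ~ Normal(0, theta_kc),

gait speed is left-censored at a known floor (a Tobit term), and weight loss
is two-part: a class-level Bernoulli occurrence plus a Gaussian magnitude in
kg that itself loads on the factor.  The invariance template of the active
:class:`~syndromix.family.FMMSpec` decides which blocks are class-specific.

Estimation is EM with fixed-node Gauss-Hermite quadrature over the factor
(the pair (class, node) is treated as the missing datum, making each
iteration's conditional-maximization updates closed-form and the quadrature
log-likelihood monotone).  Models without a factor block reduce to a single
trivial node.  For fully Gaussian (and censored-Gaussian) item sets the
marginal likelihood is also available in closed form via rank-one
multivariate-normal marginalization, used as a cross-check path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp, log_ndtr
from scipy.stats import norm

from .family import FMMSpec, GAUSSIAN_ITEM_MODELS, count_parameters
from .prep import FMMItemMatrix

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class ItemData:
    """Internal item container: values, observed / censored cell masks, and
    the optional occurrence indicator of the two-part item."""

    y: np.ndarray                 # (n, C); entries under ~obs are ignored
    obs: np.ndarray               # (n, C) bool: observed and uncensored
    cens: np.ndarray              # (n, C) bool: left-censored at the floor
    occurrence: np.ndarray | None  # (n,) 0/1, or None when no two-part item
    floor: float

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def C(self) -> int:
        return self.y.shape[1]

    @classmethod
    def from_any(cls, items) -> "ItemData":
        if isinstance(items, ItemData):
            return items
        if isinstance(items, FMMItemMatrix):
            n = items.n
            obs = ~np.isnan(items.y)
            cens = np.zeros((n, 5), dtype=bool)
            cens[:, 3] = items.censored
            obs[:, 3] = ~items.censored
            y = np.nan_to_num(items.y)
            return cls(y=y, obs=obs, cens=cens,
                       occurrence=items.occurrence.copy(), floor=items.floor)
        y = np.asarray(items, dtype=float)
        if y.ndim != 2:
            raise ValueError("plain item arrays must be 2-D (subjects x items)")
        return cls(
            y=y, obs=np.ones_like(y, dtype=bool),
            cens=np.zeros_like(y, dtype=bool), occurrence=None, floor=-np.inf,
        )


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class FMMParams:
    """Full parameter set of a factor mixture model.

    Rows of class-invariant blocks are stored replicated across classes, so
    every array is shaped by (K, C) or (K,) regardless of the template.
    """

    pi: np.ndarray          # (K,) mixing proportions
    intercepts: np.ndarray  # (K, C)
    loadings: np.ndarray    # (K, C); zero rows for class-only models
    theta: np.ndarray       # (K, C) residual variances
    alpha: np.ndarray       # (K,) factor means
    psi: np.ndarray         # (K,) factor variances (zero when no factor)
    occ_logit: np.ndarray | None = None  # (K,) occurrence logit, or None
    floor: float = -np.inf
    item_models: tuple = GAUSSIAN_ITEM_MODELS

    def __post_init__(self) -> None:
        for name in ("pi", "intercepts", "loadings", "theta", "alpha", "psi"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.occ_logit is not None:
            self.occ_logit = np.asarray(self.occ_logit, dtype=float)

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def has_factor(self) -> bool:
        return bool(np.any(self.loadings != 0.0) or np.any(self.psi > 0.0))

    def copy(self) -> "FMMParams":
        return FMMParams(
            pi=self.pi.copy(), intercepts=self.intercepts.copy(),
            loadings=self.loadings.copy(), theta=self.theta.copy(),
            alpha=self.alpha.copy(), psi=self.psi.copy(),
            occ_logit=None if self.occ_logit is None else self.occ_logit.copy(),
            floor=self.floor, item_models=self.item_models,
        )

    def permute_classes(self, order) -> "FMMParams":
        order = np.asarray(order)
        return FMMParams(
            pi=self.pi[order], intercepts=self.intercepts[order],
            loadings=self.loadings[order], theta=self.theta[order],
            alpha=self.alpha[order], psi=self.psi[order],
            occ_logit=None if self.occ_logit is None else self.occ_logit[order],
            floor=self.floor, item_models=self.item_models,
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "intercepts": self.intercepts.tolist(),
            "loadings": self.loadings.tolist(),
            "theta": self.theta.tolist(),
            "alpha": self.alpha.tolist(),
            "psi": self.psi.tolist(),
            "occ_logit": None if self.occ_logit is None else self.occ_logit.tolist(),
            "floor": self.floor,
            "item_models": list(self.item_models),
        }


def params_from_cohort_config(config) -> FMMParams:
    """Generative FMM parameters implied by a cohort configuration.

    Uses the configuration's intercept / loading / variance blocks directly
    (the weight-loss magnitude column keeps its Gaussian-model intercept and
    loading, not the generator's log-normal law -- the two coincide only in
    mean structure, which is what parameter-recovery checks target).
    """
    K = config.K_true
    return FMMParams(
        pi=config.mixing.copy(),
        intercepts=config.intercepts.copy(),
        loadings=np.tile(config.loadings, (K, 1)),
        theta=config.residual_variances.copy(),
        alpha=config.factor_means.copy(),
        psi=config.factor_variances.copy(),
        occ_logit=config.weightloss_occurrence_logit.copy(),
        floor=config.gait_censor_floor,
        item_models=("gaussian", "gaussian", "gaussian",
                     "censored-gaussian", "two-part-magnitude"),
    )


# ---------------------------------------------------------------------------
# Quadrature likelihood
# ---------------------------------------------------------------------------

def _nodes(Q: int, has_factor: bool):
    """Standard-normal Gauss-Hermite nodes and weights (probabilists')."""
    if not has_factor:
        return np.zeros(1), np.ones(1)
    z, w = hermegauss(Q)
    return z, w / w.sum()


def _design_cache(data: ItemData) -> dict:
    """Per-dataset constants reused across EM iterations."""
    Mf = data.obs.astype(float)
    y0 = np.where(data.obs, data.y, 0.0)  # masked cells may hold NaN
    return {
        "Mf": Mf,
        "My": y0,
        "Myy": y0 * y0,
        "X3": np.hstack([Mf, y0, y0 * y0]),  # fused design for M-step sums
        "occ": None if data.occurrence is None else data.occurrence.astype(float),
    }


def _log_density_cells(params: FMMParams, data: ItemData, z: np.ndarray,
                       cache: dict | None = None):
    """Log f(y_i | class k, node q) -> (n, K, Q); also returns eta (K, Q)."""
    if cache is None:
        cache = _design_cache(data)
    K, C = params.intercepts.shape
    Q = z.shape[0]
    s = np.sqrt(np.maximum(params.psi, 0.0))
    eta = params.alpha[:, None] + s[:, None] * z[None, :]          # (K, Q)
    mu = (params.intercepts[:, None, :]
          + params.loadings[:, None, :] * eta[:, :, None])         # (K, Q, C)
    inv_t = 1.0 / params.theta                                      # (K, C)
    logn = -0.5 * (_LOG2PI + np.log(params.theta))                  # (K, C)

    Mf, My, Myy = cache["Mf"], cache["My"], cache["Myy"]
    n = Mf.shape[0]
    t1 = Myy @ (-0.5 * inv_t).T + Mf @ logn.T                       # (n, K)
    B1 = (mu * inv_t[:, None, :]).transpose(2, 0, 1).reshape(C, K * Q)
    B2 = (-0.5 * mu * mu * inv_t[:, None, :]).transpose(2, 0, 1).reshape(C, K * Q)
    ld = (My @ B1 + Mf @ B2).reshape(n, K, Q)
    ld += t1[:, :, None]

    if data.cens.any():
        # all censored cells share the floor; contribution depends on (k, q, c)
        for c in np.flatnonzero(data.cens.any(axis=0)):
            rows = data.cens[:, c]
            sd = np.sqrt(params.theta[:, c])[:, None]               # (K, 1)
            beta = (data.floor - mu[:, :, c]) / sd                  # (K, Q)
            ld[rows] += log_ndtr(beta)[None, :, :]

    occ = cache["occ"]
    if params.occ_logit is not None and occ is not None:
        p = 1.0 / (1.0 + np.exp(-params.occ_logit))
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        t4 = occ[:, None] * np.log(p)[None, :] \
            + (1.0 - occ)[:, None] * np.log1p(-p)[None, :]          # (n, K)
        ld += t4[:, :, None]
    return ld, eta


def loglikelihood(
    params: FMMParams,
    items,
    method: str = "auto",
    quadrature_points: int = 21,
) -> float:
    """Marginal log-likelihood Sum_i log Sum_k pi_k f_k(y_i).

    ``method='analytic'`` marginalizes the factor in closed form (multivariate
    normal with covariance F psi_k F' + Theta_k; censored cells contribute the
    conditional normal left tail).  ``method='quadrature'`` integrates the
    factor on a fixed Gauss-Hermite grid, the same objective the EM fit
    maximizes.  ``'auto'`` uses the analytic path whenever the item set is
    conditionally Gaussian (the default items qualify), else quadrature.
    """
    data = ItemData.from_any(items)
    if method == "auto":
        method = "analytic"
    if method == "analytic":
        return _loglik_analytic(params, data)
    z, w = _nodes(quadrature_points, params.has_factor)
    ld, _ = _log_density_cells(params, data, z)
    lw = np.log(np.clip(params.pi, 1e-300, None))[:, None] + np.log(w)[None, :]
    return float(logsumexp(ld + lw[None, :, :], axis=(1, 2)).sum())


def _loglik_analytic(params: FMMParams, data: ItemData) -> float:
    """Exact marginal via rank-one MVN marginalization, per missing pattern."""
    n, C = data.y.shape
    K = params.K
    per_class = np.empty((n, K))
    for k in range(K):
        lam = params.loadings[k]
        th = params.theta[k]
        psi = params.psi[k] if params.has_factor else 0.0
        mean = params.intercepts[k] + lam * params.alpha[k]
        per_class[:, k] = _class_logdens_pattern(
            data, mean, lam, psi, th, params.floor
        )
        if params.occ_logit is not None and data.occurrence is not None:
            p = float(np.clip(1.0 / (1.0 + np.exp(-params.occ_logit[k])),
                              1e-9, 1.0 - 1e-9))
            occ = data.occurrence.astype(float)
            per_class[:, k] += occ * np.log(p) + (1 - occ) * np.log1p(-p)
    lp = np.log(np.clip(params.pi, 1e-300, None))
    return float(logsumexp(per_class + lp[None, :], axis=1).sum())


def _class_logdens_pattern(
    data: ItemData, mean, lam, psi, theta, floor
) -> np.ndarray:
    """log N(y_obs; mu, lam psi lam' + diag(theta)) with a censored-cell tail
    factor, vectorized over rows grouped by (obs, cens) pattern."""
    n = data.n
    out = np.zeros(n)
    key = np.concatenate([data.obs, data.cens], axis=1)
    _, inverse = np.unique(key, axis=0, return_inverse=True)
    for g in np.unique(inverse):
        rows = inverse == g
        o = np.flatnonzero(data.obs[np.flatnonzero(rows)[0]])
        e = np.flatnonzero(data.cens[np.flatnonzero(rows)[0]])
        if len(e) > 1:
            raise NotImplementedError("at most one censored cell per row")
        Y = data.y[np.ix_(rows, o)]
        mu_o, lam_o, th_o = mean[o], lam[o], theta[o]
        # Woodbury for Sigma_oo = psi lam lam' + diag(theta)
        r = Y - mu_o
        a = np.sum(lam_o * lam_o / th_o)
        denom = 1.0 + psi * a
        quad = np.sum(r * r / th_o, axis=1) \
            - psi * (r @ (lam_o / th_o)) ** 2 / denom
        logdet = np.sum(np.log(th_o)) + np.log(denom)
        val = -0.5 * (len(o) * _LOG2PI + logdet + quad)
        if len(e) == 1:
            c = e[0]
            # conditional distribution of the censored coordinate
            cov_co = psi * lam[c] * lam_o                    # (|o|,)
            sol = _solve_rank1(cov_co, lam_o, th_o, psi)
            mu_c = mean[c] + r @ sol
            var_c = psi * lam[c] ** 2 + theta[c] - cov_co @ sol
            val = val + log_ndtr((floor - mu_c) / np.sqrt(var_c))
        out[rows] = val
    return out


def _solve_rank1(b, lam_o, th_o, psi):
    """Solve (psi lam lam' + diag(th)) x = b via Sherman-Morrison."""
    x0 = b / th_o
    if psi == 0.0:
        return x0
    u = lam_o / th_o
    denom = 1.0 + psi * np.sum(lam_o * u)
    return x0 - u * (psi * (lam_o @ x0) / denom)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------

@dataclass
class FMMFit:
    spec: FMMSpec
    params: FMMParams
    loglik: float
    n_params: int
    bic: float
    posteriors: np.ndarray
    entropy: float        # NaN when K = 1
    converged: bool
    degenerate: bool
    n_starts_used: int
    n: int
    start_logliks: list = field(default_factory=list)
    loglik_trace: np.ndarray | None = None

    @property
    def K(self) -> int:
        return self.spec.K

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "entropy": None if np.isnan(self.entropy) else self.entropy,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_starts_used": self.n_starts_used,
            "n": self.n,
        }


class DegenerateFitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# EM machinery
# ---------------------------------------------------------------------------

def _estep(params: FMMParams, data: ItemData, z, w, cache=None):
    ld, eta = _log_density_cells(params, data, z, cache)
    lw = np.log(np.clip(params.pi, 1e-300, None))[:, None] + np.log(w)[None, :]
    joint = ld
    joint += lw[None, :, :]
    n, K, Q = joint.shape
    flat = joint.reshape(n, K * Q)
    m = flat.max(axis=1)
    W = np.exp(flat - m[:, None])
    s = W.sum(axis=1)
    W /= s[:, None]
    ll = float((m + np.log(s)).sum())
    return ll, W.reshape(n, K, Q), eta


def _censored_truncation_moments(mu, sd, floor):
    """Mean / variance of Normal(mu, sd^2) truncated to (-inf, floor]."""
    beta = (floor - mu) / sd
    # phi(beta) / Phi(beta), computed stably
    h = np.exp(-0.5 * beta * beta - 0.5 * _LOG2PI
               - np.clip(log_ndtr(beta), -700, None))
    m1 = mu - sd * h
    var = sd**2 * np.clip(1.0 - beta * h - h * h, 1e-12, None)
    return m1, var


def _mstep(params: FMMParams, data: ItemData, spec: FMMSpec, W, eta, z,
           theta_floor, psi_floor, cache=None):
    """Closed-form conditional-maximization updates for every free block."""
    if cache is None:
        cache = _design_cache(data)
    n, C = data.y.shape
    K, Q = eta.shape
    new = params.copy()

    # per-(i, k) node reductions, one GEMM per class:
    # columns of F_k are [1, eta_k, eta_k^2, z, z^2]
    G = np.empty((n, K, 5))
    for k in range(K):
        Fk = np.empty((Q, 5))
        Fk[:, 0] = 1.0
        Fk[:, 1] = eta[k]
        Fk[:, 2] = eta[k] * eta[k]
        Fk[:, 3] = z
        Fk[:, 4] = z * z
        G[:, k, :] = W[:, k, :] @ Fk
    U, V, V2, Vz, Vz2 = (G[:, :, j] for j in range(5))

    # sufficient statistics per (k, c) over observed-uncensored cells,
    # fused into one GEMM: X3 = [Mf | My | Myy], R = [U | V | V2]
    Mf, My = cache["Mf"], cache["My"]
    R = G[:, :, :3].transpose(0, 2, 1).reshape(n, 3 * K)
    S = cache["X3"].T @ R                  # (3C, 3K)
    Sw = S[0:C, 0:K].T
    Sx = S[0:C, K:2 * K].T
    Sxx = S[0:C, 2 * K:3 * K].T
    Sy = S[C:2 * C, 0:K].T
    Sxy = S[C:2 * C, K:2 * K].T
    Syy = S[2 * C:3 * C, 0:K].T
    Scorr = np.zeros((K, C))

    # censored cells: expected value / variance of the latent response
    cens_cells = {}
    if data.cens.any():
        sd_k = np.sqrt(params.theta)                     # (K, C)
        mu_cells = (params.intercepts[:, None, :]
                    + params.loadings[:, None, :] * eta[:, :, None])
        for c in np.flatnonzero(data.cens.any(axis=0)):
            rows = np.flatnonzero(data.cens[:, c])
            m1, var = _censored_truncation_moments(
                mu_cells[:, :, c], sd_k[:, c][:, None], data.floor
            )                                            # (K, Q) each
            Wc = W[rows]                                 # (nc, K, Q)
            cens_cells[c] = (rows, m1, var, Wc)
            Sw[:, c] += Wc.sum(axis=(0, 2))
            Sx[:, c] += np.einsum("ikq,kq->k", Wc, eta)
            Sxx[:, c] += np.einsum("ikq,kq->k", Wc, eta * eta)
            Sy[:, c] += np.einsum("ikq,kq->k", Wc, m1)
            Sxy[:, c] += np.einsum("ikq,kq->k", Wc, m1 * eta)
            Syy[:, c] += np.einsum("ikq,kq->k", Wc, m1 * m1)
            Scorr[:, c] += np.einsum("ikq,kq->k", Wc, var)

    eps = 1e-12
    # pooled updates across classes must weight each class's statistics by
    # its current inverse residual variance (classes may have unequal theta)
    A = 1.0 / params.theta  # (K, C)

    # -- CM-1: intercepts and loadings ---------------------------------
    for c in range(C):
        a = A[:, c]
        anchor = spec.has_factor and c == 0
        if not spec.has_factor:
            if spec.intercepts_vary:
                new.intercepts[:, c] = Sy[:, c] / np.maximum(Sw[:, c], eps)
            else:
                new.intercepts[:, c] = (a @ Sy[:, c]) / max(a @ Sw[:, c], eps)
            new.loadings[:, c] = 0.0
            continue
        if anchor:
            new.loadings[:, c] = 1.0
            if spec.intercepts_vary:
                new.intercepts[:, c] = (Sy[:, c] - Sx[:, c]) / np.maximum(Sw[:, c], eps)
            else:
                new.intercepts[:, c] = (a @ (Sy[:, c] - Sx[:, c])) / max(
                    a @ Sw[:, c], eps
                )
            continue
        if spec.intercepts_vary and spec.loadings_vary:
            for k in range(K):
                sw, sx, sxx = Sw[k, c], Sx[k, c], Sxx[k, c]
                sy, sxy = Sy[k, c], Sxy[k, c]
                det = sw * sxx - sx * sx
                if det > eps:
                    new.intercepts[k, c] = (sxx * sy - sx * sxy) / det
                    new.loadings[k, c] = (sw * sxy - sx * sy) / det
        elif spec.intercepts_vary:
            num = a @ (Sxy[:, c] - Sx[:, c] * Sy[:, c] / np.maximum(Sw[:, c], eps))
            den = a @ (Sxx[:, c] - Sx[:, c] ** 2 / np.maximum(Sw[:, c], eps))
            lam = num / den if den > eps else new.loadings[0, c]
            new.loadings[:, c] = lam
            new.intercepts[:, c] = (Sy[:, c] - lam * Sx[:, c]) / np.maximum(Sw[:, c], eps)
        else:
            sw, sx, sxx = a @ Sw[:, c], a @ Sx[:, c], a @ Sxx[:, c]
            sy, sxy = a @ Sy[:, c], a @ Sxy[:, c]
            det = sw * sxx - sx * sx
            if det > eps:
                new.intercepts[:, c] = (sxx * sy - sx * sxy) / det
                new.loadings[:, c] = (sw * sxy - sx * sy) / det

    # -- residual variances --------------------------------------------
    I, L = new.intercepts, new.loadings
    rss = (
        Syy - 2.0 * (I * Sy + L * Sxy) + I * I * Sw
        + 2.0 * I * L * Sx + L * L * Sxx + Scorr
    )
    if spec.residuals_vary:
        new.theta = np.maximum(rss / np.maximum(Sw, eps), theta_floor[None, :])
    else:
        pooled = rss.sum(axis=0) / np.maximum(Sw.sum(axis=0), eps)
        new.theta = np.tile(np.maximum(pooled, theta_floor), (K, 1))

    # -- occurrence item ------------------------------------------------
    if new.occ_logit is not None and data.occurrence is not None:
        # occurrence thresholds are class-specific in every family
        occ = cache["occ"]
        num = occ @ U
        den = U.sum(axis=0)
        p = np.clip(num / np.maximum(den, eps), 1e-6, 1.0 - 1e-6)
        new.occ_logit = np.log(p / (1.0 - p))

    # -- CM-2: factor means and variances -------------------------------
    if spec.has_factor:
        lam_t = new.loadings / new.theta                     # (K, C)
        lam2_t = new.loadings * lam_t
        g = Mf @ lam2_t.T                                    # (n, K)
        resid = My @ lam_t.T - Mf @ (lam_t * new.intercepts).T
        a0 = np.einsum("ik,ik->k", g, U)
        a1 = np.einsum("ik,ik->k", g, Vz)
        a2 = np.einsum("ik,ik->k", g, Vz2)
        b0 = np.einsum("ik,ik->k", resid, U)
        b1 = np.einsum("ik,ik->k", resid, Vz)
        for c, (rows, m1, var, Wc) in cens_cells.items():
            lt = lam_t[:, c]
            l2 = lam2_t[:, c]
            r_kq = m1 * lt[:, None] - (lt * new.intercepts[:, c])[:, None]
            a0 += l2 * Wc.sum(axis=(0, 2))
            a1 += l2 * np.einsum("ikq,q->k", Wc, z)
            a2 += l2 * np.einsum("ikq,q->k", Wc, z * z)
            b0 += np.einsum("ikq,kq->k", Wc, r_kq)
            b1 += np.einsum("ikq,kq->k", Wc, r_kq * z[None, :])

        alpha_free = np.zeros(K, dtype=bool)
        if spec.n_free_factor_means:
            alpha_free[: spec.n_free_factor_means] = True

        if spec.factor_variance_vary:
            s = np.zeros(K)
            for k in range(K):
                if alpha_free[k]:
                    det = a0[k] * a2[k] - a1[k] ** 2
                    if det > eps:
                        new.alpha[k] = (a2[k] * b0[k] - a1[k] * b1[k]) / det
                        s[k] = (a0[k] * b1[k] - a1[k] * b0[k]) / det
                else:
                    new.alpha[k] = 0.0
                    s[k] = b1[k] / a2[k] if a2[k] > eps else np.sqrt(params.psi[k])
            new.psi = np.maximum(s * s, psi_floor)
        else:
            num = den = 0.0
            for k in range(K):
                if alpha_free[k] and a0[k] > eps:
                    num += b1[k] - a1[k] * b0[k] / a0[k]
                    den += a2[k] - a1[k] ** 2 / a0[k]
                else:
                    num += b1[k]
                    den += a2[k]
            s = num / den if den > eps else np.sqrt(params.psi[0])
            for k in range(K):
                if alpha_free[k] and a0[k] > eps:
                    new.alpha[k] = (b0[k] - s * a1[k]) / a0[k]
                else:
                    new.alpha[k] = 0.0
            new.psi = np.full(K, max(s * s, psi_floor))
    else:
        new.alpha[:] = 0.0
        new.psi[:] = 0.0

    # -- mixing ----------------------------------------------------------
    pi = U.sum(axis=0) / n
    new.pi = np.clip(pi, 1e-10, None)
    new.pi /= new.pi.sum()
    return new


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def _kmeans(X: np.ndarray, K: int, rng, n_iter: int = 15) -> np.ndarray:
    n = X.shape[0]
    # distance-weighted (k-means++-style) seeding
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    for k in range(1, K):
        d2 = np.min(
            ((X[:, None, :] - centers[None, :k, :]) ** 2).sum(axis=2), axis=1
        )
        tot = d2.sum()
        if tot <= 0:
            centers[k] = X[rng.integers(n)]
        else:
            centers[k] = X[rng.choice(n, p=d2 / tot)]
    lab = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = d.argmin(axis=1)
        for k in range(K):
            if np.any(lab == k):
                centers[k] = X[lab == k].mean(axis=0)
            else:
                centers[k] = X[rng.integers(n)]
    return lab


def _filled_matrix(data: ItemData) -> np.ndarray:
    X = data.y.copy()
    X[data.cens] = data.floor
    col_mean = np.nanmean(np.where(data.obs | data.cens, X, np.nan), axis=0)
    bad = ~(data.obs | data.cens)
    X[bad] = np.take(col_mean, np.where(bad)[1])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    # cluster on well-observed columns; a mostly-missing magnitude column
    # carries no distance information, the occurrence indicator does
    keep = (data.obs | data.cens).mean(axis=0) >= 0.6
    feats = Xs[:, keep]
    if data.occurrence is not None:
        occ = data.occurrence.astype(float)
        s = occ.std() or 1.0
        feats = np.column_stack([feats, (occ - occ.mean()) / s])
    return feats, X


def _initial_params(data: ItemData, spec: FMMSpec, rng, jitter: float) -> FMMParams:
    Xs, X = _filled_matrix(data)
    n, C = X.shape
    K = spec.K
    lab = (_kmeans(Xs, K, rng) if K > 1 else np.zeros(n, dtype=int))
    if jitter > 0:
        flip = rng.random(n) < jitter
        lab = np.where(flip, rng.integers(0, K, size=n), lab)

    counts = np.array([(lab == k).sum() for k in range(K)], dtype=float)
    counts = np.maximum(counts, 1.0)
    pi = counts / counts.sum()
    Mk = np.stack([
        X[lab == k].mean(axis=0) if np.any(lab == k) else X.mean(axis=0)
        for k in range(K)
    ])
    # order classes by the anchor item so the identification constraints
    # (last-class factor mean = 0) start from the robust end
    order = np.argsort(Mk[:, 0])
    Mk, pi = Mk[order], pi[order]
    lab = np.argsort(order)[lab]
    Vk = np.stack([
        X[lab == k].var(axis=0) + 1e-3 if (lab == k).sum() > 1 else X.var(axis=0)
        for k in range(K)
    ])

    intercepts = Mk.copy()
    loadings = np.zeros((K, C))
    alpha = np.zeros(K)
    psi = np.zeros(K)
    theta = Vk.copy()
    if spec.has_factor:
        # anchor-scaled loadings from pooled within-class covariance
        resid = X - Mk[lab]
        Cw = np.cov(resid.T) + 1e-6 * np.eye(C)
        lam = Cw[:, 0] / Cw[0, 0]
        lam[0] = 1.0
        loadings = np.tile(lam, (K, 1))
        psi_val = max(Cw[0, 0] * 0.5, 1e-3)
        psi = np.full(K, psi_val)
        theta = np.maximum(Vk - np.outer(np.ones(K), lam**2 * psi_val), 0.1 * Vk)
        if spec.n_free_factor_means:
            # classes differ through the factor mean (anchor loading = 1)
            alpha = Mk[:, 0] - Mk[-1, 0]
            alpha[-1] = 0.0
            intercepts = np.tile(Mk[-1], (K, 1))
        else:
            alpha = np.zeros(K)
            intercepts = Mk - loadings * alpha[:, None]
    if not spec.intercepts_vary:
        if spec.n_free_factor_means == 0:
            intercepts = np.tile(X.mean(axis=0), (K, 1))
    if not spec.residuals_vary:
        theta = np.tile(theta.mean(axis=0), (K, 1))

    occ_logit = None
    if data.occurrence is not None:
        rate = np.zeros(K)
        for k in range(K):
            sel = lab == k
            rate[k] = data.occurrence[sel].mean() if sel.any() else data.occurrence.mean()
        rate = np.clip(rate, 0.01, 0.99)
        occ_logit = np.log(rate / (1 - rate))

    return FMMParams(
        pi=pi, intercepts=intercepts, loadings=loadings, theta=np.maximum(theta, 1e-4),
        alpha=alpha, psi=psi, occ_logit=occ_logit, floor=data.floor,
        item_models=spec.item_models,
    )


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def split_class_params(params: FMMParams, jitter: float = 0.7) -> FMMParams:
    """Warm start for a (K+1)-class fit: split the largest class in two.

    The duplicated class is pushed apart along the factor (when present) or
    along the item intercepts, and the mixing mass is halved.  Used to seed
    incremental class-count searches from the previous solution.
    """
    k = int(np.argmax(params.pi))
    ins = lambda arr: np.insert(arr, k + 1, arr[k], axis=0)  # noqa: E731
    out = FMMParams(
        pi=ins(params.pi), intercepts=ins(params.intercepts),
        loadings=ins(params.loadings), theta=ins(params.theta),
        alpha=ins(params.alpha), psi=ins(params.psi),
        occ_logit=None if params.occ_logit is None else ins(params.occ_logit),
        floor=params.floor, item_models=params.item_models,
    )
    out.pi[[k, k + 1]] = params.pi[k] / 2.0
    if params.has_factor and params.psi[k] > 0:
        # push along the factor; constraint projection at fit time absorbs
        # this into intercepts for templates with fixed factor means
        delta = jitter * np.sqrt(params.psi[k])
        out.alpha[k] -= delta
        out.alpha[k + 1] += delta
    else:
        shift = jitter * np.sqrt(params.theta[k])
        out.intercepts[k] -= 0.5 * shift
        out.intercepts[k + 1] += 0.5 * shift
    return out


def _prepare_init(params: FMMParams, spec: FMMSpec) -> FMMParams:
    """Project a warm start into the spec's constraint set.

    Canonical (frail-anchored) or foreign-family parameters need not satisfy
    the identification the EM iterates under (last-class factor mean zero,
    pooled invariant blocks); starting outside the feasible set would make
    the first M-step a non-monotone jump.
    """
    out = params.copy()
    K = out.K
    if K != spec.K:
        raise ValueError(f"warm start has K={K}, spec requires K={spec.K}")
    if spec.has_factor:
        if spec.n_free_factor_means > 0:
            shift = out.alpha[-1]
            if shift != 0.0:
                out.alpha = out.alpha - shift
                out.intercepts = out.intercepts + out.loadings * shift
        else:
            out.intercepts = out.intercepts + out.loadings * out.alpha[:, None]
            out.alpha = np.zeros(K)
        if np.all(out.psi <= 0):
            out.psi = np.full(K, 1.0)
        if not spec.factor_variance_vary:
            out.psi = np.full(K, float(out.psi.mean()))
        if not spec.loadings_vary:
            pooled = out.loadings.mean(axis=0)
            out.loadings = np.tile(pooled, (K, 1))
        out.loadings[:, 0] = 1.0
    else:
        out.intercepts = out.intercepts + out.loadings * out.alpha[:, None]
        out.loadings = np.zeros_like(out.loadings)
        out.alpha = np.zeros(K)
        out.psi = np.zeros(K)
    if not spec.intercepts_vary:
        out.intercepts = np.tile(out.intercepts.mean(axis=0), (K, 1))
    if not spec.residuals_vary:
        out.theta = np.tile(out.theta.mean(axis=0), (K, 1))
    out.pi = np.clip(out.pi, 1e-6, None)
    out.pi = out.pi / out.pi.sum()
    return out


def _guard_extrapolated(x, template, spec, theta_floor, psi_floor):
    """Unpack an extrapolated free vector, clipping variance and mixing
    cells back into the feasible region."""
    p = unpack_free_parameters(x, template, spec)
    p.theta = np.maximum(p.theta, theta_floor[None, :])
    if spec.has_factor:
        p.psi = np.maximum(p.psi, psi_floor)
    p.pi = np.clip(p.pi, 1e-10, None)
    p.pi = p.pi / p.pi.sum()
    return p


def _em_run(params, data, spec, z, w, cache, theta_floor, psi_floor,
            max_iter, tol):
    """One EM run with safeguarded SQUAREM-style extrapolation.

    Every cycle takes two EM steps; the secant extrapolation through them is
    accepted only when it improves the objective, so the recorded
    log-likelihood trace stays monotone while flat-ridge convergence speeds
    up several-fold.
    """
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    stepmax = 4.0  # SQUAREM step-length bound, grown on accepted jumps
    while it < max_iter:
        ll0, W, eta = _estep(params, data, z, w, cache)
        trace.append(ll0)
        it += 1
        if np.isfinite(ll_prev) and abs(ll0 - ll_prev) < tol:
            converged = True
            break
        p1 = _mstep(params, data, spec, W, eta, z, theta_floor, psi_floor, cache)
        ll1, W1, eta1 = _estep(p1, data, z, w, cache)
        trace.append(ll1)
        it += 1
        if abs(ll1 - ll0) < tol:
            params, ll_prev = p1, ll0
            converged = True
            break
        p2 = _mstep(p1, data, spec, W1, eta1, z, theta_floor, psi_floor, cache)

        accepted = False
        if abs(ll1 - ll0) > 50.0 * tol:  # extrapolate only on slow stretches
            x0 = pack_free_parameters(params, spec)
            x1 = pack_free_parameters(p1, spec)
            x2 = pack_free_parameters(p2, spec)
            r = x1 - x0
            v = (x2 - x1) - r
            vn = float(np.linalg.norm(v))
        else:
            vn = 0.0
        if vn > 1e-12:
            alpha = max(1.0, min(float(np.linalg.norm(r)) / vn, stepmax))
            xs = x0 + 2.0 * alpha * r + alpha * alpha * v
            cand = _guard_extrapolated(xs, params, spec, theta_floor, psi_floor)
            with np.errstate(over="ignore", invalid="ignore"):
                ll_c, Wc, etac = _estep(cand, data, z, w, cache)
            if np.isfinite(ll_c) and ll_c > ll1:
                # stabilization step keeps the iterate an EM fixed-point path
                params = _mstep(cand, data, spec, Wc, etac, z, theta_floor,
                                psi_floor, cache)
                trace.append(ll_c)
                it += 1
                accepted = True
                if alpha >= stepmax:
                    stepmax *= 4.0
            elif alpha >= stepmax and stepmax > 4.0:
                stepmax = max(stepmax / 4.0, 4.0)
        if not accepted:
            params = p2
        ll_prev = ll1 if not accepted else trace[-1]
    ll, W, eta = _estep(params, data, z, w, cache)
    trace.append(ll)
    return params, ll, np.asarray(trace), converged


def fit_fmm(
    items,
    spec: FMMSpec,
    n_starts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
    quadrature_points: int = 21,
    init_params: FMMParams | None = None,
    min_class_count: float = 5.0,
) -> FMMFit:
    """Maximize the (quadrature) likelihood under the spec's constraints.

    EM from ``n_starts`` perturbed k-means-style initializations (plus the
    optional warm start); the best non-degenerate run is retained.  A run
    whose smallest expected class count falls below ``min_class_count`` is
    discarded and flagged, mirroring stopped searches on degenerate
    solutions.  If every start degenerates the best run is returned with
    ``degenerate=True`` and ``converged=False``.
    """
    data = ItemData.from_any(items)
    n = data.n
    rng = np.random.default_rng(seed)
    z, w = _nodes(quadrature_points, spec.has_factor)
    cache = _design_cache(data)
    marg_var = np.nanvar(np.where(data.obs | data.cens, data.y, np.nan), axis=0)
    theta_floor = 1e-4 * np.maximum(marg_var, 1e-8)
    psi_floor = 1e-6

    best = None
    best_ll = -np.inf
    any_degenerate = False
    starts: list[FMMParams] = []
    if init_params is not None:
        starts.append(_prepare_init(init_params, spec))
    for s in range(n_starts):
        jitter = 0.0 if s == 0 else min(0.05 * s, 0.4)
        starts.append(_initial_params(data, spec, rng, jitter))

    start_lls = []
    for params in starts:
        params, ll, trace, converged = _em_run(
            params, data, spec, z, w, cache, theta_floor, psi_floor,
            max_iter, tol,
        )
        start_lls.append(ll)
        degenerate = bool(np.min(params.pi) * n < min_class_count)
        if degenerate:
            any_degenerate = True
            if best is not None:
                continue
        if ll > best_ll or best is None:
            best_ll = ll
            best = (params, ll, np.array(trace), converged, degenerate)

    params, ll, trace, converged, degenerate = best
    params = _canonicalize(params, spec)
    post = posterior_matrix(params, data, quadrature_points)
    ent = relative_entropy(post) if spec.K > 1 else float("nan")
    npar = count_parameters(spec)
    return FMMFit(
        spec=spec, params=params, loglik=ll, n_params=npar,
        bic=-2.0 * ll + npar * np.log(n), posteriors=post, entropy=ent,
        converged=converged and not degenerate, degenerate=degenerate,
        n_starts_used=len(starts), n=n,
        start_logliks=start_lls, loglik_trace=trace,
    )


def _canonicalize(params: FMMParams, spec: FMMSpec) -> FMMParams:
    """Sort classes frail-first on the model-implied anchor mean and restore
    the last-class-zero normalization of the factor means."""
    implied = params.intercepts[:, 0] + params.loadings[:, 0] * params.alpha
    order = np.argsort(implied)
    out = params.permute_classes(order)
    if spec.has_factor and spec.n_free_factor_means:
        # re-anchor the factor mean at zero in the frailest class, the
        # convention the generator and reported class tables use
        shift = out.alpha[0]
        if shift != 0.0:
            out.alpha = out.alpha - shift
            out.intercepts = out.intercepts + out.loadings * shift
    return out


def posterior_matrix(params: FMMParams, items, quadrature_points: int = 21) -> np.ndarray:
    """Class posterior probabilities (n, K) by Bayes' rule."""
    data = ItemData.from_any(items)
    z, w = _nodes(quadrature_points, params.has_factor)
    ld, _ = _log_density_cells(params, data, z)
    lw = np.log(np.clip(params.pi, 1e-300, None))[:, None] + np.log(w)[None, :]
    joint = logsumexp(ld + lw[None, :, :], axis=2)      # (n, K)
    return np.exp(joint - logsumexp(joint, axis=1)[:, None])


def posterior_probs(fit: FMMFit, items):
    """Posterior matrix plus modal assignment (lowest index wins ties)."""
    post = posterior_matrix(fit.params, items)
    return post, post.argmax(axis=1)


def relative_entropy(posteriors: np.ndarray) -> float:
    """1 - (total posterior Shannon entropy) / (n ln K); 1 = crisp classes."""
    n, K = posteriors.shape
    if K < 2:
        return float("nan")
    p = np.clip(posteriors, 1e-12, 1.0)
    H = float(-(p * np.log(p)).sum())
    return 1.0 - H / (n * np.log(K))


entropy = relative_entropy


# ---------------------------------------------------------------------------
# Simulation from a fitted / configured model
# ---------------------------------------------------------------------------

def simulate_items(params: FMMParams, n: int, rng) -> ItemData:
    """Draw an item matrix from the model (the parametric-bootstrap kernel)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    K, C = params.intercepts.shape
    cls = rng.choice(K, size=n, p=params.pi / params.pi.sum())
    if params.has_factor:
        eta = rng.normal(params.alpha[cls], np.sqrt(np.maximum(params.psi[cls], 0)))
    else:
        eta = np.zeros(n)
    y = (params.intercepts[cls] + params.loadings[cls] * eta[:, None]
         + rng.standard_normal((n, C)) * np.sqrt(params.theta[cls]))
    obs = np.ones((n, C), dtype=bool)
    cens = np.zeros((n, C), dtype=bool)
    occurrence = None
    for c, tag in enumerate(params.item_models):
        if tag == "censored-gaussian" and np.isfinite(params.floor):
            under = y[:, c] <= params.floor
            cens[:, c] = under
            obs[:, c] = ~under
            y[under, c] = params.floor
        elif tag == "two-part-magnitude":
            p = 1.0 / (1.0 + np.exp(-params.occ_logit[cls]))
            occurrence = (rng.random(n) < p).astype(int)
            obs[:, c] = occurrence == 1
    data = ItemData(y=y, obs=obs, cens=cens, occurrence=occurrence,
                    floor=params.floor)
    data.true_class = cls  # attached for recovery diagnostics
    return data


def mean_centered_classification_params(params: FMMParams):
    """Intercepts re-expressed at the population factor mean, with loadings.

    Class-invariant intercepts are identified only up to where the factor
    scale is anchored; anchoring at a small extreme class makes their
    estimates track that class's sampling noise.  Shifting the anchor to the
    mixture-weighted factor mean (I* = I + F * sum_k pi_k alpha_k) yields the
    parameterization in which intercepts equal marginal item locations and
    recovery is well-posed.  Returns (intercepts_star (K, C), loadings).
    """
    shift = float(np.sum(params.pi * params.alpha))
    return params.intercepts + params.loadings * shift, params.loadings


# ---------------------------------------------------------------------------
# Free-parameter vectorization (for numerical information matrices)
# ---------------------------------------------------------------------------

def free_parameter_cells(spec: FMMSpec, C: int | None = None) -> list[tuple]:
    """Ordered list of (block, k, c) describing every free scalar parameter.

    ``k`` is None for class-invariant blocks (stored replicated); ``c`` is
    None for per-class scalars.  Mixing contributes the first K - 1 cells.
    """
    if C is None:
        C = len(spec.item_models)
    n_cont = sum(m != "bernoulli" for m in spec.item_models)
    has_occ = any(m == "two-part-magnitude" for m in spec.item_models)
    K = spec.K
    cells: list[tuple] = []
    for k in range(K - 1):
        cells.append(("pi", k, None))
    kk = range(K) if spec.intercepts_vary else [None]
    for k in kk:
        for c in range(n_cont):
            cells.append(("intercepts", k, c))
    if spec.has_factor:
        lk = range(K) if spec.loadings_vary else [None]
        for k in lk:
            for c in range(1, n_cont):  # anchor c=0 fixed at 1
                cells.append(("loadings", k, c))
        for k in range(spec.n_free_factor_means):
            cells.append(("alpha", k, None))
        pk = range(K) if spec.factor_variance_vary else [None]
        for k in pk:
            cells.append(("psi", k, None))
    tk = range(K) if spec.residuals_vary else [None]
    for k in tk:
        for c in range(n_cont):
            cells.append(("theta", k, c))
    if has_occ:
        for k in range(K):  # class-specific in every family
            cells.append(("occ_logit", k, None))
    return cells


def pack_free_parameters(params: FMMParams, spec: FMMSpec) -> np.ndarray:
    cells = free_parameter_cells(spec)
    out = np.empty(len(cells))
    for j, (block, k, c) in enumerate(cells):
        arr = getattr(params, block)
        ki = 0 if k is None else k
        out[j] = arr[ki] if c is None else arr[ki, c]
    return out


def unpack_free_parameters(x: np.ndarray, template: FMMParams,
                           spec: FMMSpec) -> FMMParams:
    params = template.copy()
    cells = free_parameter_cells(spec)
    for j, (block, k, c) in enumerate(cells):
        arr = getattr(params, block)
        rows = range(params.K) if k is None else [k]
        for ki in rows:
            if c is None:
                arr[ki] = x[j]
            else:
                arr[ki, c] = x[j]
    params.pi = np.clip(params.pi, 1e-10, None)
    params.pi[-1] = max(1.0 - params.pi[:-1].sum(), 1e-10)
    return params


# ---------------------------------------------------------------------------
# Confirmatory factor dimension (step 2)
# ---------------------------------------------------------------------------

#: Two-set split suggested by class-specific intercept orderings: muscle
#: strength (gait, grip) versus an exhaustion cluster (vitality, activity,
#: weight loss).
TWO_FACTOR_SPLIT = ((0, 1, 4), (2, 3))


class _PatternStats:
    """Per-missing-pattern sufficient statistics for repeated MVN evaluation.

    Groups rows by their (observed, censored) pattern.  Groups without a
    censored cell contribute through (count, mean, scatter); censored groups
    keep their raw rows (they are few) for the conditional-tail factor.
    """

    def __init__(self, data: ItemData):
        self.floor = data.floor
        self.groups = []
        key = np.concatenate([data.obs, data.cens], axis=1)
        _, inverse = np.unique(key, axis=0, return_inverse=True)
        for g in np.unique(inverse):
            rows = np.flatnonzero(inverse == g)
            o = np.flatnonzero(data.obs[rows[0]])
            e = np.flatnonzero(data.cens[rows[0]])
            if len(e) > 1:
                raise NotImplementedError("at most one censored cell per row")
            Y = data.y[np.ix_(rows, o)]
            ng = len(rows)
            ybar = Y.mean(axis=0)
            S = (Y - ybar).T @ (Y - ybar) / ng
            self.groups.append({"o": o, "e": e, "n": ng, "ybar": ybar,
                                "S": S, "Y": Y if len(e) else None})

    def loglik(self, mean, Sigma) -> float:
        total = 0.0
        for grp in self.groups:
            o, e, ng = grp["o"], grp["e"], grp["n"]
            So = Sigma[np.ix_(o, o)]
            sign, logdet = np.linalg.slogdet(So)
            if sign <= 0:
                return -np.inf
            inv = np.linalg.inv(So)
            d = grp["ybar"] - mean[o]
            total += -0.5 * ng * (
                len(o) * _LOG2PI + logdet
                + np.trace(inv @ grp["S"]) + d @ inv @ d
            )
            if len(e) == 1:
                c = e[0]
                cov_co = Sigma[c, o]
                sol = inv @ cov_co
                mu_c = mean[c] + (grp["Y"] - mean[o]) @ sol
                var_c = Sigma[c, c] - cov_co @ sol
                total += log_ndtr((self.floor - mu_c) / np.sqrt(var_c)).sum()
        return float(total)


def _cfa_loglik(mu, Lam, theta, stats: _PatternStats) -> float:
    """K = 1 confirmatory factor log-likelihood, identity factor covariance."""
    Sigma = Lam @ Lam.T + np.diag(theta)
    return stats.loglik(mu, Sigma)


def _fit_cfa(data: ItemData, n_factors: int, seed: int = 0):
    """ML fit of a K = 1 exploratory-style factor model.

    One factor: 5 free loadings.  Two factors: 10 loadings minus one echelon
    zero (item 1 does not load on factor 2), factor covariance fixed to the
    identity; the second factor is initialized on the gait / grip pair.
    Returns (loglik, n_free_parameters).
    """
    from scipy.optimize import minimize

    C = data.C
    stats = _PatternStats(data)
    mu = np.array([
        data.y[data.obs[:, c] | data.cens[:, c], c].mean() for c in range(C)
    ])
    var = np.array([
        data.y[data.obs[:, c] | data.cens[:, c], c].var() + 1e-8 for c in range(C)
    ])

    def unpack(x):
        if n_factors == 1:
            Lam = x[:C].reshape(C, 1)
            th = np.exp(x[C:])
        else:
            Lam = np.zeros((C, 2))
            Lam[:, 0] = x[:C]
            free2 = [c for c in range(C) if c != 0]
            Lam[free2, 1] = x[C:C + C - 1]
            th = np.exp(x[C + C - 1:])
        return Lam, th

    def negll(x):
        Lam, th = unpack(x)
        return -_cfa_loglik(mu, Lam, th, stats)

    lam0 = np.sqrt(np.maximum(var * 0.5, 1e-6))
    if n_factors == 1:
        x0 = np.concatenate([lam0, np.log(var * 0.5)])
        n_free = C + C + C  # mu (profiled at sample means) not counted below
        n_load = C
    else:
        lam2 = np.zeros(C - 1)
        for j, c in enumerate([c for c in range(C) if c != 0]):
            if c in TWO_FACTOR_SPLIT[1]:
                lam2[j] = lam0[c] * 0.7
        x0 = np.concatenate([lam0 * 0.8, lam2, np.log(var * 0.5)])
        n_load = 2 * C - 1
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(2):
        xs = x0 if attempt == 0 else x0 * (1 + 0.2 * rng.standard_normal(x0.shape))
        res = minimize(negll, xs, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12})
        if best is None or res.fun < best.fun:
            best = res
    n_free = C + n_load + C  # means + loadings + residual variances
    return -float(best.fun), n_free


def compare_factor_dimension(items, seed: int = 0) -> dict:
    """Likelihood-ratio test of one versus two factors at K = 1.

    The two-factor alternative frees the loadings of the muscle-strength set
    (gait speed, grip strength) from the exhaustion / activity / weight-loss
    axis.  Returns the chi-square statistic, its parameter-count degrees of
    freedom, and the p-value; non-rejection supports a single dimension.
    """
    from scipy.stats import chi2 as chi2_dist

    data = ItemData.from_any(items)
    ll1, p1 = _fit_cfa(data, 1, seed)
    ll2, p2 = _fit_cfa(data, 2, seed)
    stat = max(0.0, -2.0 * (ll1 - ll2))
    df = p2 - p1
    return {"chi2": stat, "df": int(df), "p": float(chi2_dist.sf(stat, df))}
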