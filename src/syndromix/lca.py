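"""Latent class analysis of the five dichotomized frailty components.

A K-class mixture of independent Bernoulli indicators, estimated by EM over
the 32 response patterns (subjects are aggregated by pattern, so iteration
cost is independent of n).  Reports the maximized log-likelihood, BIC with
6K - 1 free parameters, per-subject posteriors, and the Pearson chi-square
goodness of fit over all 2^5 patterns with (2^5 - 1) - (6K - 1) degrees of
freedom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2 as chi2_dist

#: Lower bound on class-conditional response probabilities; keeps log(0) off
#: the boundary (a mild deviation from unconstrained ML, documented).
PROB_FLOOR = 1e-6


@dataclass
class BinaryLCAFit:
    K: int
    mixing: np.ndarray          # (K,)
    response_probs: np.ndarray  # (K, 5) P(deficit | class)
    loglik: float
    n_params: int
    bic: float
    posteriors: np.ndarray      # (n, K)
    converged: bool
    n_starts_used: int
    n: int
    columns: tuple = ()
    observed_pattern_counts: np.ndarray | None = None  # (2^J,) for GOF

    @property
    def thresholds(self) -> np.ndarray:
        """Class thresholds on the logit scale, -logit(P)."""
        p = np.clip(self.response_probs, 1e-12, 1 - 1e-12)
        return -np.log(p / (1 - p))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "mixing": self.mixing.tolist(),
            "response_probs": self.response_probs.tolist(),
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "columns": list(self.columns),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_matrix(binary) -> tuple[np.ndarray, tuple]:
    if isinstance(binary, pd.DataFrame):
        return binary.to_numpy().astype(int), tuple(binary.columns)
    arr = np.asarray(binary, dtype=int)
    return arr, tuple(f"item{j}" for j in range(arr.shape[1]))


def _pattern_stats(X: np.ndarray):
    """Unique response patterns, counts, and the per-subject pattern index."""
    patterns, inverse, counts = np.unique(
        X, axis=0, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), inverse


def _pattern_logdens(patterns: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """log P(pattern | class) -> (n_patterns, K)."""
    lp = np.log(probs)
    lq = np.log1p(-probs)
    return patterns @ lp.T + (1 - patterns) @ lq.T


def loglik_brute_force(X: np.ndarray, mixing, probs) -> float:
    """Independent oracle: per-subject sum over classes, no aggregation."""
    X = np.asarray(X, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    probs = np.asarray(probs, dtype=float)
    total = 0.0
    for row in X:
        acc = 0.0
        for k in range(len(mixing)):
            lik = mixing[k]
            for j, x in enumerate(row):
                lik *= probs[k, j] if x == 1 else 1.0 - probs[k, j]
            acc += lik
        total += np.log(acc)
    return total


def fit_binary_lca(
    binary,
    K: int,
    n_starts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-7,
) -> BinaryLCAFit:
    """EM fit of the K-class Bernoulli mixture; best of ``n_starts`` kept.

    Classes are sorted by mean deficit prevalence (healthy first) so that
    reported tables are deterministic under label switching.  Non-convergence
    in every start yields a flagged fit, not an exception.
    """
    X, columns = _as_matrix(binary)
    n, J = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n < 10 * K:
        raise ValueError(f"need n >= 10 K subjects (n={n}, K={K})")
    patterns, counts, inverse = _pattern_stats(X)
    rng = np.random.default_rng(seed)

    best_ll, best, converged_any = -np.inf, None, False
    n_runs = 1 if K == 1 else n_starts
    for _ in range(n_runs):
        if K == 1:
            probs = X.mean(axis=0, keepdims=True)
            mixing = np.ones(1)
        else:
            probs = rng.uniform(0.1, 0.9, size=(K, J))
            mixing = rng.dirichlet(np.ones(K) * 5.0)
        probs = np.clip(probs, PROB_FLOOR, 1 - PROB_FLOOR)
        ll_prev, converged = -np.inf, False
        for _ in range(max_iter):
            ld = _pattern_logdens(patterns, probs) + np.log(mixing)[None, :]
            ll_pat = logsumexp(ld, axis=1)
            ll = float(counts @ ll_pat)
            R = np.exp(ld - ll_pat[:, None]) * counts[:, None]  # (P, K)
            Nk = R.sum(axis=0)
            mixing = Nk / Nk.sum()
            probs = (R.T @ patterns) / np.maximum(Nk[:, None], 1e-300)
            probs = np.clip(probs, PROB_FLOOR, 1 - PROB_FLOOR)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        ld = _pattern_logdens(patterns, probs) + np.log(mixing)[None, :]
        ll = float(counts @ logsumexp(ld, axis=1))
        converged_any |= converged
        if ll > best_ll:
            best_ll, best = ll, (mixing, probs, converged)

    mixing, probs, converged = best
    order = np.argsort(probs.mean(axis=1))
    mixing, probs = mixing[order], probs[order]
    ld = _pattern_logdens(patterns, probs) + np.log(mixing)[None, :]
    post_pat = np.exp(ld - logsumexp(ld, axis=1)[:, None])
    posteriors = post_pat[inverse]
    n_params = (J + 1) * K - 1
    idx = X @ (1 << np.arange(J - 1, -1, -1))
    observed = np.bincount(idx, minlength=2 ** J).astype(float)
    return BinaryLCAFit(
        K=K, mixing=mixing, response_probs=probs, loglik=best_ll,
        n_params=n_params, bic=-2.0 * best_ll + n_params * np.log(n),
        posteriors=posteriors, converged=converged, n_starts_used=n_runs,
        n=n, columns=columns, observed_pattern_counts=observed,
    )


def lca_goodness_of_fit(fit: BinaryLCAFit) -> dict:
    """Pearson chi-square over the 2^J response patterns.

    df = (2^J - 1) - n_params.  A pattern with zero expected count but a
    positive observed count yields an infinite statistic, reported as such.
    """
    J = fit.response_probs.shape[1]
    all_patterns = np.array(
        [[(i >> j) & 1 for j in range(J - 1, -1, -1)] for i in range(2 ** J)],
        dtype=float,
    )
    ld = _pattern_logdens(all_patterns, fit.response_probs) \
        + np.log(fit.mixing)[None, :]
    p_model = np.exp(logsumexp(ld, axis=1))
    expected = fit.n * p_model

    observed = fit.observed_pattern_counts
    if observed is None:
        raise ValueError("fit lacks observed pattern counts")
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (observed - expected) ** 2 / expected
    contrib = np.where(expected == 0, np.where(observed > 0, np.inf, 0.0), contrib)
    chi2 = float(np.sum(contrib))
    df = (2 ** J - 1) - fit.n_params
    p = float(chi2_dist.sf(chi2, df)) if np.isfinite(chi2) else 0.0
    return {"chi2": chi2, "df": int(df), "p": p}


def class_prevalence_profile(fit: BinaryLCAFit) -> pd.DataFrame:
    """Per-class component deficit prevalences, classes sorted healthy-first
    by mean prevalence (the fit already stores them in that order)."""
    df = pd.DataFrame(
        fit.response_probs,
        columns=list(fit.columns) or None,
        index=[f"class_{k + 1}" for k in range(fit.K)],
    )
    df["mean_prevalence"] = fit.response_probs.mean(axis=1)
    df["mixing"] = fit.mixing
    return df


def simulate_binary(mixing, probs, n: int, rng) -> np.ndarray:
    """Draw an n x J binary matrix from a Bernoulli-mixture parameter set."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    mixing = np.asarray(mixing, dtype=float)
    probs = np.asarray(probs, dtype=float)
    cls = rng.choice(len(mixing), size=n, p=mixing / mixing.sum())
    return (rng.random((n, probs.shape[1])) < probs[cls]).astype(int)
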