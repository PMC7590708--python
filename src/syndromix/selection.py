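"""Model comparison: BIC differences, the bootstrap likelihood-ratio test,
and Monte-Carlo acceptability diagnostics.

The BLRT follows the parametric-bootstrap recipe: fit null and alternative
to the observed data, simulate B datasets from the fitted null, refit both
models to each replicate, and report p = (1 + #{LRT_b >= LRT_obs}) / (B + 1).
Replicates that fail to converge are dropped and counted; a result losing
more than 20% of its replicates is flagged unreliable.

Monte-Carlo diagnostics follow the standard simulation-acceptability recipe:
R datasets are simulated at the fitted (or hypothesized) parameter values and
refit; parameter bias, standard-error bias (model-based SE against the
replication SD), 95% coverage and power against a zero null are tabulated
per free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lca as _lca
from .family import FMMSpec, is_nested, NULL_CATEGORICAL, NON_NULL
from .fmm import (
    FMMFit,
    FMMParams,
    ItemData,
    fit_fmm,
    free_parameter_cells,
    loglikelihood,
    pack_free_parameters,
    simulate_items,
    unpack_free_parameters,
)


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------

def bic_difference(fit_a, fit_b) -> float:
    """BIC(a) - BIC(b); negative favours model a.  Requires the same n."""
    if fit_a.n != fit_b.n:
        raise ValueError(
            f"fits are on different sample sizes ({fit_a.n} vs {fit_b.n})"
        )
    return float(fit_a.bic - fit_b.bic)


# ---------------------------------------------------------------------------
# Bootstrap likelihood-ratio test
# ---------------------------------------------------------------------------

@dataclass
class BLRTResult:
    lrt_observed: float
    B: int
    bootstrap_lrts: np.ndarray
    p_value: float
    n_failed_replicates: int
    seed: int
    unreliable: bool = False
    early_stopped: bool = False
    fit_null: FMMFit | None = None
    fit_alt: FMMFit | None = None

    def to_dict(self) -> dict:
        return {
            "lrt_observed": self.lrt_observed,
            "B": self.B,
            "p_value": self.p_value,
            "n_failed_replicates": self.n_failed_replicates,
            "unreliable": self.unreliable,
            "early_stopped": self.early_stopped,
            "seed": self.seed,
        }


def _blrt_core(
    lrt_obs: float,
    simulate,
    refit_pair,
    B: int,
    seed: int,
    alpha_stop: float | None,
) -> tuple[np.ndarray, int, bool]:
    """Shared bootstrap loop.

    With ``alpha_stop`` set, the loop stops as soon as the number of
    bootstrap statistics at or above the observed one guarantees
    p > alpha_stop; the rejection decision at that level is unchanged, only
    the tail of the null distribution goes unexplored.
    """
    rng = np.random.default_rng(seed)
    lrts = []
    failed = 0
    stop_at = None
    if alpha_stop is not None:
        stop_at = int(np.floor(alpha_stop * (B + 1)))  # exceedances that kill rejection
    exceed = 0
    early = False
    max_attempts = B + max(5, B // 4)  # top up a few failed replicates
    attempts = 0
    while len(lrts) < B and attempts < max_attempts:
        attempts += 1
        data_b = simulate(rng)
        val = refit_pair(data_b, rng)
        if val is None:
            failed += 1
            continue
        lrts.append(val)
        if val >= lrt_obs:
            exceed += 1
            if stop_at is not None and exceed >= stop_at:
                early = True
                break
    return np.asarray(lrts), failed, early


def _finish_blrt(lrt_obs, lrts, failed, early, B, seed, fit_null, fit_alt):
    n_used = len(lrts)
    p = (1 + int(np.sum(lrts >= lrt_obs))) / (n_used + 1)
    unreliable = failed > 0.2 * B
    return BLRTResult(
        lrt_observed=lrt_obs, B=B, bootstrap_lrts=lrts, p_value=float(p),
        n_failed_replicates=failed, seed=seed, unreliable=unreliable,
        early_stopped=early, fit_null=fit_null, fit_alt=fit_alt,
    )


def blrt(
    items,
    spec_alt: FMMSpec,
    spec_null: FMMSpec,
    B: int = 1000,
    n_starts: int = 10,
    seed: int = 0,
    fit_null: FMMFit | None = None,
    fit_alt: FMMFit | None = None,
    obs_n_starts: int = 50,
    max_iter: int = 500,
    replicate_max_iter: int = 150,
    replicate_tol: float = 1e-6,
    quadrature_points: int = 21,
    alpha_stop: float | None = None,
) -> BLRTResult:
    """Bootstrap likelihood-ratio test of ``spec_null`` against ``spec_alt``.

    Pre-computed observed fits can be passed in; otherwise both models are
    fit with ``obs_n_starts`` starts.  Replicates are fit with ``n_starts``
    random starts plus a warm start at the generating (null) parameters, a
    documented tractability reduction relative to the observed fits.
    """
    if not is_nested(spec_null, spec_alt):
        raise ValueError(
            f"{spec_null.label} is not nested in {spec_alt.label}"
        )
    data = ItemData.from_any(items)
    n = data.n
    if fit_null is None:
        fit_null = fit_fmm(data, spec_null, n_starts=obs_n_starts, seed=seed,
                           max_iter=max_iter, quadrature_points=quadrature_points)
    if fit_alt is None:
        fit_alt = fit_fmm(data, spec_alt, n_starts=obs_n_starts, seed=seed + 1,
                          max_iter=max_iter, quadrature_points=quadrature_points)
    lrt_obs = max(0.0, -2.0 * (fit_null.loglik - fit_alt.loglik))

    null_params = fit_null.params
    alt_params = fit_alt.params

    def simulate(rng):
        return simulate_items(null_params, n, rng)

    def refit_pair(data_b, rng):
        s = int(rng.integers(2**31 - 1))
        fn = fit_fmm(data_b, spec_null, n_starts=max(n_starts - 1, 0), seed=s,
                     max_iter=replicate_max_iter, tol=replicate_tol,
                     quadrature_points=quadrature_points,
                     init_params=null_params)
        fa = fit_fmm(data_b, spec_alt, n_starts=max(n_starts - 1, 0), seed=s + 1,
                     max_iter=replicate_max_iter, tol=replicate_tol,
                     quadrature_points=quadrature_points,
                     init_params=alt_params)
        # degenerate-flagged fits still carry their best likelihood (the
        # observed fits are treated identically), so only numerical failures
        # drop a replicate
        if not (np.isfinite(fn.loglik) and np.isfinite(fa.loglik)):
            return None
        return max(0.0, -2.0 * (fn.loglik - fa.loglik))

    lrts, failed, early = _blrt_core(lrt_obs, simulate, refit_pair, B, seed,
                                     alpha_stop)
    return _finish_blrt(lrt_obs, lrts, failed, early, B, seed, fit_null, fit_alt)


def blrt_binary_lca(
    binary,
    K_alt: int,
    K_null: int,
    B: int = 1000,
    n_starts: int = 10,
    seed: int = 0,
    obs_n_starts: int = 50,
    alpha_stop: float | None = None,
) -> BLRTResult:
    """Bootstrap likelihood-ratio test for the class count of a binary LCA."""
    if K_null >= K_alt:
        raise ValueError("the null class count must be smaller")
    X, _ = _lca._as_matrix(binary)
    n = X.shape[0]
    fit_null = _lca.fit_binary_lca(X, K_null, n_starts=obs_n_starts, seed=seed)
    fit_alt = _lca.fit_binary_lca(X, K_alt, n_starts=obs_n_starts, seed=seed + 1)
    lrt_obs = max(0.0, -2.0 * (fit_null.loglik - fit_alt.loglik))

    def simulate(rng):
        return _lca.simulate_binary(fit_null.mixing, fit_null.response_probs, n, rng)

    def refit_pair(Xb, rng):
        s = int(rng.integers(2**31 - 1))
        fn = _lca.fit_binary_lca(Xb, K_null, n_starts=n_starts, seed=s)
        fa = _lca.fit_binary_lca(Xb, K_alt, n_starts=n_starts, seed=s + 1)
        return max(0.0, -2.0 * (fn.loglik - fa.loglik))

    lrts, failed, early = _blrt_core(lrt_obs, simulate, refit_pair, B, seed,
                                     alpha_stop)
    res = _finish_blrt(lrt_obs, lrts, failed, early, B, seed, None, None)
    res.fit_null, res.fit_alt = fit_null, fit_alt
    return res


# ---------------------------------------------------------------------------
# Standard errors via numerically differentiated observed information
# ---------------------------------------------------------------------------

def observed_information_se(
    params: FMMParams,
    spec: FMMSpec,
    items,
    quadrature_points: int = 21,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Model-based SEs from the central-difference Hessian of the
    log-likelihood at the supplied (maximized) parameter values."""
    data = ItemData.from_any(items)
    x0 = pack_free_parameters(params, spec)
    p = len(x0)

    def f(x):
        pr = unpack_free_parameters(x, params, spec)
        return loglikelihood(pr, data, method="quadrature",
                             quadrature_points=quadrature_points)

    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = f(x0)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(x0 + e)
        fm[i] = f(x0 - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            e = np.zeros(p)
            e[i], e[j] = h[i], h[j]
            fpp = f(x0 + e)
            e[i], e[j] = -h[i], -h[j]
            fmm_ = f(x0 + e)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] - fm[i] - fm[j] + fmm_ + 2 * f0
            ) / (2 * h[i] * h[j])
    info = -H
    # guard against non-invertible curvature on flat directions
    try:
        cov = np.linalg.inv(info)
        var = np.diag(cov).copy()
    except np.linalg.LinAlgError:
        var = 1.0 / np.clip(np.diag(info), 1e-12, None)
    var = np.where(var > 0, var, np.nan)
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# Monte-Carlo acceptability diagnostics
# ---------------------------------------------------------------------------

@dataclass
class MCDiagnostics:
    table: pd.DataFrame       # per-parameter bias / SE bias / coverage / power
    R: int
    n: int
    flags: list = field(default_factory=list)

    @property
    def max_se_bias(self) -> float:
        return float(np.nanmax(np.abs(self.table["se_bias_pct"])))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True)


def monte_carlo_diagnostics(
    params: FMMParams,
    spec: FMMSpec,
    n: int,
    R: int,
    seed: int = 0,
    n_starts: int = 3,
    max_iter: int = 300,
    quadrature_points: int = 21,
    compute_se: bool = True,
) -> MCDiagnostics:
    """Simulate R datasets of size n from ``params``, refit under ``spec``,
    and tabulate relative bias (%), SE bias (%), 95% coverage and power.

    Parameters with true value 0 report absolute instead of relative bias.
    Refits are warm-started at the truth, the standard practice for
    simulation acceptability checks.
    """
    if R < 2:
        raise ValueError("R must be >= 2 (replication SD undefined otherwise)")
    rng = np.random.default_rng(seed)
    cells = free_parameter_cells(spec)
    true = pack_free_parameters(params, spec)
    est = np.full((R, len(cells)), np.nan)
    ses = np.full((R, len(cells)), np.nan)
    for r in range(R):
        data = simulate_items(params, n, rng)
        fit = fit_fmm(data, spec, n_starts=n_starts,
                      seed=int(rng.integers(2**31 - 1)),
                      max_iter=max_iter, quadrature_points=quadrature_points,
                      init_params=params)
        est[r] = pack_free_parameters(fit.params, spec)
        if compute_se:
            ses[r] = observed_information_se(
                fit.params, spec, data, quadrature_points=quadrature_points
            )

    mean_est = est.mean(axis=0)
    sd_est = est.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_bias = np.where(
            true != 0.0, 100.0 * (mean_est - true) / true, np.nan
        )
    abs_bias = mean_est - true
    mean_se = np.nanmean(ses, axis=0)
    se_bias = 100.0 * (mean_se - sd_est) / np.where(sd_est > 0, sd_est, np.nan)
    lo = est - 1.96 * ses
    hi = est + 1.96 * ses
    coverage = np.nanmean((lo <= true[None, :]) & (true[None, :] <= hi), axis=0)
    power = np.nanmean(np.abs(est / ses) > 1.96, axis=0)

    names = [
        f"{block}[{k if k is not None else 'inv'}"
        + (f",{c}]" if c is not None else "]")
        for block, k, c in cells
    ]
    table = pd.DataFrame(
        {
            "true": true,
            "mean_estimate": mean_est,
            "rel_bias_pct": rel_bias,
            "abs_bias": abs_bias,
            "sd_estimates": sd_est,
            "mean_model_se": mean_se,
            "se_bias_pct": se_bias,
            "coverage95": coverage,
            "power": power,
        },
        index=names,
    )
    flags = [nm for nm, sb in zip(names, se_bias) if np.isfinite(sb) and abs(sb) > 10.0]
    return MCDiagnostics(table=table, R=R, n=n, flags=flags)


# ---------------------------------------------------------------------------
# Family comparison ledger
# ---------------------------------------------------------------------------

@dataclass
class ComparisonEntry:
    label: str
    model_a: str
    model_b: str
    bic_a: float
    bic_b: float
    bic_diff: float
    blrt_p: float | None
    decision: str
    rationale: str

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class ComparisonLedger:
    entries: list = field(default_factory=list)
    alpha: float = 0.05

    def add(self, entry: ComparisonEntry) -> None:
        if not entry.rationale:
            raise ValueError("every ledger decision must cite its statistic")
        self.entries.append(entry)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_dict() for e in self.entries])

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "entries": [e.to_dict() for e in self.entries]}


def compare_family(
    fits: dict,
    blrts: dict | None = None,
    alpha: float = 0.05,
) -> ComparisonLedger:
    """Build the decision ledger over a family of fitted models.

    ``fits`` maps label -> FMMFit (all on one dataset).  ``blrts`` maps
    (null_label, alt_label) -> BLRTResult for the nested pairs that were
    bootstrap-tested.  Decision rule: the BLRT governs nested comparisons
    (class counts, ev against uv); BIC governs non-nested comparisons
    (surviving non-null families against the strong-invariance null).
    """
    blrts = blrts or {}
    labels = list(fits)
    ns = {fits[a].n for a in labels}
    if len(ns) > 1:
        raise ValueError("all fits must share one dataset")
    ledger = ComparisonLedger(alpha=alpha)

    roles = {a: fits[a].spec for a in labels}
    somi_label = None
    for a in labels:
        from .family import hypothesis_role

        if hypothesis_role(roles[a]) == NULL_CATEGORICAL:
            if somi_label is None or fits[a].bic < fits[somi_label].bic:
                somi_label = a

    # nested pairs with bootstrap tests
    for (null_l, alt_l), res in blrts.items():
        if null_l not in fits or alt_l not in fits:
            raise ValueError(f"missing required pair ({null_l}, {alt_l})")
        fa, fn = fits[alt_l], fits[null_l]
        reject = res.p_value <= alpha
        decision = alt_l if reject else null_l
        ledger.add(ComparisonEntry(
            label=f"{alt_l} vs {null_l}",
            model_a=alt_l, model_b=null_l,
            bic_a=fa.bic, bic_b=fn.bic, bic_diff=fa.bic - fn.bic,
            blrt_p=res.p_value, decision=decision,
            rationale=(
                f"BLRT p={res.p_value:.4g} {'<=' if reject else '>'} "
                f"alpha={alpha}; BIC diff={fa.bic - fn.bic:.1f}"
            ),
        ))

    # non-null models against the categorical-approximation null, by BIC
    if somi_label is not None:
        from .family import hypothesis_role

        for a in labels:
            if a == somi_label or hypothesis_role(roles[a]) != NON_NULL:
                continue
            fa, fs = fits[a], fits[somi_label]
            diff = fa.bic - fs.bic
            decision = a if diff < 0 else somi_label
            ledger.add(ComparisonEntry(
                label=f"{a} vs {somi_label} (null)",
                model_a=a, model_b=somi_label,
                bic_a=fa.bic, bic_b=fs.bic, bic_diff=diff,
                blrt_p=None, decision=decision,
                rationale=f"non-nested comparison decided by BIC diff={diff:.1f}",
            ))
    return ledger
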