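"""Factor-mixture core: likelihood oracles, EM behaviour, posteriors,
entropy, factor-dimension comparison."""

import numpy as np
import pytest
from scipy import integrate, stats

import syndromix as sx
from syndromix import fmm
from syndromix.family import GAUSSIAN_ITEM_MODELS, build_spec


def brute_force_loglik(params, data, zlim=10.0):
    """Oracle: per-subject adaptive numerical integration of the factor."""
    total = 0.0
    for i in range(data.n):
        acc = 0.0
        for k in range(params.K):
            def integrand(z):
                eta = params.alpha[k] + np.sqrt(max(params.psi[k], 0.0)) * z
                val = stats.norm.pdf(z)
                for c in range(data.C):
                    mu = params.intercepts[k, c] + params.loadings[k, c] * eta
                    sd = np.sqrt(params.theta[k, c])
                    if data.cens[i, c]:
                        val *= stats.norm.cdf((data.floor - mu) / sd)
                    elif data.obs[i, c]:
                        val *= stats.norm.pdf(data.y[i, c], mu, sd)
                return val

            if params.has_factor:
                I, _ = integrate.quad(integrand, -zlim, zlim, limit=300,
                                      epsabs=1e-14, epsrel=1e-12)
            else:
                I = integrand(0.0) / stats.norm.pdf(0.0)
            if params.occ_logit is not None and data.occurrence is not None:
                p = 1 / (1 + np.exp(-params.occ_logit[k]))
                I *= p if data.occurrence[i] == 1 else 1 - p
            acc += params.pi[k] * I
        total += np.log(acc)
    return total


def test_loglik_k1_zero_loadings_is_independent_normals():
    params = fmm.FMMParams(
        pi=[1.0], intercepts=[[1.0, 2.0, 3.0, 4.0, 5.0]],
        loadings=[[0.0] * 5], theta=[[1.0, 2.0, 0.5, 1.5, 1.0]],
        alpha=[0.0], psi=[1.0], item_models=GAUSSIAN_ITEM_MODELS,
    )
    rng = np.random.default_rng(0)
    y = rng.normal(size=(30, 5)) + np.arange(1, 6)
    ll = sx.loglikelihood(params, y)
    direct = float(
        stats.norm.logpdf(
            y, loc=np.arange(1, 6), scale=np.sqrt([1.0, 2.0, 0.5, 1.5, 1.0])
        ).sum()
    )
    assert ll == pytest.approx(direct, abs=1e-8)


def test_quadrature_matches_brute_force_gaussian(small_gaussian_params):
    """21-node quadrature against adaptive integration, well-scaled case."""
    data = fmm.simulate_items(small_gaussian_params, 20, np.random.default_rng(7))
    oracle = brute_force_loglik(small_gaussian_params, data)
    lq = sx.loglikelihood(small_gaussian_params, data, method="quadrature",
                          quadrature_points=21)
    assert abs(lq - oracle) < 1e-6
    la = sx.loglikelihood(small_gaussian_params, data, method="analytic")
    assert abs(la - oracle) < 1e-6


def test_analytic_matches_brute_force_mixed_items(mixed_item_params):
    """Closed-form marginal against numerical integration with censoring and
    the two-part weight-loss item."""
    data = fmm.simulate_items(mixed_item_params, 50, np.random.default_rng(4))
    assert data.cens.sum() >= 1  # at least one censored gait value
    oracle = brute_force_loglik(mixed_item_params, data)
    la = sx.loglikelihood(mixed_item_params, data, method="analytic")
    assert abs(la - oracle) < 1e-6


def test_censored_tail_term_closed_form():
    """At K=1 with zero loading the censored cell contributes exactly the
    normal left-tail probability."""
    params = fmm.FMMParams(
        pi=[1.0], intercepts=[[0.0, 0.0, 0.0, 44.0, 0.0]],
        loadings=[[0.0] * 5], theta=[[1.0, 1.0, 1.0, 150.0, 1.0]],
        alpha=[0.0], psi=[1e-12], floor=15.0,
        item_models=("gaussian", "gaussian", "gaussian",
                     "censored-gaussian", "two-part-magnitude"),
        occ_logit=[0.0],
    )
    y = np.zeros((1, 5))
    y[0, 3] = 15.0
    y[0, 4] = np.nan
    data = fmm.ItemData(
        y=y, obs=np.array([[True, True, True, False, False]]),
        cens=np.array([[False, False, False, True, False]]),
        occurrence=np.array([0]), floor=15.0,
    )
    ll = sx.loglikelihood(params, data, method="quadrature")
    expect = (
        3 * stats.norm.logpdf(0.0)
        + stats.norm.logcdf((15.0 - 44.0) / np.sqrt(150.0))
        + np.log(0.5)  # occurrence = 0 at logit 0
    )
    assert ll == pytest.approx(expect, abs=1e-7)


def test_lca_gaussian_fit_matches_sklearn_mixture():
    """Zero-loading class-varying-intercept fit coincides with an
    unstructured diagonal Gaussian mixture (independent oracle)."""
    from sklearn.mixture import GaussianMixture

    rng = np.random.default_rng(11)
    n = 500
    cls = rng.random(n) < 0.4
    y = np.where(
        cls[:, None],
        rng.normal([0, 0, 0, 0, 0], 1.0, (n, 5)),
        rng.normal([3, 4, 3, 5, 3], 1.3, (n, 5)),
    )
    spec = build_spec("LCA", 2, "uv", GAUSSIAN_ITEM_MODELS)
    fit = sx.fit_fmm(y, spec, n_starts=10, seed=0, tol=1e-10)
    gm = GaussianMixture(2, covariance_type="diag", n_init=10, tol=1e-10,
                        reg_covar=1e-12, max_iter=2000, random_state=0).fit(y)
    assert fit.loglik == pytest.approx(gm.score(y) * n, abs=1e-4)


def test_one_class_factor_recovery():
    true = fmm.FMMParams(
        pi=[1.0], intercepts=[[0.0, 1.0, -1.0, 0.5, 0.2]],
        loadings=[[1.0, 0.8, 1.2, 0.6, 0.9]],
        theta=[[0.5, 0.7, 0.6, 0.8, 0.5]], alpha=[0.0], psi=[1.5],
        item_models=GAUSSIAN_ITEM_MODELS,
    )
    data = fmm.simulate_items(true, 2000, np.random.default_rng(21))
    spec = build_spec("SoMI", 1, "uv", GAUSSIAN_ITEM_MODELS)
    fit = sx.fit_fmm(data, spec, n_starts=3, seed=1, tol=1e-8)
    est_l = fit.params.loadings[0]
    est_p = fit.params.psi[0]
    assert np.abs((est_l[1:] - true.loadings[0][1:]) / true.loadings[0][1:]).max() < 0.10
    assert abs(est_p - 1.5) / 1.5 < 0.10


def test_em_monotone_and_constrained_below_unconstrained(frele_items):
    fits = {}
    for fam, var, K in [("SiMI", "ev", 2), ("SoMI", "uv", 2),
                        ("WMI", "uv", 2), ("NMI", "uv", 2)]:
        spec = build_spec(fam, K, var)
        fit = sx.fit_fmm(frele_items, spec, n_starts=2, seed=3,
                         max_iter=300, quadrature_points=15)
        fits[fam] = fit
        diffs = np.diff(fit.loglik_trace)
        assert diffs.min() > -1e-6, f"{fam} EM decreased the log-likelihood"
    # invariance ladder: each relaxation can only raise the maximized loglik
    assert fits["SiMI"].loglik <= fits["SoMI"].loglik + 1e-4
    assert fits["SoMI"].loglik <= fits["WMI"].loglik + 1e-4
    assert fits["WMI"].loglik <= fits["NMI"].loglik + 1e-4


def test_loglik_invariant_under_class_permutation(mixed_item_params):
    data = fmm.simulate_items(mixed_item_params, 100, np.random.default_rng(5))
    base = sx.loglikelihood(mixed_item_params, data)
    flipped = mixed_item_params.permute_classes([1, 0])
    assert sx.loglikelihood(flipped, data) == pytest.approx(base, abs=1e-9)


def test_posteriors_match_bayes_oracle(small_gaussian_params):
    data = fmm.simulate_items(small_gaussian_params, 60, np.random.default_rng(9))
    post = fmm.posterior_matrix(small_gaussian_params, data)
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-10)
    # independent Bayes recomputation from per-class marginal densities
    p = small_gaussian_params
    logd = np.empty((data.n, p.K))
    for k in range(p.K):
        only_k = fmm.FMMParams(
            pi=[1.0], intercepts=p.intercepts[[k]], loadings=p.loadings[[k]],
            theta=p.theta[[k]], alpha=p.alpha[[k]], psi=p.psi[[k]],
            item_models=p.item_models,
        )
        for i in range(data.n):
            sub = fmm.ItemData(
                y=data.y[[i]], obs=data.obs[[i]], cens=data.cens[[i]],
                occurrence=None, floor=data.floor,
            )
            logd[i, k] = sx.loglikelihood(only_k, sub, method="analytic")
    joint = logd + np.log(p.pi)
    oracle = np.exp(joint - joint.max(axis=1, keepdims=True))
    oracle /= oracle.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(post, oracle, atol=1e-6)


def test_entropy_limits_and_hand_computed_value():
    n, K = 50, 3
    assert sx.relative_entropy(np.full((n, K), 1 / K)) == pytest.approx(0.0, abs=1e-12)
    crisp = np.zeros((n, K))
    crisp[:, 0] = 1.0
    assert sx.relative_entropy(crisp) == pytest.approx(1.0, abs=1e-9)
    # frozen hand computation on a 3 x 2 posterior matrix
    post = np.array([[0.9, 0.1], [0.2, 0.8], [0.5, 0.5]])
    assert sx.relative_entropy(post) == pytest.approx(0.269691, abs=1e-5)
    assert np.isnan(sx.relative_entropy(np.ones((10, 1))))


def test_degenerate_class_is_flagged():
    """Fitting far more classes than the data support flags degeneracy."""
    rng = np.random.default_rng(13)
    y = rng.normal(size=(60, 5))  # one blob, no class structure
    spec = build_spec("LCA", 5, "uv", GAUSSIAN_ITEM_MODELS)
    fit = sx.fit_fmm(y, spec, n_starts=4, seed=0, min_class_count=10.0)
    assert fit.degenerate
    assert not fit.converged


def test_compare_factor_dimension_null_and_alternative():
    rng = np.random.default_rng(17)
    # one-factor truth: non-rejection in the large majority of replicates
    true = fmm.FMMParams(
        pi=[1.0], intercepts=[[0.0, 0.0, 0.0, 0.0, 0.0]],
        loadings=[[1.0, 0.9, 0.8, 0.7, 0.6]],
        theta=[[1.0, 1.0, 1.0, 1.0, 1.0]], alpha=[0.0], psi=[1.0],
        item_models=GAUSSIAN_ITEM_MODELS,
    )
    rejections = 0
    n_rep = 25
    for r in range(n_rep):
        data = fmm.simulate_items(true, 250, rng)
        res = sx.compare_factor_dimension(data, seed=r)
        assert res["df"] == 4
        rejections += res["p"] <= 0.05
    assert rejections <= 0.10 * n_rep + 2  # >= 90% non-rejection

    # two orthogonal strong factors: decisive rejection
    n = 400
    f1, f2 = rng.normal(0, 2, n), rng.normal(0, 2, n)
    lam1 = np.array([1.0, 0.9, 0.0, 0.0, 0.8])
    lam2 = np.array([0.0, 0.0, 1.0, 1.1, 0.0])
    y = np.outer(f1, lam1) + np.outer(f2, lam2) + rng.standard_normal((n, 5))
    res = sx.compare_factor_dimension(y, seed=0)
    assert res["p"] < 1e-6
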