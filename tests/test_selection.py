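"""BIC differences, bootstrap LRT behaviour, Monte-Carlo diagnostics."""

from types import SimpleNamespace

import numpy as np
import pytest

import syndromix as sx
from syndromix import fmm
from syndromix.family import GAUSSIAN_ITEM_MODELS, build_spec
from syndromix.selection import (
    bic_difference,
    blrt,
    blrt_binary_lca,
    compare_family,
    monte_carlo_diagnostics,
)


def test_bic_difference_basics():
    a = SimpleNamespace(n=100, bic=500.0)
    b = SimpleNamespace(n=100, bic=510.0)
    assert bic_difference(a, a) == 0.0
    assert bic_difference(a, b) == -10.0
    with pytest.raises(ValueError):
        bic_difference(a, SimpleNamespace(n=200, bic=500.0))


def test_extra_useless_parameter_costs_log_n():
    """Same log-likelihood, one extra parameter: BIC difference = ln n."""
    n, ll = 320, -1234.5
    k = 7
    fit_small = SimpleNamespace(n=n, bic=-2 * ll + k * np.log(n))
    fit_big = SimpleNamespace(n=n, bic=-2 * ll + (k + 1) * np.log(n))
    assert bic_difference(fit_big, fit_small) == pytest.approx(np.log(n))


def test_uv_favoured_on_uv_truth_by_bic():
    """On data with genuinely unequal class variances the uv model wins the
    BIC comparison in the large majority of replicates."""
    spec_ev = build_spec("LCA", 2, "ev", GAUSSIAN_ITEM_MODELS)
    spec_uv = build_spec("LCA", 2, "uv", GAUSSIAN_ITEM_MODELS)
    true = fmm.FMMParams(
        pi=[0.5, 0.5],
        intercepts=[[0, 0, 0, 0, 0], [3, 3, 3, 3, 3]],
        loadings=np.zeros((2, 5)), theta=[[0.5] * 5, [3.0] * 5],
        alpha=[0, 0], psi=[0, 0], item_models=GAUSSIAN_ITEM_MODELS,
    )
    wins = 0
    n_rep = 20
    for s in range(n_rep):
        data = fmm.simulate_items(true, 1643, np.random.default_rng(1000 + s))
        f_ev = sx.fit_fmm(data, spec_ev, n_starts=4, seed=s)
        f_uv = sx.fit_fmm(data, spec_uv, n_starts=4, seed=s)
        wins += bic_difference(f_uv, f_ev) < 0
    assert wins >= 0.9 * n_rep


def test_blrt_null_equals_alt_gives_p_one():
    spec = build_spec("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS)
    y = np.random.default_rng(3).normal(size=(150, 5))
    res = blrt(y, spec, spec, B=9, seed=0, obs_n_starts=1, n_starts=1)
    assert res.lrt_observed == pytest.approx(0.0, abs=1e-6)
    assert res.p_value == 1.0


def test_blrt_separated_two_class_hits_floor():
    rng = np.random.default_rng(5)
    n = 400
    cls = rng.random(n) < 0.5
    y = np.where(cls[:, None], rng.normal(0, 1, (n, 5)), rng.normal(6, 1, (n, 5)))
    alt = build_spec("LCA", 2, "ev", GAUSSIAN_ITEM_MODELS)
    null = build_spec("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS)
    B = 19
    res = blrt(y, alt, null, B=B, seed=1, obs_n_starts=4, n_starts=1)
    assert res.p_value == pytest.approx(1.0 / (B + 1))
    assert 1.0 / (B + 1) <= res.p_value <= 1.0


def test_blrt_seed_reproducibility():
    rng = np.random.default_rng(6)
    y = rng.normal(size=(200, 5))
    alt = build_spec("LCA", 2, "ev", GAUSSIAN_ITEM_MODELS)
    null = build_spec("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS)
    r1 = blrt(y, alt, null, B=9, seed=42, obs_n_starts=2, n_starts=1)
    r2 = blrt(y, alt, null, B=9, seed=42, obs_n_starts=2, n_starts=1)
    np.testing.assert_array_equal(r1.bootstrap_lrts, r2.bootstrap_lrts)
    assert r1.p_value == r2.p_value


def test_blrt_requires_nesting():
    alt = build_spec("WMI", 2, "ev")
    null = build_spec("NMI", 2, "uv")
    with pytest.raises(ValueError, match="nested"):
        blrt(np.zeros((50, 5)), alt, null, B=9)


def test_blrt_binary_lca_rejects_on_two_class_truth():
    from syndromix.lca import simulate_binary

    X = simulate_binary(
        [0.5, 0.5], [[0.9, 0.85, 0.9, 0.8, 0.85], [0.1, 0.1, 0.05, 0.1, 0.1]],
        600, np.random.default_rng(8),
    )
    res = blrt_binary_lca(X, K_alt=2, K_null=1, B=19, seed=0, obs_n_starts=10,
                          n_starts=4)
    assert res.p_value == pytest.approx(1.0 / 20)


def test_mc_diagnostics_requires_replicates():
    spec = build_spec("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS)
    params = fmm.FMMParams(
        pi=[1.0], intercepts=[[0] * 5], loadings=[[0] * 5],
        theta=[[1.0] * 5], alpha=[0.0], psi=[0.0],
        item_models=GAUSSIAN_ITEM_MODELS,
    )
    with pytest.raises(ValueError, match="R"):
        monte_carlo_diagnostics(params, spec, n=100, R=1)


def test_mc_diagnostics_one_class_consistency():
    """Generous n, simple one-class profile: small bias, nominal coverage,
    and model SEs near the replication SDs."""
    spec = build_spec("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS)
    params = fmm.FMMParams(
        pi=[1.0], intercepts=[[2.0, -1.5, 3.0, 1.0, 0.5]],
        loadings=[[0.0] * 5], theta=[[1.0, 2.0, 0.8, 1.5, 1.2]],
        alpha=[0.0], psi=[0.0], item_models=GAUSSIAN_ITEM_MODELS,
    )
    diag = monte_carlo_diagnostics(params, spec, n=3000, R=320, seed=0)
    tab = diag.table
    assert np.nanmax(np.abs(tab["rel_bias_pct"])) < 2.0
    cov = tab["coverage95"].to_numpy()
    assert 0.93 < cov.mean() < 0.97
    assert (cov > 0.90).all() and (cov < 0.99).all()
    # SE sanity: information-matrix SEs within 20% of replication SDs
    assert np.nanmax(np.abs(tab["se_bias_pct"])) < 20.0
    # every true mean/variance is nonzero: power ~ 1
    assert (tab["power"] > 0.99).all()
    assert not diag.flags


def test_mc_diagnostics_flags_misspecified_variances():
    """Refitting an equal-variance spec on unequal-variance truth raises
    standard-error bias flags."""
    true = fmm.FMMParams(
        pi=[0.5, 0.5],
        intercepts=[[0, 0, 0, 0, 0], [2.5, 2.5, 2.5, 2.5, 2.5]],
        loadings=np.zeros((2, 5)), theta=[[0.3] * 5, [4.0] * 5],
        alpha=[0, 0], psi=[0, 0], item_models=GAUSSIAN_ITEM_MODELS,
    )
    spec_ev = build_spec("LCA", 2, "ev", GAUSSIAN_ITEM_MODELS)
    # align the misspecified template with the truth's mean structure
    mis = true.copy()
    mis.theta = np.tile(true.theta.mean(axis=0), (2, 1))
    diag = monte_carlo_diagnostics(mis, spec_ev, n=600, R=24, seed=1,
                                   n_starts=2)
    assert len(diag.flags) > 0


def test_compare_family_single_fit_defers():
    spec = build_spec("SiMI", 1, "ev", GAUSSIAN_ITEM_MODELS)
    y = np.random.default_rng(2).normal(size=(200, 5))
    fit = sx.fit_fmm(y, spec, n_starts=2, seed=0)
    ledger = compare_family({"one-class": fit})
    assert ledger.entries == []


def test_compare_family_cites_statistics():
    rng = np.random.default_rng(4)
    true = fmm.FMMParams(
        pi=[0.5, 0.5], intercepts=[[0] * 5, [3] * 5],
        loadings=np.zeros((2, 5)), theta=np.ones((2, 5)),
        alpha=[0, 0], psi=[0, 0], item_models=GAUSSIAN_ITEM_MODELS,
    )
    data = fmm.simulate_items(true, 500, rng)
    f_lca = sx.fit_fmm(data, build_spec("LCA", 2, "uv", GAUSSIAN_ITEM_MODELS),
                       n_starts=4, seed=0)
    f_somi = sx.fit_fmm(data, build_spec("SoMI", 2, "uv", GAUSSIAN_ITEM_MODELS),
                        n_starts=4, seed=1)
    ledger = compare_family({"LCA-uv(2)": f_lca, "SoMI-uv(2)": f_somi})
    assert len(ledger.entries) == 1
    entry = ledger.entries[0]
    assert "BIC" in entry.rationale
    assert entry.decision in ("LCA-uv(2)", "SoMI-uv(2)")
    frame = ledger.to_frame()
    assert len(frame) == 1
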