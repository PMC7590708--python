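"""Synthetic-cohort generator: determinism, invariants, moments."""

import numpy as np
import pytest

import syndromix as sx
from syndromix.cohort import ConfigurationError, analytic_class_means


def test_seed_determinism_bit_identical():
    cfg = sx.default_config_frele(n_subjects=400)
    a = sx.generate_cohort(cfg)
    b = sx.generate_cohort(cfg)
    assert a.equals(b)
    c = sx.generate_cohort(cfg, seed=999)
    assert not a.equals(c)


def test_cohort_invariants(frele_cohort):
    sx.validate_cohort(frele_cohort)
    df = frele_cohort
    floor = df.attrs["gait_censor_floor"]
    assert ((df.gait == floor) == df.gait_censored).all()
    kg = df.weight_lost_kg
    assert (kg[df.weight_lost_any == 1] > 0).all()
    assert kg[df.weight_lost_any == 0].isna().all()


def test_noise_free_limit_recovers_classes_exactly():
    """With vanishing residual noise every subject sits at its class mean and
    the true class is recoverable from the nearest class-mean profile."""
    cfg = sx.config_lca_3class(n_subjects=300, seed=3)
    d = cfg.to_dict()
    d["residual_variances"] = (np.full((3, 5), 1e-12)).tolist()
    d["sex_shift"] = [0.0] * 5
    d["gait_censor_floor"] = -1e9
    cfg = sx.CohortConfig.from_dict(d)
    df = sx.generate_cohort(cfg)
    comp = df[["exhaustion", "activity", "grip", "gait"]].to_numpy()
    means = np.asarray(cfg.intercepts)[:, :4]
    assigned = np.argmin(
        ((comp[:, None, :] - means[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    assert (assigned == df.true_class.to_numpy()).all()
    # components equal the class means exactly (no loading term: loadings 0)
    np.testing.assert_allclose(comp, means[df.true_class], atol=1e-4)


def test_one_class_means_within_three_standard_errors():
    cfg = sx.config_one_class(n_subjects=4000, seed=5)
    df = sx.generate_cohort(cfg)
    expect = analytic_class_means(cfg)[0]
    for j, col in enumerate(["exhaustion", "activity", "grip"]):
        x = df[col]
        se = x.std() / np.sqrt(len(x))
        assert abs(x.mean() - expect[j]) < 3 * se


def test_default_config_class_means_match_analytic():
    """Per-class component means at n=5000 reproduce I + F*alpha (+ sex
    shift) within Monte-Carlo error."""
    cfg = sx.default_config_frele(n_subjects=5000, seed=77)
    df = sx.generate_cohort(cfg)
    expect = analytic_class_means(cfg, include_sex=True)
    for k in range(cfg.K_true):
        sub = df[df.true_class == k]
        for j, col in enumerate(["exhaustion", "activity", "grip"]):
            sd_k = np.sqrt(
                cfg.loadings[j] ** 2 * cfg.factor_variances[k]
                + cfg.residual_variances[k, j]
            )
            mc_se = sd_k / np.sqrt(len(sub))
            assert abs(sub[col].mean() - expect[k, j]) < 5 * mc_se, (k, col)


def test_default_config_printed_fields():
    cfg = sx.default_config_frele()
    assert cfg.loadings[0] == 1.00
    assert cfg.loadings[1] == 4.10
    # no class with expected count < 25 at the study n
    assert (cfg.mixing * 1643 >= 25).all()
    # weight-loss occurrence averaged over classes near the published 13%
    p = 1 / (1 + np.exp(-cfg.weightloss_occurrence_logit))
    assert 0.10 < float(cfg.mixing @ p) < 0.15


def test_per_class_covariance_matches_factor_structure():
    """Sample covariance of the uncensored continuous block matches
    F psi_k F' + Theta_k within Monte-Carlo error at large n."""
    cfg = sx.default_config_frele(n_subjects=20000, seed=11)
    d = cfg.to_dict()
    d["sex_shift"] = [0.0] * 5
    d["gait_censor_floor"] = -1e9
    cfg = sx.CohortConfig.from_dict(d)
    df = sx.generate_cohort(cfg)
    lam = cfg.loadings[:4]
    for k in (2, 3):  # the two largest classes
        sub = df[df.true_class == k]
        X = sub[["exhaustion", "activity", "grip", "gait"]].to_numpy()
        S = np.cov(X.T)
        Sigma = cfg.factor_variances[k] * np.outer(lam, lam) + np.diag(
            cfg.residual_variances[k, :4]
        )
        nk = len(sub)
        for i in range(4):
            for j in range(4):
                # MC error of a covariance entry
                se = np.sqrt(
                    (Sigma[i, i] * Sigma[j, j] + Sigma[i, j] ** 2) / nk
                )
                assert abs(S[i, j] - Sigma[i, j]) < 5 * se, (k, i, j)


def test_censoring_fraction_matches_normal_tail():
    cfg = sx.default_config_frele(n_subjects=40000, seed=13)
    df = sx.generate_cohort(cfg)
    lam, floor = cfg.loadings[3], cfg.gait_censor_floor
    p = 0.0
    from scipy.stats import norm

    for k in range(cfg.K_true):
        mu = cfg.intercepts[k, 3] + lam * cfg.factor_means[k] \
            + cfg.sex_ratio * cfg.sex_shift[3]
        # sex shift makes the tail a two-component mixture; average it
        pk = 0.0
        for shift, w in ((0.0, 1 - cfg.sex_ratio), (cfg.sex_shift[3], cfg.sex_ratio)):
            m = cfg.intercepts[k, 3] + lam * cfg.factor_means[k] + shift
            sd = np.sqrt(lam**2 * cfg.factor_variances[k]
                         + cfg.residual_variances[k, 3])
            pk += w * norm.cdf((floor - m) / sd)
        p += cfg.mixing[k] * pk
    obs = df.gait_censored.mean()
    se = np.sqrt(p * (1 - p) / len(df))
    assert abs(obs - p) < 5 * se


@pytest.mark.parametrize(
    "field,value,match",
    [
        ("mixing", [0.5, 0.4], "mixing"),
        ("loadings", [1.0, 2.0], "loadings"),
        ("factor_variances", [-1.0, 1.0, 1.0, 1.0], "factor_variances"),
        ("residual_variances", np.zeros((4, 5)), "residual_variances"),
    ],
)
def test_invalid_config_names_offending_field(field, value, match):
    d = sx.default_config_frele().to_dict()
    d[field] = np.asarray(value).tolist()
    with pytest.raises(ConfigurationError, match=match):
        sx.CohortConfig.from_dict(d)


def test_config_json_roundtrip(tmp_path):
    cfg = sx.default_config_frele(n_subjects=123)
    path = tmp_path / "cfg.json"
    cfg.to_json(path)
    back = sx.CohortConfig.from_json(path)
    assert back.to_dict() == cfg.to_dict()
    assert sx.generate_cohort(back).equals(sx.generate_cohort(cfg))
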