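"""Model-family templates, parameter counts, roles, nesting."""

import pytest

from syndromix.family import (
    DEFAULT_ITEM_MODELS,
    GAUSSIAN_ITEM_MODELS,
    IllegalSpecError,
    NON_NULL,
    NULL_CATEGORICAL,
    NULL_ONE_CLASS,
    build_spec,
    count_parameters,
    family_table,
    hypothesis_role,
    is_nested,
)
from syndromix.fmm import free_parameter_cells


def test_somi_template():
    spec = build_spec("SoMI", 4, "uv")
    assert not spec.intercepts_vary
    assert not spec.loadings_vary
    assert spec.residuals_vary and spec.factor_variance_vary
    assert spec.n_free_factor_means == 3


def test_lca_template_has_no_factor():
    spec = build_spec("LCA", 3, "ev")
    assert not spec.has_factor
    assert spec.intercepts_vary and not spec.residuals_vary


def test_nmi_everything_varies():
    spec = build_spec("NMI", 3, "uv")
    assert spec.intercepts_vary and spec.loadings_vary
    assert spec.residuals_vary and spec.factor_variance_vary
    assert spec.n_free_factor_means == 0  # absorbed by class intercepts


def test_simi_uv_is_illegal():
    with pytest.raises(IllegalSpecError, match="SiMI"):
        build_spec("SiMI", 3, "uv")


@pytest.mark.parametrize(
    "family,K,variance,items,expected",
    [
        # binary 5-item LCA: 5K + (K-1); K=3 forced by the chi-square df 14
        ("LCA", 3, "ev", ("bernoulli",) * 5, 17),
        ("LCA", 2, "ev", ("bernoulli",) * 5, 11),
        # gaussian 5-item strong invariance, K=4:
        # 5 I + 4 loadings + 3 alpha + 1 psi + 5 theta + 3 mixing
        ("SoMI", 4, "ev", GAUSSIAN_ITEM_MODELS, 21),
        # one-class gaussian profile: 5 means + 5 variances
        ("LCA", 1, "ev", GAUSSIAN_ITEM_MODELS, 10),
    ],
)
def test_parameter_counts(family, K, variance, items, expected):
    assert count_parameters(build_spec(family, K, variance, items)) == expected


@pytest.mark.parametrize("family", ["LCA", "SoMI", "WMI", "NMI"])
@pytest.mark.parametrize("K", [2, 3, 4])
def test_uv_minus_ev_count_additivity(family, K):
    """uv adds (K-1) x (number of variance cells freed) parameters."""
    if family == "SoMI":
        ev, uv = build_spec("SiMI", K, "ev"), build_spec("SoMI", K, "uv")
    else:
        ev, uv = build_spec(family, K, "ev"), build_spec(family, K, "uv")
    n_var_cells = 5 + (1 if ev.has_factor else 0)  # theta cells + psi
    assert count_parameters(uv) - count_parameters(ev) == (K - 1) * n_var_cells


@pytest.mark.parametrize("family,K,expected", [
    ("SoMI", 4, NULL_CATEGORICAL),
    ("SiMI", 2, NULL_CATEGORICAL),
    ("LCA", 4, NON_NULL),
    ("WMI", 3, NON_NULL),
    ("NMI", 2, NON_NULL),
    ("SoMI", 1, NULL_ONE_CLASS),
    ("LCA", 1, NULL_ONE_CLASS),
])
def test_hypothesis_roles(family, K, expected):
    spec = build_spec(family, K, "ev" if family == "SiMI" else "uv")
    assert hypothesis_role(spec) == expected


def test_nesting_graph_matches_tested_pairs():
    pairs = [
        (("LCA", 3, "ev"), ("LCA", 4, "uv")),
        (("SiMI", 2, "ev"), ("SoMI", 4, "uv")),
        (("WMI", 3, "ev"), ("WMI", 3, "uv")),
        (("NMI", 2, "ev"), ("NMI", 3, "uv")),
        (("SoMI", 3, "uv"), ("WMI", 3, "uv")),
        (("WMI", 3, "uv"), ("NMI", 3, "uv")),
        (("SiMI", 1, "ev"), ("SoMI", 2, "uv")),
    ]
    for null, alt in pairs:
        assert is_nested(build_spec(*null), build_spec(*alt)), (null, alt)
    # and the graph is acyclic: no pair nested both ways
    for null, alt in pairs:
        assert not is_nested(build_spec(*alt), build_spec(*null)), (null, alt)
    # uv is never nested in ev
    assert not is_nested(build_spec("LCA", 2, "uv"), build_spec("LCA", 3, "ev"))


@pytest.mark.parametrize("family,variance", [
    ("LCA", "ev"), ("LCA", "uv"), ("SiMI", "ev"), ("SoMI", "uv"),
    ("WMI", "ev"), ("WMI", "uv"), ("NMI", "ev"), ("NMI", "uv"),
])
@pytest.mark.parametrize("K", [1, 2, 4])
@pytest.mark.parametrize("items", [DEFAULT_ITEM_MODELS, GAUSSIAN_ITEM_MODELS])
def test_free_cells_agree_with_counts(family, variance, K, items):
    if family == "SiMI" and variance == "uv":
        pytest.skip("illegal combination")
    spec = build_spec(family, K, variance, items)
    assert len(free_parameter_cells(spec)) == count_parameters(spec)


def test_family_table_lists_seven_models():
    rows = family_table(3)
    labels = {(r["family"], r["K"] == 1) for r in rows}
    assert len(rows) == 8  # seven basic models; LCA contributes ev and uv
    roles = [r["null_status"] for r in rows]
    assert roles.count(NULL_ONE_CLASS) == 2
    assert roles.count(NULL_CATEGORICAL) == 2
    assert roles.count(NON_NULL) == 4
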