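"""Cut points, dichotomization, the Fried index and item encoding."""

import json
import pathlib

import numpy as np
import pandas as pd
import pytest

import syndromix as sx
from syndromix.prep import (
    BINARY_COLUMNS,
    CutPointTable,
    StratumError,
    derive_cut_points,
    dichotomize,
    encode_fmm_items,
    frailty_index,
)

FIXTURES = pathlib.Path(__file__).parent / "fixtures"


def brute_force_quintile(values):
    """Independent order-statistic oracle: sorted-order 20th percentile with
    linear interpolation between closest ranks."""
    v = np.sort(np.asarray(values, dtype=float))
    h = 0.2 * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_thresholds_equal_brute_force_order_statistics():
    cfg = sx.default_config_frele(n_subjects=500, seed=9)
    df = sx.generate_cohort(cfg)
    cuts = derive_cut_points(df)

    assert cuts.thresholds["exhaustion"]["all"] == pytest.approx(
        brute_force_quintile(df.exhaustion)
    )
    for s in ("female", "male"):
        sub = df[df.sex == s]
        assert cuts.thresholds["activity"][s] == pytest.approx(
            brute_force_quintile(sub.activity)
        )
        split = sub.height_cm.mean()
        assert cuts.height_split_cm[s] == pytest.approx(split)
        short = sub[sub.height_cm <= split]
        assert cuts.thresholds["slowness"][f"{s}|short"] == pytest.approx(
            brute_force_quintile(short.gait)
        )
        edges = np.quantile(sub.bmi, [0.2, 0.4, 0.6, 0.8])
        q = np.searchsorted(edges, sub.bmi.to_numpy(), side="left")
        for j in range(5):
            assert cuts.thresholds["weakness"][f"{s}|q{j + 1}"] == pytest.approx(
                brute_force_quintile(sub.grip.to_numpy()[q == j])
            )


def test_degenerate_stratum_constant_value():
    """All women sharing one PASE value makes that value the threshold."""
    cfg = sx.default_config_frele(n_subjects=300, seed=2)
    df = sx.generate_cohort(cfg)
    df.loc[df.sex == "female", "activity"] = 55.5
    cuts = derive_cut_points(df)
    assert cuts.thresholds["activity"]["female"] == 55.5


def test_published_cutpoint_fixture_dialect():
    cuts = CutPointTable.from_json(FIXTURES / "frele_cutpoints_published.json")
    assert cuts.thresholds["activity"]["female"] == 32.33
    assert cuts.thresholds["activity"]["male"] == 39.35
    assert cuts.thresholds["exhaustion"]["all"] == 46.88
    assert cuts.height_split_cm["female"] == 155.81
    # a subject exactly at the published threshold counts as a deficit
    df = pd.DataFrame(
        {
            "exhaustion": [46.88, 46.89],
            "activity": [32.33, 32.34],
            "grip": [37.0, 37.1],
            "gait": [5.6, 5.7],
            "height_cm": [150.0, 150.0],
            "bmi": [22.0, 22.0],
            "sex": ["female", "female"],
            "weight_lost_any": [0, 0],
        }
    )
    b = dichotomize(df, cuts)
    assert b.iloc[0].tolist() == [0, 1, 1, 1, 1]
    assert b.iloc[1].tolist() == [0, 0, 0, 0, 0]


def test_empty_stratum_raises_with_name():
    cfg = sx.default_config_frele(n_subjects=200, seed=3)
    df = sx.generate_cohort(cfg)
    # removing all males leaves the male strata empty; the error names one
    women = df[df.sex == "female"].reset_index(drop=True)
    with pytest.raises(StratumError, match="male"):
        derive_cut_points(women)


def test_dichotomize_prevalence_near_quintile(frele_cohort):
    cuts = derive_cut_points(frele_cohort)
    b = dichotomize(frele_cohort, cuts)
    assert list(b.columns) == list(BINARY_COLUMNS)
    # quintile-based components land near 20% deficit prevalence
    for col in ("exhaustion", "low_activity", "slowness", "weakness"):
        assert 0.15 < b[col].mean() < 0.27, col


def test_uncovered_stratum_errors():
    cfg = sx.default_config_frele(n_subjects=300, seed=4)
    df = sx.generate_cohort(cfg)
    cuts = derive_cut_points(df)
    del cuts.thresholds["activity"]["male"]
    with pytest.raises(StratumError, match="male"):
        dichotomize(df, cuts)


def test_frailty_index_rule():
    rows = pd.DataFrame(
        [
            [0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0],
            [1, 1, 1, 0, 1],
            [1, 1, 1, 1, 1],
            [0, 1, 0, 0, 0],
        ],
        columns=list(BINARY_COLUMNS),
    )
    fi = frailty_index(rows)
    assert fi.deficit_count.tolist() == [0, 2, 4, 5, 1]
    assert fi.label.tolist() == ["robust", "prefrail", "frail", "frail", "prefrail"]
    counts = fi.label.value_counts()
    assert counts.sum() == len(rows)


def test_frailty_index_rejects_non_binary():
    rows = pd.DataFrame([[0, 2, 0, 0, 0]], columns=list(BINARY_COLUMNS))
    with pytest.raises(ValueError):
        frailty_index(rows)


def test_encode_roundtrip_and_censor_flags(frele_cohort):
    items = encode_fmm_items(frele_cohort)
    assert items.censored.sum() == frele_cohort.gait_censored.sum()
    back = items.to_cohort_block()
    for col in ("exhaustion", "activity", "grip", "gait"):
        np.testing.assert_array_equal(back[col], frele_cohort[col].to_numpy())
    np.testing.assert_array_equal(
        back.weight_lost_any, frele_cohort.weight_lost_any.to_numpy()
    )
    lost = frele_cohort.weight_lost_any == 1
    np.testing.assert_allclose(
        back.weight_lost_kg[lost.to_numpy()],
        frele_cohort.weight_lost_kg[lost].to_numpy(),
    )
    assert back.weight_lost_kg[~lost.to_numpy()].isna().all()


def test_encode_rejects_negative_kg(frele_cohort):
    df = frele_cohort.copy()
    df.attrs = dict(frele_cohort.attrs)
    loser = df.index[df.weight_lost_any == 1][0]
    df.loc[loser, "weight_lost_kg"] = -2.0
    with pytest.raises(ValueError, match="negative"):
        encode_fmm_items(df)


def test_weakness_monotone_in_grip(frele_cohort):
    """Raising a subject's grip strength never creates a weakness deficit."""
    cuts = derive_cut_points(frele_cohort)
    base = dichotomize(frele_cohort, cuts)
    raised = frele_cohort.copy()
    raised.attrs = dict(frele_cohort.attrs)
    raised["grip"] = raised["grip"] + 5.0
    after = dichotomize(raised, cuts)
    flips = (base["weakness"] == 0) & (after["weakness"] == 1)
    assert not flips.any()


def test_cutpoint_table_json_roundtrip(tmp_path, frele_cohort):
    cuts = derive_cut_points(frele_cohort)
    p = tmp_path / "cuts.json"
    cuts.to_json(p)
    back = CutPointTable.from_json(p)
    assert back.thresholds == json.loads(json.dumps(cuts.thresholds))
    b1 = dichotomize(frele_cohort, cuts)
    b2 = dichotomize(frele_cohort, back)
    assert b1.equals(b2)
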