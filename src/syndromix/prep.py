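"""Cut points, dichotomization, the Fried index and FMM item encoding.

Implements the a-priori dichotomization pipeline used for the classic
phenotype operationalization: stratum-specific first-quintile cut points
(sex-stratified for physical activity, sex-by-height for slowness,
sex-by-BMI-quintile for weakness), the 0 / 1-2 / >=3 robust-prefrail-frail
index, and the continuous six-item encoding (four continuous components, a
censoring flag on gait, and a two-part weight-loss item) consumed by the
factor-mixture machinery.

Conventions (one dialect, enforced consistently):

* first quintile = empirical 20th percentile with linear interpolation;
* deficit side is inclusive (``<=`` the threshold);
* slowness thresholds are stored on gait *speed*, deficit = speed at or
  below the stratum threshold;
* the height split is at the sex-specific sample mean, recomputed per
  cohort, never hard-coded;
* the exhaustion (vitality) quintile is unstratified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Column order of the binary deficit matrix.
BINARY_COLUMNS = ("weight_loss", "exhaustion", "low_activity", "slowness", "weakness")


class StratumError(ValueError):
    """A stratification cell is empty or too small to yield a quantile."""


@dataclass
class CutPointTable:
    """Stratum-specific deficit thresholds for the four measured components.

    ``thresholds`` maps component -> {stratum key -> threshold}.  Stratum keys
    are ``"all"`` (exhaustion), ``"female"``/``"male"`` (activity),
    ``"female|short"`` etc. (slowness) and ``"female|q1"`` .. ``"male|q5"``
    (weakness).  ``height_split_cm`` holds the per-sex mean heights and
    ``bmi_edges`` the per-sex inner BMI quintile edges used to route subjects
    to strata.  Deficit is always on the low side (value <= threshold).
    """

    thresholds: dict = field(default_factory=dict)
    height_split_cm: dict = field(default_factory=dict)
    bmi_edges: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "thresholds": self.thresholds,
            "height_split_cm": self.height_split_cm,
            "bmi_edges": {k: list(v) for k, v in self.bmi_edges.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CutPointTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            thresholds=d["thresholds"],
            height_split_cm=d.get("height_split_cm", {}),
            bmi_edges={k: np.asarray(v) for k, v in d.get("bmi_edges", {}).items()},
        )


def _first_quintile(values: np.ndarray, stratum: str) -> float:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise StratumError(f"empty stratum {stratum!r}")
    if values.size < 5:
        raise StratumError(
            f"stratum {stratum!r} has only {values.size} subjects (need >= 5)"
        )
    return float(np.quantile(values, 0.2, method="linear"))


def derive_cut_points(cohort: pd.DataFrame) -> CutPointTable:
    """Derive the per-stratum first-quintile thresholds from a cohort.

    Weight loss has no empirical threshold (the occurrence rule -- loss of at
    least 10% of usual weight or 4.5 kg -- is applied upstream and recorded in
    ``weight_lost_any``).
    """
    cuts = CutPointTable()
    sex = cohort["sex"].to_numpy()

    cuts.thresholds["exhaustion"] = {
        "all": _first_quintile(cohort["exhaustion"].to_numpy(), "all")
    }

    cuts.thresholds["activity"] = {}
    for s in ("female", "male"):
        mask = sex == s
        cuts.thresholds["activity"][s] = _first_quintile(
            cohort.loc[mask, "activity"].to_numpy(), f"activity:{s}"
        )

    cuts.thresholds["slowness"] = {}
    for s in ("female", "male"):
        mask = sex == s
        if not mask.any():
            raise StratumError(f"empty stratum 'slowness:{s}'")
        split = float(cohort.loc[mask, "height_cm"].mean())
        cuts.height_split_cm[s] = split
        for half, hmask in (
            ("short", cohort["height_cm"] <= split),
            ("tall", cohort["height_cm"] > split),
        ):
            m = mask & hmask.to_numpy()
            cuts.thresholds["slowness"][f"{s}|{half}"] = _first_quintile(
                cohort.loc[m, "gait"].to_numpy(), f"slowness:{s}|{half}"
            )

    cuts.thresholds["weakness"] = {}
    for s in ("female", "male"):
        mask = sex == s
        if not mask.any():
            raise StratumError(f"empty stratum 'weakness:{s}'")
        bmi = cohort.loc[mask, "bmi"].to_numpy()
        edges = np.quantile(bmi, [0.2, 0.4, 0.6, 0.8], method="linear")
        cuts.bmi_edges[s] = edges
        q = np.searchsorted(edges, bmi, side="left")  # 0..4
        grip = cohort.loc[mask, "grip"].to_numpy()
        for j in range(5):
            cuts.thresholds["weakness"][f"{s}|q{j + 1}"] = _first_quintile(
                grip[q == j], f"weakness:{s}|q{j + 1}"
            )
    return cuts


def _stratum_value(table: dict, key: str, component: str) -> float:
    try:
        return table[key]
    except KeyError:
        raise StratumError(
            f"subject falls in stratum {key!r} not covered by the "
            f"{component} cut-point table"
        ) from None


def dichotomize(cohort: pd.DataFrame, cuts: CutPointTable) -> pd.DataFrame:
    """Map a cohort to the n x 5 binary deficit matrix.

    A component is a deficit when it lies on the low side of its stratum
    threshold, boundary included.  Columns follow :data:`BINARY_COLUMNS`.
    """
    n = len(cohort)
    sex = cohort["sex"].to_numpy()
    out = np.zeros((n, 5), dtype=int)

    out[:, 0] = cohort["weight_lost_any"].to_numpy().astype(int)

    thr = cuts.thresholds["exhaustion"]["all"]
    out[:, 1] = (cohort["exhaustion"].to_numpy() <= thr).astype(int)

    act = cohort["activity"].to_numpy()
    for i in range(n):
        t = _stratum_value(cuts.thresholds["activity"], sex[i], "activity")
        out[i, 2] = act[i] <= t

    gait = cohort["gait"].to_numpy()
    height = cohort["height_cm"].to_numpy()
    for i in range(n):
        split = cuts.height_split_cm.get(sex[i])
        if split is None:
            raise StratumError(
                f"subject falls in stratum {sex[i]!r} not covered by the "
                "slowness cut-point table"
            )
        half = "short" if height[i] <= split else "tall"
        t = _stratum_value(cuts.thresholds["slowness"], f"{sex[i]}|{half}", "slowness")
        out[i, 3] = gait[i] <= t

    grip = cohort["grip"].to_numpy()
    bmi = cohort["bmi"].to_numpy()
    for i in range(n):
        edges = cuts.bmi_edges.get(sex[i])
        if edges is None:
            raise StratumError(
                f"subject falls in stratum {sex[i]!r} not covered by the "
                "weakness cut-point table"
            )
        q = int(np.searchsorted(edges, bmi[i], side="left")) + 1
        t = _stratum_value(cuts.thresholds["weakness"], f"{sex[i]}|q{q}", "weakness")
        out[i, 4] = grip[i] <= t

    return pd.DataFrame(out, columns=list(BINARY_COLUMNS), index=cohort.index)


def frailty_index(binary: pd.DataFrame) -> pd.DataFrame:
    """Deficit count and the robust / prefrail / frail label per subject."""
    arr = binary[list(BINARY_COLUMNS)].to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("binary component matrix must contain only 0/1")
    count = arr.sum(axis=1)
    label = np.where(count == 0, "robust", np.where(count <= 2, "prefrail", "frail"))
    return pd.DataFrame(
        {
            "deficit_count": count,
            "label": pd.Categorical(
                label, categories=["robust", "prefrail", "frail"], ordered=True
            ),
        },
        index=binary.index,
    )


# ---------------------------------------------------------------------------
# Continuous item encoding for the factor mixture model
# ---------------------------------------------------------------------------

#: Column order of the continuous item block.
ITEM_COLUMNS = ("exhaustion", "activity", "grip", "gait", "weight_loss_kg")


@dataclass
class FMMItemMatrix:
    """Six-item block: four continuous components (with censoring flags on
    gait), weight-loss occurrence, and weight-loss magnitude in kg (defined
    only for subjects with any loss; NaN otherwise)."""

    y: np.ndarray          # (n, 5) float; column 4 NaN when occurrence = 0
    censored: np.ndarray   # (n,) bool, gait at floor
    occurrence: np.ndarray  # (n,) 0/1
    floor: float           # gait censoring floor

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.occurrence = np.asarray(self.occurrence, dtype=int)
        n = self.y.shape[0]
        if self.y.shape != (n, 5):
            raise ValueError(f"item block must be (n, 5), got {self.y.shape}")
        if self.censored.shape != (n,) or self.occurrence.shape != (n,):
            raise ValueError("censoring/occurrence vectors must have length n")
        kg = self.y[:, 4]
        if np.any((self.occurrence == 0) & ~np.isnan(kg)):
            raise ValueError("magnitude must be missing iff occurrence = 0")
        if np.any((self.occurrence == 1) & ~(kg > 0)):
            raise ValueError("magnitude must be positive when occurrence = 1")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def to_cohort_block(self) -> pd.DataFrame:
        """Inverse of :func:`encode_fmm_items` on the component columns."""
        return pd.DataFrame(
            {
                "exhaustion": self.y[:, 0],
                "activity": self.y[:, 1],
                "grip": self.y[:, 2],
                "gait": self.y[:, 3],
                "gait_censored": self.censored,
                "weight_lost_any": self.occurrence,
                "weight_lost_kg": self.y[:, 4],
            }
        )


def encode_fmm_items(cohort: pd.DataFrame) -> FMMItemMatrix:
    """Deterministically re-encode the component block as FMM items."""
    kg = cohort["weight_lost_kg"].to_numpy(dtype=float)
    occ = cohort["weight_lost_any"].to_numpy().astype(int)
    if np.any(kg[occ == 1] < 0):
        raise ValueError("negative weight loss in kg")
    y = np.column_stack(
        [
            cohort["exhaustion"].to_numpy(dtype=float),
            cohort["activity"].to_numpy(dtype=float),
            cohort["grip"].to_numpy(dtype=float),
            cohort["gait"].to_numpy(dtype=float),
            np.where(occ == 1, kg, np.nan),
        ]
    )
    censored = cohort["gait_censored"].to_numpy().astype(bool)
    floor = cohort.attrs.get("gait_censor_floor")
    if floor is None:
        floor = float(y[censored, 3].min()) if censored.any() else -np.inf
    return FMMItemMatrix(y=y, censored=censored, occurrence=occ, floor=float(floor))
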