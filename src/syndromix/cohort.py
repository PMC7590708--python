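"""Synthetic five-component frailty cohorts.

Generates subject-level tables with the generative structure the downstream
analysis assumes: K latent classes mixing a one-factor Gaussian measurement
model over the five Fried phenotype components (exhaustion / SF-36 vitality,
physical activity / PASE, grip strength / vigorimeter, gait speed, and
unintentional weight loss), a left-censored gait-speed item, a two-part
(occurrence + magnitude) weight-loss item, sex-shifted component
distributions, and class-linked covariates.

The default configuration mirrors the published FRéLE four-class solution:
invariant intercepts and loadings with class-specific factor means, a small
frail class, and covariate gradients (age, disability, mortality) that run
monotonically from the frail to the robust class.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Component order used throughout the package for the continuous block.
COMPONENTS = ("exhaustion", "activity", "grip", "gait", "weight_loss_kg")
N_COMPONENTS = 5

#: Covariates drawn per class; (sampling law, dispersion for normals).
_COVARIATE_LAWS = {
    "age": ("normal", 6.0),
    "education": ("normal", 3.0),
    "self_rated_health": ("normal", 0.9),
    "chronic_diseases": ("poisson", None),
    "cognition": ("normal", 3.0),
    "depressed": ("bernoulli", None),
    "iadl_disability": ("bernoulli", None),
    "adl_disability": ("bernoulli", None),
    "deceased_3y": ("bernoulli", None),
}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Generative configuration for a synthetic frailty cohort.

    Class-level arrays are indexed frail-first: class 0 is the least healthy
    class (lowest factor mean) and class ``K_true - 1`` the most robust.
    """

    n_subjects: int
    K_true: int
    mixing: np.ndarray            # (K,) class probabilities
    intercepts: np.ndarray        # (K, 5) component intercepts, metric units
    loadings: np.ndarray          # (5,) factor loadings, anchor = exhaustion
    factor_means: np.ndarray      # (K,)
    factor_variances: np.ndarray  # (K,) > 0
    residual_variances: np.ndarray  # (K, 5) > 0
    gait_censor_floor: float      # cm/s; inability to walk recorded here
    weightloss_occurrence_logit: np.ndarray  # (K,) logit of P(any loss)
    weightloss_magnitude_mean_kg: np.ndarray  # (K,) mean kg among losers
    weightloss_magnitude_sd_kg: np.ndarray    # (K,) sd kg among losers
    sex_ratio: float = 0.5        # P(male)
    sex_shift: np.ndarray = field(
        default_factory=lambda: np.zeros(N_COMPONENTS)
    )                             # additive shift for males, per component
    height_mean_cm: tuple[float, float] = (155.81, 169.55)  # (women, men)
    height_sd_cm: tuple[float, float] = (6.5, 7.0)
    bmi_mean: float = 27.5
    bmi_sd: float = 4.8
    covariate_profiles: dict = field(default_factory=dict)  # name -> (K,) means
    seed: int = 20101             # study recruitment year; overridable

    def __post_init__(self) -> None:
        for name in (
            "mixing", "intercepts", "loadings", "factor_means",
            "factor_variances", "residual_variances",
            "weightloss_occurrence_logit", "weightloss_magnitude_mean_kg",
            "weightloss_magnitude_sd_kg", "sex_shift",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    def validate(self) -> None:
        K, C = self.K_true, N_COMPONENTS
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be a positive integer")
        if K < 1:
            raise ConfigurationError("K_true must be >= 1")
        shapes = {
            "mixing": (K,),
            "intercepts": (K, C),
            "loadings": (C,),
            "factor_means": (K,),
            "factor_variances": (K,),
            "residual_variances": (K, C),
            "weightloss_occurrence_logit": (K,),
            "weightloss_magnitude_mean_kg": (K,),
            "weightloss_magnitude_sd_kg": (K,),
            "sex_shift": (C,),
        }
        for name, shape in shapes.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ConfigurationError(
                    f"{name} has shape {arr.shape}, expected {shape}"
                )
        if abs(self.mixing.sum() - 1.0) > 1e-12:
            raise ConfigurationError("mixing must sum to 1 within 1e-12")
        if np.any(self.mixing < 0):
            raise ConfigurationError("mixing must be non-negative")
        if np.any(self.factor_variances <= 0):
            raise ConfigurationError("factor_variances must be > 0")
        if np.any(self.residual_variances <= 0):
            raise ConfigurationError("residual_variances must be > 0")
        if np.any(self.weightloss_magnitude_sd_kg <= 0):
            raise ConfigurationError("weightloss_magnitude_sd_kg must be > 0")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigurationError("sex_ratio must be a probability")
        for name, means in self.covariate_profiles.items():
            if name not in _COVARIATE_LAWS:
                raise ConfigurationError(f"unknown covariate_profiles entry {name!r}")
            if len(np.atleast_1d(means)) != K:
                raise ConfigurationError(
                    f"covariate_profiles[{name!r}] must have one value per class"
                )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif isinstance(v, dict):
                v = {k: list(np.atleast_1d(x)) for k, x in v.items()}
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("height_mean_cm", "height_sd_cm"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def analytic_class_means(config: CohortConfig, include_sex: bool = True) -> np.ndarray:
    """Population class means of the component block implied by the config.

    Returns a (K, 5) matrix ``I + loadings * factor_mean`` (the weight-loss
    column is the configured per-class magnitude mean among losers, since the
    generator draws kg from its own two-part law).  With ``include_sex`` the
    male component shift is averaged in at the configured sex ratio.
    Censoring of gait is not corrected for.
    """
    means = config.intercepts + np.outer(config.factor_means, config.loadings)
    means[:, 4] = config.weightloss_magnitude_mean_kg
    if include_sex:
        means = means + config.sex_ratio * config.sex_shift
    return means


def generate_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw a seeded synthetic cohort.

    Subjects are drawn class-first (categorical on the mixing weights), then a
    factor score Normal(alpha_k, psi_k), then components
    ``I_kc + F_c * eta + Normal(0, theta_kc)``.  Gait speed is left-censored at
    the configured floor; weight loss is two-part (Bernoulli occurrence with a
    log-normal magnitude in kg among losers); covariates are drawn from the
    class profile.  Identical seeds give bit-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, K = config.n_subjects, config.K_true

    cls = rng.choice(K, size=n, p=config.mixing / config.mixing.sum())
    eta = rng.normal(
        config.factor_means[cls], np.sqrt(config.factor_variances[cls])
    )
    noise = rng.standard_normal((n, N_COMPONENTS))
    y = (
        config.intercepts[cls]
        + np.outer(eta, config.loadings)
        + noise * np.sqrt(config.residual_variances[cls])
    )

    male = rng.random(n) < config.sex_ratio
    y = y + np.where(male[:, None], config.sex_shift[None, :], 0.0)

    gait = y[:, 3]
    censored = gait <= config.gait_censor_floor
    gait = np.where(censored, config.gait_censor_floor, gait)

    occ_p = 1.0 / (1.0 + np.exp(-config.weightloss_occurrence_logit[cls]))
    lost = rng.random(n) < occ_p
    m = config.weightloss_magnitude_mean_kg[cls]
    s = config.weightloss_magnitude_sd_kg[cls]
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    kg_all = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
    kg = np.where(lost, kg_all, np.nan)

    height = np.where(
        male,
        rng.normal(config.height_mean_cm[1], config.height_sd_cm[1], n),
        rng.normal(config.height_mean_cm[0], config.height_sd_cm[0], n),
    )
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)

    data = {
        "exhaustion": y[:, 0],
        "activity": y[:, 1],
        "grip": y[:, 2],
        "gait": gait,
        "gait_censored": censored,
        "weight_lost_any": lost.astype(int),
        "weight_lost_kg": kg,
        "sex": np.where(male, "male", "female"),
        "height_cm": height,
        "bmi": bmi,
    }
    for name, means in config.covariate_profiles.items():
        law, sd = _COVARIATE_LAWS[name]
        per = np.atleast_1d(np.asarray(means, dtype=float))[cls]
        if law == "normal":
            data[name] = rng.normal(per, sd)
        elif law == "poisson":
            data[name] = rng.poisson(per)
        else:  # bernoulli
            data[name] = (rng.random(n) < per).astype(int)
    data["true_class"] = cls

    df = pd.DataFrame(data)
    df.attrs["gait_censor_floor"] = float(config.gait_censor_floor)
    return df


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the CohortTable invariants; raise ``ValueError`` on violation."""
    comp = cohort[["exhaustion", "activity", "grip", "gait"]]
    if comp.isna().any().any():
        raise ValueError("missing values in the component block")
    lost = cohort["weight_lost_any"].to_numpy()
    kg = cohort["weight_lost_kg"].to_numpy()
    if np.any((lost == 1) & ~(kg > 0)):
        raise ValueError("weight_lost_kg must be > 0 when weight_lost_any = 1")
    if np.any((lost == 0) & ~np.isnan(kg)):
        raise ValueError("weight_lost_kg must be undefined when weight_lost_any = 0")


# ---------------------------------------------------------------------------
# Canned configurations
# ---------------------------------------------------------------------------

def default_config_frele(n_subjects: int = 1643, seed: int = 20101) -> CohortConfig:
    """FRéLE-like four-class configuration (categorical rendering of a continuum).

    Intercepts, loadings, factor means, class shares, per-class weight-loss
    occurrence rates and magnitude means are taken from the published
    four-class strong-invariance solution; classes are ordered frail (0) to
    robust (3).  Residual and factor variances, sex shifts and dispersions are
    package choices documented in the methods note.
    """
    K = 4
    intercepts = np.tile([43.15, 0.00, 34.77, 44.28, 7.05], (K, 1))
    cov = {
        "age": [83.3, 83.9, 78.0, 73.0],
        "education": [4.18, 4.55, 5.48, 6.30],
        "self_rated_health": [3.43, 3.23, 2.64, 2.06],
        "chronic_diseases": [4.70, 4.30, 3.10, 2.20],
        "cognition": [20.5, 22.3, 24.2, 25.5],
        "depressed": [0.651, 0.453, 0.150, 0.052],
        "iadl_disability": [0.995, 0.854, 0.348, 0.088],
        "adl_disability": [0.841, 0.495, 0.177, 0.071],
        "deceased_3y": [0.409, 0.229, 0.095, 0.049],
    }
    return CohortConfig(
        n_subjects=n_subjects,
        K_true=K,
        mixing=np.array([0.027, 0.251, 0.534, 0.188]),
        intercepts=intercepts,
        loadings=np.array([1.00, 4.10, 1.21, 2.17, -0.35]),
        factor_means=np.array([0.0, 8.5, 21.7, 32.2]),
        factor_variances=np.array([80.0, 55.0, 45.0, 35.0]),
        residual_variances=np.array(
            [
                [130.0, 1100.0, 150.0, 250.0, 9.0],
                [120.0, 1000.0, 130.0, 200.0, 9.0],
                [110.0, 900.0, 120.0, 160.0, 9.0],
                [100.0, 850.0, 110.0, 140.0, 9.0],
            ]
        ),
        gait_censor_floor=15.0,
        weightloss_occurrence_logit=_logit([0.386, 0.218, 0.095, 0.032]),
        weightloss_magnitude_mean_kg=np.array([12.1, 4.4, 3.9, 4.2]),
        weightloss_magnitude_sd_kg=np.array([6.0, 2.5, 2.0, 2.0]),
        sex_ratio=0.5,
        sex_shift=np.array([0.0, 8.0, 16.0, 4.0, 0.0]),
        covariate_profiles=cov,
        seed=seed,
    )


def config_one_class(n_subjects: int = 1643, seed: int = 20101) -> CohortConfig:
    """Homogeneous one-class cohort: a single factor, no latent classes.

    Sex shifts are zero here by design: an additive male shift on grip or
    activity is itself a two-group mixture on those components, which would
    contradict the homogeneity this configuration exists to represent.
    """
    cov = {
        "age": [78.0],
        "self_rated_health": [2.7],
        "chronic_diseases": [3.2],
        "deceased_3y": [0.13],
    }
    return CohortConfig(
        n_subjects=n_subjects,
        K_true=1,
        mixing=np.array([1.0]),
        intercepts=np.array([[55.0, 60.0, 50.0, 75.0, 5.0]]),
        loadings=np.array([1.00, 4.10, 1.21, 2.17, -0.35]),
        factor_means=np.array([5.0]),
        factor_variances=np.array([60.0]),
        residual_variances=np.array([[110.0, 900.0, 120.0, 170.0, 9.0]]),
        gait_censor_floor=15.0,
        weightloss_occurrence_logit=_logit([0.13]),
        weightloss_magnitude_mean_kg=np.array([5.0]),
        weightloss_magnitude_sd_kg=np.array([2.5]),
        sex_ratio=0.5,
        sex_shift=np.zeros(5),
        covariate_profiles=cov,
        seed=seed,
    )


def config_lca_3class(n_subjects: int = 1643, seed: int = 20101) -> CohortConfig:
    """Well-separated three-class profile cohort with a single gradient.

    Loadings are zero (pure latent profile structure); class mean vectors
    are ordered identically on every component (one gradient) but their
    between-class steps are deliberately far from proportional -- exhaustion
    and grip saturate early while activity and gait jump late -- so the
    class-mean matrix has strong rank-2 structure that no one-factor
    categorical model can absorb.  Residual variances shrink from the frail
    to the robust class (a genuinely unequal-variance profile).
    """
    cov = {
        "age": [84.0, 79.0, 74.0],
        "self_rated_health": [3.4, 2.8, 2.2],
        "chronic_diseases": [4.5, 3.2, 2.3],
        "deceased_3y": [0.35, 0.13, 0.05],
    }
    return CohortConfig(
        n_subjects=n_subjects,
        K_true=3,
        mixing=np.array([0.15, 0.45, 0.40]),
        intercepts=np.array(
            [
                [40.0, 15.0, 38.0, 45.0, 12.0],
                [68.0, 40.0, 62.0, 92.0, 6.0],
                [78.0, 140.0, 70.0, 110.0, 3.0],
            ]
        ),
        loadings=np.zeros(5),
        factor_means=np.zeros(3),
        factor_variances=np.ones(3),
        residual_variances=np.array(
            [
                [90.0, 560.0, 90.0, 140.0, 9.0],
                [64.0, 400.0, 64.0, 100.0, 6.0],
                [40.0, 250.0, 40.0, 64.0, 4.0],
            ]
        ),
        gait_censor_floor=15.0,
        weightloss_occurrence_logit=_logit([0.50, 0.22, 0.03]),
        weightloss_magnitude_mean_kg=np.array([12.0, 6.0, 3.0]),
        weightloss_magnitude_sd_kg=np.array([5.0, 2.5, 1.5]),
        sex_ratio=0.5,
        sex_shift=np.array([0.0, 8.0, 16.0, 4.0, 0.0]),
        covariate_profiles=cov,
        seed=seed,
    )


FIXTURE_CONFIGS = {
    "one_class": config_one_class,
    "lca_3class": config_lca_3class,
    "somi_4class": default_config_frele,
}


def _logit(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))
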