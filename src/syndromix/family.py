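"""The measurement-invariance model family for factor mixture models.

Seven basic models are spanned by a family label, a class count K and a
residual-variance regime (``ev`` equal / ``uv`` unequal across classes):

* ``LCA`` -- latent class / profile analysis: no factor block, class-specific
  intercepts; ev or uv.
* ``SiMI`` -- strict measurement invariance: intercepts, loadings, residual
  variances and the factor variance all invariant; classes differ only in the
  factor mean (ev by definition).
* ``SoMI`` -- strong measurement invariance: intercepts and loadings
  invariant, residual and factor variances free to differ (classes remain a
  categorical rendering of a single continuum).
* ``WMI`` -- weak invariance: loadings invariant, intercepts class-specific.
* ``NMI`` -- no invariance: loadings and intercepts both class-specific.

With K > 1, SiMI/SoMI are null hypotheses (categorical approximation of a
continuous process); LCA/WMI/NMI are non-null (true heterogeneity); any
K = 1 model is the one-class null.

Identification rules used for parameter counting and estimation:

* the anchor loading (exhaustion) is fixed at 1 (per class under NMI);
* under SiMI/SoMI the last class's factor mean is fixed at 0 and the K - 1
  remaining means are free;
* under WMI/NMI all factor means are fixed at 0 (absorbed by the
  class-specific intercepts);
* the weight-loss occurrence logit follows the intercept block (invariant
  when intercepts are invariant) and carries no factor loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FAMILIES = ("LCA", "SiMI", "SoMI", "WMI", "NMI")
NULL_ONE_CLASS = "null-one-class"
NULL_CATEGORICAL = "null-categorical-approximation"
NON_NULL = "non-null"

#: Item-model tags.  ``gaussian`` items contribute a Normal density,
#: ``censored-gaussian`` a Tobit-type left-censored Normal, ``bernoulli`` a
#: class-level occurrence probability and ``two-part-magnitude`` a Normal
#: defined only when the paired occurrence item equals one.
DEFAULT_ITEM_MODELS = (
    "gaussian",            # exhaustion (anchor)
    "gaussian",            # physical activity
    "gaussian",            # grip strength
    "censored-gaussian",   # gait speed
    "two-part-magnitude",  # weight loss in kg
)
GAUSSIAN_ITEM_MODELS = ("gaussian",) * 5


class IllegalSpecError(ValueError):
    """A family / K / variance combination outside the seven basic models."""


@dataclass(frozen=True)
class FMMSpec:
    """One member of the model family, fully expanded into block templates."""

    family: str
    K: int
    variance: str                      # 'ev' | 'uv'
    item_models: tuple = DEFAULT_ITEM_MODELS
    # expanded constraint template
    has_factor: bool = field(init=False)
    intercepts_vary: bool = field(init=False)
    loadings_vary: bool = field(init=False)
    residuals_vary: bool = field(init=False)
    factor_variance_vary: bool = field(init=False)
    n_free_factor_means: int = field(init=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise IllegalSpecError(f"unknown family {self.family!r}")
        if self.K < 1:
            raise IllegalSpecError("K must be >= 1")
        if self.variance not in ("ev", "uv"):
            raise IllegalSpecError("variance must be 'ev' or 'uv'")
        if self.family == "SiMI" and self.variance == "uv":
            raise IllegalSpecError(
                "SiMI requires equal residual variances: strict invariance "
                "adds equal residuals to strong invariance, so SiMI-uv is "
                "not a member of the family (use SoMI-uv)"
            )
        has_factor = self.family != "LCA"
        object.__setattr__(self, "has_factor", has_factor)
        object.__setattr__(
            self, "intercepts_vary", self.family in ("LCA", "WMI", "NMI") and self.K > 1
        )
        object.__setattr__(
            self, "loadings_vary", self.family == "NMI" and self.K > 1
        )
        object.__setattr__(
            self, "residuals_vary", self.variance == "uv" and self.K > 1
        )
        object.__setattr__(
            self,
            "factor_variance_vary",
            has_factor and self.variance == "uv" and self.K > 1,
        )
        object.__setattr__(
            self,
            "n_free_factor_means",
            self.K - 1 if (has_factor and self.family in ("SiMI", "SoMI")) else 0,
        )

    @property
    def label(self) -> str:
        return f"{self.family}-{self.variance} K={self.K}"

    def with_K(self, K: int) -> "FMMSpec":
        return build_spec(self.family, K, self.variance, self.item_models)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "K": self.K,
            "variance": self.variance,
            "item_models": list(self.item_models),
            "null_status": hypothesis_role(self),
            "n_params": count_parameters(self),
        }


def build_spec(
    family: str,
    K: int,
    variance: str = "uv",
    item_models: tuple = DEFAULT_ITEM_MODELS,
) -> FMMSpec:
    """Construct and validate a family member."""
    return FMMSpec(family=family, K=K, variance=variance, item_models=tuple(item_models))


def _item_blocks(item_models: tuple) -> tuple[int, int, int]:
    """(# continuous items, # with a free-able loading, # occurrence items)."""
    n_cont = sum(m != "bernoulli" for m in item_models)
    n_occ = sum(m == "two-part-magnitude" for m in item_models)
    return n_cont, n_cont, n_occ


def count_parameters(spec: FMMSpec) -> int:
    """Number of free parameters under this package's identification rules.

    Binary-indicator LCA (all items ``bernoulli``) has 5K + (K - 1)
    parameters.  For continuous items each of the K x C blocks contributes
    according to the invariance template; the anchor loading and the fixed
    factor means are not counted.
    """
    K = spec.K
    if all(m == "bernoulli" for m in spec.item_models):
        return len(spec.item_models) * K + (K - 1)

    n_cont, _, n_occ = _item_blocks(spec.item_models)
    count = K - 1  # mixing
    count += n_cont * (K if spec.intercepts_vary else 1)
    # occurrence logits are classification parameters in every family:
    # the item carries no factor loading, so class variation in occurrence
    # can only enter through class-specific thresholds
    count += n_occ * K
    if spec.has_factor:
        free_load = n_cont - 1  # anchor fixed to 1
        count += free_load * (K if spec.loadings_vary else 1)
        count += spec.n_free_factor_means
        count += K if spec.factor_variance_vary else 1
    count += n_cont * (K if spec.residuals_vary else 1)
    return count


def hypothesis_role(spec: FMMSpec) -> str:
    """Map a spec to its null / non-null status in the syndrome test."""
    if spec.K == 1:
        return NULL_ONE_CLASS
    if spec.family in ("SiMI", "SoMI"):
        return NULL_CATEGORICAL
    return NON_NULL


def is_nested(null: FMMSpec, alt: FMMSpec) -> bool:
    """True when ``null`` is a constrained version of ``alt``.

    Covers the pairs the selection machinery tests: fewer classes within one
    family/variance; ev within uv at equal family and K; and the invariance
    ladder SiMI < SoMI < WMI < NMI at equal K (each relaxes constraints of
    the previous), with LCA K=1 nested in any one-class model on the same
    items.
    """
    if null.item_models != alt.item_models:
        return False
    if null.K > alt.K:
        return False
    ladder = {"SiMI": 0, "SoMI": 1, "WMI": 2, "NMI": 3}
    if null.family == alt.family:
        if null.variance == "uv" and alt.variance == "ev":
            return False
        return True
    if null.K == 1:
        return True
    if null.family in ladder and alt.family in ladder:
        if ladder[null.family] <= ladder[alt.family]:
            return not (null.variance == "uv" and alt.variance == "ev")
    return False


def family_table(K: int = 2) -> list[dict]:
    """The seven basic models with roles and parameter counts at a given K."""
    rows = []
    combos = [
        ("LCA", 1, "ev"), ("SiMI", 1, "ev"),
        ("LCA", K, "ev"), ("LCA", K, "uv"),
        ("SiMI", K, "ev"), ("SoMI", K, "uv"),
        ("WMI", K, "uv"), ("NMI", K, "uv"),
    ]
    for fam, k, var in combos:
        spec = build_spec(fam, k, var)
        rows.append(spec.to_dict())
    return rows
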