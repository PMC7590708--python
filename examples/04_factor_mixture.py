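"""Fit factor mixture models under different invariance templates.

Compares a strong-invariance model (classes differ only in their factor
mean: a categorical rendering of one continuum) against a latent-profile
model (free class intercepts, no factor) on the continuous items.
"""

import syndromix as sx

cohort = sx.generate_cohort(sx.default_config_frele(seed=20101))
items = sx.encode_fmm_items(cohort)

somi = sx.fit_fmm(items, sx.build_spec("SoMI", 4, "uv"),
                  n_starts=4, seed=1, quadrature_points=15)
lpa = sx.fit_fmm(items, sx.build_spec("LCA", 4, "uv"),
                 n_starts=4, seed=2)

for name, fit in (("SoMI-uv (4)", somi), ("LPA-uv (4)", lpa)):
    print(f"{name}: loglik {fit.loglik:.1f}  BIC {fit.bic:.1f}  "
          f"entropy {fit.entropy:.3f}  params {fit.n_params}")

print(f"\nBIC difference (SoMI - LPA): {somi.bic - lpa.bic:.1f}  "
      "(negative favours the continuum rendering)")
print("\nSoMI loadings (anchor = exhaustion):",
      somi.params.loadings[0].round(2))
print("SoMI class factor means (frail -> robust):",
      somi.params.alpha.round(1))

# On cohorts generated from a single-factor continuum the strong-invariance
# model wins the BIC comparison despite the profile model's extra
# class-specific intercepts, and its entropy is modest: the classes are
# slices of a continuum, not well-separated syndromic groups.
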