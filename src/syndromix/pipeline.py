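"""End-to-end structural-validity pipeline for syndromic frailty.

Runs the eight analytical steps on a subject-level cohort:

1. cut points, dichotomization and a 3-class latent class analysis of the
   binary components;
2. confirmatory one- versus two-factor comparison on the continuous items;
3. one-class null against two classes for every family member (BIC + BLRT);
4. search for the minimal acceptable class count per family, stopping on
   degenerate solutions;
5. equal against unequal residual-variance variants;
6. ordering of class-specific intercepts across components, excluding models
   whose components are ordered differently (multiple putative syndromes);
7. surviving heterogeneity models against the strong-invariance null
   (a categorical rendering of a single continuum);
8. class profiles on components and risk factors for the final model and for
   the classic robust / prefrail / frail index.

The verdict is ``homogeneous`` when no family rejects the one-class null,
``categorical-approximation-of-continuum`` when the strong-invariance null
survives step 7, and ``syndromic`` when a single-gradient heterogeneity
model beats it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import prep
from .family import build_spec, hypothesis_role, NON_NULL
from .fmm import (
    compare_factor_dimension,
    fit_fmm,
    posterior_probs,
    split_class_params,
)
from .lca import fit_binary_lca, lca_goodness_of_fit
from .selection import blrt, ComparisonLedger, ComparisonEntry

VERDICT_HOMOGENEOUS = "homogeneous"
VERDICT_CATEGORICAL = "categorical-approximation-of-continuum"
VERDICT_SYNDROMIC = "syndromic"

#: Direction of health per ordering column: +1 when a higher value is
#: healthier, -1 when a higher value marks a deficit.  Stored in the config,
#: overridable.
DEFAULT_DIRECTIONS = {
    "exhaustion": +1.0,
    "activity": +1.0,
    "grip": +1.0,
    "gait": +1.0,
    "weight_loss_kg": -1.0,
    "weight_loss_occurrence": -1.0,
}

#: The Table-3-shaped family battery: (family, variance) pairs.
DEFAULT_FAMILIES = (
    ("LCA", "ev"), ("LCA", "uv"),
    ("SiMI", "ev"), ("SoMI", "uv"),
    ("WMI", "ev"), ("WMI", "uv"),
    ("NMI", "ev"), ("NMI", "uv"),
)

#: Verdict-relevant battery used by the reduced profile: the unequal-variance
#: member of each heterogeneity family plus the two invariance nulls.  The
#: equal-variance variants only ever compete in step 5 and are dominated on
#: heteroscedastic data; the full default battery retains them.
REDUCED_FAMILIES = (
    ("LCA", "uv"), ("SiMI", "ev"), ("SoMI", "uv"),
    ("WMI", "uv"), ("NMI", "uv"),
)


# ---------------------------------------------------------------------------
# Ordering of classification parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderingReport:
    permutations: dict          # component -> tuple of class ranks
    groups: dict                # permutation tuple (as str) -> [components]
    verdict: str                # 'single-gradient' | 'multiple-orderings'

    def to_dict(self) -> dict:
        return {
            "permutations": {k: list(v) for k, v in self.permutations.items()},
            "groups": {k: list(v) for k, v in self.groups.items()},
            "verdict": self.verdict,
        }


def _rank_with_ties(values: np.ndarray, tol: float) -> tuple:
    """Dense ranks of classes; values within ``tol`` share a rank."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    rank = 0
    prev = None
    for pos, idx in enumerate(order):
        if prev is not None and values[idx] - prev > tol:
            rank += 1
        ranks[idx] = rank
        prev = values[idx]
    return tuple(int(r) for r in ranks)


def ordering_check(
    intercepts: np.ndarray,
    directions=None,
    components=None,
    tol: float = 1e-6,
) -> OrderingReport:
    """Compare the class ordering induced by each component's intercepts.

    ``intercepts`` is K x C; ``directions`` aligns every column so that a
    larger aligned value means healthier.  Ties within ``tol`` collapse to a
    shared rank.  The verdict is single-gradient exactly when all components
    induce one and the same class ranking.
    """
    intercepts = np.asarray(intercepts, dtype=float)
    K, C = intercepts.shape
    if K < 2:
        raise ValueError("ordering requires at least two classes")
    if components is None:
        components = [f"component_{c}" for c in range(C)]
    if directions is None:
        dirs = np.ones(C)
    elif isinstance(directions, dict):
        dirs = np.array([directions.get(name, 1.0) for name in components])
    else:
        dirs = np.asarray(directions, dtype=float)
    aligned = intercepts * dirs[None, :]

    permutations = {}
    groups: dict[tuple, list] = {}
    for c, name in enumerate(components):
        perm = _rank_with_ties(aligned[:, c], tol)
        permutations[name] = perm
        groups.setdefault(perm, []).append(name)
    verdict = "single-gradient" if len(groups) == 1 else "multiple-orderings"
    return OrderingReport(
        permutations=permutations,
        groups={str(k): v for k, v in groups.items()},
        verdict=verdict,
    )


def ordering_matrix_from_fit(fit) -> tuple[np.ndarray, list]:
    """Class-specific classification parameters of a fitted model, with the
    occurrence logit appended when a two-part item is present."""
    p = fit.params
    cols = list(prep.ITEM_COLUMNS[: p.intercepts.shape[1]])
    mat = p.intercepts.copy()
    if p.occ_logit is not None:
        mat = np.column_stack([mat, p.occ_logit])
        cols.append("weight_loss_occurrence")
    return mat, cols


# ---------------------------------------------------------------------------
# Class profiles
# ---------------------------------------------------------------------------

def profile_classes(assignments, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-class means / rates on components and covariates.

    Weight loss is profiled as the occurrence rate plus the mean magnitude
    among losers.  Empty classes yield a zero-size row flagged in the
    ``empty`` column.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != len(cohort):
        raise ValueError("one assignment per subject required")
    K = int(assignments.max()) + 1
    n = len(cohort)
    rows = []
    numeric = [
        c for c in cohort.columns
        if c not in ("sex", "true_class", "weight_lost_kg", "weight_lost_any",
                     "gait_censored")
        and np.issubdtype(cohort[c].dtype, np.number)
    ]
    for k in range(K):
        sel = assignments == k
        size = int(sel.sum())
        row = {"class": k + 1, "size": size, "share": size / n, "empty": size == 0}
        if size:
            sub = cohort.loc[sel]
            for c in numeric:
                row[c] = float(sub[c].mean())
            row["pct_male"] = float((sub["sex"] == "male").mean())
            row["weight_loss_rate"] = float(sub["weight_lost_any"].mean())
            losers = sub["weight_lost_any"] == 1
            row["weight_loss_kg_mean"] = (
                float(sub.loc[losers, "weight_lost_kg"].mean()) if losers.any()
                else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")


# ---------------------------------------------------------------------------
# Pipeline configuration and report
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    alpha: float = 0.05
    B_blrt: int = 1000
    K_max: int = 5
    n_starts: int = 50
    replicate_starts: int = 2
    quadrature_points: int = 21
    max_iter: int = 500
    replicate_max_iter: int = 150
    replicate_tol: float = 1e-6
    early_stop_blrt: bool = True
    families: tuple = DEFAULT_FAMILIES
    directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    ordering_tol: float = 1e-6
    min_class_count: float = 5.0
    seed: int = 0

    @classmethod
    def fast_profile(cls, seed: int = 0, B: int = 19) -> "PipelineConfig":
        """Reduced-scale profile: smaller bootstrap, coarser quadrature and
        fewer starts; decision logic identical."""
        return cls(
            B_blrt=B, K_max=3, n_starts=2, replicate_starts=1,
            quadrature_points=11, max_iter=400, replicate_max_iter=200,
            replicate_tol=1e-6, families=REDUCED_FAMILIES, seed=seed,
        )


@dataclass
class PipelineReport:
    verdict: str
    steps: dict
    ledger: ComparisonLedger
    config: PipelineConfig
    truncated_at: int | None = None

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["families"] = [list(f) for f in self.config.families]
        return {
            "verdict": self.verdict,
            "steps": self.steps,
            "ledger": self.ledger.to_dict(),
            "config": cfg,
            "truncated_at": self.truncated_at,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineReport":
        cfg = dict(d["config"])
        cfg["families"] = tuple(tuple(f) for f in cfg["families"])
        ledger = ComparisonLedger(alpha=d["ledger"]["alpha"])
        for e in d["ledger"]["entries"]:
            ledger.add(ComparisonEntry(**e))
        return cls(
            verdict=d["verdict"], steps=d["steps"], ledger=ledger,
            config=PipelineConfig(**cfg), truncated_at=d.get("truncated_at"),
        )


# ---------------------------------------------------------------------------
# Eight steps
# ---------------------------------------------------------------------------

def _spec_label(fam: str, var: str, K: int) -> str:
    return f"{fam}-{var}({K})"


def run_eight_steps(cohort: pd.DataFrame, config: PipelineConfig | None = None
                    ) -> PipelineReport:
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    steps: dict = {}
    ledger = ComparisonLedger(alpha=cfg.alpha)
    alpha_stop = cfg.alpha if cfg.early_stop_blrt else None

    try:
        # ---- step 1: dichotomized 3-class LCA -------------------------
        cuts = prep.derive_cut_points(cohort)
        binary = prep.dichotomize(cohort, cuts)
        index = prep.frailty_index(binary)
        lca_fits = {
            K: fit_binary_lca(binary, K, n_starts=max(cfg.n_starts, 10),
                              seed=int(rng.integers(2**31 - 1)))
            for K in (1, 2, 3)
        }
        steps[1] = {
            "deficit_prevalence": binary.mean().round(4).to_dict(),
            "fried_shares": index["label"].value_counts(normalize=True)
            .round(4).to_dict(),
            "lca": {
                K: {
                    "loglik": f.loglik, "bic": f.bic,
                    **lca_goodness_of_fit(f),
                }
                for K, f in lca_fits.items()
            },
        }

        # ---- step 2: factor dimension ---------------------------------
        items = prep.encode_fmm_items(cohort)
        cfa = compare_factor_dimension(items, seed=int(rng.integers(2**31 - 1)))
        steps[2] = {"cfa_one_vs_two_factors": cfa}

        # ---- steps 3-5: family battery --------------------------------
        fits: dict[str, object] = {}
        blrts: dict[tuple, object] = {}

        def get_fit(fam, var, K):
            # all one-class factor models coincide; so do one-class profiles
            if K == 1:
                alias = ("LCA", "ev", 1) if fam == "LCA" else ("SiMI", "ev", 1)
                fam, var, K = alias
            label = _spec_label(fam, var, K)
            if label not in fits:
                spec = build_spec(fam, K, var)
                # seed the search with a split of the (K-1)-class solution
                # alongside the fresh k-means starts
                init = None
                prev = fits.get(_spec_label(fam, var, K - 1)) if K > 2 else None
                if prev is not None and not prev.degenerate:
                    init = split_class_params(prev.params)
                fits[label] = fit_fmm(
                    items, spec, n_starts=cfg.n_starts,
                    seed=int(rng.integers(2**31 - 1)), max_iter=cfg.max_iter,
                    quadrature_points=cfg.quadrature_points,
                    min_class_count=cfg.min_class_count,
                    init_params=init,
                )
            return label, fits[label]

        def run_blrt(fam, var, K_alt, K_null):
            la, fa = get_fit(fam, var, K_alt)
            ln, fn = get_fit(fam, var, K_null)
            key = (ln, la)
            if key not in blrts:
                blrts[key] = blrt(
                    items, fa.spec, fn.spec, B=cfg.B_blrt,
                    n_starts=cfg.replicate_starts,
                    seed=int(rng.integers(2**31 - 1)),
                    fit_null=fn, fit_alt=fa,
                    replicate_max_iter=cfg.replicate_max_iter,
                    replicate_tol=cfg.replicate_tol,
                    quadrature_points=cfg.quadrature_points,
                    alpha_stop=alpha_stop,
                )
            return blrts[key]

        step3 = {}
        rejected_one_class = {}
        for fam, var in cfg.families:
            l1, f1 = get_fit(fam, var, 1)
            l2, f2 = get_fit(fam, var, 2)
            if f2.degenerate:
                rejected_one_class[(fam, var)] = False
                step3[f"{fam}-{var}"] = {"degenerate_at_2": True}
                continue
            res = run_blrt(fam, var, 2, 1)
            rej = res.p_value <= cfg.alpha
            rejected_one_class[(fam, var)] = rej
            step3[f"{fam}-{var}"] = {
                "bic_1": f1.bic, "bic_2": f2.bic, "bic_diff": f2.bic - f1.bic,
                "blrt_p": res.p_value, "reject_one_class": bool(rej),
            }
        steps[3] = step3

        # ---- step 4: minimal acceptable K -----------------------------
        selected = {}
        step4 = {}
        for fam, var in cfg.families:
            if not rejected_one_class[(fam, var)]:
                selected[(fam, var)] = 1
                step4[f"{fam}-{var}"] = {"selected_K": 1}
                continue
            K = 2
            notes = []
            while K < cfg.K_max:
                _, fnext = get_fit(fam, var, K + 1)
                if fnext.degenerate:
                    notes.append(
                        f"search stopped at K={K + 1}: smallest class expected "
                        f"count below {cfg.min_class_count:g}"
                    )
                    break
                res = run_blrt(fam, var, K + 1, K)
                if res.p_value <= cfg.alpha:
                    K += 1
                else:
                    break
            selected[(fam, var)] = K
            step4[f"{fam}-{var}"] = {"selected_K": K, "notes": notes}
        steps[4] = step4

        # ---- step 5: ev against uv ------------------------------------
        step5 = {}
        branch_winner = {}
        pairs = [("LCA", "LCA"), ("SiMI", "SoMI"), ("WMI", "WMI"), ("NMI", "NMI")]
        for fam_ev, fam_uv in pairs:
            have_ev = (fam_ev, "ev") in selected
            have_uv = (fam_uv, "uv") in selected
            if not (have_ev and have_uv):
                # reduced batteries may carry only one variance variant;
                # its selected model wins the branch by default
                if have_uv:
                    K_uv = selected[(fam_uv, "uv")]
                    branch_winner[fam_uv] = (fam_uv, "uv", K_uv)
                    step5[f"{fam_uv}"] = {
                        "winner": _spec_label(fam_uv, "uv", K_uv),
                        "note": "single variance variant in battery",
                    }
                elif have_ev:
                    K_ev = selected[(fam_ev, "ev")]
                    branch_winner[fam_uv] = (fam_ev, "ev", K_ev)
                    step5[f"{fam_uv}"] = {
                        "winner": _spec_label(fam_ev, "ev", K_ev),
                        "note": "single variance variant in battery",
                    }
                continue
            K_ev, K_uv = selected[(fam_ev, "ev")], selected[(fam_uv, "uv")]
            l_ev, f_ev = get_fit(fam_ev, "ev", K_ev)
            l_uv, f_uv = get_fit(fam_uv, "uv", K_uv)
            if K_ev == 1 and K_uv == 1:
                branch_winner[fam_uv] = (fam_ev, "ev", 1)
                step5[f"{fam_uv}"] = {"winner": l_ev, "note": "one-class"}
                continue
            if K_ev <= K_uv:
                res = blrt(
                    items, f_uv.spec, f_ev.spec, B=cfg.B_blrt,
                    n_starts=cfg.replicate_starts,
                    seed=int(rng.integers(2**31 - 1)),
                    fit_null=f_ev, fit_alt=f_uv,
                    replicate_max_iter=cfg.replicate_max_iter,
                    replicate_tol=cfg.replicate_tol,
                    quadrature_points=cfg.quadrature_points,
                    alpha_stop=alpha_stop,
                )
                blrts[(l_ev, l_uv)] = res
                uv_wins = res.p_value <= cfg.alpha
                p_rec = res.p_value
            else:
                # ev branch settled on more classes than uv: the selected
                # pair is not nested, so BIC decides
                uv_wins = f_uv.bic < f_ev.bic
                p_rec = None
                ledger.add(ComparisonEntry(
                    label=f"{l_uv} vs {l_ev}",
                    model_a=l_uv, model_b=l_ev, bic_a=f_uv.bic, bic_b=f_ev.bic,
                    bic_diff=f_uv.bic - f_ev.bic, blrt_p=None,
                    decision=l_uv if uv_wins else l_ev,
                    rationale=(
                        "selected class counts make the pair non-nested; "
                        f"decided by BIC diff={f_uv.bic - f_ev.bic:.1f}"
                    ),
                ))
            winner = (fam_uv, "uv", K_uv) if uv_wins else (fam_ev, "ev", K_ev)
            branch_winner[fam_uv] = winner
            step5[f"{fam_uv}"] = {
                "winner": _spec_label(*winner), "blrt_p": p_rec,
                "bic_diff_uv_minus_ev": f_uv.bic - f_ev.bic,
            }
        steps[5] = step5

        for (null_l, alt_l), res in blrts.items():
            fa, fn = fits[alt_l], fits[null_l]
            rej = res.p_value <= cfg.alpha
            ledger.add(ComparisonEntry(
                label=f"{alt_l} vs {null_l}",
                model_a=alt_l, model_b=null_l, bic_a=fa.bic, bic_b=fn.bic,
                bic_diff=fa.bic - fn.bic, blrt_p=res.p_value,
                decision=alt_l if rej else null_l,
                rationale=(
                    f"nested pair decided by BLRT p={res.p_value:.4g} at "
                    f"alpha={cfg.alpha}; BIC diff={fa.bic - fn.bic:.1f}"
                ),
            ))

        # ---- step 6: component ordering -------------------------------
        step6 = {}
        surviving_non_null = []
        for fam in ("LCA", "WMI", "NMI"):
            win = branch_winner.get(fam)
            if win is None or win[2] < 2:
                continue
            label, fit = get_fit(*win)
            if hypothesis_role(fit.spec) != NON_NULL:
                continue
            mat, cols = ordering_matrix_from_fit(fit)
            rep = ordering_check(mat, cfg.directions, cols, cfg.ordering_tol)
            step6[label] = rep.to_dict()
            if rep.verdict == "single-gradient":
                surviving_non_null.append(win)
            else:
                step6[label]["excluded"] = True
        steps[6] = step6

        # ---- step 7: against the strong-invariance null ----------------
        # The null is the winning categorical-approximation model, or the
        # one-class factor model when no class split survived in that branch.
        null_branch = branch_winner.get("SoMI")
        if null_branch is None or null_branch[2] < 2:
            null_branch = ("SiMI", "ev", 1)
        null_label, null_fit = get_fit(*null_branch)
        step7 = {}
        null_rejected = False
        for win in surviving_non_null:
            label, fit = get_fit(*win)
            diff = fit.bic - null_fit.bic
            rejects = diff < 0
            null_rejected |= rejects
            step7[label] = {
                "bic": fit.bic, "null_bic": null_fit.bic, "bic_diff": diff,
                "rejects_null": bool(rejects),
            }
            ledger.add(ComparisonEntry(
                label=f"{label} vs {null_label} (null)",
                model_a=label, model_b=null_label,
                bic_a=fit.bic, bic_b=null_fit.bic, bic_diff=diff,
                blrt_p=None, decision=label if rejects else null_label,
                rationale=(
                    "non-nested comparison with the "
                    + ("categorical-approximation" if null_branch[2] >= 2
                       else "one-class")
                    + f" null decided by BIC diff={diff:.1f}"
                ),
            ))
        steps[7] = step7

        # ---- verdict ----------------------------------------------------
        # One-class homogeneity is judged within the factor framework: a
        # class-free profile model over-extracts classes whenever a
        # continuous gradient is present, so its one-class rejection alone
        # does not establish heterogeneity (any surviving profile model
        # still competes against the null in step 7).
        factor_reject_one = any(
            rej for (fam, _v), rej in rejected_one_class.items() if fam != "LCA"
        )
        if null_rejected:
            verdict = VERDICT_SYNDROMIC
        elif factor_reject_one and null_branch[2] >= 2:
            verdict = VERDICT_CATEGORICAL
        else:
            verdict = VERDICT_HOMOGENEOUS

        # ---- step 8: profiles ------------------------------------------
        if verdict == VERDICT_SYNDROMIC:
            best = min(
                surviving_non_null,
                key=lambda win: get_fit(*win)[1].bic,
            )
            final_label, final_fit = get_fit(*best)
        else:
            final_label, final_fit = get_fit(*null_branch)
        _, modal = posterior_probs(final_fit, items)
        fried_codes = index["label"].cat.codes.to_numpy()
        steps[8] = {
            "final_model": final_label,
            "final_entropy": None if np.isnan(final_fit.entropy)
            else final_fit.entropy,
            "class_profile": profile_classes(modal, cohort)
            .reset_index().to_dict(orient="records"),
            "fried_profile": profile_classes(fried_codes, cohort)
            .reset_index().to_dict(orient="records"),
        }
        steps["fits_bic"] = {
            label: {"bic": f.bic, "loglik": f.loglik, "K": f.spec.K,
                    "entropy": None if np.isnan(f.entropy) else f.entropy,
                    "degenerate": f.degenerate}
            for label, f in fits.items()
        }
        return PipelineReport(verdict=verdict, steps=_plainify(steps),
                              ledger=ledger, config=cfg)
    except Exception as exc:  # truncation with diagnostics, not a crash
        done = max([k for k in steps if isinstance(k, int)], default=0)
        steps["error"] = f"{type(exc).__name__}: {exc}"
        return PipelineReport(
            verdict="undetermined", steps=_plainify(steps), ledger=ledger,
            config=cfg, truncated_at=done + 1,
        )


def _plainify(obj):
    """Recursively convert numpy scalars / arrays for JSON round-tripping."""
    if isinstance(obj, dict):
        return {str(k): _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_report(report: PipelineReport, out_dir) -> dict:
    """Write the machine (JSON) and human (markdown) renderings; returns the
    file paths."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jpath = out / "report.json"
    with open(jpath, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)

    lines = ["# Syndromic-frailty structural validity report", ""]
    lines.append(f"**Verdict:** `{report.verdict}`")
    if report.truncated_at is not None:
        lines.append(f"**Truncated at step {report.truncated_at}**")
        lines.append(f"Error: {report.steps.get('error', 'unknown')}")
    lines.append("")

    s1 = report.steps.get("1")
    if s1:
        lines += ["## Step 1 - dichotomized latent class analysis", ""]
        lines.append("| K | log-likelihood | chi-square | df | BIC |")
        lines.append("|---|---|---|---|---|")
        for K, row in sorted(s1["lca"].items(), key=lambda kv: -int(kv[0])):
            lines.append(
                f"| {K} | {row['loglik']:.1f} | {row['chi2']:.1f} "
                f"| {row['df']} | {row['bic']:.1f} |"
            )
        lines.append("")

    s2 = report.steps.get("2")
    if s2:
        cfa = s2["cfa_one_vs_two_factors"]
        lines += [
            "## Step 2 - factor dimension",
            "",
            f"One vs two factors: chi2 = {cfa['chi2']:.2f}, df = {cfa['df']},"
            f" p = {cfa['p']:.3f}",
            "",
        ]

    if report.ledger.entries:
        lines += ["## Model comparisons", ""]
        lines.append("| comparison | BIC diff | BLRT p | decision |")
        lines.append("|---|---|---|---|")
        for e in report.ledger.entries:
            ptxt = "-" if e.blrt_p is None else f"{e.blrt_p:.4g}"
            lines.append(
                f"| {e.label} | {e.bic_diff:.1f} | {ptxt} | {e.decision} |"
            )
        lines.append("")
    else:
        lines += ["## Model comparisons", "", "No comparisons were run.", ""]

    s8 = report.steps.get("8")
    if s8:
        lines += ["## Final model class profile", ""]
        lines.append(f"Final model: `{s8['final_model']}`")
        prof = pd.DataFrame(s8["class_profile"])
        lines.append("")
        lines.append(prof.round(2).to_markdown(index=False))
        lines.append("")

    mpath = out / "report.md"
    mpath.write_text("\n".join(lines))
    return {"json": str(jpath), "markdown": str(mpath)}
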