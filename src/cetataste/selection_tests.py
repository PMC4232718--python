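"""Likelihood-ratio tests for relaxed and divergent selection.

The central comparison ladder for a pseudogenized gene fits five branch
models — one ratio (A), omega fixed at 1 (B), two-ratio with a foreground
omega on pseudogenized branches (C), two-ratio with the foreground omega
fixed at 1 (D), and free-ratio (E) — and tests:

* B vs A: is there selection at all (omega != 1 tree-wide)?
* A vs C: is omega on the pseudogenized branches different (relaxation when
  omega_fg > omega_bg)?
* D vs C: is constraint *fully* removed on those branches (rejecting D means
  omega_fg != 1, i.e. constraint not fully removed)?
* C vs E: is omega heterogeneous beyond the two-ratio description?

Clade model C vs M2a_rel asks whether one site class evolves under a
divergent omega in a designated clade; M1a vs M2a and M8a vs M8 are the
standard positive-selection site tests.  2*Delta(lnL) is referred to a
chi-square with df equal to the difference in free parameter counts.  M8a
vs M8 is referred to a plain chi-square with df 1 by default (the 50:50
boundary mixture is available behind a flag).  Raw p-values are reported;
no multiple-testing correction is applied across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaincc

from .alignment import CodonAlignment
from .codon_models import (
    NESTED_PAIRS,
    FitOptions,
    ModelFit,
    ModelSpec,
    fit,
    site_log_likelihoods,
)
from .phylo import PhyloTree

__all__ = [
    "LRTResult",
    "LadderReport",
    "chi2_sf",
    "lrt",
    "lrt_statistic",
    "run_ladder",
    "run_clade_test",
    "run_site_tests",
    "ladder_table",
]


def chi2_sf(x: float, df: int) -> float:
    """Chi-square upper-tail probability Q(df/2, x/2).

    The regularized upper incomplete gamma function; accurate to ~1e-10
    relative error well below p = 1e-300 territory.
    """
    if x < 0 or not np.isfinite(x):
        raise ValueError(f"statistic must be >= 0, got {x}")
    if df < 1 or int(df) != df:
        raise ValueError(f"df must be a positive integer, got {df}")
    return float(gammaincc(df / 2.0, x / 2.0))


def lrt_statistic(lnl_null: float, lnl_alt: float) -> float:
    """2 * (lnL_alt - lnL_null), clipped at 0."""
    return max(0.0, 2.0 * (lnl_alt - lnl_null))


@dataclass
class LRTResult:
    null_fit: ModelFit
    alt_fit: ModelFit
    stat: float
    df: int
    p: float
    warning: str | None = None

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def lrt(null_fit: ModelFit, alt_fit: ModelFit, boundary_mixture: bool = False) -> LRTResult:
    """Nested-model likelihood-ratio test.

    ``boundary_mixture`` refers the statistic to the 50:50 mixture of
    chi-square(df) and a point mass at 0 appropriate when the null pins a
    parameter at the boundary (e.g. omega_s = 1 in M8a); the default is the
    plain chi-square.
    """
    pair = (null_fit.spec.family, alt_fit.spec.family)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    df = alt_fit.np - null_fit.np
    if df < 1:
        raise ValueError(f"np(alt)={alt_fit.np} must exceed np(null)={null_fit.np}")
    stat = lrt_statistic(null_fit.lnL, alt_fit.lnL)
    p = chi2_sf(stat, df)
    if boundary_mixture:
        p = 0.5 * p if stat > 0 else 1.0
    warning = None
    if not (null_fit.converged and alt_fit.converged):
        warning = "one or both fits did not report convergence"
    if 2.0 * (alt_fit.lnL - null_fit.lnL) < -1e-6:
        warning = (
            (warning + "; " if warning else "")
            + "alternative lnL below null (optimizer failure); stat clipped to 0"
        )
    return LRTResult(null_fit, alt_fit, stat, df, p, warning)


# ---------------------------------------------------------------------------
# the branch-model ladder


@dataclass
class LadderReport:
    gene: str
    fits: dict[str, ModelFit]  # keys A..E
    comparisons: dict[str, LRTResult]  # "B_vs_A", "A_vs_C", "D_vs_C", "C_vs_E"
    verdict: str
    alpha: float = 0.05


_LADDER_FAMILIES = {
    "A": "branch_one_ratio",
    "B": "branch_fixed1",
    "C": "branch_two_ratio",
    "D": "branch_two_ratio_fg1",
    "E": "branch_free",
}


def _refit_if_below(
    null_fit: ModelFit,
    alt_fit: ModelFit,
    aln: CodonAlignment,
    tree: PhyloTree,
    options: FitOptions,
) -> ModelFit:
    """Enforce nesting: if the alternative fit fell below the null, refit it
    warm-started from the null's MLE (the embedded point)."""
    if alt_fit.lnL >= null_fit.lnL - 1e-9:
        return alt_fit
    redo = fit(
        aln,
        tree,
        alt_fit.spec,
        replace(options, warm_start=null_fit, n_starts=1),
    )
    return redo if redo.lnL > alt_fit.lnL else alt_fit


def run_ladder(
    aln: CodonAlignment,
    tree: PhyloTree,
    foreground_branches: list[str] | None = None,
    options: FitOptions | None = None,
    gene: str = "",
    alpha: float = 0.05,
    include_free_ratio: bool = True,
) -> LadderReport:
    """Fit the A–E branch-model ladder and run the four nested LRTs.

    ``foreground_branches`` (branch names) are tagged partition 1 before
    fitting; if None, existing tree tags are used.  An empty foreground is
    refused for C/D, which would silently collapse onto A/B.

    Verdict rule: ``fully_relaxed`` if A-vs-C is significant with
    omega_fg > omega_bg and D-vs-C is not significant; ``partially_relaxed``
    if D-vs-C is also significant; otherwise ``heterogeneous`` when C-vs-E is
    significant, else ``purifying``.
    """
    if options is None:
        options = FitOptions()
    tree = tree.copy()
    if foreground_branches is not None:
        tree.clear_tags()
        for name in foreground_branches:
            tree.set_tag(name, 1)
    if not any(br.tag == 1 for br in tree.branches):
        raise ValueError(
            "ladder models C/D need a non-empty foreground; tag branches first"
        )

    fits: dict[str, ModelFit] = {}
    fits["B"] = fit(aln, tree, ModelSpec("branch_fixed1"), options)
    fits["A"] = fit(
        aln, tree, ModelSpec("branch_one_ratio"), replace(options, warm_start=fits["B"])
    )
    fits["A"] = _refit_if_below(fits["B"], fits["A"], aln, tree, options)
    fits["C"] = fit(
        aln, tree, ModelSpec("branch_two_ratio"), replace(options, warm_start=fits["A"])
    )
    fits["C"] = _refit_if_below(fits["A"], fits["C"], aln, tree, options)
    fits["D"] = fit(
        aln,
        tree,
        ModelSpec("branch_two_ratio_fg1"),
        replace(options, warm_start=fits["A"]),
    )
    # D is also nested in C: C must not fall below D
    fits["C"] = _refit_if_below(fits["D"], fits["C"], aln, tree, options)
    comparisons = {
        "B_vs_A": lrt(fits["B"], fits["A"]),
        "A_vs_C": lrt(fits["A"], fits["C"]),
        "D_vs_C": lrt(fits["D"], fits["C"]),
    }
    if include_free_ratio:
        fits["E"] = fit(
            aln, tree, ModelSpec("branch_free"), replace(options, warm_start=fits["C"])
        )
        fits["E"] = _refit_if_below(fits["C"], fits["E"], aln, tree, options)
        comparisons["C_vs_E"] = lrt(fits["C"], fits["E"])

    relaxed = (
        comparisons["A_vs_C"].significant(alpha)
        and fits["C"].params["omega_fg"] > fits["C"].params["omega_bg"]
    )
    not_fully_removed = comparisons["D_vs_C"].significant(alpha)
    if relaxed:
        verdict = "partially_relaxed" if not_fully_removed else "fully_relaxed"
    elif "C_vs_E" in comparisons and comparisons["C_vs_E"].significant(alpha):
        verdict = "heterogeneous"
    else:
        verdict = "purifying"
    return LadderReport(gene=gene, fits=fits, comparisons=comparisons, verdict=verdict, alpha=alpha)


def run_clade_test(
    aln: CodonAlignment,
    tree: PhyloTree,
    clade_branches: list[str] | None = None,
    options: FitOptions | None = None,
) -> tuple[ModelFit, ModelFit, LRTResult]:
    """Clade model C vs its null M2a_rel (df = 1).

    Returns (null_fit, clade_fit, lrt); the clade fit's omega2 is the
    background divergent-class omega and omega3 the foreground's.
    """
    if options is None:
        options = FitOptions()
    tree = tree.copy()
    if clade_branches is not None:
        tree.clear_tags()
        for name in clade_branches:
            tree.set_tag(name, 1)
    null_fit = fit(aln, tree, ModelSpec("clade_M2a_rel"), options)
    alt_fit = fit(
        aln, tree, ModelSpec("clade_C"), replace(options, warm_start=null_fit)
    )
    alt_fit = _refit_if_below(null_fit, alt_fit, aln, tree, options)
    return null_fit, alt_fit, lrt(null_fit, alt_fit)


def run_site_tests(
    aln: CodonAlignment,
    tree: PhyloTree,
    options: FitOptions | None = None,
    boundary_mixture_m8: bool = False,
) -> dict:
    """M1a-vs-M2a and M8a-vs-M8 LRTs plus naive-empirical-Bayes posteriors
    for the positive-selection class at every site (from the M2a and M8 fits)."""
    if options is None:
        options = FitOptions()
    out: dict = {}
    m1a = fit(aln, tree, ModelSpec("site_M1a"), options)
    m2a = fit(aln, tree, ModelSpec("site_M2a"), replace(options, warm_start=m1a))
    m2a = _refit_if_below(m1a, m2a, aln, tree, options)
    out["M1a"] = m1a
    out["M2a"] = m2a
    out["M1a_vs_M2a"] = lrt(m1a, m2a)
    m8a = fit(aln, tree, ModelSpec("site_M8a"), options)
    m8 = fit(aln, tree, ModelSpec("site_M8"), replace(options, warm_start=m8a))
    m8 = _refit_if_below(m8a, m8, aln, tree, options)
    out["M8a"] = m8a
    out["M8"] = m8
    out["M8a_vs_M8"] = lrt(m8a, m8, boundary_mixture=boundary_mixture_m8)
    out["site_posteriors_M2a"] = neb_site_posteriors(aln, tree, m2a)
    out["site_posteriors_M8"] = neb_site_posteriors(aln, tree, m8)
    return out


def neb_site_posteriors(
    aln: CodonAlignment, tree: PhyloTree, site_fit: ModelFit
) -> pd.DataFrame:
    """Naive empirical Bayes class posteriors per site.

    The last class is the candidate positive-selection class for M2a and M8.
    """
    logs, props = site_log_likelihoods(
        aln,
        tree,
        site_fit.spec,
        site_fit.params,
        site_fit.kappa,
        pi=site_fit.pi,
        branch_lengths=site_fit.branch_lengths,
    )
    keep = props > 0
    logw = np.full_like(props, -np.inf)
    logw[keep] = np.log(props[keep])
    joint = logs + logw[:, None]
    joint -= joint.max(axis=0, keepdims=True)
    post = np.exp(joint)
    post /= post.sum(axis=0, keepdims=True)
    df = pd.DataFrame(
        {
            "site": np.arange(1, aln.n_codons + 1),
            "positive_class_posterior": post[-1],
        }
    )
    for c in range(post.shape[0]):
        df[f"class_{c}"] = post[c]
    return df


def ladder_table(report: LadderReport) -> pd.DataFrame:
    """Flatten a LadderReport into the tabular report schema
    (model label, omega estimates, -lnL, np, comparison, 2dlnL, p)."""
    rows = []
    comp_for = {"A": "B_vs_A", "C": "A_vs_C", "E": "C_vs_E"}
    for key in ("A", "B", "C", "D", "E"):
        if key not in report.fits:
            continue
        f = report.fits[key]
        omegas = {
            k: round(v, 5) for k, v in f.params.items() if k.startswith("omega")
        }
        comp_key = comp_for.get(key)
        comp = report.comparisons.get(comp_key) if comp_key else None
        if key == "D" and "D_vs_C" in report.comparisons:
            comp, comp_key = report.comparisons["D_vs_C"], "D_vs_C"
        rows.append(
            dict(
                gene=report.gene,
                model=key,
                family=f.spec.family,
                omega="; ".join(f"{k}={v}" for k, v in omegas.items()) or "variable",
                minus_lnL=round(-f.lnL, 2),
                np=f.np,
                comparison=comp_key or "",
                stat_2dlnL=round(comp.stat, 2) if comp else "",
                p_value=f"{comp.p:.3g}" if comp else "",
                note="raw p-values, no multiple-testing correction",
            )
        )
    return pd.DataFrame(rows)
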