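"""Likelihood ratio tests and the per-gene model battery.

The battery fits the one-ratio model M0 (estimating branch lengths, which
are then fixed for every other model of the gene), the seven
site-heterogeneous models, and — for each requested foreground branch — the
branch-site pair Model A / Model A null.  Every hierarchically nested pair
is compared by an LRT with degrees of freedom equal to the difference in
free-parameter counts; a positive-selection call requires both a winning
alternative and a selected-class omega above 1.

Alternatives are warm-started from their null's MLE, which (together with
the optimizer's best-seen bookkeeping) makes the maximized lnL respect the
nesting partial order by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .alignment import CodonAlignment, apply_inclusion_criteria
from .catalog import NESTED_PAIRS, OMEGA_CAP, get_model
from .model import CodonModel, CodonModelResults
from .trees import SpeciesTree, mark_foreground

#: LRTs run by the battery among site models (null, alternative)
SITE_LRTS = (("M0", "M3k2"), ("M0", "M3k3"), ("M1a", "M2a"),
             ("M7", "M8"), ("M8a", "M8"))

#: pairs whose null pins a parameter at the boundary of the alternative's space
BOUNDARY_PAIRS = frozenset({("M8a", "M8"), ("ModelAnull", "ModelA")})


@dataclass
class LRTResult:
    """One nested-model comparison."""

    null_id: str
    alt_id: str
    stat: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05
    optimization_failure: bool = False

    def __str__(self) -> str:
        flag = " (optimization failure)" if self.optimization_failure else ""
        return (f"{self.alt_id} vs {self.null_id}: 2dlnL = {self.stat:.4f}, "
                f"df = {self.df}, p = {self.p_value:.4g}{flag}")


def lrt(null_fit: CodonModelResults, alt_fit: CodonModelResults,
        alpha: float = 0.05, boundary: str = "chi2") -> LRTResult:
    """Likelihood ratio test between two hierarchically nested fits.

    The statistic 2(lnL_alt - lnL_null) is clamped at zero; a negative value
    beyond 1e-6 flags an optimization failure rather than raising.  The
    p-value comes from the upper tail of chi-square with df equal to the
    difference in free parameters; for boundary nulls (M8a vs M8, Model A
    null vs Model A) an optional 50:50 chi0/chi1 mixture reference is
    available via ``boundary="mixture"``.
    """
    pair = (null_fit.model_id, alt_fit.model_id)
    if pair not in NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a nested null/alternative pair")
    df = alt_fit.n_free_params - null_fit.n_free_params
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom for pair {pair}")
    raw = 2.0 * (alt_fit.lnL - null_fit.lnL)
    failure = raw < -1e-6
    stat = max(0.0, raw)
    if boundary == "mixture" and pair in BOUNDARY_PAIRS:
        p = 0.5 * chi2.sf(stat, df) + (0.5 if stat == 0.0 else 0.0)
    else:
        p = float(chi2.sf(stat, df))
    return LRTResult(null_id=null_fit.model_id, alt_id=alt_fit.model_id,
                     stat=stat, df=df, p_value=p,
                     significant=bool(p <= alpha and not failure), alpha=alpha,
                     optimization_failure=bool(failure))


def percent_selected(fit: CodonModelResults, decimals: int = 2) -> float:
    """Percentage of sites in positively selected classes.

    Model A: (p2a + p2b) x 100.  M2a / M8: the weight of the omega > 1
    class x 100 (zero if that omega does not exceed 1).  Models without a
    selected class (M1a, M7, M8a, and M0 with omega <= 1) report 0.
    """
    mid = fit.model_id
    if mid == "ModelA" or mid == "ModelAnull":
        w = sum(c.weight for c in fit.mle.classes
                if c.foreground_omega is not None and c.fg != c.omega)
        om2 = fit.params.get("omega2", 1.0)
        pct = w * 100.0 if om2 > 1.0 else 0.0
    elif mid in ("M2a", "M8"):
        om = fit.selected_class_omega()
        pct = fit.mle.classes[-1].weight * 100.0 if om and om > 1.0 else 0.0
    elif mid == "M0":
        pct = 100.0 if fit.params["omega"] > 1.0 else 0.0
    else:
        pct = 0.0
    return round(pct, decimals)


@dataclass
class BranchResult:
    """Branch-site outcome for one foreground selector."""

    selector: str
    null_fit: CodonModelResults | None
    alt_fit: CodonModelResults | None
    test: LRTResult | None
    positive_selection: bool
    error: str = ""


@dataclass
class ComparisonTable:
    """All fits and LRTs for one gene, with positive-selection calls."""

    fits: dict[str, CodonModelResults]
    site_tests: list[LRTResult]
    branch_results: list[BranchResult]
    errors: dict[str, str] = field(default_factory=dict)
    alpha: float = 0.05

    def site_positive_selection(self) -> dict[str, bool]:
        """Per alternative site model: LRT won and selected-class omega > 1."""
        out = {}
        for t in self.site_tests:
            fit = self.fits.get(t.alt_id)
            if fit is None:
                continue
            om = fit.selected_class_omega()
            has_sel = om is not None and om > 1.0
            out[t.alt_id] = bool(t.significant and has_sel
                                 and not t.optimization_failure)
        return out

    def best_fit_model(self) -> str:
        """Model of best fit resolved by the LRT partial order: start from
        M0 and move to an alternative only when it wins its test; ties break
        toward the simpler model."""
        wins = {t.alt_id: t.significant for t in self.site_tests}
        best = "M0"
        if wins.get("M3k2") or wins.get("M3k3"):
            best = "M3k3" if wins.get("M3k3") else "M3k2"
        if wins.get("M2a"):
            best = "M2a"
        if wins.get("M8"):
            # require both M7-vs-M8 and M8a-vs-M8 wins when both were run
            m8a = [t for t in self.site_tests if t.null_id == "M8a"]
            if not m8a or m8a[0].significant:
                best = "M8"
        return best

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mid, fit in self.fits.items():
            rows.append({
                "model": mid, "lnL": fit.lnL,
                "n_free": fit.n_free_params,
                "converged": fit.converged,
                "percent_selected": percent_selected(fit),
            })
        for br in self.branch_results:
            for fit in (br.null_fit, br.alt_fit):
                if fit is None:
                    continue
                rows.append({
                    "model": f"{fit.model_id}[{br.selector}]", "lnL": fit.lnL,
                    "n_free": fit.n_free_params, "converged": fit.converged,
                    "percent_selected": percent_selected(fit),
                })
        return pd.DataFrame(rows)


def run_battery(aln: CodonAlignment, tree: SpeciesTree,
                branches: list[str | list[str]] = (),
                models: tuple[str, ...] | None = None,
                alpha: float = 0.05, seed: int = 0, n_starts: int = 2,
                frequencies: str = "F3x4",
                enforce_inclusion: bool = True,
                min_taxa: int = 6, min_length: int = 167,
                maxiter: int = 500) -> ComparisonTable:
    """Fit the model battery for one gene and run every nested LRT.

    Branch lengths are estimated under M0 and fixed for all other models.
    ``models`` restricts the site-model set (M0 is always fitted);
    ``branches`` lists foreground selectors (leaf name, internal label, or
    taxon set for an MRCA) for the branch-site pair.
    """
    if enforce_inclusion:
        decision = apply_inclusion_criteria(aln, min_taxa=min_taxa,
                                            min_length=min_length)
        if not decision.accepted:
            raise ValueError("alignment fails inclusion criteria: "
                             + "; ".join(decision.reasons))
    # M8a precedes M8 so M8 can start from both of its nulls
    site_models = ["M1a", "M2a", "M3k2", "M3k3", "M7", "M8a", "M8"]
    if models is not None:
        site_models = [m for m in site_models if m in models]

    fits: dict[str, CodonModelResults] = {}
    errors: dict[str, str] = {}

    m0 = CodonModel(aln, tree, "M0", frequencies=frequencies,
                    branch_lengths="estimate").fit(
        n_starts=1, seed=seed, maxiter=maxiter)
    fits["M0"] = m0
    bl = m0.branch_lengths

    # warm-start chains within nested families; `extras` carries the exact
    # embedded image of each null's MLE so nesting holds by construction
    warm: dict[str, dict[str, float]] = {}
    extras: dict[str, list[dict[str, float]]] = {}
    warm["M3k2"] = {"kappa": m0.params["kappa"], "omega0": m0.params["omega"],
                    "omega1": min(m0.params["omega"] * 2 + 0.5, OMEGA_CAP * 0.9)}
    extras["M3k2"] = [{"kappa": m0.params["kappa"], "p0": 0.5,
                       "omega0": m0.params["omega"],
                       "omega1": m0.params["omega"]}]
    extras["M3k3"] = [{"kappa": m0.params["kappa"], "v1": 0.5, "v2": 0.5,
                       "omega0": m0.params["omega"],
                       "omega1": m0.params["omega"],
                       "omega2": m0.params["omega"]}]
    for mid in site_models:
        try:
            start = warm.get(mid)
            fit = CodonModel(aln, tree, mid, frequencies=frequencies,
                             branch_lengths=bl).fit(
                start=start, n_starts=n_starts,
                seed=seed + sum(map(ord, mid)) % 1000,
                maxiter=maxiter, extra_start_points=extras.get(mid))
            fits[mid] = fit
            _chain_warm_starts(warm, extras, mid, fit)
        except Exception as exc:  # recorded per cell, not fatal
            errors[mid] = str(exc)

    site_tests = []
    for null_id, alt_id in SITE_LRTS:
        if null_id in fits and alt_id in fits:
            site_tests.append(lrt(fits[null_id], fits[alt_id], alpha=alpha))

    branch_results = []
    for selector in branches:
        label = selector if isinstance(selector, str) else "MRCA(" + ",".join(sorted(selector)) + ")"
        try:
            marked = mark_foreground(tree, selector)
            null_fit = CodonModel(aln, marked, "ModelAnull",
                                  frequencies=frequencies,
                                  branch_lengths=bl).fit(
                n_starts=n_starts, seed=seed + 7, maxiter=maxiter)
            a_start = dict(null_fit.params)
            a_start["omega2"] = 2.0
            embedded = dict(null_fit.params)
            embedded["omega2"] = 1.0
            alt_fit = CodonModel(aln, marked, "ModelA",
                                 frequencies=frequencies,
                                 branch_lengths=bl).fit(
                start=a_start, n_starts=n_starts, seed=seed + 11,
                maxiter=maxiter, extra_start_points=[embedded])
            test = lrt(null_fit, alt_fit, alpha=alpha)
            positive = bool(test.significant and alt_fit.params["omega2"] > 1.0
                            and not test.optimization_failure)
            branch_results.append(BranchResult(label, null_fit, alt_fit,
                                               test, positive))
        except Exception as exc:
            branch_results.append(BranchResult(label, None, None, None,
                                               False, error=str(exc)))

    return ComparisonTable(fits=fits, site_tests=site_tests,
                           branch_results=branch_results, errors=errors,
                           alpha=alpha)


def _chain_warm_starts(warm: dict, extras: dict, mid: str,
                       fit: CodonModelResults) -> None:
    """Seed the next model in each nested family from this fit's MLE: a warm
    start for exploration plus the exact embedded-null point."""
    p = fit.params
    if mid == "M1a":
        warm["M2a"] = {"kappa": p["kappa"], "v1": p["p0"],
                       "v2": 1 - 1e-6, "omega0": p["omega0"], "omega2": 2.0}
        # omega2 = 1 makes classes 1 and 2 both neutral: exactly M1a
        extras["M2a"] = [{"kappa": p["kappa"], "v1": p["p0"], "v2": 0.5,
                          "omega0": p["omega0"], "omega2": 1.0}]
    elif mid == "M3k2":
        warm["M3k3"] = {"kappa": p["kappa"], "v1": p["p0"], "v2": 1 - 1e-6,
                        "omega0": p["omega0"], "omega1": p["omega1"],
                        "omega2": min(p["omega1"] * 2 + 0.5, OMEGA_CAP * 0.9)}
        extras.setdefault("M3k3", []).append(
            {"kappa": p["kappa"], "v1": p["p0"], "v2": 0.5,
             "omega0": p["omega0"], "omega1": p["omega1"],
             "omega2": p["omega1"]})
    elif mid == "M7":
        warm["M8a"] = {"kappa": p["kappa"], "p": p["p"], "q": p["q"],
                       "p0": 1 - 1e-6}
        extras["M8a"] = [{"kappa": p["kappa"], "p": p["p"], "q": p["q"],
                          "p0": 1 - 1e-9}]
        extras.setdefault("M8", []).append(
            {"kappa": p["kappa"], "p": p["p"], "q": p["q"],
             "p0": 1 - 1e-9, "omega_s": 1.0})
    elif mid == "M8a":
        warm["M8"] = {"kappa": p["kappa"], "p": p["p"], "q": p["q"],
                      "p0": p["p0"], "omega_s": 1.0 + 1e-4}
        extras.setdefault("M8", []).append(
            {"kappa": p["kappa"], "p": p["p"], "q": p["q"],
             "p0": p["p0"], "omega_s": 1.0})
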