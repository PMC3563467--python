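"""Empirical-Bayes identification of positively selected sites.

NEB (naive empirical Bayes) plugs the MLEs straight into Bayes' rule:
P(class k | site h) is proportional to w_k L_hk.  BEB (Bayes empirical
Bayes) instead integrates the mixture weights and the selected-class omega
over a discrete uniform grid prior, weighting each grid point by the data
likelihood, which guards against over-confident posteriors when the MLEs
are poorly resolved.  The grid uses 10 equally spaced points per integrated
dimension: weight coordinates on (0, 1) and the selected omega on (1, 11);
the remaining parameters (kappa, omega0, beta shapes) stay at their MLEs.

Sites are reported by 1-based alignment column and can be mapped to the
ungapped residue numbering of a chosen reference taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._genetic_code import MISSING
from .alignment import CodonAlignment
from .catalog import MixtureWeights
from .engine import _logsumexp
from .model import CodonModelResults

#: models for which a BEB grid is defined (those with a selected class)
BEB_MODELS = ("M2a", "M8", "ModelA")

_GRID = (2 * np.arange(1, 11) - 1) / 20.0  # centers of 10 bins on (0,1)


@dataclass
class SitePosterior:
    """Per-column posterior class membership and selected-class probability."""

    column: int                 # 1-based alignment codon site
    class_posteriors: np.ndarray
    pp_selected: float
    method: str                 # "NEB" or "BEB"
    reference_residue: int | None = None
    false_positive: bool = False

    def __post_init__(self) -> None:
        total = float(self.class_posteriors.sum())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"class posteriors sum to {total}, not 1")
        if not (0.0 <= self.pp_selected <= 1.0 + 1e-12):
            raise ValueError(f"pp_selected out of [0,1]: {self.pp_selected}")


def _selected_class_mask(spec: CodonModelSpec, model_id: str) -> np.ndarray:
    if model_id in ("ModelA", "ModelAnull"):
        return np.array([c.foreground_omega is not None and c.fg > 1.0
                         for c in spec.classes])
    return np.array([c.omega > 1.0 for c in spec.classes])


def neb_site_posteriors(fit: CodonModelResults) -> list[SitePosterior]:
    """Naive empirical Bayes: posterior(class k | site) = w_k L_hk / sum_j w_j L_hj
    at the MLEs, expanded from patterns back to alignment columns."""
    logL = fit.class_logliks()            # (K, n_patterns)
    weights = fit.mle.weights
    logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    joint = logw[:, None] + logL
    denom = _logsumexp(joint, axis=0)
    if not np.isfinite(denom).all():
        bad = int(np.argmin(np.isfinite(denom)))
        site = int(np.nonzero(fit.model.engine.pattern_table.site_to_pattern == bad)[0][0]) + 1
        raise FloatingPointError(f"all class likelihoods are zero at site {site}")
    post = np.exp(joint - denom[None, :])  # (K, n_patterns)
    sel = _selected_class_mask(fit.mle, fit.model_id)
    pp_sel = post[sel].sum(axis=0) if sel.any() else np.zeros(post.shape[1])
    return _expand(fit, post, pp_sel, "NEB")


def _expand(fit: CodonModelResults, post: np.ndarray, pp_sel: np.ndarray,
            method: str) -> list[SitePosterior]:
    s2p = fit.model.engine.pattern_table.site_to_pattern
    return [
        SitePosterior(column=h + 1,
                      class_posteriors=post[:, s2p[h]].copy(),
                      pp_selected=float(np.clip(pp_sel[s2p[h]], 0.0, 1.0)),
                      method=method)
        for h in range(len(s2p))
    ]


# ---------------------------------------------------------------------------
# BEB
# ---------------------------------------------------------------------------

def _beb_grid_states(fit: CodonModelResults):
    """Enumerate grid states: (weights over classes, class specs) plus the
    per-state class list sharing likelihoods through unique omega values."""
    mid = fit.model_id
    p = fit.params
    omega_sel_grid = 1.0 + 10.0 * _GRID  # 10 points spanning (1, 11)
    states = []
    if mid == "M2a":
        om0 = p["omega0"]
        for g0 in _GRID:
            for g1 in _GRID:
                w = (g0, (1 - g0) * g1, (1 - g0) * (1 - g1))
                for om2 in omega_sel_grid:
                    states.append((w, (("bg", om0), ("bg", 1.0), ("bg", om2))))
    elif mid == "M8":
        beta_classes = [c.omega for c in fit.mle.classes[:-1]]
        K = len(beta_classes)
        for g0 in _GRID:
            for oms in omega_sel_grid:
                w = tuple([g0 / K] * K + [1 - g0])
                cl = tuple([("bg", om) for om in beta_classes] + [("bg", oms)])
                states.append((w, cl))
    elif mid == "ModelA":
        om0 = p["omega0"]
        for g0 in _GRID:
            for g1 in _GRID:
                mw = MixtureWeights(g0 * g1, g0 * (1 - g1))
                w = mw.as_tuple()
                for om2 in omega_sel_grid:
                    states.append((w, (("bg", om0), ("bg", 1.0),
                                       ("fg", om0, om2), ("fg", 1.0, om2))))
    else:
        raise ValueError(f"BEB is not defined for model {mid!r}; "
                         f"supported: {BEB_MODELS}")
    return states


def beb_site_posteriors(fit: CodonModelResults) -> list[SitePosterior]:
    """Bayes empirical Bayes site posteriors for M2a, M8, or Model A."""
    if fit.model_id not in BEB_MODELS:
        raise ValueError(f"BEB is not defined for model {fit.model_id!r}; "
                         f"supported: {BEB_MODELS}")
    engine = fit.model.engine
    kappa = fit.params["kappa"]
    # hold branch lengths fixed on the MLE's time scale across the grid
    t_eff = fit.branch_lengths / engine.mixture_scale(fit.mle)
    states = _beb_grid_states(fit)

    # compute per-pattern log-likelihoods once per unique class description
    cache: dict[tuple, np.ndarray] = {}

    def class_loglik(desc: tuple) -> np.ndarray:
        if desc not in cache:
            fg = desc[2] if desc[0] == "fg" else None
            cache[desc] = engine.class_loglik_raw(kappa, desc[1], t_eff, fg)
        return cache[desc]

    counts = engine.pattern_table.counts
    npat = engine.pattern_table.n_patterns
    n_classes = len(fit.mle.classes)
    # positional mask: on the grid the selected class's omega is always > 1
    sel_mask = np.zeros(n_classes, dtype=bool)
    if fit.model_id == "ModelA":
        sel_mask[[2, 3]] = True
    else:  # M2a, M8: last class
        sel_mask[-1] = True

    log_post_states = np.empty(len(states))
    site_sel = np.empty((len(states), npat))
    site_cls: list[np.ndarray] = []
    for s_idx, (w, class_descs) in enumerate(states):
        logw = np.log(np.maximum(np.asarray(w), 1e-300))
        logL = np.stack([class_loglik(d) for d in class_descs])
        joint = logw[:, None] + logL
        mix = _logsumexp(joint, axis=0)
        site_sel[s_idx] = np.exp(_logsumexp(joint[sel_mask], axis=0) - mix)
        site_cls.append(np.exp(joint - mix[None, :]))
        log_post_states[s_idx] = float(counts @ mix)  # + log uniform prior

    log_post_states -= log_post_states.max()
    state_post = np.exp(log_post_states)
    state_post /= state_post.sum()

    pp_sel = state_post @ site_sel
    post = np.tensordot(state_post, np.stack(site_cls), axes=(0, 0))  # (K, npat)
    post = np.clip(post, 0.0, None)
    post /= post.sum(axis=0, keepdims=True)
    if post.shape[0] != n_classes:
        raise RuntimeError("BEB grid class count mismatch")
    return _expand(fit, post, pp_sel, "BEB")


def site_posteriors(fit: CodonModelResults, method: str = "BEB") -> list[SitePosterior]:
    """Dispatch to NEB or BEB; BEB is preferred for reporting when available."""
    if method == "NEB":
        return neb_site_posteriors(fit)
    if method == "BEB":
        return beb_site_posteriors(fit)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------

def classify_sites(posteriors: list[SitePosterior],
                   thresholds: tuple[float, ...] = (0.50, 0.95, 0.99)) -> dict[float, int]:
    """Count sites whose selected-class posterior strictly exceeds each
    threshold; counts are non-increasing across ascending thresholds."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return {t: sum(1 for s in posteriors if s.pp_selected > t) for t in thresholds}


def format_site_bins(counts: dict[float, int]) -> str:
    """Render threshold counts as a report string, e.g. ``3 > 0.50, 1 > 0.95,
    0 > 0.99``."""
    return ", ".join(f"{n} > {t:.2f}" for t, n in counts.items())


def map_column_to_reference(aln: CodonAlignment, reference_taxon: str,
                            column: int, offset: int = 0) -> int | None:
    """Residue number of ``column`` (1-based) in the ungapped reference
    sequence, or None when the reference itself is gapped/missing there.

    ``offset`` shifts the numbering to accommodate a database entry whose
    coordinates differ from the aligned gene model.
    """
    row = aln.codes[aln.row(reference_taxon)]
    if not (1 <= column <= aln.n_sites):
        raise IndexError(f"column {column} outside 1..{aln.n_sites}")
    if row[column - 1] == MISSING:
        return None
    return int((row[:column] != MISSING).sum()) + offset


def attach_reference_numbering(posteriors: list[SitePosterior],
                               aln: CodonAlignment, reference_taxon: str,
                               offset: int = 0) -> list[SitePosterior]:
    for sp in posteriors:
        sp.reference_residue = map_column_to_reference(
            aln, reference_taxon, sp.column, offset
        )
    return posteriors
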