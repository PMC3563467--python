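"""Maximum-likelihood fitting of codon models.

`CodonModel` binds an alignment, a tree, and one catalog model; `fit()`
maximizes the log-likelihood over the model's free parameters (and,
optionally, branch lengths) and returns a `CodonModelResults` carrying the
MLEs, the maximized lnL, and diagnostics.

Optimization is multi-start quasi-Newton (L-BFGS-B) on transformed
parameters: positive scale parameters move on a log scale, interval-bounded
ratios and stick-breaking weight coordinates through a scaled logistic.  The
objective wrapper records the best point ever evaluated, so the reported
optimum is monotone in the starting value — warm-starting an alternative
model from its null's MLE therefore guarantees the nested-model lnL
ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .alignment import CodonAlignment
from .catalog import (
    OMEGA_CAP,
    FreeParam,
    ModelDefinition,
    get_model,
)
from .engine import (
    CodonModelSpec,
    FrequencyVector,
    LikelihoodEngine,
    estimate_codon_frequencies,
)
from .trees import SpeciesTree

_Z_BOUND = 25.0


def _to_unconstrained(x: float, p: FreeParam) -> float:
    if p.transform == "log":
        return float(np.log(np.clip(x, p.lo, p.hi)))
    frac = (np.clip(x, p.lo + 1e-12, p.hi - 1e-12) - p.lo) / (p.hi - p.lo)
    return float(np.log(frac / (1 - frac)))


def _from_unconstrained(z: float, p: FreeParam) -> float:
    if p.transform == "log":
        return float(np.exp(z))
    return float(p.lo + (p.hi - p.lo) / (1.0 + np.exp(-z)))


def _bounds(p: FreeParam) -> tuple[float, float]:
    if p.transform == "log":
        return (np.log(p.lo), np.log(p.hi))
    return (-_Z_BOUND, _Z_BOUND)


_BL_PARAM = FreeParam("t", 1e-7, 30.0, 0.1, "log")


@dataclass
class FitResult:
    """One model's maximized fit: identity, lnL, MLEs, diagnostics."""

    model_id: str
    lnL: float
    mle: CodonModelSpec
    params: dict[str, float]
    branch_lengths: np.ndarray
    converged: bool
    n_free_params: int
    n_starts: int = 1
    message: str = ""


class CodonModel:
    """A codon substitution model bound to data, ready to fit.

    Parameters
    ----------
    alignment
        Validated in-frame codon alignment.
    tree
        Species tree covering exactly the alignment's taxa; must carry a
        foreground mark for the branch-site models.
    model
        Catalog id (``"M0"``, ``"M1a"``, ... ``"ModelA"``) or a
        :class:`~lineageselect.catalog.ModelDefinition`.
    frequencies
        Codon frequency scheme (``F3x4`` default) or a ready
        :class:`FrequencyVector`.
    branch_lengths
        ``"fixed"`` uses the tree's lengths; ``"estimate"`` optimizes them
        jointly; an array fixes them explicitly (indexed by engine node id);
        ``"auto"`` estimates for M0 and fixes from the tree otherwise,
        matching the battery strategy of estimating lengths once under M0.
    """

    def __init__(self, alignment: CodonAlignment, tree: SpeciesTree,
                 model: str | ModelDefinition = "M0",
                 frequencies: str | FrequencyVector = "F3x4",
                 branch_lengths: str | np.ndarray = "auto",
                 beta_categories: int = 10):
        self.definition = model if isinstance(model, ModelDefinition) else get_model(model)
        if self.definition.is_branch_site and tree.foreground_node is None:
            raise ValueError(
                f"{self.definition.id} requires a foreground-marked branch; "
                "use mark_foreground() first"
            )
        if isinstance(frequencies, FrequencyVector):
            freq = frequencies
        else:
            freq = estimate_codon_frequencies(alignment, frequencies)
        self.engine = LikelihoodEngine(alignment, tree, freq)
        self.alignment = alignment
        self.tree = tree
        self.beta_categories = beta_categories
        if isinstance(branch_lengths, str):
            if branch_lengths not in ("auto", "fixed", "estimate"):
                raise ValueError(f"bad branch_lengths mode {branch_lengths!r}")
            if branch_lengths == "auto":
                branch_lengths = "estimate" if self.definition.id == "M0" else "fixed"
            self._bl_mode = branch_lengths
            self._fixed_bl = self.engine.tree_branch_lengths()
        else:
            self._bl_mode = "fixed"
            self._fixed_bl = np.asarray(branch_lengths, dtype=float)

    # -- likelihood ----------------------------------------------------

    def spec_for(self, params: dict[str, float]) -> CodonModelSpec:
        classes = self.definition.build_classes(params, self.beta_categories)
        return CodonModelSpec(params["kappa"], classes, self.engine.frequency)

    def loglike(self, params: dict[str, float],
                branch_lengths: np.ndarray | None = None) -> float:
        bl = self._fixed_bl if branch_lengths is None else branch_lengths
        return self.engine.loglik(self.spec_for(params), bl)

    # -- optimization --------------------------------------------------

    def _free_edges(self) -> np.ndarray:
        ti = self.engine.tindex
        return np.array([i for i in range(ti.n_nodes) if i != ti.root])

    def _pack(self, params: dict[str, float], bl: np.ndarray) -> np.ndarray:
        z = [_to_unconstrained(params[p.name], p) for p in self.definition.free_params]
        if self._bl_mode == "estimate":
            z += [_to_unconstrained(bl[i], _BL_PARAM) for i in self._free_edges()]
        return np.array(z)

    def _unpack(self, z: np.ndarray) -> tuple[dict[str, float], np.ndarray]:
        fp = self.definition.free_params
        params = {p.name: _from_unconstrained(z[i], p) for i, p in enumerate(fp)}
        bl = self._fixed_bl.copy()
        if self._bl_mode == "estimate":
            for j, i in enumerate(self._free_edges()):
                bl[i] = _from_unconstrained(z[len(fp) + j], _BL_PARAM)
        return params, bl

    def _default_start(self) -> dict[str, float]:
        return {p.name: p.start for p in self.definition.free_params}

    def _perturb(self, start: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
        out = {}
        for p in self.definition.free_params:
            z = _to_unconstrained(start[p.name], p)
            z += rng.normal(0.0, 0.7)
            lo, hi = _bounds(p)
            out[p.name] = _from_unconstrained(float(np.clip(z, lo, hi)), p)
        return out

    def fit(self, start: dict[str, float] | None = None, n_starts: int = 3,
            seed: int = 0, maxiter: int = 500, ftol: float = 1e-8,
            extra_start_points: list[dict[str, float]] | None = None
            ) -> "CodonModelResults":
        """Maximize the log-likelihood; returns the best of ``n_starts``
        optimizer runs (start 1 at the supplied/default starting values,
        the rest perturbed deterministically from ``seed``).

        ``extra_start_points`` are parameter dicts evaluated through the
        same best-point tracker before optimizing: passing the embedded
        image of a nested null's MLE guarantees the reported optimum never
        falls below the null's (the nesting partial order holds by
        construction, not by optimizer luck).
        """
        rng = np.random.default_rng(seed)
        base = self._default_start()
        if start is not None:
            base.update({k: v for k, v in start.items() if k in base})
        starts = [base] + [self._perturb(base, rng) for _ in range(n_starts - 1)]

        best: dict = {"f": np.inf, "z": None}

        def objective(z: np.ndarray) -> float:
            params, bl = self._unpack(z)
            try:
                f = -self.loglike(params, bl)
            except FloatingPointError:
                return 1e12
            if f < best["f"]:
                best["f"] = f
                best["z"] = z.copy()
            return f

        fp = self.definition.free_params
        bounds = [_bounds(p) for p in fp]
        if self._bl_mode == "estimate":
            bounds += [_bounds(_BL_PARAM)] * len(self._free_edges())

        for pt in extra_start_points or ():
            full = self._default_start()
            full.update({k: v for k, v in pt.items() if k in full})
            objective(self._pack(full, self._fixed_bl))

        any_success = False
        message = ""
        for s in starts:
            z0 = self._pack(s, self._fixed_bl)
            res = minimize(objective, z0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter, "ftol": ftol,
                                    "maxfun": 40 * maxiter})
            any_success = any_success or bool(res.success)
            message = str(res.message)
        if best["z"] is None:  # every evaluation failed
            best["z"] = self._pack(base, self._fixed_bl)
            best["f"] = np.inf
            any_success = False
            message = "all likelihood evaluations failed"
        params, bl = self._unpack(best["z"])
        return CodonModelResults(
            model=self,
            result=FitResult(
                model_id=self.definition.id,
                lnL=-best["f"],
                mle=self.spec_for(params),
                params=params,
                branch_lengths=bl,
                converged=any_success and np.isfinite(best["f"]),
                n_free_params=self.definition.n_free,
                n_starts=n_starts,
                message=message,
            ),
        )


def fit_parameters(tree: SpeciesTree, aln: CodonAlignment,
                   model: str | ModelDefinition = "M0",
                   **kwargs) -> "CodonModelResults":
    """Functional wrapper: build a :class:`CodonModel` and fit it.

    ``kwargs`` split between the constructor (``frequencies``,
    ``branch_lengths``, ``beta_categories``) and ``fit`` (``start``,
    ``n_starts``, ``seed``, ``maxiter``, ``ftol``).
    """
    ctor = {k: kwargs.pop(k) for k in ("frequencies", "branch_lengths", "beta_categories")
            if k in kwargs}
    return CodonModel(aln, tree, model, **ctor).fit(**kwargs)


@dataclass
class CodonModelResults:
    """Fitted model: estimates, uncertainty proxies, and reporting.

    Wraps the raw :class:`FitResult` and keeps a reference to the model so
    site posteriors and likelihood decompositions can be recomputed at the
    MLE without refitting.
    """

    model: CodonModel
    result: FitResult
    _class_logliks: np.ndarray | None = field(default=None, repr=False)

    # passthrough conveniences -----------------------------------------
    @property
    def model_id(self) -> str:
        return self.result.model_id

    @property
    def llf(self) -> float:
        return self.result.lnL

    @property
    def lnL(self) -> float:
        return self.result.lnL

    @property
    def params(self) -> dict[str, float]:
        return self.result.params

    @property
    def mle(self) -> CodonModelSpec:
        return self.result.mle

    @property
    def branch_lengths(self) -> np.ndarray:
        return self.result.branch_lengths

    @property
    def converged(self) -> bool:
        return self.result.converged

    @property
    def n_free_params(self) -> int:
        return self.result.n_free_params

    def class_logliks(self) -> np.ndarray:
        """(n_classes, n_patterns) log-likelihoods at the MLE (cached)."""
        if self._class_logliks is None:
            self._class_logliks = self.model.engine.class_logliks(
                self.mle, self.branch_lengths
            )
        return self._class_logliks

    # reporting --------------------------------------------------------

    def omega_at_cap(self) -> bool:
        """True when any estimated omega sits at the 999 reporting cap,
        conventionally read as omega >> 1."""
        return any(
            om >= OMEGA_CAP - 1e-6
            for c in self.mle.classes
            for om in (c.omega, c.fg)
        )

    def selected_class_omega(self) -> float | None:
        """Omega of the positively selected class, if the model has one."""
        mid = self.model_id
        if mid in ("ModelA", "ModelAnull"):
            return self.params.get("omega2", 1.0)
        if mid == "M2a":
            return self.params["omega2"]
        if mid == "M8":
            return self.params["omega_s"]
        if mid == "M0":
            return self.params["omega"]
        return None

    def summary(self) -> str:
        r = self.result
        lines = [
            f"Codon model fit: {r.model_id}",
            "=" * 46,
            f"log-likelihood      {r.lnL:.6f}",
            f"free parameters     {r.n_free_params}",
            f"converged           {r.converged}",
            f"taxa / codon sites  {self.model.alignment.n_taxa} / "
            f"{self.model.alignment.n_sites}",
            f"frequency scheme    {self.model.engine.frequency.scheme}",
            "-" * 46,
        ]
        for name, value in r.params.items():
            lines.append(f"{name:<10s} = {value:.5f}")
        lines.append("-" * 46)
        lines.append("class  weight   omega(bg)  omega(fg)")
        for k, c in enumerate(self.mle.classes):
            lines.append(f"{k:<6d} {c.weight:8.5f} {min(c.omega, OMEGA_CAP):10.5f}"
                         f" {min(c.fg, OMEGA_CAP):10.5f}")
        if self.omega_at_cap():
            lines.append("note: omega at reporting cap 999.00000 (omega >> 1)")
        return "\n".join(lines)

    def to_record(self) -> dict:
        """JSON-style fit record (serializable engine state)."""
        r = self.result
        return {
            "model": r.model_id,
            "lnL": r.lnL,
            "params": {k: float(v) for k, v in r.params.items()},
            "classes": [
                {"weight": c.weight, "omega": c.omega,
                 "foreground_omega": c.foreground_omega}
                for c in self.mle.classes
            ],
            "branch_lengths": [float(x) for x in r.branch_lengths],
            "converged": bool(r.converged),
            "n_free_params": r.n_free_params,
        }
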