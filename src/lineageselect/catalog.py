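"""The nine-model catalog and its parameter arithmetic.

Site-heterogeneous models: M0 (one ratio), M1a (nearly neutral), M2a
(selection), M3 discrete with k=2 and k=3, M7 (beta), M8 (beta plus a free
omega > 1 class), M8a (M8 with that class pinned at omega = 1).
Branch-site models: Model A and its null (foreground omega2 fixed at 1).

Each definition knows its free parameters, their box bounds, default starting
values, and how to turn a parameter dictionary into a concrete list of omega
classes for the likelihood engine.  Mixture weights are optimized through
stick-breaking coordinates in (0, 1), so every free parameter lives in an
interval and can be mapped to an unconstrained scale by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta as beta_dist

from .engine import OmegaClass

#: reporting cap for omega; estimates at the cap should be read as "omega >> 1"
OMEGA_CAP = 999.0

MODEL_IDS = ("M0", "M1a", "M2a", "M3k2", "M3k3", "M7", "M8", "M8a",
             "ModelA", "ModelAnull")

#: hierarchically nested (null, alternative) pairs eligible for an LRT
NESTED_PAIRS = frozenset({
    ("M0", "M3k2"), ("M0", "M3k3"), ("M3k2", "M3k3"),
    ("M1a", "M2a"), ("M7", "M8"), ("M8a", "M8"),
    ("ModelAnull", "ModelA"),
})


@dataclass(frozen=True)
class FreeParam:
    """One free parameter: name, box bounds, default start, transform kind.

    ``transform`` is ``"log"`` (positive scale parameters, branch lengths)
    or ``"logit"`` (interval-bounded ratios and stick-breaking weights).
    """

    name: str
    lo: float
    hi: float
    start: float
    transform: str = "logit"


@dataclass(frozen=True)
class ModelDefinition:
    """Catalog entry: identity, free parameters, fixed constraints, and the
    builder mapping a parameter dict to (weight, omega, foreground-omega)
    class tuples."""

    id: str
    description: str
    free_params: tuple[FreeParam, ...]
    constraints: tuple[str, ...] = ()
    beta_categories: int = 0
    is_branch_site: bool = False

    @property
    def n_free(self) -> int:
        return len(self.free_params)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.free_params)

    def build_classes(self, params: dict[str, float],
                      K: int = 10) -> list[OmegaClass]:
        return _BUILDERS[self.id](params, K)


# -- beta discretization ----------------------------------------------------

def discretize_beta(p: float, q: float, K: int = 10) -> list[tuple[float, float]]:
    """K equal-weight omega categories for a beta(p, q) distribution on (0,1).

    Category k is represented by the beta inverse CDF evaluated at the
    midpoint quantile (2k - 1) / (2K).
    """
    if p <= 0 or q <= 0:
        raise ValueError(f"beta shapes must be positive, got p={p}, q={q}")
    if K < 1:
        raise ValueError("K must be at least 1")
    quantiles = (2 * np.arange(1, K + 1) - 1) / (2 * K)
    omegas = beta_dist.ppf(quantiles, p, q)
    return [(float(w), 1.0 / K) for w in omegas]


# -- Model A mixture arithmetic --------------------------------------------

@dataclass
class MixtureWeights:
    """The four Model A class proportions.

    p0 (conserved on all branches), p1 (neutral on all branches), and the
    derived foreground classes p2a (conserved background, selected
    foreground) and p2b (neutral background, selected foreground), with
    p2a = (1 - p0 - p1) p0 / (p0 + p1) and p2b analogous.
    """

    p0: float
    p1: float
    p2a: float = field(init=False)
    p2b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.p0 < 0 or self.p1 < 0:
            raise ValueError("proportions must be non-negative")
        s = self.p0 + self.p1
        if s == 0:
            raise ValueError("p0 + p1 must be positive")
        if s > 1 + 1e-12:
            raise ValueError("p0 + p1 must not exceed 1")
        rest = max(0.0, 1.0 - s)
        self.p2a = rest * self.p0 / s
        self.p2b = rest * self.p1 / s

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p0, self.p1, self.p2a, self.p2b)


def modelA_class_proportions(p0: float, p1: float) -> MixtureWeights:
    """Derived class-2a/2b proportions from the two free Model A weights."""
    return MixtureWeights(p0, p1)


# -- class builders ---------------------------------------------------------

def _stick2(v1: float, v2: float) -> tuple[float, float, float]:
    """Three simplex weights from two stick-breaking coordinates in (0,1)."""
    p0 = v1
    p1 = (1 - v1) * v2
    return p0, p1, 1 - p0 - p1


def _m0(params, K):
    return [OmegaClass(1.0, params["omega"])]


def _m1a(params, K):
    return [OmegaClass(params["p0"], params["omega0"]),
            OmegaClass(1 - params["p0"], 1.0)]


def _m2a(params, K):
    p0, p1, p2 = _stick2(params["v1"], params["v2"])
    return [OmegaClass(p0, params["omega0"]),
            OmegaClass(p1, 1.0),
            OmegaClass(p2, params["omega2"])]


def _m3k2(params, K):
    return [OmegaClass(params["p0"], params["omega0"]),
            OmegaClass(1 - params["p0"], params["omega1"])]


def _m3k3(params, K):
    p0, p1, p2 = _stick2(params["v1"], params["v2"])
    return [OmegaClass(p0, params["omega0"]),
            OmegaClass(p1, params["omega1"]),
            OmegaClass(p2, params["omega2"])]


def _m7(params, K):
    return [OmegaClass(w, om) for om, w in discretize_beta(params["p"], params["q"], K)]


def _m8_like(params, K, omega_s):
    p0 = params["p0"]
    classes = [OmegaClass(p0 * w, om)
               for om, w in discretize_beta(params["p"], params["q"], K)]
    classes.append(OmegaClass(1 - p0, omega_s))
    return classes


def _m8(params, K):
    return _m8_like(params, K, params["omega_s"])


def _m8a(params, K):
    return _m8_like(params, K, 1.0)


def _modelA_like(params, K, omega2):
    mw = MixtureWeights(params["s"] * params["r"], params["s"] * (1 - params["r"]))
    om0 = params["omega0"]
    return [OmegaClass(mw.p0, om0, om0),
            OmegaClass(mw.p1, 1.0, 1.0),
            OmegaClass(mw.p2a, om0, omega2),
            OmegaClass(mw.p2b, 1.0, omega2)]


def _modelA(params, K):
    return _modelA_like(params, K, params["omega2"])


def _modelAnull(params, K):
    return _modelA_like(params, K, 1.0)


_BUILDERS = {
    "M0": _m0, "M1a": _m1a, "M2a": _m2a, "M3k2": _m3k2, "M3k3": _m3k3,
    "M7": _m7, "M8": _m8, "M8a": _m8a, "ModelA": _modelA,
    "ModelAnull": _modelAnull,
}

_KAPPA = FreeParam("kappa", 0.02, 100.0, 2.0, "log")
_OMEGA_FREE = dict(lo=1e-4, hi=OMEGA_CAP, transform="log")
_OMEGA_01 = dict(lo=1e-6, hi=1.0, start=0.1, transform="logit")
_OMEGA_GT1 = dict(lo=1.0, hi=OMEGA_CAP, start=2.0, transform="logit")
_WEIGHT = dict(lo=1e-9, hi=1 - 1e-9, transform="logit")
_SHAPE = dict(lo=0.005, hi=99.0, transform="log")

_CATALOG: dict[str, ModelDefinition] = {}


def _register(defn: ModelDefinition) -> None:
    _CATALOG[defn.id] = defn


_register(ModelDefinition(
    "M0", "one-ratio homogeneous model: a single omega for all sites",
    (_KAPPA, FreeParam("omega", start=0.2, **_OMEGA_FREE)),
))
_register(ModelDefinition(
    "M1a", "nearly neutral: omega0 < 1 free, omega1 = 1 fixed",
    (_KAPPA, FreeParam("p0", start=0.7, **_WEIGHT), FreeParam("omega0", **_OMEGA_01)),
    constraints=("omega1 = 1",),
))
_register(ModelDefinition(
    "M2a", "selection: M1a plus a free omega2 > 1 class",
    (_KAPPA, FreeParam("v1", start=0.7, **_WEIGHT), FreeParam("v2", start=0.8, **_WEIGHT),
     FreeParam("omega0", **_OMEGA_01), FreeParam("omega2", **_OMEGA_GT1)),
    constraints=("omega1 = 1",),
))
_register(ModelDefinition(
    "M3k2", "discrete, two free omega classes",
    (_KAPPA, FreeParam("p0", start=0.7, **_WEIGHT),
     FreeParam("omega0", start=0.1, **_OMEGA_FREE),
     FreeParam("omega1", start=1.5, **_OMEGA_FREE)),
))
_register(ModelDefinition(
    "M3k3", "discrete, three free omega classes",
    (_KAPPA, FreeParam("v1", start=0.6, **_WEIGHT), FreeParam("v2", start=0.7, **_WEIGHT),
     FreeParam("omega0", start=0.05, **_OMEGA_FREE),
     FreeParam("omega1", start=0.5, **_OMEGA_FREE),
     FreeParam("omega2", start=2.0, **_OMEGA_FREE)),
))
_register(ModelDefinition(
    "M7", "beta-distributed omega on (0,1), K discrete categories",
    (_KAPPA, FreeParam("p", start=0.5, **_SHAPE), FreeParam("q", start=1.5, **_SHAPE)),
    beta_categories=10,
))
_register(ModelDefinition(
    "M8", "beta plus a free omega_s > 1 selected class",
    (_KAPPA, FreeParam("p", start=0.5, **_SHAPE), FreeParam("q", start=1.5, **_SHAPE),
     FreeParam("p0", start=0.9, **_WEIGHT), FreeParam("omega_s", **_OMEGA_GT1)),
    beta_categories=10,
))
_register(ModelDefinition(
    "M8a", "M8 with the selected class's omega fixed at 1",
    (_KAPPA, FreeParam("p", start=0.5, **_SHAPE), FreeParam("q", start=1.5, **_SHAPE),
     FreeParam("p0", start=0.9, **_WEIGHT)),
    constraints=("omega_s = 1",),
    beta_categories=10,
))
_register(ModelDefinition(
    "ModelA", "branch-site: foreground omega2 >= 1 on classes 2a/2b",
    (_KAPPA, FreeParam("s", start=0.9, **_WEIGHT), FreeParam("r", start=0.8, **_WEIGHT),
     FreeParam("omega0", **_OMEGA_01), FreeParam("omega2", **_OMEGA_GT1)),
    is_branch_site=True,
))
_register(ModelDefinition(
    "ModelAnull", "branch-site null: foreground omega2 fixed at 1",
    (_KAPPA, FreeParam("s", start=0.9, **_WEIGHT), FreeParam("r", start=0.8, **_WEIGHT),
     FreeParam("omega0", **_OMEGA_01)),
    constraints=("omega2 = 1",),
    is_branch_site=True,
))


def model_catalog() -> list[ModelDefinition]:
    """The full nine-model catalog (M3 contributes two entries, k=2 and k=3)."""
    return [_CATALOG[m] for m in MODEL_IDS]


def get_model(model_id: str) -> ModelDefinition:
    try:
        return _CATALOG[model_id]
    except KeyError:
        raise KeyError(f"unknown model id {model_id!r}; known: {MODEL_IDS}") from None
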