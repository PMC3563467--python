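"""Codon-model likelihood core.

Implements the Goldman-Yang style codon substitution process: a 61x61
reversible generator parameterized by the transition/transversion rate ratio
kappa and the nonsynonymous/synonymous rate ratio omega, with stationary
codon frequencies pi.  Site-class mixtures share kappa and pi; a foreground
branch may substitute a class-specific foreground omega (branch-site models).
Likelihoods are computed by Felsenstein pruning over compressed site
patterns with per-node rescaling, so long alignments do not underflow.

Transition probabilities are obtained from the spectral decomposition of the
pi-symmetrized generator, which makes P(t) cheap for every branch once the
generator is diagonalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, expm

from ._genetic_code import (
    IS_SYNONYMOUS,
    IS_TRANSITION,
    MISSING,
    N_CODONS,
    NT_INDEX,
    ONE_DIFF,
    SENSE_CODONS,
)
from .alignment import CodonAlignment
from .trees import SpeciesTree

# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

_SCHEMES = ("F61", "F3x4", "F1x4", "uniform")

#: codon -> nucleotide index at each of the three positions, shape (61, 3)
_CODON_NT = np.array(
    [[NT_INDEX[c[k]] for k in range(3)] for c in SENSE_CODONS], dtype=np.int64
)


@dataclass
class FrequencyVector:
    """Stationary sense-codon frequencies and the scheme that produced them."""

    pi: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise ValueError("pi must have length 61")
        if (self.pi < 0).any():
            raise ValueError("pi entries must be non-negative")
        total = self.pi.sum()
        if not np.isfinite(total) or total <= 0:
            raise ValueError("pi must have positive finite mass")
        self.pi = self.pi / total


def estimate_codon_frequencies(aln: CodonAlignment, scheme: str = "F3x4") -> FrequencyVector:
    """Estimate stationary codon frequencies from the observed alignment.

    ``F61`` uses raw sense-codon proportions; ``F3x4`` multiplies
    position-specific nucleotide frequencies over sense codons and
    renormalizes; ``F1x4`` does the same with pooled nucleotide frequencies;
    ``uniform`` is 1/61 everywhere.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown frequency scheme {scheme!r}")
    if scheme == "uniform":
        return FrequencyVector(np.full(N_CODONS, 1.0 / N_CODONS), scheme)
    observed = aln.codes[aln.codes != MISSING]
    if observed.size == 0:
        raise ValueError("cannot estimate frequencies from an all-missing alignment")
    if scheme == "F61":
        counts = np.bincount(observed, minlength=N_CODONS).astype(float)
        return FrequencyVector(counts / counts.sum(), scheme)
    # positional nucleotide counts over observed codons
    nt_pos = np.zeros((3, 4))
    for k in range(3):
        nt_pos[k] = np.bincount(_CODON_NT[observed, k], minlength=4)
    if scheme == "F1x4":
        pooled = nt_pos.sum(axis=0)
        pooled /= pooled.sum()
        nt_pos = np.tile(pooled, (3, 1))
    else:  # F3x4
        nt_pos /= nt_pos.sum(axis=1, keepdims=True)
    pi = nt_pos[0, _CODON_NT[:, 0]] * nt_pos[1, _CODON_NT[:, 1]] * nt_pos[2, _CODON_NT[:, 2]]
    return FrequencyVector(pi, scheme)


# ---------------------------------------------------------------------------
# rate matrix and transition probabilities
# ---------------------------------------------------------------------------

def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray | FrequencyVector,
                      normalize: bool = True) -> np.ndarray:
    """61x61 generator: off-diagonal rate pi_j * {1, kappa, omega, omega*kappa}
    for synonymous transversion/transition and nonsynonymous
    transversion/transition single-nucleotide changes; zero for
    multi-nucleotide changes; diagonal = -row sum.

    With ``normalize=True`` the matrix is scaled so the expected rate
    ``-sum_i pi_i q_ii`` equals 1 (one expected substitution per codon per
    unit branch length at this omega).
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    if isinstance(pi, FrequencyVector):
        pi = pi.pi
    pi = np.asarray(pi, dtype=float)
    mult = np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_SYNONYMOUS, 1.0, omega)
    q = np.where(ONE_DIFF, mult * pi[None, :], 0.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if normalize:
        rate = -float(pi @ np.diag(q))
        if rate <= 0:
            raise ValueError("degenerate generator: zero expected rate")
        q = q / rate
    return q


def transition_matrix(q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, tiny negative entries are clamped."""
    if not np.isfinite(t):
        raise ValueError(f"branch length must be finite, got {t}")
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    p = expm(q * t)
    if p.min() < -1e-10:
        raise FloatingPointError("transition matrix entry below -1e-10")
    np.clip(p, 0.0, None, out=p)
    return p / p.sum(axis=1, keepdims=True)


class SpectralGenerator:
    """Diagonalized reversible generator; evaluates P(t) for many branches
    cheaply via the pi-symmetrized eigendecomposition."""

    __slots__ = ("pi", "_inv_sqrt", "_sqrt", "_U", "_lam")

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        pi_f = np.maximum(pi, 1e-12)
        pi_f = pi_f / pi_f.sum()
        self.pi = pi_f
        self._sqrt = np.sqrt(pi_f)
        self._inv_sqrt = 1.0 / self._sqrt
        s = q * self._sqrt[:, None] * self._inv_sqrt[None, :]
        s = 0.5 * (s + s.T)
        self._lam, self._U = eigh(s)

    def probability(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        middle = (self._U * np.exp(self._lam * t)) @ self._U.T
        p = self._inv_sqrt[:, None] * middle * self._sqrt[None, :]
        np.clip(p, 0.0, None, out=p)
        rowsum = p.sum(axis=1, keepdims=True)
        return p / rowsum


# ---------------------------------------------------------------------------
# model specification (mixture of omega classes)
# ---------------------------------------------------------------------------

@dataclass
class OmegaClass:
    """One site class: mixture weight, background omega, and the omega used
    on the foreground branch (defaults to the background value)."""

    weight: float
    omega: float
    foreground_omega: float | None = None

    @property
    def fg(self) -> float:
        return self.omega if self.foreground_omega is None else self.foreground_omega


@dataclass
class CodonModelSpec:
    """A concrete parameterization: kappa, site classes, and frequencies."""

    kappa: float
    classes: list[OmegaClass]
    frequency: FrequencyVector

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        w = np.array([c.weight for c in self.classes])
        if (w < -1e-12).any():
            raise ValueError("negative mixture weight")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError(f"mixture weights sum to {w.sum():.6f}, not 1")
        for c in self.classes:
            if c.omega < 0 or (c.foreground_omega is not None and c.foreground_omega < 0):
                raise ValueError("omega must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.classes])

    def has_foreground(self) -> bool:
        return any(c.foreground_omega is not None for c in self.classes)


# ---------------------------------------------------------------------------
# pattern compression
# ---------------------------------------------------------------------------

@dataclass
class PatternTable:
    """Unique alignment columns with multiplicities (likelihood speedup)."""

    patterns: np.ndarray       # (n_taxa, n_patterns)
    counts: np.ndarray         # (n_patterns,)
    site_to_pattern: np.ndarray  # (n_sites,)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[1]


def compress_patterns(aln: CodonAlignment) -> PatternTable:
    cols, inverse, counts = np.unique(
        aln.codes.T, axis=0, return_inverse=True, return_counts=True
    )
    return PatternTable(cols.T.copy(), counts.astype(float), inverse.ravel())


# ---------------------------------------------------------------------------
# tree indexing for pruning
# ---------------------------------------------------------------------------

@dataclass
class TreeIndex:
    """Array form of a SpeciesTree for pruning: nodes in postorder, with the
    taxon row of each leaf, each edge's length, and its foreground flag."""

    n_nodes: int
    postorder: list[int]              # internal node ids in postorder (root last)
    children: list[list[int]]         # child node ids per node
    parent: np.ndarray
    edge_length: np.ndarray           # length of edge above each node (root: 0)
    is_foreground: np.ndarray         # edge above node is the marked branch
    leaf_row: np.ndarray              # taxon row index per node, -1 for internal
    root: int

    @classmethod
    def build(cls, tree: SpeciesTree, taxon_names: list[str],
              default_edge_length: float = 0.1) -> "TreeIndex":
        dtree = tree.dendropy_tree
        nodes = list(dtree.postorder_node_iter())
        ids = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        edge_length = np.zeros(n)
        is_fg = np.zeros(n, dtype=bool)
        leaf_row = np.full(n, -1, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        row_of = {t: i for i, t in enumerate(taxon_names)}
        fg_node = tree.foreground_node
        for nd in nodes:
            i = ids[id(nd)]
            if nd.parent_node is not None:
                parent[i] = ids[id(nd.parent_node)]
                children[parent[i]].append(i)
                edge_length[i] = (nd.edge.length if nd.edge.length is not None
                                  else default_edge_length)
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in row_of:
                    raise ValueError(f"tree leaf {label!r} not found among alignment taxa")
                leaf_row[i] = row_of[label]
            if fg_node is not None and nd is fg_node:
                is_fg[i] = True
        postorder = [ids[id(nd)] for nd in nodes if not nd.is_leaf()]
        root = ids[id(dtree.seed_node)]
        return cls(n_nodes=n, postorder=postorder, children=children,
                   parent=parent, edge_length=edge_length, is_foreground=is_fg,
                   leaf_row=leaf_row, root=root)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

def _leaf_partial(pattern_states: np.ndarray) -> np.ndarray:
    """(n_patterns, 61) one-hot partials; missing codons give all ones."""
    npat = pattern_states.shape[0]
    partial = np.zeros((npat, N_CODONS))
    miss = pattern_states == MISSING
    partial[miss] = 1.0
    obs = ~miss
    partial[np.nonzero(obs)[0], pattern_states[obs]] = 1.0
    return partial


def class_site_loglik(tindex: TreeIndex, patterns: np.ndarray, pi: np.ndarray,
                      p_edges: dict[int, np.ndarray],
                      branch_lengths: np.ndarray | None = None) -> np.ndarray:
    """Per-pattern log-likelihood under a single omega class.

    ``p_edges`` maps node id -> transition matrix of the edge above it.
    Rescales partials at every internal node to avoid underflow.
    """
    npat = patterns.shape[1]
    partials: dict[int, np.ndarray] = {}
    logscale = np.zeros(npat)
    for i in range(tindex.n_nodes):
        if tindex.leaf_row[i] >= 0:
            partials[i] = _leaf_partial(patterns[tindex.leaf_row[i]])
    for i in tindex.postorder:
        acc = np.ones((npat, N_CODONS))
        for child in tindex.children[i]:
            acc *= partials.pop(child) @ p_edges[child].T
        scale = acc.max(axis=1)
        safe = np.where(scale > 0, scale, 1.0)
        acc /= safe[:, None]
        logscale += np.where(scale > 0, np.log(safe), -np.inf)
        partials[i] = acc
    site_lik = partials[tindex.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(site_lik) + logscale


class LikelihoodEngine:
    """Caches pattern table, tree index, and spectral decompositions so that
    repeated likelihood evaluations during optimization are cheap."""

    def __init__(self, aln: CodonAlignment, tree: SpeciesTree,
                 frequency: FrequencyVector):
        missing = set(tree.leaf_names) - set(aln.taxon_names)
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
        extra = set(aln.taxon_names) - set(tree.leaf_names)
        if extra:
            raise ValueError(f"alignment taxa missing from tree: {sorted(extra)}")
        self.aln = aln
        self.tree = tree
        self.frequency = frequency
        self.pattern_table = compress_patterns(aln)
        self.tindex = TreeIndex.build(tree, aln.taxon_names)
        self._spectral_cache: dict[tuple[float, float], SpectralGenerator] = {}
        # mean-rate normalization uses the background mixture; foreground
        # classes share the same time scale
        self._rate_cache: dict[tuple[float, float], float] = {}

    @property
    def pi(self) -> np.ndarray:
        return self.frequency.pi

    def _generator(self, kappa: float, omega: float) -> SpectralGenerator:
        key = (kappa, omega)
        gen = self._spectral_cache.get(key)
        if gen is None:
            q = build_rate_matrix(kappa, omega, self.pi, normalize=False)
            gen = SpectralGenerator(q, self.pi)
            self._spectral_cache[key] = gen
            if len(self._spectral_cache) > 256:
                self._spectral_cache.pop(next(iter(self._spectral_cache)))
        return gen

    def _unnormalized_rate(self, kappa: float, omega: float) -> float:
        key = (kappa, omega)
        r = self._rate_cache.get(key)
        if r is None:
            q = build_rate_matrix(kappa, omega, self.pi, normalize=False)
            r = -float(self.pi @ np.diag(q))
            self._rate_cache[key] = r
        return r

    def mixture_scale(self, spec: CodonModelSpec) -> float:
        """Common time-scale factor: expected background substitution rate of
        the mixture, so branch lengths stay in substitutions per codon."""
        return float(sum(
            c.weight * self._unnormalized_rate(spec.kappa, c.omega)
            for c in spec.classes
        ))

    def class_logliks(self, spec: CodonModelSpec,
                      branch_lengths: np.ndarray) -> np.ndarray:
        """(n_classes, n_patterns) per-class per-pattern log-likelihoods.

        ``branch_lengths`` is indexed by node id (edge above each node).
        Foreground classes use their foreground omega on the marked branch.
        """
        if spec.has_foreground() and self.tree.foreground_node is None:
            raise ValueError("branch-site spec requires a marked foreground branch")
        scale = self.mixture_scale(spec)
        if scale <= 0:
            raise ValueError("degenerate mixture: zero expected rate")
        t_eff = np.asarray(branch_lengths, dtype=float) / scale
        out = np.empty((len(spec.classes), self.pattern_table.n_patterns))
        for k, cls_k in enumerate(spec.classes):
            bg = self._generator(spec.kappa, cls_k.omega)
            fg = (self._generator(spec.kappa, cls_k.fg)
                  if cls_k.fg != cls_k.omega else bg)
            p_edges: dict[int, np.ndarray] = {}
            for i in range(self.tindex.n_nodes):
                if i == self.tindex.root:
                    continue
                gen = fg if self.tindex.is_foreground[i] else bg
                p_edges[i] = gen.probability(t_eff[i])
            out[k] = class_site_loglik(self.tindex, self.pattern_table.patterns,
                                       self.pi, p_edges)
        return out

    def class_loglik_raw(self, kappa: float, omega: float,
                         t_eff: np.ndarray,
                         foreground_omega: float | None = None) -> np.ndarray:
        """Per-pattern log-likelihood for one omega class at explicit
        effective branch lengths (no rate renormalization) — lets callers
        hold the time scale fixed while varying omega, as the empirical-
        Bayes grid integration must."""
        bg = self._generator(kappa, omega)
        fg = (self._generator(kappa, foreground_omega)
              if foreground_omega is not None and foreground_omega != omega
              else bg)
        p_edges: dict[int, np.ndarray] = {}
        for i in range(self.tindex.n_nodes):
            if i == self.tindex.root:
                continue
            gen = fg if self.tindex.is_foreground[i] else bg
            p_edges[i] = gen.probability(t_eff[i])
        return class_site_loglik(self.tindex, self.pattern_table.patterns,
                                 self.pi, p_edges)

    def loglik_from_class_logliks(self, weights: np.ndarray,
                                  class_logliks: np.ndarray) -> float:
        """Total lnL = sum over patterns of count * log sum_k w_k L_hk."""
        logw = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
        site = _logsumexp(logw[:, None] + class_logliks, axis=0)
        if not np.isfinite(site).all():
            bad = int(np.argmin(np.isfinite(site)))
            raise FloatingPointError(
                f"zero site likelihood at pattern {bad}; data/model mismatch"
            )
        return float(self.pattern_table.counts @ site)

    def loglik(self, spec: CodonModelSpec, branch_lengths: np.ndarray) -> float:
        return self.loglik_from_class_logliks(
            spec.weights, self.class_logliks(spec, branch_lengths)
        )

    def tree_branch_lengths(self) -> np.ndarray:
        """Edge lengths from the input tree, indexed by node id."""
        t = self.tindex.edge_length.copy()
        t[self.tindex.root] = 0.0
        return t


def _logsumexp(a: np.ndarray, axis: int = 0) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    out = np.log(np.sum(np.exp(a - m_safe), axis=axis)) + np.squeeze(m_safe, axis=axis)
    return np.where(np.isfinite(np.squeeze(m, axis=axis)), out, -np.inf)


def log_likelihood(tree: SpeciesTree, aln: CodonAlignment,
                   spec: CodonModelSpec,
                   branch_lengths: np.ndarray | None = None) -> float:
    """Mixture log-likelihood of an alignment on a tree under a concrete
    model spec.  Branch lengths default to those stored on the tree."""
    engine = LikelihoodEngine(aln, tree, spec.frequency)
    if branch_lengths is None:
        branch_lengths = engine.tree_branch_lengths()
    return engine.loglik(spec, branch_lengths)
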