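"""Synthetic data with the statistical structure the analysis assumes.

Three generators:

* codon alignments evolved along a tree under any catalog model — sites draw
  a mixture class i.i.d., the root draws from the stationary frequencies,
  and states evolve branch-wise through the class's transition matrices
  (foreground branches use the foreground omega where the class has one);
* planted gene-conversion tracts (copy a donor segment into a recipient);
* phased haplotype panels built from a founder-copying mosaic, with an
  optional recent sweep: derived-allele carriers at the core are near-copies
  of one founder, with per-SNP switch probability scaled down by the sweep
  strength.  The founder model is deliberately simpler than a coalescent
  with recombination — it produces the EHH contrast the iHS statistic
  measures at desk scale.

Fixed seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._genetic_code import N_CODONS
from .alignment import CodonAlignment
from .catalog import ModelDefinition, get_model
from .engine import (
    CodonModelSpec,
    FrequencyVector,
    SpectralGenerator,
    TreeIndex,
    build_rate_matrix,
)
from .trees import SpeciesTree


@dataclass
class SimulationRecipe:
    """Everything needed to evolve a codon alignment.

    ``spec`` is a concrete parameterization (kappa, classes, frequencies);
    build one from a catalog model via :func:`spec_from_model`.
    """

    tree: SpeciesTree
    spec: CodonModelSpec
    n_sites: int
    seed: int = 0
    record_site_classes: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        w = self.spec.weights
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")


def spec_from_model(model: str | ModelDefinition, params: dict[str, float],
                    frequency: FrequencyVector | None = None,
                    beta_categories: int = 10) -> CodonModelSpec:
    """Concrete spec from a catalog model id and parameter dict; frequencies
    default to uniform over the 61 sense codons."""
    defn = model if isinstance(model, ModelDefinition) else get_model(model)
    if frequency is None:
        frequency = FrequencyVector(np.full(N_CODONS, 1.0 / N_CODONS), "uniform")
    classes = defn.build_classes(params, beta_categories)
    return CodonModelSpec(params["kappa"], classes, frequency)


def _draw_categorical(rng: np.random.Generator, cum_rows: np.ndarray,
                      states: np.ndarray) -> np.ndarray:
    """Vectorized draw: next state for each site given its current state."""
    u = rng.random(states.size)
    return (u[:, None] > cum_rows[states]).sum(axis=1).astype(np.int64)


def simulate_codon_alignment(recipe: SimulationRecipe
                             ) -> tuple[CodonAlignment, np.ndarray | None]:
    """Evolve an alignment; returns (alignment, per-site class labels or
    None).  Branch lengths are in expected substitutions per codon under
    the mixture's background mean rate, matching the likelihood engine."""
    spec = recipe.spec
    tree = recipe.tree
    if spec.has_foreground() and tree.foreground_node is None:
        raise ValueError("branch-site simulation requires a marked foreground branch")
    rng = np.random.default_rng(recipe.seed)
    pi = spec.frequency.pi
    taxa = tree.leaf_names
    tindex = TreeIndex.build(tree, taxa)

    # common time scale: background mixture mean rate
    rates = [
        -float(pi @ np.diag(build_rate_matrix(spec.kappa, c.omega, pi, normalize=False)))
        for c in spec.classes
    ]
    scale = float(np.dot(spec.weights, rates))
    generators: dict[float, SpectralGenerator] = {}

    def gen(omega: float) -> SpectralGenerator:
        if omega not in generators:
            q = build_rate_matrix(spec.kappa, omega, pi, normalize=False)
            generators[omega] = SpectralGenerator(q, pi)
        return generators[omega]

    site_class = rng.choice(len(spec.classes), size=recipe.n_sites, p=spec.weights)
    root_states = rng.choice(N_CODONS, size=recipe.n_sites, p=pi / pi.sum())

    states = {tindex.root: root_states}
    codes = np.zeros((len(taxa), recipe.n_sites), dtype=np.int16)
    preorder = _preorder(tindex)  # walk edges root-to-tip
    for node in preorder:
        if node == tindex.root:
            continue
        parent_states = states[tindex.parent[node]]
        t_eff = tindex.edge_length[node] / scale
        child = np.empty(recipe.n_sites, dtype=np.int64)
        for k, cls_k in enumerate(spec.classes):
            mask = site_class == k
            if not mask.any():
                continue
            omega = cls_k.fg if tindex.is_foreground[node] else cls_k.omega
            p = gen(omega).probability(t_eff)
            cum = np.cumsum(p, axis=1)
            child[mask] = _draw_categorical(rng, cum, parent_states[mask])
        states[node] = child
        if tindex.leaf_row[node] >= 0:
            codes[tindex.leaf_row[node]] = child.astype(np.int16)

    aln = CodonAlignment(list(taxa), codes, source_format="simulated")
    labels = site_class if recipe.record_site_classes else None
    return aln, labels


def _preorder(tindex: TreeIndex) -> list[int]:
    children = tindex.children
    out, stack = [], [tindex.root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(children[node])
    return out


def plant_conversion_tract(aln: CodonAlignment, donor: str, recipient: str,
                           start: int, end: int) -> CodonAlignment:
    """Copy the donor's codons over [start, end] (1-based, inclusive) into
    the recipient; every other cell is unchanged."""
    if donor == recipient:
        raise ValueError("donor and recipient must differ")
    if not (1 <= start <= end <= aln.n_sites):
        raise IndexError(
            f"tract [{start}, {end}] outside 1..{aln.n_sites}"
        )
    out = aln.copy()
    di, ri = out.row(donor), out.row(recipient)
    out.codes[ri, start - 1:end] = out.codes[di, start - 1:end]
    out.source_format = aln.source_format
    return out


# ---------------------------------------------------------------------------
# haplotype panels
# ---------------------------------------------------------------------------

@dataclass
class SweepRecipe:
    """Founder-copying haplotype panel, optionally with a sweep at the core.

    ``sweep_strength`` in [0, 1] is the copying fidelity of derived-allele
    carriers: 0 gives a neutral panel (derived and ancestral classes are
    exchangeable), 1 makes every derived carrier an exact copy of one
    founder.  ``recomb_switch_rate`` is the per-SNP probability of switching
    founders while copying (mosaic recombination).
    """

    n_haplotypes: int = 100
    n_snps: int = 200
    core_index: int = 100
    derived_freq: float = 0.5
    sweep_strength: float = 0.0
    recomb_switch_rate: float = 0.05
    snp_spacing_bp: int = 1000
    n_founders: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.derived_freq < 1.0):
            raise ValueError("derived_freq must be in (0, 1)")
        if not (0 <= self.core_index < self.n_snps):
            raise IndexError("core_index out of range")
        if not (0.0 <= self.sweep_strength <= 1.0):
            raise ValueError("sweep_strength must be in [0, 1]")
        n_derived = round(self.n_haplotypes * self.derived_freq)
        if n_derived < 2 or self.n_haplotypes - n_derived < 2:
            raise ValueError("derived_freq yields fewer than 2 carriers of an allele")


def simulate_haplotypes(recipe: SweepRecipe):
    """Generate a phased panel; returns a HaplotypeMatrix.

    Half the founders carry the derived core allele.  A derived carrier
    starts copying (outward from the core in both directions) from founder 0
    with probability ``sweep_strength``, otherwise from a random
    derived-carrying founder; its per-SNP founder-switch probability is
    ``recomb_switch_rate * (1 - sweep_strength)``.  Ancestral carriers start
    from a random ancestral-carrying founder and switch at the full rate.
    At sweep_strength = 0 the two classes are exchangeable by construction.
    """
    from .ihs import HaplotypeMatrix

    rng = np.random.default_rng(recipe.seed)
    H, S, F = recipe.n_haplotypes, recipe.n_snps, recipe.n_founders
    core = recipe.core_index
    freqs = rng.uniform(0.1, 0.9, size=S)
    founders = (rng.random((F, S)) < freqs).astype(np.int8)
    half = F // 2
    founders[:half, core] = 1   # derived-carrying founders
    founders[half:, core] = 0

    n_derived = round(H * recipe.derived_freq)
    haps = np.zeros((H, S), dtype=np.int8)
    for h in range(H):
        derived = h < n_derived
        if derived:
            if rng.random() < recipe.sweep_strength:
                start_founder = 0
            else:
                start_founder = rng.integers(0, half)
            switch = recipe.recomb_switch_rate * (1.0 - recipe.sweep_strength)
        else:
            start_founder = rng.integers(half, F)
            switch = recipe.recomb_switch_rate
        for direction in (1, -1):
            f = start_founder
            snp = core
            while 0 <= snp < S:
                haps[h, snp] = founders[f, snp]
                snp += direction
                if rng.random() < switch:
                    f = rng.integers(0, F)
    positions = np.arange(S, dtype=np.int64) * recipe.snp_spacing_bp + 1
    return HaplotypeMatrix(haps, positions)
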