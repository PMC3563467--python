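"""Shared fixtures: small trees, synthetic alignments, rng helpers."""

from __future__ import annotations

import numpy as np
import pytest

import lineageselect as ls
from lineageselect.simulate import (
    SimulationRecipe,
    simulate_codon_alignment,
    spec_from_model,
)


def balanced_newick(names: list[str], bl: float = 0.15) -> str:
    """Balanced topology with uniform branch lengths."""
    nodes = [f"{n}:{bl}" for n in names]
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(f"({nodes[i]},{nodes[i + 1]}):{bl}")
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0] + ";"


def make_tree(n_taxa: int, bl: float = 0.15) -> ls.SpeciesTree:
    return ls.SpeciesTree.from_newick(
        balanced_newick([f"t{i}" for i in range(n_taxa)], bl)
    )


def simulate(model: str, params: dict, n_taxa: int = 8, n_sites: int = 100,
             seed: int = 0, bl: float = 0.15, foreground=None):
    tree = make_tree(n_taxa, bl)
    if foreground is not None:
        tree = ls.mark_foreground(tree, foreground)
    spec = spec_from_model(model, params)
    aln, labels = simulate_codon_alignment(
        SimulationRecipe(tree=tree, spec=spec, n_sites=n_sites, seed=seed)
    )
    return aln, tree, labels


@pytest.fixture
def tree3() -> ls.SpeciesTree:
    return ls.SpeciesTree.from_newick("((A:0.2,B:0.3):0.1,C:0.4);")


@pytest.fixture
def aln3(tree3) -> ls.CodonAlignment:
    spec = spec_from_model("M0", {"kappa": 2.0, "omega": 0.4})
    aln, _ = simulate_codon_alignment(
        SimulationRecipe(tree=tree3, spec=spec, n_sites=40, seed=7)
    )
    return aln


@pytest.fixture
def uniform_pi() -> np.ndarray:
    return np.full(61, 1.0 / 61)
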