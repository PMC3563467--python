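"""Independent oracles for acceptance and unit checks."""

from __future__ import annotations

import itertools

import numpy as np

import lineageselect as ls
from lineageselect._genetic_code import MISSING, N_CODONS


def brute_force_loglik(tree: ls.SpeciesTree, aln: ls.CodonAlignment,
                       spec) -> float:
    """Independent oracle: sum over all internal-node state assignments.

    Works on any small rooted tree; enumerates the full product of internal
    states per site class, so only feasible for <= 2 internal nodes.
    """
    from lineageselect.engine import TreeIndex, build_rate_matrix

    tindex = TreeIndex.build(tree, aln.taxon_names)
    pi = spec.frequency.pi
    # same mixture-mean scaling as the engine
    rates = [
        -float(pi @ np.diag(build_rate_matrix(spec.kappa, c.omega, pi,
                                              normalize=False)))
        for c in spec.classes
    ]
    scale = float(np.dot(spec.weights, rates))
    internal = [i for i in range(tindex.n_nodes) if tindex.leaf_row[i] < 0]
    total = 0.0
    for site in range(aln.n_sites):
        site_lik = 0.0
        for cls_k in spec.classes:
            p_edge = {}
            for i in range(tindex.n_nodes):
                if i == tindex.root:
                    continue
                omega = cls_k.fg if tindex.is_foreground[i] else cls_k.omega
                q = build_rate_matrix(spec.kappa, omega, pi, normalize=False)
                p_edge[i] = ls.transition_matrix(q, tindex.edge_length[i] / scale)
            lik = 0.0
            for assignment in itertools.product(range(N_CODONS),
                                                repeat=len(internal)):
                states = dict(zip(internal, assignment))
                for i in range(tindex.n_nodes):
                    if tindex.leaf_row[i] >= 0:
                        states[i] = aln.codes[tindex.leaf_row[i], site]
                term = pi[states[tindex.root]]
                for i in range(tindex.n_nodes):
                    if i == tindex.root:
                        continue
                    s = states[i]
                    sp = states[tindex.parent[i]]
                    if s == MISSING:
                        term *= 1.0  # marginalized leaf: all-ones partial
                    else:
                        term *= p_edge[i][sp, s]
                lik += term
            site_lik += cls_k.weight * lik
        total += np.log(site_lik)
    return total
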