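"""Gene-conversion screening by a Sawyer-style permutation test.

Recombination-like exchange between lineages produces pairwise alignment
segments of unusually high identity at polymorphic sites, which codon-model
LRTs can misread as positive selection.  The screen condenses the alignment
to its polymorphic columns, finds each taxon pair's maximal runs of
consecutive identical polymorphic sites (zero-mismatch fragments), and
compares the observed run scores against a null built by jointly permuting
the polymorphic columns across taxa.  The global p-value of a fragment of
score s is (1 + #{permutation max score >= s}) / (R + 1), taken over the
maximum across all pairs, so it is already corrected for multiple pairs.

Positively selected sites that fall inside a significant fragment span are
flagged as false positives (and retained, flagged, not deleted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._genetic_code import MISSING
from .alignment import CodonAlignment
from .posteriors import SitePosterior


@dataclass
class CondensedAlignment:
    """Polymorphic columns only, with their original 1-based indices."""

    polymorphic_columns: np.ndarray   # original 1-based codon indices, increasing
    states: np.ndarray                # (n_taxa, n_polymorphic)
    taxon_names: list[str]

    @property
    def n_polymorphic(self) -> int:
        return self.states.shape[1]


@dataclass
class ConversionFragment:
    """A candidate converted segment between one taxon pair."""

    taxon_pair: tuple[str, str]
    start: int      # original 1-based codon coordinate, inclusive
    end: int
    score: int      # fragment length in polymorphic sites
    p_value: float

    @property
    def nucleotide_span(self) -> tuple[int, int]:
        return (3 * (self.start - 1) + 1, 3 * self.end)

    def contains(self, column: int) -> bool:
        return self.start <= column <= self.end


def condense_polymorphic(aln: CodonAlignment) -> CondensedAlignment:
    """Drop monomorphic and all-missing columns, keeping original indices."""
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    keep = []
    for j in range(aln.n_sites):
        col = aln.codes[:, j]
        states = np.unique(col[col != MISSING])
        if states.size >= 2:
            keep.append(j)
    idx = np.array(keep, dtype=np.int64)
    return CondensedAlignment(polymorphic_columns=idx + 1,
                              states=aln.codes[:, idx].copy(),
                              taxon_names=list(aln.taxon_names))


def _identity_runs(identical: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) indices into the condensed axis."""
    padded = np.concatenate(([False], identical, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def pairwise_fragments(cond: CondensedAlignment,
                       pair: tuple[str, str]) -> list[ConversionFragment]:
    """Maximal zero-mismatch fragments for one taxon pair, scored by length
    in polymorphic sites.  Missing data breaks a run (conservative)."""
    a, b = pair
    try:
        ia, ib = cond.taxon_names.index(a), cond.taxon_names.index(b)
    except ValueError as exc:
        raise KeyError(f"unknown taxon in pair {pair}") from exc
    ra, rb = cond.states[ia], cond.states[ib]
    identical = (ra == rb) & (ra != MISSING) & (rb != MISSING)
    out = []
    for s, e in _identity_runs(identical):
        out.append(ConversionFragment(
            taxon_pair=(a, b),
            start=int(cond.polymorphic_columns[s]),
            end=int(cond.polymorphic_columns[e]),
            score=e - s + 1,
            p_value=np.nan,
        ))
    return out


def _all_pair_identity(cond: CondensedAlignment) -> np.ndarray:
    """(n_pairs, n_polymorphic) boolean identity matrix over all taxon pairs."""
    n = len(cond.taxon_names)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = cond.states[i], cond.states[j]
            rows.append((ri == rj) & (ri != MISSING) & (rj != MISSING))
    return np.array(rows)


def _max_run(flat: np.ndarray) -> int:
    """Longest run of True in a 1-D boolean array."""
    padded = np.concatenate(([False], flat, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    if starts.size == 0:
        return 0
    ends = np.nonzero(d == -1)[0]
    return int((ends - starts).max())


def geneconv_scan(aln: CodonAlignment, permutations: int = 10000,
                  alpha: float = 0.05, seed: int = 0,
                  include_all: bool = False) -> list[ConversionFragment]:
    """Permutation screen for gene-conversion fragments.

    Shuffles the condensed polymorphic columns jointly across taxa
    (preserving per-column allele configurations), records the maximum
    fragment score across all pairs per permutation, and returns fragments
    with global p <= ``alpha`` (all scored fragments if ``include_all``).
    """
    cond = condense_polymorphic(aln)
    if cond.n_polymorphic < 2:
        import warnings
        warnings.warn("fewer than 2 polymorphic sites; nothing to screen")
        return []
    identity = _all_pair_identity(cond)
    n_pairs, n_poly = identity.shape
    sep = np.zeros((n_pairs, 1), dtype=bool)

    rng = np.random.default_rng(seed)
    null_max = np.empty(permutations, dtype=np.int64)
    for r in range(permutations):
        perm = rng.permutation(n_poly)
        null_max[r] = _max_run(
            np.concatenate([identity[:, perm], sep], axis=1).ravel()
        )

    names = cond.taxon_names
    out = []
    k = 0
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for frag in pairwise_fragments(cond, (names[i], names[j])):
                frag.p_value = float(
                    (1 + int((null_max >= frag.score).sum())) / (permutations + 1)
                )
                if include_all or frag.p_value <= alpha:
                    out.append(frag)
            k += 1
    out.sort(key=lambda f: (f.p_value, -f.score, f.start))
    return out


def filter_false_positives(sites: list[SitePosterior],
                           fragments: list[ConversionFragment]) -> list[SitePosterior]:
    """Flag (never delete) each site lying inside any significant fragment
    span; spans are inclusive on both ends."""
    for sp in sites:
        sp.false_positive = any(f.contains(sp.column) for f in fragments)
    return sites
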