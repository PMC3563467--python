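"""Standard genetic code tables for the 61 sense codons.

Codons are ordered TTT, TTC, TTA, ... (nucleotide order T, C, A, G at each
position), with the three standard stop codons removed.  All loci handled by
this package are nuclear protein-coding genes, so only the standard code is
provided.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "TCAG"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_name["Standard"]
STOP_CODONS = frozenset(_standard.stop_codons)  # TAA, TAG, TGA

#: the 61 sense codons in T/C/A/G positional order
SENSE_CODONS: tuple[str, ...] = tuple(
    "".join(c)
    for c in itertools.product(NUCLEOTIDES, repeat=3)
    if "".join(c) not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

#: amino acid (one-letter) encoded by each sense codon
AMINO_ACIDS: tuple[str, ...] = tuple(_standard.forward_table[c] for c in SENSE_CODONS)

#: integer state used for a missing / ambiguous / gapped codon
MISSING = -1

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _pair_tables():
    one_diff = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    is_ts = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    is_syn = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            one_diff[i, j] = True
            is_ts[i, j] = _is_transition(ci[k], cj[k])
            is_syn[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return one_diff, is_ts, is_syn


#: boolean pair tables over sense codons: single-nucleotide difference,
#: transition (vs transversion), synonymous (same amino acid)
ONE_DIFF, IS_TRANSITION, IS_SYNONYMOUS = _pair_tables()


def codon_to_index(codon: str) -> int:
    """Map a codon string to its sense-codon index.

    Returns :data:`MISSING` for any codon containing a character outside
    A/C/G/T (gaps, ambiguity codes, ``N`` ...).  Raises ``ValueError`` for a
    stop codon, which is never a valid aligned state.
    """
    codon = codon.upper().replace("U", "T")
    if any(ch not in "ACGT" for ch in codon):
        return MISSING
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not a valid alignment state")
    return CODON_INDEX[codon]
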