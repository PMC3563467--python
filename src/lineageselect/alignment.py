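"""In-frame codon alignments: reading, writing, validation, inclusion criteria.

A :class:`CodonAlignment` stores one integer state per taxon per codon column:
an index into the 61 sense codons of the standard genetic code, or
:data:`~lineageselect._genetic_code.MISSING` for a codon containing any
non-ACGT character (gap or ambiguity code).  Missing codons contribute an
all-ones partial likelihood downstream rather than triggering column
deletion, so per-taxon information elsewhere in the column is preserved; a
strict mode that drops such columns globally is available on request.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetic_code import MISSING, SENSE_CODONS, STOP_CODONS, codon_to_index

_FORMATS = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


class AlignmentError(ValueError):
    """Raised for malformed or invalid codon alignment input."""


@dataclass
class CodonAlignment:
    """A taxa-by-codon-site matrix of sense-codon states.

    Parameters
    ----------
    taxon_names
        Unique sequence identifiers, one per row.
    codes
        Integer matrix (n_taxa, n_sites); entries index ``SENSE_CODONS`` or
        equal ``MISSING`` (-1).
    genetic_code
        Code-table identifier (only ``"standard"`` is supported).
    source_format
        Format tag recording where the alignment came from.
    """

    taxon_names: list[str]
    codes: np.ndarray
    genetic_code: str = "standard"
    source_format: str = "memory"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise AlignmentError("codes must be a 2-D taxa x sites matrix")
        if len(self.taxon_names) != self.codes.shape[0]:
            raise AlignmentError("taxon_names length does not match matrix rows")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dupes = sorted({t for t in self.taxon_names if self.taxon_names.count(t) > 1})
            raise AlignmentError(f"duplicate taxon names: {dupes}")
        if self.n_sites < 1:
            raise AlignmentError("alignment must contain at least one codon site")
        if self.codes.max(initial=MISSING) >= len(SENSE_CODONS) or self.codes.min(initial=0) < MISSING:
            raise AlignmentError("codon state out of range")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        """Number of codon columns (nucleotide length / 3)."""
        return self.codes.shape[1]

    def row(self, taxon: str) -> int:
        try:
            return self.taxon_names.index(taxon)
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def sequence_string(self, taxon: str) -> str:
        """Nucleotide string for one taxon; missing codons render as ``---``."""
        out = []
        for s in self.codes[self.row(taxon)]:
            out.append("---" if s == MISSING else SENSE_CODONS[s])
        return "".join(out)

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def subset_taxa(self, keep: list[str]) -> "CodonAlignment":
        rows = [self.row(t) for t in keep]
        return CodonAlignment(list(keep), self.codes[rows].copy(),
                              self.genetic_code, self.source_format)

    def drop_missing_columns(self) -> "CodonAlignment":
        """Strict mode: delete every column containing a missing codon."""
        keep = ~self.missing_mask().any(axis=0)
        if not keep.any():
            raise AlignmentError("strict mode removed every column")
        return CodonAlignment(list(self.taxon_names), self.codes[:, keep],
                              self.genetic_code, self.source_format)

    def copy(self) -> "CodonAlignment":
        return CodonAlignment(list(self.taxon_names), self.codes.copy(),
                              self.genetic_code, self.source_format)


@dataclass
class InclusionDecision:
    """Outcome of the dataset inclusion screen (taxon and length thresholds)."""

    accepted: bool
    n_taxa: int
    n_sites: int
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.accepted == (not self.reasons)


def _codons_from_nucleotides(name: str, seq: str) -> list[int]:
    seq = seq.strip()
    if len(seq) % 3 != 0:
        raise AlignmentError(
            f"sequence {name!r} has length {len(seq)}, not divisible by 3"
        )
    states = []
    for site, start in enumerate(range(0, len(seq), 3), start=1):
        codon = seq[start:start + 3].upper().replace("U", "T")
        if codon in STOP_CODONS:
            raise AlignmentError(
                f"internal stop codon {codon} in taxon {name!r} at codon site {site}"
            )
        states.append(codon_to_index(codon))
    return states


def alignment_from_strings(records: list[tuple[str, str]],
                           source_format: str = "memory") -> CodonAlignment:
    """Build a validated CodonAlignment from (name, nucleotide string) pairs."""
    if not records:
        raise AlignmentError("empty alignment")
    names = [n for n, _ in records]
    rows = [_codons_from_nucleotides(n, s) for n, s in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise AlignmentError(f"sequences have unequal codon lengths: {sorted(lengths)}")
    return CodonAlignment(names, np.array(rows, dtype=np.int16),
                          source_format=source_format)


def read_codon_alignment(path: str | Path, format: str = "fasta") -> CodonAlignment:
    """Read and validate an in-frame codon alignment.

    Parameters
    ----------
    path
        File to read.
    format
        One of ``fasta``, ``phylip`` (relaxed names), ``nexus``.
    """
    if format not in _FORMATS:
        raise AlignmentError(f"unknown alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        msa = AlignIO.read(str(path), _FORMATS[format])
    except Exception as exc:  # Biopython raises assorted types for bad input
        raise AlignmentError(f"could not parse {path} as {format}: {exc}") from exc
    records = [(rec.id, str(rec.seq)) for rec in msa]
    return alignment_from_strings(records, source_format=format)


def write_codon_alignment(aln: CodonAlignment, path: str | Path,
                          format: str = "fasta") -> None:
    """Write an alignment; missing codons are emitted as ``---`` gaps."""
    if format not in _FORMATS:
        raise AlignmentError(f"unknown alignment format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(aln.sequence_string(t)), id=t, description="",
                  annotations={"molecule_type": "DNA"})
        for t in aln.taxon_names
    )
    buf = io.StringIO()
    AlignIO.write(msa, buf, _FORMATS[format])
    Path(path).write_text(buf.getvalue())


def apply_inclusion_criteria(aln: CodonAlignment, min_taxa: int = 6,
                             min_length: int = 167,
                             length_units: str = "codons") -> InclusionDecision:
    """Screen an alignment against the dataset inclusion thresholds.

    Defaults require at least 6 taxa and more than 500 nucleotides of aligned
    coding sequence (167 codons); both thresholds are configurable, and the
    length may be stated in ``"codons"`` or ``"nucleotides"``.  The decision
    lists every violated criterion rather than stopping at the first.
    """
    if aln.n_taxa == 0:
        raise AlignmentError("empty alignment")
    if length_units == "codons":
        min_codons = min_length
    elif length_units == "nucleotides":
        min_codons = int(np.ceil(min_length / 3))
    else:
        raise ValueError(f"length_units must be 'codons' or 'nucleotides', got {length_units!r}")
    reasons = []
    if aln.n_taxa < min_taxa:
        reasons.append(f"taxa < {min_taxa} (found {aln.n_taxa})")
    if aln.n_sites < min_codons:
        reasons.append(
            f"alignment length < {min_codons} codons (found {aln.n_sites})"
        )
    return InclusionDecision(accepted=not reasons, n_taxa=aln.n_taxa,
                             n_sites=aln.n_sites, reasons=reasons)
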