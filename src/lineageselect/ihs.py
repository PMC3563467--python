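"""Extended haplotype homozygosity (EHH) and the integrated haplotype score.

For a core SNP, EHH at distance d is the probability that two randomly drawn
carriers of a given core allele are identical over the entire interval from
the core out to d.  Integrating EHH against physical distance (bp,
trapezoidal, truncated where EHH drops below a cutoff) separately for
carriers of the ancestral and derived allele gives iHH_A and iHH_D; the raw
iHS is ln(iHH_A / iHH_D).  Standardizing within derived-allele-frequency
bins yields an approximately normal score, and |iHS| > 2 flags unusually
long haplotypes around the core: strongly positive when the ancestral
haplotype is long (derived allele still segregating on a short background),
strongly negative when the derived haplotype is long (a recent rise in
frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class HaplotypeMatrix:
    """Phased binary haplotypes with physical positions and polarity.

    ``haplotypes`` is (n_haplotypes, n_snps) of 0/1; by convention allele 1
    is derived wherever ``ones_are_derived`` is True (the default for every
    SNP).
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    ones_are_derived: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.n_haplotypes < 4:
            raise ValueError("need at least 4 haplotypes")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if self.positions.shape != (self.n_snps,):
            raise ValueError("positions length must match SNP count")
        if not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if self.ones_are_derived is None:
            self.ones_are_derived = np.ones(self.n_snps, dtype=bool)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def derived_frequency(self, snp: int) -> float:
        col = self.haplotypes[:, snp]
        freq1 = float(col.mean())
        return freq1 if self.ones_are_derived[snp] else 1.0 - freq1

    # -- TSV dialect shared with the synthetic-data generator ----------

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.haplotypes,
                          columns=[str(p) for p in self.positions])
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypeMatrix":
        df = pd.read_csv(path, sep="\t")
        positions = np.array([int(c) for c in df.columns])
        return cls(df.to_numpy(dtype=np.int8), positions)


@dataclass
class IhsResult:
    """Per-SNP iHS output."""

    snp_index: int
    position: int
    derived_freq: float
    ihh_ancestral: float
    ihh_derived: float
    raw_ihs: float          # NaN when undefined
    std_ihs: float = np.nan
    significant: bool = False
    direction: str = ""     # "positive", "negative", or ""


def _carrier_rows(haps: HaplotypeMatrix, core: int, allele: str) -> np.ndarray:
    if allele not in ("ancestral", "derived"):
        raise ValueError(f"allele must be 'ancestral' or 'derived', got {allele!r}")
    want_one = (allele == "derived") == bool(haps.ones_are_derived[core])
    return np.nonzero(haps.haplotypes[:, core] == (1 if want_one else 0))[0]


def ehh_curve(haps: HaplotypeMatrix, core: int, allele: str,
              direction: str = "right") -> tuple[np.ndarray, np.ndarray]:
    """EHH per flanking SNP in one direction from the core.

    Returns (snp indices from the core outward, EHH values); the first entry
    is the core itself with EHH = 1.  EHH at SNP d is the fraction of
    carrier pairs identical over every SNP in [core, d].
    """
    carriers = _carrier_rows(haps, core, allele)
    n = carriers.size
    if n < 2:
        raise ValueError(f"fewer than 2 carriers of the {allele} allele at SNP {core}")
    if direction == "right":
        span = np.arange(core, haps.n_snps)
    elif direction == "left":
        span = np.arange(core, -1, -1)
    else:
        raise ValueError("direction must be 'left' or 'right'")
    total_pairs = n * (n - 1) / 2.0
    # group haplotypes by identity over the growing interval
    groups = np.zeros(n, dtype=np.int64)
    ehh = np.empty(span.size)
    for k, snp in enumerate(span):
        col = haps.haplotypes[carriers, snp]
        # refine groups by this SNP's alleles
        groups = groups * 2 + col
        _, groups = np.unique(groups, return_inverse=True)
        sizes = np.bincount(groups)
        ehh[k] = (sizes * (sizes - 1) / 2.0).sum() / total_pairs
    return span, ehh


def integrate_ihh(ehh: np.ndarray, positions: np.ndarray,
                  cutoff: float = 0.05) -> float:
    """Trapezoidal area of one direction's EHH curve against physical
    distance, truncated at the last consecutive point with EHH >= cutoff."""
    ehh = np.asarray(ehh, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if ehh.size == 0:
        raise ValueError("empty EHH curve")
    if abs(ehh[0] - 1.0) > 1e-12:
        raise ValueError("EHH curve must start at 1 at the core")
    below = np.nonzero(ehh < cutoff)[0]
    stop = below[0] if below.size else ehh.size
    if stop < 2:
        return 0.0
    x = np.abs(positions[:stop] - positions[0])
    return float(np.trapezoid(ehh[:stop], x))


def raw_ihs(ihh_ancestral: float, ihh_derived: float) -> float:
    """ln(iHH_A / iHH_D); NaN (missing) when either integral is zero."""
    if ihh_ancestral <= 0 or ihh_derived <= 0:
        return float("nan")
    return float(np.log(ihh_ancestral / ihh_derived))


def snp_ihh(haps: HaplotypeMatrix, core: int, allele: str,
            cutoff: float = 0.05) -> float:
    """Both-direction integrated EHH for one core allele."""
    total = 0.0
    for direction in ("left", "right"):
        span, ehh = ehh_curve(haps, core, allele, direction)
        total += integrate_ihh(ehh, haps.positions[span], cutoff)
    return total


def standardize_ihs(raw: np.ndarray, derived_freq: np.ndarray,
                    n_bins: int = 20, min_per_bin: int = 2,
                    freq_range: tuple[float, float] = (0.05, 0.95),
                    reference: tuple[np.ndarray, np.ndarray] | None = None
                    ) -> np.ndarray:
    """Standardize raw scores within derived-allele-frequency bins.

    Within each occupied bin the scores get the bin mean subtracted and are
    divided by the bin standard deviation.  Scores in bins with fewer than
    ``min_per_bin`` members, with zero variance, or with derived frequency
    outside ``freq_range`` are reported missing (NaN).

    By default the bin statistics come from the scores themselves; pass
    ``reference = (ref_raw, ref_freq)`` to standardize against an external
    empirical distribution (the genome-wide panel of the original statistic)
    — essential when the scanned region itself may contain the sweep, since
    a local sweep perturbs many flanking SNPs and would otherwise inflate
    the local bin variance and mask its own signal.
    """
    raw = np.asarray(raw, dtype=float)
    freq = np.asarray(derived_freq, dtype=float)
    if reference is None:
        ref_raw, ref_freq = raw, freq
    else:
        ref_raw = np.asarray(reference[0], dtype=float)
        ref_freq = np.asarray(reference[1], dtype=float)
    out = np.full(raw.shape, np.nan)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bins = np.clip(np.digitize(freq, edges) - 1, 0, n_bins - 1)
    ref_bins = np.clip(np.digitize(ref_freq, edges) - 1, 0, n_bins - 1)
    usable = (np.isfinite(raw) & (freq >= freq_range[0]) & (freq <= freq_range[1]))
    ref_usable = (np.isfinite(ref_raw) & (ref_freq >= freq_range[0])
                  & (ref_freq <= freq_range[1]))
    for b in range(n_bins):
        mask = usable & (bins == b)
        ref_mask = ref_usable & (ref_bins == b)
        if not mask.any() or ref_mask.sum() < min_per_bin:
            continue
        mu = ref_raw[ref_mask].mean()
        sd = ref_raw[ref_mask].std()
        if sd <= 0:
            continue
        out[mask] = (raw[mask] - mu) / sd
    return out


def flag_significant(std_ihs: float, threshold: float = 2.0) -> str:
    """Direction label: 'positive' if score > +threshold, 'negative' if
    score < -threshold, else '' (missing scores are not evaluated)."""
    if not np.isfinite(std_ihs):
        return ""
    if std_ihs > threshold:
        return "positive"
    if std_ihs < -threshold:
        return "negative"
    return ""


def ihs_scan(haps: HaplotypeMatrix, cutoff: float = 0.05,
             threshold: float = 2.0, n_bins: int = 20,
             freq_range: tuple[float, float] = (0.05, 0.95),
             reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Full per-SNP scan: EHH integrals, raw and standardized iHS, flags.

    Returns a DataFrame with one row per SNP; SNPs where either allele has
    fewer than 2 carriers, or where an EHH integral is zero, carry missing
    raw/std scores.  ``reference`` may be a previous scan's DataFrame (with
    ``raw_ihs`` and ``derived_freq`` columns) providing the genome-wide
    empirical distribution used for standardization.
    """
    rows = []
    for s in range(haps.n_snps):
        freq = haps.derived_frequency(s)
        ihh_a = ihh_d = 0.0
        r = float("nan")
        try:
            ihh_a = snp_ihh(haps, s, "ancestral", cutoff)
            ihh_d = snp_ihh(haps, s, "derived", cutoff)
            r = raw_ihs(ihh_a, ihh_d)
        except ValueError:
            pass
        rows.append(IhsResult(snp_index=s, position=int(haps.positions[s]),
                              derived_freq=freq, ihh_ancestral=ihh_a,
                              ihh_derived=ihh_d, raw_ihs=r))
    raw = np.array([x.raw_ihs for x in rows])
    freq = np.array([x.derived_freq for x in rows])
    ref = None
    if reference is not None:
        ref = (reference["raw_ihs"].to_numpy(), reference["derived_freq"].to_numpy())
    std = standardize_ihs(raw, freq, n_bins=n_bins, freq_range=freq_range,
                          reference=ref)
    for x, z in zip(rows, std):
        x.std_ihs = float(z)
        x.direction = flag_significant(z, threshold)
        x.significant = x.direction != ""
    return pd.DataFrame([vars(x) for x in rows])
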