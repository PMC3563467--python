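"""Per-gene orchestration: validate, screen, fit, test, filter, annotate.

Stage order is fixed: inclusion screen, gene-conversion scan, model battery
(site models plus branch-site pairs per requested branch), site posteriors
(BEB preferred), false-positive filtering against significant conversion
fragments, and the variant-proximity report.  The recombination screen runs
before any selection call so the false-positive filter is always applied.
All randomness is seeded through the config; rerunning an identical config
reproduces the report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import (
    CodonAlignment,
    InclusionDecision,
    apply_inclusion_criteria,
    read_codon_alignment,
)
from .battery import ComparisonTable, percent_selected, run_battery
from .catalog import OMEGA_CAP
from .geneconv import ConversionFragment, filter_false_positives, geneconv_scan
from .posteriors import (
    SitePosterior,
    attach_reference_numbering,
    classify_sites,
    format_site_bins,
    site_posteriors,
)
from .annotate import proximity_report, read_variant_table
from .trees import SpeciesTree, prune_tree, read_species_tree


@dataclass
class PipelineConfig:
    """Declarative per-gene run configuration (YAML-loadable)."""

    alignment: str
    tree: str
    gene: str = "gene"
    alignment_format: str = "fasta"
    branches: list = field(default_factory=list)
    models: list | None = None
    min_taxa: int = 6
    min_length: int = 167
    permutations: int = 10000
    alpha: float = 0.05
    pp_thresholds: tuple = (0.50, 0.95, 0.99)
    proximity_window: int = 10
    reference_taxon: str | None = None
    variants: str | None = None
    frequencies: str = "F3x4"
    seed: int = 0
    n_starts: int = 2
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate_paths()
        return cfg

    def validate_paths(self) -> None:
        for label, p in (("alignment", self.alignment), ("tree", self.tree),
                         ("variants", self.variants)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} file not found: {p}")


@dataclass
class GeneReport:
    """Everything the pipeline computed for one gene."""

    gene: str
    inclusion: InclusionDecision
    fragments: list[ConversionFragment]
    table: ComparisonTable | None
    sites: dict[str, list[SitePosterior]]       # keyed by model/branch label
    proximity: pd.DataFrame | None
    seed: int
    notes: list[str] = field(default_factory=list)

    def positive_selection_calls(self) -> dict[str, bool]:
        """Headline calls: each traces to a significant LRT and an omega > 1
        class; a call whose sites are all conversion-flagged is withdrawn."""
        calls: dict[str, bool] = {}
        if self.table is None:
            return calls
        calls.update(self.table.site_positive_selection())
        for br in self.table.branch_results:
            calls[f"ModelA[{br.selector}]"] = br.positive_selection
        for label, sites in self.sites.items():
            if label in calls and calls[label]:
                informative = [s for s in sites if s.pp_selected > 0.5]
                if informative and all(s.false_positive for s in informative):
                    calls[label] = False
                    self.notes.append(
                        f"{label}: selection call withdrawn — every pp > 0.5 "
                        "site overlaps a significant conversion fragment"
                    )
        return calls


def run_pipeline(config: PipelineConfig) -> GeneReport:
    """Execute the full per-gene analysis for one config."""
    config.validate_paths()
    aln = read_codon_alignment(config.alignment, config.alignment_format)
    tree = read_species_tree(config.tree)
    shared = sorted(set(tree.leaf_names) & set(aln.taxon_names))
    if len(shared) < 2:
        raise ValueError("tree and alignment share fewer than 2 taxa")
    if set(tree.leaf_names) != set(aln.taxon_names):
        tree = prune_tree(tree, shared)
        aln = aln.subset_taxa(shared)

    inclusion = apply_inclusion_criteria(aln, config.min_taxa, config.min_length)
    notes: list[str] = []
    if not inclusion.accepted:
        return GeneReport(config.gene, inclusion, [], None, {}, None,
                          config.seed,
                          notes=[f"excluded: {'; '.join(inclusion.reasons)}"])

    fragments = geneconv_scan(aln, permutations=config.permutations,
                              alpha=config.alpha, seed=config.seed)

    table = run_battery(
        aln, tree, branches=config.branches,
        models=tuple(config.models) if config.models else None,
        alpha=config.alpha, seed=config.seed, n_starts=config.n_starts,
        frequencies=config.frequencies,
        min_taxa=config.min_taxa, min_length=config.min_length,
    )

    sites: dict[str, list[SitePosterior]] = {}
    for mid, significant in table.site_positive_selection().items():
        fit = table.fits.get(mid)
        if fit is None or not significant:
            continue
        method = "BEB" if mid in ("M2a", "M8") else "NEB"
        sp = site_posteriors(fit, method)
        sites[mid] = sp
    for br in table.branch_results:
        if br.alt_fit is not None and br.positive_selection:
            sites[f"ModelA[{br.selector}]"] = site_posteriors(br.alt_fit, "BEB")

    mapped_residues: list[int] = []
    for label, sp in sites.items():
        filter_false_positives(sp, fragments)
        if config.reference_taxon:
            attach_reference_numbering(sp, aln, config.reference_taxon)
            mapped_residues += [
                s.reference_residue for s in sp
                if s.pp_selected > 0.5 and not s.false_positive
                and s.reference_residue is not None
            ]

    proximity = None
    if config.variants and mapped_residues:
        variants = read_variant_table(config.variants)
        proximity = proximity_report(sorted(set(mapped_residues)), variants,
                                     window=config.proximity_window)

    report = GeneReport(config.gene, inclusion, fragments, table, sites,
                        proximity, config.seed, notes=notes)
    if config.output_dir:
        _write_outputs(report, config)
    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _format_model_a_params(fit) -> str:
    p = fit.params
    from .catalog import MixtureWeights
    mw = MixtureWeights(p["s"] * p["r"], p["s"] * (1 - p["r"]))
    om2 = min(p.get("omega2", 1.0), OMEGA_CAP)
    return (f"p_0_ = {mw.p0:.5f}, p_1_ = {mw.p1:.5f}, "
            f"p_2_ = {mw.p2a:.5f}, p_3_ = {mw.p2b:.5f} "
            f"ω_0_ = {p['omega0']:.5f}, ω_1_ = 1.00000, "
            f"ω_2_ = {om2:.5f}")


def _format_params(fit) -> str:
    if fit.model_id in ("ModelA", "ModelAnull"):
        return _format_model_a_params(fit)
    parts = []
    for name, value in fit.params.items():
        if name in ("v1", "v2", "s", "r", "kappa"):
            continue
        shown = min(value, OMEGA_CAP) if name.startswith("omega") else value
        parts.append(f"{name} = {shown:.5f}")
    return ", ".join(parts)


def render_summary(report: GeneReport,
                   thresholds: tuple[float, ...] = (0.50, 0.95, 0.99)
                   ) -> pd.DataFrame:
    """Comparison-table rows: one per (gene, model-or-branch) with lnL,
    formatted estimates, a positive-selection flag, and the site-count bin
    string for models carrying site posteriors."""
    rows = []
    if report.table is None:
        return pd.DataFrame(columns=["Gene", "Model", "lnL",
                                     "Parameter Estimates",
                                     "Positive Selection",
                                     "Positively Selected Sites"])
    calls = report.positive_selection_calls()

    def site_bins(label: str) -> str:
        sp = report.sites.get(label)
        if not sp:
            return ""
        usable = [s for s in sp if not s.false_positive]
        return format_site_bins(classify_sites(usable, thresholds))

    for mid, fit in report.table.fits.items():
        rows.append({
            "Gene": report.gene, "Model": mid, "lnL": round(fit.lnL, 6),
            "Parameter Estimates": _format_params(fit),
            "Positive Selection": "Yes" if calls.get(mid) else "No",
            "Positively Selected Sites": site_bins(mid),
        })
    for br in report.table.branch_results:
        for fit in (br.null_fit, br.alt_fit):
            if fit is None:
                continue
            label = f"{fit.model_id}[{br.selector}]"
            rows.append({
                "Gene": report.gene, "Model": label,
                "lnL": round(fit.lnL, 6),
                "Parameter Estimates": _format_params(fit),
                "Positive Selection": "Yes" if calls.get(label) else "No",
                "Positively Selected Sites": site_bins(label),
            })
    return pd.DataFrame(rows, columns=["Gene", "Model", "lnL",
                                       "Parameter Estimates",
                                       "Positive Selection",
                                       "Positively Selected Sites"])


def _write_outputs(report: GeneReport, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_summary(report, config.pp_thresholds).to_csv(
        out / f"{report.gene}_summary.tsv", sep="\t", index=False)
    frag_rows = [{
        "taxon_a": f.taxon_pair[0], "taxon_b": f.taxon_pair[1],
        "start_codon": f.start, "end_codon": f.end,
        "start_nt": f.nucleotide_span[0], "end_nt": f.nucleotide_span[1],
        "score": f.score, "p_value": f.p_value,
    } for f in report.fragments]
    pd.DataFrame(frag_rows, columns=["taxon_a", "taxon_b", "start_codon",
                                     "end_codon", "start_nt", "end_nt",
                                     "score", "p_value"]).to_csv(
        out / f"{report.gene}_fragments.tsv", sep="\t", index=False)
    site_rows = []
    for label, sp in report.sites.items():
        for s in sp:
            site_rows.append({
                "model": label, "column": s.column,
                "reference_residue": s.reference_residue,
                "method": s.method,
                "pp_selected": s.pp_selected,
                "false_positive": s.false_positive,
            })
    pd.DataFrame(site_rows, columns=["model", "column", "reference_residue",
                                     "method", "pp_selected",
                                     "false_positive"]).to_csv(
        out / f"{report.gene}_sites.tsv", sep="\t", index=False)
    if report.proximity is not None:
        report.proximity.to_csv(out / f"{report.gene}_proximity.tsv",
                                sep="\t", index=False)
    manifest = {
        "gene": report.gene,
        "seed": report.seed,
        "alpha": config.alpha,
        "permutations": config.permutations,
        "models": config.models or "all",
        "branches": [str(b) for b in config.branches],
        "thresholds": list(config.pp_thresholds),
        "positive_selection": report.positive_selection_calls(),
        "notes": report.notes,
        "fits": {m: f.to_record() for m, f in report.table.fits.items()}
        if report.table else {},
    }
    (out / f"{report.gene}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
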