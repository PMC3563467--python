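# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `lineageselect`, and what the test suite does and does not
establish about behavior on real data.

## Codon substitution model

The substitution process on the 61 sense codons of the standard genetic
code is the usual reversible Markov generator: the instantaneous rate from
codon *i* to *j* is zero unless the codons differ at exactly one
nucleotide, and otherwise equals π_j multiplied by κ for a transition,
by ω for a nonsynonymous change, and by κω for a nonsynonymous transition
(π the stationary codon frequencies, κ the transition/transversion rate
ratio, ω = dN/dS).  The diagonal makes rows sum to zero.

Stationary frequencies come from the alignment under one of four schemes —
F61 (observed codon proportions), **F3x4 (default)** (products of
position-specific nucleotide frequencies over sense codons, renormalized),
F1x4, or uniform.  The choice is a modelling convention, not an estimate of
interest; it is switchable per fit.

**Rate scaling.** Each mixture model's generators are divided by the
mixture's expected background rate, so branch lengths are expected
substitutions per codon under that model.  Foreground-branch generators
(branch-site models) share the background scale, keeping one time axis per
gene.

**Mixtures.** Site classes are independent across sites.  Class structure
per model:

| model | classes | free parameters (besides κ) |
|---|---|---|
| M0 | 1 | ω |
| M1a | ω₀<1, ω₁=1 | p₀, ω₀ |
| M2a | + ω₂≥1 | p₀, p₁ (stick-breaking), ω₀, ω₂ |
| M3 (k=2,3) | k free ω | weights, ω's |
| M7 | beta(p,q), K=10 equal-weight categories at midpoint quantiles | p, q |
| M8 | p₀·beta + (1−p₀)·ω_s≥1 | p, q, p₀, ω_s |
| M8a | M8 with ω_s≡1 | p, q, p₀ |
| Model A | (p₀: ω₀/ω₀), (p₁: 1/1), (p₂ₐ: ω₀/ω₂), (p₂ᵦ: 1/ω₂) | p₀+p₁ and p₀:(p₀+p₁) ratio, ω₀, ω₂ |
| Model A null | ω₂≡1 | as Model A minus ω₂ |

Model A's derived weights obey p₂ₐ = (1−p₀−p₁)·p₀/(p₀+p₁) and the
analogous p₂ᵦ — the proportions of sites that switch to the foreground ω₂
from the conserved and neutral background classes respectively.

ω is capped at 999; an estimate at the cap is reported as `999.00000` and
should be read as ω ≫ 1 (the magnitude beyond that carries no biological
information).

## Likelihood and optimization

Likelihoods use Felsenstein pruning over unique site patterns with
multiplicities, rescaling partials at every internal node (log-space
accumulators), so alignments of thousands of codons do not underflow.
Transition matrices come from the eigendecomposition of the π-symmetrized
generator, diagonalized once per (κ, ω) and reused across branches;
frequencies are floored at 1e−12 for the decomposition.

Optimization is L-BFGS-B on transformed parameters: log scale for κ,
branch lengths, and unconstrained ω's; a scaled logistic for
interval-bounded ratios and stick-breaking weight coordinates.  Defaults:
3 starts (the first at κ=2, ω starts spread over {0.1, 1, 2}; the rest
perturbed deterministically from the seed), lnL tolerance 1e−8, box bounds
κ ∈ (0.02, 100), t ∈ (1e−7, 30).  The objective wrapper records the best
point ever evaluated; alternatives are additionally seeded with the exact
embedded image of their null's MLE (e.g. M2a at ω₂=1 reproduces M1a), so
maximized lnL can never fall below the null's — the nested-model partial
order holds by construction.

Branch lengths are estimated once under M0 and fixed for all other models
of the gene (re-optimization per model is a constructor flag).  This keeps
the ten-model battery tractable and matches common practice for LRT
screens.

## LRTs and selection calls

2Δℓ is clamped at zero and referred to χ² with df equal to the
free-parameter difference; a negative statistic beyond 1e−6 flags an
optimization failure instead of being silently clamped.  For the two
boundary nulls (M8a/M8 and Model A null/Model A) the default reference is
plain χ²₁, with a 50:50 χ²₀:χ²₁ mixture available as an option; the plain
χ²₁ reference is conservative.  A positive-selection call requires both a
winning LRT and a selected-class ω above 1.

The null distribution of the M1a-vs-M2a statistic has a large point mass
at zero (the extra class's weight sits on the boundary and ω₂ is then
unidentifiable), so it is *stochastically dominated by* χ²₂ rather than
distributed as χ²₂; the calibration test checks exactly that dominance
plus the rejection rate.

## Site posteriors

NEB plugs the MLEs into Bayes' rule per site.  BEB integrates the mixture
weights and the selected-class ω over a uniform grid prior — 10 equally
spaced points per dimension: two stick-breaking weight coordinates on
(0,1) and ω₂ (or ω_s) on (1,11); κ, ω₀ and the beta shapes stay at their
MLEs, and branch lengths stay on the MLE's time scale across the grid
(holding the time axis fixed is what makes grid states comparable).  Grid
dimensionality is 3 for M2a and Model A, 2 for M8.  Threshold summaries
count sites with posterior strictly above 0.50 / 0.95 / 0.99.

Mapping to a reference sequence's numbering is the ungapped codon count of
the chosen reference taxon up to the column; a configurable offset
accommodates database entries whose numbering differs from the aligned
gene model.  Columns where the reference is gapped are reported unmapped,
never guessed.

## Gene-conversion screen

The alignment is condensed to polymorphic columns; for every taxon pair,
maximal runs of consecutive identical polymorphic sites are scored by
length (zero-mismatch fragments; missing data breaks a run).  The null
shuffles whole condensed columns jointly across taxa — preserving each
column's allele configuration — and records the maximum fragment score
over all pairs per permutation; a fragment of score *s* gets global
p = (1 + #{perm max ≥ s}) / (R+1), already corrected for the number of
pairs.  Default R = 10,000, α = 0.05.  Mismatch-penalty scoring and
outer-sequence fragments are deliberate extension points.  Selected sites
inside a significant fragment span (inclusive, codon coordinates; spans
also reported in nucleotides) are flagged false positives and retained.

## iHS

EHH at distance *d* from a core SNP is the fraction of carrier pairs of a
given core allele identical over the whole interval; iHH integrates EHH
against physical distance (bp) by trapezoids, truncated at the last
consecutive point with EHH ≥ 0.05, summed over both directions; raw
iHS = ln(iHH_ancestral / iHH_derived).  Standardization subtracts the bin
mean and divides by the bin SD within 20 derived-allele-frequency bins
(SNPs with derived frequency outside [0.05, 0.95], bins with fewer than 2
scores, or zero variance give missing scores; zero iHH propagates as
missing, never ±∞).  The bin statistics may come from the scanned panel
itself or from an external reference scan: a local region containing the
sweep perturbs its own flanking SNPs, so sweep detection standardizes
against a sweep-free reference, mirroring the genome-wide empirical
distributions the statistic was designed around.  |iHS| > 2 is flagged
with its direction.  Physical distance is the integration measure
throughout — the synthetic panels carry no genetic map.

## Synthetic data

*Codon alignments*: a site draws its mixture class i.i.d., the root draws
from π, and states evolve branch-wise through the class's transition
matrices (computed once per branch and class); foreground branches use the
foreground ω.  Fixed seeds give bit-identical output.  The generator makes
exactly the assumptions the likelihood does (site independence, no indels,
one genealogy = the species tree), so parameter-recovery tests validate
the estimator, not the realism of those assumptions; alignment error,
recombination within genes, and rate variation beyond the mixture are
real-data features the simulations do not probe.

*Conversion tracts* are planted by copying a donor segment into a
recipient.

*Haplotype panels* use a founder-copying mosaic rather than a coalescent
with recombination: 10 founders (half carrying the derived core allele),
each haplotype copies outward from the core, switching founders with
per-SNP probability 0.05; derived carriers start from one designated
founder with probability equal to the sweep strength and switch at rate
scaled by (1 − strength).  At strength 0 the two allele classes are
exchangeable by construction; at strength 0.95 the derived class is
near-clonal.  This reproduces the EHH contrast iHS measures at desk scale
but has no demography, mutation-age structure, or genetic map — the iHS
calibration figures below are statements about this generator, not about
human panels.

## Pipeline

Stage order is fixed: inclusion screen (defaults: ≥ 6 taxa and > 500
aligned nucleotides, i.e. 167 codons — the length unit is explicit because
thresholds of "500" appear in both amino-acid and nucleotide conventions;
both knobs are configurable) → conversion scan → M0 and site models →
branch-site pair per requested foreground → LRTs → site posteriors (BEB
preferred where defined) → false-positive filter → proximity report
(default window 10 residues, configurable per query).  The conversion
screen runs before any selection call so the filter is always applied; the
filter is applied per gene across all calls.  Reruns of an identical
config are byte-identical; the manifest records seed, models, and
thresholds.

## Problem sizes used by the acceptance tests

Chosen to exercise each property at desk scale: likelihood oracle on 3–4
taxa × 2–3 codons against exhaustive enumeration (1e−8); nesting on five
6-taxon × 150-codon genes; null calibration on twenty 12-taxon ×
300-codon nearly-neutral replicates (branch lengths fixed at their
simulated values — the standard device for isolating the test statistic's
calibration from branch-length estimation error); power on one 18-taxon ×
500-codon branch-site simulation with an ancestral foreground branch and
ω₂ = 5; conversion screen on a planted 30-codon tract in an 8-taxon ×
300-codon alignment plus twenty null replicates; iHS on 100-haplotype ×
200-SNP panels (three neutral panels as the standardization reference,
ten sweep replicates at strength 0.95).

## Known limitations

No indels or alignment-error model; a single genealogy shared by all sites
(no recombination within the modeled gene — conversion is screened, not
modeled); χ²-based boundary tests are conservative; BEB integrates a
3-dimensional grid, not the full parameter posterior; iHS uses physical
distance and a mosaic panel generator; per-branch dN and dS are not
decomposed (only ω is modeled).
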