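# Methods

## The density-shift statistic

A gradient is a set of ~50 fractions, each with a buoyant density ρ_f
(measured directly or via refractometry, ρ = 10.927·n_c − 13.593, the CsCl
calibration), a DNA yield (ng) and an amplicon count vector. For one OTU in
one gradient, the analyzed fractions are those with DNA above a floor
(default 0.1 ng — "detectable DNA"); per fraction the OTU's DNA mass is its
relative amplicon abundance times the fraction's DNA yield, and the masses
are normalized to sum to 1. This treats amplicon counts as compositional
within a fraction and uses the DNA yield to restore scale across fractions;
a lone OTU's distribution therefore equals the DNA-yield profile itself.

The weighted mean density is WM = Σ ρ_f·p_f. The paired statistic is
ΔWM = WM(¹³C) − WM(¹²C), computed on each gradient's own density axis (a
weighted mean needs no cross-gradient alignment). Significance is
one-sided — label makes DNA heavier — and requires ΔWM > 0.005 g/ml plus
the normality filter below in *both* gradients. No multiple-testing
correction is applied; raw KS p-values are reported.

### Normality filter

Counts are not raw samples but a weighted discrete distribution over
fraction densities, so the Kolmogorov–Smirnov comparison is constructed
deterministically: the weighted empirical CDF evaluated at the fraction
densities is compared against the normal CDF with the distribution's own
weighted mean and weighted SD; the statistic D is the largest discrepancy
(each step approached from both sides), and the p-value uses the asymptotic
KS distribution with effective sample size n = number of fractions with
positive weight. Distributions supported on fewer than 4 fractions, or with
zero spread, are "untestable" and fail the filter. With ~50 fractions this
construction passes clean Gaussian bands comfortably (discretization alone
gives D of a few percent) and rejects well-separated bimodal bands; at very
small fraction counts (n ≲ 20) its power is limited — a consequence of the
deterministic, pseudo-sampling-free design, documented here and swappable.

### Filters before testing

OTUs with fewer than 10 reads summed over all fractions of both gradients
are removed; the 200 most abundant OTUs of the pair (summed per-gradient
relative abundance, ties broken by OTU id) are analyzed. OTUs absent from
one gradient are reported with null statistics rather than dropped.

## Shift ↔ excess atom fraction

The unlabeled buoyant density of DNA is linear in GC fraction G:
ρ = 1.646057 + 0.083506·G (g/ml). The average nucleotide molar mass is
M = 307.691 + 0.496·G (g/mol), and it carries 10 − 0.5·G carbon atoms
(A, T, G have 10 carbons; C has 9). A relative density increase Δρ/ρ maps
to the same relative molar-mass increase, so

    EAF = (M_light · ΔWM / WM₁₂) / ((10 − 0.5·G) · 1.003355) · (1 − 0.011112)

where 1.003355 g/mol is the ¹³C–¹²C mass difference and 0.011112 the
natural ¹³C atom fraction. G is inferred from the control-gradient WM by
inverting the density calibration. All six constants are explicit
`LabelingModel` fields, overridable from the YAML config and logged per
run. Negative shifts give negative EAF (never clipped), keeping
control–control comparisons symmetric around zero. At the 0.005 g/ml
threshold the model yields 0.092 EAF (≈9 APE) and varies by < 0.001 across
unlabeled densities 1.68–1.72 g/ml, so the headline correspondence does not
hinge on a GC assumption. The exact inverse (shift for a given EAF) places
labeled bands in the simulator and round-trips to 1e−12 relative.

## Gradient simulator

The simulator generates the statistical structure the analysis assumes and
nothing more. Each taxon bands as a Gaussian in density (the
diffusion–sedimentation equilibrium approximation) centered at its
GC-implied density, displaced in the labeled gradient by the shift its true
EAF implies. Band mass is integrated over each fraction's half-open density
interval (mass-conserving, not midpoint-sampled). Reads are multinomial per
fraction — 20 000 by default, constant across fractions, a per-fraction
vector accepted — so fractions with zero community DNA yield zero reads.
DNA yield per fraction is the community mass profile scaled to a total
(default 500 ng) with lognormal noise (CV 5%). Refractive indices are
emitted by inverting the density calibration plus Gaussian noise
(SD 1e−4); since that noise can invert neighboring fractions, written
fractions are ordered by measured density (each fraction keeps its own
counts). Identical seeds give byte-identical files.

Default study conditions: 50 fractions spanning 1.66–1.77 g/ml; the
bundled community generator draws 200 taxa with lognormal abundances
(σ = 1.5 — a few dominants, a long rare tail), GC uniform on 0.30–0.65
(marine bacterioplankton range), 30 labeled taxa with EAF uniform on
0.09–0.55 scattered across the abundance spectrum. Band SD defaults to
0.006 g/ml; nothing in typical fraction data constrains it tightly, so it
is a stated, per-taxon-configurable assumption.

What the simulator does *not* emulate: PCR/primer bias, chimeras,
cross-fraction carryover, non-Gaussian band tails, gradient-to-gradient
density-axis distortion, and compositional coupling between many labeled
taxa shifting at once. Passing the recovery tests therefore shows the
statistic is consistent and unbiased under its own model, not that real
gradients are free of these artifacts.

## Tracer uptake rates

Two-pool mixing: particulate carbon is ambient carbon at the baseline (t₀)
¹³C atom fraction plus substrate-derived carbon at the substrate's atom
fraction (default 0.99, configurable — lot purity is rarely reported).
Carbon uptake = POC·(AF_t − AF_t0)/((AF_substrate − AF_t0)·Δt), in nM C/day;
dividing by carbons per molecule (10 for naphthalene) gives nM substrate/day.
Zero or negative enrichment is reported as rate 0 with a below-detection
flag. Atom fractions are assumed instrument-corrected; filter-retention
losses are not corrected, so rates are conservative. Replicates aggregate
to mean ± SD per site. The amendment check converts solubility to µM
(1000·mg/l ÷ g/mol; 30 mg/l naphthalene = 234 µM) and reports its ratio to
the amended concentration.

## Coverage response

Q2Q3 mean coverage sorts a MAG's per-base coverages, drops the lowest and
highest ⌊n/4⌋ positions, and averages the rest — robust to conserved genes
and islands. Trim counts use floor per tail; the stable sort makes ties at
the boundary deterministic. Coverages are normalized per million library
reads and log10(x+1)-transformed (pseudocount 1; both configurable).
Amended-vs-baseline comparison is a one-sided rank-sum test: the null is
enumerated exactly over group assignments (midranks for ties) when both
groups have ≤ 8 samples, otherwise the tie-corrected normal approximation;
a MAG is enriched when p < 0.05 *and* the amended median is higher. The
single-copy-gene cell fraction is (gene reads / total reads) divided by a
benchmark single-copy gene's expected metagenome fraction (default 0.1%).

## Numerical and design choices

- Gradient tables are TSV, '.' decimal, '#' comments, one gradient per
  file; OTU columns are everything outside the reserved set
  {fraction, n_c, density, dna_ng}.
- Fraction order may be heavy-to-light or light-to-heavy on disk; profiles
  are reordered to increasing density internally. Non-monotonic density
  sequences are an error naming the offending fractions.
- When both density and refractive index are present they must agree within
  1e-4 g/ml under the calibration.
- No refractometry temperature correction is applied.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  output embeds a digest of the effective configuration.
- Plots (optional, `--no-plots` / config flag) draw both gradients' curves
  against density with weighted-mean verticals and the ΔWM annotation to 4
  decimals, on the non-interactive backend.

## Problem sizes used in the test suite

Recovery and false-positive properties run 20 seeded replicates of the
default study (200 taxa, 50 fractions, 20 000 reads/fraction); the
detection-power monotonicity grid uses 3 EAF × 3 abundance levels with a
4-taxon community and 5 000 reads/fraction, 20 seeds per cell. These sizes
give stable frequencies while keeping the default suite fast.

## Known limitations

- ¹³C only; ¹⁸O/¹⁵N labeling would need different mass constants.
- No per-taxon measured-GC overrides; GC is inferred from the control WM.
- No bootstrap confidence intervals on EAF; no growth-rate estimators.
- The KS filter's power is low for distributions supported on few
  fractions (by construction it can never reject below ~20 supporting
  fractions at α = 0.05); such OTUs pass the filter rather than being
  flagged, so sparse multi-banded artifacts are caught mainly by the
  read-count and abundance filters.
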