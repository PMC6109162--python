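# Methods

This note documents the models, estimators, numerical choices and known
limitations of `andescan`, in the order the pipeline runs them.

## Data model and inclusion rules

Genotypes are derived-allele dosages (0/1/2, −1 missing) over variants ×
samples. Polarization comes from the VCF `AA` INFO tag, optionally
overridden by a TSV; SNPs without an ancestral assignment stay in PBS and
XP-EHH (both are invariant to allele relabeling) but are dropped from iHS,
which needs ancestral/derived orientation. Missing genotypes shrink
per-group chromosome counts SNP-wise; no call-rate threshold is imposed
beyond the scan's inclusion rule, which keeps exactly the SNPs segregating
(0 < derived frequency < 1) in at least two of the three groups.
Coordinates are 1-based in VCF and the variant table, half-open 0-based in
BED, converted at the boundary.

## FST and PBS

The default FST estimator is the Reynolds (1983) coancestry moment
estimator for a biallelic locus, computed on group-pooled counts. With
sample frequencies p₁, p₂, diploid sizes n₁ = c₁/2, n₂ = c₂/2 (c = called
chromosomes) and αᵢ = 2pᵢ(1−pᵢ):

    a = (p₁−p₂)² − (n₁+n₂)(n₁α₁+n₂α₂) / (4n₁n₂(n₁+n₂−1))
    b = (n₁α₁+n₂α₂)(4n₁n₂−n₁−n₂) / (4n₁n₂(n₁+n₂−1))
    FST = a / (a + b)

`a` is exactly unbiased for zero when both samples come from one
population (verified analytically and by simulation), and FST → 1 at a
fixed difference. Hudson (Bhatia et al. 2013 form) and Weir–Cockerham
(1984) estimators are available behind a flag. Whether group-pooled counts
or averaged per-population FSTs are the right aggregation is genuinely
open; pooled counts are the implemented default.

Raw FST may be negative; it is clamped to [0, 1−1e−9] only inside the
branch transform T = −log(1−FST) (the cap keeps T finite at fixed
differences). PBS = (T_and_meso + T_and_amaz − T_meso_amaz)/2 is recorded
as-is, including negative values.

Windows hold exactly 20 SNPs and advance by 5; they restart at chromosome
boundaries and trailing remainders are dropped rather than shrunk.
Percentile thresholds use linear interpolation (numpy default, type-7).
Outlier windows above a tier threshold whose SNP spans overlap or touch
are merged into one peak; the peak's top SNP is the maximum per-SNP PBS in
the merged span. Nearest-gene assignment returns distance 0 inside an
interval, otherwise the minimal bp distance to an interval boundary, ties
broken toward the smaller interval start.

## Demographic models and the coalescent null

Three presets, with splits at 15,000 yBP (Mesoamerican) and 12,000 yBP
(Andean/Amazonian) converted at 25 y/generation:

* **constant** — Ne 7,000 everywhere;
* **bottleneck** — Ne 8,000 (Mesoamerican), 4,000 (Andean), 2,000
  (Amazonian); the Amazonian bottleneck starts at the 10,000 yBP
  colonization date, with the lineage at the Andean source size 4,000
  between split and colonization; ancestral lineages take Ne 8,000;
* **bottleneck_expansion** — the bottleneck model with every population
  halved over the last 10,000 years and a sharp expansion over the last
  8,000 years. The expansion factor is not pinned down by the historical
  record we model; it defaults to 10× the bottlenecked size and is a
  parameter.

The simulator is a standard structured coalescent without migration:
within a population, k lineages coalesce at rate k(k−1)/2 per 2Ne(t)
generations with piecewise-constant Ne, and whole populations merge at
split times. Waiting times are drawn epoch-aware and vectorised; pair
choices are pre-drawn per phase, which makes 10,000 replicates at the
study sizes (126/212/306 chromosomes) take well under a minute.

Each null replicate places a single mutation on a branch chosen
proportionally to branch length (infinite sites, one segregating site per
replicate — the null needs per-SNP PBS values and no mutation rate is
involved), applies the same polymorphic-in-≥2-groups filter as the
empirical scan (failing replicates are redrawn wholesale and counted), and
scores Reynolds-FST PBS. Simulation p-values use the add-one rule
p = (1 + #{null ≥ obs}) / (n_reps + 1), so the smallest attainable value
at 9,999 replicates is 1e−4.

Two subtleties surfaced while validating the simulator, both documented in
the validation utilities:

* The drift law E[FST] = 1 − exp(−t/2Ne) for a clean two-population split
  applies to *ancestral standing variation*. Sites generated as single
  mutations anywhere on the tree converge instead to Slatkin's
  t/(t+2Ne). `standing_variation_fst` therefore conditions on mutations
  older than the split; with that conditioning the law is reproduced to
  three decimals.
* The 1/i neutral site-frequency spectrum is a property of
  mutation-rate-weighted sites, i.e. of expected branch-class lengths
  E[Lᵢ] ∝ 1/i. Conditioning one mutation per tree weights trees by the
  reciprocal of their total length and visibly distorts the spectrum, so
  `panmictic_sfs_lengths` accumulates class lengths directly.

## Haplotype statistics

EHH of a core allele at flank x is Σᵢ C(eᵢ,2) / C(n,2) over the identity
classes of the carrier haplotypes between core and flank inclusive,
computed by incremental partition refinement (non-increasing by
construction). iHH integrates the decay curve trapezoidally over physical
distance, each side truncated at the first flank where EHH < 0.05 (that
flank's trapezoid included) or at a gap > 200 kb; a side that never decays
is integrated to the data edge and flagged censored. These defaults follow
common rehh conventions; the exact settings behind published rehh analyses
are generally unrecoverable, so numerical reproduction of published XP-EHH
values is not attempted.

iHS = ln(iHH_ancestral / iHH_derived), standardized within 20 equal-width
derived-frequency bins. XP-EHH uses allele-agnostic EHH (all haplotypes,
core column included in the identity check, so the curve starts at the
core-site homozygosity), raw = ln(iHH_test / iHH_ref), standardized
genome-wide; positive means extended homozygosity in the test (Andean)
population. The default XP-EHH p-value is the one-sided empirical rank
p = (1 + #{other scores > s}) / (N + 1); a normal upper-tail option exists
behind a flag. Published score/p pairs for this statistic are inconsistent
with simple normal tails, which is why the empirical rank is the default.

Haplotype statistics require phased input; phasing real genotypes is out
of scope and the synthetic generator supplies phased data.

## Synthetic data

The generator's defaults are the study conditions: 63 Andean, 106
Amazonian and 153 Mesoamerican individuals in 11 named populations with
plausible Altiplano/Amazon/Mesoamerica coordinates and altitudes; 5,000
SNPs (2,000 in the sweep-recovery analyses, large enough that a swept core
does not contaminate the genome-wide XP-EHH standardization) spaced ~5 kb;
ancestral frequencies from Beta(0.8, 0.8) truncated to [0.05, 0.95] to
mimic array ascertainment toward common variants.

Genotypes come from either a hierarchical Balding–Nichols backend — group
frequencies drawn with per-branch F = 1 − exp(−∫dt/2Ne(t)) along the
((Andean, Amazonian), Mesoamerican) topology of the chosen demographic
model, genotypes binomial — or from the coalescent backend, which draws
one filtered genealogy + mutation per SNP from the same simulator as the
null (used where observed and null PBS must share a distribution, e.g.
calibration checks).

Haplotypes are mosaics copied from a 24-founder panel with geometric block
lengths (mean 15 SNPs), giving background LD that decays with distance. A
sweep is realised two ways, matching how each statistic sees a real sweep:

* **frequency view** (`inject_sweep`): the target SNP's genotypes are
  redrawn binomially at 0.40 (Andean) and 0.05 (both lowland groups) —
  the magnitudes of the reported candidate loci — leaving all other SNPs
  untouched;
* **haplotype view** (`generate_haplotypes` with a sweep): a carrier
  fraction equal to the target frequency shares one founder haplotype
  over a 300 kb core with sparse flips (rate 0.002 per SNP, standing in
  for recombination leakage; de-novo mutations would not be
  array-ascertained SNPs).

The mosaic model does not emulate genealogical recombination, ascertainment
correction, or drift between sub-populations of a group; passing tests
show the statistics respond correctly to sweep-like structure, not that
the generator reproduces real LD spectra.

### What the windowed scan can and cannot recover

A deliberate finding from the package's own power analysis: at the
0.40-vs-0.05 contrast the target's per-SNP PBS (~0.45) is essentially
always in the genome-wide top handful, and clears the per-SNP 99.5th
percentile in ~95% of replicates, but a *single* elevated SNP diluted
1/20 in window means clears the empirical 99.5th window percentile only
about half the time (a lone SNP would need PBS ≈ 0.8). Windowed detection
of real sweeps rests on hitchhiking clusters; with a realistic shared-core
fixture the window is flagged, but the top SNP of the peak is then often a
perfect-LD proxy inside the core rather than the focal SNP — just as
several SNPs per candidate locus carry similar PBS in real scans. The
acceptance suite states the strict windowed recovery check and reports the
outcome honestly rather than redefining recovery.

## Bootstrap and geography

Bootstrap CIs resample individuals with replacement within each population
(preserving per-population size and genotypic proportions), recompute the
size-weighted group frequency per replicate, and take the 2.5th/97.5th
percentiles of 10,000 replicates. Empirical coverage at the study's
lowland sizes is ~94–95%. The highland/lowland cutoff is 4,000 m for the
bootstrap contrast; the 2,500 m descriptive bound is exposed as a
parameter (both cutoffs are legitimate and neither is guessed to be an
error).

IDW surfaces use power 2 and haversine great-circle distances, include
only populations with n ≥ 3, are exact interpolators at sample
coordinates and bounded by the sample extrema. Output is a plain TSV
raster (lat, lon, value); cartography is out of scope.

## Reproducibility

Every stochastic stage takes a seed derived from a master seed by stable
hashing of the stage name (CRC32, reduced below 2³¹), so stages have
independent streams and a full-scan rerun is byte-identical. Manifests
record the resolved configuration and seeds and contain no timestamps.

Problem sizes in the test and acceptance runs are the package's own
choices: 10,000 replicates for the null, bootstrap and coalescent
validation checks; 1,000–5,000-SNP fixtures for oracle and calibration
checks; 20 seeded replicates for sweep recovery; the end-to-end
determinism check runs a reduced configuration (400 SNPs, 400/500
replicates) because determinism is independent of replicate counts.
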