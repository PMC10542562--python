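# Methods

This note documents the models, rules, and numerical choices behind each
stage of the pipeline, the design decisions that were genuinely open, and
what the synthetic-data tests do and do not establish about real cohorts.

## Virome typing

Presence of an RNA virus or M satellite is called from a multi-primer-pair
PCR panel by the rule *present iff ≥ 1 unmasked pair is positive*. Survey
panels use multiple pairs precisely because template-level and sequence
variation make single pairs unreliable; requiring a quorum would instead
miss low-abundance or variant elements, so single-pair evidence is
accepted. Pairs listed in a panel's `cdna_mask` are attributable to a
nuclear cDNA copy of the element (an annotation supplied with the data —
detecting such copies from genome sequence is out of scope); masked
positives never contribute to presence and instead raise a `cdna_signal`
flag, which the curing checker treats as exempt (a chromosomal cDNA keeps
amplifying after the cytoplasmic element is cured).

The PCR genotype is the ordered 0/1 product string, so a v-pair virus
admits at most 2^v − 1 non-null genotypes. Relative quantification follows
the standard 2^(−ΔΔCq) method: ΔΔCq = (target − reference) cycles in the
sample minus the same difference in a calibrator; the quantity is
dimensionless, equals 1 when sample and calibrator deltas agree, and halves
per extra cycle. L-BC abundance is dichotomized: gel path (4.6-kb band ⇒
hi) or qPCR path (relative level ≥ `hi_threshold`, default 2.0 relative
units). The default threshold is a package choice — no numeric cut is
published — set so that clearly band-positive levels (severalfold above the
calibrator) land hi and sub-calibrator levels land lo; it is a keyword
argument. Supplying both evidence paths at once is an error rather than a
precedence rule, so the caller's intent is always explicit.

Cohort validators emit violations as data, not exceptions: helper
dependence (M satellite present without L-A), satellite exclusion (two M
species in one strain), cocuring (derivative retains M after L-A loss), and
inconsistent curing (a "cured" derivative still L-A positive).

## Killer phenotyping

Assay scores are qualitative bins {2, 1, 0.5, 0} for both killing-zone size
and methylene-blue staining, in decreasing order of killing. Killer status
derives from the maximum zone bin across all tested lawns: ≥ 1 ⇒ K⁺, 0.5 ⇒
K± (partial), 0 ⇒ K⁻. M-satellite dependence holds when a killing parent
loses all killing upon curing; any retained killing raises a residual flag,
the signature of a chromosomally encoded toxin. Resistance of a lawn to a
toxin requires zone 0 and staining ≤ 0.5 against *every* K⁺ reference
killer of that toxin; with no active reference the call is refused for lack
of evidence.

For association, the zone bin is the phenotype and is normalized by the
rank map {0, 0.5, 1, 2} → {0, 1, 2, 3}; the stain bin is retained as a
secondary annotation because no published rule combines the two scores.

The six KHS1 classes cross the allele category with two phenotypes
(killing the *C. glabrata* tester; being killed by the strong reference
Khs1 killer): (no-kill, killed) ⇒ 1; (no-kill, resistant) ⇒ 2; (kill,
resistant) ⇒ 3A for full-length ORFs else 3B; (kill, killed) ⇒ 4A for
premature-stop/absent alleles else 4B. Absent and double-stop alleles
group with opal on the non-functional side, consistent with class 1
containing absent, opal, and opal+ochre strains. "Kills *C. glabrata*"
means any zone bin > 0 (killing is reported "to varying degrees"); a
stain-based tie-break for borderline killed-by-reference calls is not
published, so the zone rule is used throughout. Khr1 testing exists only
as an assay condition (pH 6, SD+MB medium); no Khr1-specific caller is
provided because no Khr1 killing is observed in this design.

## ORF screening

Premature stops are in-frame TAA (ochre), TAG (amber), TGA (opal) strictly
before the final codon, reported with 1-based codon indices (codon 1 =
ATG), matching allele names like W66-opal. Inputs must be annotated ORFs:
frame 0, starting ATG, length divisible by 3, ACGT only — a
reverse-complement or out-of-frame sequence fails validation rather than
being scanned silently. Allele categories: absent (no sequence),
full_length (no premature stop), opal (exactly one opal), opal_ochre (one
opal + one ochre), other.

Species of origin is assigned by percent identity against the two
reference ORFs: positionwise ungapped identity for equal lengths,
edit-distance identity (1 − d/max length, via edlib) otherwise. A margin
under 1 percentage point (configurable) is called ambiguous. This is an
allele-level proxy: real introgression calls come from genome-scale
analysis, which is out of scope.

## Association

The stage mirrors a sparse-GRM mixed-model GWAS of an ordinal phenotype.

*Site filtering.* Minor allele frequency ≥ 0.05, inclusive. LD pruning is
greedy and windowed: within each sliding window (default 50 sites, step
5), sites are considered in order of decreasing MAF (ties by ascending
index) and kept only if their squared dosage correlation with every
already-kept site in the window is ≤ 0.5. The published analysis used a
pairwise-r² pruning option whose window and step are not stated; these
defaults are declared package choices and a known divergence risk, both
configurable.

*GRM.* K_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i)/(2p_i(1−p_i)) with
sample allele frequencies; missing dosages are mean-imputed per site, and
monomorphic sites are excluded with a warning (zero variance). The sparse
GRM zeroes off-diagonal entries below 0.05 (diagonal untouched), which
also removes all negative entries; this follows the sparse-threshold
family of mixed-model GWAS tools. In the pipeline the GRM is estimated
from LD-pruned sites, and all MAF-passing sites are then tested.

*Mixed model.* y = μ + g + e, cov(g) = σ²_g K, cov(e) = σ²_e I. Variance
components come from Haseman–Elston regression — σ²_g is the regression of
pairwise phenotype cross-products on the off-diagonal GRM entries, clamped
to [0, var(y)], with σ²_e the remainder (floored at 10⁻⁸·var(y) so weights
stay finite; a constant phenotype then yields p = 1 everywhere rather than
an error). Each site gets a generalized-least-squares score test with the
intercept projected out, p from χ²₁, two-sided by construction. K is
eigendecomposed once, after which every phenotype replicate's GLS reduces
to diagonally weighted sums in the rotated basis; permutation and jitter
replicates are therefore processed as matrix batches with variance
components re-estimated per replicate. With an identity K the HE numerator
vanishes and the test reduces exactly to the ordinary score test
χ² = n·r².

*Permutation threshold.* Phenotypes are permuted wholesale across strains
(breaking both the genotype link and the phenotype–relatedness link; the
published analysis does not state whether structure was preserved), the
model is refit per permutation, and the threshold is the 0.05 quantile of
the minimum-p distribution over 1,000 permutations. Under independent null
sites this tracks the Šidák value 1 − 0.95^(1/m); the comparison is only
clean when the GRM comes from a separate panel, since a GRM estimated from
the tested sites themselves couples the tests.

*Jitter filter.* Each of 100 replicates adds N(0, 0.25²) elementwise to
the normalized 0–3 phenotype — randomizing rank order within ordinal
classes while essentially preserving it between classes (adjacent classes
are 1 apart, so a cross-class inversion per pair has probability
Φ(−1/(0.25√2)) ≈ 0.23%) — and a site is reported only if it stays below
the threshold in ≥ 70% of replicates. The SD of 0.25 is meaningful only on
the normalized scale, which is why normalization precedes jittering. A
"peak" is a single site; adjacent significant sites are not merged.

## Synthetic cohorts

The generator produces cohorts with the structure the analysis assumes,
not population-genetic realism. Genotypes follow the Balding–Nichols
model: ancestral frequencies Uniform(0.1, 0.9); subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) so expected differentiation equals `fst`
(default 0.2, three equal subpopulations of 100 strains — a stylized
version of a structured survey cohort); dosages are two binomial draws.
There is no linkage disequilibrium, recombination map, or coalescent
history — duplicated columns are the only LD the pruning tests see — so
passing tests demonstrate correct statistics under the assumed model, not
robustness to real LD structure or uneven sampling.

The ordinal phenotype comes from a latent liability: causal effect ×
standardized causal dosage + a polygenic term with covariance proportional
to the realized GRM (variance = `heritability_background`, default 0.3) +
Gaussian residual (the remainder), cut at the empirical 50/75/90%
quantiles into bins {0, 0.5, 1, 2} to mimic the rarity of strong killers.
When a causal site is planted its ancestral frequency is pinned at 0.5
(subpopulation drift still applies): a planted-locus recovery experiment
presumes a common variant, and without the pin some draws put the "causal"
allele near fixation or below the MAF filter, where recovery is undefined
rather than failed.

Virome tables enforce the dependency rules by construction (satellites
only in L-A⁺ strains, at most one M species each, L-BC universal with a
hi/lo split); default prevalences reproduce the observed cohort rates
(30% L-A⁺, 26% 20S⁺, 14% 23S⁺, satellites at 5/3/0/7 of the 30 L-A⁺
strains). Per-pair dropout (default 0.15) generates PCR-genotype variety
for the viruses; satellites show none, as observed. Killer assays follow
the noiseless rule (active toxin × unprotected lawn ⇒ strength bin, else
0), with misclassification implemented as adjacent-bin swaps only — assay
noise is local on an ordinal scale.

All randomness derives from one root seed; each stage draws from a child
generator keyed by a CRC32-hashed stage name through NumPy's SeedSequence,
so stages are independent and reruns bit-identical across platforms.

## Problem sizes used in the checks

The simulation-based checks run at desk scale, chosen to make the
diagnostics statistically meaningful while keeping the suite quick: null
calibration at n = 200 strains × 2,000 sites over 50 cohorts (genomic
inflation λ = median χ² / χ²₀.₅); Šidák comparison with a GRM from a
separate 2,000-site panel and 100 tested sites; planted-locus recovery at
n = 100 × 500 over 50 cohorts with the full permutation + jitter pipeline.
The published genome-scale numbers (142,313 sites, thresholds of order
10⁻⁶–10⁻⁹) require the real cohort's variant data and are deliberately not
reproduced.

## Known limitations

- The packaged L-BC table encodes the printed column counts (33 hi / 67
  lo); the source's own text gives 31 or 32 in places, and the discrepancy
  is documented rather than resolved.
- The per-strain KHS1 table is a synthetic stand-in realizing the
  published class-level description; it exercises the classification
  logic but is not measured data.
- Species-of-origin calls are percent-identity proxies; no alignment-based
  introgression tract detection.
- The mixed model has no covariates, dominance terms, or multi-trait
  support; the exact r×c test is Monte Carlo beyond total count 30.
- Sparse-GRM correction leaves a small upward drift of λ relative to the
  full GRM on strongly structured cohorts (the cost of discarding negative
  relatedness entries); the calibration check quantifies it.
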