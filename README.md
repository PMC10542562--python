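# killerome

Analysis pipeline for population surveys of yeast RNA viruses, M satellites,
and killer phenotypes — the kind of survey that types a cohort of
*Saccharomyces cerevisiae* strains for the cytoplasmic totiviruses (L-A,
L-BC), narnaviruses (20S, 23S), and L-A-dependent M satellites (M1, M2, M28,
Mlus) by multi-primer PCR and gel electrophoresis, scores killer phenotypes
on methylene-blue plates, screens the chromosomal killer genes *KHS1* and
*KHR1* for premature stop codons, and asks which genotypes explain the
killing phenotypes.

It is aimed at yeast geneticists who have per-strain PCR panels, assay score
matrices, genotype matrices (TSV dosage or VCF), and ORF FASTA files, and
want the published calling, classification, and association logic as tested,
reusable code — plus a synthetic-cohort generator so every stage can be
exercised and validated without any real data.

## What it computes

**Virome typing** (`killerome.virome`). A virus is present iff at least one
unmasked primer pair yields a product; pairs attributable to nuclear cDNA
copies are masked and can only produce a "cDNA signal" flag. Per-virus PCR
genotypes are the 0/1 product patterns (e.g. `0,1,0`). L-BC abundance is
dichotomized hi/lo from a 4.6-kb gel band or, where gels are unavailable,
from RT-qPCR relative quantification 2^(-ΔΔCq). Cohort-level validators
enforce helper dependence (M satellites require L-A), satellite exclusion
(one M species per strain), and cocuring (L-A⁺M⁺ → L-A⁰M⁰).

**Killer phenotyping** (`killerome.killer`). Killing-zone and staining
scores live on the ordinal bins {2, 1, 0.5, 0}; a strain's status is K⁺ /
K± / K⁻ from its maximum zone over lawns, and M-satellite dependence is
decided by parent-versus-cured comparison. The six KHS1 classes cross the
allele category with killing of the *C. glabrata* tester and being killed
by the strong reference Khs1 killer.

**ORF screening** (`killerome.orfs`). In-frame premature stops (TGA=opal,
TAA=ochre, TAG=amber) with 1-based codon indices — the classic W66-opal
*khs1* allele reports as `(66, opal)` — plus species-of-origin assignment
by percent identity against *S. cerevisiae* and *S. paradoxus* references
(introgression detection at the allele level).

**Association** (`killerome.assoc`). For an ordinal phenotype normalized to
the 0–3 scale: MAF ≥ 0.05 filtering, greedy windowed LD pruning (r² > 0.5),
a genetic relationship matrix from standardized dosages

```
K_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),
```

sparsified at 0.05; the mixed model y = μ + g + e with cov(g) = σ²_g K,
variance components by Haseman–Elston regression, and a per-site GLS score
test (χ², 1 df). The family-wise threshold is the 0.05 quantile of the
minimum p over 1,000 phenotype permutations, and fragile peaks are removed
by requiring significance in ≥ 70% of 100 jittered replicates
(y + N(0, 0.25²)).

**Contingency statistics** (`killerome.stats`). Fisher's exact test (2×2),
a margin-conditional exact/Monte-Carlo test for r×c tables, and a pairwise
co-occurrence screen with Benjamini–Hochberg correction.

**Synthetic cohorts** (`killerome.simulate`). Balding–Nichols structured
genotypes, latent-liability ordinal phenotypes with a planted causal locus,
virome tables obeying the dependency rules, ORF sets with planted stops,
and killer-assay matrices from a toxin/resistance truth.

Packaged reference tables (`killerome.datasets`) encode the published
survey summaries (PCR panel design, L-BC genotype-by-level counts, the
17-strain M-satellite table) and a synthetic per-strain stand-in for the
KHS1 class census.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
100-strain cohort and write their tables under `results/`:

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/05_association.py    --seed 1
```

prints

```
tested 481 sites (of 500) after MAF filtering
permutation family-wise threshold (0.05 quantile of min p): 2.112e-04
sites passing threshold: 1
robust sites (>=70% jitter retention): 1
  site00251: p=1.77e-10, effect=+0.931, jitter retention 100% <- planted causal locus
```

i.e. of the 500 simulated sites, 481 pass the MAF filter, the permutation
min-p distribution puts the family-wise 5% threshold at 2.1×10⁻⁴, and the
single site exceeding it in ≥70% of jittered replicates is exactly the
planted causal locus (liability effect 1.5 SD). The other drivers type the
virome (`02`), census the ORF alleles and KHS1 classes (`03`), call killer
status and M dependence (`04`), and run the co-occurrence screen (`06`).

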