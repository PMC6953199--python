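# soyadapt

A pipeline for dissecting local adaptation in soya bean landrace panels:
from per-site sequencing read depths to called genotypes, population
structure, linkage disequilibrium and diversity statistics, bioclimatic
traits derived from collection-site passports, genome-wide association
scans, and selection-signal classification of trait-associated SNPs (TASs).

Landraces — farmer-developed varieties predating modern breeding — carry
adaptive alleles (for example photoperiod-response variants governing
flowering time) that track the latitude of their home sites. The analyses
here treat both measured phenotypes (days to flowering at two common-garden
locations) and bioclimatic variables of the collection sites — temperature
annual range (TAR), annual precipitation (AP), and the maximum daylength
between sowing and harvest (MDL) — as quantitative traits for association
mapping. Because the motivating panels involve thousands of accessions of
restricted-access germplasm, the package ships a first-class synthetic-data
generator that reproduces the statistical structure every stage assumes
(differentiated subpopulations, distance-decaying LD, selfing-level
homozygosity, additive flowering-time genetics, Poisson read depths), so the
whole pipeline is testable end to end on a desktop.

## The models at the core

**Genotype calling.** With read counts (n_major, n_minor, n_other) at a cell
(total n), a site is called homozygous for the allele with more reads when
that allele has ≥ 2 reads and ≥ 90% of n; heterozygous when both alleles
have ≥ 1 read, each ≥ 20% of n, and together ≥ 5 reads making ≥ 90% of n;
otherwise missing. Filtering retains sites with MAF ≥ 1%, heterozygosity
≤ 20% and missingness ≤ 70%, drops samples with ≥ 80% missing data, imputes,
and re-screens (≥ 20 homozygous-minor carriers).

**Differentiation and diversity.** Weir–Cockerham (1984) Fst from the a, b,
c variance components (per SNP, 30-kb windows, and the genome-wide ratio of
sums Σa/Σ(a+b+c)); Watterson's θ_w = S/(a_{n−1}·L) per window;
composite LD r² as the squared dosage correlation, binned into 1-kb distance
classes; the reported LD extent is the distance at which mean r² halves.
Pst = (c/h²)σ²_B / ((c/h²)σ²_B + 2σ²_W) proxies Qst for trait
differentiation.

**Photoperiod.** The CBM daylength model: θ = 0.2163108 +
2·arctan(0.9671396·tan(0.00860(J−186))), δ = arcsin(0.39795·cos θ), and
D = 24 − (24/π)·arccos[(sin p + sin φ sin δ)/(cos φ cos δ)] hours at
latitude φ, with p = 0.8333° for apparent sunrise/sunset. MDL maximizes D
over the sowing-to-harvest window.

**Association.** A FarmCPU-style iterative scan alternates a fixed-effect
model (testing each SNP with current pseudo-QTNs as covariates) with a
random-effect model (kinship built from pseudo-QTN dosages selects, by
restricted likelihood, how many binned top candidates to keep), with the
Bonferroni convention α/m for significance. Per-TAS phenotypic variance
explained comes from full-versus-reduced linear models (PVE_j = R²_full −
R²_j); narrow-sense heritability h² = σ²_a/(σ²_a + σ²_e) from GRM-REML with
the variance-standardized relationship matrix.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on the bundled
desk-scale panel (600 accessions, 4000 SNPs; one wild group plus NR/HR/SR
landrace subpopulations at the published pairwise Fst levels):

```sh
python analysis/01_simulate_panel.py
python analysis/02_call_genotypes.py
python analysis/03_population_structure.py
...
python analysis/08_selection.py
```

Selected output from a run (seed 20210905):

```
final call set: 3977 sites x 600 samples
concordance with truth at depth 13 (post-imputation): 0.9850
assignment: 600/600 non-admixed, accuracy vs truth 1.000
LD half-decay distance (wild): 15 kb
LD half-decay distance (landrace): 55 kb
corr(MDL, TAR) = 0.97
FT_loc1: 11 TAS at p<=3e-06, lambda_GC=0.997
joint PVE of the TAS set (location 1): 63.7%
early-allele count vs flowering time: r = -0.75 (p = 4.3e-108)
```

Reading this: calling from mean-depth-13 reads recovers 98.5% of true
genotypes after imputation; PCA/k-means recovers the simulated
subpopulations; landraces hold LD over longer distances than the wild group
(a bottleneck signature); MDL and TAR are nearly collinear because both
track latitude, which is why photoperiod and temperature signals are hard to
separate; the flowering-time scan recovers most of the planted architecture,
and accessions stacking more early-flowering alleles flower earlier.

Equivalent single commands: `soyadapt all --config analysis/config.yaml`
runs every stage; individual subcommands (`simulate`, `structure`, `gwas`,
...) stop after the named stage.

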