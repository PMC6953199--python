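# Methods

This note documents the models, estimators and design choices behind each
pipeline stage, what the synthetic panel does and does not emulate, and the
numerical conventions that matter for reproducing results.

## The synthetic panel

The generator produces a structured diversity panel that mimics a
geo-referenced landrace collection plus a wild outgroup. All randomness
derives from a single integer seed; each operation (geography, climate,
genotypes, phenotypes, depths) draws from its own sub-stream keyed by
operation name, so re-running one stage never perturbs another.

**Geography.** Accessions are placed uniformly within group latitude bands —
WILD 24–53°N, NR 40–51.4°N, HR 34–40°N, SR 18.2–34°N; longitudes 80.5–134°E;
gamma-distributed nonnegative altitudes — and carry group-level sowing and
harvest days (spring sowing in the north through later, longer seasons in
the south). Landrace ecotype labels are sampled in proportion to the seven
ecotype counts of the reference panel (NESp 269, NSp 362, HSp 26, HSu 415,
SSp 249, SSu 529, SAu 88).

**Climate.** TAR and AP are linear latitude trends plus Gaussian noise, with
slopes calibrated so the simulated ranges over 18.2–51.4°N match the
reference panel (TAR 14.4–58.7 °C rising north; AP 81–1986 mm rising south;
noise sd 2.5 °C and 120 mm). MDL is computed deterministically from the
daylength model — consequently corr(MDL, TAR) ≈ 0.97, reproducing the
near-collinearity of photoperiod and temperature variables that complicates
bioclimatic association mapping. No raster emulation is attempted.

**Genotypes.** Differentiation follows the Balding–Nichols model: ancestral
frequencies p ~ U(0.05, 0.95); each group's frequency is Beta-distributed
with drift parameter F_g. Pairwise Weir–Cockerham Fst between independent
groups satisfies E[Fst] ≈ (F_g + F_h)/2, so per-group F values are solved by
least squares from the pairwise targets (exact for any two-group design and
for the default landrace triple 0.077/0.136/0.164; infeasible targets raise
an error naming the pair). LD is created by a copula-style copying process:
along a chromosome, each haplotype reuses the previous site's latent uniform
with probability exp(−d/λ) (λ = `ld_copy_decay_bp`, default 100 kb; the wild
group uses 20 kb to reproduce its faster decay). Copying correlates the
Bernoulli draws without touching the marginal frequencies, so Fst recovery
stays unbiased. Individuals are near-fully homozygous: with probability
`selfing_fis` (default 0.95) a cell is autozygous (both haplotypes share one
allele draw), giving heterozygosity 2pq(1−F_IS) ≈ 1–2%, the level a selfing
crop shows and the level the het ≤ 20% site filter presupposes. Sites are
re-oriented after simulation so code 2 is always the realized panel-wide
minor allele.

**Phenotypes.** Flowering time is additive: 20 causal SNPs (default) with
per-allele effects drawn ∝ 1/√(2pq) — the standardized-effect convention the
GRM-REML model assumes, so every causal site contributes equal expected
variance — plus an intercept (60 d), a location offset (0 / −15 d), and
Gaussian noise scaled from the empirical genetic variance so that the
additive h² equals `h2_target` (default 0.66, between the two reference
location estimates 0.625 and 0.704) at each location. The two locations
share identical genetic values, so their phenotypic correlation converges to
h². A stated design goal of "correlation near 0.9 with h² near 0.6–0.7" is
not jointly attainable in a purely additive shared-genetics model; the
correlation-equals-h² behaviour is the one guaranteed and tested.

**Read depths.** Per-cell total depth is Poisson (mean 13); a `missing_rate`
fraction of cells is zeroed; reads split binomially by true dosage with a
symmetric sequencing error (default 0.002) toward the other allele.

**What the panel does not emulate.** No coalescent history (no site
frequency spectrum realism, no private-allele structure beyond BN sampling),
no recombination maps, no genotype-environment interaction, and — notably —
no geographic cline in causal-allele frequencies: flowering-time effects are
drawn independently of group membership, so on the default panel the
phenotype shows little latitudinal differentiation, Pst for flowering time
is near 0, and the selection scans correctly report no signal at the planted
TASs. Tests of Pst and of the selection scans therefore construct divergence
explicitly. Passing tests demonstrate estimator correctness under the stated
statistical structure, not performance on real panels.

## Genotype calling and filtering

Calling is per-cell with exact rational-arithmetic thresholds (10·x ≥ 9·n
for "≥ 90%"), the homozygote rule evaluated before the heterozygote rule,
and read-count ties resolved under the heterozygote rule alone (the two
rules cannot both fire for totals ≥ 2; the exhaustive truth-table test
asserts this). The "20% of total" denominators include `other_reads` — a
literal reading of "total". The cascade order is fixed: site discovery
(pooled bi-allelic fraction ≥ 80% over cells with ≥ 5 reads) → calling →
site filters (MAF ≥ 1% over called alleles only, het ≤ 20%, missing ≤ 70%)
→ sample filter (missing ≥ 80% removed) → imputation → post-filter
(≥ 20 homozygous-minor carriers, MAF/het re-checked). All filters are
idempotent. The ≥ 20-carrier rule is calibrated for ~2000-sample panels; the
desk-scale configs scale it down proportionally.

Imputation offers two deterministic methods: `mode` (site-wise modal
genotype) and `knn-haplotype` (modal genotype of the k = 5 nearest samples
by mean dosage distance over a ±10-site window, exploiting local LD; falls
back to the site mode). Neither reimplements a haplotype-cluster model —
downstream statistics need completeness, not posterior dosages; the
masked-entry test verifies knn beats mode under high LD.

## Population structure

The relationship matrix standardizes each dosage column by its HWE scale
((x − 2p)/√(2p(1−p))) and averages the cross-product over polymorphic sites —
the PLINK `--make-rel` convention. PCA eigendecomposes this matrix;
coordinates are eigenvectors scaled by √eigenvalue with the largest-|loading|
entry forced positive for reproducibility. Admixture-model clustering is
replaced by k-means (20 restarts, fixed seed) on the top 3 PCs with
membership proportions from normalized inverse centroid distances; a sample
is MIXED when its top proportion falls below 0.55. Clusters are renamed
WILD (highest wild fraction) then NR/HR/SR by decreasing mean latitude.
Neighbour joining implements the Saitou–Nei Q-criterion with negative branch
lengths clamped to zero and the deficit moved to the sister branch; topology
is checked against an independent NJ implementation and against exact
recovery from additive distances.

## Differentiation, diversity, LD, Pst

Weir–Cockerham Fst uses the full a/b/c variance components including the
heterozygosity terms, which keeps the estimator valid for inbred panels
(verified by target recovery at F_IS = 0.95). Sites need ≥ 2 called samples
per group. The genome-wide value is the ratio of summed components; windowed
values are means of per-SNP estimates over 30-kb tiling windows (the window
is configurable; tiling is the default where a sliding step is not
specified). θ_w is reported per bp per 1-Mb window with S counted at
group-MAF ≥ 1%. LD r² is the squared Pearson correlation of dosage columns
(composite LD — inputs are unphased), restricted to intra-chromosome pairs
≤ 1 Mb. The decay profile bins pairs into 1-kb classes; the half-maximum
distance is the smallest bin midpoint at or below half the maximum bin mean
after isotonic (non-increasing) smoothing weighted by pair counts — raw bin
noise makes the first crossing unstable; the smoothing flag is recorded.
A TAS LD block is bounded by the farthest SNPs within ±1 Mb reaching
r² ≥ 0.8 with the focal SNP, collapsing to the focal position on empty
sides. Pst defaults to c = h² = 1 (both exposed) with variance components
from one-way ANOVA and a within-group bootstrap (1000 draws, percentile 95%
CI).

## Association scans

The baseline scan is per-SNP least squares with covariates (top 3 PCs by
default), t-test p-values, and not-estimable flags for SNPs collinear with
the design. The iterative scan follows the fixed/random circulating scheme:
(1) fixed-effect scan with current pseudo-QTNs as covariates, their own
p-values carried from the iteration that selected them; (2) candidates are
the best SNP per physical bin, swept over bin sizes {0.1, 0.5, 1} Mb,
screened at an entry p-value (default 0.01/m — without a screen, the
likelihood-based selection admits spurious pseudo-QTNs under the null and
family-wise error is uncontrollable); (3) candidates pruned to mutual
r² < 0.7 and capped at 20; (4) the accepted set is the candidate prefix
maximizing the restricted likelihood of a model whose kinship is built from
the pseudo-QTN dosages themselves. Iteration stops when the accepted set
repeats. Ties break by genome order; the scan is fully deterministic. With
`max_qtn = 0` it reduces exactly to the baseline scan. Significance uses the
Bonferroni convention α/m (α = 0.01), with the one-significant-figure
rounding reported alongside; a core-panel flag switches to the 1e-6
convention for smaller panels. λ_GC is the median observed χ²(1) quantile
over 0.4549.

## PVE, heritability, contrasts

PVE fits all TASs jointly by OLS (R²_full) and drops one TAS at a time
(PVE_j = R²_full − R²_j); collinear members are dropped with a warning.
Heritability uses single-random-effect REML via one eigendecomposition of
the kinship and bounded scalar optimization of the log variance ratio
(log-λ ∈ [−10, 10]; boundary solutions are flagged). The kinship is rescaled
to mean diagonal 1 before fitting: an HWE-standardized GRM has diagonal
≈ 1 + F, and without the rescaling h² on a selfing panel is deflated by that
factor (≈ 1.95 at F_IS = 0.95); with outbred data the rescaling is a no-op.
Allele-effect contrasts compare the two homozygote classes only (Welch t),
heterozygotes excluded; classes under 2 members are flagged not-estimable.
The early allele at a TAS is the homozygote class with the smaller mean
flowering time at the discovery location; the stacking score counts
early-homozygous TASs per sample with heterozygotes worth 0.5
(configurable). Interval overlap is closed-interval on 1-based coordinates;
BED output (0-based half-open) is the single place coordinates convert.

## Selection classification

A TAS carries a domestication signal when its wild-vs-landrace per-SNP Fst
exceeds the genome-wide empirical quantile (default 0.95) and the
focal-allele frequency shifts by ≥ 0.1 between panels; a diversification
signal when any pairwise landrace-subpopulation Fst exceeds that pair's own
genome-wide quantile. Groups where the TAS minor-allele frequency falls
below 0.05 are listed as subpopulation-specific. The two flags combine into
four categories. The numeric criteria are explicit, configurable stand-ins —
the reference analyses do not state theirs — and both cutoffs are recorded
in the report; under a neutral panel the flag rate calibrates to
1 − quantile, and raising the quantile never adds flags.

## Problem sizes and tolerances

Desk-scale defaults: the bundled analysis panel is 600 samples × 4000 SNPs
over 20 chromosomes of 40 Mb; recovery experiments use 5000 SNPs with
n = 1000 (heritability, 20 replicates), 300/group (Fst, 10 replicates),
200,000 synthetic pairs (LD half-maximum), and n = 1000 with nine TASs
(PVE, 20 replicates). REML tolerance is 1e-6 on log-λ; oracle comparisons
assert 1e-10 agreement for closed-form statistics and 1e-8 against
independent OLS fits. The GREML sampling sd at n = 1000, m = 5000 is ≈ 0.1
per replicate (≈ √(2m)/n), which is why heritability recovery is averaged
over replicates.

## Known limitations

Beyond the generator gaps above: the imputation stand-ins are not a
haplotype-cluster model and will underperform it at low depth; the iterative
scan is a simplified reimplementation (fixed bin sweep, explicit entry
screen) rather than a port of the published package; Evanno-style cluster
number selection is not provided (k is a parameter); window statistics
assume a 365-day calendar with no leap handling; and the selection-scan
cutoffs are package conventions, not reconstructions of the reference
analyses.
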