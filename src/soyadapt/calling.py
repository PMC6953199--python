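"""Read-depth genotype calling and the site/sample filtering cascade.

The caller works on per-cell (major, minor, other) read counts from a
reduced-representation (GBS-style) assay. Calling rules, with total = major +
minor + other reads at the cell:

* homozygous for the allele with more reads when that allele has >= 2 reads
  and >= 90% of total;
* heterozygous when both alleles have >= 1 read, each >= 20% of total, and
  together >= 5 reads making up >= 90% of total;
* otherwise missing.

The homozygous rule is evaluated first; a tie between the two alleles is
resolved under the heterozygous rule only. The canonical pipeline order is
discover -> call -> filter_sites_pre -> filter_samples -> impute ->
filter_sites_post.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import MISSING, AlleleDepthMatrix, GenotypeMatrix

__all__ = [
    "call_genotype",
    "call_matrix",
    "discover_sites",
    "filter_sites_pre",
    "filter_samples",
    "impute",
    "filter_sites_post",
    "run_calling_pipeline",
]

logger = logging.getLogger(__name__)

HOM_MIN_READS = 2
HOM_MIN_FRACTION = 0.90
HET_MIN_ALLELE_FRACTION = 0.20
HET_MIN_SUM_READS = 5
HET_MIN_SUM_FRACTION = 0.90


def call_genotype(major_reads: int, minor_reads: int, other_reads: int = 0) -> int:
    """Call one cell; returns 0 (hom major), 1 (het), 2 (hom minor) or -1."""
    if major_reads < 0 or minor_reads < 0 or other_reads < 0:
        raise ValueError("read counts must be nonnegative")
    total = major_reads + minor_reads + other_reads
    if total == 0:
        return MISSING
    # homozygous rule, for the allele with strictly more reads
    if major_reads != minor_reads:
        top, code = (
            (major_reads, 0) if major_reads > minor_reads else (minor_reads, 2)
        )
        # exact rational comparisons (10*x >= 9*total <=> x >= 90% of total)
        if top >= HOM_MIN_READS and 10 * top >= 9 * total:
            return code
    # heterozygous rule (also covers exact ties)
    s = major_reads + minor_reads
    if (
        major_reads >= 1
        and minor_reads >= 1
        and 5 * major_reads >= total
        and 5 * minor_reads >= total
        and s >= HET_MIN_SUM_READS
        and 10 * s >= 9 * total
    ):
        return 1
    return MISSING


def call_matrix(depths: AlleleDepthMatrix) -> GenotypeMatrix:
    """Vectorized per-cell calling over a depth matrix."""
    maj = depths.major.astype(np.int64)
    mnr = depths.minor.astype(np.int64)
    oth = depths.other.astype(np.int64)
    total = maj + mnr + oth
    codes = np.full(maj.shape, MISSING, dtype=np.int8)

    top = np.maximum(maj, mnr)
    hom_ok = (maj != mnr) & (top >= HOM_MIN_READS) & (10 * top >= 9 * total)
    codes[hom_ok & (maj > mnr)] = 0
    codes[hom_ok & (mnr > maj)] = 2

    s = maj + mnr
    het_ok = (
        (~hom_ok)
        & (maj >= 1)
        & (mnr >= 1)
        & (5 * maj >= total)
        & (5 * mnr >= total)
        & (s >= HET_MIN_SUM_READS)
        & (10 * s >= 9 * total)
    )
    codes[het_ok] = 1
    return GenotypeMatrix(
        sites=depths.sites.copy(), codes=codes, samples=list(depths.samples)
    )


def discover_sites(
    depths: AlleleDepthMatrix,
    min_quality_applied_upstream: bool = True,
    min_reads_per_sample: int = 5,
    min_biallelic_fraction: float = 0.80,
) -> np.ndarray:
    """Site mask: pooled bi-allelic read fraction >= 80%.

    Only cells covered by at least ``min_reads_per_sample`` reads contribute
    to the pooled counts; per-base quality filtering happens upstream of this
    artifact and is acknowledged by the flag.
    """
    del min_quality_applied_upstream  # upstream concern; recorded by signature
    total = depths.total
    consider = total >= min_reads_per_sample
    bi = np.where(consider, depths.major + depths.minor, 0).sum(axis=1).astype(float)
    all_reads = np.where(consider, total, 0).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(all_reads > 0, bi / np.maximum(all_reads, 1), 0.0)
    return (all_reads > 0) & (frac >= min_biallelic_fraction)


def filter_sites_pre(
    genotypes: GenotypeMatrix,
    min_maf: float = 0.01,
    max_het: float = 0.20,
    max_missing: float = 0.70,
) -> GenotypeMatrix:
    """Pre-imputation site filter: MAF >= 1%, het <= 20%, missing <= 70%.

    MAF is computed from called alleles only. Sites with zero calls are
    dropped and counted in the log.
    """
    maf = genotypes.site_maf()
    het = genotypes.site_het_rate()
    miss = genotypes.site_missing_rate()
    zero_call = ~np.isfinite(maf)
    keep = (
        ~zero_call
        & (np.nan_to_num(maf) >= min_maf)
        & (np.nan_to_num(het) <= max_het)
        & (miss <= max_missing)
    )
    if zero_call.any():
        logger.info("filter_sites_pre: dropped %d sites with zero calls", int(zero_call.sum()))
    logger.info(
        "filter_sites_pre: %d -> %d sites", genotypes.n_sites, int(keep.sum())
    )
    return genotypes.take_sites(keep)


def filter_samples(genotypes: GenotypeMatrix, threshold: float = 0.80) -> GenotypeMatrix:
    """Remove samples whose missing-data rate is >= threshold (default 80%)."""
    miss = genotypes.sample_missing_rate()
    keep = miss < threshold
    if not keep.any():
        raise ValueError("all samples removed by missing-rate filter")
    n_removed = int((~keep).sum())
    logger.info("filter_samples: removed %d of %d samples", n_removed, genotypes.n_samples)
    return genotypes.take_samples(keep)


def impute(
    genotypes: GenotypeMatrix,
    method: str = "mode",
    seed: int = 0,
    k: int = 5,
    window: int = 10,
) -> GenotypeMatrix:
    """Fill missing genotypes; non-missing entries are never altered.

    ``mode`` fills each missing cell with the site's most frequent called
    genotype. ``knn-haplotype`` fills from the k samples nearest in mean
    dosage distance over a +-window local site neighbourhood, exploiting
    local LD; it falls back to the site mode when no neighbour is callable.
    Both are deterministic stand-ins for a full haplotype-cluster imputer.
    """
    del seed  # both methods are deterministic; kept for interface stability
    codes = genotypes.codes.copy()
    missing = codes == MISSING
    if not missing.any():
        return GenotypeMatrix(
            sites=genotypes.sites.copy(), codes=codes, samples=list(genotypes.samples)
        )

    n_calls = (codes != MISSING).sum(axis=1)
    dead = np.flatnonzero(n_calls == 0)
    if dead.size:
        raise ValueError(
            f"cannot impute sites with zero calls (site indices {dead[:10].tolist()}...)"
        )

    # per-site modal genotype over {0,1,2}; ties -> smaller code
    counts = np.stack([(codes == g).sum(axis=1) for g in (0, 1, 2)])
    site_mode = counts.argmax(axis=0).astype(np.int8)

    if method == "mode":
        rows, cols = np.nonzero(missing)
        codes[rows, cols] = site_mode[rows]
    elif method == "knn-haplotype":
        dose = codes.astype(float)
        dose[missing] = np.nan
        m = genotypes.n_sites
        for i, s in zip(*np.nonzero(missing)):
            lo, hi = max(0, i - window), min(m, i + window + 1)
            block = dose[lo:hi]
            target = block[:, s]
            diff = np.abs(block - target[:, None])
            shared = np.isfinite(diff)
            n_shared = shared.sum(axis=0)
            with np.errstate(invalid="ignore"):
                dist = np.where(n_shared > 0, np.nansum(diff, axis=0) / np.maximum(n_shared, 1), np.inf)
            dist[s] = np.inf
            dist[~np.isfinite(dose[i])] = np.inf  # neighbour must be called at i
            order = np.argsort(dist, kind="stable")
            nearest = [j for j in order[:k] if np.isfinite(dist[j])]
            if nearest:
                vals = codes[i, nearest]
                cnt = np.bincount(vals, minlength=3)
                codes[i, s] = np.int8(cnt.argmax())
            else:
                codes[i, s] = site_mode[i]
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    return GenotypeMatrix(
        sites=genotypes.sites.copy(), codes=codes, samples=list(genotypes.samples)
    )


def filter_sites_post(
    genotypes: GenotypeMatrix,
    min_homozygous_minor: int = 20,
    min_maf: float = 0.01,
    max_het: float = 0.20,
) -> GenotypeMatrix:
    """Post-imputation filter: >= 20 homozygous-minor carriers, MAF/het re-check."""
    n_hom_minor = (genotypes.codes == 2).sum(axis=1)
    maf = genotypes.site_maf()
    het = genotypes.site_het_rate()
    keep = (
        (n_hom_minor >= min_homozygous_minor)
        & np.isfinite(maf)
        & (np.nan_to_num(maf) >= min_maf)
        & (np.nan_to_num(het) <= max_het)
    )
    logger.info("filter_sites_post: %d -> %d sites", genotypes.n_sites, int(keep.sum()))
    return genotypes.take_sites(keep)


def run_calling_pipeline(
    depths: AlleleDepthMatrix,
    sample_missing_threshold: float = 0.80,
    impute_method: str = "mode",
    min_homozygous_minor: int = 20,
) -> GenotypeMatrix:
    """discover -> call -> filter sites -> filter samples -> impute -> re-filter."""
    mask = discover_sites(depths)
    kept = AlleleDepthMatrix(
        sites=depths.sites.iloc[np.flatnonzero(mask)].reset_index(drop=True),
        major=depths.major[mask],
        minor=depths.minor[mask],
        other=depths.other[mask],
        samples=list(depths.samples),
    )
    geno = call_matrix(kept)
    geno = filter_sites_pre(geno)
    geno = filter_samples(geno, threshold=sample_missing_threshold)
    geno = impute(geno, method=impute_method)
    geno = filter_sites_post(geno, min_homozygous_minor=min_homozygous_minor)
    return geno
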