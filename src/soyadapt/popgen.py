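"""Differentiation, diversity, LD and phenotypic-differentiation statistics.

Implements the Weir & Cockerham (1984) variance-components Fst estimator
(per SNP, 30-kb windows, and the genome-wide ratio of summed components),
Watterson's theta per window, genotype-level composite r-squared, the LD
decay profile with its half-maximum distance, the focal-SNP LD block used to
delimit trait-associated regions, and Pst (a Qst proxy) with bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix

__all__ = [
    "FstResult",
    "wc_fst",
    "watterson_theta",
    "ld_r2",
    "LDProfile",
    "ld_decay_profile",
    "LDBlock",
    "ld_block",
    "PstResult",
    "pst",
]


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst


@dataclass
class FstResult:
    per_snp: np.ndarray          # per-SNP theta-hat (NaN where undefined)
    components: np.ndarray       # (n_snps, 3) a, b, c variance components
    windows: pd.DataFrame        # chrom, start, end, mean_fst, n_snps
    genome_wide: float           # ratio of sums: sum(a) / sum(a+b+c)


def _wc_components(
    codes: np.ndarray, group_idx: list[np.ndarray]
) -> np.ndarray:
    """Per-site (a, b, c) components for r groups; NaN rows where undefined."""
    m = codes.shape[0]
    r = len(group_idx)
    n_i = np.zeros((m, r))
    p_i = np.zeros((m, r))
    h_i = np.zeros((m, r))
    for g, idx in enumerate(group_idx):
        sub = codes[:, idx]
        called = sub != MISSING
        n = called.sum(axis=1).astype(float)
        dose = np.where(called, sub, 0).sum(axis=1)
        het = np.where(called, sub == 1, False).sum(axis=1)
        n_i[:, g] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[:, g] = np.where(n > 0, dose / np.maximum(2 * n, 1), np.nan)
            h_i[:, g] = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    ok = (n_i >= 2).all(axis=1)

    nbar = n_i.mean(axis=1)
    n_sum = n_i.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_sum - (n_i**2).sum(axis=1) / n_sum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=1) / n_sum
        s2 = (n_i * (p_i - pbar[:, None]) ** 2).sum(axis=1) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=1) / n_sum

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    comp = np.stack([a, b, c], axis=1)
    comp[~ok] = np.nan
    return comp


def wc_fst(
    genotypes: GenotypeMatrix,
    groups: np.ndarray,
    labels: tuple | None = None,
    window_bp: int = 30_000,
) -> FstResult:
    """Weir-Cockerham Fst between two (or more) groups.

    ``groups`` is a per-sample label array; ``labels`` picks the compared
    groups (default: all distinct labels). Sites need >= 2 called samples in
    every group to contribute.
    """
    groups = np.asarray(groups)
    if labels is None:
        labels = tuple(pd.unique(groups))
    group_idx = []
    for lab in labels:
        idx = np.flatnonzero(groups == lab)
        if idx.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        group_idx.append(idx)
    comp = _wc_components(genotypes.codes, group_idx)
    a, bc = comp[:, 0], comp[:, 1] + comp[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_snp = np.where(a + bc != 0, a / (a + bc), np.nan)
    valid = np.isfinite(comp).all(axis=1)
    genome = float(np.nansum(a[valid]) / np.nansum((a + bc)[valid]))

    rows = []
    chroms = genotypes.sites["chrom"].to_numpy()
    pos = genotypes.sites["pos"].to_numpy()
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        p = pos[on]
        f = per_snp[on]
        last = int(p.max())
        for start in range(1, last + 1, window_bp):
            end = start + window_bp - 1
            inw = (p >= start) & (p <= end)
            vals = f[inw]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                rows.append((chrom, start, end, float(vals.mean()), int(vals.size)))
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_fst", "n_snps"])
    return FstResult(per_snp=per_snp, components=comp, windows=windows, genome_wide=genome)


# ---------------------------------------------------------------------------
# Watterson's theta


def watterson_theta(
    genotypes: GenotypeMatrix,
    sample_mask: np.ndarray | None = None,
    window_bp: int = 1_000_000,
    min_maf: float = 0.01,
) -> tuple[pd.DataFrame, float, tuple]:
    """Per-window Watterson's theta (per bp) within a sample set.

    theta_w = S / (a_{n-1} L) with S the segregating sites in the window
    (group MAF >= ``min_maf``), n the allele count (2 x samples) and L the
    window length. Returns (window table, genome mean, central 95% range).
    """
    if sample_mask is not None:
        genotypes = genotypes.take_samples(np.asarray(sample_mask))
    maf = genotypes.site_maf()
    seg = np.isfinite(maf) & (maf >= min_maf)
    n_alleles = 2 * genotypes.n_samples
    if n_alleles < 2:
        raise ValueError("need at least one diploid sample")
    a_n = float(np.sum(1.0 / np.arange(1, n_alleles)))

    chroms = genotypes.sites["chrom"].to_numpy()
    pos = genotypes.sites["pos"].to_numpy()
    rows = []
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        p = pos[on]
        s = seg[on]
        last = int(p.max())
        for start in range(1, last + 1, window_bp):
            end = start + window_bp - 1
            inw = (p >= start) & (p <= end)
            s_count = int(s[inw].sum())
            theta = s_count / (a_n * window_bp)
            rows.append((chrom, start, end, s_count, theta))
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "S", "theta_w"])
    vals = table["theta_w"].to_numpy()
    mean = float(vals.mean()) if vals.size else 0.0
    lo, hi = (np.quantile(vals, [0.025, 0.975]) if vals.size else (0.0, 0.0))
    return table, mean, (float(lo), float(hi))


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_r2(
    genotypes: GenotypeMatrix,
    max_distance_bp: int = 1_000_000,
    min_maf: float = 0.01,
) -> pd.DataFrame:
    """Composite (genotype-level) r-squared for intra-chromosome SNP pairs.

    r2 is the squared Pearson correlation of dosage vectors — the standard
    unphased-data LD statistic. Only pairs within ``max_distance_bp`` on the
    same chromosome are returned, as records (chrom, pos1, pos2, dist, r2).
    """
    maf = genotypes.site_maf()
    keep = np.isfinite(maf) & (maf >= min_maf)
    geno = genotypes.take_sites(keep)
    chroms = geno.sites["chrom"].to_numpy()
    pos = geno.sites["pos"].to_numpy()
    d = geno.dosage()
    rows = []
    for chrom in pd.unique(chroms):
        on = np.flatnonzero(chroms == chrom)
        p = pos[on]
        x = d[on]
        # standardize over called entries; with imputed data this is exact
        mask = np.isfinite(x)
        mu = np.nanmean(x, axis=1)
        xc = np.where(mask, x - mu[:, None], 0.0)
        for i in range(len(on)):
            js = np.flatnonzero((p > p[i]) & (p - p[i] <= max_distance_bp))
            for j in js:
                both = mask[i] & mask[j]
                if both.sum() < 3:
                    continue
                xi = x[i, both] - x[i, both].mean()
                xj = x[j, both] - x[j, both].mean()
                denom = np.sqrt((xi**2).sum() * (xj**2).sum())
                if denom == 0:
                    continue
                r = float((xi * xj).sum() / denom)
                rows.append((chrom, int(p[i]), int(p[j]), int(p[j] - p[i]), r * r))
    return pd.DataFrame(rows, columns=["chrom", "pos1", "pos2", "dist", "r2"])


@dataclass
class LDProfile:
    bin_edges_bp: np.ndarray       # contiguous 1-kb bin edges
    mean_r2: np.ndarray            # NaN where a bin is empty
    counts: np.ndarray
    half_max_distance_bp: float | None
    smoothed: bool

    @property
    def half_max_reached(self) -> bool:
        return self.half_max_distance_bp is not None


def ld_decay_profile(
    pairs: pd.DataFrame,
    bin_width_bp: int = 1_000,
    max_distance_bp: int = 1_000_000,
    smooth: bool = True,
) -> LDProfile:
    """Mean r2 in 1-kb distance bins and the half-maximum decay distance.

    The half-maximum distance is the smallest bin midpoint at which the mean
    r2 has declined to one-half of the maximum bin mean. With ``smooth`` the
    bin means are first projected onto a non-increasing sequence (isotonic
    regression weighted by pair counts), which stabilizes the first crossing
    against bin noise; the flag is recorded on the profile.
    """
    dist = pairs["dist"].to_numpy(float)
    r2 = pairs["r2"].to_numpy(float)
    ok = np.isfinite(dist) & np.isfinite(r2) & (dist >= 0) & (dist <= max_distance_bp)
    if not ok.any():
        raise ValueError("no usable pairs for the LD profile")
    dist, r2 = dist[ok], r2[ok]
    edges = np.arange(0, max_distance_bp + bin_width_bp, bin_width_bp)
    idx = np.clip(np.digitize(dist, edges) - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=r2, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    filled = counts > 0
    if not filled.any():
        raise ValueError("all LD bins empty")
    work = means.copy()
    if smooth:
        from sklearn.isotonic import IsotonicRegression

        x = np.flatnonzero(filled).astype(float)
        iso = IsotonicRegression(increasing=False)
        work[filled] = iso.fit_transform(x, means[filled], sample_weight=counts[filled])

    mids = (edges[:-1] + edges[1:]) / 2.0
    peak = np.nanmax(work)
    half = peak / 2.0
    below = filled & (work <= half)
    half_dist = float(mids[np.argmax(below)]) if below.any() else None
    return LDProfile(
        bin_edges_bp=edges,
        mean_r2=means,
        counts=counts,
        half_max_distance_bp=half_dist,
        smoothed=smooth,
    )


@dataclass
class LDBlock:
    chrom: str
    focal_pos: int
    start: int
    end: int
    n_members: int


def ld_block(
    genotypes: GenotypeMatrix,
    focal_chrom: str,
    focal_pos: int,
    r2_threshold: float = 0.8,
    context_bp: int = 1_000_000,
) -> LDBlock:
    """Block bounded by the farthest +-1 Mb SNPs with r2 >= 0.8 to the focal SNP.

    A side with no SNP in LD collapses to the focal position on that side.
    """
    fi = genotypes.site_index(focal_chrom, focal_pos)
    chroms = genotypes.sites["chrom"].to_numpy()
    pos = genotypes.sites["pos"].to_numpy()
    on = np.flatnonzero(
        (chroms == focal_chrom)
        & (np.abs(pos - focal_pos) <= context_bp)
        & (pos != focal_pos)
    )
    d = genotypes.dosage()
    x = d[fi]
    start = end = focal_pos
    n_members = 0
    for j in on:
        both = np.isfinite(x) & np.isfinite(d[j])
        if both.sum() < 3:
            continue
        xi = x[both] - x[both].mean()
        xj = d[j, both] - d[j, both].mean()
        denom = np.sqrt((xi**2).sum() * (xj**2).sum())
        if denom == 0:
            continue
        r2 = float((xi * xj).sum() / denom) ** 2
        if r2 >= r2_threshold:
            n_members += 1
            start = min(start, int(pos[j]))
            end = max(end, int(pos[j]))
    return LDBlock(chrom=focal_chrom, focal_pos=focal_pos, start=start, end=end, n_members=n_members)


# ---------------------------------------------------------------------------
# Pst


@dataclass
class PstResult:
    estimate: float
    ci_low: float
    ci_high: float
    c: float
    h2: float
    n_boot: int
    fst_comparison: float | None = None


def _pst_point(values: np.ndarray, codes: np.ndarray, k: int, c: float, h2: float) -> float:
    n = values.size
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    n0_num = 0.0
    for g in range(k):
        v = values[codes == g]
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
        n0_num += v.size**2
    ms_within = ss_within / (n - k)
    ms_between = ss_between / (k - 1)
    n0 = (n - n0_num / n) / (k - 1)
    var_between = max((ms_between - ms_within) / n0, 0.0)
    scale = c / h2
    denom = scale * var_between + 2.0 * ms_within
    return float(scale * var_between / denom) if denom > 0 else 0.0


def pst(
    values: np.ndarray,
    groups: np.ndarray,
    c: float = 1.0,
    h2: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    fst_comparison: float | None = None,
) -> PstResult:
    """Pst = (c/h2) sigma2_B / ((c/h2) sigma2_B + 2 sigma2_W), bootstrap CI.

    Variance components come from one-way ANOVA across groups; the bootstrap
    resamples individuals within groups. ``fst_comparison`` carries the mean
    pairwise Weir-Cockerham Fst for a Qst-Fst style contrast.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    labs = pd.unique(groups)
    codes = np.searchsorted(np.sort(labs), groups) if labs.dtype != object else np.array(
        [list(labs).index(g) for g in groups]
    )
    k = len(labs)
    if k < 2:
        raise ValueError("Pst needs at least two groups")
    for g in range(k):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {labs[g]!r} has fewer than 2 individuals")
    est = _pst_point(values, codes, k, c, h2)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    group_rows = [np.flatnonzero(codes == g) for g in range(k)]
    for b in range(n_boot):
        vb = np.empty_like(values)
        for g, rows in enumerate(group_rows):
            vb[rows] = values[rng.choice(rows, size=rows.size, replace=True)]
        boot[b] = _pst_point(vb, codes, k, c, h2)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(np.sort(boot), [alpha, 1.0 - alpha])
    return PstResult(
        estimate=est,
        ci_low=float(lo),
        ci_high=float(hi),
        c=c,
        h2=h2,
        n_boot=n_boot,
        fst_comparison=fst_comparison,
    )
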