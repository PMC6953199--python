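"""Synthetic structured-panel generator.

Emulates the statistical structure of a geo-referenced landrace diversity
panel: three regional landrace subpopulations plus a wild group with
calibrated pairwise differentiation (Balding–Nichols allele frequencies),
distance-decaying linkage disequilibrium, latitude-driven climate variables,
an additive flowering-time architecture shared between two phenotyping
locations, and Poisson-distributed sequencing read depths.

All randomness flows from one integer seed; each operation draws from its own
sub-stream (keyed by operation name) so stages can be re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioclim import mdl
from .core import ECOTYPES, GROUPS, MISSING, AlleleDepthMatrix, GenotypeMatrix, TruthSet

__all__ = [
    "SimConfig",
    "simulate_geography",
    "simulate_climate",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_read_depths",
    "simulate_panel",
    "solve_group_f",
]

#: latitude bands (degrees N) of the collection regions, per group
LATITUDE_BANDS = {
    "WILD": (24.0, 53.0),
    "NR": (40.0, 51.4),
    "HR": (34.0, 40.0),
    "SR": (18.2, 34.0),
}
LONGITUDE_BAND = (80.5, 134.0)

#: group-level sowing/harvest windows (day-of-year), spring sowing in the
#: north through later sowing and harvest in the south
DEFAULT_SOWING_HARVEST = {
    "WILD": (130, 280),
    "NR": (120, 270),
    "HR": (150, 290),
    "SR": (180, 330),
}

#: landrace ecotype composition of the study panel (seven ecotypes)
ECOTYPE_COUNTS = {
    "NESp": 269,
    "NSp": 362,
    "HSp": 26,
    "HSu": 415,
    "SSp": 249,
    "SSu": 529,
    "SAu": 88,
}
#: ecotypes belonging to each landrace region
ECOTYPES_BY_GROUP = {
    "NR": ("NESp", "NSp"),
    "HR": ("HSp", "HSu"),
    "SR": ("SSp", "SSu", "SAu"),
}

#: panel accounting of the genotyping study the generator emulates
STUDY_N_GENOTYPED = 2368
STUDY_N_REMOVED = 333
STUDY_N_RETAINED = 2035

#: published pairwise Fst among the landrace subpopulations, and a wild level
#: chosen so the 4-group system stays (near-)consistent
DEFAULT_FST_TARGETS = {
    ("NR", "HR"): 0.077,
    ("NR", "SR"): 0.136,
    ("HR", "SR"): 0.164,
    ("WILD", "NR"): 0.105,
    ("WILD", "HR"): 0.133,
    ("WILD", "SR"): 0.192,
}

# climate trends: calibrated so the simulated ranges over 18.2-51.4 degN match
# the study panel (TAR 14.4-58.7 degC increasing north, AP 81-1986 mm
# increasing south)
DEFAULT_CLIMATE = {
    "tar_slope": 1.334,   # degC per degree latitude
    "tar_intercept": -9.9,
    "tar_noise_sd": 2.5,
    "ap_slope": -57.4,    # mm per degree latitude
    "ap_intercept": 3030.0,
    "ap_noise_sd": 120.0,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic panel.

    Defaults are the study conditions: mean read depth 13, landrace pairwise
    Fst at the published levels, additive flowering-time heritability 0.66
    (between the two published location estimates 0.625 and 0.704).
    """

    seed: int = 0
    n_per_group: dict = field(
        default_factory=lambda: {"WILD": 50, "NR": 150, "HR": 150, "SR": 250}
    )
    n_snps: int = 2000
    n_chromosomes: int = 20
    chrom_length_bp: int = 50_000_000
    fst_targets: dict = field(default_factory=lambda: dict(DEFAULT_FST_TARGETS))
    ld_copy_decay_bp: float = 100_000.0
    wild_ld_copy_decay_bp: float | None = 20_000.0  # wild panel decays faster
    #: within-individual inbreeding coefficient; soya bean is a near-complete
    #: selfer, so accessions are almost fully homozygous
    selfing_fis: float = 0.95
    n_causal: int = 20
    h2_target: float = 0.66
    intercept_days: float = 60.0
    location_offsets: tuple = (0.0, -15.0)  # Beijing-like, Wuhan-like
    depth_mean: float = 13.0
    seq_error: float = 0.002
    missing_rate: float = 0.05
    climate_params: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE))
    sowing_harvest_by_group: dict = field(
        default_factory=lambda: dict(DEFAULT_SOWING_HARVEST)
    )
    daylength_coefficient: float = 0.8333

    def __post_init__(self) -> None:
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected {GROUPS}")
            if self.n_per_group[g] < 0:
                raise ValueError("group counts must be nonnegative")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must lie in (0, 1)")
        if not 0 <= self.seq_error < 0.5:
            raise ValueError("seq_error must lie in [0, 0.5)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.selfing_fis <= 1:
            raise ValueError("selfing_fis must lie in [0, 1]")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        # symmetrize fst targets; keys may arrive in either orientation
        sym = {}
        for (a, b), v in self.fst_targets.items():
            if not 0 < v < 1:
                raise ValueError(f"fst target for ({a},{b}) must lie in (0,1)")
            sym[(a, b)] = v
            sym[(b, a)] = v
        self.fst_targets = sym

    @property
    def groups(self) -> list[str]:
        return [g for g in GROUPS if self.n_per_group.get(g, 0) > 0]


def _rng(config: SimConfig, op_name: str) -> np.random.Generator:
    """Operation-keyed sub-stream of the config's master seed."""
    key = zlib.crc32(op_name.encode())
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(config.seed, spawn_key=(key,)))
    )


# ---------------------------------------------------------------------------
# geography and climate


def simulate_geography(config: SimConfig) -> pd.DataFrame:
    """Passport table with group latitude bands and sowing windows."""
    rng = _rng(config, "geography")
    rows = []
    i = 0
    for g in GROUPS:
        n = config.n_per_group.get(g, 0)
        lo, hi = LATITUDE_BANDS[g]
        lats = rng.uniform(lo, hi, size=n)
        lons = rng.uniform(*LONGITUDE_BAND, size=n)
        alts = rng.gamma(shape=2.0, scale=250.0, size=n)  # nonnegative, ~500 m
        sow, harv = config.sowing_harvest_by_group[g]
        if g == "WILD":
            ecos = [""] * n
        else:
            choices = ECOTYPES_BY_GROUP[g]
            weights = np.array([ECOTYPE_COUNTS[e] for e in choices], float)
            ecos = rng.choice(choices, size=n, p=weights / weights.sum())
        for j in range(n):
            rows.append(
                {
                    "sample_id": f"S{i:05d}",
                    "latitude": lats[j],
                    "longitude": lons[j],
                    "altitude": alts[j],
                    "ecotype": ecos[j],
                    "group": g,
                    "sowing_doy": sow,
                    "harvest_doy": harv,
                }
            )
            i += 1
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "latitude",
            "longitude",
            "altitude",
            "ecotype",
            "group",
            "sowing_doy",
            "harvest_doy",
        ],
    )


def simulate_climate(samples: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """TAR/AP as noisy latitude trends; MDL deterministically from daylength.

    TAR (temperature annual range, degC) increases with latitude; AP (annual
    precipitation, mm) decreases with latitude. MDL is the maximum daylength
    (h) between sowing and harvest and carries no noise, so corr(MDL, TAR) is
    strongly positive by construction.
    """
    if "latitude" not in samples.columns:
        raise ValueError("sample table lacks latitude")
    rng = _rng(config, "climate")
    p = config.climate_params
    lat = samples["latitude"].to_numpy(float)
    n = len(samples)
    tar = p["tar_intercept"] + p["tar_slope"] * lat + rng.normal(0, p["tar_noise_sd"], n)
    ap = p["ap_intercept"] + p["ap_slope"] * lat + rng.normal(0, p["ap_noise_sd"], n)
    ap = np.maximum(ap, 0.0)
    mdl_vals = np.array(
        [
            mdl(
                samples["latitude"].iat[k],
                int(samples["sowing_doy"].iat[k]),
                int(samples["harvest_doy"].iat[k]),
                coefficient=config.daylength_coefficient,
            )
            for k in range(n)
        ]
    )
    out = samples[["sample_id"]].copy()
    out["TAR"] = tar
    out["AP"] = ap
    out["MDL"] = mdl_vals
    return out


# ---------------------------------------------------------------------------
# genotypes


def solve_group_f(fst_targets: dict, groups: list[str]) -> dict:
    """Per-group Balding–Nichols F from pairwise Fst targets.

    Between two independent groups with drift coefficients F_g and F_h the
    expected Weir–Cockerham Fst is (F_g + F_h)/2, so targets give the linear
    system F_g + F_h = 2 t_gh, solved by least squares (exact whenever the
    targets are mutually consistent, e.g. any two-group configuration).
    """
    if len(groups) == 1:
        return {groups[0]: 0.0}
    pairs = []
    for i, g in enumerate(groups):
        for h in groups[i + 1 :]:
            if (g, h) in fst_targets:
                pairs.append((g, h, fst_targets[(g, h)]))
    if not pairs:
        raise ValueError("no fst_targets provided for the configured groups")
    A = np.zeros((len(pairs), len(groups)))
    b = np.zeros(len(pairs))
    for r, (g, h, t) in enumerate(pairs):
        A[r, groups.index(g)] = 1.0
        A[r, groups.index(h)] = 1.0
        b[r] = 2.0 * t
    f, *_ = np.linalg.lstsq(A, b, rcond=None)
    for g, h, t in pairs:
        fg, fh = f[groups.index(g)], f[groups.index(h)]
        if fg < 0 or fg >= 1 or fh < 0 or fh >= 1:
            raise ValueError(
                f"infeasible Fst target for pair ({g}, {h}) = {t}: "
                f"implied F ({fg:.3f}, {fh:.3f}) outside [0, 1)"
            )
    return dict(zip(groups, f))


def _copula_haplotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    positions: np.ndarray,
    n_hap: int,
    decay_bp: float,
) -> np.ndarray:
    """Haplotypes with distance-decaying LD and exact Bernoulli marginals.

    Each haplotype walks along the chromosome reusing the previous site's
    latent uniform with probability exp(-d/decay_bp); the allele at site j is
    always 1(u < p_j), so marginal frequencies are untouched by the copying.
    """
    m = len(freqs)
    u = rng.uniform(size=(m, n_hap))
    if decay_bp > 0 and m > 1:
        d = np.diff(positions).astype(float)
        copy_prob = np.exp(-d / decay_bp)
        keep = rng.uniform(size=(m - 1, n_hap)) < copy_prob[:, None]
        for j in range(1, m):
            u[j] = np.where(keep[j - 1], u[j - 1], u[j])
    return (u < freqs[:, None]).astype(np.int8)


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, TruthSet]:
    """Structured genotypes: Balding–Nichols differentiation + copying LD."""
    rng = _rng(config, "genotypes")
    groups = config.groups
    if not groups:
        raise ValueError("no samples configured")
    group_f = solve_group_f(config.fst_targets, groups)

    # positions: n_snps spread over chromosomes, sorted and unique
    n_chrom = config.n_chromosomes
    per_chrom = np.full(n_chrom, config.n_snps // n_chrom)
    per_chrom[: config.n_snps % n_chrom] += 1
    site_rows = []
    positions_by_chrom = []
    for c in range(n_chrom):
        m = int(per_chrom[c])
        pos = np.sort(rng.choice(np.arange(1, config.chrom_length_bp + 1), size=m, replace=False))
        positions_by_chrom.append(pos)
        chrom = f"Chr{c + 1:02d}"
        site_rows.extend((chrom, int(p)) for p in pos)

    m_total = config.n_snps
    anc = rng.uniform(0.05, 0.95, size=m_total)

    # per-group allele frequencies
    group_freqs = {}
    for g in groups:
        f = group_f[g]
        if f <= 1e-12:
            group_freqs[g] = anc.copy()
        else:
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            group_freqs[g] = rng.beta(a, b)

    n_total = sum(config.n_per_group.get(g, 0) for g in groups)
    codes = np.empty((m_total, n_total), dtype=np.int8)
    true_group = []
    col = 0
    for g in groups:
        n_g = config.n_per_group[g]
        decay = config.ld_copy_decay_bp
        if g == "WILD" and config.wild_ld_copy_decay_bp is not None:
            decay = config.wild_ld_copy_decay_bp
        offset = 0
        for pos in positions_by_chrom:
            m = len(pos)
            fr = group_freqs[g][offset : offset + m]
            h1 = _copula_haplotypes(rng, fr, pos, n_g, decay)
            h2 = _copula_haplotypes(rng, fr, pos, n_g, decay)
            if config.selfing_fis > 0:
                # autozygous cells carry two copies of the same haplotype
                # allele; marginal allele frequencies are untouched but the
                # heterozygosity drops to 2pq(1 - F_IS)
                auto = rng.uniform(size=(m, n_g)) < config.selfing_fis
                h2 = np.where(auto, h1, h2)
            codes[offset : offset + m, col : col + n_g] = h1 + h2
            offset += m
        true_group.extend([g] * n_g)
        col += n_g

    # orient codes to the realized panel-wide minor allele so that code 2
    # always means homozygous minor (the convention every downstream stage
    # and the VCF reader assume)
    freq = codes.mean(axis=1) / 2.0
    flip = freq > 0.5
    codes[flip] = 2 - codes[flip]

    sites = pd.DataFrame(site_rows, columns=["chrom", "pos"])
    sites["major"] = np.where(flip, "T", "A")
    sites["minor"] = np.where(flip, "A", "T")
    geno = GenotypeMatrix(sites=sites, codes=codes, samples=[f"S{i:05d}" for i in range(n_total)])

    causal = np.sort(rng.choice(m_total, size=config.n_causal, replace=False))
    # effects on the standardized-genotype scale: per-allele effect
    # proportional to 1/sqrt(2 p q) so each causal site contributes equal
    # expected variance (the infinitesimal-model convention used by GRM-REML)
    p_hat = codes[causal].mean(axis=1) / 2.0
    p_hat = np.clip(p_hat, 0.01, 0.99)
    raw = rng.normal(size=config.n_causal)
    effects = 3.0 * raw / np.sqrt(2.0 * p_hat * (1.0 - p_hat))  # days/allele

    truth = TruthSet(
        causal_indices=causal,
        causal_effects=effects,
        true_genotypes=geno,
        true_group=np.array(true_group),
    )
    return geno, truth


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Flowering time at two locations with shared genetic values.

    phenotype = intercept + location offset + sum(effect * dosage) + noise;
    the noise variance is set from the empirical genetic variance so the
    additive heritability equals ``h2_target`` at each location. Locations
    share identical genetic values, so their phenotypic correlation
    approaches h2 in large samples.
    """
    rng = _rng(config, "phenotypes")
    if not 0 < config.h2_target < 1:
        raise ValueError("h2_target must lie in (0, 1)")
    dose = truth.true_genotypes.codes[truth.causal_indices].astype(float)
    g = truth.causal_effects @ dose
    var_g = float(np.var(g))
    var_e = var_g * (1.0 / config.h2_target - 1.0)
    n = truth.true_genotypes.n_samples
    out = pd.DataFrame({"sample_id": truth.true_genotypes.samples})
    for loc, offset in enumerate(config.location_offsets, start=1):
        noise = rng.normal(0.0, np.sqrt(var_e), size=n) if var_e > 0 else np.zeros(n)
        out[f"FT_loc{loc}"] = config.intercept_days + offset + g + noise
    return out


# ---------------------------------------------------------------------------
# read depths


def simulate_read_depths(truth: TruthSet, config: SimConfig) -> AlleleDepthMatrix:
    """Poisson total depth, binomial allele split with sequencing error."""
    rng = _rng(config, "depths")
    geno = truth.true_genotypes
    m, n = geno.n_sites, geno.n_samples
    depth = rng.poisson(config.depth_mean, size=(m, n))
    if config.missing_rate > 0:
        depth[rng.uniform(size=(m, n)) < config.missing_rate] = 0
    # probability a read shows the minor allele, by true dosage
    e = config.seq_error
    p_minor_by_code = np.array([e, 0.5, 1.0 - e])
    p_minor = p_minor_by_code[geno.codes]
    minor = rng.binomial(depth, p_minor)
    major = depth - minor
    other = np.zeros_like(depth)
    return AlleleDepthMatrix(
        sites=geno.sites.copy(),
        major=major,
        minor=minor,
        other=other,
        samples=list(geno.samples),
    )


# ---------------------------------------------------------------------------
# convenience driver


def simulate_panel(config: SimConfig) -> dict:
    """Run every generator stage; returns a dict of all artifacts."""
    samples = simulate_geography(config)
    climate = simulate_climate(samples, config)
    geno, truth = simulate_genotypes(config)
    pheno = simulate_phenotypes(truth, config)
    depths = simulate_read_depths(truth, config)
    traits = climate.merge(pheno, on="sample_id")
    return {
        "samples": samples,
        "traits": traits,
        "genotypes": geno,
        "truth": truth,
        "depths": depths,
        "config": config,
    }
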