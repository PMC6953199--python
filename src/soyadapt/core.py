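"""Core in-memory containers shared by every pipeline stage.

Coordinates are 1-based closed throughout the package; the BED writer in
:mod:`soyadapt.io` is the single place where they are converted.
Genotypes are coded relative to the panel-wide major allele:
0 = homozygous major, 1 = heterozygous, 2 = homozygous minor, -1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING: int = -1

#: canonical group labels: one wild panel and three landrace subpopulations
#: (northern, Huanghuai/central, southern regions), plus the admixed class.
GROUPS = ("WILD", "NR", "HR", "SR")
MIXED = "MIXED"

ECOTYPES = ("NESp", "NSp", "HSp", "HSu", "SSp", "SSu", "SAu")

SITE_COLUMNS = ["chrom", "pos", "major", "minor"]


def _check_sites(sites: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("chrom", "pos") if c not in sites.columns]
    if missing:
        raise ValueError(f"site table lacks columns {missing}")
    pos = sites["pos"].to_numpy()
    for chrom, sub in sites.groupby("chrom", sort=False):
        p = sub["pos"].to_numpy()
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")
    if np.any(pos < 1):
        raise ValueError("positions must be 1-based (>= 1)")
    return sites.reset_index(drop=True)


@dataclass
class AlleleDepthMatrix:
    """Per site x sample read counts of the major, minor and other alleles."""

    sites: pd.DataFrame
    major: np.ndarray  # (n_sites, n_samples) int
    minor: np.ndarray
    other: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        for name in ("major", "minor", "other"):
            arr = getattr(self, name)
            if arr.shape != (len(self.sites), len(self.samples)):
                raise ValueError(f"{name} read matrix has wrong shape {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"negative read counts in {name}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def total(self) -> np.ndarray:
        return self.major + self.minor + self.other


@dataclass
class GenotypeMatrix:
    """Sites x samples dosage codes with site metadata.

    ``codes`` holds the dosage of the panel-wide *minor* allele
    (0/1/2) or :data:`MISSING`.
    """

    sites: pd.DataFrame
    codes: np.ndarray  # (n_sites, n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = _check_sites(self.sites)
        if self.codes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(f"genotype matrix has wrong shape {self.codes.shape}")
        valid = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def called_mask(self) -> np.ndarray:
        return self.codes != MISSING

    def site_missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=1)

    def sample_missing_rate(self) -> np.ndarray:
        return (self.codes == MISSING).mean(axis=0)

    def site_maf(self) -> np.ndarray:
        """Minor-allele frequency per site from called genotypes only.

        The matrix is coded against the panel-wide major allele, so the raw
        minor-dosage frequency is folded at 0.5.
        """
        called = self.called_mask()
        n_alleles = 2 * called.sum(axis=1)
        dose = np.where(called, self.codes, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, dose / np.maximum(n_alleles, 1), np.nan)
        return np.minimum(freq, 1.0 - freq)

    def site_het_rate(self) -> np.ndarray:
        called = self.called_mask()
        n = called.sum(axis=1)
        het = (self.codes == 1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / np.maximum(n, 1), np.nan)

    def dosage(self) -> np.ndarray:
        """Float dosage matrix with missing as NaN."""
        d = self.codes.astype(float)
        d[self.codes == MISSING] = np.nan
        return d

    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.iloc[index].reset_index(drop=True),
            codes=self.codes[index],
            samples=list(self.samples),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            sites=self.sites.copy(),
            codes=self.codes[:, index],
            samples=[self.samples[i] for i in index],
        )

    def site_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.sites["chrom"].to_numpy() == chrom)
            & (self.sites["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"site {chrom}:{pos} not in genotype matrix")
        return int(hit[0])


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Check passport-table invariants and return the table unchanged."""
    required = {"sample_id", "latitude", "longitude"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample table lacks columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        raise ValueError("sample ids are not unique")
    lat = samples["latitude"].to_numpy(float)
    lon = samples["longitude"].to_numpy(float)
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude out of [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude out of [-180, 180]")
    if {"sowing_doy", "harvest_doy"} <= set(samples.columns):
        same = samples["sowing_doy"].to_numpy() == samples["harvest_doy"].to_numpy()
        if np.any(same):
            raise ValueError("sowing and harvest day-of-year must differ")
    return samples


@dataclass
class TruthSet:
    """Ground truth emitted by the generator for downstream validation."""

    causal_indices: np.ndarray
    causal_effects: np.ndarray  # days per minor-allele copy
    true_genotypes: GenotypeMatrix
    true_group: np.ndarray  # per-sample group label

    def __post_init__(self) -> None:
        idx = np.asarray(self.causal_indices)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("causal indices must be unique")
        if idx.size and (idx.min() < 0 or idx.max() >= self.true_genotypes.n_sites):
            raise ValueError("causal index out of range")
        if not np.all(np.isfinite(self.causal_effects)):
            raise ValueError("causal effects must be finite")
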