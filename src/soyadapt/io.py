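"""File formats and run manifests.

Genotypes travel as VCF (1-based positions, FORMAT GT and AD); internal
coordinates are 1-based closed, and BED output (0-based half-open) is the
only place they are converted. Genotype codes are re-oriented on read so that
0 always means homozygous for the panel-wide major allele — the calling rules
are phrased in major/minor terms, not ref/alt.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, AlleleDepthMatrix, GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "write_association",
    "write_blocks_bed",
    "write_manifest",
]

logger = logging.getLogger(__name__)


def write_vcf(
    path: str | Path,
    genotypes: GenotypeMatrix,
    depths: AlleleDepthMatrix | None = None,
    contigs: list[str] | None = None,
) -> None:
    """Write genotypes (and optional allele depths) as an uncompressed VCF.

    REF is the major allele, ALT the minor, so GT dosage of ALT equals the
    internal minor-dosage code directly.
    """
    path = Path(path)
    sites = genotypes.sites
    if contigs is None:
        contigs = list(pd.unique(sites["chrom"]))
    gt_str = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=soyadapt\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        fmt = "GT:AD" if depths is not None else "GT"
        major = sites["major"] if "major" in sites else pd.Series(["A"] * len(sites))
        minor = sites["minor"] if "minor" in sites else pd.Series(["T"] * len(sites))
        for i in range(genotypes.n_sites):
            cells = []
            for s in range(genotypes.n_samples):
                g = gt_str[int(genotypes.codes[i, s])]
                if depths is not None:
                    g += f":{depths.major[i, s]},{depths.minor[i, s]}"
                cells.append(g)
            fh.write(
                f"{sites['chrom'].iat[i]}\t{sites['pos'].iat[i]}\t.\t"
                f"{major.iat[i]}\t{minor.iat[i]}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, AlleleDepthMatrix | None]:
    """Load bi-allelic SNPs from a VCF into the internal containers.

    GT is parsed to ALT dosage, then re-oriented so code 0 is the panel-wide
    major allele; AD, when present, is re-oriented the same way (extra
    alleles' depths pool into "other"). Multi-allelic records are skipped
    with a logged count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, codes_rows = [], []
    ad_major, ad_minor, ad_other = [], [], []
    have_ad = False
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.array(rec.genotypes, dtype=int)
        a1, a2 = gts[:, 0], gts[:, 1]
        dose = np.where((a1 < 0) | (a2 < 0), MISSING, a1 + a2).astype(np.int8)

        called = dose != MISSING
        alt_freq = dose[called].sum() / max(2 * called.sum(), 1) if called.any() else 0.0
        flip = alt_freq > 0.5
        if flip:
            major, minor = rec.ALT[0], rec.REF
            dose = np.where(dose == MISSING, MISSING, 2 - dose).astype(np.int8)
        else:
            major, minor = rec.REF, rec.ALT[0]

        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            have_ad = True
            ad = np.asarray(ad)
            ad = np.where(ad < 0, 0, ad)
            ref_d, alt_d = ad[:, 0], ad[:, 1]
            rest = ad[:, 2:].sum(axis=1) if ad.shape[1] > 2 else np.zeros(len(samples), int)
            if flip:
                ad_major.append(alt_d)
                ad_minor.append(ref_d)
            else:
                ad_major.append(ref_d)
                ad_minor.append(alt_d)
            ad_other.append(rest)
        rows.append((rec.CHROM, rec.POS, major, minor))
        codes_rows.append(dose)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-bi-allelic records", n_skipped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "major", "minor"])
    geno = GenotypeMatrix(sites=sites, codes=np.array(codes_rows, dtype=np.int8), samples=samples)
    depths = None
    if have_ad:
        depths = AlleleDepthMatrix(
            sites=sites.copy(),
            major=np.array(ad_major, dtype=np.int64),
            minor=np.array(ad_minor, dtype=np.int64),
            other=np.array(ad_other, dtype=np.int64),
            samples=samples,
        )
    return geno, depths


ASSOCIATION_COLUMNS = ["chrom", "pos", "maf", "beta", "p", "pve"]


def write_association(path: str | Path, table: pd.DataFrame) -> None:
    """Association results as tab-delimited with a fixed schema."""
    out = table.copy()
    if "pve" not in out.columns:
        out["pve"] = np.nan
    out[ASSOCIATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_association(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association file lacks columns {missing}")
    return table


def block_to_bed_line(chrom: str, start_1based: int, end_1based: int, name: str = ".") -> str:
    """Convert a 1-based closed interval to a BED (0-based half-open) line."""
    return f"{chrom}\t{start_1based - 1}\t{end_1based}\t{name}"


def write_blocks_bed(path: str | Path, blocks) -> None:
    with open(path, "w") as fh:
        for blk in blocks:
            fh.write(
                block_to_bed_line(
                    blk.chrom, blk.start, blk.end, f"{blk.chrom}:{blk.focal_pos}"
                )
                + "\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals converted back to internal 1-based closed coordinates."""
    table = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    table["start"] = table["start"] + 1
    return table


def write_manifest(path: str | Path, config: dict, seed: int, stages: list[str]) -> dict:
    """Run manifest with a config hash for reproducibility audits."""
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config_hash": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "stages": stages,
        "package": "soyadapt",
        "version": "0.1.0",
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
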