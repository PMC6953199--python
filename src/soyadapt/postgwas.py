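"""Post-scan quantification.

Phenotypic variance explained (PVE) by full/reduced linear models, GRM-REML
narrow-sense heritability, homozygote-contrast allele effects, early-allele
stacking scores, and overlap of LD blocks with candidate-gene intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, GenotypeMatrix
from .mixed import VarianceComponents, fit_reml
from .popgen import LDBlock

__all__ = [
    "pve",
    "heritability",
    "allele_contrast",
    "early_allele_score",
    "interval_overlap",
    "VarianceComponents",
]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Coefficient of determination of y ~ [1, X] by least squares."""
    n = y.size
    design = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / tss


def pve(tas_dosages: np.ndarray, trait: np.ndarray) -> tuple[float, np.ndarray, list[int]]:
    """Joint and leave-one-out variance explained by a TAS set.

    ``tas_dosages`` is (n_tas, n_samples). The full model fits all TASs
    jointly giving R2_full; the reduced model for TAS j omits its dosage, and
    PVE_j = R2_full - R2_j. Returns (R2_full, PVE per TAS, dropped indices)
    where collinear TAS columns were dropped with a warning (their PVE is 0).
    """
    X = np.asarray(tas_dosages, float)
    if X.ndim == 1:
        X = X[None, :]
    y = np.asarray(trait, float)
    q, n = X.shape
    if q >= n:
        raise ValueError("more TASs than samples")

    kept: list[int] = []
    dropped: list[int] = []
    for j in range(q):
        trial = np.column_stack([np.ones(n)] + [X[i] for i in kept + [j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            kept.append(j)
        else:
            dropped.append(j)
    if dropped:
        warnings.warn(f"dropped collinear TAS columns {dropped}")

    r2_full = _r2(y, X[kept].T)
    pve_j = np.zeros(q)
    for j in kept:
        others = [i for i in kept if i != j]
        r2_red = _r2(y, X[others].T if others else np.empty((n, 0)))
        pve_j[j] = r2_full - r2_red
    return r2_full, pve_j, dropped


def heritability(
    relmat: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> VarianceComponents:
    """Narrow-sense h2 from the GRM-REML variance components.

    The kinship is rescaled to mean diagonal 1 before fitting so that
    sigma2_a stays on the phenotypic scale for inbred panels too (a
    HWE-standardized GRM has diagonal ~1+F, which would otherwise deflate
    h2 by that factor on a selfing species). Warns when the kinship is
    degenerate (duplicated samples create unit off-diagonal relatedness,
    which biases h2 toward 1).
    """
    K = np.asarray(relmat, float)
    mean_diag = float(np.mean(np.diag(K)))
    if mean_diag <= 0:
        raise ValueError("relationship matrix has non-positive mean diagonal")
    K = K / mean_diag
    y = np.asarray(trait, float)
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        c = np.asarray(covariates, float)
        if c.ndim == 1:
            c = c[:, None]
        X = np.column_stack([X, c])
    vals = np.linalg.eigvalsh((K + K.T) / 2.0)
    if vals.min() < -1e-6 * max(abs(vals.max()), 1.0):
        raise ValueError("relationship matrix is not positive semi-definite")
    # duplicate-sample degeneracy: off-diagonal entries matching the diagonal
    diag = np.diag(K)
    offd = K - np.diag(diag)
    if np.any(offd > 0.99 * np.median(diag)):
        warnings.warn("degenerate kinship: near-duplicate samples inflate h2")
    return fit_reml(y, K=K, X=X)


def allele_contrast(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    tas: tuple,
    sample_mask: np.ndarray | None = None,
    group: str = "",
    location: str = "",
) -> dict:
    """Homozygote-class flowering-time contrast at one TAS.

    Heterozygotes are excluded; the difference (major-homozygote mean minus
    minor-homozygote mean, days) is tested with Welch's t. Classes with < 2
    members yield a not-estimable row.
    """
    chrom, pos = tas
    i = genotypes.site_index(chrom, pos)
    codes = genotypes.codes[i]
    y = np.asarray(trait, float)
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask, bool)
        codes = codes[sample_mask]
        y = y[sample_mask]
    hom0 = y[(codes == 0) & np.isfinite(y)]
    hom2 = y[(codes == 2) & np.isfinite(y)]
    row = {
        "chrom": chrom,
        "pos": pos,
        "group": group,
        "location": location,
        "n_hom_major": int(hom0.size),
        "n_hom_minor": int(hom2.size),
        "mean_hom_major": float(hom0.mean()) if hom0.size else np.nan,
        "mean_hom_minor": float(hom2.mean()) if hom2.size else np.nan,
        "estimable": hom0.size >= 2 and hom2.size >= 2,
    }
    if row["estimable"]:
        diff = row["mean_hom_major"] - row["mean_hom_minor"]
        t, p = stats.ttest_ind(hom0, hom2, equal_var=False)
        row.update(
            {
                "difference_days": float(diff),
                "t": float(t),
                "p": float(p),
                "direction": int(np.sign(diff)) if diff != 0 else 0,
            }
        )
    else:
        row.update({"difference_days": np.nan, "t": np.nan, "p": np.nan, "direction": 0})
    return row


def contrast_consistency(rows: list[dict]) -> bool:
    """True when all estimable contrasts for one TAS share a direction sign."""
    signs = {r["direction"] for r in rows if r["estimable"] and r["direction"] != 0}
    return len(signs) <= 1


def early_allele_score(
    genotypes: GenotypeMatrix,
    tas_list: list[tuple],
    early_allele_code: dict,
    trait: np.ndarray | None = None,
    het_weight: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Per-sample count of TASs carrying the designated early allele.

    ``early_allele_code`` maps (chrom, pos) -> 0 or 2, the homozygote class
    with the earlier flowering mean at the discovery location. Homozygotes
    for the early allele contribute 1, heterozygotes ``het_weight``.
    Optionally reports the Pearson correlation of the score with a trait.
    """
    n = genotypes.n_samples
    score = np.zeros(n)
    for tas in tas_list:
        i = genotypes.site_index(*tas)
        early = early_allele_code[tas]
        codes = genotypes.codes[i]
        score += np.where(
            codes == early, 1.0, np.where(codes == 1, het_weight, 0.0)
        )
    stats_out: dict = {"n_tas": len(tas_list)}
    if trait is not None and len(tas_list) > 0 and np.std(score) > 0:
        y = np.asarray(trait, float)
        ok = np.isfinite(y)
        r, p = stats.pearsonr(score[ok], y[ok])
        stats_out.update({"r": float(r), "p": float(p), "defined": True})
    else:
        stats_out.update({"r": np.nan, "p": np.nan, "defined": False})
    return score, stats_out


def designate_early_alleles(
    genotypes: GenotypeMatrix, trait: np.ndarray, tas_list: list[tuple]
) -> dict:
    """Early allele per TAS: the homozygote class with the smaller trait mean."""
    out = {}
    for tas in tas_list:
        row = allele_contrast(genotypes, trait, tas)
        if not row["estimable"]:
            out[tas] = 0
        else:
            out[tas] = 0 if row["mean_hom_major"] <= row["mean_hom_minor"] else 2
    return out


def interval_overlap(blocks: list[LDBlock], intervals: pd.DataFrame) -> pd.DataFrame:
    """Closed-interval overlap of LD blocks with 1-based candidate intervals.

    For blocks without any overlap the distance to the nearest interval on
    the same chromosome is reported (NaN when the chromosome has none).
    """
    rows = []
    for blk in blocks:
        sub = intervals[intervals["chrom"] == blk.chrom]
        hits = sub[(sub["start"] <= blk.end) & (sub["end"] >= blk.start)]
        if len(hits):
            for _, iv in hits.iterrows():
                rows.append(
                    {
                        "chrom": blk.chrom,
                        "focal_pos": blk.focal_pos,
                        "block_start": blk.start,
                        "block_end": blk.end,
                        "interval": iv["name"],
                        "overlap": True,
                        "distance": 0,
                    }
                )
        else:
            if len(sub):
                gaps = np.where(
                    sub["start"].to_numpy() > blk.end,
                    sub["start"].to_numpy() - blk.end,
                    np.where(
                        sub["end"].to_numpy() < blk.start,
                        blk.start - sub["end"].to_numpy(),
                        0,
                    ),
                )
                j = int(np.argmin(gaps))
                nearest, dist = sub.iloc[j]["name"], int(gaps[j])
            else:
                nearest, dist = None, np.nan
            rows.append(
                {
                    "chrom": blk.chrom,
                    "focal_pos": blk.focal_pos,
                    "block_start": blk.start,
                    "block_end": blk.end,
                    "interval": nearest,
                    "overlap": False,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows)
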