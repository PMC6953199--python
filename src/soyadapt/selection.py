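"""Selection-history classification of trait-associated SNPs.

A TAS carries a domestication signal when its wild-vs-landrace differentiation
is extreme (genome-wide empirical Fst quantile) and the focal-allele frequency
shifted materially between the wild and landrace panels; it carries a
diversification signal when any pairwise subpopulation Fst is extreme for that
pair. The two flags combine into a four-way category. Both cutoffs are
explicit, configurable stand-ins recorded in the report header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix
from .popgen import wc_fst

__all__ = ["domestication_scan", "diversification_scan", "classify", "SelectionReport"]


@dataclass
class SelectionReport:
    table: pd.DataFrame
    category_counts: dict
    params: dict = field(default_factory=dict)


def _allele_freq(codes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = codes[:, mask]
    called = sub != MISSING
    n = 2.0 * called.sum(axis=1)
    dose = np.where(called, sub, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, dose / np.maximum(n, 1), np.nan)


def domestication_scan(
    genotypes: GenotypeMatrix,
    wild_mask: np.ndarray,
    landrace_mask: np.ndarray,
    tas_list: list[tuple],
    fst_quantile: float = 0.95,
    min_delta: float = 0.1,
) -> pd.DataFrame:
    """Wild-vs-landrace Fst outlier + allele-frequency-shift flag per TAS."""
    wild_mask = np.asarray(wild_mask, bool)
    landrace_mask = np.asarray(landrace_mask, bool)
    if not wild_mask.any() or not landrace_mask.any():
        raise ValueError("both wild and landrace masks must be non-empty")
    labels = np.where(wild_mask, "wild", np.where(landrace_mask, "landrace", "other"))
    res = wc_fst(genotypes, labels, labels=("wild", "landrace"))
    fst = res.per_snp
    cutoff = float(np.nanquantile(fst, fst_quantile))
    freq_w = _allele_freq(genotypes.codes, wild_mask)
    freq_l = _allele_freq(genotypes.codes, landrace_mask)
    rows = []
    for tas in tas_list:
        i = genotypes.site_index(*tas)
        delta = abs(freq_l[i] - freq_w[i])
        flagged = bool(np.isfinite(fst[i]) and fst[i] > cutoff and delta >= min_delta)
        rows.append(
            {
                "chrom": tas[0],
                "pos": tas[1],
                "fst_wild_landrace": float(fst[i]) if np.isfinite(fst[i]) else np.nan,
                "freq_wild": float(freq_w[i]),
                "freq_landrace": float(freq_l[i]),
                "freq_delta": float(delta),
                "fst_cutoff": cutoff,
                "domestication_selected": flagged,
            }
        )
    return pd.DataFrame(rows)


def diversification_scan(
    genotypes: GenotypeMatrix,
    group_labels: np.ndarray,
    tas_list: list[tuple],
    fst_quantile: float = 0.95,
    maf_threshold: float = 0.05,
    groups: tuple = ("NR", "HR", "SR"),
) -> pd.DataFrame:
    """Pairwise-subpopulation Fst outlier flag + subpopulation-specific lists.

    A TAS is flagged when any pairwise subpopulation Fst exceeds that pair's
    genome-wide quantile; groups where the TAS minor-allele frequency falls
    below ``maf_threshold`` are reported as subpop-specific.
    """
    group_labels = np.asarray(group_labels)
    pair_stats = {}
    for i, g in enumerate(groups):
        for h in groups[i + 1 :]:
            res = wc_fst(genotypes, group_labels, labels=(g, h))
            cutoff = float(np.nanquantile(res.per_snp, fst_quantile))
            pair_stats[(g, h)] = (res.per_snp, cutoff)
    freq_by_group = {
        g: _allele_freq(genotypes.codes, group_labels == g) for g in groups
    }
    rows = []
    for tas in tas_list:
        i = genotypes.site_index(*tas)
        flagged = False
        pair_vals = {}
        for (g, h), (fst, cutoff) in pair_stats.items():
            v = fst[i]
            pair_vals[f"fst_{g}_{h}"] = float(v) if np.isfinite(v) else np.nan
            if np.isfinite(v) and v > cutoff:
                flagged = True
        mafs = {}
        specific = []
        for g in groups:
            f = freq_by_group[g][i]
            maf = min(f, 1 - f) if np.isfinite(f) else np.nan
            mafs[f"maf_{g}"] = float(maf)
            if np.isfinite(maf) and maf < maf_threshold:
                specific.append(g)
        rows.append(
            {
                "chrom": tas[0],
                "pos": tas[1],
                **pair_vals,
                **mafs,
                "subpop_specific": tuple(specific),
                "diversification_selected": flagged,
            }
        )
    return pd.DataFrame(rows)


def classify(
    domestication: pd.DataFrame, diversification: pd.DataFrame
) -> SelectionReport:
    """Four-way category per TAS from the two selection flags."""
    merged = domestication.merge(
        diversification, on=["chrom", "pos"], validate="one_to_one"
    )

    def cat(row) -> str:
        dom, div = row["domestication_selected"], row["diversification_selected"]
        if dom and div:
            return "both"
        if dom:
            return "domestication_only"
        if div:
            return "diversification_only"
        return "none"

    merged["category"] = merged.apply(cat, axis=1)
    counts = merged["category"].value_counts().to_dict()
    for key in ("both", "domestication_only", "diversification_only", "none"):
        counts.setdefault(key, 0)
    return SelectionReport(table=merged, category_counts=counts)
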