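"""Association scans for phenotypic and bioclimatic traits.

Two scans are provided: a covariate-adjusted single-marker least-squares scan
(the baseline and null-calibration reference) and an iterative fixed/random
scan in the FarmCPU style, where markers selected as pseudo-QTNs circulate
between the fixed-effect model (as covariates) and a random-effect model
(as the kinship source) until the selected set stabilizes. Thresholding
follows the Bonferroni convention (alpha / number of tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .mixed import fit_reml, reml_loglik_null

__all__ = [
    "AssociationResult",
    "scan_glm",
    "scan_farmcpu",
    "bonferroni_threshold",
    "qq_and_inflation",
]


@dataclass
class AssociationResult:
    """Per-SNP scan output plus scan metadata."""

    table: pd.DataFrame  # chrom, pos, maf, beta, p, estimable
    trait: str = ""
    n_covariates: int = 0
    pseudo_qtns: list = field(default_factory=list)
    threshold: float | None = None
    lambda_gc: float | None = None
    converged: bool = True

    def significant(self, threshold: float | None = None) -> pd.DataFrame:
        thr = threshold if threshold is not None else self.threshold
        if thr is None:
            raise ValueError("no significance threshold set")
        t = self.table
        return t[(t["estimable"]) & (t["p"] <= thr)].reset_index(drop=True)


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    c = np.asarray(covariates, float)
    if c.ndim == 1:
        c = c[:, None]
    W = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        # identify the offending columns for the error message
        bad = []
        for j in range(1, W.shape[1]):
            if np.linalg.matrix_rank(W[:, : j + 1]) < j + 1:
                bad.append(j - 1)
        raise ValueError(f"collinear covariate columns: {bad}")
    return W


def _residualize(W: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Project the columns of A off the column space of W."""
    coef, *_ = np.linalg.lstsq(W, A, rcond=None)
    return A - W @ coef


def scan_glm(
    genotypes: GenotypeMatrix | np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    trait_name: str = "",
) -> AssociationResult:
    """Single-marker least-squares scan: trait ~ intercept + covariates + dosage.

    The p-value comes from the t-statistic of the dosage coefficient. SNPs
    collinear with the covariates (zero residual variance) are flagged
    not-estimable with NaN effect and p.
    """
    if isinstance(genotypes, GenotypeMatrix):
        dose = genotypes.codes.astype(float)
        sites = genotypes.sites
    else:
        dose = np.asarray(genotypes, float)
        sites = pd.DataFrame(
            {"chrom": "Chr01", "pos": np.arange(1, dose.shape[0] + 1)}
        )
    if np.isnan(dose).any():
        raise ValueError("scan requires no missing genotypes")
    y = np.asarray(trait, float)
    n = y.size
    if np.std(y) == 0:
        raise ValueError("trait is constant")
    W = _design(n, covariates)
    q = W.shape[1]
    df = n - q - 1
    if df < 1:
        raise ValueError("not enough samples for the design")

    y_r = _residualize(W, y[:, None])[:, 0]
    x_r = _residualize(W, dose.T).T  # sites x samples residualized
    sxx = (x_r**2).sum(axis=1)
    sxy = x_r @ y_r
    syy = float(y_r @ y_r)
    estimable = sxx > 1e-10 * max(1.0, float(np.max(sxx, initial=1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(estimable, sxy / np.maximum(sxx, 1e-300), np.nan)
        sse = np.maximum(syy - beta**2 * sxx, 0.0)
        se = np.sqrt(sse / df / np.maximum(sxx, 1e-300))
        tstat = beta / se
    p = np.full(dose.shape[0], np.nan)
    ok = estimable & np.isfinite(tstat)
    p[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), df)
    p[ok] = np.maximum(p[ok], np.finfo(float).tiny)  # keep p in (0, 1]

    freq = dose.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1 - freq)
    table = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "maf": maf,
            "beta": beta,
            "p": p,
            "estimable": estimable & np.isfinite(p),
        }
    )
    return AssociationResult(
        table=table,
        trait=trait_name,
        n_covariates=q - 1,
    )


def _prune_by_r2(dose: np.ndarray, order: list[int], r2_cap: float, max_qtn: int) -> list[int]:
    """Greedy prefix pruning: keep candidates mutually below the r2 cap."""
    kept: list[int] = []
    for j in order:
        x = dose[j]
        if np.std(x) == 0:
            continue
        ok = True
        for kpt in kept:
            r = np.corrcoef(x, dose[kpt])[0, 1]
            if r * r >= r2_cap:
                ok = False
                break
        if ok:
            kept.append(j)
        if len(kept) >= max_qtn:
            break
    return kept


def scan_farmcpu(
    genotypes: GenotypeMatrix | np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    bin_sizes: tuple = (100_000, 500_000, 1_000_000),
    max_qtn: int = 20,
    max_iter: int = 10,
    r2_prune: float = 0.7,
    p_entry: float | None = None,
    trait_name: str = "",
) -> AssociationResult:
    """Iterative fixed/random-model scan (FarmCPU style).

    Each iteration: (1) a fixed-effect scan with the current pseudo-QTNs as
    covariates (pseudo-QTNs keep the p-value from the scan at which they were
    selected); (2) candidates = best SNP per physical bin, swept over
    ``bin_sizes`` and ranked by p, screened at ``p_entry`` (default: the
    Bonferroni threshold 0.01/m); (3) candidates pruned to mutual r2 <
    ``r2_prune`` and capped at ``max_qtn``; (4) the accepted set is the
    candidate prefix maximizing the restricted likelihood of a random-effect
    model whose kinship is built from pseudo-QTN dosages. Iteration stops when
    the accepted set repeats. With ``max_qtn = 0`` the scan reduces exactly to
    :func:`scan_glm`. Ties in p are broken by genome order.
    """
    if isinstance(genotypes, GenotypeMatrix):
        dose = genotypes.codes.astype(float)
        chroms = genotypes.sites["chrom"].to_numpy()
        pos = genotypes.sites["pos"].to_numpy()
    else:
        dose = np.asarray(genotypes, float)
        chroms = np.array(["Chr01"] * dose.shape[0])
        pos = np.arange(1, dose.shape[0] + 1)
    m = dose.shape[0]
    y = np.asarray(trait, float)
    base_cov = None if covariates is None else np.asarray(covariates, float)
    if base_cov is not None and base_cov.ndim == 1:
        base_cov = base_cov[:, None]
    if p_entry is None:
        p_entry = bonferroni_threshold(0.01, m)[0]

    def scan_with(pseudo: list[int]) -> AssociationResult:
        cov = base_cov
        if pseudo:
            qd = dose[pseudo].T
            cov = qd if cov is None else np.column_stack([cov, qd])
        return scan_glm(
            genotypes if isinstance(genotypes, GenotypeMatrix) else dose,
            y,
            cov,
            trait_name=trait_name,
        )

    pseudo: list[int] = []
    pseudo_pvals: dict[int, float] = {}
    converged = False
    result = scan_with(pseudo)

    if max_qtn > 0:
        seen = [tuple(pseudo)]
        for _ in range(max_iter):
            pvals = result.table["p"].to_numpy().copy()
            for j in pseudo:
                pvals[j] = pseudo_pvals[j]

            # candidate selection: best SNP per bin, swept over bin sizes
            cand: set[int] = set()
            finite = np.isfinite(pvals)
            for bs in bin_sizes:
                bins = {}
                for j in np.flatnonzero(finite & (pvals <= p_entry)):
                    key = (chroms[j], pos[j] // bs)
                    cur = bins.get(key)
                    if cur is None or (pvals[j], chroms[j], pos[j]) < (
                        pvals[cur],
                        chroms[cur],
                        pos[cur],
                    ):
                        bins[key] = j
                cand.update(bins.values())
            order = sorted(cand, key=lambda j: (pvals[j], chroms[j], pos[j]))
            pruned = _prune_by_r2(dose, order, r2_prune, max_qtn)

            # prefix selection by restricted likelihood of the QTN-kinship model
            best_s, best_ll = 0, reml_loglik_null(y, _design(y.size, base_cov))
            for s in range(1, len(pruned) + 1):
                z = dose[pruned[:s]].astype(float)
                z = z - z.mean(axis=1, keepdims=True)
                sd = z.std(axis=1)
                sd[sd == 0] = 1.0
                z = z / sd[:, None]
                kin = z.T @ z / s
                vc = fit_reml(y, K=kin, X=_design(y.size, base_cov))
                if vc.loglik > best_ll + 1e-6:
                    best_s, best_ll = s, vc.loglik
            accepted = pruned[:best_s]

            for j in accepted:
                if j not in pseudo_pvals:
                    pseudo_pvals[j] = float(pvals[j])
            pseudo = accepted
            if tuple(pseudo) in seen:
                converged = True
                break
            seen.append(tuple(pseudo))
            result = scan_with(pseudo)
        else:
            converged = False
        # final fixed-effect scan with the stabilized pseudo-QTN set
        result = scan_with(pseudo)
        pvals = result.table["p"].to_numpy()
        for j in pseudo:
            pvals[j] = pseudo_pvals[j]
            result.table.loc[j, "estimable"] = True
        result.table["p"] = pvals
        betas = result.table["beta"].to_numpy()
        result.table["beta"] = betas
    else:
        converged = True

    result.pseudo_qtns = [(chroms[j], int(pos[j])) for j in pseudo]
    result.converged = converged
    result.n_covariates = 0 if base_cov is None else base_cov.shape[1]
    return result


def bonferroni_threshold(alpha: float, n_tests: int) -> tuple[float, float]:
    """(exact alpha/n threshold, the same rounded to one significant figure)."""
    if n_tests < 1:
        raise ValueError("n_tests must be positive")
    exact = alpha / n_tests
    if exact <= 0:
        raise ValueError("alpha must be positive")
    exponent = np.floor(np.log10(exact))
    rounded = round(exact / 10**exponent) * 10**exponent
    return float(exact), float(rounded)


def qq_and_inflation(result: AssociationResult) -> tuple[pd.DataFrame, float, bool]:
    """QQ pairs (expected vs observed -log10 p) and the genomic inflation factor.

    lambda_GC = median observed chi-square(1 df) quantile / 0.4549. A single
    usable p-value yields a low-confidence flag.
    """
    p = result.table.loc[result.table["estimable"], "p"].to_numpy()
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no usable p-values")
    chi2 = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
    obs = -np.log10(np.sort(p))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    pairs = pd.DataFrame({"expected": exp, "observed": obs})
    low_confidence = p.size < 30
    return pairs, lam, low_confidence
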