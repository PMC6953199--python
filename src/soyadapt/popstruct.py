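"""Population structure: GRM, PCA, allele-sharing distances, NJ tree,
subpopulation assignment with an admixed class.

The relationship matrix is the variance-standardized genomic relationship
matrix (each dosage column centered by 2p and scaled by sqrt(2p(1-p)),
cross-product divided by the number of polymorphic sites). STRUCTURE-style
admixture inference is replaced by PCA + k-means with a membership-proportion
rule for the MIXED class: the pipeline only consumes hard labels plus an
admixed flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import GROUPS, MISSING, GenotypeMatrix

__all__ = [
    "relationship_matrix",
    "pca",
    "allele_sharing_distance",
    "nj_tree",
    "assign_groups",
    "GroupAssignment",
]


def relationship_matrix(genotypes: GenotypeMatrix, mode: str = "variance-standardized") -> np.ndarray:
    """Samples x samples genomic relationship matrix (no missing allowed)."""
    if (genotypes.codes == MISSING).any():
        raise ValueError("relationship matrix requires a fully imputed matrix")
    x = genotypes.codes.astype(float)  # sites x samples
    p = x.mean(axis=1) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all sites monomorphic; relationship matrix undefined")
    x = x[poly]
    p = p[poly]
    centered = x - 2.0 * p[:, None]
    if mode == "variance-standardized":
        centered = centered / np.sqrt(2.0 * p * (1.0 - p))[:, None]
    elif mode != "centered":
        raise ValueError(f"unknown mode {mode!r}")
    k = centered.T @ centered / centered.shape[0]
    return (k + k.T) / 2.0


def pca(relmat: np.ndarray, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-k PCs of a relationship matrix.

    Returns (coords, explained) where coords[:, i] is eigenvector i scaled by
    sqrt(eigenvalue) and explained are eigenvalue fractions of the total.
    Sign convention: the largest-|loading| entry of each axis is positive.
    """
    n = relmat.shape[0]
    vals, vecs = np.linalg.eigh(relmat)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    positive = vals > 1e-9
    rank = int(positive.sum())
    if k > rank:
        warnings.warn(f"requested {k} PCs but matrix rank is {rank}; truncating")
        k = rank
    vals_k, vecs_k = vals[:k], vecs[:, :k]
    for i in range(k):
        j = np.argmax(np.abs(vecs_k[:, i]))
        if vecs_k[j, i] < 0:
            vecs_k[:, i] = -vecs_k[:, i]
    coords = vecs_k * np.sqrt(np.maximum(vals_k, 0.0))
    total = vals[vals > 0].sum()
    explained = np.maximum(vals_k, 0.0) / total
    return coords, explained


def allele_sharing_distance(genotypes: GenotypeMatrix) -> np.ndarray:
    """d(i,j) = 1 - shared alleles / (2 x compared sites), over called pairs."""
    d = genotypes.dosage()  # sites x samples, NaN for missing
    n = genotypes.n_samples
    out = np.zeros((n, n))
    called = np.isfinite(d)
    # shared allele count per site for codes a,b: 2 - |a - b| ... except the
    # het/het pair, which shares both alleles (|1-1| = 0 -> 2 shared): the
    # formula holds for all unphased pairs.
    for i in range(n):
        diff = np.abs(d - d[:, [i]])
        both = called & called[:, [i]]
        shared = np.where(both, 2.0 - diff, 0.0).sum(axis=0)
        n_comp = both.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(n_comp > 0, 1.0 - shared / (2.0 * np.maximum(n_comp, 1)), 0.0)
    out[np.diag_indices(n)] = 0.0
    return (out + out.T) / 2.0


def nj_tree(distances: np.ndarray, labels: list[str] | None = None) -> str:
    """Neighbour-joining (Saitou-Nei) tree from a distance matrix, as Newick.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch, keeping the joined pair's path length intact.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 leaves")
    if labels is None:
        labels = [f"L{i}" for i in range(n)]
    nodes = [f"{lab}" for lab in labels]  # newick fragments
    active = list(range(n))
    dm = d.copy()

    while len(active) > 2:
        r = len(active)
        sub = dm[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        i_loc, j_loc = np.unravel_index(np.argmin(q), q.shape)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = sub[i_loc, j_loc]
        bi = 0.5 * dij + (row_sums[i_loc] - row_sums[j_loc]) / (2.0 * (r - 2))
        bj = dij - bi
        # clamp negatives, moving the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bj = max(bj, 0.0)
        new = f"({nodes[i]}:{bi:.10g},{nodes[j]}:{bj:.10g})"
        # distances from the new node u to every other active node
        du = 0.5 * (dm[i, :] + dm[j, :] - dij)
        dm = np.vstack([dm, du[None, :]])
        du2 = np.append(du, 0.0)
        dm = np.hstack([dm, du2[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    i, j = active
    b = max(dm[i, j], 0.0)
    return f"({nodes[i]}:{b / 2.0:.10g},{nodes[j]}:{b / 2.0:.10g});"


@dataclass
class GroupAssignment:
    labels: np.ndarray          # per-sample label in {NR,HR,SR,WILD,MIXED} or cluster id
    proportions: np.ndarray     # samples x clusters, rows sum to 1
    cluster_names: list[str]


def assign_groups(
    coords: np.ndarray,
    k: int = 4,
    admixture_threshold: float = 0.55,
    seed: int = 0,
    n_pcs: int = 3,
    latitudes: np.ndarray | None = None,
    wild_flags: np.ndarray | None = None,
    n_restarts: int = 20,
) -> GroupAssignment:
    """k-means clusters on the top PCs, with an admixed (MIXED) class.

    Membership proportions are inverse-distance weights to the centroids; a
    sample whose top proportion falls below ``admixture_threshold`` is MIXED.
    With latitudes and wild flags, clusters are renamed WILD (most wild
    members) then NR/HR/SR by decreasing mean latitude.
    """
    if k < 2:
        raise ValueError("need at least 2 clusters")
    x = coords[:, : min(n_pcs, coords.shape[1])]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    hard = km.fit_predict(x)
    dist = np.linalg.norm(x[:, None, :] - km.cluster_centers_[None, :, :], axis=2)
    inv = 1.0 / np.maximum(dist, 1e-12)
    prop = inv / inv.sum(axis=1, keepdims=True)

    cluster_names = [f"C{c}" for c in range(k)]
    if latitudes is not None:
        latitudes = np.asarray(latitudes, float)
        remaining = list(range(k))
        names = {}
        if wild_flags is not None and np.asarray(wild_flags).any():
            wild_flags = np.asarray(wild_flags, bool)
            frac_wild = [
                wild_flags[hard == c].mean() if (hard == c).any() else 0.0
                for c in range(k)
            ]
            wild_c = int(np.argmax(frac_wild))
            names[wild_c] = "WILD"
            remaining.remove(wild_c)
        mean_lat = {
            c: (latitudes[hard == c].mean() if (hard == c).any() else -np.inf)
            for c in remaining
        }
        for name, c in zip(
            ("NR", "HR", "SR"), sorted(remaining, key=lambda c: -mean_lat[c])
        ):
            names[c] = name
        for c in remaining:
            names.setdefault(c, f"C{c}")
        cluster_names = [names.get(c, f"C{c}") for c in range(k)]

    labels = np.array([cluster_names[c] for c in hard], dtype=object)
    top = prop.max(axis=1)
    labels[top < admixture_threshold] = "MIXED"
    return GroupAssignment(labels=labels, proportions=prop, cluster_names=cluster_names)
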