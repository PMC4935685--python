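"""Species-wide category discovery and validation.

Units are clustered directly on the DTW dissimilarity matrix with
k-medoids (Partitioning Around Medoids, BUILD + SWAP), and the number of
clusters is read off the *corrected* global silhouette index (GSI): the
mean silhouette width at each k minus the mean GSI obtained on null
datasets (independent Gaussian samples whose per-dimension standard
deviations match an NMDS embedding of the empirical matrix), so that the
baseline optimism of silhouette scores on structureless data is removed.

An independent route to the same question fits Bayesian-information-
criterion-selected Gaussian mixtures on an NMDS ordination and then merges
components whose directly-estimated mutual misclassification probability
is high, so over-split Gaussian fits collapse back to the underlying
clusters.  Agreement between routes is quantified by the adjusted Rand
index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn import manifold
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .dtw import DissimilarityMatrix

logger = logging.getLogger("songculture")


@dataclass
class Partition:
    """Assignment of units to clusters, with validation scores."""

    labels: np.ndarray
    k: int
    medoids: list[int] = field(default_factory=list)
    gsi: float = np.nan
    cost: float = np.nan

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        sizes = np.bincount(self.labels, minlength=self.k)
        if self.k < 1 or np.any(sizes[: self.k] == 0):
            raise ValueError("every cluster must be non-empty")


@dataclass
class Ordination:
    """A Euclidean configuration of the units with its goodness-of-fit."""

    coords: np.ndarray
    stress: float
    var_explained: float


def pam_cluster(D: DissimilarityMatrix | np.ndarray, k: int, compute_gsi: bool = False) -> Partition:
    """Partitioning Around Medoids on a precomputed dissimilarity matrix.

    BUILD greedily seeds k medoids; SWAP exchanges a medoid with a
    non-medoid while any exchange lowers the total distance of units to
    their nearest medoid.  The final configuration is locally minimal.
    """
    dm = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    n = dm.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, n-1], got k={k}, n={n}")

    # BUILD
    medoids = [int(np.argmin(dm.sum(axis=1)))]
    d_near = dm[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(d_near[None, :] - dm, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        best = int(np.argmax(gains))
        medoids.append(best)
        d_near = np.minimum(d_near, dm[best])

    # SWAP (first-improvement over full scans until no improving swap exists)
    medoid_arr = np.array(medoids)
    def total_cost(meds: np.ndarray) -> float:
        return float(dm[meds].min(axis=0).sum())

    cost = total_cost(medoid_arr)
    improved = True
    while improved:
        improved = False
        non_medoids = np.setdiff1d(np.arange(n), medoid_arr)
        sub = dm[medoid_arr]
        order = np.argsort(sub, axis=0)
        d1 = sub[order[0], np.arange(n)]
        nearest = order[0]
        d2 = sub[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        for mi in range(k):
            backup = np.where(nearest == mi, d2, d1)
            for h in non_medoids:
                new_cost = float(np.minimum(backup, dm[h]).sum())
                if new_cost < cost - 1e-12:
                    medoid_arr[mi] = h
                    cost = new_cost
                    improved = True
                    break
            if improved:
                break

    labels_raw = np.argmin(dm[medoid_arr], axis=0)
    # medoids belong to their own cluster even under distance ties
    for mi, m in enumerate(medoid_arr):
        labels_raw[m] = mi
    part = Partition(labels=labels_raw, k=k, medoids=[int(m) for m in medoid_arr], cost=cost)
    if compute_gsi and k >= 2:
        part.gsi = global_silhouette(dm, part.labels)
    return part


def global_silhouette(D: DissimilarityMatrix | np.ndarray, labels: np.ndarray) -> float:
    """GSI: the mean silhouette width over all units, in [-1, 1]."""
    dm = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    return float(silhouette_score(dm, labels, metric="precomputed"))


def nmds_embed(
    D: DissimilarityMatrix | np.ndarray,
    d: int = 3,
    seed: int = 1,
    n_starts: int = 20,
    max_iter: int = 300,
    eps: float = 1e-7,
) -> Ordination:
    """Non-metric multidimensional scaling of the dissimilarity matrix.

    Kruskal stress-1 is minimised from ``n_starts`` random initialisations;
    ``var_explained`` is the squared Pearson correlation between the
    configuration distances and the input dissimilarities.
    """
    dm = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    if d < 1:
        raise ValueError("embedding dimension must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mds = manifold.MDS(
            n_components=d,
            metric=False,
            dissimilarity="precomputed",
            n_init=n_starts,
            max_iter=max_iter,
            eps=eps,
            random_state=seed,
            normalized_stress=True,
        )
        coords = mds.fit_transform(dm)
    emb = pdist(coords)
    orig = squareform(dm, checks=False)
    var_explained = float(np.corrcoef(emb, orig)[0, 1] ** 2) if orig.std() > 0 else 1.0
    return Ordination(coords=coords, stress=float(mds.stress_), var_explained=var_explained)


def gsi_scan(
    D: DissimilarityMatrix | np.ndarray,
    k_range: range | list[int] = range(2, 21),
    null_reps: int = 10,
    nmds_dim: int = 3,
    seed: int = 1,
) -> pd.DataFrame:
    """Corrected GSI over a range of cluster numbers.

    For each k the GSI of the PAM partition is computed, and corrected by
    subtracting the mean GSI of ``null_reps`` reference datasets: Gaussian
    point clouds whose per-dimension SDs equal those of an ``nmds_dim``-
    dimensional NMDS embedding of the data, clustered and scored the same
    way.  A clear peak in the corrected index indicates clustering tendency.

    Returns a data frame with columns k, gsi, null_gsi, corrected_gsi.
    """
    dm = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    n = dm.shape[0]
    if n < 4:
        raise ValueError("need at least 4 units for a GSI scan")
    ks = [k for k in k_range]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")

    gsi = np.array([pam_cluster(dm, k, compute_gsi=True).gsi for k in ks])

    ord_ = nmds_embed(dm, d=min(nmds_dim, n - 2), seed=seed, n_starts=4)
    sds = ord_.coords.std(axis=0, ddof=0)
    rng = np.random.default_rng(seed)
    null = np.zeros((null_reps, len(ks)))
    for r in range(null_reps):
        pts = rng.normal(scale=sds, size=(n, len(sds)))
        dnull = squareform(pdist(pts))
        null[r] = [pam_cluster(dnull, k, compute_gsi=True).gsi for k in ks]
    null_mean = null.mean(axis=0)
    return pd.DataFrame(
        {"k": ks, "gsi": gsi, "null_gsi": null_mean, "corrected_gsi": gsi - null_mean}
    )


def gmm_merge_cluster(
    X: np.ndarray,
    max_k: int = 10,
    seed: int = 1,
    merge_threshold: float = 0.025,
    reg_covar: float = 1e-6,
) -> Partition:
    """BIC-selected Gaussian mixture with misclassification-based merging.

    Unconstrained-covariance mixtures are fitted by EM for k = 1..max_k and
    the order with the lowest BIC is kept (ties resolved toward smaller k).
    Component pairs are then merged, highest first, while the directly
    estimated misclassification probability between a pair exceeds
    ``merge_threshold``: for clusters (i, j) this is the larger of the mean
    posterior mass of j among points assigned to i and vice versa.
    """
    X = np.asarray(X, float)
    n, d = X.shape
    if n <= d + 1:
        raise ValueError("need more points than dimensions + 1")
    fits, bics = [], []
    for k in range(1, max_k + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed,
            reg_covar=reg_covar, n_init=3,
        )
        try:
            gm.fit(X)
        except ValueError:
            logger.warning("GMM fit failed at k=%d; applying ridge regularisation", k)
            gm = GaussianMixture(
                n_components=k, covariance_type="full", random_state=seed,
                reg_covar=1e-3, n_init=3,
            )
            gm.fit(X)
        fits.append(gm)
        bics.append(gm.bic(X))
    best = int(np.argmin(bics))  # argmin takes the first (smallest k) on ties
    gm = fits[best]
    tau = gm.predict_proba(X)  # (n, k)

    groups = [[c] for c in range(gm.n_components)]
    while len(groups) > 1:
        post = np.stack([tau[:, g].sum(axis=1) for g in groups], axis=1)
        assign = np.argmax(post, axis=1)
        k = len(groups)
        mis = np.zeros((k, k))
        for i in range(k):
            members = assign == i
            if members.sum() == 0:
                continue
            mis[i] = post[members].mean(axis=0)
        np.fill_diagonal(mis, 0.0)
        pair_mis = np.maximum(mis, mis.T)
        i, j = np.unravel_index(np.argmax(pair_mis), pair_mis.shape)
        if pair_mis[i, j] <= merge_threshold:
            break
        groups[min(i, j)] = groups[min(i, j)] + groups[max(i, j)]
        del groups[max(i, j)]

    post = np.stack([tau[:, g].sum(axis=1) for g in groups], axis=1)
    labels = np.argmax(post, axis=1)
    # relabel to consecutive non-empty ids
    uniq, labels = np.unique(labels, return_inverse=True)
    return Partition(labels=labels, k=len(uniq))


def adjusted_rand(p1: Partition | np.ndarray, p2: Partition | np.ndarray) -> float:
    """Permutation-model-adjusted Rand index between two partitions."""
    l1 = p1.labels if isinstance(p1, Partition) else np.asarray(p1)
    l2 = p2.labels if isinstance(p2, Partition) else np.asarray(p2)
    if len(l1) != len(l2):
        raise ValueError("partitions must cover the same unit set")
    return float(adjusted_rand_score(l1, l2))
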