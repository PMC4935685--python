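"""Population- and continent-level divergence statistics.

The central question — have song cultures diverged between colonies? — is
answered on the DTW dissimilarity matrix without assuming any distribution:

* ``mrpp`` (multiresponse permutation procedure) compares the observed
  weighted mean within-group dissimilarity delta with its permutation
  expectation m_delta, permuting whole individuals between groups (all of an
  individual's units move together).  The effect size is
  ``A = 1 - delta/m_delta``; small positive A with small p means groups are
  statistically distinct but barely more homogeneous than random ones.
* ``type_frequency_test`` asks whether unit *types* are used at different
  frequencies across groups: a Pearson chi-square on the type x group table
  with a permutation p-value from individual-level shuffles, and Cramer's V
  as the effect size.
* ``spatial_median`` and ``nj_dendrogram`` summarise each group by the
  geometric median of its ordination coordinates and display between-group
  structure as a neighbor-joining tree whose branch lengths reflect median
  dissimilarities.

Grouping by continent instead of population is the same code path with a
coarser group label.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio import TreeNode
from skbio.tree import nj

from .dtw import DissimilarityMatrix

logger = logging.getLogger("songculture")


@dataclass
class MRPPResult:
    delta: float
    m_delta: float
    A: float
    p: float
    n_perm: int

    def __post_init__(self) -> None:
        if abs(self.A - (1.0 - self.delta / self.m_delta)) > 1e-12:
            raise ValueError("MRPP effect size must satisfy A = 1 - delta/m_delta")


@dataclass
class ContingencyResult:
    chi2: float
    df: int
    p_perm: float
    cramers_v: float
    table: pd.DataFrame


def _weighted_within_delta(dm: np.ndarray, group_codes: np.ndarray, n_groups: int) -> float:
    """delta = sum_g (n_g/N) * mean pairwise dissimilarity within group g."""
    n = len(group_codes)
    delta = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(group_codes == g)
        if len(idx) < 2:
            continue
        sub = dm[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(len(idx), k=1)].mean()
        delta += (len(idx) / n) * mean_within
    return delta


def mrpp(
    D: DissimilarityMatrix | np.ndarray,
    groups: Sequence[str],
    n_perm: int = 10000,
    seed: int = 1,
    individuals: Sequence[str] | None = None,
    unit_of_permutation: str = "individual",
) -> MRPPResult:
    """Multiresponse permutation procedure with group weights n_g/N.

    ``unit_of_permutation='individual'`` shuffles individuals between
    groups (all of an individual's units move together, preserving the
    number of individuals per group); ``'unit'`` shuffles single units, for
    sensitivity analysis.  p is the add-one lower-tail permutation p-value
    (small delta = groups internally homogeneous).
    """
    dm = D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, float)
    groups = np.asarray(groups)
    if individuals is None and isinstance(D, DissimilarityMatrix) and D.individuals:
        individuals = D.individuals
    rng = np.random.default_rng(seed)

    # drop groups with fewer than two units
    keep_groups = [g for g in np.unique(groups) if np.sum(groups == g) >= 2]
    dropped = set(np.unique(groups)) - set(keep_groups)
    if dropped:
        logger.warning("groups with <2 units excluded from MRPP: %s", sorted(dropped))
    keep = np.isin(groups, keep_groups)
    dm = dm[np.ix_(keep, keep)]
    groups = groups[keep]
    if individuals is not None:
        individuals = np.asarray(individuals)[keep]
    if len(keep_groups) < 2:
        raise ValueError("MRPP needs at least two groups with two or more units each")

    uniq, codes = np.unique(groups, return_inverse=True)
    delta_obs = _weighted_within_delta(dm, codes, len(uniq))

    if unit_of_permutation == "individual":
        if individuals is None:
            raise ValueError("individual-level permutation requires individual labels")
        ind_uniq, ind_codes = np.unique(individuals, return_inverse=True)
        # group of each individual (all units of an individual share a group)
        ind_group = np.empty(len(ind_uniq), dtype=int)
        for i in range(len(ind_uniq)):
            gset = np.unique(codes[ind_codes == i])
            if len(gset) > 1:
                raise ValueError(f"individual {ind_uniq[i]!r} appears in multiple groups")
            ind_group[i] = gset[0]
        deltas = np.empty(n_perm)
        for r in range(n_perm):
            perm = rng.permutation(ind_group)
            deltas[r] = _weighted_within_delta(dm, perm[ind_codes], len(uniq))
    elif unit_of_permutation == "unit":
        deltas = np.empty(n_perm)
        for r in range(n_perm):
            deltas[r] = _weighted_within_delta(dm, rng.permutation(codes), len(uniq))
    else:
        raise ValueError("unit_of_permutation must be 'individual' or 'unit'")

    m_delta = float(deltas.mean())
    p = float((np.sum(deltas <= delta_obs + 1e-15) + 1) / (n_perm + 1))
    return MRPPResult(
        delta=float(delta_obs),
        m_delta=m_delta,
        A=float(1.0 - delta_obs / m_delta),
        p=p,
        n_perm=n_perm,
    )


def type_frequency_test(
    type_labels: Sequence,
    groups: Sequence[str],
    n_perm: int = 10000,
    seed: int = 1,
    individuals: Sequence[str] | None = None,
) -> ContingencyResult:
    """Permutation chi-square test on the type x group contingency table.

    The statistic is the Pearson chi-square with analytic margins; the
    p-value comes from shuffling individuals (or units, if no individual
    labels are given) between groups.  Cramer's V =
    sqrt(chi2 / (N * min(r-1, c-1))).
    """
    types = np.asarray(type_labels)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)

    table = pd.crosstab(pd.Series(types, name="type"), pd.Series(groups, name="group"))
    empty_rows = table.index[(table.sum(axis=1) == 0)]
    empty_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(empty_rows) or len(empty_cols):
        logger.warning("dropping empty rows/columns: %s %s", list(empty_rows), list(empty_cols))
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        raise ValueError("contingency test needs at least two types and two groups")

    def chi2_of(tab: np.ndarray) -> float:
        res = chi2_contingency(tab, correction=False)
        return float(res.statistic)

    obs_tab = table.to_numpy()
    chi2 = chi2_of(obs_tab)
    df = (r - 1) * (c - 1)
    n = obs_tab.sum()
    cramers_v = float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))

    type_codes = pd.Categorical(types, categories=table.index).codes
    group_codes = pd.Categorical(groups, categories=table.columns).codes
    valid = (type_codes >= 0) & (group_codes >= 0)
    type_codes, group_codes = type_codes[valid], group_codes[valid]

    if individuals is not None:
        individuals = np.asarray(individuals)[valid]
        ind_uniq, ind_codes = np.unique(individuals, return_inverse=True)
        ind_group = np.empty(len(ind_uniq), dtype=int)
        for i in range(len(ind_uniq)):
            ind_group[i] = group_codes[ind_codes == i][0]
    count = 0
    for _ in range(n_perm):
        if individuals is not None:
            perm_groups = rng.permutation(ind_group)[ind_codes]
        else:
            perm_groups = rng.permutation(group_codes)
        tab = np.zeros((r, c))
        np.add.at(tab, (type_codes, perm_groups), 1)
        # guard against degenerate permuted tables
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            stat = 0.0
        else:
            stat = chi2_of(tab)
        if stat >= chi2 - 1e-12:
            count += 1
    p_perm = float((count + 1) / (n_perm + 1))
    return ContingencyResult(chi2=chi2, df=df, p_perm=p_perm, cramers_v=cramers_v, table=table)


def spatial_median(coords: np.ndarray, tol: float = 1e-9, max_iter: int = 1000) -> np.ndarray:
    """Geometric median by iteratively re-weighted averaging (Weiszfeld).

    The median minimises the summed Euclidean distances to the points; when
    an iterate lands on a data point the standard perturbation safeguard is
    applied.
    """
    pts = np.atleast_2d(np.asarray(coords, float))
    if len(pts) == 1:
        return pts[0].copy()
    x = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - x, axis=1)
        on_point = d < 1e-14
        if on_point.any():
            # Vardi-Zhang step: treat the coincident point explicitly
            others = ~on_point
            if not others.any():
                return x
            w = 1.0 / d[others]
            t = (pts[others] * w[:, None]).sum(axis=0) / w.sum()
            r = np.linalg.norm(((pts[others] - x) / d[others, None]).sum(axis=0))
            step = max(0.0, 1.0 - on_point.sum() / r) if r > 0 else 0.0
            x_new = step * t + (1 - step) * x
        else:
            w = 1.0 / d
            x_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(x_new - x) < tol:
            return x_new
        x = x_new
    return x


def nj_dendrogram(M: np.ndarray, names: Sequence[str]) -> TreeNode:
    """Saitou-Nei neighbor joining of a symmetric distance matrix.

    Branch lengths reproduce the input exactly when it is additive;
    negative estimated branch lengths are clamped to zero with a warning.
    Serialise with ``str(tree)`` or ``tree.write(...)`` (newick).
    """
    M = np.asarray(M, float)
    if M.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three groups")
    if not np.allclose(M, M.T) or np.any(M < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    dm = SkbioDistanceMatrix(M, ids=list(names))
    tree = nj(dm)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        logger.warning("clamped %d negative branch lengths to zero", clamped)
    return tree


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def group_median_matrix(
    coords: np.ndarray, groups: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Distance matrix between the spatial medians of each group's points."""
    groups = np.asarray(groups)
    names = sorted(np.unique(groups))
    medians = np.stack([spatial_median(coords[groups == g]) for g in names])
    diff = medians[:, None, :] - medians[None, :, :]
    return np.sqrt((diff**2).sum(axis=2)), list(names)
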