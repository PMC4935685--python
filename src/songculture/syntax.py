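"""Motif composition and syntactical structure of song sequences.

Three questions about how motifs are built from typed units:

* Do particular transitions occur more or less often than expected from
  type frequencies alone?  ``transition_bias`` scores every ordered type
  pair (including START and END pseudo-states, which capture the
  accumulation of particular types at motif edges) with the signed bias
  ``(p_obs - p_exp) / max(p_obs, p_exp)`` in [-1, 1].
* Do motifs contain more (or fewer) distinct types than random assembly
  predicts?  ``types_per_motif_test`` permutes units between motifs within
  populations, preserving motif lengths.
* How predictable are sequences overall?  ``markov_redundancy`` computes
  ``1 - H1/H0`` where ``H0`` is the entropy of the type frequencies and
  ``H1`` the first-order conditional entropy of next type given current
  type, both Miller-Madow corrected for finite samples.  0 means no
  syntactical structure, 1 a fully deterministic syntax.

``syntactic_redundancy_scan`` re-clusters units partly on the basis of
which partition maximises redundancy, which inflates the estimate even on
random data; the estimate is therefore corrected by subtracting the mean
obtained on simulated structureless dissimilarity matrices, and a 99%
bootstrap interval over individuals is attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .clustering import pam_cluster
from .dtw import DissimilarityMatrix

logger = logging.getLogger("songculture")

START = "START"
END = "END"

Sequences = Sequence[Sequence[Hashable]]


@dataclass
class TransitionTable:
    """Observed vs expected transition probabilities with signed biases."""

    types: list
    counts: pd.DataFrame
    p_obs: pd.DataFrame
    p_exp: pd.DataFrame
    bias: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.counts.index:
            for b in self.counts.columns:
                rows.append(
                    (a, b, self.counts.loc[a, b], self.p_obs.loc[a, b],
                     self.p_exp.loc[a, b], self.bias.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["from_type", "to_type", "count", "p_obs", "p_exp", "bias"])


def transition_bias(sequences: Sequences, types: Sequence | None = None) -> TransitionTable:
    """Signed transition biases over typed unit sequences.

    ``bias = (p_obs - p_exp) / max(p_obs, p_exp)``; positive values mean the
    transition occurs more often than expected under independent draws from
    the type frequencies, negative less often, 0 exactly as expected.
    START -> x and x -> END rows capture motif-position effects.  Expected
    probabilities are products of token frequencies, where each motif
    contributes one START and one END token.
    """
    if not sequences:
        raise ValueError("need at least one motif")
    seq_types = sorted({t for s in sequences for t in s}, key=str)
    if types is None:
        types = seq_types
    else:
        unseen = set(seq_types) - set(types)
        if unseen:
            raise ValueError(f"sequences contain types not in the declared set: {unseen}")
        types = list(types)
    full = list(types) + [START, END]
    counts = pd.DataFrame(0, index=full, columns=full, dtype=float)
    n_motifs = len(sequences)
    n_units = 0
    for s in sequences:
        if len(s) == 0:
            raise ValueError("motifs must contain at least one unit")
        n_units += len(s)
        counts.loc[START, s[0]] += 1
        for a, b in zip(s[:-1], s[1:]):
            counts.loc[a, b] += 1
        counts.loc[s[-1], END] += 1

    total_transitions = counts.to_numpy().sum()  # = n_units + n_motifs
    p_obs = counts / total_transitions

    n_tokens = n_units + 2 * n_motifs
    freq = pd.Series(0.0, index=full)
    for s in sequences:
        for t in s:
            freq[t] += 1
    freq[START] = freq[END] = n_motifs
    freq /= n_tokens
    p_exp = pd.DataFrame(np.outer(freq, freq), index=full, columns=full)
    # structurally impossible transitions carry no expectation
    p_exp.loc[END, :] = 0.0
    p_exp.loc[:, START] = 0.0
    p_exp.loc[START, END] = 0.0

    denom = np.maximum(p_obs.to_numpy(), p_exp.to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        bias = np.where(denom > 0, (p_obs.to_numpy() - p_exp.to_numpy()) / denom, 0.0)
    return TransitionTable(
        types=full,
        counts=counts,
        p_obs=p_obs,
        p_exp=p_exp,
        bias=pd.DataFrame(bias, index=full, columns=full),
    )


def types_per_motif_test(
    sequences: Sequences,
    populations: Sequence[str] | None = None,
    n_perm: int = 1000,
    seed: int = 1,
) -> tuple[float, float, float]:
    """Permutation test for the number of distinct types per motif.

    Units are randomly permuted between motifs (within populations),
    preserving motif lengths and population composition.  Returns
    ``(observed mean, null mean, two-sided add-one p-value)``.
    """
    if populations is None:
        populations = ["all"] * len(sequences)
    rng = np.random.default_rng(seed)

    by_pop: dict[str, list[int]] = {}
    for i, p in enumerate(populations):
        by_pop.setdefault(p, []).append(i)
    usable = []
    for p, idx in by_pop.items():
        if len(idx) < 2:
            logger.warning("population %r has a single motif; excluded from permutation", p)
        else:
            usable.extend(idx)
    if not usable:
        raise ValueError("no population with at least two motifs")
    seqs = [list(sequences[i]) for i in usable]

    def mean_types(ss: list[list]) -> float:
        return float(np.mean([len(set(s)) for s in ss]))

    obs = mean_types(seqs)
    pops_u = [populations[i] for i in usable]
    pool_by_pop = {p: [t for s, sp in zip(seqs, pops_u) if sp == p for t in s] for p in set(pops_u)}
    null = np.empty(n_perm)
    for r in range(n_perm):
        shuffled = {p: rng.permutation(pool) for p, pool in pool_by_pop.items()}
        cursor = {p: 0 for p in shuffled}
        perm_seqs = []
        for s, p in zip(seqs, pops_u):
            c = cursor[p]
            perm_seqs.append(list(shuffled[p][c : c + len(s)]))
            cursor[p] = c + len(s)
        null[r] = mean_types(perm_seqs)
    null_mean = float(null.mean())
    p = (np.sum(np.abs(null - null_mean) >= abs(obs - null_mean) - 1e-12) + 1) / (n_perm + 1)
    return obs, null_mean, float(p)


def _miller_madow_entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) plus the Miller-Madow bias correction."""
    counts = np.asarray(counts, float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts[counts > 0] / n
    h = float(-(p * np.log(p)).sum())
    return h + (len(p) - 1) / (2.0 * n)


def markov_redundancy(sequences: Sequences) -> float:
    """First-order Markov redundancy ``1 - H1/H0`` of unit sequences.

    H0 is the (Miller-Madow corrected) entropy of the type frequencies; H1
    the conditional entropy of the next type given the current type,
    row-wise corrected.  Transitions are counted within motifs only.
    """
    tokens = [t for s in sequences for t in s]
    types = sorted(set(tokens), key=str)
    if len(types) < 2:
        raise ValueError("redundancy undefined with fewer than two types (H0 = 0)")
    index = {t: i for i, t in enumerate(types)}
    k = len(types)
    trans = np.zeros((k, k))
    n_trans = 0
    for s in sequences:
        for a, b in zip(s[:-1], s[1:]):
            trans[index[a], index[b]] += 1
            n_trans += 1
    if n_trans == 0:
        raise ValueError("need at least one within-motif transition")
    marg = np.bincount([index[t] for t in tokens], minlength=k).astype(float)
    h0 = _miller_madow_entropy(marg)
    row_n = trans.sum(axis=1)
    h1 = 0.0
    for i in range(k):
        if row_n[i] > 0:
            h1 += (row_n[i] / n_trans) * _miller_madow_entropy(trans[i])
    return float(np.clip(1.0 - h1 / h0, 0.0, 1.0))


@dataclass
class RedundancyEstimate:
    """Corrected redundancy at one number of syntactic clusters."""

    k_syntactic: int
    redundancy: float
    null_redundancy: float
    corrected: float
    ci99: tuple[float, float]
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


def _sequences_from_labels(
    motif_units: Sequence[Sequence[int]], labels: np.ndarray
) -> list[list[int]]:
    return [[int(labels[u]) for u in motif] for motif in motif_units]


def _greedy_redundancy_search(
    motif_units: Sequence[Sequence[int]],
    labels0: np.ndarray,
    k: int,
    rng: np.random.Generator,
    allowed: Sequence[Sequence[int]] | None = None,
    restarts: int = 5,
    max_sweeps: int = 20,
) -> tuple[np.ndarray, float]:
    """Greedy single-unit reassignment maximising redundancy.

    First-improvement moves over a random unit order; the objective never
    decreases across accepted moves.  ``allowed`` restricts each unit to an
    acoustically plausible candidate label set, so the partition stays
    anchored to the dissimilarity structure and only ambiguous units are
    free to serve the syntax.  The first restart begins from ``labels0``;
    later restarts perturb a fraction of the movable units within their
    allowed sets to escape plateaus, and the best partition found is
    returned.
    """
    n = len(labels0)
    if allowed is None:
        allowed = [np.arange(k)] * n
    movable = [u for u in range(n) if len(allowed[u]) > 1]

    def objective(labels: np.ndarray) -> float:
        seqs = _sequences_from_labels(motif_units, labels)
        try:
            return markov_redundancy(seqs)
        except ValueError:
            return -np.inf

    best_labels, best_val = labels0.copy(), objective(labels0)
    for restart in range(restarts):
        labels = labels0.copy()
        if restart > 0 and movable:
            # graded perturbation: later restarts scramble more of the
            # movable units, diversifying the basins the search visits
            frac = restart / restarts
            n_perturb = max(1, int(len(movable) * frac))
            for u in rng.choice(movable, size=n_perturb, replace=False):
                labels[u] = rng.choice(allowed[u])
        val = objective(labels)
        for _ in range(max_sweeps):
            improved = False
            for u in rng.permutation(n):
                cur = labels[u]
                if np.sum(labels == cur) == 1:
                    continue  # never empty a cluster
                for c in allowed[u]:
                    if c == cur:
                        continue
                    labels[u] = c
                    new_val = objective(labels)
                    if new_val > val + 1e-12:
                        val = new_val
                        improved = True
                        break
                    labels[u] = cur
                else:
                    continue
            if not improved:
                break
        if val > best_val:
            best_labels, best_val = labels.copy(), val
    return best_labels, best_val


def syntactic_redundancy_scan(
    D: DissimilarityMatrix,
    motif_units: Sequence[Sequence[int]],
    k_range: Sequence[int],
    null_reps: int = 3,
    boot_reps: int = 200,
    seed: int = 1,
    null_dim: int = 50,
    individuals: Sequence[str] | None = None,
    acoustic_slack: float = 1.5,
) -> list[RedundancyEstimate]:
    """Redundancy as a function of the number of syntactic clusters.

    For each k the PAM partition of the dissimilarity matrix seeds a greedy
    search that reassigns units between clusters while redundancy
    increases; a unit may only take the label of a cluster whose medoid is
    within ``acoustic_slack`` times its nearest-medoid distance, so the
    partition remains anchored to acoustic structure and only acoustically
    ambiguous units are free to maximise syntactical structure.  Because
    the search inflates redundancy even on random data,
    ``null_reps`` structureless datasets (independent Gaussians whose
    per-dimension SDs equal those of up to ``null_dim`` principal
    coordinates of the empirical matrix) are run through the identical
    procedure and their mean redundancy is subtracted.  The 99% CI is a
    percentile bootstrap over individuals of the corrected estimate under
    the found partition; each bootstrap replicate subtracts a randomly
    drawn null replicate rather than the null mean, so the uncertainty of
    the null correction itself is propagated into the interval.

    ``motif_units`` lists, per motif, the row indices into ``D`` of its
    units in order.
    """
    n = D.n
    ks = list(k_range)
    if min(ks) < 2 or max(ks) > n - 1:
        raise ValueError(f"k values must lie within [2, {n - 1}]")
    for motif in motif_units:
        for u in motif:
            if not 0 <= u < n:
                raise ValueError(f"unit index {u} outside the dissimilarity matrix")
    if individuals is None:
        individuals = D.individuals if D.individuals else [str(i) for i in range(len(motif_units))]
    rng = np.random.default_rng(seed)

    # per-dimension SDs of a principal-coordinates embedding of the data
    # (exact Euclidean variance decomposition of the dissimilarity matrix)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (D.values**2) @ j
    vals = np.sort(np.linalg.eigvalsh(b))[::-1]
    vals = vals[: min(null_dim, n - 1)]
    sds = np.sqrt(np.clip(vals, 0.0, None) / n)
    null_matrices = []
    for _ in range(null_reps):
        pts = rng.normal(scale=sds, size=(n, len(sds)))
        null_matrices.append(squareform(pdist(pts)))

    uniq_ind = sorted(set(individuals))
    motifs_of_ind = {
        ind: [mi for mi, _ in enumerate(motif_units) if individuals[mi] == ind]
        for ind in uniq_ind
    }

    def candidate_labels(dm: np.ndarray, part) -> list[np.ndarray]:
        med = dm[:, part.medoids]  # (n, k) distance of each unit to each medoid
        nearest = med.min(axis=1)
        return [np.flatnonzero(med[u] <= acoustic_slack * max(nearest[u], 1e-12) + 1e-12)
                for u in range(dm.shape[0])]

    results = []
    for k in ks:
        part0 = pam_cluster(D, k)
        dm = D.values
        labels, red = _greedy_redundancy_search(
            motif_units, part0.labels, k, rng, allowed=candidate_labels(dm, part0)
        )

        null_vals = []
        for dm_null in null_matrices:
            np0 = pam_cluster(dm_null, k)
            _, nr = _greedy_redundancy_search(
                motif_units, np0.labels, k, rng,
                allowed=candidate_labels(dm_null, np0),
            )
            null_vals.append(nr)
        null_mean = float(np.mean(null_vals))
        corrected = red - null_mean

        boot = np.empty(boot_reps)
        for b in range(boot_reps):
            chosen = rng.choice(uniq_ind, size=len(uniq_ind), replace=True)
            seqs = []
            for ind in chosen:
                for mi in motifs_of_ind[ind]:
                    seqs.append([int(labels[u]) for u in motif_units[mi]])
            try:
                boot[b] = markov_redundancy(seqs) - null_vals[rng.integers(len(null_vals))]
            except ValueError:
                boot[b] = np.nan
        boot = boot[np.isfinite(boot)]
        if boot.size:
            lo, hi = np.percentile(boot, [0.5, 99.5])
            lo, hi = float(min(lo, corrected)), float(max(hi, corrected))
        else:
            lo = hi = corrected
        results.append(
            RedundancyEstimate(
                k_syntactic=k,
                redundancy=red,
                null_redundancy=null_mean,
                corrected=corrected,
                ci99=(lo, hi),
                labels=labels,
            )
        )
    return results


def dissimilarity_strata(
    D: DissimilarityMatrix,
) -> dict[str, np.ndarray]:
    """Pairwise dissimilarities stratified by sharing level.

    Returns the whole-sample distances, those between units of the same
    population, and those between units of the same individual (nested, as
    in the description of within- vs between-population dissimilarity
    distributions).  A description utility: no test statistic is attached.
    """
    iu = np.triu_indices(D.n, k=1)
    vals = D.values[iu]
    pops = np.asarray(D.populations)
    inds = np.asarray(D.individuals)
    same_pop = pops[iu[0]] == pops[iu[1]] if pops.size else np.zeros(len(vals), bool)
    same_ind = inds[iu[0]] == inds[iu[1]] if inds.size else np.zeros(len(vals), bool)
    return {
        "all": vals,
        "within_population": vals[same_pop],
        "within_individual": vals[same_ind],
    }
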