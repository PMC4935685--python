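"""Dynamic-time-warping dissimilarity between song units.

Two units (elements or syllables) are compared frame-by-frame over five
features: the four acoustic contours (FF, mean frequency, frequency change,
harmonicity), each normalised by its standard deviation pooled over the
whole dataset, plus time-within-unit weighted by ``q * p`` where ``p`` is
the inverse duration of the longer unit and ``q`` defaults to 5.  The
``q * p`` weighting makes length differences count logarithmically: all
else equal, 2 ms vs 4 ms units are as dissimilar as 20 ms vs 40 ms units.

The DTW distance is the minimum over monotone warp paths (steps right, down
and diagonal) of the *mean* frame distance along the path, computed exactly
by Dinkelbach's parametric reformulation: lambda is optimal iff the minimum
over paths of sum(cost - lambda) is zero, and iterating lambda <- mean cost
of the current optimal path converges finitely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .songio import FRAME_STEP_MS, Motif, Syllable

logger = logging.getLogger("songculture")

DEFAULT_Q = 5.0

_FEATURES = ("ff", "mf", "fc", "harm")


@dataclass
class UnitContour:
    """A song unit as time-indexed acoustic feature vectors.

    ``t_ms`` is measured from unit onset in real time; for syllables the
    time axis includes internal gaps (no frames are placed inside gaps), so
    syllable rhythm is preserved.
    """

    unit_id: str
    t_ms: np.ndarray
    ff: np.ndarray
    mf: np.ndarray
    fc: np.ndarray
    harm: np.ndarray
    individual: str = ""
    population: str = ""
    motif_id: str = ""
    position: int = 0  # index of the unit within its motif
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_ms", *_FEATURES):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if self.t_ms.size == 0:
            raise ValueError("unit contour must contain at least one frame")
        if self.duration_ms is None:
            self.duration_ms = float(self.t_ms[-1] - self.t_ms[0] + FRAME_STEP_MS)
        self._impute_missing()

    def _impute_missing(self) -> None:
        """Fill unvoiced (NaN) feature values from neighbouring frames."""
        for name in _FEATURES:
            x = getattr(self, name)
            bad = ~np.isfinite(x)
            if bad.all():
                raise ValueError(f"unit {self.unit_id} is entirely unvoiced in {name}")
            if bad.any():
                x = x.copy()
                x[bad] = np.interp(self.t_ms[bad], self.t_ms[~bad], x[~bad])
                setattr(self, name, x)

    @property
    def n_frames(self) -> int:
        return len(self.t_ms)

    def features(self) -> np.ndarray:
        """(n_frames, 4) array in the order ff, mf, fc, harm."""
        return np.column_stack([self.ff, self.mf, self.fc, self.harm])


def unit_from_element(motif: Motif, index: int, unit_id: str | None = None) -> UnitContour:
    el = motif.elements[index]
    arr = el.feature_array()
    return UnitContour(
        unit_id=unit_id or f"{motif.individual_id}/{motif.motif_id}/e{index}",
        t_ms=arr[:, 0],
        ff=arr[:, 1],
        mf=arr[:, 2],
        fc=arr[:, 3],
        harm=arr[:, 4],
        individual=motif.individual_id,
        population=motif.population,
        motif_id=motif.motif_id,
        position=index,
        duration_ms=el.duration_ms,
    )


def unit_from_syllable(
    motif: Motif, syllable: Syllable, position: int = 0, unit_id: str | None = None
) -> UnitContour:
    """Concatenate a syllable's element frames, keeping real-time positions."""
    onset = syllable.onset_ms
    t, cols = [], {name: [] for name in _FEATURES}
    for el in syllable.elements:
        arr = el.feature_array()
        t.append(arr[:, 0] + (el.onset_ms - onset))
        for j, name in enumerate(_FEATURES):
            cols[name].append(arr[:, j + 1])
    return UnitContour(
        unit_id=unit_id or f"{motif.individual_id}/{motif.motif_id}/s{position}",
        t_ms=np.concatenate(t),
        ff=np.concatenate(cols["ff"]),
        mf=np.concatenate(cols["mf"]),
        fc=np.concatenate(cols["fc"]),
        harm=np.concatenate(cols["harm"]),
        individual=motif.individual_id,
        population=motif.population,
        motif_id=motif.motif_id,
        position=position,
        duration_ms=syllable.duration_ms,
    )


def motifs_to_units(motifs: Sequence[Motif], level: str = "element",
                    gap_threshold_ms: float = 5.0) -> list[UnitContour]:
    """Extract all element- or syllable-level unit contours from motifs."""
    from .songio import segment_into_syllables

    units: list[UnitContour] = []
    for m in motifs:
        if level == "element":
            units.extend(unit_from_element(m, i) for i in range(m.n_elements))
        elif level == "syllable":
            for i, syl in enumerate(segment_into_syllables(m, gap_threshold_ms)):
                units.append(unit_from_syllable(m, syl, position=i))
        else:
            raise ValueError(f"level must be 'element' or 'syllable', got {level!r}")
    return units


@dataclass(frozen=True)
class FeatureScaling:
    """Pooled feature standard deviations and the time-weight parameter q.

    SDs are computed once over all frames of all units in the dataset so
    that distances are comparable across populations and reproducible
    across runs.
    """

    sd_ff: float
    sd_mf: float
    sd_fc: float
    sd_harm: float
    q: float = DEFAULT_Q

    def __post_init__(self) -> None:
        if min(self.sd_ff, self.sd_mf, self.sd_fc, self.sd_harm) <= 0:
            raise ValueError("all feature SDs must be positive")
        if self.q < 0:
            raise ValueError("q must be non-negative")

    @classmethod
    def from_units(cls, units: Sequence[UnitContour], q: float = DEFAULT_Q) -> "FeatureScaling":
        pooled = np.concatenate([u.features() for u in units], axis=0)
        sds = pooled.std(axis=0, ddof=0)
        return cls(sd_ff=float(sds[0]), sd_mf=float(sds[1]), sd_fc=float(sds[2]),
                   sd_harm=float(sds[3]), q=q)

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_ff, self.sd_mf, self.sd_fc, self.sd_harm])


def frame_distance(
    a_features: np.ndarray,
    a_t_ms: float,
    b_features: np.ndarray,
    b_t_ms: float,
    scaling: FeatureScaling,
    longer_duration_ms: float,
) -> float:
    """Euclidean distance across the four SD-normalised features plus time.

    The time term is ``q * (t_a - t_b) / L`` with ``L`` the duration of the
    longer of the two units.
    """
    if longer_duration_ms <= 0:
        raise ValueError("longer_duration_ms must be positive")
    diff = (np.asarray(a_features, float) - np.asarray(b_features, float)) / scaling.sds
    tdiff = scaling.q * (a_t_ms - b_t_ms) / longer_duration_ms
    return float(np.sqrt(np.dot(diff, diff) + tdiff * tdiff))


def _cost_matrix(u: UnitContour, v: UnitContour, scaling: FeatureScaling) -> np.ndarray:
    l_max = max(u.duration_ms, v.duration_ms)
    fu = u.features() / scaling.sds
    fv = v.features() / scaling.sds
    sq = ((fu[:, None, :] - fv[None, :, :]) ** 2).sum(axis=2)
    tdiff = scaling.q * (u.t_ms[:, None] - v.t_ms[None, :]) / l_max
    return np.sqrt(sq + tdiff**2)


@njit(cache=False)
def _min_sum_path(A):  # pragma: no cover - exercised via min_mean_path
    """Min over monotone paths of sum(A); returns (min_sum, path_length)."""
    n, m = A.shape
    D = np.empty((n, m))
    L = np.empty((n, m), dtype=np.int64)
    D[0, 0] = A[0, 0]
    L[0, 0] = 1
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + A[0, j]
        L[0, j] = j + 1
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + A[i, 0]
        L[i, 0] = i + 1
        for j in range(1, m):
            best = D[i - 1, j - 1]
            bl = L[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
                bl = L[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
                bl = L[i, j - 1]
            D[i, j] = best + A[i, j]
            L[i, j] = bl + 1
    return D[n - 1, m - 1], L[n - 1, m - 1]


@njit(cache=False)
def min_mean_path(C, tol=1e-12, max_iter=200):  # pragma: no cover
    """Minimum over monotone warp paths of the mean cost along the path.

    Dinkelbach iteration: for the current estimate lambda, find the path
    minimising sum(C - lambda); if that minimum is (numerically) zero,
    lambda is the optimal mean, otherwise the minimising path's mean cost
    strictly improves lambda.
    """
    lam = C[0, 0]
    for _ in range(max_iter):
        val, length = _min_sum_path(C - lam)
        new_lam = lam + val / length
        if abs(val) <= tol * max(1.0, length) or abs(new_lam - lam) <= tol:
            return new_lam
        lam = new_lam
    return lam


def dtw_distance(u: UnitContour, v: UnitContour, scaling: FeatureScaling) -> float:
    """Mean frame distance along the optimal start-to-end warp path."""
    if u.n_frames == 0 or v.n_frames == 0:
        raise ValueError("cannot warp an empty unit")
    return float(min_mean_path(_cost_matrix(u, v, scaling)))


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise DTW distances between units, with unit metadata."""

    unit_ids: list[str]
    values: np.ndarray
    level: str = "element"
    individuals: list[str] = field(default_factory=list)
    populations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        n = len(self.unit_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of unit ids")
        if np.any(self.values < 0):
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("dissimilarity matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangular entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, idx: Sequence[int]) -> "DissimilarityMatrix":
        idx = list(idx)
        return DissimilarityMatrix(
            unit_ids=[self.unit_ids[i] for i in idx],
            values=self.values[np.ix_(idx, idx)],
            level=self.level,
            individuals=[self.individuals[i] for i in idx] if self.individuals else [],
            populations=[self.populations[i] for i in idx] if self.populations else [],
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.unit_ids, columns=self.unit_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, level: str = "element") -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(unit_ids=[str(c) for c in df.columns], values=df.to_numpy(float), level=level)

    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP-style lower-triangular text output."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i in range(self.n):
                row = " ".join(f"{self.values[i, j]:.10g}" for j in range(i))
                fh.write(f"{self.unit_ids[i]}\t{row}\n".rstrip() + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, level: str = "element") -> "DissimilarityMatrix":
        with open(path) as fh:
            n = int(fh.readline())
            ids, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                ids.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        values = np.zeros((n, n))
        for i, row in enumerate(rows):
            for j, v in enumerate(row):
                values[i, j] = values[j, i] = v
        return cls(unit_ids=ids, values=values, level=level)


def pairwise_matrix(
    units: Sequence[UnitContour],
    scaling: FeatureScaling | None = None,
    level: str = "element",
) -> DissimilarityMatrix:
    """All-pairs DTW distances.  SDs default to pooling over ``units``."""
    if len(units) < 2:
        raise ValueError("need at least two units for a pairwise matrix")
    if scaling is None:
        scaling = FeatureScaling.from_units(units)
    n = len(units)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = dtw_distance(units[i], units[j], scaling)
    return DissimilarityMatrix(
        unit_ids=[u.unit_id for u in units],
        values=values,
        level=level,
        individuals=[u.individual for u in units],
        populations=[u.population for u in units],
    )
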