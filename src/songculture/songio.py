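"""Song data model, contour-table I/O and motif -> syllable segmentation.

A *motif* is the stereotyped sequence of sound units a male zebra finch
repeats within a song bout.  The atomic unit is the *element* (a single
presumed vocal gesture); elements separated by very short (or negative)
gaps group into *syllables*.  The canonical on-disk representation is a
delimited contour table with one row per spectrogram frame:

    individual, population, motif_id, element_idx, t_ms, ff_hz, mf_hz, fc, harm

``t_ms`` in the table is time within the motif, so element onsets and
inter-element gaps survive a round trip; in memory each element stores its
frames with unit-relative times plus its onset within the motif.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("songculture")

#: frame step of the canonical contour grid (ms)
FRAME_STEP_MS = 0.5

#: gaps strictly longer than this (ms) separate syllables
DEFAULT_GAP_THRESHOLD_MS = 5.0

REQUIRED_COLUMNS = (
    "individual",
    "population",
    "motif_id",
    "element_idx",
    "t_ms",
    "ff_hz",
    "mf_hz",
    "fc",
    "harm",
)


class ContourFormatError(ValueError):
    """Raised when a contour table is missing required columns."""


class ContourValidationError(ValueError):
    """Raised when a contour table row violates a feature invariant."""


@dataclass(frozen=True)
class FeatureFrame:
    """One spectrogram frame of the four acoustic feature contours."""

    t_ms: float
    ff_hz: float
    mf_hz: float
    fc: float
    harm: float

    def __post_init__(self) -> None:
        if self.t_ms < 0:
            raise ContourValidationError(f"t_ms must be >= 0, got {self.t_ms}")
        if self.ff_hz <= 0 or self.mf_hz <= 0:
            raise ContourValidationError(
                f"frequencies must be positive, got ff={self.ff_hz}, mf={self.mf_hz}"
            )
        if not 0.0 <= self.fc <= 1.0:
            raise ContourValidationError(f"fc must lie in [0, 1], got {self.fc}")
        if not 0.0 <= self.harm <= 1.0:
            raise ContourValidationError(f"harm must lie in [0, 1], got {self.harm}")


@dataclass
class Element:
    """An ordered run of feature frames forming one vocal gesture."""

    frames: list[FeatureFrame]
    onset_ms: float = 0.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ContourValidationError("element must contain at least one frame")
        t = np.array([f.t_ms for f in self.frames])
        if np.any(np.diff(t) <= 0):
            raise ContourValidationError("frame times within an element must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return self.frames[-1].t_ms - self.frames[0].t_ms + FRAME_STEP_MS

    @property
    def end_ms(self) -> float:
        return self.onset_ms + self.duration_ms

    def feature_array(self) -> np.ndarray:
        """(n_frames, 5) array of t_ms, ff_hz, mf_hz, fc, harm."""
        return np.array([[f.t_ms, f.ff_hz, f.mf_hz, f.fc, f.harm] for f in self.frames])


@dataclass
class Motif:
    """An individual's ordered element sequence with inter-element gaps (ms).

    ``gaps_ms[i]`` is ``elements[i+1].onset - elements[i].end``; negative gaps
    (overlapping elements) are permitted.
    """

    individual_id: str
    population: str
    elements: list[Element]
    gaps_ms: list[float] = field(default_factory=list)
    motif_id: str = "0"

    def __post_init__(self) -> None:
        if not self.elements:
            raise ContourValidationError("motif must contain at least one element")
        if not self.gaps_ms:
            self.gaps_ms = [
                self.elements[i + 1].onset_ms - self.elements[i].end_ms
                for i in range(len(self.elements) - 1)
            ]
        if len(self.gaps_ms) != len(self.elements) - 1:
            raise ContourValidationError(
                f"expected {len(self.elements) - 1} gaps, got {len(self.gaps_ms)}"
            )

    @property
    def n_elements(self) -> int:
        return len(self.elements)


@dataclass
class Syllable:
    """One or more elements whose internal gaps do not exceed the threshold."""

    elements: list[Element]
    internal_gaps_ms: list[float] = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def onset_ms(self) -> float:
        return self.elements[0].onset_ms

    @property
    def duration_ms(self) -> float:
        return self.elements[-1].end_ms - self.elements[0].onset_ms


def read_contour_table(path: str | Path, sep: str | None = None) -> list[Motif]:
    """Read a contour table (CSV/TSV, UTF-8, header row) into motifs.

    Motifs are grouped by (individual, motif_id) and elements ordered by
    onset.  Frame steps other than 0.5 ms are resampled by linear
    interpolation.  Malformed rows raise errors naming the offending line.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    return motifs_from_frame(df)


def motifs_from_frame(df: pd.DataFrame) -> list[Motif]:
    """Build motifs from an in-memory contour table (see module docstring)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ContourFormatError(f"contour table missing required columns: {missing}")
    if df.empty:
        logger.warning("contour table is empty; returning no motifs")
        return []

    motifs: list[Motif] = []
    for (indiv, motif_id), mdf in df.groupby(["individual", "motif_id"], sort=True):
        pops = mdf["population"].unique()
        if len(pops) > 1:
            raise ContourValidationError(
                f"motif {indiv}/{motif_id} spans multiple populations: {list(pops)}"
            )
        elements = []
        for el_idx, edf in mdf.groupby("element_idx", sort=True):
            edf = edf.sort_values("t_ms")
            t = edf["t_ms"].to_numpy(float)
            if len(t) > 1 and np.any(np.diff(t) <= 0):
                rows = edf.index[np.flatnonzero(np.diff(t) <= 0) + 1].tolist()
                raise ContourValidationError(
                    f"non-monotone frame times in element {el_idx} of motif "
                    f"{indiv}/{motif_id} (table rows {rows})"
                )
            onset = float(t[0])
            rel = t - onset
            feats = edf[["ff_hz", "mf_hz", "fc", "harm"]].to_numpy(float)
            step = np.median(np.diff(rel)) if len(rel) > 1 else FRAME_STEP_MS
            if len(rel) > 1 and abs(step - FRAME_STEP_MS) > 1e-9:
                logger.info(
                    "resampling element %s of motif %s/%s from %.3g ms to %.3g ms step",
                    el_idx, indiv, motif_id, step, FRAME_STEP_MS,
                )
                new_t = np.arange(0.0, rel[-1] + 1e-9, FRAME_STEP_MS)
                feats = np.column_stack(
                    [np.interp(new_t, rel, feats[:, j]) for j in range(feats.shape[1])]
                )
                rel = new_t
            frames = []
            for k in range(len(rel)):
                try:
                    frames.append(
                        FeatureFrame(
                            t_ms=float(rel[k]),
                            ff_hz=float(feats[k, 0]),
                            mf_hz=float(feats[k, 1]),
                            fc=float(feats[k, 2]),
                            harm=float(feats[k, 3]),
                        )
                    )
                except ContourValidationError as exc:
                    row = edf.index[min(k, len(edf) - 1)]
                    raise ContourValidationError(
                        f"invalid feature value at table row {row} "
                        f"(element {el_idx}, motif {indiv}/{motif_id}): {exc}"
                    ) from exc
            elements.append(Element(frames=frames, onset_ms=onset))
        elements.sort(key=lambda e: e.onset_ms)
        motifs.append(
            Motif(
                individual_id=str(indiv),
                population=str(pops[0]),
                elements=elements,
                motif_id=str(motif_id),
            )
        )
    return motifs


def motifs_to_frame(motifs: Iterable[Motif]) -> pd.DataFrame:
    rows = []
    for m in motifs:
        for ei, el in enumerate(m.elements):
            for f in el.frames:
                rows.append(
                    (
                        m.individual_id,
                        m.population,
                        m.motif_id,
                        ei,
                        el.onset_ms + f.t_ms,
                        f.ff_hz,
                        f.mf_hz,
                        f.fc,
                        f.harm,
                    )
                )
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def write_contour_table(motifs: Iterable[Motif], path: str | Path, sep: str = ",") -> None:
    """Write motifs back to the canonical contour-table format."""
    motifs_to_frame(motifs).to_csv(path, sep=sep, index=False)


def segment_into_syllables(
    motif: Motif, gap_threshold_ms: float = DEFAULT_GAP_THRESHOLD_MS
) -> list[Syllable]:
    """Split a motif into syllables at inter-element gaps > ``gap_threshold_ms``.

    The comparison is strict: a gap exactly at the threshold keeps its
    flanking elements in the same syllable, and negative gaps (overlapping
    elements) never split.  Element order is preserved and the concatenation
    of the returned syllables reproduces the motif's element sequence.
    """
    syllables: list[Syllable] = []
    cur_elements = [motif.elements[0]]
    cur_gaps: list[float] = []
    for gap, nxt in zip(motif.gaps_ms, motif.elements[1:]):
        if gap > gap_threshold_ms:
            syllables.append(Syllable(elements=cur_elements, internal_gaps_ms=cur_gaps))
            cur_elements, cur_gaps = [nxt], []
        else:
            cur_elements.append(nxt)
            cur_gaps.append(gap)
    syllables.append(Syllable(elements=cur_elements, internal_gaps_ms=cur_gaps))
    return syllables


def signed_log_bin_edges(gaps_ms: np.ndarray) -> np.ndarray:
    """Bin edges on a signed, approximately logarithmic gap scale.

    0.5 ms bins between -1 and 1 ms (the spectrogram's measurement limit);
    power-of-two bins beyond, mirrored for negative gaps since elements can
    overlap in time.
    """
    gaps_ms = np.asarray(gaps_ms, float)
    edges = [-1.0, -0.5, 0.0, 0.5, 1.0]
    hi = 1.0
    while hi < max(gaps_ms.max(), 1.0):
        hi *= 2.0
        edges.append(hi)
    lo = -1.0
    while lo > min(gaps_ms.min(), -1.0):
        lo *= 2.0
        edges.insert(0, lo)
    return np.array(edges)


def gap_histogram(
    motifs: Sequence[Motif], edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of inter-element gaps over signed-log bins.

    Returns ``(counts, edges)``; the counts sum to the number of gaps.  With
    no gaps present an empty histogram is returned.
    """
    gaps = np.concatenate([np.asarray(m.gaps_ms, float) for m in motifs]) if motifs else np.array([])
    if gaps.size == 0:
        logger.warning("no inter-element gaps present; empty histogram")
        return np.array([], dtype=int), np.array([])
    if edges is None:
        edges = signed_log_bin_edges(gaps)
    # np.histogram's last bin is closed on the right, so every gap is counted
    counts, _ = np.histogram(gaps, bins=edges)
    return counts, edges
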