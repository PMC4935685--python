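"""Acoustic feature contours from spectrogram frames.

Four features are measured per spectrogram frame and tracked through each
element as a contour:

* fundamental frequency (FF), estimated by harmonic-comb scoring with a
  continuity penalty across frames;
* mean frequency, the intensity-weighted mean of the band frequencies;
* frequency change, the arctan-mapped slope of a local linear regression of
  the FF contour (0 = falling infinitely fast, 0.5 = flat, 1 = rising
  infinitely fast);
* harmonicity, the proportion of spectral intensity lying within +-FF/4 of
  integer multiples of the FF.

Spectrograms use a 256-point Hamming window at a 0.5 ms time step on audio
at 22.05 kHz, with a 420 Hz high-pass cut-off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("songculture")


class UndefinedFeatureError(ValueError):
    """Raised when a feature is undefined for a frame (e.g. zero intensity)."""


@dataclass(frozen=True)
class SpectroConfig:
    window_pts: int = 256
    step_ms: float = 0.5
    window: str = "hamming"
    highpass_hz: float = 420.0
    sample_rate_hz: float = 22050.0
    # frequency-change regression window (frames) and slope scaling: a slope
    # of +-50 Hz/ms maps to fc = 0.75 / 0.25
    fc_window_frames: int = 5
    fc_slope_scale_hz_per_ms: float = 50.0
    # FF tracker settings
    ff_min_hz: float = 300.0
    ff_max_hz: float = 8000.0
    ff_candidates: int = 240
    ff_continuity_penalty: float = 0.6
    ff_voicing_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.step_ms <= 0:
            raise ValueError("step_ms must be positive")
        if self.highpass_hz < 0:
            raise ValueError("highpass_hz must be non-negative")


@dataclass
class SpectrogramFrame:
    """Intensity per frequency band at one time point.

    ``band_width_hz`` is the analysis bandwidth of each band (the FFT bin
    width for a real spectrogram); when omitted it is taken from the band
    spacing.
    """

    freqs_hz: np.ndarray
    intens: np.ndarray
    t_ms: float = 0.0
    band_width_hz: float | None = None

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.intens = np.asarray(self.intens, float)
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("band frequencies must be strictly increasing")
        if np.any(self.intens < 0):
            raise ValueError("intensities must be non-negative")

    def band_widths(self) -> np.ndarray:
        if self.band_width_hz is not None:
            return np.full(len(self.freqs_hz), float(self.band_width_hz))
        f = self.freqs_hz
        if len(f) == 1:
            return np.array([f[0] / 2.0])
        width = np.empty_like(f)
        width[1:-1] = (f[2:] - f[:-2]) / 2.0
        width[0] = f[1] - f[0]
        width[-1] = f[-1] - f[-2]
        return width


def mean_frequency(frame: SpectrogramFrame) -> float:
    """Intensity-weighted mean of the band frequencies (Hz)."""
    total = frame.intens.sum()
    if total <= 0:
        raise UndefinedFeatureError("mean frequency undefined for an all-zero frame")
    return float(np.dot(frame.freqs_hz, frame.intens) / total)


def _harmonic_window_coverage(lo: np.ndarray, hi: np.ndarray, ff_hz: float) -> np.ndarray:
    """Length of [lo, hi] covered by the union of windows [k*FF - FF/4, k*FF + FF/4].

    Uses the cumulative covered length F(x) so that bands straddling window
    edges are apportioned by overlap fraction.  Windows are disjoint (width
    FF/2, spaced FF apart) and start at k = 1.
    """

    def covered_upto(x: np.ndarray) -> np.ndarray:
        x = np.maximum(x, 0.0)
        k = np.floor(x / ff_hz + 0.25).astype(int)  # windows fully below x
        full = np.maximum(k - 1, 0) * (ff_hz / 2.0)
        # partial overlap with window k (for k >= 1)
        wlo = k * ff_hz - ff_hz / 4.0
        partial = np.clip(x - wlo, 0.0, ff_hz / 2.0)
        return full + np.where(k >= 1, partial, 0.0)

    return covered_upto(hi) - covered_upto(lo)


def harmonicity(frame: SpectrogramFrame, ff_hz: float) -> float:
    """Proportion of spectral intensity within +-FF/4 of each harmonic of FF."""
    if ff_hz <= 0:
        raise ValueError("ff_hz must be positive")
    total = frame.intens.sum()
    if total <= 0:
        raise UndefinedFeatureError("harmonicity undefined for an all-zero frame")
    f = frame.freqs_hz
    width = frame.band_widths()
    lo, hi = f - width / 2.0, f + width / 2.0
    frac = _harmonic_window_coverage(lo, hi, ff_hz) / (hi - lo)
    return float(np.clip(np.dot(frac, frame.intens) / total, 0.0, 1.0))


def frequency_change(
    ff_hz: np.ndarray,
    t_ms: np.ndarray,
    slope_scale_hz_per_ms: float = SpectroConfig.fc_slope_scale_hz_per_ms,
) -> float:
    """Arctan-mapped slope of a linear regression of the FF track.

    Returns arctan(slope / scale) / pi + 0.5, so a flat track gives exactly
    0.5 and the value tends to 0 (1) as the slope tends to -inf (+inf).
    """
    ff_hz = np.asarray(ff_hz, float)
    t_ms = np.asarray(t_ms, float)
    valid = np.isfinite(ff_hz)
    if valid.sum() < 2:
        raise UndefinedFeatureError("frequency change needs at least two valid FF points")
    t, y = t_ms[valid], ff_hz[valid]
    tc = t - t.mean()
    slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
    return float(np.arctan(slope / slope_scale_hz_per_ms) / np.pi + 0.5)


def fc_contour(ff_hz: np.ndarray, cfg: SpectroConfig = SpectroConfig()) -> np.ndarray:
    """Per-frame frequency change over a centred moving regression window."""
    ff_hz = np.asarray(ff_hz, float)
    n = len(ff_hz)
    half = cfg.fc_window_frames // 2
    t = np.arange(n) * cfg.step_ms
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if np.isfinite(ff_hz[lo:hi]).sum() >= 2:
            out[i] = frequency_change(ff_hz[lo:hi], t[lo:hi], cfg.fc_slope_scale_hz_per_ms)
    return out


def estimate_ff(
    frames: list[SpectrogramFrame], cfg: SpectroConfig = SpectroConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Track the fundamental frequency across spectrogram frames.

    Each candidate FF on a log-spaced grid is scored by a harmonic comb:
    every band contributes its intensity weighted by 1/k for its nearest
    harmonic k and by a triangular taper over the +-FF/4 window (so energy
    exactly on a harmonic counts fully, energy at a window edge not at
    all), normalised by total intensity.  The taper breaks the octave ties
    a flat comb leaves between a candidate and its subharmonics.  The track
    is the Viterbi path under a penalty on log-frequency jumps between
    consecutive frames; frames whose best comb score falls below the
    voicing threshold are marked unvoiced (NaN).

    Returns ``(ff_hz, confidence)``, both of length ``len(frames)``.
    """
    if not frames:
        return np.array([]), np.array([])
    cand = np.geomspace(cfg.ff_min_hz, cfg.ff_max_hz, cfg.ff_candidates)
    scores = np.zeros((len(frames), len(cand)))
    for i, fr in enumerate(frames):
        total = fr.intens.sum()
        if total <= 0:
            continue
        f = fr.freqs_hz[:, None]
        k = np.maximum(np.round(f / cand[None, :]), 1.0)  # nearest harmonic index
        off = np.abs(f - k * cand[None, :])
        taper = np.clip(1.0 - off / (cand[None, :] / 4.0), 0.0, None)
        scores[i] = (fr.intens[:, None] * taper / k).sum(axis=0) / total
    voiced = scores.max(axis=1) >= cfg.ff_voicing_threshold

    # Viterbi over the candidate grid with a log-frequency jump penalty
    logc = np.log(cand)
    jump = np.abs(logc[:, None] - logc[None, :]) * cfg.ff_continuity_penalty
    cost = np.where(voiced[:, None], -scores, 0.0)
    acc = cost[0].copy()
    back = np.zeros((len(frames), len(cand)), dtype=int)
    for i in range(1, len(frames)):
        trans = acc[None, :] + jump  # (to, from)
        back[i] = np.argmin(trans, axis=1)
        acc = trans[np.arange(len(cand)), back[i]] + cost[i]
    path = np.zeros(len(frames), dtype=int)
    path[-1] = int(np.argmin(acc))
    for i in range(len(frames) - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    ff = cand[path].astype(float)
    conf = scores[np.arange(len(frames)), path]
    ff[~voiced] = np.nan
    conf[~voiced] = 0.0
    return ff, conf


def spectrogram_frames(
    wave: np.ndarray, sample_rate_hz: float, cfg: SpectroConfig = SpectroConfig()
) -> list[SpectrogramFrame]:
    """Short-time power spectrogram of a mono waveform as per-frame bands.

    Audio not at the configured rate is resampled first; bands below the
    high-pass cut-off are zeroed.
    """
    wave = np.asarray(wave, float)
    if sample_rate_hz != cfg.sample_rate_hz:
        n_new = int(round(len(wave) * cfg.sample_rate_hz / sample_rate_hz))
        wave = sps.resample(wave, n_new)
        logger.info("resampled audio from %g Hz to %g Hz", sample_rate_hz, cfg.sample_rate_hz)
    hop = max(1, int(round(cfg.step_ms * 1e-3 * cfg.sample_rate_hz)))
    freqs, times, sxx = sps.spectrogram(
        wave,
        fs=cfg.sample_rate_hz,
        window=cfg.window,
        nperseg=cfg.window_pts,
        noverlap=cfg.window_pts - hop,
        mode="magnitude",
    )
    keep = freqs >= cfg.highpass_hz
    if not np.any(keep):
        raise ValueError("high-pass cut-off removes every frequency band")
    return [
        SpectrogramFrame(freqs_hz=freqs[keep], intens=sxx[keep, i], t_ms=times[i] * 1e3)
        for i in range(sxx.shape[1])
    ]


def contour_from_audio(
    wave: np.ndarray, sample_rate_hz: float, cfg: SpectroConfig = SpectroConfig()
) -> dict[str, np.ndarray]:
    """Full feature contour (t_ms, ff_hz, mf_hz, fc, harm) from raw audio."""
    frames = spectrogram_frames(wave, sample_rate_hz, cfg)
    ff, conf = estimate_ff(frames, cfg)
    mf = np.array(
        [mean_frequency(fr) if fr.intens.sum() > 0 else np.nan for fr in frames]
    )
    harm = np.array(
        [
            harmonicity(fr, ff[i]) if np.isfinite(ff[i]) and fr.intens.sum() > 0 else np.nan
            for i, fr in enumerate(frames)
        ]
    )
    fc = fc_contour(ff, cfg)
    t = np.array([fr.t_ms for fr in frames])
    return {"t_ms": t, "ff_hz": ff, "mf_hz": mf, "fc": fc, "harm": harm, "confidence": conf}
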