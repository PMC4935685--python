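"""Synthetic contour datasets with known cluster, population and syntax truth.

Every analysis stage in this package is validated against data whose
generating process is known exactly.  The generator emits contour tables in
the canonical format: motifs of elements drawn from a library of ten
archetypal templates (flat, high flat, noisy flat, slide, lower slide,
noisy high, declining high, high, low, upsweep) spanning the two broad
fundamental-frequency classes of zebra finch song units (low ~0.8 kHz,
high ~3.5 kHz).  Element type sequences follow a planted first-order
Markov chain with START/END biases (slide-like units concentrated at motif
start, flat-like units at motif end); inter-element gaps are drawn from a
bimodal mixture (short within-syllable mode around 1 ms — occasionally
negative, since elements may overlap — and a long between-syllable mode
around 40 ms) so the 5 ms segmentation threshold recovers the planted
syllable structure.  Per-population multipliers on type usage plant
population divergence of known size.

The templates are test fixtures shaped like reported element-type
summaries, not claims of acoustic fidelity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .features import SpectroConfig
from .songio import FRAME_STEP_MS, Motif, motifs_from_frame

logger = logging.getLogger("songculture")

START = "START"
END = "END"


@dataclass(frozen=True)
class TypeTemplate:
    """Prototype contour for one element type."""

    name: str
    ff_start_hz: float
    ff_end_hz: float
    duration_ms: float
    mf_hz: float
    harm: float

    @property
    def high_ff(self) -> bool:
        return 0.5 * (self.ff_start_hz + self.ff_end_hz) > 2000.0


def default_templates() -> list[TypeTemplate]:
    """Ten archetypes covering the low-FF and high-FF element classes."""
    return [
        TypeTemplate("flat", 650, 600, 90, 3450, 0.89),
        TypeTemplate("high_flat", 1130, 1050, 44, 4050, 0.83),
        TypeTemplate("noisy_flat", 950, 840, 50, 4140, 0.62),
        TypeTemplate("slide", 1260, 560, 47, 4140, 0.68),
        TypeTemplate("lower_slide", 880, 520, 51, 3210, 0.75),
        TypeTemplate("noisy_high", 3310, 2600, 37, 4530, 0.74),
        TypeTemplate("declining_high", 4380, 2450, 25, 3790, 0.91),
        TypeTemplate("high", 4680, 4710, 27, 4910, 0.98),
        TypeTemplate("low", 1290, 1280, 24, 1580, 0.93),
        TypeTemplate("upsweep", 860, 1420, 20, 3480, 0.69),
    ]


@dataclass
class NoiseSpec:
    """Within-type spread per feature; smooth across frames by default."""

    ff_hz: float = 120.0
    mf_hz: float = 250.0
    fc: float = 0.03
    harm: float = 0.04
    duration_log_sd: float = 0.18
    smooth: bool = True  # correlated across frames (contour continuity)
    smooth_frames: float = 8.0


@dataclass
class GeneratorSpec:
    n_populations: int = 2
    individuals_per_pop: int = 12
    motifs_per_individual: int = 1
    type_templates: list[TypeTemplate] = field(default_factory=default_templates)
    pop_frequency_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    transition_matrix: pd.DataFrame | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    min_motif_len: int = 2
    max_motif_len: int = 10
    syllable_boundary_prob: float = 0.5
    within_gap_mean_ms: float = 1.0
    within_gap_sd_ms: float = 0.8
    between_gap_log_mean_ms: float = 40.0
    between_gap_log_sd: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        names = [t.name for t in self.type_templates]
        if len(set(names)) != len(names):
            raise ValueError("template names must be unique")
        for t in self.type_templates:
            if not (300 <= min(t.ff_start_hz, t.ff_end_hz) and max(t.ff_start_hz, t.ff_end_hz) <= 8000):
                raise ValueError(f"template {t.name}: FF outside the plausible 0.3-8 kHz range")
            if not 5 <= t.duration_ms <= 150:
                raise ValueError(f"template {t.name}: duration outside 5-150 ms")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(names)
        validate_transition_matrix(self.transition_matrix, names)


def default_transition_matrix(names: list[str], end_prob: float = 0.18) -> pd.DataFrame:
    """Near-uniform chain with motif-position biases.

    Slide-like types are favoured after START, flat-like types before END,
    high-frequency types are rare at either end, and immediate
    self-repetition is discouraged (elements are rarely repeated).
    """
    k = len(names)
    rows = [START] + names
    cols = names + [END]
    m = pd.DataFrame(1.0, index=rows, columns=cols)
    for n in names:
        if "slide" in n or n == "upsweep":
            m.loc[START, n] *= 3.0
            m.loc[n, END] = 0.3
        if n.startswith("flat") or n == "high_flat":
            m.loc[n, END] = 3.0
            m.loc[START, n] *= 0.3
        if "high" in n and n != "high_flat":
            m.loc[START, n] *= 0.3
            m.loc[n, END] = 0.3
    for n in names:
        m.loc[n, n] *= 0.4  # immediate repetition is uncommon
    m.loc[START, END] = 0.0
    # scale END column so the unconditional stopping probability is end_prob
    type_part = m.loc[:, names]
    m.loc[:, names] = type_part.div(type_part.sum(axis=1), axis=0) * (1.0 - end_prob)
    m[END] = np.where(m[END] > 0, m[END], 0.0)
    end_w = m.loc[names, END]
    m.loc[names, END] = end_w / end_w.mean() * end_prob
    m.loc[START, END] = 0.0
    m.loc[START, names] = m.loc[START, names] / m.loc[START, names].sum()
    m.loc[names] = m.loc[names].div(m.loc[names].sum(axis=1), axis=0)
    return m


def validate_transition_matrix(m: pd.DataFrame, names: list[str]) -> None:
    if list(m.index) != [START] + names or list(m.columns) != names + [END]:
        raise ValueError("transition matrix must have rows START+types and columns types+END")
    if (m.to_numpy() < 0).any():
        raise ValueError("transition probabilities must be non-negative")
    if not np.allclose(m.sum(axis=1).to_numpy(), 1.0):
        raise ValueError("transition matrix rows must sum to 1")
    if m.loc[START, names].sum() <= 0:
        raise ValueError("START must reach at least one type (absorbing START is infeasible)")


def within_motif_chain(m: pd.DataFrame) -> pd.DataFrame:
    """Type -> type transition probabilities, renormalised without END."""
    names = [c for c in m.columns if c != END]
    p = m.loc[names, names].copy()
    return p.div(p.sum(axis=1), axis=0)


def _stationary(P: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _is_irreducible(P: np.ndarray) -> bool:
    reach = (P > 0).astype(bool)
    closure = reach.copy()
    for _ in range(P.shape[0]):
        closure = closure | (closure @ reach)
    return bool(closure.all())


def analytic_redundancy(P: np.ndarray | pd.DataFrame) -> float:
    """Closed-form redundancy 1 - H1/H0 of an irreducible Markov chain.

    H0 is the entropy of the stationary distribution, H1 the expected
    entropy of the transition rows under it.
    """
    P = P.to_numpy(float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    if not _is_irreducible(P):
        raise ValueError("transition matrix must be irreducible")
    pi = _stationary(P)

    def entropy(p: np.ndarray) -> float:
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h0 = entropy(pi)
    if h0 == 0:
        raise ValueError("degenerate chain: stationary entropy is zero")
    h1 = float(sum(pi[i] * entropy(P[i]) for i in range(len(pi))))
    return 1.0 - h1 / h0


def chain_with_redundancy(k: int, target: float) -> np.ndarray:
    """Circulant k-state chain whose analytic redundancy equals ``target``.

    Rows are (p, (1-p)/(k-1), ...) rotated; the stationary distribution is
    uniform so redundancy depends on p alone and is solved by bisection.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target redundancy must lie in [0, 1)")

    def build(p: float) -> np.ndarray:
        row = np.full(k, (1.0 - p) / (k - 1))
        row[0] = p
        return np.stack([np.roll(row, i) for i in range(k)])

    def f(p: float) -> float:
        return analytic_redundancy(build(p)) - target

    p = brentq(f, 1.0 / k + 1e-9, 1.0 - 1e-12)
    return build(p)


def generate_markov_sequences(
    P: np.ndarray | pd.DataFrame,
    n_tokens: int,
    seq_len: int = 100,
    seed: int = 1,
) -> list[list[int]]:
    """Sequences of ~``n_tokens`` total states from a stationary chain."""
    P = P.to_numpy(float) if isinstance(P, pd.DataFrame) else np.asarray(P, float)
    rng = np.random.default_rng(seed)
    pi = _stationary(P)
    k = P.shape[0]
    seqs = []
    produced = 0
    while produced < n_tokens:
        n = min(seq_len, n_tokens - produced)
        s = [int(rng.choice(k, p=pi))]
        for _ in range(n - 1):
            s.append(int(rng.choice(k, p=P[s[-1]])))
        seqs.append(s)
        produced += n
    return seqs


def uniform_transition_matrix(names: list[str], end_prob: float = 0.18) -> pd.DataFrame:
    """Type sequence with no syntactical structure: iid uniform types."""
    rows = [START] + names
    cols = names + [END]
    m = pd.DataFrame(0.0, index=rows, columns=cols)
    m.loc[START, names] = 1.0 / len(names)
    m.loc[names, names] = (1.0 - end_prob) / len(names)
    m.loc[names, END] = end_prob
    return m


def null_spec(
    n_types: int = 3,
    individuals: int = 24,
    seed: int = 1,
    noise: NoiseSpec | None = None,
) -> GeneratorSpec:
    """The generator's null construction: no structure of any kind.

    One population; types drawn iid uniform (no syntax); and every type
    shares a single acoustic archetype, so the unit cloud is one
    structureless blob (within-type noise only) — the process the Gaussian
    reference matrices used for redundancy correction emulate.  Downstream,
    MRPP effect sizes and corrected redundancies on this data are expected
    to sit at zero.
    """
    base = TypeTemplate("blob", 1500, 1450, 45, 3800, 0.8)
    templates = [
        TypeTemplate(f"type{i}", base.ff_start_hz, base.ff_end_hz,
                     base.duration_ms, base.mf_hz, base.harm)
        for i in range(n_types)
    ]
    names = [t.name for t in templates]
    return GeneratorSpec(
        n_populations=1,
        individuals_per_pop=individuals,
        type_templates=templates,
        transition_matrix=uniform_transition_matrix(names),
        noise=noise or NoiseSpec(),
        seed=seed,
    )


@dataclass
class GroundTruth:
    """What the generator actually did, unit by unit."""

    units: pd.DataFrame  # unit_id, individual, population, motif_id, position, true_type
    transition_matrix: pd.DataFrame
    true_redundancy: float
    pop_effects: dict[str, dict[str, float]]
    syllable_sizes: dict[tuple[str, str], list[int]]  # (individual, motif_id) -> sizes


def _shifted_matrix(m: pd.DataFrame, shifts: dict[str, float]) -> pd.DataFrame:
    """Multiply type-usage columns and renormalise rows (END mass preserved)."""
    out = m.copy()
    names = [c for c in m.columns if c != END]
    for t, mult in shifts.items():
        if t not in names:
            raise ValueError(f"unknown type in pop_frequency_shifts: {t!r}")
        out[t] = out[t] * mult
    type_mass = 1.0 - out[END]
    s = out[names].sum(axis=1)
    out.loc[:, names] = out[names].mul(type_mass / s, axis=0)
    return out


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, spec: NoiseSpec) -> np.ndarray:
    if sd == 0 or n == 0:
        return np.zeros(n)
    if not spec.smooth:
        return rng.normal(0.0, sd, n)
    pad = int(3 * spec.smooth_frames)
    white = rng.normal(0.0, 1.0, n + 2 * pad)
    kernel = np.exp(-0.5 * (np.arange(-pad, pad + 1) / spec.smooth_frames) ** 2)
    kernel /= np.sqrt((kernel**2).sum())  # unit output variance
    smooth = np.convolve(white, kernel, mode="same")[pad : pad + n]
    return sd * smooth


def _element_rows(
    rng: np.random.Generator,
    template: TypeTemplate,
    onset_ms: float,
    noise: NoiseSpec,
    cfg: SpectroConfig = SpectroConfig(),
) -> tuple[pd.DataFrame, float]:
    dur = float(np.clip(template.duration_ms * np.exp(rng.normal(0, noise.duration_log_sd)),
                        5.0, 150.0))
    t = np.arange(0.0, dur - FRAME_STEP_MS / 2, FRAME_STEP_MS)
    frac = t / max(t[-1], FRAME_STEP_MS)
    ff_clean = template.ff_start_hz + (template.ff_end_hz - template.ff_start_hz) * frac
    # per-element frequency offset plus smooth within-element wobble
    ff = ff_clean + rng.normal(0, noise.ff_hz) + _smooth_noise(rng, len(t), noise.ff_hz / 2, noise)
    ff = np.clip(ff, 150.0, 7900.0)
    mf = (template.mf_hz + rng.normal(0, noise.mf_hz)
          + _smooth_noise(rng, len(t), noise.mf_hz / 2, noise))
    mf = np.clip(mf, 300.0, 10000.0)
    slope = (template.ff_end_hz - template.ff_start_hz) / dur  # Hz/ms
    fc_level = np.arctan(slope / cfg.fc_slope_scale_hz_per_ms) / np.pi + 0.5
    fc = np.clip(fc_level + _smooth_noise(rng, len(t), noise.fc, noise), 0.005, 0.995)
    harm = np.clip(template.harm + rng.normal(0, noise.harm)
                   + _smooth_noise(rng, len(t), noise.harm / 2, noise), 0.005, 0.995)
    df = pd.DataFrame({"t_ms": onset_ms + t, "ff_hz": ff, "mf_hz": mf, "fc": fc, "harm": harm})
    return df, dur


def generate_dataset(spec: GeneratorSpec) -> tuple[list[Motif], GroundTruth]:
    """Draw a full contour dataset plus its ground truth.

    Deterministic under ``spec.seed``.  Motif type sequences are sampled
    from the planted chain (START row to begin, full rows until END is
    drawn, truncated to ``max_motif_len`` and resampled below
    ``min_motif_len``); element contours are templates plus smooth noise;
    gaps come from the bimodal within/between-syllable mixture.
    """
    rng = np.random.default_rng(spec.seed)
    names = [t.name for t in spec.type_templates]
    templates = {t.name: t for t in spec.type_templates}
    base_m = spec.transition_matrix

    rows = []
    truth_rows = []
    syllable_sizes: dict[tuple[str, str], list[int]] = {}
    for p in range(spec.n_populations):
        pop = f"pop{p}"
        shifts = spec.pop_frequency_shifts.get(pop, {})
        m = _shifted_matrix(base_m, shifts) if shifts else base_m
        m_np = m.to_numpy()
        col_of = {c: i for i, c in enumerate(m.columns)}
        row_of = {r: i for i, r in enumerate(m.index)}
        for i in range(spec.individuals_per_pop):
            ind = f"{pop}_ind{i:03d}"
            for mo in range(spec.motifs_per_individual):
                motif_id = f"m{mo}"
                # type sequence from the planted chain
                while True:
                    seq = []
                    cur = START
                    while len(seq) < spec.max_motif_len:
                        probs = m_np[row_of[cur]]
                        nxt = m.columns[rng.choice(len(probs), p=probs / probs.sum())]
                        if nxt == END:
                            break
                        seq.append(nxt)
                        cur = nxt
                    if len(seq) >= spec.min_motif_len:
                        break
                # contours and gaps
                onset = 0.0
                sizes = [1]
                for pos, tname in enumerate(seq):
                    df, dur = _element_rows(rng, templates[tname], onset, spec.noise)
                    df.insert(0, "element_idx", pos)
                    df.insert(0, "motif_id", motif_id)
                    df.insert(0, "population", pop)
                    df.insert(0, "individual", ind)
                    rows.append(df)
                    truth_rows.append((f"{ind}/{motif_id}/e{pos}", ind, pop, motif_id, pos, tname))
                    if pos < len(seq) - 1:
                        if rng.random() < spec.syllable_boundary_prob:
                            gap = float(np.exp(rng.normal(np.log(spec.between_gap_log_mean_ms),
                                                          spec.between_gap_log_sd)))
                            sizes.append(1)
                        else:
                            gap = float(rng.normal(spec.within_gap_mean_ms, spec.within_gap_sd_ms))
                            sizes[-1] += 1
                        onset += dur + gap
                syllable_sizes[(ind, motif_id)] = sizes

    table = pd.concat(rows, ignore_index=True)
    motifs = motifs_from_frame(table)
    truth = GroundTruth(
        units=pd.DataFrame(
            truth_rows,
            columns=["unit_id", "individual", "population", "motif_id", "position", "true_type"],
        ),
        transition_matrix=base_m,
        true_redundancy=analytic_redundancy(within_motif_chain(base_m)),
        pop_effects=dict(spec.pop_frequency_shifts),
        syllable_sizes=syllable_sizes,
    )
    return motifs, truth
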