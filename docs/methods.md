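# Methods

This note documents the models and estimators implemented in
`songculture`, the assumptions behind the synthetic-data generator, the
numerical choices that matter, and known limitations.

## Data model and segmentation

The canonical input is a contour table: one row per spectrogram frame with
columns `individual, population, motif_id, element_idx, t_ms, ff_hz,
mf_hz, fc, harm`.  `t_ms` in the table is time within the motif, so
element onsets and inter-element gaps (including negative gaps, where
elements overlap in time) survive a round trip; in memory, frames are
stored unit-relative.  The frame grid is fixed at 0.5 ms; tables with
other steps are resampled by linear interpolation and the resampling is
logged.

Motifs are segmented into syllables purely by gap duration: a gap strictly
greater than the threshold (default 5 ms) separates syllables; gaps at or
below the threshold — including negative ones — keep their flanking
elements together.  The threshold sits in the trough of the strongly
bimodal inter-element gap distribution (short within-syllable gaps around
1 ms, long between-syllable gaps of tens of ms), which the
`gap_histogram` utility displays on a signed, approximately logarithmic
axis (0.5 ms bins between −1 and 1 ms, the spectrogram's measurement
limit; power-of-two bins beyond, mirrored for negative gaps).
Segmentation is idempotent, and raising the threshold can only merge
syllables, never split them.

Introductory notes are assumed to be excluded upstream by the data
supplier; no automatic detection is attempted.  Element boundaries
themselves are taken as given in the input — the criteria used to place
them (silent gaps, abrupt spectral changes) are perceptual and no
algorithmic boundary detector is claimed here.

## Acoustic features

Spectrograms use a 256-point Hamming window at a 0.5 ms step on 22.05 kHz
audio with a 420 Hz high-pass.  Per frame:

* **Mean frequency** — intensity-weighted mean of band frequencies.
* **Harmonicity** — fraction of spectral intensity within ±FF/4 of the
  harmonics k·FF, k ≥ 1.  Bands are treated as intervals of the analysis
  bandwidth and apportioned by overlap fraction where they straddle a
  window edge; windows are truncated at the spectrogram's upper limit.  A
  spectrally flat frame scores ≈ 0.5 (the windows cover half the axis).
* **Frequency change** — `fc = arctan(slope/c)/π + 0.5` where the slope
  comes from a linear regression of the FF track over a 5-frame (2.5 ms)
  centred window.  A flat contour gives exactly 0.5; fc → 0 (1) as the
  slope → −∞ (+∞).  The scale constant `c = 50 Hz/ms` maps a ±50 Hz/ms
  sweep to 0.25/0.75.  The constant is a package convention — the arctan
  scaling used by the original contour-measurement software is
  unpublished, so fc values are comparable only within this
  implementation.
* **Fundamental frequency** — harmonic-comb scoring on a log-spaced
  candidate grid (240 candidates, 0.3–8 kHz): each band contributes its
  intensity weighted by 1/k for its nearest harmonic k and by a triangular
  taper over the ±FF/4 window.  The taper breaks the octave ties a flat
  comb leaves between a candidate and its subharmonics.  The track is the
  Viterbi path under a penalty proportional to the log-frequency jump
  between consecutive frames (an automatic replacement for per-element
  manual jump-suppression tuning; agreement with manually tuned trackers
  is not claimed).  Frames whose best score falls below 0.1 are unvoiced.
  Dereverberation is not implemented; the synthetic fixtures contain no
  reverberation.

On synthetic stimuli with analytically known features the implementation
is accurate to well under 2% (FF, mean frequency) and 0.02 (fc,
harmonicity); the test suite asserts these bounds.

## DTW dissimilarity

Two units are compared over five features: the four contours, each divided
by its standard deviation pooled over all frames of all units in the
dataset (computed once and stored, so matrices are reproducible and
cross-population comparisons are not distorted by per-population scaling),
plus time-within-unit.  The frame distance is Euclidean over the
normalised features with the time term `q·(t_a − t_b)/L_max`, where
`L_max` is the duration of the longer unit and `q = 5`.  This `q·p`
normalisation makes duration differences scale-free: doubling both
durations (features unchanged) leaves the distance invariant.

The DTW distance is the **minimum over monotone warp paths** (steps
(1,0), (0,1), (1,1), unit weights) **of the mean frame distance along the
path**.  Averaging over the path rather than summing keeps short and long
units comparable; taking the optimum of the mean (not the mean of the
minimum-sum path) makes the quantity well defined.  It is computed exactly
by Dinkelbach's parametric reformulation: λ is optimal iff the minimum
over paths of Σ(cost − λ) is zero, and iterating λ ← (mean cost of the
current optimal path) converges in a finite number of O(nm) dynamic
programs (tolerance 10⁻¹², typically < 6 iterations).  The test suite
verifies equality with exhaustive path enumeration on all pairs up to 6
frames.  No warping band is imposed (units are short).

Syllable-level contours concatenate the frames of their elements with
real-time positions (gaps contribute to the time axis but carry no
frames), preserving syllable rhythm without inventing silent-frame
features.  Unvoiced frames are imputed by linear interpolation from
neighbouring voiced frames; units with no voiced frames are rejected.

## Cluster validation

PAM (BUILD + SWAP to a local optimum of the total distance to nearest
medoids) runs directly on the dissimilarity matrix.  The global silhouette
index (GSI) is the mean silhouette width over units, in [−1, 1].  Because
silhouette scores are optimistic even on structureless data, the scan
reports a **corrected GSI**: the GSI at each k minus the mean GSI of null
datasets — independent Gaussian clouds whose per-dimension SDs match a
3-dimensional NMDS embedding of the data — clustered and scored
identically.  "Corrected" is an interpretation choice: the null-subtraction
construction mirrors the Gaussian reference matrices used elsewhere in the
pipeline.  A clear peak in the corrected index indicates the number of
categories.

The independent route fits full-covariance Gaussian mixtures (EM,
k = 1..max_k, three initialisations) on an NMDS ordination, selects k by
BIC (ties toward smaller k), then merges component pairs while their
directly estimated misclassification probability — the larger of the mean
posterior mass of one component among points assigned to the other, in
either direction — exceeds 0.025.  NMDS minimises Kruskal stress-1 from 20
random starts (tolerance 10⁻⁷) and reports the squared correlation between
configuration distances and input dissimilarities as variance explained;
the embedding dimension is a config parameter, since no automatic
criterion for it is claimed.

## Syntax statistics

Transition biases use `(p_obs − p_exp)/max(p_obs, p_exp)` over all ordered
type pairs including START and END pseudo-states (one per motif).
Expected probabilities are products of token frequencies (independence
null), with structurally impossible transitions (into START, out of END)
assigned zero expectation.

Redundancy is `1 − H₁/H₀`: H₀ the entropy of type frequencies, H₁ the
conditional entropy of next type given current type, both Miller–Madow
corrected (plug-in entropy + (K−1)/(2N) with K the number of occupied
cells).  Only within-motif transitions enter the entropies; motif-boundary
transitions appear in the bias table but not in redundancy, since the
redundancy of interest is the predictability of unit-to-unit sequencing.

The syntactic clustering scan asks how much redundancy a partition of the
units *can* express at each k.  Starting from the PAM partition, a greedy
first-improvement search reassigns single units while redundancy
increases, under an acoustic anchor: a unit may only take the label of a
cluster whose medoid lies within 1.5× its nearest-medoid distance.
Without this constraint the search saturates redundancy at 1 on any
dataset; with it, only acoustically ambiguous units are free to serve the
syntax.  Five restarts are used, the first from the PAM labels and the
rest from gradedly perturbed copies (an increasing fraction of the movable
units randomly reassigned).  Because the search inflates redundancy even
on random data, three null datasets — Gaussian clouds whose per-dimension
SDs equal those of the principal coordinates (up to 50) of the empirical
matrix — are run through the identical procedure and their mean is
subtracted.  The 99% confidence interval is a percentile bootstrap over
individuals; each bootstrap replicate subtracts a randomly drawn null
replicate rather than the null mean, so the uncertainty of the null
correction itself is inside the interval.

**Limitation.**  The Gaussian null models a structureless unit cloud.  When
the acoustic space is strongly clustered but the syntax is random, the
null search is freer than the empirical one and the corrected redundancy
is biased downward (conservative).  The correction is well calibrated
exactly when the data process resembles the null — the regime the
structureless `null_spec` generator reproduces and the tests verify.

## Divergence statistics

MRPP: δ = Σ_g (n_g/N) · (mean within-group pairwise dissimilarity), with
group weights n_g/N (the standard choice).  Permutations shuffle whole
individuals between groups — all of an individual's units move together,
preserving the number of individuals per group — because units of one bird
are not exchangeable; unit-level permutation is available for sensitivity
analysis.  p is the add-one lower-tail permutation p-value and the effect
size is A = 1 − δ/m_δ (checked as an identity on every result).  Type
usage differences use Pearson χ² with analytic margins, a permutation
p-value from the same individual-level shuffles, and Cramér's V
= sqrt(χ²/(N·min(r−1, c−1))).  Under structureless data both permutation
p-values are uniform (verified by Kolmogorov–Smirnov over 200 seeded
replicates).  Population summaries use the geometric median (Weiszfeld
iteration, tolerance 10⁻⁹, with the Vardi–Zhang safeguard when an iterate
lands on a data point) of ordination coordinates, and neighbor joining
(Saitou–Nei, via scikit-bio) of the between-median distances; negative
branch-length estimates are clamped to zero with a warning.  Continent-
level analysis is the same code path with a coarser group label.

## Cultural-evolution simulator

Songs are fixed-length sequences (default 5) of syllable feature vectors
(default 5 dimensions) confined to a species range (default the unit
interval per dimension).  Each year a fraction of singers (default 0.5,
one generation-equivalent per two years) is replaced; every syllable of a
new singer is copied exactly from a uniformly chosen (tutor, position)
pair with probability 1 − e and improvised uniformly from the species
range with probability e.  An optional copy-noise SD exists but defaults
to 0.  A founder population (default 100) burns in for 50 years, splits
into two disjoint daughters (default 30), and both evolve independently;
at sampling intervals songs are ordinated by principal coordinates
analysis (subsampled to ≤ 200 songs) and divergence is the GSI with the
two populations as the two clusters, while within-population diversity is
the mean pairwise song distance.

The song distance is the minimum-mean DTW alignment of the two syllable
sequences under Euclidean syllable costs (the same parametric DP as the
contour DTW; for single-syllable songs it reduces to the Euclidean
distance).  Two reference quantities accompany it: the exact closed-form
expected distance between two uniform points on the species range
(erf-based, via the Laplace-transform identity for E[√S]) — the analytic
diversity ceiling for single-syllable songs, where no warping exists — and
a sampled ceiling, the mean pairwise song distance of independently drawn
uniform songs through the same metric.  For multi-syllable songs the
optimal alignment sits measurably below the per-syllable closed form
(≈ 0.83× for 5 syllables in 5 dimensions), so the sampled ceiling is the
correct saturation point for the simulator's diversity at e = 1, and the
closed form serves as the alignment-free anchor the tests check it
against.

Population sizes, song lengths and the turnover rate are package defaults
chosen to represent a small, rapidly mixing colony; the simulator's
conclusions are asserted in the tests as directional properties (final
divergence decreasing in e; diversity non-decreasing in e and saturating
at the ceiling) that are robust to these choices.  The test configuration
uses populations of 30, a 100-year horizon and 10 replicates per error
rate.

## Synthetic-data generator

The generator emits contour tables plus exact ground truth.  Ten element
archetypes (flat, high flat, noisy flat, slide, lower slide, noisy high,
declining high, high, low, upsweep) span the two broad FF classes of
zebra finch elements (low ~0.6–1.3 kHz, high ~2.5–4.7 kHz); they are
test fixtures shaped like reported element-type summaries, not claims of
acoustic fidelity.  Element contours are linear FF ramps plus smooth
(Gaussian-kernel-correlated, ~8-frame scale) within-element noise and
per-element offsets; durations jitter log-normally within 5–150 ms.
Default within-type spreads: 120 Hz (FF), 250 Hz (mean frequency), 0.03
(fc), 0.04 (harmonicity).

Type sequences are drawn from a planted first-order chain with START and
END pseudo-states: slide-like types favoured after START, flat-like types
before END, high types rare at either edge, immediate self-repetition
discouraged, and an unconditional stopping probability of 0.18 per step
(mean motif length ≈ 5.5, truncated to 2–10 elements).  Motif lengths are
therefore chain-driven rather than fixed: planting edge biases and a
length distribution simultaneously would make the two inconsistent.
Inter-element gaps come from a bimodal mixture — within-syllable gaps
normal around 1 ms (occasionally negative, as overlapping elements
permit), between-syllable gaps log-normal around 40 ms — so the 5 ms
threshold recovers the planted syllable grouping essentially always
(≥ 99% of motifs in the tests).  Per-population multipliers on type-usage
columns (renormalised per row) plant population divergence of known size;
`analytic_redundancy` supplies the closed-form redundancy of the planted
within-motif chain, and `chain_with_redundancy` constructs circulant
chains hitting any target redundancy exactly (bisection on the
self-transition weight).

`null_spec()` is the fully structureless construction used for
calibration: one population, uniform iid types, all types sharing a single
acoustic archetype.

**What passing tests do and do not show.**  The generator's contours are
smooth, unimodal-noise caricatures; real zebra finch elements have
harmonic structure, amplitude modulation and recording artefacts the
generator does not model.  Recovery of planted structure therefore
validates the statistical machinery (distances, cluster validation,
permutation calibration, redundancy correction), not the acoustic
front-end's behaviour on field recordings, and no attempt is made to
reproduce any real dataset's effect sizes.

## Numerical conventions

* All permutation p-values are add-one: (count + 1)/(n_perm + 1).
* All stochastic procedures take explicit seeds; generation is
  deterministic under seed.
* GSI aggregates silhouette widths per unit (global mean), not per
  cluster.
* Mixture fits fall back to a stronger covariance ridge (10⁻³) if EM
  fails at the default regularisation.
* PAM SWAP uses first-improvement scans; the objective never increases.
* Degenerate inputs fail loudly: empty units, all-unvoiced units,
  single-type redundancy (H₀ = 0), k outside [2, n−1], groups with fewer
  than two units (excluded with a warning).
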