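# songculture

Analysis toolkit for the phonology, syntax and cultural evolution of zebra
finch (*Taeniopygia guttata*) song.

Zebra finch song is learned: each male assembles a stereotyped **motif**
from smaller sound units — **elements** (single vocal gestures) grouped
into **syllables** wherever inter-element gaps are at most ~5 ms.  Because
song is culturally transmitted with substantial learning error, two
questions arise for anyone comparing colonies: do song units fall into
species-wide categories, and have isolated populations developed their own
vocal traditions?  `songculture` implements a complete, testable pipeline
for both questions, operating on acoustic *feature contours* (per-frame
fundamental frequency, mean frequency, frequency change and harmonicity)
rather than raw audio, together with an agent-based simulator that shows
why high learning-error rates prevent populations from diverging.

## What it computes

* **Unit dissimilarity** — dynamic time warping over the four feature
  contours plus time.  Features are normalised by their pooled standard
  deviations; the time feature of a frame pair is weighted by `q·p`, with
  `p` the inverse duration of the longer unit and `q = 5`, so duration
  differences count logarithmically (2 ms vs 4 ms units are exactly as far
  apart as 20 ms vs 40 ms units).  The distance is the minimum over
  monotone warp paths of the mean frame distance along the path
  (`sqrt(Σ_f ((a_f−b_f)/σ_f)² + (q·Δt/L_max)²)` per frame pair), solved
  exactly by parametric dynamic programming.
* **Category discovery** — k-medoids (PAM) on the dissimilarity matrix,
  validated by the *corrected global silhouette index*
  (GSI, mean silhouette width minus its value on matched Gaussian null
  data); independently, BIC-selected Gaussian mixtures on a non-metric MDS
  ordination with misclassification-based component merging.  Agreement is
  measured by the adjusted Rand index.
* **Syntax** — transition biases `(p_obs − p_exp)/max(p_obs, p_exp)`
  including START/END pseudo-states; a types-per-motif permutation test;
  and first-order Markov **redundancy** `R = 1 − H₁/H₀` (0 = units placed
  at random, 1 = deterministic syntax), Miller–Madow corrected and
  null-corrected for the search bias of syntactic clustering.
* **Population divergence** — the multiresponse permutation procedure
  (MRPP: effect size `A = 1 − δ/m_δ`, permuting whole individuals),
  permutation χ² with Cramér's V for type-usage differences, and
  neighbor-joining dendrograms of population spatial medians.
* **Cultural evolution** — two daughter populations founded from a common
  stock, each syllable of each new singer copied from a tutor with
  probability `1 − e` or improvised uniformly from the species range with
  probability `e`; divergence tracked as the between-population GSI in
  principal-coordinates song space.
* **Synthetic data** — a generator emitting contour tables with planted
  cluster, syntax and population structure (and the matching ground
  truth), so every stage above is testable without recordings.

## Worked example

Generate a two-population dataset whose elements come from two broad
fundamental-frequency classes (low ~0.8 kHz, high ~3.5 kHz), with the high
class used three times more heavily in one population, then run the core
pipeline:

```python
import numpy as np
import songculture as sc
from songculture.synthgen import TypeTemplate, GeneratorSpec, default_transition_matrix

templates = [TypeTemplate("low_flat", 800, 780, 60, 3400, 0.88),
             TypeTemplate("high", 3500, 3520, 40, 4600, 0.95)]
spec = GeneratorSpec(
    n_populations=2, individuals_per_pop=10, type_templates=templates,
    transition_matrix=default_transition_matrix([t.name for t in templates]),
    pop_frequency_shifts={"pop1": {"high": 3.0}}, seed=1,
)
motifs, truth = sc.generate_dataset(spec)
units = sc.motifs_to_units(motifs, level="element")
D = sc.pairwise_matrix(units)

scan = sc.gsi_scan(D, range(2, 7), null_reps=5, seed=1)
print(scan.round(3).to_string(index=False))

k_hat = int(scan.loc[scan["corrected_gsi"].idxmax(), "k"])
part = sc.pam_cluster(D, k_hat, compute_gsi=True)
res = sc.mrpp(D, D.populations, n_perm=1000, seed=1, individuals=D.individuals)
print(f"MRPP: delta={res.delta:.4f}, m_delta={res.m_delta:.4f}, A={res.A:.4f}, p={res.p:.4f}")
```

Output:

```
 k   gsi  null_gsi  corrected_gsi
 2 0.570     0.353          0.218
 3 0.399     0.302          0.097
 4 0.237     0.282         -0.045
 5 0.188     0.260         -0.072
 6 0.171     0.262         -0.091
MRPP: delta=2.3585, m_delta=2.3741, A=0.0066, p=0.0859
```

The corrected GSI peaks at k = 2 — the scan recovers the two planted
frequency classes (the PAM labels at k = 2 match the planted types with
adjusted Rand index 1.0) — while raw GSI alone would keep rising with k.
The MRPP effect size is small (A = 0.0066): the populations share the same
two categories and differ only in how often they use them, so within-
population dissimilarity (δ) is barely below its permutation expectation
(m_δ).  This is the typical signature of weak cultural divergence.

A command-line interface covers the same steps for file-based workflows:

```
songculture synth --seed 2 --individuals 8 -o data/
songculture dtw data/contours.csv --level element -o dist.csv
songculture cluster dist.csv --kmax 10 -o labels.csv
songculture diverge dist.csv meta.csv --groups population -o report/
songculture simulate --seed 1 -o trajectory.csv
```

## Documentation

`docs/methods.md` describes the models and estimators, the synthetic-data
generator's assumptions, all numerical choices, and known limitations.
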