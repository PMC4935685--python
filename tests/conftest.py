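"""Shared fixtures: small synthetic datasets pushed through the DTW stage."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import songculture as sc
from songculture.synthgen import GeneratorSpec, TypeTemplate, default_transition_matrix

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def two_class_templates() -> list[TypeTemplate]:
    """Two templates, one per broad FF class, far apart relative to noise."""
    return [
        TypeTemplate("low_flat", 800, 780, 60, 3400, 0.88),
        TypeTemplate("high", 3500, 3520, 40, 4600, 0.95),
    ]


def seven_class_templates() -> list[TypeTemplate]:
    """Seven syllable-like archetypes spread across the feature space."""
    return [
        TypeTemplate("t1", 600, 580, 80, 2800, 0.90),
        TypeTemplate("t2", 1400, 1350, 55, 5200, 0.60),
        TypeTemplate("t3", 2300, 1500, 40, 3600, 0.75),
        TypeTemplate("t4", 900, 1800, 25, 4400, 0.95),
        TypeTemplate("t5", 3600, 3550, 35, 6000, 0.85),
        TypeTemplate("t6", 5200, 3800, 20, 4000, 0.98),
        TypeTemplate("t7", 700, 690, 15, 1500, 0.55),
    ]


def spec_for(templates, seed: int, individuals: int = 12, **kwargs) -> GeneratorSpec:
    return GeneratorSpec(
        n_populations=1,
        individuals_per_pop=individuals,
        type_templates=templates,
        transition_matrix=kwargs.pop(
            "transition_matrix", default_transition_matrix([t.name for t in templates])
        ),
        seed=seed,
        **kwargs,
    )


def dataset_through_dtw(spec: GeneratorSpec):
    """Generate, extract element units and compute the DTW matrix.

    Returns (motifs, truth, units, D, motif_units, individuals) where
    ``motif_units`` indexes each motif's units into D.
    """
    motifs, truth = sc.generate_dataset(spec)
    units = sc.motifs_to_units(motifs)
    D = sc.pairwise_matrix(units)
    idx = {u: i for i, u in enumerate(D.unit_ids)}
    motif_units, individuals = [], []
    for m in motifs:
        motif_units.append(
            [idx[f"{m.individual_id}/{m.motif_id}/e{i}"] for i in range(m.n_elements)]
        )
        individuals.append(m.individual_id)
    return motifs, truth, units, D, motif_units, individuals


def true_labels(truth, D) -> np.ndarray:
    tmap = dict(zip(truth.units.unit_id, truth.units.true_type))
    return np.unique([tmap[u] for u in D.unit_ids], return_inverse=True)[1]


@pytest.fixture(scope="session")
def small_two_class():
    """Two-FF-class dataset with its DTW matrix (session-wide)."""
    return dataset_through_dtw(spec_for(two_class_templates(), seed=11, individuals=10))


@pytest.fixture(scope="session")
def default_dataset():
    """Default ten-template dataset, two populations, through DTW."""
    return dataset_through_dtw(
        GeneratorSpec(n_populations=2, individuals_per_pop=6, seed=3)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
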