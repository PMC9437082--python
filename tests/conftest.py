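"""Shared fixtures: small synthetic genome sets with known species structure."""

from __future__ import annotations

import pandas as pd
import pytest

from magcat import kmer_distance as kd
from magcat import synthetic_data as sd


def make_species_set(
    n_species: int = 3,
    n_genomes: int = 4,
    target_ani: float = 97.0,
    root_length: int = 30_000,
    seed: int = 100,
):
    """Genomes from independent species roots plus quality table and truth labels."""
    genomes = {}
    truth_species = {}
    rows = []
    for si in range(n_species):
        spec = sd.SpeciesSpec(
            species_id=f"sp{si + 1}",
            root_length=root_length,
            n_genomes=n_genomes,
            target_ani=target_ani,
            seed=seed + si,
        )
        gs, _ = sd.evolve_conspecific_genomes(spec)
        for gi, g in enumerate(gs):
            genomes[g.id] = g
            truth_species[g.id] = spec.species_id
            rows.append(
                {
                    "genome_id": g.id,
                    "completeness": 99.0 - gi,  # distinct scores, deterministic rep choice
                    "contamination": 0.5,
                    "n50": 50_000,
                    "chimera_pass": True,
                }
            )
    quality = pd.DataFrame(rows).set_index("genome_id")
    return genomes, quality, truth_species


def cached_distance_fn(genomes: dict, k: int = 21, s: int = 1000, seed: int = 42):
    cache: dict[tuple[str, str], kd.PairwiseDistance] = {}

    def fn(a: str, b: str) -> kd.PairwiseDistance:
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = kd.ani_af_estimate(genomes[key[0]], genomes[key[1]], k=k, s=s, seed=seed)
        return cache[key]

    return fn


@pytest.fixture(scope="session")
def three_species():
    genomes, quality, truth = make_species_set()
    return genomes, quality, truth, cached_distance_fn(genomes)
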