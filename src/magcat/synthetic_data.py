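"""Seeded generators for every input the catalog pipeline consumes.

Each generator is a pure function of its seed and returns its ground truth
alongside the payload, so downstream estimators can be tested by parameter
recovery:

* conspecific genome sets evolved from a random root at a controlled target
  ANI (iid per-site substitution, uniform over the three alternative bases);
* degraded bins with known completeness (contigs dropped) and contamination
  (foreign contigs appended);
* read pileups with a known polymorphic-site fraction;
* gene presence/absence matrices with core/accessory structure and planted
  group-differential genes;
* random phylogenies with exponential branch lengths;
* random quality tables and random/mutated protein sets.

The substitution model is deliberately minimal (no indels, no rate
heterogeneity): positional identity of the full sequences is then an exact
alignment, which is what makes the ANI generators oracle-testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genome_qc import GenomeRecord, GenomeSource

__all__ = [
    "SpeciesSpec",
    "PileupSpec",
    "evolve_conspecific_genomes",
    "degrade_genome",
    "simulate_pileup",
    "simulate_presence_matrix",
    "random_tree",
    "simulate_quality_table",
    "random_protein",
    "mutate_protein",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = "ACDEFGHIKLMNPQRSTVWY"


def _bases_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def substitution_rate_for_ani(target_ani: float) -> float:
    """Per-genome substitution rate so expected *pairwise* identity hits target.

    Two genomes independently mutated from the root at rate r disagree at a
    site with probability 2r(1-r) + (2/3)r^2, so pairwise identity is
    1 - 2r + (4/3)r^2; solve the quadratic for r.
    """
    t = target_ani / 100.0
    disc = 4.0 - (16.0 / 3.0) * (1.0 - t)
    return (2.0 - math.sqrt(disc)) * 3.0 / 8.0


@dataclass
class SpeciesSpec:
    """Stated world for one synthetic species."""

    species_id: str = "sp1"
    root_length: int = 100_000
    n_genomes: int = 4
    target_ani: float = 97.0  # pairwise, percent
    contig_log_median: float = 50_000.0  # log-normal contig length median (bp)
    contig_log_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 90.0 < self.target_ani <= 100.0:
            raise ValueError("target ANI must be in (90, 100] (within-species generator)")


def _split_contigs(codes: np.ndarray, rng: np.random.Generator, spec: SpeciesSpec, gid: str):
    lengths: list[int] = []
    remaining = codes.size
    while remaining > 0:
        l = int(rng.lognormal(math.log(spec.contig_log_median), spec.contig_log_sigma))
        l = max(1000, min(l, remaining))
        if remaining - l < 1000:
            l = remaining
        lengths.append(l)
        remaining -= l
    contigs = []
    start = 0
    for i, l in enumerate(lengths):
        contigs.append((f"{gid}_c{i + 1}", _bases_to_str(codes[start : start + l])))
        start += l
    return contigs


def evolve_conspecific_genomes(spec: SpeciesSpec) -> tuple[list[GenomeRecord], pd.DataFrame]:
    """Evolve ``n_genomes`` conspecific genomes from one random root.

    Returns the genomes plus a truth table of realized pairwise identities
    (exact positional comparison — the model has no indels) and the species
    label.
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.integers(0, 4, size=spec.root_length, dtype=np.uint8)
    r = substitution_rate_for_ani(spec.target_ani)
    genome_codes: list[np.ndarray] = []
    genomes: list[GenomeRecord] = []
    for i in range(spec.n_genomes):
        codes = root.copy()
        mask = rng.random(spec.root_length) < r
        # uniform over the three alternative bases
        shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
        codes[mask] = (codes[mask] + shift) % 4
        gid = f"{spec.species_id}_g{i + 1}"
        genome_codes.append(codes)
        genomes.append(
            GenomeRecord(
                id=gid,
                contigs=_split_contigs(codes, rng, spec, gid),
                source=GenomeSource.MAG,
            )
        )
    rows = []
    for i in range(spec.n_genomes):
        for j in range(i + 1, spec.n_genomes):
            ident = float((genome_codes[i] == genome_codes[j]).mean())
            rows.append(
                {
                    "id_a": genomes[i].id,
                    "id_b": genomes[j].id,
                    "true_identity_pct": 100.0 * ident,
                    "species": spec.species_id,
                }
            )
    return genomes, pd.DataFrame(rows)


def degrade_genome(
    genome: GenomeRecord,
    completeness: float,
    contamination: float = 0.0,
    foreign_source: GenomeRecord | None = None,
    seed: int = 0,
) -> tuple[GenomeRecord, dict]:
    """Imitate an incomplete/contaminated bin; returns (bin, truth).

    A random prefix of shuffled contigs is retained until the kept base
    fraction reaches ``completeness`` (so the realized value is within one
    contig of the target); foreign contigs are appended the same way to reach
    the ``contamination`` base fraction.
    """
    if not 0 < completeness <= 1:
        raise ValueError("completeness must be in (0, 1]")
    if contamination < 0:
        raise ValueError("contamination must be >= 0")
    if contamination > 0 and foreign_source is None:
        raise ValueError("contamination requested without a foreign_source genome")
    rng = np.random.default_rng(seed)
    total = genome.length
    order = rng.permutation(len(genome.contigs))
    kept: list[tuple[str, str]] = []
    kept_bases = 0
    for idx in order:
        if kept_bases / total >= completeness:
            break
        cid, seq = genome.contigs[idx]
        kept.append((cid, seq))
        kept_bases += len(seq)
    kept.sort(key=lambda c: c[0])
    foreign_bases = 0
    if contamination > 0:
        assert foreign_source is not None
        f_order = rng.permutation(len(foreign_source.contigs))
        for idx in f_order:
            if foreign_bases / (kept_bases + foreign_bases) >= contamination:
                break
            cid, seq = foreign_source.contigs[idx]
            kept.append((f"foreign_{cid}", seq))
            foreign_bases += len(seq)
    degraded = GenomeRecord(
        id=f"{genome.id}_bin", contigs=kept, source=genome.source, sample_id=genome.sample_id
    )
    truth = {
        "true_completeness": kept_bases / total,
        "true_contamination": foreign_bases / (kept_bases + foreign_bases),
        "source_genome": genome.id,
    }
    return degraded, truth


@dataclass
class PileupSpec:
    """Stated world for a synthetic read pileup."""

    n_sites: int = 10_000
    depth_mean: float = 100.0
    depth_overdispersion: float = 0.0  # 0 => Poisson; else NB with this 1/size
    polymorphic_fraction: float = 0.01
    maf_range: tuple[float, float] = (0.30, 0.50)
    qual_mean: float = 37.0
    qual_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.polymorphic_fraction <= 0.5:
            raise ValueError("polymorphic fraction must be in [0, 0.5]")
        if self.depth_mean < 0:
            raise ValueError("depth mean must be >= 0")


def simulate_pileup(spec: PileupSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate per-position base counts in the native TSV pileup dialect.

    Polymorphic sites carry a minor allele at a frequency drawn from
    ``maf_range``; every read additionally errs to a uniform random other
    base at the quality-implied rate 10^(-q/10).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sites
    if spec.depth_overdispersion > 0:
        size = 1.0 / spec.depth_overdispersion
        depth = rng.negative_binomial(size, size / (size + spec.depth_mean), n)
    else:
        depth = rng.poisson(spec.depth_mean, n)
    ref = rng.integers(0, 4, n)
    poly = rng.random(n) < spec.polymorphic_fraction
    maf = rng.uniform(*spec.maf_range, n)
    qual = np.clip(rng.normal(spec.qual_mean, spec.qual_sd, n), 2.0, None)
    err = 10.0 ** (-qual / 10.0)
    base_names = "ACGT"
    rows = []
    for i in range(n):
        counts = np.zeros(4, dtype=int)
        d = int(depth[i])
        minor_b = (ref[i] + 1 + rng.integers(0, 3)) % 4
        n_minor = rng.binomial(d, maf[i]) if poly[i] else 0
        counts[minor_b] += n_minor
        counts[ref[i]] += d - n_minor
        n_err = rng.binomial(d, err[i])
        for _ in range(n_err):
            src = minor_b if rng.random() < (n_minor / d if d else 0) else ref[i]
            if counts[src] == 0:
                continue
            counts[src] -= 1
            counts[(src + 1 + rng.integers(0, 3)) % 4] += 1
        rows.append(
            {
                "contig_id": "contig_1",
                "pos": i + 1,
                "ref": base_names[ref[i]],
                "count_A": counts[0],
                "count_C": counts[1],
                "count_G": counts[2],
                "count_T": counts[3],
                "mean_qual": round(float(qual[i]), 2),
            }
        )
    truth = {
        "polymorphic_fraction": spec.polymorphic_fraction,
        "polymorphic_sites": np.flatnonzero(poly) + 1,
    }
    return pd.DataFrame(rows), truth


def simulate_presence_matrix(
    n_genomes: int = 100,
    n_core: int = 500,
    n_accessory: int = 1500,
    prevalence_range: tuple[float, float] = (0.05, 0.95),
    group_effect: Sequence[tuple[float, float]] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Binary genomes x genes matrix with core/accessory structure.

    Genomes are split into two equal groups ``A``/``B``.  ``group_effect``
    lists per-gene (prevalence_in_A, prevalence_in_B) pairs for planted
    differential genes.  Core genes have prevalence 1.  All-zero gene
    columns (possible at low prevalence) are dropped.  Returns (matrix,
    group labels, truth).
    """
    rng = np.random.default_rng(seed)
    genomes = [f"g{i + 1:04d}" for i in range(n_genomes)]
    groups = pd.Series(
        ["A"] * (n_genomes // 2) + ["B"] * (n_genomes - n_genomes // 2), index=genomes
    )
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if n_core:
        blocks.append(np.ones((n_genomes, n_core), dtype=np.int8))
        names += [f"core{i + 1:05d}" for i in range(n_core)]
    if n_accessory:
        prev = rng.uniform(*prevalence_range, n_accessory)
        blocks.append((rng.random((n_genomes, n_accessory)) < prev).astype(np.int8))
        names += [f"acc{i + 1:05d}" for i in range(n_accessory)]
    planted: list[str] = []
    if group_effect:
        in_a = (groups == "A").to_numpy()
        eff = np.empty((n_genomes, len(group_effect)), dtype=np.int8)
        for j, (pa, pb) in enumerate(group_effect):
            p = np.where(in_a, pa, pb)
            eff[:, j] = rng.random(n_genomes) < p
        blocks.append(eff)
        planted = [f"diff{j + 1:04d}" for j in range(len(group_effect))]
        names += planted
    pm = pd.DataFrame(np.hstack(blocks), index=genomes, columns=names)
    pm = pm.loc[:, pm.sum(axis=0) > 0]
    truth = {"planted_differential": [g for g in planted if g in pm.columns]}
    return pm, groups, truth


def random_tree(n_leaves: int, seed: int = 0, branch_scale: float = 0.1) -> TreeNode:
    """Random binary topology with exponential branch lengths (root included)."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.exponential(branch_scale))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(branch_scale))
        nodes.append(parent)
    return nodes[0]


def simulate_quality_table(
    n: int = 1000,
    frac_near_complete: float = 0.784,
    frac_high_of_near: float = 0.182,
    frac_fail: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random quality table whose admitted rows hit the configured tier mix.

    Defaults mirror a realistic large MAG catalog: ~78% of admitted genomes
    near-complete and ~18% of those meeting the rRNA/tRNA bar for the high
    tier.  ``frac_fail`` adds rows that miss the admission filter.  Tier
    composition is stratified (exact counts, shuffled order) so the
    configured fractions hold by construction, not just in expectation.
    """
    rng = np.random.default_rng(seed)
    n_fail = round(n * frac_fail)
    n_near = round((n - n_fail) * frac_near_complete)
    n_high = round(n_near * frac_high_of_near)
    tiers = (
        ["fail"] * n_fail
        + ["high"] * n_high
        + ["near_complete"] * (n_near - n_high)
        + ["medium"] * (n - n_fail - n_near)
    )
    rng.shuffle(tiers)
    rows = []
    for i, planned in enumerate(tiers):
        gid = f"Q{i + 1:05d}"
        if planned == "fail":
            comp = rng.uniform(20, 50)
            cont = rng.uniform(0, 4)
        elif planned in ("near_complete", "high"):
            comp = rng.uniform(90.5, 100)
            cont = rng.uniform(0, 4.5)
        else:
            cont = rng.uniform(0, 4.5)
            comp = rng.uniform(max(52.0, 50.0 + 5.0 * cont + 0.5), 90.0)
        high = planned == "high"
        tier = "near_complete" if planned == "high" else planned
        rows.append(
            {
                "genome_id": gid,
                "completeness": round(comp, 2),
                "contamination": round(cont, 2),
                "chimera_pass": True,
                "n50": int(rng.lognormal(math.log(50_000), 1.0)) + 1,
                "rrna_5s": high or rng.random() < 0.3,
                "rrna_16s": high or rng.random() < 0.3,
                "rrna_23s": high,
                "n_trna_types": int(rng.integers(18, 21)) if high else int(rng.integers(0, 18)),
                "true_tier": "high" if high else tier,
            }
        )
    return pd.DataFrame(rows).set_index("genome_id")


def random_protein(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_AA), size=length))


def mutate_protein(seq: str, n_substitutions: int, seed: int = 0) -> str:
    """Substitute exactly n residues (always to a different amino acid)."""
    rng = np.random.default_rng(seed)
    if n_substitutions > len(seq):
        raise ValueError("more substitutions than residues")
    positions = rng.choice(len(seq), size=n_substitutions, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in _AA if a != out[p]]
        out[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)
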