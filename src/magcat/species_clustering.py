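"""Greedy dereplication of genomes into species-level genome bins (SGBs).

Genomes are processed in descending representative score
(completeness - 5*contamination + 0.5*log10(N50)); each genome joins the best
(highest-ANI) existing representative satisfying ANI >= 95% and alignment
fraction >= 0.30, else founds a new cluster.  A primary pre-grouping at Mash
distance <= 0.10 limits the comparisons actually evaluated.  For very large
collections, random chunks are dereplicated independently and the chunk
representatives re-clustered; members inherit the final cluster of their
chunk representative.

SGBs are labeled cultured (cSGB: at least one MAG and one isolate),
uncultured (uSGB: MAGs only) or non-early-life (isolates only); the
uncultured score of an SGB is the fraction of its members that are MAGs.
Whenever a cluster contains isolate genomes, the best-scoring isolate is
promoted to representative (isolates are prioritized over MAGs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_qc import representative_score
from .kmer_distance import PairwiseDistance

__all__ = [
    "SGBCluster",
    "CatalogPartition",
    "score_order",
    "greedy_dereplicate",
    "chunked_dereplicate",
    "label_sgbs",
    "rarefy_clusters",
    "catalog_summary",
]

DistanceFn = Callable[[str, str], PairwiseDistance]


@dataclass
class SGBCluster:
    sgb_id: str
    members: list[str]
    representative: str
    label: str | None = None  # cSGB / uSGB / non_early_life
    uncultured_score: float | None = None

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError(f"representative {self.representative!r} not a member of {self.sgb_id}")


@dataclass
class CatalogPartition:
    clusters: list[SGBCluster]
    ani_threshold: float = 95.0
    af_threshold: float = 0.30
    primary_distance: float = 0.10
    seed: int | None = None

    @property
    def membership(self) -> dict[str, str]:
        """genome id -> sgb id."""
        out: dict[str, str] = {}
        for c in self.clusters:
            for m in c.members:
                if m in out:
                    raise ValueError(f"genome {m!r} in two clusters")
                out[m] = c.sgb_id
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for m in c.members:
                rows.append(
                    {
                        "genome_id": m,
                        "sgb_id": c.sgb_id,
                        "is_representative": m == c.representative,
                        "label": c.label,
                        "uncultured_score": c.uncultured_score,
                    }
                )
        return pd.DataFrame(rows)


def _score_key(quality: pd.DataFrame, gid: str) -> tuple:
    row = quality.loc[gid]
    score = representative_score(row["completeness"], row["contamination"], row["n50"])
    # descending score, then completeness, then N50; lexicographic id last
    return (-score, -row["completeness"], -row["n50"], gid)


def score_order(genome_ids: Iterable[str], quality: pd.DataFrame) -> list[str]:
    """Genome ids sorted by descending representative score (documented tie-breaks)."""
    ids = list(genome_ids)
    missing = [g for g in ids if g not in quality.index]
    if missing:
        raise ValueError(f"missing quality rows for {missing}")
    return sorted(ids, key=lambda g: _score_key(quality, g))


def greedy_dereplicate(
    genome_ids: Sequence[str],
    quality: pd.DataFrame,
    distances_fn: DistanceFn,
    ani_t: float = 95.0,
    af_t: float = 0.30,
    primary_distance: float = 0.10,
    isolate_flags: Mapping[str, bool] | None = None,
    exhaustive: bool = False,
    assign: str = "best",
) -> CatalogPartition:
    """Single-pass greedy dereplication at ANI >= ani_t and AF >= af_t.

    ``quality`` is indexed by genome id with columns completeness,
    contamination, n50.  ``distances_fn(id_a, id_b)`` returns a
    :class:`~magcat.kmer_distance.PairwiseDistance`.  ``exhaustive=True``
    disables the primary pre-grouping (every representative is evaluated);
    ``assign="first"`` joins the first qualifying representative in founding
    order instead of the best-ANI one.
    """
    if assign not in ("best", "first"):
        raise ValueError("assign must be 'best' or 'first'")
    order = score_order(genome_ids, quality)
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for gid in order:
        best_rep: str | None = None
        best_ani = -1.0
        for rep in reps:
            pd_ = distances_fn(gid, rep)
            if not exhaustive and pd_.distance > primary_distance:
                continue
            if pd_.ani_estimate >= ani_t and pd_.af_estimate >= af_t:
                if assign == "first":
                    best_rep = rep
                    break
                if pd_.ani_estimate > best_ani:
                    best_ani = pd_.ani_estimate
                    best_rep = rep
        if best_rep is None:
            reps.append(gid)
            members[gid] = [gid]
        else:
            members[best_rep].append(gid)
    clusters = [
        SGBCluster(sgb_id=f"SGB{i + 1:05d}", members=mem, representative=rep)
        for i, (rep, mem) in enumerate(members.items())
    ]
    part = CatalogPartition(
        clusters=clusters, ani_threshold=ani_t, af_threshold=af_t, primary_distance=primary_distance
    )
    if isolate_flags is not None:
        _promote_isolates(part, quality, isolate_flags)
    return part


def _promote_isolates(
    partition: CatalogPartition, quality: pd.DataFrame, isolate_flags: Mapping[str, bool]
) -> None:
    """Promote the best-scoring isolate to representative (membership untouched)."""
    for c in partition.clusters:
        isolates = [m for m in c.members if isolate_flags.get(m, False)]
        if isolates and not isolate_flags.get(c.representative, False):
            c.representative = score_order(isolates, quality)[0]


def chunked_dereplicate(
    genome_ids: Sequence[str],
    quality: pd.DataFrame,
    distances_fn: DistanceFn,
    chunk_size: int = 30_000,
    seed: int = 0,
    **kwargs,
) -> CatalogPartition:
    """Two-round dereplication: within random chunks, then over chunk representatives.

    Non-representative members inherit the final cluster of their round-1
    representative.  With ``chunk_size >= n`` this reduces exactly to
    :func:`greedy_dereplicate`.
    """
    if chunk_size < 2:
        raise ValueError("chunk_size must be >= 2")
    ids = list(genome_ids)
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(ids))
    round1_members: dict[str, list[str]] = {}
    for start in range(0, len(shuffled), chunk_size):
        chunk = shuffled[start : start + chunk_size]
        part = greedy_dereplicate(chunk, quality, distances_fn, **kwargs)
        for c in part.clusters:
            round1_members[c.representative] = list(c.members)
    final = greedy_dereplicate(list(round1_members), quality, distances_fn, **kwargs)
    for c in final.clusters:
        expanded: list[str] = []
        for rep1 in c.members:
            expanded.extend(round1_members[rep1])
        c.members = expanded
    final.seed = seed
    return final


def label_sgbs(
    partition: CatalogPartition, isolate_flags: Mapping[str, bool]
) -> CatalogPartition:
    """Attach cSGB/uSGB/non-early-life labels and uncultured scores in place."""
    for c in partition.clusters:
        unknown = [m for m in c.members if m not in isolate_flags]
        if unknown:
            raise ValueError(f"unknown genome ids in isolate flags: {unknown}")
        n_iso = sum(bool(isolate_flags[m]) for m in c.members)
        n_mag = len(c.members) - n_iso
        if n_mag and n_iso:
            c.label = "cSGB"
        elif n_mag:
            c.label = "uSGB"
        else:
            c.label = "non_early_life"
        c.uncultured_score = n_mag / len(c.members)
    return partition


def rarefy_clusters(
    membership: Mapping[str, str],
    n_perm: int = 10,
    exclude_singletons: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """Mean accumulation curve of distinct clusters vs genomes added.

    Position i (0-based) of the returned array is the mean number of distinct
    clusters seen after drawing i+1 genomes uniformly at random without
    replacement.  With ``exclude_singletons`` a cluster counts only once at
    least two of its members have been drawn.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = sorted(membership)
    labels = pd.Categorical([membership[g] for g in ids])
    codes = np.asarray(labels.codes)
    n, n_clusters = len(ids), len(labels.categories)
    rng = np.random.default_rng(seed)
    total = np.zeros(n, dtype=float)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        seen = np.zeros(n_clusters, dtype=np.int64)
        count = 0
        curve = np.empty(n, dtype=float)
        threshold = 2 if exclude_singletons else 1
        for i, idx in enumerate(perm):
            seen[codes[idx]] += 1
            if seen[codes[idx]] == threshold:
                count += 1
            curve[i] = count
        total += curve
    return total / n_perm


def catalog_summary(partition: CatalogPartition, quality: pd.DataFrame | None = None) -> dict:
    """Bookkeeping counts and percentages for a labeled catalog.

    Reports SGB counts by label, the uSGB share of SGBs, the share of MAGs
    sitting in uSGBs, and (when a quality table with a ``tier`` column is
    given) tier fractions of the member genomes.
    """
    if not partition.clusters:
        raise ValueError("no clusters")
    n_sgb = len(partition.clusters)
    n_c = sum(c.label == "cSGB" for c in partition.clusters)
    n_u = sum(c.label == "uSGB" for c in partition.clusters)
    n_non = sum(c.label == "non_early_life" for c in partition.clusters)
    early = [c for c in partition.clusters if c.label in ("cSGB", "uSGB")]
    n_early = len(early)
    # MAG counts from uncultured scores (n_mag = score * n_members, exact)
    n_mags = sum(round((c.uncultured_score or 0.0) * len(c.members)) for c in partition.clusters)
    n_mags_usgb = sum(len(c.members) for c in partition.clusters if c.label == "uSGB")
    out = {
        "n_sgb": n_sgb,
        "n_csgb": n_c,
        "n_usgb": n_u,
        "n_non_early_life": n_non,
        "pct_usgb": 100.0 * n_u / n_early if n_early else float("nan"),
        "n_mags": n_mags,
        "n_mags_in_usgb": n_mags_usgb,
        "pct_mags_in_usgb": 100.0 * n_mags_usgb / n_mags if n_mags else float("nan"),
    }
    if quality is not None and "tier" in quality.columns:
        fractions = quality["tier"].value_counts(normalize=True)
        out["tier_fractions"] = fractions.to_dict()
    return out
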