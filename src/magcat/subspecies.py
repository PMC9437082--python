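"""Within-species population structure from pairwise genome distances.

Conspecific genomes are agglomerated by complete-linkage hierarchical
clustering on their pairwise Mash-style distances, and subspecies are read
off by cutting the dendrogram at fixed heights: 0.03 (97% ANI) and 0.01
(99% ANI).  A cut joins genomes whose merge height is <= the cutoff
(inclusive), so the maximum intra-subcluster distance never exceeds the
height at which the subcluster formed.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

__all__ = [
    "complete_linkage_cut",
    "distance_to_ani",
    "subspecies_counts",
    "median_pairwise_distance",
]


def _as_distance_matrix(dm) -> DistanceMatrix:
    if isinstance(dm, DistanceMatrix):
        return dm
    return DistanceMatrix(np.asarray(dm, dtype=float))  # validates symmetry / zero diagonal


def complete_linkage_cut(dm: DistanceMatrix | np.ndarray, cutoff: float) -> list[set[str]]:
    """Partition genomes into subclusters at a complete-linkage height cutoff.

    Returns a list of id sets.  Raises on non-symmetric input (validated by
    the distance-matrix container).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    dm = _as_distance_matrix(dm)
    ids = list(dm.ids)
    if len(ids) == 1:
        return [set(ids)]
    condensed = squareform(dm.data, checks=False)
    z = linkage(condensed, method="complete")
    assignments = fcluster(z, t=cutoff, criterion="distance")
    out: dict[int, set[str]] = {}
    for gid, a in zip(ids, assignments):
        out.setdefault(int(a), set()).add(gid)
    return list(out.values())


def distance_to_ani(cutoff: float) -> float:
    """ANI percentage equivalent of a genome distance: (1 - d) * 100."""
    if not 0 <= cutoff <= 1:
        raise ValueError(f"distance {cutoff} outside [0, 1]")
    return (1.0 - cutoff) * 100.0


def subspecies_counts(
    dm: DistanceMatrix | np.ndarray, cutoffs: tuple[float, float] = (0.03, 0.01)
) -> tuple[int, ...]:
    """Number of complete-linkage subclusters at each cutoff (default 0.03, 0.01)."""
    dm = _as_distance_matrix(dm)
    return tuple(len(complete_linkage_cut(dm, c)) for c in cutoffs)


def median_pairwise_distance(dm: DistanceMatrix, mag_ids: set[str] | None = None) -> float:
    """Median off-diagonal distance; optionally restricted to MAG members only."""
    dm = _as_distance_matrix(dm)
    if mag_ids is not None:
        keep = [i for i in dm.ids if i in mag_ids]
        if len(keep) < 2:
            raise ValueError("need at least two genomes for a pairwise median")
        dm = dm.filter(keep)
    return float(np.median(squareform(dm.data, checks=False)))
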