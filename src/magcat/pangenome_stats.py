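"""Pan-genome statistics on gene presence/absence, PERMANOVA, and protein homology.

A pan-genome is summarized from a binary genomes x gene-clusters matrix:
core genes are present in at least 90% of genomes (inclusive), the rest are
accessory.  Gene-content structure between groups of genomes (delivery mode,
children vs adults, ...) is quantified by PERMANOVA on Jaccard (gene
presence/absence) or Hamming (core-gene characters) distances, and by
differential prevalence (> 70% in one group, < 30% in the other, strict).

Protein-level operations mirror the standard greedy incremental clustering
at 95% identity (identity over the shorter sequence; longest-first; best
matching representative) and a homolog scan against a reference gene cluster
(identity >= 70% over the local alignment, query coverage >= 50%, best hit
per query).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix

__all__ = [
    "core_accessory_split",
    "pan_accumulation",
    "differential_prevalence",
    "gene_content_distances",
    "core_hamming",
    "PermanovaResult",
    "permanova",
    "ProteinCluster",
    "greedy_protein_cluster",
    "HomologHit",
    "HomologScanResult",
    "hmo_homolog_scan",
]


def _validate_pm(pm: pd.DataFrame) -> pd.DataFrame:
    if pm.shape[0] == 0 or pm.shape[1] == 0:
        raise ValueError("empty presence/absence matrix")
    values = pm.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("presence/absence matrix must be binary")
    return pm


def core_accessory_split(
    pm: pd.DataFrame, core_fraction: float = 0.90
) -> tuple[list[str], list[str]]:
    """Split gene clusters into (core, accessory) at inclusive prevalence >= core_fraction."""
    _validate_pm(pm)
    prevalence = pm.mean(axis=0)
    core = list(pm.columns[prevalence >= core_fraction])
    accessory = list(pm.columns[prevalence < core_fraction])
    return core, accessory


def pan_accumulation(pm: pd.DataFrame, n_perm: int = 10, seed: int = 0) -> np.ndarray:
    """Mean cumulative count of distinct genes as genomes are added in random order."""
    _validate_pm(pm)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = pm.to_numpy(dtype=bool)
    n = x.shape[0]
    rng = np.random.default_rng(seed)
    total = np.zeros(n)
    for _ in range(n_perm):
        order = rng.permutation(n)
        total += np.cumsum(x[order], axis=0).astype(bool).sum(axis=1)
    return total / n_perm


def differential_prevalence(
    pm: pd.DataFrame,
    groups: pd.Series | Mapping[str, str],
    hi: float = 0.70,
    lo: float = 0.30,
) -> pd.DataFrame:
    """Genes prevalent in exactly one of two groups (> hi there, < lo in the other).

    Returns a table with per-group prevalences and the group each flagged
    gene favors.  Both inequalities are strict.
    """
    _validate_pm(pm)
    groups = pd.Series(groups).reindex(pm.index)
    if groups.isna().any():
        raise ValueError("every genome needs a group label")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a, b = levels
    prev_a = pm.loc[groups == a].mean(axis=0)
    prev_b = pm.loc[groups == b].mean(axis=0)
    flag_a = (prev_a > hi) & (prev_b < lo)
    flag_b = (prev_b > hi) & (prev_a < lo)
    out = pd.DataFrame(
        {
            f"prevalence_{a}": prev_a,
            f"prevalence_{b}": prev_b,
            "favors": np.where(flag_a, a, np.where(flag_b, b, "")),
        }
    )
    return out[out["favors"] != ""]


def gene_content_distances(pm: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distances (1 - |∩|/|∪|) between genomes' gene sets."""
    _validate_pm(pm)
    x = pm.to_numpy(dtype=bool)
    if (x.sum(axis=1) == 0).any():
        empty = list(pm.index[x.sum(axis=1) == 0])
        raise ValueError(f"genomes with zero genes: {empty}")
    inter = (x[:, None, :] & x[None, :, :]).sum(axis=2)
    union = (x[:, None, :] | x[None, :, :]).sum(axis=2)
    d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(pm.index))


def core_hamming(char_matrix: pd.DataFrame, gap: str = "-") -> DistanceMatrix:
    """Hamming distance over core-gene characters, ignoring pairwise gap positions."""
    x = char_matrix.to_numpy(dtype="U1")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (x[i] != gap) & (x[j] != gap)
            d[i, j] = d[j, i] = int(((x[i] != x[j]) & both).sum())
    return DistanceMatrix(d, ids=list(char_matrix.index))


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_permutations: int


def permanova(
    dm: DistanceMatrix | np.ndarray,
    labels: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    Decomposes the squared-distance sums into among- and within-group parts:
    SS_total = sum_{i<j} d_ij^2 / n, SS_within = sum over groups of the same
    quantity restricted to a group, pseudo-F = (SS_among/(a-1)) /
    (SS_within/(n-a)), R^2 = SS_among/SS_total, and the p-value is
    (1 + #{permuted F >= observed F}) / (1 + n_perm) under free label
    permutation.
    """
    d = dm.data if isinstance(dm, DistanceMatrix) else np.asarray(dm, dtype=float)
    labels = np.asarray(labels)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("label count must match distance matrix size")
    levels, codes = np.unique(labels, return_inverse=True)
    a = len(levels)
    sizes = np.bincount(codes)
    if a < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    d2 = d**2
    sst = d2.sum() / (2.0 * n)

    def _ssw(code_vec: np.ndarray) -> float:
        ssw = 0.0
        for g in range(a):
            idx = np.flatnonzero(code_vec == g)
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
        return ssw

    def _f(code_vec: np.ndarray) -> float:
        ssw = _ssw(code_vec)
        ssa = sst - ssw
        return (ssa / (a - 1)) / (ssw / (n - a))

    f_obs = _f(codes)
    r2 = (sst - _ssw(codes)) / sst
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if _f(rng.permutation(codes)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(pseudo_f=float(f_obs), r2=float(r2), p_value=float(p), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# protein-level operations


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def _best_alignment(aligner: Align.PairwiseAligner, target: str, query: str):
    alignments = aligner.align(target, query)
    try:
        return alignments[0]
    except IndexError:
        return None


def _identity_counts(alignment) -> tuple[int, int]:
    """(identical positions, alignment columns) of a local alignment."""
    counts = alignment.counts()
    return counts.identities, alignment.length


@dataclass
class ProteinCluster:
    representative: str
    members: list[str]
    identity_threshold: float


def greedy_protein_cluster(
    proteins: Mapping[str, str], identity: float = 0.95
) -> list[ProteinCluster]:
    """Greedy incremental clustering at an identity threshold.

    Sequences are processed longest-first; each joins the best-matching
    existing representative whose identity (identical residues over the
    length of the shorter sequence) is >= the threshold, else founds a new
    cluster.
    """
    if not proteins:
        raise ValueError("empty protein set")
    for pid, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty sequence {pid!r}")
    aligner = _make_aligner()
    order = sorted(proteins, key=lambda p: (-len(proteins[p]), p))
    clusters: list[ProteinCluster] = []
    for pid in order:
        seq = proteins[pid]
        best: ProteinCluster | None = None
        best_ident = -1.0
        for cluster in clusters:
            rep_seq = proteins[cluster.representative]
            aln = _best_alignment(aligner, rep_seq, seq)
            if aln is None:
                continue
            ident, _ = _identity_counts(aln)
            frac = ident / min(len(rep_seq), len(seq))
            if frac >= identity and frac > best_ident:
                best_ident = frac
                best = cluster
        if best is None:
            clusters.append(ProteinCluster(representative=pid, members=[pid], identity_threshold=identity))
        else:
            best.members.append(pid)
    return clusters


@dataclass
class HomologHit:
    query_id: str
    target_id: str
    percent_identity: float
    query_coverage: float
    qualifies: bool


@dataclass
class HomologScanResult:
    hits: list[HomologHit]
    n_queries: int

    @property
    def n_homologs(self) -> int:
        return sum(h.qualifies for h in self.hits)

    @property
    def percent_of_cluster(self) -> float:
        return 100.0 * self.n_homologs / self.n_queries


def hmo_homolog_scan(
    cluster_queries: Mapping[str, str],
    target_proteins: Mapping[str, str],
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
) -> HomologScanResult:
    """Count reference gene-cluster members with a qualifying homolog.

    Each query (e.g., one of the 30 proteins of the HMO utilization cluster)
    is locally aligned against every target; the best hit qualifies if its
    identity over the alignment is >= ``min_identity`` and the alignment
    covers >= ``min_coverage`` of the query.  At most one qualifying hit is
    counted per query.
    """
    if not cluster_queries:
        raise ValueError("empty query cluster")
    aligner = _make_aligner()
    hits: list[HomologHit] = []
    for qid, qseq in cluster_queries.items():
        best_hit: HomologHit | None = None
        for tid, tseq in target_proteins.items():
            aln = _best_alignment(aligner, tseq, qseq)
            if aln is None:
                continue
            ident, cols = _identity_counts(aln)
            if cols == 0:
                continue
            pid = ident / cols
            qranges = aln.aligned[1]
            cov = (qranges[-1][1] - qranges[0][0]) / len(qseq) if len(qranges) else 0.0
            qualifies = pid >= min_identity and cov >= min_coverage
            cand = HomologHit(qid, tid, 100.0 * pid, cov, qualifies)
            if best_hit is None or (cand.qualifies, cand.percent_identity) > (
                best_hit.qualifies,
                best_hit.percent_identity,
            ):
                best_hit = cand
        if best_hit is not None:
            hits.append(best_hit)
    return HomologScanResult(hits=hits, n_queries=len(cluster_queries))
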