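"""Species-level dereplication, SGB labeling, rarefaction and bookkeeping."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from magcat.genome_qc import representative_score
from magcat.kmer_distance import PairwiseDistance
from magcat.species_clustering import (
    CatalogPartition,
    SGBCluster,
    catalog_summary,
    chunked_dereplicate,
    greedy_dereplicate,
    label_sgbs,
    rarefy_clusters,
    score_order,
)
from tests.conftest import cached_distance_fn, make_species_set


def _quality(ids, scores=None):
    rows = []
    for i, gid in enumerate(ids):
        comp = scores[i] if scores else 95.0
        rows.append({"genome_id": gid, "completeness": comp, "contamination": 0.0, "n50": 10_000})
    return pd.DataFrame(rows).set_index("genome_id")


def _matrix_distance_fn(ids, ani, af=None):
    """Distance function from an explicit ANI matrix (AF defaults to 1)."""
    idx = {g: i for i, g in enumerate(ids)}

    def fn(a, b):
        v = ani[idx[a]][idx[b]]
        return PairwiseDistance(
            id_a=a,
            id_b=b,
            jaccard=0.0,
            distance=1.0 - v / 100.0,
            ani_estimate=v,
            af_estimate=af[idx[a]][idx[b]] if af else 1.0,
        )

    return fn


def test_single_genome_is_singleton():
    q = _quality(["only"])
    part = greedy_dereplicate(["only"], q, _matrix_distance_fn(["only"], [[100.0]]))
    assert len(part.clusters) == 1
    assert part.clusters[0].representative == "only"


def test_identical_pair_rep_is_higher_score():
    ids = ["lo", "hi"]
    q = _quality(ids, scores=[80.0, 90.0])
    ani = [[100.0, 100.0], [100.0, 100.0]]
    part = greedy_dereplicate(ids, q, _matrix_distance_fn(ids, ani))
    assert len(part.clusters) == 1
    assert part.clusters[0].representative == "hi"


def test_best_vs_first_assignment():
    # g joins the best-ANI rep (b at 99) not the first-founded qualifying rep (a at 96)
    ids = ["a", "b", "g"]
    ani = {
        ("a", "b"): 80.0,
        ("a", "g"): 96.0,
        ("b", "g"): 99.0,
    }
    mat = [[100.0] * 3 for _ in range(3)]
    for (x, y), v in ani.items():
        mat[ids.index(x)][ids.index(y)] = mat[ids.index(y)][ids.index(x)] = v
    q = _quality(ids, scores=[99.0, 98.0, 90.0])
    best = greedy_dereplicate(ids, q, _matrix_distance_fn(ids, mat))
    by_member = {m: c.representative for c in best.clusters for m in c.members}
    assert by_member["g"] == "b"
    first = greedy_dereplicate(ids, q, _matrix_distance_fn(ids, mat), assign="first")
    by_member = {m: c.representative for c in first.clusters for m in c.members}
    assert by_member["g"] == "a"


def test_af_gate_blocks_merge():
    ids = ["a", "b"]
    q = _quality(ids, scores=[99.0, 98.0])
    fn = _matrix_distance_fn(ids, [[100.0, 97.0], [97.0, 100.0]], af=[[1.0, 0.2], [0.2, 1.0]])
    part = greedy_dereplicate(ids, q, fn)
    assert len(part.clusters) == 2  # ANI qualifies but AF 0.2 < 0.30


def test_synthetic_species_recovered(three_species):
    """3 species × 4 genomes at within-ANI 97 / between ~random: exact recovery."""
    from sklearn.metrics import rand_score

    genomes, quality, truth, fn = three_species
    part = greedy_dereplicate(list(genomes), quality, fn)
    assert len(part.clusters) == 3
    membership = part.membership
    ids = sorted(genomes)
    assert rand_score([truth[g] for g in ids], [membership[g] for g in ids]) == 1.0
    # every member within thresholds of its representative
    for c in part.clusters:
        for m in c.members:
            if m != c.representative:
                pdist = fn(m, c.representative)
                assert pdist.ani_estimate >= 95.0 and pdist.af_estimate >= 0.30


def test_partition_covers_input(three_species):
    genomes, quality, _, fn = three_species
    part = greedy_dereplicate(list(genomes), quality, fn)
    members = [m for c in part.clusters for m in c.members]
    assert sorted(members) == sorted(genomes)  # disjoint cover


def test_representative_dominance(three_species):
    genomes, quality, _, fn = three_species
    part = greedy_dereplicate(list(genomes), quality, fn)
    for c in part.clusters:
        rep_score = representative_score(
            quality.loc[c.representative, "completeness"],
            quality.loc[c.representative, "contamination"],
            quality.loc[c.representative, "n50"],
        )
        for m in c.members:
            s = representative_score(
                quality.loc[m, "completeness"],
                quality.loc[m, "contamination"],
                quality.loc[m, "n50"],
            )
            assert rep_score >= s - 1e-12


def _reference_greedy(ids, quality, fn, ani_t=95.0, af_t=0.30):
    """Independently coded brute-force greedy clustering (assignment by best ANI)."""
    order = sorted(
        ids,
        key=lambda g: (
            -representative_score(
                quality.loc[g, "completeness"], quality.loc[g, "contamination"], quality.loc[g, "n50"]
            ),
            -quality.loc[g, "completeness"],
            -quality.loc[g, "n50"],
            g,
        ),
    )
    clusters: list[list[str]] = []
    for g in order:
        candidates = []
        for cl in clusters:
            p = fn(g, cl[0])
            if p.ani_estimate >= ani_t and p.af_estimate >= af_t:
                candidates.append((p.ani_estimate, cl))
        if candidates:
            max(candidates, key=lambda t: t[0])[1].append(g)
        else:
            clusters.append([g])
    return sorted(frozenset(c) for c in clusters)


def test_greedy_matches_bruteforce_reference(three_species):
    genomes, quality, _, fn = three_species
    part = greedy_dereplicate(list(genomes), quality, fn, exhaustive=True)
    got = sorted(frozenset(c.members) for c in part.clusters)
    assert got == _reference_greedy(list(genomes), quality, fn)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_chunked_equals_single_pass(three_species, seed):
    genomes, quality, _, fn = three_species
    single = greedy_dereplicate(list(genomes), quality, fn)
    chunked = chunked_dereplicate(list(genomes), quality, fn, chunk_size=5, seed=seed)
    assert sorted(frozenset(c.members) for c in chunked.clusters) == sorted(
        frozenset(c.members) for c in single.clusters
    )
    # contract: every member within ANI threshold of its final representative
    for c in chunked.clusters:
        for m in c.members:
            if m != c.representative:
                assert fn(m, c.representative).ani_estimate >= 95.0


def test_chunked_single_chunk_identical(three_species):
    genomes, quality, _, fn = three_species
    single = greedy_dereplicate(list(genomes), quality, fn)
    chunked = chunked_dereplicate(list(genomes), quality, fn, chunk_size=100, seed=9)
    assert sorted(frozenset(c.members) for c in chunked.clusters) == sorted(
        frozenset(c.members) for c in single.clusters
    )


def test_isolate_promotion():
    ids = ["mag_hi", "iso_lo"]
    q = _quality(ids, scores=[99.0, 80.0])
    fn = _matrix_distance_fn(ids, [[100.0, 99.0], [99.0, 100.0]])
    part = greedy_dereplicate(ids, q, fn, isolate_flags={"mag_hi": False, "iso_lo": True})
    assert len(part.clusters) == 1
    assert part.clusters[0].representative == "iso_lo"  # isolates beat MAGs
    assert sorted(part.clusters[0].members) == sorted(ids)  # membership unchanged


@pytest.mark.parametrize(
    "flags,label,score",
    [
        ({"m1": False, "m2": False, "i1": True}, "cSGB", 2 / 3),
        ({"m1": False, "m2": False, "m3": False}, "uSGB", 1.0),
        ({"i1": True, "i2": True}, "non_early_life", 0.0),
    ],
)
def test_label_sgbs(flags, label, score):
    members = sorted(flags)
    part = CatalogPartition(
        clusters=[SGBCluster(sgb_id="SGB1", members=members, representative=members[0])]
    )
    label_sgbs(part, flags)
    assert part.clusters[0].label == label
    assert part.clusters[0].uncultured_score == pytest.approx(score)


def test_label_sgbs_unknown_id():
    part = CatalogPartition(clusters=[SGBCluster("S1", ["a"], "a")])
    with pytest.raises(ValueError, match="unknown genome"):
        label_sgbs(part, {"b": True})


def _expected_accumulation(cluster_sizes, n_draws, threshold):
    """Closed-form hypergeometric expectation of clusters discovered."""
    n = sum(cluster_sizes)
    exp = 0.0
    for size in cluster_sizes:
        # P(at least `threshold` members of this cluster among the first n_draws)
        p = sum(
            math.comb(size, t) * math.comb(n - size, n_draws - t) / math.comb(n, n_draws)
            for t in range(threshold, min(size, n_draws) + 1)
        )
        exp += p
    return exp


def test_rarefaction_degenerate_cases():
    one_cluster = {f"g{i}": "c" for i in range(6)}
    np.testing.assert_allclose(rarefy_clusters(one_cluster, n_perm=5, seed=1), np.ones(6))
    singletons = {f"g{i}": f"c{i}" for i in range(6)}
    np.testing.assert_allclose(
        rarefy_clusters(singletons, n_perm=5, seed=1), np.arange(1, 7, dtype=float)
    )
    np.testing.assert_allclose(
        rarefy_clusters(singletons, n_perm=5, exclude_singletons=True, seed=1), np.zeros(6)
    )


@pytest.mark.parametrize("exclude", [False, True])
def test_rarefaction_matches_enumeration(exclude):
    """10 genomes in 5 pairs: simulated curve matches the exact expectation."""
    membership = {f"g{i}": f"pair{i // 2}" for i in range(10)}
    threshold = 2 if exclude else 1
    curve = rarefy_clusters(membership, n_perm=6000, exclude_singletons=exclude, seed=3)
    expected = [_expected_accumulation([2] * 5, m, threshold) for m in range(1, 11)]
    np.testing.assert_allclose(curve, expected, atol=0.06)


def test_rarefaction_nondecreasing(three_species):
    genomes, quality, _, fn = three_species
    membership = greedy_dereplicate(list(genomes), quality, fn).membership
    curve = rarefy_clusters(membership, n_perm=20, seed=5)
    assert (np.diff(curve) >= -1e-12).all()


def _paper_scale_partition():
    """A labeled partition with the headline catalog's printed composition."""
    clusters = []
    # 1398 uSGBs holding 2910 MAGs (each at least one member)
    sizes = [1] * 1398
    for i in range(2910 - 1398):
        sizes[i % 1398] += 1
    for i, take in enumerate(sizes):
        members = [f"u{i}_m{j}" for j in range(take)]
        clusters.append(SGBCluster(f"uSGB{i}", members, members[0], "uSGB", 1.0))
    # 774 cSGBs holding the remaining 29,367 MAGs plus one isolate each
    mags_left = 32_277 - 2910
    for i in range(774):
        take = mags_left // 774 + (1 if i < mags_left % 774 else 0)
        members = [f"c{i}_iso"] + [f"c{i}_m{j}" for j in range(take)]
        clusters.append(
            SGBCluster(f"cSGB{i}", members, members[0], "cSGB", take / (take + 1))
        )
    return CatalogPartition(clusters=clusters)


def test_catalog_summary_headline_percentages():
    """2172 SGBs with 774 cultured: uSGB share 64.4%, 9% of MAGs in uSGBs."""
    summary = catalog_summary(_paper_scale_partition())
    assert summary["n_sgb"] == 2172
    assert summary["n_usgb"] == 1398
    assert round(summary["pct_usgb"], 1) == 64.4
    assert summary["n_mags"] == 32_277
    assert round(summary["pct_mags_in_usgb"]) == 9


def test_catalog_summary_empty_errors():
    with pytest.raises(ValueError, match="no clusters"):
        catalog_summary(CatalogPartition(clusters=[]))


def test_species_count_recovery_across_seeds():
    """Species count error is 0 across 20 seeds (within-ANI 97, between ~random)."""
    for seed in range(20):
        genomes, quality, truth, _ = None, None, None, None
        genomes, quality, truth = make_species_set(
            n_species=3, n_genomes=4, target_ani=97.0, root_length=20_000, seed=5000 + 10 * seed
        )
        fn = cached_distance_fn(genomes)
        part = greedy_dereplicate(list(genomes), quality, fn)
        assert len(part.clusters) == 3, f"seed {seed}"
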