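"""Config-driven end-to-end catalog construction.

Stages run in dependency order: quality filtering -> sketching -> species
clustering -> SGB labeling -> summary, with optional subspecies,
strain-heterogeneity, phylogenetic-diversity and pan-genome stages when
their inputs are configured.  A JSON manifest records the verbatim config,
seeds, thresholds, per-stage row counts and output checksums, so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_qc import assign_tier, filter_catalog, QualityReport
from .io import (
    read_fasta_dir,
    read_id_list,
    read_quality_table,
    write_distance_matrix,
    write_quality_table,
    write_sketches,
)
from .kmer_distance import (
    DEFAULT_K,
    DEFAULT_SKETCH_SIZE,
    Sketch,
    ani_af_estimate,
    genome_kmer_hashes,
)
from .phylo_pd import parse_newick, pd_gain
from .species_clustering import chunked_dereplicate, catalog_summary, label_sgbs
from .strain_heterogeneity import filter_table, heterogeneity_rate, read_pileup_tsv
from .subspecies import subspecies_counts
from skbio import DistanceMatrix

log = logging.getLogger("magcat")


@dataclass
class RunConfig:
    fasta_dir: str
    quality_table: str
    out_dir: str
    isolates_file: str | None = None
    pileup: str | None = None
    tree: str | None = None
    cultured_leaves: str | None = None
    k: int = DEFAULT_K
    sketch_size: int = DEFAULT_SKETCH_SIZE
    seed: int = 0
    chunk_size: int = 30_000
    ani_threshold: float = 95.0
    af_threshold: float = 0.30
    primary_distance: float = 0.10
    subspecies_min_members: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
    }
    t0 = time.time()

    # --- qc ---------------------------------------------------------------
    qpath = Path(config.quality_table)
    if not qpath.exists():
        raise FileNotFoundError(f"quality table not found: {qpath}")
    quality = read_quality_table(qpath)
    admitted = filter_catalog(quality)
    admitted = admitted.assign(
        tier=[
            assign_tier(
                QualityReport(
                    completeness=row.completeness,
                    contamination=row.contamination,
                    chimera_pass=bool(row.chimera_pass),
                    n50=int(row.n50),
                    rrna_5s=bool(getattr(row, "rrna_5s", False)),
                    rrna_16s=bool(getattr(row, "rrna_16s", False)),
                    rrna_23s=bool(getattr(row, "rrna_23s", False)),
                    n_trna_types=int(getattr(row, "n_trna_types", 0)),
                )
            )
            for row in admitted.itertuples()
        ]
    )
    write_quality_table(admitted, out / "admitted.tsv")
    manifest["stages"]["qc"] = {"n_input": len(quality), "n_admitted": len(admitted)}
    log.info("qc: %d/%d genomes admitted (%.1fs)", len(admitted), len(quality), time.time() - t0)

    # --- sketch -----------------------------------------------------------
    isolate_ids = set(read_id_list(config.isolates_file)) if config.isolates_file else set()
    genomes = {
        g.id: g for g in read_fasta_dir(config.fasta_dir, isolate_ids=isolate_ids)
    }
    admitted_ids = [g for g in admitted.index if g in genomes]
    hashes = {
        gid: genome_kmer_hashes(genomes[gid], k=config.k, seed=config.seed)
        for gid in admitted_ids
    }
    sketches = [
        Sketch(
            genome_id=gid,
            k=config.k,
            s=config.sketch_size,
            seed=config.seed,
            hashes=h[: config.sketch_size],
            n_kmers=h.size,
        )
        for gid, h in hashes.items()
    ]
    write_sketches(sketches, out / "sketches.jsonl")
    manifest["stages"]["sketch"] = {"n_sketches": len(sketches), "k": config.k, "s": config.sketch_size}

    # --- cluster ----------------------------------------------------------
    cache: dict[tuple[str, str], object] = {}

    def distances_fn(a: str, b: str):
        key = (a, b) if a <= b else (b, a)
        if key not in cache:
            cache[key] = ani_af_estimate(
                genomes[key[0]], genomes[key[1]], k=config.k, s=config.sketch_size, seed=config.seed
            )
        return cache[key]

    partition = chunked_dereplicate(
        admitted_ids,
        admitted,
        distances_fn,
        chunk_size=config.chunk_size,
        seed=config.seed,
        ani_t=config.ani_threshold,
        af_t=config.af_threshold,
        primary_distance=config.primary_distance,
        isolate_flags={gid: gid in isolate_ids for gid in admitted_ids},
    )
    label_sgbs(partition, {gid: gid in isolate_ids for gid in admitted_ids})
    partition.to_frame().to_csv(out / "sgbs.tsv", sep="\t", index=False)
    summary = catalog_summary(partition, admitted)
    manifest["stages"]["cluster"] = {
        "n_clusters": len(partition.clusters),
        "summary": {k: v for k, v in summary.items() if not isinstance(v, dict)},
        "seed": config.seed,
    }
    log.info("cluster: %d SGBs from %d genomes", len(partition.clusters), len(admitted_ids))

    # --- subspecies (per SGB with enough members) -------------------------
    sub_rows = []
    for c in partition.clusters:
        if len(c.members) < config.subspecies_min_members:
            continue
        ids = sorted(c.members)
        import numpy as np

        d = np.zeros((len(ids), len(ids)))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d[i, j] = d[j, i] = distances_fn(ids[i], ids[j]).distance
        dm = DistanceMatrix(d, ids=ids)
        n03, n01 = subspecies_counts(dm)
        sub_rows.append({"sgb_id": c.sgb_id, "n_members": len(ids), "n_sub_097": n03, "n_sub_099": n01})
    pd.DataFrame(sub_rows).to_csv(out / "subclusters.tsv", sep="\t", index=False)
    manifest["stages"]["subspecies"] = {"n_sgbs_analyzed": len(sub_rows)}

    # --- optional: strain heterogeneity -----------------------------------
    if config.pileup:
        cols = filter_table(read_pileup_tsv(config.pileup))
        het = heterogeneity_rate(cols)
        pd.DataFrame(
            [
                {
                    "n_considered": het.n_considered,
                    "n_polymorphic": het.n_polymorphic,
                    "rate_pct": het.rate,
                }
            ]
        ).to_csv(out / "het.tsv", sep="\t", index=False)
        manifest["stages"]["heterogeneity"] = {"n_considered": het.n_considered, "rate_pct": het.rate}

    # --- optional: phylogenetic diversity ---------------------------------
    if config.tree and config.cultured_leaves:
        tree = parse_newick(Path(config.tree).read_text())
        gain = pd_gain(tree, read_id_list(config.cultured_leaves))
        pd.DataFrame(
            [
                {
                    "pd_all": gain.pd_all,
                    "pd_cultured": gain.pd_subset,
                    "gain_pct": gain.gain_percent,
                }
            ]
        ).to_csv(out / "pd.tsv", sep="\t", index=False)
        manifest["stages"]["pd"] = {"gain_pct": gain.gain_percent}

    # --- manifest ---------------------------------------------------------
    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
    }
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
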