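"""Readers and writers for the package's plain-text interchange formats.

Everything is TSV, JSON-lines or FASTA/Newick so that catalogs remain
diff-able and version-controllable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix

from .genome_qc import GenomeRecord, GenomeSource
from .kmer_distance import Sketch

QUALITY_COLUMNS = [
    "genome_id",
    "completeness",
    "contamination",
    "chimera_pass",
    "n50",
    "rrna_5s",
    "rrna_16s",
    "rrna_23s",
    "n_trna_types",
]


def read_quality_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "genome_id" not in df.columns:
        raise ValueError(f"{path}: quality table needs a genome_id column")
    for col in ("chimera_pass", "rrna_5s", "rrna_16s", "rrna_23s"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().map({"true": True, "false": False})
    return df.set_index("genome_id")


def write_quality_table(df: pd.DataFrame, path) -> None:
    out = df.reset_index() if df.index.name == "genome_id" else df
    out.to_csv(path, sep="\t", index=False)


def read_fasta_genome(path, source: GenomeSource = GenomeSource.MAG) -> GenomeRecord:
    path = Path(path)
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not contigs:
        raise ValueError(f"{path}: no sequences")
    return GenomeRecord(id=path.stem, contigs=contigs, source=source)


def read_fasta_dir(directory, isolate_ids: set[str] | None = None) -> list[GenomeRecord]:
    directory = Path(directory)
    genomes = []
    for path in sorted(directory.glob("*.fa")) + sorted(directory.glob("*.fasta")):
        source = (
            GenomeSource.ISOLATE
            if isolate_ids and path.stem in isolate_ids
            else GenomeSource.MAG
        )
        genomes.append(read_fasta_genome(path, source=source))
    if not genomes:
        raise ValueError(f"no FASTA files found in {directory}")
    return genomes


def write_genome_fasta(genome: GenomeRecord, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs
    ]
    SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_protein_fasta(proteins: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in proteins.items()]
    SeqIO.write(records, str(path), "fasta")


def write_sketches(sketches: Iterable[Sketch], path) -> None:
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(
                json.dumps(
                    {
                        "genome_id": sk.genome_id,
                        "k": sk.k,
                        "s": sk.s,
                        "seed": sk.seed,
                        "n_kmers": sk.n_kmers,
                        "hashes": [int(h) for h in sk.hashes],
                    }
                )
                + "\n"
            )


def read_sketches(path) -> list[Sketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            out.append(
                Sketch(
                    genome_id=rec["genome_id"],
                    k=rec["k"],
                    s=rec["s"],
                    seed=rec["seed"],
                    hashes=np.asarray(rec["hashes"], dtype=np.uint64),
                    n_kmers=rec["n_kmers"],
                )
            )
    return out


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_presence_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_group_labels(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def read_id_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
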