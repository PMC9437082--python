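"""Strain heterogeneity: the polymorphic-position rate of a genome's pileup.

Reads mapped back to an assembled genome yield per-position base counts.
Bases with PHRED quality below 30 are discarded first; a position is then
*considered* only if the remaining depth is at least 10x.  A considered
position is non-polymorphic if its dominant allele frequency is > 80%
(strictly), polymorphic otherwise.  Strain heterogeneity is the percentage
of considered positions that are polymorphic; optionally only substitutions
that change the encoded amino acid (translation table 11) are counted, using
gene models supplied as GFF3.

The native pileup dialect is a TSV with columns
``contig_id, pos, ref, count_A, count_C, count_G, count_T, mean_qual``
(1-based positions, one mean base quality per column); a reader for
``samtools mpileup`` text output is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "PileupColumn",
    "CodingContext",
    "HeterogeneityResult",
    "filter_column",
    "classify_polymorphic",
    "heterogeneity_rate",
    "read_pileup_tsv",
    "filter_table",
    "read_mpileup",
    "annotate_columns",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class CodingContext:
    """Where a position sits inside a protein-coding gene.

    ``codon`` holds the three reference bases in gene orientation and
    ``codon_pos`` the 0-based offset of this position within that codon.
    """

    gene_id: str
    strand: str  # '+' or '-'
    codon_pos: int  # 0, 1 or 2
    codon: str  # reference codon, gene-oriented


@dataclass
class PileupColumn:
    contig_id: str
    position: int  # 1-based
    ref_base: str
    counts: dict[str, int]
    coding_context: CodingContext | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be 1-based (>= 1)")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative base count")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class HeterogeneityResult:
    n_considered: int
    n_polymorphic: int

    @property
    def rate(self) -> float:
        """Polymorphic positions as a percentage of considered positions."""
        if self.n_considered == 0:
            return 0.0
        return 100.0 * self.n_polymorphic / self.n_considered


def filter_column(
    contig_id: str,
    position: int,
    ref_base: str,
    bases: Sequence[tuple[str, float]],
    min_qual: float = 30,
    min_depth: int = 10,
    coding_context: CodingContext | None = None,
) -> PileupColumn | None:
    """Quality-filter one pileup column; ``None`` if depth falls below min_depth.

    Bases below ``min_qual`` are removed *before* the depth test.  Indels and
    non-ACGT base calls are ignored.
    """
    counts = {b: 0 for b in _BASES}
    for base, qual in bases:
        b = base.upper()
        if b in counts and qual >= min_qual:
            counts[b] += 1
    col = PileupColumn(contig_id, position, ref_base.upper(), counts, coding_context)
    return col if col.depth >= min_depth else None


def classify_polymorphic(column: PileupColumn) -> bool:
    """True unless the dominant allele frequency exceeds 80% (strictly)."""
    depth = column.depth
    if depth == 0:
        raise ValueError(f"zero depth at {column.contig_id}:{column.position}")
    return max(column.counts.values()) / depth <= 0.80


_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _translate(codon: str) -> str:
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table.get(codon, "X")


def _minor_allele(column: PileupColumn) -> str:
    ranked = sorted(column.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[1][0]


def is_nonsynonymous(column: PileupColumn) -> bool:
    """Whether the second-most-frequent allele changes the encoded amino acid.

    The minor allele is substituted into the reference codon at this
    position; the other two codon positions keep the reference base.
    """
    ctx = column.coding_context
    if ctx is None:
        raise ValueError(f"no coding context at {column.contig_id}:{column.position}")
    minor = _minor_allele(column)
    base = minor if ctx.strand == "+" else _COMPLEMENT[minor]
    codon = list(ctx.codon)
    codon[ctx.codon_pos] = base
    return _translate("".join(codon)) != _translate(ctx.codon)


def heterogeneity_rate(
    columns: Iterable[PileupColumn], nonsynonymous_only: bool = False
) -> HeterogeneityResult:
    """Polymorphism rate over quality-filtered pileup columns.

    With ``nonsynonymous_only`` the considered set shrinks to columns inside
    annotated genes and a polymorphic call additionally requires the minor
    allele to change the encoded amino acid.
    """
    cols = list(columns)
    if nonsynonymous_only:
        cols = [c for c in cols if c.coding_context is not None]
        if not cols:
            raise ValueError("nonsynonymous mode requires columns with coding context")
    n_poly = 0
    for c in cols:
        if classify_polymorphic(c) and (not nonsynonymous_only or is_nonsynonymous(c)):
            n_poly += 1
    return HeterogeneityResult(n_considered=len(cols), n_polymorphic=n_poly)


PILEUP_COLUMNS = [
    "contig_id",
    "pos",
    "ref",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "mean_qual",
]


def read_pileup_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pileup table lacks columns {missing}")
    return df


def filter_table(
    df: pd.DataFrame, min_qual: float = 30, min_depth: int = 10
) -> list[PileupColumn]:
    """Apply quality/depth filtering to the TSV pileup dialect.

    The dialect records one mean quality per column, so the base-quality
    filter either keeps all counts (mean_qual >= min_qual) or none.
    """
    out: list[PileupColumn] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            if float(row.mean_qual) < min_qual:
                continue
            counts = {
                "A": int(row.count_A),
                "C": int(row.count_C),
                "G": int(row.count_G),
                "T": int(row.count_T),
            }
            col = PileupColumn(str(row.contig_id), int(row.pos), str(row.ref).upper(), counts)
        except (ValueError, TypeError) as err:
            raise ValueError(f"malformed pileup row at line {i + 2}: {err}") from err
        if col.depth >= min_depth:
            out.append(col)
    return out


def read_mpileup(path, min_qual: float = 30, min_depth: int = 10) -> list[PileupColumn]:
    """Parse samtools-mpileup text and quality-filter each column."""
    columns: list[PileupColumn] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"malformed mpileup line {lineno}")
            contig, pos, ref, _depth, basestr, qualstr = fields[:6]
            bases = _parse_mpileup_bases(basestr, ref.upper(), qualstr, lineno)
            col = filter_column(contig, int(pos), ref, bases, min_qual, min_depth)
            if col is not None:
                columns.append(col)
    return columns


def _parse_mpileup_bases(
    basestr: str, ref: str, qualstr: str, lineno: int
) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    qi = 0
    i = 0
    while i < len(basestr):
        ch = basestr[i]
        if ch == "^":
            i += 2  # mapping-quality char follows
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            i += 1
            num = ""
            while i < len(basestr) and basestr[i].isdigit():
                num += basestr[i]
                i += 1
            i += int(num)  # indel sequence carries no quality
            continue
        if qi >= len(qualstr):
            raise ValueError(f"base/quality length mismatch at mpileup line {lineno}")
        qual = float(ord(qualstr[qi]) - 33)
        qi += 1
        if ch in ".,":
            out.append((ref, qual))
        elif ch.upper() in _BASES:
            out.append((ch.upper(), qual))
        # '*' (deletion placeholder) and other codes consume a quality, ignored
        i += 1
    return out


def annotate_columns(
    columns: Iterable[PileupColumn],
    gff_path,
    contig_sequences: Mapping[str, str],
) -> list[PileupColumn]:
    """Attach coding context to columns that fall inside GFF3 CDS features.

    GFF3 coordinates are 1-based inclusive; codons are read strand-aware from
    the supplied contig sequences.  Columns outside any CDS keep
    ``coding_context=None``.
    """
    gff = pd.read_csv(
        gff_path,
        sep="\t",
        comment="#",
        header=None,
        names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
    )
    cds = gff[gff["type"] == "CDS"]
    features: dict[str, list[tuple[int, int, str, str]]] = {}
    for row in cds.itertuples(index=False):
        gene_id = "unknown"
        for part in str(row.attributes).split(";"):
            if part.startswith("ID="):
                gene_id = part[3:]
                break
        features.setdefault(str(row.seqid), []).append(
            (int(row.start), int(row.end), str(row.strand), gene_id)
        )
    out: list[PileupColumn] = []
    for col in columns:
        ctx = None
        for start, end, strand, gene_id in features.get(col.contig_id, []):
            if start <= col.position <= end:
                seq = contig_sequences[col.contig_id].upper()
                gene = seq[start - 1 : end]
                if strand == "-":
                    gene = str(Seq(gene).reverse_complement())
                    offset = end - col.position
                else:
                    offset = col.position - start
                codon_idx, codon_pos = divmod(offset, 3)
                codon = gene[3 * codon_idx : 3 * codon_idx + 3]
                if len(codon) == 3:
                    ctx = CodingContext(gene_id, strand, codon_pos, codon)
                break
        out.append(
            PileupColumn(col.contig_id, col.position, col.ref_base, dict(col.counts), ctx)
        )
    return out
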