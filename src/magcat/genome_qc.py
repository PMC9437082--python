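"""Genome quality metrics and catalog admission rules.

Quality of a metagenome-assembled genome (MAG) is summarized by the genome
quality score ``QS = completeness - 5 * contamination`` and, for choosing
cluster representatives, by ``Score = completeness - 5 * contamination +
0.5 * log10(N50)``.  Completeness and contamination are consumed as inputs
(marker-gene estimation is out of scope for this package); rRNA/tRNA presence
and the chimerism flag likewise arrive as precomputed columns.

Admission to the catalog requires completeness > 50%, contamination < 5%,
QS > 50 and a passing chimerism check — all inequalities strict.  Genomes are
tiered as ``high`` (near-complete plus 5S/16S/23S rRNA and >= 18 distinct tRNA
types), ``near_complete`` (> 90% complete, < 5% contaminated), ``medium``
(> 50% complete, < 5% contaminated; the community MIMAG standard's looser
< 10% contamination bound is available as a toggle) or ``fail``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "GenomeRecord",
    "QualityReport",
    "AgeBin",
    "AGE_BINS",
    "compute_n50",
    "quality_score",
    "representative_score",
    "assign_tier",
    "filter_catalog",
    "assign_age_bin",
]

_VALID_BASES = frozenset("ACGTN")


class GenomeSource(str, Enum):
    MAG = "MAG"
    ISOLATE = "isolate"


@dataclass
class GenomeRecord:
    """A genome assembly: ordered contigs plus provenance.

    ``source`` distinguishes metagenome-assembled genomes from cultured
    isolate genomes; the distinction drives representative promotion and
    cSGB/uSGB labeling downstream.
    """

    id: str
    contigs: list[tuple[str, str]]
    source: GenomeSource = GenomeSource.MAG
    sample_id: str | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cid, seq in self.contigs:
            if cid in seen:
                raise ValueError(f"duplicate contig id {cid!r} in genome {self.id!r}")
            seen.add(cid)
            if not seq:
                raise ValueError(f"empty contig {cid!r} in genome {self.id!r}")
            bad = set(seq.upper()) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid!r} in genome {self.id!r} has invalid characters {sorted(bad)}"
                )

    @property
    def length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    @property
    def contig_lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.contigs]

    def sequence(self) -> str:
        """Concatenated contig sequence (used only for whole-genome stats)."""
        return "".join(seq for _, seq in self.contigs)


@dataclass
class QualityReport:
    """Per-genome quality metrics consumed from upstream estimators."""

    completeness: float
    contamination: float
    chimera_pass: bool = True
    n50: int | None = None
    rrna_5s: bool = False
    rrna_16s: bool = False
    rrna_23s: bool = False
    n_trna_types: int = 0
    strain_heterogeneity: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"contamination {self.contamination} is negative")
        if not 0 <= self.n_trna_types <= 20:
            raise ValueError("n_trna_types must count distinct amino-acid types (0-20)")

    @property
    def qs(self) -> float:
        """Genome quality score, recomputed (never stored independently)."""
        return quality_score(self.completeness, self.contamination)


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """Smallest contig length L such that contigs >= L cover half the assembly.

    Raises ``ValueError`` on an empty list; the result is always a member of
    the input.
    """
    if len(contig_lengths) == 0:
        raise ValueError("no contigs")
    if any(l <= 0 for l in contig_lengths):
        raise ValueError("contig lengths must be positive")
    total = sum(contig_lengths)
    running = 0
    for length in sorted(contig_lengths, reverse=True):
        running += length
        if 2 * running >= total:
            return length
    raise AssertionError("unreachable")  # pragma: no cover


def quality_score(completeness: float, contamination: float) -> float:
    """QS = completeness - 5 * contamination (percent scale, may be negative)."""
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValueError(f"contamination {contamination} is negative")
    return completeness - 5.0 * contamination


def representative_score(completeness: float, contamination: float, n50: float) -> float:
    """Score used to rank candidate cluster representatives.

    Score = completeness - 5 * contamination + 0.5 * log10(N50), with N50 in
    bases.
    """
    if n50 < 1:
        raise ValueError(f"n50 must be >= 1, got {n50}")
    return quality_score(completeness, contamination) + 0.5 * math.log10(n50)


def assign_tier(report: QualityReport, *, mimag_medium: bool = False) -> str:
    """Tier a genome as ``high`` / ``near_complete`` / ``medium`` / ``fail``.

    Tiers are evaluated strictly high -> fail, so they are mutually
    exclusive.  ``mimag_medium=True`` relaxes the medium contamination bound
    from the catalog's < 5% to the community MIMAG standard's < 10%.
    """
    near = report.completeness > 90 and report.contamination < 5
    if (
        near
        and report.rrna_5s
        and report.rrna_16s
        and report.rrna_23s
        and report.n_trna_types >= 18
    ):
        return "high"
    if near:
        return "near_complete"
    cont_bound = 10 if mimag_medium else 5
    if report.completeness > 50 and report.contamination < cont_bound:
        return "medium"
    return "fail"


_REQUIRED_FILTER_COLS = ("completeness", "contamination", "chimera_pass")


def filter_catalog(reports: pd.DataFrame) -> pd.DataFrame:
    """Admit genomes with completeness > 50, contamination < 5, QS > 50 and a
    passing chimerism flag (all strict).

    ``reports`` is a table with at least columns ``completeness``,
    ``contamination`` and ``chimera_pass`` (``genome_id`` is carried through
    untouched).  Rows with missing values in required columns raise, naming
    the offending row.
    """
    for col in _REQUIRED_FILTER_COLS:
        if col not in reports.columns:
            raise ValueError(f"quality table lacks required column {col!r}")
    bad = reports[list(_REQUIRED_FILTER_COLS)].isna().any(axis=1)
    if bad.any():
        row = reports.index[bad][0]
        raise ValueError(f"missing quality fields in row {row!r}")
    qs = reports["completeness"] - 5.0 * reports["contamination"]
    keep = (
        (reports["completeness"] > 50)
        & (reports["contamination"] < 5)
        & (qs > 50)
        & reports["chimera_pass"].astype(bool)
    )
    return reports.loc[keep].copy()


@dataclass(frozen=True)
class AgeBin:
    """One age stratum: a month label and its inclusive day range."""

    months: int
    day_lo: int
    day_hi: int

    @property
    def label(self) -> str:
        return f"{self.months} months"


#: Age strata in days since birth.  The printed ranges place day 900 in both
#: the 30- and 36-month bins; here the lower bin's inclusive upper bound wins,
#: so the 36-month bin starts at day 901.
AGE_BINS: tuple[AgeBin, ...] = (
    AgeBin(0, 0, 1),
    AgeBin(1, 2, 30),
    AgeBin(3, 31, 90),
    AgeBin(6, 91, 180),
    AgeBin(12, 181, 360),
    AgeBin(18, 361, 540),
    AgeBin(24, 541, 720),
    AgeBin(30, 721, 900),
    AgeBin(36, 901, 1162),
)


def assign_age_bin(age_days: int) -> str:
    """Map an age in days to its month-bin label (``"0 months"`` ... ``"36 months"``)."""
    if age_days < 0 or age_days > 1162:
        raise ValueError(f"age {age_days} days outside study range")
    for b in AGE_BINS:
        if b.day_lo <= age_days <= b.day_hi:
            return b.label
    raise AssertionError("age bins must tile 0-1162")  # pragma: no cover
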