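"""Cross-study reproducibility of genome catalogs.

Two pipelines run on the same metagenomic samples should recover the same
species: per-sample agreement is the percentage of shared SGBs relative to
the smaller of the two per-sample SGB sets, and conspecific genome pairs are
compared by the maximum of the two per-orientation ANI and AF values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleSGBSets",
    "sgb_similarity",
    "compare_membership_tables",
    "conspecific_agreement",
]


@dataclass
class SampleSGBSets:
    sample_id: str
    study: str
    sgbs: set[str]


def sgb_similarity(a: SampleSGBSets, b: SampleSGBSets) -> float:
    """100 * |A ∩ B| / min(|A|, |B|) for the same sample across two studies."""
    if a.sample_id != b.sample_id:
        raise ValueError(f"different samples: {a.sample_id!r} vs {b.sample_id!r}")
    if not a.sgbs and not b.sgbs:
        raise ValueError(f"both SGB sets empty for sample {a.sample_id!r}")
    smaller = min(len(a.sgbs), len(b.sgbs))
    if smaller == 0:
        return float("nan")  # one-sided zero: undefined, reported as NA
    return 100.0 * len(a.sgbs & b.sgbs) / smaller


def compare_membership_tables(
    table_a: pd.DataFrame, table_b: pd.DataFrame, study_a: str = "A", study_b: str = "B"
) -> pd.DataFrame:
    """Per-sample SGB similarity from two (sample_id, genome_id, sgb_id) tables.

    Samples present in only one study are skipped; samples with an empty set
    on exactly one side get similarity NA (excluded from medians downstream).
    """
    for name, t in (("A", table_a), ("B", table_b)):
        missing = {"sample_id", "sgb_id"} - set(t.columns)
        if missing:
            raise ValueError(f"study {name} table lacks columns {sorted(missing)}")
    sets_a = table_a.groupby("sample_id")["sgb_id"].agg(set)
    sets_b = table_b.groupby("sample_id")["sgb_id"].agg(set)
    rows = []
    for sample in sorted(set(sets_a.index) & set(sets_b.index)):
        a = SampleSGBSets(sample, study_a, sets_a[sample])
        b = SampleSGBSets(sample, study_b, sets_b[sample])
        rows.append(
            {
                "sample_id": sample,
                "n_A": len(a.sgbs),
                "n_B": len(b.sgbs),
                "n_shared": len(a.sgbs & b.sgbs),
                "similarity_pct": sgb_similarity(a, b),
            }
        )
    return pd.DataFrame(rows)


def conspecific_agreement(
    pairs: Iterable[tuple[str, str, Sequence[float], Sequence[float]]],
) -> pd.DataFrame:
    """Per-pair max ANI/AF over orientations, plus distribution summaries.

    ``pairs`` yields (genome_a, genome_b, ani_values, af_values) where the
    value sequences hold one or two per-orientation measurements.  Returns a
    table with per-pair maxima; medians/IQRs are attached as ``DataFrame.attrs
    ["summary"]``.
    """
    rows = []
    for id_a, id_b, anis, afs in pairs:
        if len(anis) == 0 or len(afs) == 0:
            raise ValueError(f"pair ({id_a}, {id_b}) has no measurements")
        rows.append(
            {"genome_a": id_a, "genome_b": id_b, "max_ani": max(anis), "max_af": max(afs)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df.attrs["summary"] = {
            "median_ani": float(df["max_ani"].median()),
            "iqr_ani": tuple(np.percentile(df["max_ani"], [25, 75])),
            "median_af": float(df["max_af"].median()),
            "iqr_af": tuple(np.percentile(df["max_af"], [25, 75])),
        }
    return df
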