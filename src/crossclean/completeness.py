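"""Transcriptome-completeness summaries from CEG and BUSCO report tables.

Two completeness proxies are computed per assembly: the fraction of the 248
core eukaryotic genes (CEGs) recovered by conditional reciprocal best BLAST
(``ceg_abundance`` = 100 x hits / 248), and the BUSCO abundance
(100 - missing%).  Both are sensitive to expression — a gene absent from the
sampled tissue's transcriptome is not evidence of a bad assembly — so they
are reported as percentile tables over the whole sample set rather than as
hard per-sample scores.  A configurable floor (default 57.5% BUSCO
abundance, strict <) partitions samples into retained and excluded, the
inclusion rule used for downstream taxonomic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Number of core eukaryotic genes in the CEGMA reference set.
N_CEGS = 248

DEFAULT_PERCENTILES = (5, 25, 50, 75, 95)
DEFAULT_BUSCO_FLOOR = 57.5


@dataclass
class CompletenessRecord:
    sample: str
    ceg_hits: int | None = None
    ceg_abundance: float | None = None
    busco_set: str | None = None  # eukaryota | embryophyta
    busco_complete: float | None = None
    busco_fragment: float | None = None
    busco_missing: float | None = None
    busco_abundance: float | None = None


def ceg_abundance(ceg_hits: int) -> float:
    """Percentage of the 248 CEGs recovered: 100 x hits / 248."""
    if not 0 <= ceg_hits <= N_CEGS:
        raise ValueError(f"ceg_hits must be in [0, {N_CEGS}] (got {ceg_hits})")
    return 100.0 * ceg_hits / N_CEGS


def busco_abundance(missing_pct: float) -> float:
    """BUSCO abundance: 100 minus the missing percentage."""
    if not 0.0 <= missing_pct <= 100.0:
        raise ValueError(f"missing_pct must be in [0, 100] (got {missing_pct})")
    return 100.0 - missing_pct


def percentile_summary(
    values: Sequence[float],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Summarize a distribution at the requested percentiles.

    Uses linear interpolation between closest ranks (numpy's default), the
    convention is configurable only in the sense that callers may quantile
    themselves; output is non-decreasing in percentile.
    """
    if len(values) == 0:
        raise ValueError("cannot summarize an empty collection of values")
    vals = np.asarray(values, dtype=float)
    out = np.percentile(vals, percentiles)
    return pd.DataFrame({"percentile": list(percentiles), "value": out})


def flag_low_completeness(
    records: Sequence[CompletenessRecord],
    busco_floor: float = DEFAULT_BUSCO_FLOOR,
) -> tuple[list[CompletenessRecord], list[CompletenessRecord]]:
    """Partition records into (retained, excluded) by BUSCO abundance.

    Strict comparison: abundance < floor is excluded, abundance equal to the
    floor is retained.
    """
    retained, excluded = [], []
    for r in records:
        if r.busco_abundance is not None and r.busco_abundance < busco_floor:
            excluded.append(r)
        else:
            retained.append(r)
    return retained, excluded


def read_ceg_counts(path: str | Path) -> list[CompletenessRecord]:
    """Read per-sample CEG hit counts (TSV ``sample  ceg_hits``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "ceg_hits"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'sample' and 'ceg_hits'")
    return [
        CompletenessRecord(
            sample=row["sample"],
            ceg_hits=int(row["ceg_hits"]),
            ceg_abundance=ceg_abundance(int(row["ceg_hits"])),
        )
        for _, row in df.iterrows()
    ]


def read_busco_summary(path: str | Path) -> list[CompletenessRecord]:
    """Read BUSCO short-summary percentages.

    TSV columns: ``sample  set  complete  fragment  missing`` with the three
    percentage columns summing to ~100 per row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "set": str})
    required = {"sample", "set", "complete", "fragment", "missing"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        CompletenessRecord(
            sample=row["sample"],
            busco_set=row["set"],
            busco_complete=float(row["complete"]),
            busco_fragment=float(row["fragment"]),
            busco_missing=float(row["missing"]),
            busco_abundance=busco_abundance(float(row["missing"])),
        )
        for _, row in df.iterrows()
    ]


def completeness_tables(
    ceg_records: Sequence[CompletenessRecord],
    busco_records: Sequence[CompletenessRecord],
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> pd.DataFrame:
    """Build the percentile table over completeness measures.

    One column per measure: CEG abundance, and per BUSCO set both the
    complete+fragment abundance and the complete-only percentage (the latter
    given "in parentheses" in the classic presentation).
    """
    columns: dict[str, list[float]] = {}
    if ceg_records:
        columns["ceg_abundance"] = [r.ceg_abundance for r in ceg_records]
    for busco_set in sorted({r.busco_set for r in busco_records}):
        recs = [r for r in busco_records if r.busco_set == busco_set]
        columns[f"busco_{busco_set}_abundance"] = [r.busco_abundance for r in recs]
        columns[f"busco_{busco_set}_complete_only"] = [r.busco_complete for r in recs]
    table = pd.DataFrame({"percentile": list(percentiles)})
    for name, vals in columns.items():
        table[name] = percentile_summary(vals, percentiles)["value"].values
    return table


def write_completeness_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.2f")
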