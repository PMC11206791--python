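"""Endpoint OD600 plate tables: parsing, blank subtraction, categories.

The growth readout is a single endpoint OD600 per well after anaerobic
incubation, measured in (biological) triplicate next to a no-bacteria
blank well. Replicates are summarized by the median (robust to one failed
well), the blank is subtracted, and the blank-corrected delta OD is banded
into none / moderate / good categories. The 0.4 / 1.0 thresholds are
artifact-defined: they separate the non-growing (~0.3), moderate (~0.7)
and good (~1.15) group means reported for this assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("none", "moderate", "good")
DEFAULT_THRESHOLDS = (0.4, 1.0)


class GrowthTableError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthRecord:
    strain_id: str
    substrate: str
    replicate_ods: tuple[float, ...]
    blank_od: float
    delta_od: float
    category: str


def categorize(
    delta_od: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Band a blank-corrected delta OD: none < t0 <= moderate < t1 <= good.

    Negative deltas clamp to 0 with a warning (evaporation / pipetting
    artifacts occasionally push a blank above the culture wells).
    """
    t0, t1 = thresholds
    if not t0 < t1:
        raise GrowthTableError("thresholds must be strictly increasing")
    if delta_od < 0:
        warnings.warn(
            f"negative delta OD {delta_od:.3f} clamped to 0", stacklevel=2
        )
        delta_od = 0.0
    if delta_od < t0:
        return "none"
    if delta_od < t1:
        return "moderate"
    return "good"


def summarize_delta(
    replicate_ods: Sequence[float],
    blank_od: float,
    summary: str = "median",
    subtract_blank: bool = True,
) -> float:
    if not replicate_ods:
        raise GrowthTableError("no replicate readings")
    agg = np.median if summary == "median" else np.mean
    value = float(agg(np.asarray(replicate_ods, dtype=float)))
    return value - blank_od if subtract_blank else value


def read_plate(
    path: str | Path,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    summary: str = "median",
    subtract_blank: bool = True,
) -> list[GrowthRecord]:
    """Parse a plate TSV (columns strain, substrate, rep1..repK, blank).

    Non-numeric readings and missing blanks are hard errors naming the
    offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"strain", "substrate", "blank"}
    if not required <= set(df.columns):
        raise GrowthTableError(
            f"plate table must have columns {sorted(required)} + rep1..repK"
        )
    rep_cols = [c for c in df.columns if c.startswith("rep")]
    if not rep_cols:
        raise GrowthTableError("plate table has no replicate columns")

    records: list[GrowthRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = row._asdict()
        if row_d["blank"] == "":
            raise GrowthTableError(f"missing blank in row {i}")
        try:
            reps = tuple(float(row_d[c]) for c in rep_cols
                         if row_d[c] != "")
            blank = float(row_d["blank"])
        except (TypeError, ValueError):
            raise GrowthTableError(
                f"non-numeric OD reading in row {i} "
                f"(strain {row_d.get('strain')!r})"
            ) from None
        if not reps:
            raise GrowthTableError(f"no replicate readings in row {i}")
        delta = summarize_delta(reps, blank, summary, subtract_blank)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clamped = max(delta, 0.0)
        records.append(
            GrowthRecord(
                strain_id=row_d["strain"],
                substrate=row_d["substrate"],
                replicate_ods=reps,
                blank_od=blank,
                delta_od=clamped,
                category=categorize(clamped, thresholds),
            )
        )
    return records


def write_plate(records: Sequence[GrowthRecord], path: str | Path) -> None:
    """Write records back to the plate TSV layout (3-decimal ODs), with
    delta_od and category appended."""
    if not records:
        raise GrowthTableError("no growth records to write")
    n_reps = max(len(r.replicate_ods) for r in records)
    rows = []
    for r in records:
        row = {"strain": r.strain_id, "substrate": r.substrate}
        for k in range(n_reps):
            row[f"rep{k + 1}"] = (
                f"{r.replicate_ods[k]:.3f}" if k < len(r.replicate_ods) else ""
            )
        row["blank"] = f"{r.blank_od:.3f}"
        row["delta_od"] = f"{r.delta_od:.3f}"
        row["category"] = r.category
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
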