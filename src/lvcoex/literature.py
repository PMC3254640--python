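"""RYT classification of published two-species protist experiments.

Applies the same normalize-then-classify pipeline to tabulated alone/
coexist biomasses from the literature (any consistent unit within a study,
since only ratios enter).  Published tables rarely carry usable error
estimates, so classification defaults to point estimates with a fixed
on-the-line band half-width of 0.05.

The packaged table ``data/protist_studies_synthetic.csv`` holds synthetic
illustrative coordinates for eight protist coexistence experiments — the
original figures do not print numeric values — and is intended for examples
and tests, not as digitized ground truth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ryt import RelativeYieldPoint, classify_region

__all__ = [
    "StudyRecord",
    "read_study_table",
    "classify_studies",
    "packaged_studies_path",
    "DEFAULT_BAND",
]

DEFAULT_BAND = 0.05

_REQUIRED = ("study_id", "species1", "species2", "alone1", "alone2", "coexist1", "coexist2")


@dataclass(frozen=True)
class StudyRecord:
    """One study's alone/coexist biomasses for a two-species pair."""

    study_id: str
    species1_label: str
    species2_label: str
    alone1: float
    alone2: float
    coexist1: float
    coexist2: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.alone1 <= 0 or self.alone2 <= 0:
            raise ValueError("alone biomasses must be strictly positive")
        if self.coexist1 < 0 or self.coexist2 < 0:
            raise ValueError("coexist biomasses must be non-negative")


def packaged_studies_path() -> Path:
    """Path of the packaged synthetic literature table."""
    return Path(importlib.resources.files("lvcoex") / "data" / "protist_studies_synthetic.csv")


def read_study_table(path) -> list[StudyRecord]:
    """Read and validate a study-table CSV.

    Required columns: study_id, species1, species2, alone1, alone2,
    coexist1, coexist2.  Extra columns (units, source, ...) are preserved in
    each record's ``note``.  Invalid rows are rejected with their row number.
    """
    df = pd.read_csv(path, comment="#")
    missing = set(_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"study table is missing columns: {sorted(missing)}")
    extra = [c for c in df.columns if c not in _REQUIRED]
    records = []
    for i, row in df.iterrows():
        try:
            vals = {c: float(row[c]) for c in ("alone1", "alone2", "coexist1", "coexist2")}
            rec = StudyRecord(
                study_id=str(row["study_id"]),
                species1_label=str(row["species1"]),
                species2_label=str(row["species2"]),
                note="; ".join(f"{c}={row[c]}" for c in extra),
                **vals,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"study table row {i + 1}: {exc}") from exc
        records.append(rec)
    return records


def classify_studies(
    records: list[StudyRecord],
    band_halfwidth: float = DEFAULT_BAND,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Normalize and classify each study; tally outcomes per region.

    Classification uses point estimates (no CIs are available for
    tabulated studies) and the supplied fixed band half-width.  Returns a
    per-study frame and a tally dict whose counts sum to ``len(records)``.
    """
    if not records:
        raise ValueError("need at least one study record")
    rows = []
    tallies = {"below_ryt": 0, "on_ryt": 0, "overyield_area_A": 0, "positive_interaction": 0}
    for rec in records:
        point = classify_region(
            RelativeYieldPoint(
                y1=rec.coexist1 / rec.alone1, y2=rec.coexist2 / rec.alone2
            ),
            band_halfwidth=band_halfwidth,
            ci_aware=False,
        )
        tallies[point.region] += 1
        rows.append(
            {
                "study_id": rec.study_id,
                "species1": rec.species1_label,
                "species2": rec.species2_label,
                "y1": point.y1,
                "y2": point.y2,
                "ryt": point.ryt,
                "region": point.region,
            }
        )
    return pd.DataFrame(rows), tallies
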