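"""Per-spore-bag records and their tabular representation.

The unit of observation throughout the package is the *spore bag* (ascus):
the sac of four genetically identical haploid spores formed by one
sporulating diploid yeast. A record carries the quantified state of one bag
(fluorescent-marker levels, glucose exposure) together with its germination
outcome. Times carry unit suffixes in the column names (minutes for
germination times, days for age) so CSV files are self-describing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import pandas as pd

#: Column dictionary for the record CSV format. Keys are the column names
#: written/expected by :mod:`sporelife.io`, values document meaning and unit.
RECORD_COLUMNS = {
    "bag_id": "unique identifier of the spore bag (string)",
    "capacity_true": "latent gene-expressing capacity, a.u. (generator-only ground truth)",
    "gfp_inducibility": "steady-state GFP level reached under doxycycline induction, a.u.",
    "rnap2_level": "nuclear Rpb3-mCherry fluorescence (RNA polymerase II proxy), a.u.",
    "rrna_level": "18S rRNA smFISH fluorescence, a.u.",
    "total_rna_rate": "5-EU incorporation fluorescence (total new RNA), a.u.",
    "glucose_pct": "glucose concentration the bag was exposed to, % w/v",
    "germinated": "whether at least one spore budded within the horizon (bool)",
    "germination_time_min": "time to germination, minutes; empty if not germinated",
    "censoring_horizon_min": "observation horizon, minutes (default 960)",
    "age_days": "days of ageing (incubation without nutrients) before the assay",
    "condition": "perturbation label: none / cycloheximide / thiolutin / ...",
    "primed": "whether the bag previously saw a sub-germinating glucose pulse (bool)",
}

MANDATORY_COLUMNS = ("bag_id", "glucose_pct", "germinated")


@dataclass
class SporeBagRecord:
    """Quantified state and germination outcome of one spore bag."""

    bag_id: str
    glucose_pct: float
    germinated: bool
    germination_time_min: Optional[float] = None
    censoring_horizon_min: float = 960.0
    capacity_true: Optional[float] = None
    gfp_inducibility: Optional[float] = None
    rnap2_level: Optional[float] = None
    rrna_level: Optional[float] = None
    total_rna_rate: Optional[float] = None
    age_days: float = 0.0
    condition: str = "none"
    primed: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.germinated and self.germination_time_min is None:
            raise ValueError(
                f"bag {self.bag_id!r}: germinated records need germination_time_min"
            )
        if not self.germinated and self.germination_time_min is not None:
            raise ValueError(
                f"bag {self.bag_id!r}: germination_time_min set on a non-germinated record"
            )
        for name in ("gfp_inducibility", "rnap2_level"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"bag {self.bag_id!r}: {name} must be >= 0")


def _field_names() -> list[str]:
    return [f.name for f in fields(SporeBagRecord) if f.name != "extra"]


def records_to_frame(records: list[SporeBagRecord]) -> pd.DataFrame:
    """Convert records to a DataFrame with one row per spore bag."""
    names = _field_names()
    rows = []
    for rec in records:
        row = {name: getattr(rec, name) for name in names}
        row.update(rec.extra)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=names if not rows else None)
    if rows:
        # keep canonical columns first, opaque extras after
        extras = [c for c in frame.columns if c not in names]
        frame = frame[names + extras]
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[SporeBagRecord]:
    """Convert a DataFrame back to typed records.

    Unknown columns are preserved in :attr:`SporeBagRecord.extra`.
    """
    names = set(_field_names())
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        extra = {}
        for col, value in row.items():
            if isinstance(value, float) and math.isnan(value):
                value = None
            if col in names:
                kwargs[col] = value
            else:
                extra[col] = value
        if kwargs.get("germination_time_min") is None:
            kwargs["germination_time_min"] = None
        kwargs["germinated"] = bool(kwargs["germinated"])
        if "primed" in kwargs and kwargs["primed"] is not None:
            kwargs["primed"] = bool(kwargs["primed"])
        records.append(SporeBagRecord(extra=extra, **kwargs))
    return records
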