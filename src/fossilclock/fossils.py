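"""Fossil calibration tables: records, epochs, and the oldest-per-clade rule.

A fossil record carries a minimum age (Ma), an optional maximum age, the name
of the clade it is assigned to, a placement mode (on the clade's stem branch
or anywhere within the crown group), membership in the small or the
large-only fossil set, and a flag saying whether the record is usable for
node dating (fossils whose node placement cannot be justified are excluded
from ND but still enter FBD analyses).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FossilRecord",
    "EpochInterval",
    "FossilTableError",
    "load_fossil_table",
    "fossil_table_frame",
    "write_fossil_table",
    "load_epoch_table",
    "select_oldest_per_clade",
    "fossils_in_set",
]

PLACEMENT_MODES = ("stem_branch", "within_clade")
SET_NAMES = ("small", "large_only")

REQUIRED_COLUMNS = ("name", "clade", "min_age_ma", "max_age_ma",
                    "placement", "set", "nd_usable")


class FossilTableError(ValueError):
    pass


@dataclass(frozen=True)
class FossilRecord:
    name: str
    clade: str
    min_age: float          # Ma; the hard minimum age a
    max_age: float | None   # Ma; optional
    placement: str          # stem_branch | within_clade
    set_membership: str     # small | large_only
    nd_usable: bool = True

    def __post_init__(self) -> None:
        if not self.min_age > 0:
            raise FossilTableError(
                f"fossil {self.name!r}: minimum age must be positive, got {self.min_age}")
        if self.max_age is not None and self.max_age < self.min_age:
            raise FossilTableError(
                f"fossil {self.name!r}: max age {self.max_age} < min age {self.min_age}")
        if self.placement not in PLACEMENT_MODES:
            raise FossilTableError(
                f"fossil {self.name!r}: unknown placement mode {self.placement!r}")
        if self.set_membership not in SET_NAMES:
            raise FossilTableError(
                f"fossil {self.name!r}: unknown set {self.set_membership!r}")

    @property
    def in_small_set(self) -> bool:
        return self.set_membership == "small"


@dataclass(frozen=True)
class EpochInterval:
    """A geological epoch's age range [min_age, max_age] in Ma."""

    name: str
    min_age: float
    max_age: float

    def __post_init__(self) -> None:
        if not (0 <= self.min_age < self.max_age):
            raise ValueError(
                f"epoch {self.name!r}: need 0 <= min < max, got "
                f"[{self.min_age}, {self.max_age}]")

    def contains(self, age: float) -> bool:
        return self.min_age <= age <= self.max_age


def load_fossil_table(source) -> list[FossilRecord]:
    """Read a tab-delimited fossil table (path, file object, or string).

    Columns: name, clade, min_age_ma, max_age_ma (may be empty), placement
    (stem_branch | within_clade), set (small | large_only), nd_usable (0/1).
    Schema errors name the offending row.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", dtype={"name": str, "clade": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise FossilTableError(f"fossil table missing columns: {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            min_age = float(row["min_age_ma"])
        except (TypeError, ValueError):
            raise FossilTableError(
                f"row {i} ({row['name']!r}): non-numeric min_age_ma {row['min_age_ma']!r}")
        raw_max = row["max_age_ma"]
        max_age = None if pd.isna(raw_max) or raw_max == "" else float(raw_max)
        try:
            records.append(FossilRecord(
                name=str(row["name"]), clade=str(row["clade"]),
                min_age=min_age, max_age=max_age,
                placement=str(row["placement"]),
                set_membership=str(row["set"]),
                nd_usable=bool(int(row["nd_usable"]))))
        except FossilTableError as exc:
            raise FossilTableError(f"row {i}: {exc}") from exc
    return records


def fossil_table_frame(records: list[FossilRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "name": [r.name for r in records],
        "clade": [r.clade for r in records],
        "min_age_ma": [r.min_age for r in records],
        "max_age_ma": [r.max_age for r in records],
        "placement": [r.placement for r in records],
        "set": [r.set_membership for r in records],
        "nd_usable": [int(r.nd_usable) for r in records],
    })


def write_fossil_table(records: list[FossilRecord]) -> str:
    return fossil_table_frame(records).to_csv(sep="\t", index=False)


def load_epoch_table(source) -> list[EpochInterval]:
    """Read a tab-delimited epoch table with columns name, min_ma, max_ma."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    missing = {"name", "min_ma", "max_ma"} - set(df.columns)
    if missing:
        raise FossilTableError(f"epoch table missing columns: {sorted(missing)}")
    return [EpochInterval(str(r["name"]), float(r["min_ma"]), float(r["max_ma"]))
            for _, r in df.iterrows()]


def fossils_in_set(records: list[FossilRecord], fossil_set: str) -> list[FossilRecord]:
    """The small set, or the large set (small + large_only)."""
    if fossil_set == "small":
        return [r for r in records if r.in_small_set]
    if fossil_set == "large":
        return list(records)
    raise ValueError(f"fossil_set must be 'small' or 'large', got {fossil_set!r}")


def select_oldest_per_clade(records: list[FossilRecord],
                            nd_mode: bool = True) -> list[FossilRecord]:
    """Node dating can use only one fossil per calibration node.

    In ND mode, drop records flagged unusable for node dating, then keep the
    single oldest (largest minimum age) fossil per clade. Age ties within a
    clade are broken lexicographically by fossil name (with a warning). In
    FBD mode every fossil is a tip and the input is returned unchanged.
    """
    if not nd_mode:
        return list(records)
    usable = [r for r in records if r.nd_usable]
    best: dict[str, FossilRecord] = {}
    for rec in usable:
        cur = best.get(rec.clade)
        if cur is None or rec.min_age > cur.min_age:
            best[rec.clade] = rec
        elif rec.min_age == cur.min_age and rec.name != cur.name:
            keep = min(cur, rec, key=lambda r: r.name)
            warnings.warn(
                f"clade {rec.clade!r}: fossils {cur.name!r} and {rec.name!r} "
                f"tie at {rec.min_age} Ma; keeping {keep.name!r}")
            best[rec.clade] = keep
    # preserve input order
    chosen = {id(r) for r in best.values()}
    return [r for r in usable if id(r) in chosen]
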