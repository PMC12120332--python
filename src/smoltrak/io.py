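"""Readers, validation and filtering for the five study tables.

Conventions used across the pipeline: timestamps are UTC (ISO-8601 in CSV),
distances are river-kilometres downstream of the release site (0 at
release), and CSVs are comma-separated with a header row.  A column-name
mapping can absorb local dialects on read.

Column schemas for all tables are documented under ``schemas/`` at the
repository root.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources

import pandas as pd

DETECTION_COLUMNS = ["tag_code", "receiver_id", "timestamp"]
FISH_COLUMNS = [
    "fish_id", "tag_code", "river", "year", "release_datetime",
    "fork_length_mm", "mass_g", "tag_mass_g", "release_site_km",
]
RECEIVER_COLUMNS = ["river", "year", "role", "receiver_id", "river_km", "elevation_m"]
DISCHARGE_COLUMNS = ["river", "year", "date", "discharge_m3s"]
CATCHMENT_COLUMNS = [
    "river", "grassland", "woodland", "wetland", "urban", "agricultural",
    "peat", "bedrock", "area_km2", "gradient", "barriers",
]


class ValidationError(ValueError):
    """Raised when an input table fails record-level validation."""


def _read(path, required, rename=None, parse_ts=()):
    df = pd.read_csv(path)
    if rename:
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    for col in parse_ts:
        parsed = pd.to_datetime(df[col], errors="coerce", utc=True, format="mixed")
        bad = df.index[parsed.isna() & df[col].notna()].tolist()
        if bad:
            raise ValidationError(f"{path}: unparseable {col} at rows {bad[:20]}")
        df[col] = parsed
    return df


def read_detections(path, rename=None) -> pd.DataFrame:
    return _read(path, DETECTION_COLUMNS, rename, parse_ts=("timestamp",))


def read_fish(path, rename=None) -> pd.DataFrame:
    return _read(path, FISH_COLUMNS, rename, parse_ts=("release_datetime",))


def read_receivers(path, rename=None) -> pd.DataFrame:
    df = _read(path, RECEIVER_COLUMNS, rename)
    validate_receivers(df)
    return df


def read_discharge(path, rename=None) -> pd.DataFrame:
    return _read(path, DISCHARGE_COLUMNS, rename, parse_ts=("date",))


def read_catchments(path, rename=None) -> pd.DataFrame:
    return _read(path, CATCHMENT_COLUMNS, rename)


def validate_receivers(receivers: pd.DataFrame) -> None:
    """Enforce the two-audit-receiver design per river-year.

    Exactly one ``first`` and one ``last`` receiver per river-year, with the
    last strictly downstream of the first.
    """
    for (river, year), grp in receivers.groupby(["river", "year"]):
        roles = grp["role"].value_counts()
        if roles.get("first", 0) != 1 or roles.get("last", 0) != 1:
            raise ValidationError(
                f"{river} {year}: need exactly one 'first' and one 'last' receiver, got {dict(roles)}"
            )
        first_km = float(grp.loc[grp["role"] == "first", "river_km"].iloc[0])
        last_km = float(grp.loc[grp["role"] == "last", "river_km"].iloc[0])
        if not last_km > first_km:
            raise ValidationError(
                f"{river} {year}: last receiver ({last_km} km) must be downstream of first ({first_km} km)"
            )


@dataclass
class FilterReport:
    """Counts of raw detection records removed, by defect class."""

    n_input: int = 0
    duplicates: int = 0
    out_of_window: int = 0
    unknown_tag: int = 0
    retained: int = 0

    @property
    def removed(self) -> int:
        return self.duplicates + self.out_of_window + self.unknown_tag

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self) | {"removed": self.removed}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def filter_detections(raw: pd.DataFrame, fish: pd.DataFrame, window=None):
    """Clean a raw detection download.

    Removes, in order: tag codes not present in the tagging table, records
    outside the study window, and exact (tag_code, receiver_id, timestamp)
    duplicates (the first occurrence is kept).  Input order is otherwise
    preserved.  Returns ``(clean, FilterReport)``.

    ``window`` is a ``(start, end)`` pair; if omitted it defaults to
    [first release, last detection] of the supplied tables.
    """
    report = FilterReport(n_input=len(raw))
    if len(raw) == 0:
        return raw.copy(), report

    ts = raw["timestamp"]
    if not pd.api.types.is_datetime64_any_dtype(ts):
        parsed = pd.to_datetime(ts, errors="coerce", utc=True, format="mixed")
        bad = raw.index[parsed.isna() & ts.notna()].tolist()
        if bad:
            raise ValidationError(f"unparseable timestamps at rows {bad[:20]}")
        raw = raw.assign(timestamp=parsed)

    if window is None:
        start = pd.to_datetime(fish["release_datetime"], utc=True).min()
        end = raw["timestamp"].max()
    else:
        start, end = (pd.Timestamp(w) for w in window)
        if start.tz is None:
            start = start.tz_localize("UTC")
        if end.tz is None:
            end = end.tz_localize("UTC")
    if not start < end:
        raise ValidationError(f"study window start {start} must precede end {end}")

    known = set(fish["tag_code"])
    keep_known = raw["tag_code"].isin(known)
    report.unknown_tag = int((~keep_known).sum())
    df = raw[keep_known]

    in_window = (df["timestamp"] >= start) & (df["timestamp"] <= end)
    report.out_of_window = int((~in_window).sum())
    df = df[in_window]

    dup = df.duplicated(subset=["tag_code", "receiver_id", "timestamp"], keep="first")
    report.duplicates = int(dup.sum())
    df = df[~dup]

    report.retained = len(df)
    return df.reset_index(drop=True), report


def drop_incomplete_biometrics(fish: pd.DataFrame) -> pd.DataFrame:
    """Remove fish missing either fork length or mass.

    Applies only to the individual-success analysis path; population
    summaries keep every tagged fish (entry there is detection-based).
    """
    ok = fish["fork_length_mm"].notna() & fish["mass_g"].notna()
    return fish[ok].reset_index(drop=True)


def _load_packaged(name: str) -> pd.DataFrame:
    with resources.files("smoltrak.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_cohort_summaries() -> pd.DataFrame:
    """Per-cohort (river x year) tagging summaries from the source study:
    counts, biometric means/SDs, condition and tag-burden means/SDs."""
    return _load_packaged("cohort_summaries.csv")


def load_migration_summaries() -> pd.DataFrame:
    """Per-cohort migration outcomes from the source study: migration
    success, rate of migration success (proportion km^-1), speed mean/SD."""
    return _load_packaged("migration_summaries.csv")
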