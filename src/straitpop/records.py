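"""Capture-event and effort-log data model, CSV round-trip, and per-occasion
mark-recapture aggregation.

Events are held as a pandas DataFrame with a fixed column schema
(:data:`CAPTURE_EVENT_COLUMNS`). Each row is one capture or recapture of one
animal: tag id (absent for animals captured once and removed untagged), ISO
date, subregion, WGS84 coordinates, event kind, release flag, and optional
sex / prosomal width / gear metadata.

Aggregation follows the closed-population bookkeeping used by multi-occasion
estimators: within a subregion and calendar year, occasions are the calendar
months containing at least one event, and each occasion t carries

* ``C_t`` - all capture events in the month,
* ``M_t`` - marked animals at large just before the month,
* ``R_t`` - recapture events whose tag was marked in an earlier occasion,
* ``U_t`` - newly tagged-and-released animals,

with the recurrence ``M_{t+1} = M_t + U_t``. Untagged first captures are
removals and never enter the marked pool. Tags marked in earlier years seed
``M_1`` of a later year when cross-year carryover is enabled (the default:
adults are long-lived and tagged animals are assumed to suffer no natural
mortality over the study).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from straitpop.errors import ConsistencyError, SchemaError, ValidationError

SUBREGIONS = ("Kinmen", "Penghu", "TaiwanMain")
EVENT_KINDS = ("first_capture_tagged", "first_capture_untagged", "recapture")
SEXES = ("F", "M", "unknown")
EFFORT_UNITS = ("person_time", "net_set")

#: Effort-unit convention per subregion (Penghu logs net sets, the others
#: person-times).
EFFORT_UNIT_BY_SUBREGION = {
    "Kinmen": "person_time",
    "Penghu": "net_set",
    "TaiwanMain": "person_time",
}

CAPTURE_EVENT_COLUMNS = [
    "tag_id",
    "event_date",
    "subregion",
    "latitude",
    "longitude",
    "event_kind",
    "released",
    "sex",
    "prosomal_width_cm",
    "gear",
]

#: Columns that must be present and non-null in every row.
_REQUIRED = ["event_date", "subregion", "latitude", "longitude", "event_kind", "released"]

EFFORT_COLUMNS = ["subregion", "year", "month", "effort_amount", "effort_unit"]


@dataclass(frozen=True)
class OccasionRecord:
    """Per-occasion mark-recapture aggregates (1-based occasion index)."""

    t: int
    C: int
    M: int
    R: int
    U: int

    def __post_init__(self):
        if not (0 <= self.R <= self.C):
            raise ValueError(f"occasion {self.t}: R={self.R} outside [0, C={self.C}]")
        if self.U > self.C - self.R:
            raise ValueError(f"occasion {self.t}: U={self.U} > C-R={self.C - self.R}")


@dataclass
class OccasionSeries:
    """Ordered occasions for one subregion within one closed period (year)."""

    subregion: str
    stratum: int
    occasions: list[OccasionRecord] = field(default_factory=list)
    #: (year, month) label per occasion, parallel to ``occasions``.
    months: list[tuple[int, int]] = field(default_factory=list)

    def totals(self) -> dict[str, int]:
        """Annual roll-up: total captured, newly marked and recaptured."""
        return {
            "captured": sum(o.C for o in self.occasions),
            "marked": sum(o.U for o in self.occasions),
            "recaptured": sum(o.R for o in self.occasions),
        }


def _empty_events() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in CAPTURE_EVENT_COLUMNS})
    df["latitude"] = df["latitude"].astype(float)
    df["longitude"] = df["longitude"].astype(float)
    df["prosomal_width_cm"] = df["prosomal_width_cm"].astype(float)
    df["released"] = df["released"].astype(bool)
    return df


def validate_capture_events(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Validate an event table against the data-model invariants.

    Returns the cleaned table (invalid rows dropped, sorted by subregion and
    date) and the list of row-level error messages. Raises
    :class:`SchemaError` if a required column is missing entirely.
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy().reset_index(drop=True)
    for c in CAPTURE_EVENT_COLUMNS:
        if c not in df.columns:
            df[c] = None
    df = df[CAPTURE_EVENT_COLUMNS]

    errors: list[str] = []
    bad = np.zeros(len(df), dtype=bool)
    idx = np.arange(len(df))

    dates = pd.to_datetime(df["event_date"], errors="coerce", format="ISO8601")
    for i in idx[dates.isna().to_numpy()]:
        errors.append(f"row {i}: unparseable event_date {df['event_date'].iloc[i]!r}")
        bad[i] = True
    df["event_date"] = dates

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    for i in idx[(lat.isna() | lon.isna()).to_numpy()]:
        if not bad[i]:
            errors.append(f"row {i}: unparseable coordinate")
            bad[i] = True
    with np.errstate(invalid="ignore"):
        out_lat = (lat < -90) | (lat > 90)
        out_lon = (lon < -180) | (lon > 180)
    for i in idx[out_lat.fillna(False).to_numpy()]:
        errors.append(f"row {i}: latitude {lat.iloc[i]} outside [-90, 90]")
        bad[i] = True
    for i in idx[out_lon.fillna(False).to_numpy()]:
        errors.append(f"row {i}: longitude {lon.iloc[i]} outside [-180, 180]")
        bad[i] = True
    df["latitude"] = lat
    df["longitude"] = lon

    for i in idx[~df["subregion"].isin(SUBREGIONS).to_numpy()]:
        errors.append(f"row {i}: unknown subregion {df['subregion'].iloc[i]!r}")
        bad[i] = True
    for i in idx[~df["event_kind"].isin(EVENT_KINDS).to_numpy()]:
        errors.append(f"row {i}: unknown event_kind {df['event_kind'].iloc[i]!r}")
        bad[i] = True

    tag = df["tag_id"].astype(object)
    tag = tag.where(~tag.isin([np.nan, None, ""]), None)
    df["tag_id"] = tag
    no_tag_recap = (df["event_kind"] == "recapture") & tag.isna()
    for i in idx[no_tag_recap.to_numpy()]:
        errors.append(f"row {i}: recapture without a tag_id")
        bad[i] = True

    rel = df["released"]
    if rel.dtype != bool:
        rel = rel.astype(str).str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        for i in idx[rel.isna().to_numpy()]:
            if not bad[i]:
                errors.append(f"row {i}: unparseable released flag")
                bad[i] = True
        df["released"] = rel.fillna(False).astype(bool)
    # untagged first captures contribute removals by definition
    untagged_released = (df["event_kind"] == "first_capture_untagged") & df["released"]
    for i in idx[untagged_released.to_numpy()]:
        errors.append(f"row {i}: first_capture_untagged must have released=false (removal)")
        bad[i] = True

    sex = df["sex"].astype(object).where(df["sex"].notna(), "unknown")
    sex = sex.where(sex.isin(SEXES), "unknown")
    df["sex"] = sex

    pw = pd.to_numeric(df["prosomal_width_cm"], errors="coerce")
    for i in idx[(pw < 0).fillna(False).to_numpy()]:
        errors.append(f"row {i}: negative prosomal_width_cm")
        bad[i] = True
    df["prosomal_width_cm"] = pw

    # recapture must follow an earlier event with the same tag
    clean = df.loc[~bad]
    first_seen = clean.groupby("tag_id", dropna=True)["event_date"].min()
    is_recap = (clean["event_kind"] == "recapture").to_numpy()
    for i, (tag_i, date_i) in zip(
        clean.index[is_recap],
        clean.loc[is_recap, ["tag_id", "event_date"]].itertuples(index=False),
    ):
        if tag_i not in first_seen.index or not (first_seen[tag_i] < date_i):
            errors.append(
                f"row {i}: recapture of tag {tag_i!r} with no earlier event for that tag"
            )
            bad[i] = True

    out = df.loc[~bad].sort_values(
        ["subregion", "event_date"], kind="stable"
    ).reset_index(drop=True)
    if out.empty:
        out = _empty_events()
    return out, errors


def read_capture_events(
    path, *, delimiter: str = ",", on_error: str = "raise"
) -> pd.DataFrame:
    """Read and validate a capture-event CSV.

    Parameters
    ----------
    path
        Delimited text file with a header naming the event fields.
    delimiter
        Field separator (default comma).
    on_error
        ``"raise"`` (default) raises :class:`ValidationError` if any row is
        invalid; ``"drop"`` drops invalid rows and stores the messages in
        ``df.attrs["row_errors"]``.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=object, encoding="utf-8")
    events, errors = validate_capture_events(raw)
    if errors and on_error == "raise":
        raise ValidationError(errors)
    events.attrs["row_errors"] = errors
    return events


def write_capture_events(events: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    """Write a validated event table as delimited text (lossless round-trip
    with :func:`read_capture_events`)."""
    out = events.copy()
    out["event_date"] = pd.to_datetime(out["event_date"]).dt.strftime("%Y-%m-%d")
    out["released"] = out["released"].map({True: "true", False: "false"})
    out[CAPTURE_EVENT_COLUMNS].to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_effort_records(path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read an effort log (one row per subregion-month)."""
    df = pd.read_csv(path, sep=delimiter, encoding="utf-8")
    missing = [c for c in EFFORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing effort column(s): {', '.join(missing)}")
    errors = []
    for i, row in df.iterrows():
        if not row["effort_amount"] > 0:
            errors.append(f"row {i}: effort_amount must be positive")
        if row["effort_unit"] not in EFFORT_UNITS:
            errors.append(f"row {i}: unknown effort_unit {row['effort_unit']!r}")
        expected = EFFORT_UNIT_BY_SUBREGION.get(row["subregion"])
        if expected and row["effort_unit"] != expected:
            errors.append(
                f"row {i}: {row['subregion']} logs effort in {expected}, "
                f"got {row['effort_unit']!r}"
            )
    if errors:
        raise ValidationError(errors)
    return df[EFFORT_COLUMNS]


def write_effort_records(efforts: pd.DataFrame, path, *, delimiter: str = ",") -> None:
    efforts[EFFORT_COLUMNS].to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def build_occasions(
    events: pd.DataFrame, *, carryover: bool = True
) -> dict[tuple[str, int], OccasionSeries]:
    """Aggregate validated events into per-(subregion, year) occasion series.

    Occasions are calendar months containing at least one event; each year is
    one closed period. With ``carryover`` (default), tags marked in earlier
    years of the same subregion seed ``M_1`` of later years and their
    recaptures count in ``R_t``; without it, each year starts from an empty
    marked pool and cross-year recaptures are not counted as marked.

    Raises :class:`ConsistencyError` if a recapture references a tag that was
    never marked anywhere in the table.
    """
    out: dict[tuple[str, int], OccasionSeries] = {}
    if events.empty:
        return out

    ev = events.copy()
    ev["event_date"] = pd.to_datetime(ev["event_date"])
    ev["_year"] = ev["event_date"].dt.year
    ev["_month"] = ev["event_date"].dt.month

    marked_month = {}  # (subregion, tag) -> (year, month) first marked
    tagged = ev[ev["event_kind"] == "first_capture_tagged"]
    for sub, tag_i, y, m in tagged[["subregion", "tag_id", "_year", "_month"]].itertuples(
        index=False
    ):
        key = (sub, tag_i)
        if key not in marked_month or (y, m) < marked_month[key]:
            marked_month[key] = (y, m)

    recaps = ev[ev["event_kind"] == "recapture"]
    unknown = sorted(
        {t for s, t in zip(recaps["subregion"], recaps["tag_id"]) if (s, t) not in marked_month}
    )
    if unknown:
        raise ConsistencyError(
            f"recapture of tag(s) never marked: {', '.join(map(str, unknown))}"
        )

    for (sub, year), grp in ev.groupby(["subregion", "_year"], sort=True):
        series = OccasionSeries(subregion=sub, stratum=int(year))
        if carryover:
            m_pool = sum(
                1 for (s, _), (y, _m) in marked_month.items() if s == sub and y < year
            )
        else:
            m_pool = 0
        for t, ((_, month), mgrp) in enumerate(
            grp.groupby(["_year", "_month"], sort=True), start=1
        ):
            C = len(mgrp)
            U = int((mgrp["event_kind"] == "first_capture_tagged").sum())
            R = 0
            for tag_i in mgrp.loc[mgrp["event_kind"] == "recapture", "tag_id"]:
                my, mm = marked_month[(sub, tag_i)]
                if (my == year and mm < month) or (carryover and my < year):
                    R += 1
            series.occasions.append(OccasionRecord(t=t, C=C, M=m_pool, R=R, U=U))
            series.months.append((int(year), int(month)))
            m_pool += U
        out[(sub, int(year))] = series
    return out
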