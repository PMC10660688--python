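"""Minute-epoch actigraphy I/O, quality filtering, and aggregation.

Input is one record per (participant, day, minute) carrying an activity
value and a per-epoch state label in {wake, sleep, nonwear, unknown}.  A
valid day has at least 20 h (1200 minutes) of wake+sleep data, and a
participant enters the analysis only with at least 4 valid days.  Activity
is aggregated to 5-min bins (anchored at midnight, half-open
[5b, 5b+5) minutes); non-wear and unknown minutes are excluded from bin
means rather than zero-filled, since zero-filling would deflate mesor
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STATES", "ParticipantSeries", "read_epochs", "write_epochs",
    "normalize_nhanes_minutes", "classify_valid_days", "select_participants",
    "aggregate_5min", "behavioral_covariates", "build_participant_series",
    "derive_rar_profiles",
]

STATES = ("wake", "sleep", "nonwear", "unknown")
MIN_WAKE_SLEEP_MINUTES = 1200  # 20 h
MIN_VALID_DAYS = 4

EPOCH_COLUMNS = ["participant_id", "day_index", "minute_of_day", "activity", "state"]

#: NHANES minute-file (PAXMIN-like) column map; predicted-state codes
#: 1=wake, 2=sleep, 3=nonwear, anything else -> unknown
NHANES_COLUMNS = {"SEQN": "participant_id", "PAXDAYM": "day_index",
                  "PAXMTSM": "activity", "PAXPREDM": "state"}
NHANES_STATE_CODES = {1: "wake", 2: "sleep", 3: "nonwear"}
SAMPLES_PER_MINUTE = 80 * 60  # 80 Hz accelerometer samples per minute


@dataclass
class ParticipantSeries:
    """One participant's quality-filtered series, ready for rhythm fitting."""

    participant_id: object
    valid_days: list
    bins_5min: pd.DataFrame  # columns: day_index, bin_5min, activity
    sleep_minutes_per_day: float
    total_activity: float

    def __post_init__(self):
        if len(self.valid_days) < MIN_VALID_DAYS:
            raise ValueError(
                f"participant {self.participant_id}: {len(self.valid_days)} valid "
                f"days, need >= {MIN_VALID_DAYS}")


def _validate_epochs(df: pd.DataFrame) -> pd.DataFrame:
    dup = df.duplicated(["participant_id", "day_index", "minute_of_day"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["participant_id", "day_index", "minute_of_day"]]
        raise ValueError(
            "duplicated epoch key (participant_id=%s, day_index=%s, minute_of_day=%s)"
            % tuple(key))
    minute = df["minute_of_day"]
    if ((minute < 0) | (minute >= 1440)).any():
        bad = int(minute[(minute < 0) | (minute >= 1440)].iloc[0])
        raise ValueError(f"minute_of_day out of range [0, 1440): {bad}")
    df = df.copy()
    df["state"] = df["state"].where(df["state"].isin(STATES), "unknown")
    # non-wear activity is treated as missing for all averaging
    df.loc[df["state"] == "nonwear", "activity"] = np.nan
    return df[EPOCH_COLUMNS]


def read_epochs(source, dialect: str = "csv") -> pd.DataFrame:
    """Read a minute-epoch file into the canonical epoch schema.

    ``dialect='csv'``: the package CSV dialect (columns participant_id,
    day_index, minute_of_day, activity, state).  ``dialect='xpt'``: a
    SAS-transport NHANES-like minute file (SEQN, PAXDAYM, PAXSSNMP, PAXMTSM,
    PAXPREDM).  Both produce identical EpochRecord streams.
    """
    if dialect == "csv":
        try:
            df = pd.read_csv(source)
        except pd.errors.ParserError as exc:
            raise ValueError(f"unparseable epoch file: {exc}") from exc
        missing = set(EPOCH_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"epoch CSV missing columns: {sorted(missing)}")
    elif dialect == "xpt":
        df = normalize_nhanes_minutes(pd.read_sas(source, format="xport"))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'csv' or 'xpt')")
    df["day_index"] = df["day_index"].astype(np.int64)
    df["minute_of_day"] = df["minute_of_day"].astype(np.int64)
    df["activity"] = pd.to_numeric(df["activity"], errors="coerce")
    return _validate_epochs(df)


def normalize_nhanes_minutes(df: pd.DataFrame) -> pd.DataFrame:
    """Map an NHANES-like minute table onto the canonical epoch schema."""
    out = df.rename(columns=NHANES_COLUMNS).copy()
    if "minute_of_day" not in out.columns:
        if "PAXSSNMP" not in out.columns:
            raise ValueError("need PAXSSNMP (start sample) or minute_of_day")
        out["minute_of_day"] = (
            out["PAXSSNMP"].astype(np.int64) // SAMPLES_PER_MINUTE) % 1440
    out["state"] = (pd.to_numeric(out["state"], errors="coerce")
                    .map(NHANES_STATE_CODES).fillna("unknown"))
    return out[EPOCH_COLUMNS]


def write_epochs(df: pd.DataFrame, path) -> None:
    """Write epochs in the package CSV dialect (round-trips with read_epochs)."""
    df[EPOCH_COLUMNS].to_csv(path, index=False)


def classify_valid_days(records: pd.DataFrame) -> pd.DataFrame:
    """Per (participant, day) validity: >= 1200 minutes of wake+sleep data."""
    ws = records["state"].isin(["wake", "sleep"])
    counts = (records.assign(ws=ws)
              .groupby(["participant_id", "day_index"], sort=True)["ws"].sum()
              .reset_index(name="wake_sleep_minutes"))
    counts["valid"] = counts["wake_sleep_minutes"] >= MIN_WAKE_SLEEP_MINUTES
    return counts


def select_participants(validity: pd.DataFrame) -> list:
    """Participants with at least 4 valid days of measurement."""
    n_valid = validity.groupby("participant_id")["valid"].sum()
    return sorted(n_valid[n_valid >= MIN_VALID_DAYS].index.tolist())


def _valid_subset(records: pd.DataFrame, validity: pd.DataFrame) -> pd.DataFrame:
    valid_keys = validity.loc[validity["valid"], ["participant_id", "day_index"]]
    return records.merge(valid_keys, on=["participant_id", "day_index"])


def aggregate_5min(records: pd.DataFrame, validity: pd.DataFrame) -> pd.DataFrame:
    """5-min bin means over valid days, excluding non-wear/unknown minutes.

    Bin b of a day covers minutes [5b, 5b+5); its value is the mean of the
    non-missing activity among wake/sleep minutes in the bin, or missing if
    all five minutes are excluded.
    """
    sub = _valid_subset(records, validity)
    sub = sub[sub["state"].isin(["wake", "sleep"])]
    sub = sub.assign(bin_5min=sub["minute_of_day"] // 5)
    bins = (sub.groupby(["participant_id", "day_index", "bin_5min"], sort=True)
            ["activity"].mean().reset_index())
    return bins


def behavioral_covariates(records: pd.DataFrame, validity: pd.DataFrame) -> pd.DataFrame:
    """Sleep duration (min/day) and total activity (sum/day), averaged over valid days."""
    sub = _valid_subset(records, validity)
    ws = sub["state"].isin(["wake", "sleep"])
    tmp = sub.assign(
        sleep_minutes=(sub["state"] == "sleep").astype(float),
        ws_activity=sub["activity"].where(ws, 0.0).fillna(0.0))
    per_day = (tmp.groupby(["participant_id", "day_index"], sort=True)
               [["sleep_minutes", "ws_activity"]].sum().reset_index())
    return (per_day.groupby("participant_id")[["sleep_minutes", "ws_activity"]]
            .mean().reset_index()
            .rename(columns={"sleep_minutes": "sleep_duration",
                             "ws_activity": "total_activity"}))


def build_participant_series(records: pd.DataFrame) -> list:
    """Filter, aggregate and package every eligible participant's series."""
    validity = classify_valid_days(records)
    eligible = select_participants(validity)
    bins = aggregate_5min(records, validity)
    behav = behavioral_covariates(records, validity).set_index("participant_id")
    out = []
    for pid in eligible:
        v = validity[(validity["participant_id"] == pid) & validity["valid"]]
        out.append(ParticipantSeries(
            participant_id=pid,
            valid_days=v["day_index"].tolist(),
            bins_5min=bins[bins["participant_id"] == pid].reset_index(drop=True),
            sleep_minutes_per_day=float(behav.loc[pid, "sleep_duration"]),
            total_activity=float(behav.loc[pid, "total_activity"]),
        ))
    return out


def derive_rar_profiles(records: pd.DataFrame, min_obs: int = 576) -> pd.DataFrame:
    """Full per-participant rhythm parameter table from raw minute epochs.

    Applies the valid-day/participant filters, fits the extended cosine model
    and the nonparametric metrics, and returns one row per eligible
    participant with the seven rest-activity parameters plus the behavioral
    covariates.  Non-converged fits are flagged and excluded downstream.
    """
    from .cosinor import ExtendedCosineModel
    from .nonparametric import hourly_series, interdaily_stability, \
        intradaily_variability, l5_midpoint

    validity = classify_valid_days(records)
    eligible = select_participants(validity)
    bins = aggregate_5min(records, validity)
    behav = behavioral_covariates(records, validity).set_index("participant_id")

    rows = []
    for pid in eligible:
        b = bins[bins["participant_id"] == pid]
        try:
            fit = ExtendedCosineModel.from_bins(b, min_obs=min_obs).fit()
        except ValueError:
            continue
        hours = hourly_series(b)
        l5_mid, l5_act = l5_midpoint(b)
        row = {"participant_id": pid,
               "IS": interdaily_stability(hours),
               "IV": intradaily_variability(hours),
               "l5_midpoint": l5_mid, "l5_mean_activity": l5_act,
               "sleep_duration": float(behav.loc[pid, "sleep_duration"]),
               "total_activity": float(behav.loc[pid, "total_activity"])}
        row.update(fit.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
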