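"""Message corpus: the in-memory container for geolocated message streams.

A corpus is a pandas DataFrame with one row per message and a fixed schema:

==============  =======================================================
column          meaning
==============  =======================================================
user_id         opaque author token (never echoed into reports)
message_id      opaque unique message token
time_utc        UTC timestamp (datetime64[ns, UTC])
utc_offset_min  local-time offset in minutes (nullable; diurnal use only)
lat, lon        WGS84 decimal degrees
text            message text
is_checkin      location-share flag (set by the filtering stage)
==============  =======================================================

Messages are kept sorted by (user_id, time_utc).  The interchange format is
line-delimited JSON, one message per line; CSV is supported as a secondary
dialect.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Corpus", "read_messages", "write_messages", "write_table", "read_table"]

REQUIRED_FIELDS = ("user_id", "message_id", "time_utc", "lat", "lon", "text")
COLUMNS = [
    "user_id",
    "message_id",
    "time_utc",
    "utc_offset_min",
    "lat",
    "lon",
    "text",
    "is_checkin",
]


class Corpus:
    """Geolocated messages grouped by author.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per message with at least the required schema columns.
        Copied, coerced, validated and sorted by (user_id, time_utc).
    """

    def __init__(self, frame: pd.DataFrame):
        df = frame.copy()
        for col in REQUIRED_FIELDS:
            if col not in df.columns:
                if len(df) == 0:
                    df[col] = pd.Series(dtype=object)
                else:
                    raise ValueError(f"corpus frame missing required column {col!r}")
        if "utc_offset_min" not in df.columns:
            df["utc_offset_min"] = np.nan
        if "is_checkin" not in df.columns:
            df["is_checkin"] = False
        df["user_id"] = df["user_id"].astype(str)
        df["message_id"] = df["message_id"].astype(str)
        df["time_utc"] = pd.to_datetime(df["time_utc"], utc=True)
        df["utc_offset_min"] = pd.to_numeric(df["utc_offset_min"], errors="coerce")
        df["lat"] = pd.to_numeric(df["lat"])
        df["lon"] = pd.to_numeric(df["lon"])
        df["text"] = df["text"].astype(str)
        df["is_checkin"] = df["is_checkin"].astype(bool)

        if len(df):
            bad_lat = ~df["lat"].between(-90.0, 90.0)
            bad_lon = ~df["lon"].between(-180.0, 180.0)
            if bad_lat.any() or bad_lon.any():
                raise ValueError(
                    f"{int((bad_lat | bad_lon).sum())} messages with lat/lon out of range"
                )
            if df["message_id"].duplicated().any():
                raise ValueError("duplicate message_id in corpus")

        df = df.sort_values(["user_id", "time_utc"], kind="mergesort").reset_index(drop=True)
        self.frame = df[COLUMNS]
        self.n_malformed = 0  # set by read_messages

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_messages(self) -> int:
        return len(self.frame)

    @property
    def users(self) -> list[str]:
        return self.frame["user_id"].unique().tolist()

    @property
    def n_users(self) -> int:
        return self.frame["user_id"].nunique()

    def message_counts(self) -> pd.Series:
        """Per-user message count N^(a), indexed by user_id."""
        return self.frame.groupby("user_id", sort=True).size()

    def user(self, user_id: str) -> pd.DataFrame:
        return self.frame[self.frame["user_id"] == user_id]

    def iter_users(self):
        """Yield (user_id, frame) pairs, time-sorted within user."""
        yield from self.frame.groupby("user_id", sort=True)

    def subset_users(self, user_ids: Iterable[str]) -> "Corpus":
        keep = set(map(str, user_ids))
        return Corpus(self.frame[self.frame["user_id"].isin(keep)])

    def subset_messages(self, mask) -> "Corpus":
        return Corpus(self.frame[np.asarray(mask, dtype=bool)])


def _record_from_json(line: str) -> dict | None:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError:
        return None
    if not isinstance(rec, dict):
        return None
    return rec


def _validate_record(rec: dict) -> str | None:
    """Return a reason string if the record is malformed, else None."""
    for field in REQUIRED_FIELDS:
        if field not in rec or rec[field] is None:
            return f"missing field {field!r}"
    try:
        lat = float(rec["lat"])
        lon = float(rec["lon"])
    except (TypeError, ValueError):
        return "non-numeric coordinates"
    if not (-90.0 <= lat <= 90.0):
        return f"lat out of range: {lat}"
    if not (-180.0 <= lon <= 180.0):
        return f"lon out of range: {lon}"
    try:
        if pd.isna(pd.to_datetime(rec["time_utc"], utc=True)):
            return "unparseable timestamp"
    except (ValueError, TypeError, OverflowError):
        return "unparseable timestamp"
    return None


def read_messages(path: str | Path, dialect: str = "jsonl") -> Corpus:
    """Read a message file into a Corpus, skipping (and counting) malformed records.

    Parameters
    ----------
    path : file location
    dialect : {"jsonl", "csv"}
        Line-delimited JSON (default) or comma-separated with a header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    records: list[dict] = []
    n_malformed = 0
    if dialect == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = _record_from_json(line)
                reason = "unparseable line" if rec is None else _validate_record(rec)
                if reason is not None:
                    n_malformed += 1
                    logger.warning("skipping malformed record: %s", reason)
                    continue
                records.append(rec)
    elif dialect == "csv":
        raw = pd.read_csv(path, dtype={"user_id": str, "message_id": str})
        for rec in raw.to_dict(orient="records"):
            reason = _validate_record(rec)
            if reason is not None:
                n_malformed += 1
                logger.warning("skipping malformed record: %s", reason)
                continue
            records.append(rec)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if records:
        frame = pd.DataFrame.from_records(records)
    else:
        frame = pd.DataFrame(columns=list(REQUIRED_FIELDS))
    corpus = Corpus(frame)
    corpus.n_malformed = n_malformed
    return corpus


def write_messages(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as line-delimited JSON; round-trips through read_messages."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus.frame.to_dict(orient="records"):
            out = {
                "user_id": rec["user_id"],
                "message_id": rec["message_id"],
                "time_utc": rec["time_utc"].isoformat(),
                "utc_offset_min": None
                if pd.isna(rec["utc_offset_min"])
                else int(rec["utc_offset_min"]),
                "lat": rec["lat"],
                "lon": rec["lon"],
                "text": rec["text"],
                "is_checkin": bool(rec["is_checkin"]),
            }
            fh.write(json.dumps(out, ensure_ascii=False) + "\n")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a header line."""
    rows.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
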