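"""Readers and writers for the pipeline's table formats.

All tables are plain text: long-format CSV for volumes, cryosection
counts and observations; tab-delimited probe x sample matrices with
per-sample ``gIsWellAboveBG_*`` flag columns for expression (Agilent
feature-extraction style); JSON for parameter sets, fit results and run
manifests.  Readers validate schemas and report malformed rows by line
number.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observations import ObservationSet

VOLUME_COLUMNS = ("mouse_id", "cohort", "condition", "day", "volume_mm3")
CRYO_COLUMNS = ("image_id", "day", "g1_count", "sgm_count", "ctl_count")


class FormatError(ValueError):
    """Schema or content violation in an input file."""


def _read_csv(path, required) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: no data") from None
    if df.empty:
        raise FormatError(f"{path}: no data")
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def _bad_rows(df: pd.DataFrame, mask) -> str:
    # +2: header line and 1-based numbering
    lines = [str(i + 2) for i in df.index[mask]]
    return ", ".join(lines)


def read_volumes(path) -> pd.DataFrame:
    df = _read_csv(path, VOLUME_COLUMNS)
    bad = ~(pd.to_numeric(df["volume_mm3"], errors="coerce") > 0)
    if bad.any():
        raise FormatError(
            f"{path}: nonpositive or non-numeric volume at lines {_bad_rows(df, bad)}")
    return df


def read_cryosections(path) -> pd.DataFrame:
    df = _read_csv(path, CRYO_COLUMNS)
    for col in ("g1_count", "sgm_count", "ctl_count"):
        bad = pd.to_numeric(df[col], errors="coerce") < 0
        bad |= pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            raise FormatError(
                f"{path}: invalid {col} at lines {_bad_rows(df, bad)}")
    return df


def read_observations(path) -> ObservationSet:
    df = _read_csv(path, ("observable", "day", "mean", "sd", "include"))
    sd = pd.to_numeric(df["sd"], errors="coerce")
    bad = df["include"].astype(bool) & ~(sd > 0)
    if bad.any():
        raise FormatError(
            f"{path}: included rows need sd > 0 at lines {_bad_rows(df, bad)}")
    df["reason"] = df.get("reason", "").fillna("") if "reason" in df else ""
    for col in ("day_start", "day_end"):
        if col not in df:
            df[col] = np.nan
    if "n" not in df:
        df["n"] = 1
    if "condition" not in df:
        df["condition"] = "treated"
    return ObservationSet(df)


def write_observations(obs: ObservationSet, path) -> None:
    obs.to_csv(path)


def write_expression(values: pd.DataFrame, flags: pd.DataFrame, path) -> None:
    """Tab-delimited probe x sample matrix with per-sample flag columns."""
    out = pd.DataFrame(index=values.index)
    for col in values.columns:
        out[col] = values[col]
        out[f"gIsWellAboveBG_{col}"] = flags[col].astype(int)
    out.to_csv(path, sep="\t")


def read_expression(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: no data")
    flag_cols = [c for c in df.columns if c.startswith("gIsWellAboveBG_")]
    value_cols = [c for c in df.columns if not c.startswith("gIsWellAboveBG_")]
    expected = {f"gIsWellAboveBG_{c}" for c in value_cols}
    if expected != set(flag_cols):
        raise FormatError(f"{path}: flag columns do not match sample columns")
    values = df[value_cols]
    flags = df[flag_cols].rename(
        columns=lambda c: c.removeprefix("gIsWellAboveBG_"))
    return values, flags[value_cols]


def write_json(doc: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
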