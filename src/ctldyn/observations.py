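"""Observation container for multi-modal time-series fitting.

All experimental observables are summarised into one long-format table
(one row per observable per timepoint per condition) holding the mean,
standard deviation and replication of the measurement plus an inclusion
flag.  Growth-rate observations are interval-based and carry their
interval endpoints alongside the midpoint day.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

OBSERVABLES = ("ctl_density", "growth_rate", "ifng", "ratio_sgm_g1",
               "pdcd1", "cd274", "lag3", "havcr2")

EXPRESSION_OBSERVABLES = ("ifng", "pdcd1", "cd274", "lag3", "havcr2")

COLUMNS = ("observable", "day", "day_start", "day_end", "mean", "sd", "n",
           "condition", "include", "reason")

STUDY_HORIZON = (-1.0, 14.0)


@dataclass
class ObservationSet:
    """Per-observable time series of means and standard deviations."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        unknown = set(df["observable"]) - set(OBSERVABLES)
        if unknown:
            raise ValueError(f"unknown observables: {sorted(unknown)}")
        bad_day = df[(df["day"] < STUDY_HORIZON[0]) | (df["day"] > STUDY_HORIZON[1])]
        if len(bad_day):
            raise ValueError(
                f"days outside study horizon at rows {bad_day.index.tolist()}")
        included = df[df["include"].astype(bool)]
        bad_mean = included[~np.isfinite(included["mean"].astype(float))]
        if len(bad_mean):
            raise ValueError(
                f"included observations need finite means; offending rows "
                f"{bad_mean.index.tolist()}")
        bad_sd = included[~(included["sd"] > 0)]
        if len(bad_sd):
            raise ValueError(
                f"included observations need sd > 0; offending rows "
                f"{bad_sd.index.tolist()}")
        excluded = df[~df["include"].astype(bool)]
        if (excluded["reason"].astype(str).str.len() == 0).any():
            raise ValueError("excluded observations must carry a reason code")
        self.data = df.reset_index(drop=True)

    def included(self) -> pd.DataFrame:
        return self.data[self.data["include"].astype(bool)]

    def subset(self, observables=None, condition=None) -> "ObservationSet":
        df = self.data
        if observables is not None:
            df = df[df["observable"].isin(observables)]
        if condition is not None:
            df = df[df["condition"] == condition]
        return ObservationSet(df.copy())

    def content_hash(self) -> str:
        payload = self.data[list(COLUMNS)].round(12).to_csv(index=False)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- I/O ---------------------------------------------------------

    def to_csv(self, path) -> None:
        self.data[list(COLUMNS)].to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ObservationSet":
        df = pd.read_csv(path)
        if df.empty:
            raise ValueError(f"no data in observation file {path}")
        df["reason"] = df["reason"].fillna("")
        return cls(df)


def make_row(observable: str, day: float, mean: float, sd: float, n: int,
             condition: str = "treated", include: bool = True,
             reason: str = "", day_start: float = np.nan,
             day_end: float = np.nan) -> dict:
    """Convenience constructor for one observation row."""
    return {"observable": observable, "day": day, "day_start": day_start,
            "day_end": day_end, "mean": mean, "sd": sd, "n": n,
            "condition": condition, "include": include, "reason": reason}
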