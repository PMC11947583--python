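"""Event-record (NONMEM-style) flat datasets for the microdialysis trial.

One row per event. Dosing rows have EVID=1 with AMT (mg) and RATE (mg/h);
observation rows have EVID=0 with DV and a stream code DVID:

====  ======================  ===========================================
DVID  stream                  extra columns
====  ======================  ===========================================
1     plasma total            --
2     plasma unbound          --
3     microdialysate          ISTART/IEND interval bounds, CATH (1/2)
4     retrodialysate          ISTART/IEND, CATH, PERF (perfusate, mg/L)
====  ======================  ===========================================

Covariate columns (SEX, AGE, TBW, HT, OBESE, LBW, FM, BMI, EGFR) are repeated
on every row of a subject, as is conventional for these flat files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DVID_PLASMA_TOTAL = 1
DVID_PLASMA_UNBOUND = 2
DVID_MICRODIALYSATE = 3
DVID_RETRODIALYSATE = 4

DVID_STREAM = {
    DVID_PLASMA_TOTAL: "plasma",
    DVID_PLASMA_UNBOUND: "plasma",
    DVID_MICRODIALYSATE: "microdialysate",
    DVID_RETRODIALYSATE: "retrodialysate",
}

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "EVID", "DV", "DVID",
    "ISTART", "IEND", "CATH", "PERF",
    "SEX", "AGE", "TBW", "HT", "OBESE", "LBW", "FM", "BMI", "EGFR",
]


class DatasetError(ValueError):
    """Raised when an event-record dataset fails validation."""


def validate_dataset(df: pd.DataFrame) -> None:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"dataset lacks columns {missing}")
    if not set(df["EVID"].unique()) <= {0, 1}:
        raise DatasetError("EVID must be 0 (observation) or 1 (dose)")
    obs = df[df["EVID"] == 0]
    bad = set(obs["DVID"].unique()) - set(DVID_STREAM)
    if bad:
        raise DatasetError(f"unrecognised DVID codes {sorted(bad)}")
    for sid, sub in df.groupby("ID"):
        if not (sub["EVID"] == 1).any():
            raise DatasetError(f"subject {sid} has no dosing event")
        dial = sub[(sub["EVID"] == 0) & sub["DVID"].isin([3, 4])]
        if dial["ISTART"].isna().any() or dial["IEND"].isna().any():
            raise DatasetError(f"subject {sid}: dialysate records need ISTART/IEND")
        if (dial["IEND"] <= dial["ISTART"]).any():
            raise DatasetError(f"subject {sid}: dialysate intervals must have IEND > ISTART")
    if (df.loc[df["EVID"] == 1, "AMT"] <= 0).any():
        raise DatasetError("dose amounts must be positive")


def write_dataset(df: pd.DataFrame, path) -> None:
    validate_dataset(df)
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_dataset(df)
    return df


def subject_regimen_events(sub: pd.DataFrame) -> list[tuple[float, float, float]]:
    """(start, amount, duration) tuples from a subject's dosing rows."""
    doses = sub[sub["EVID"] == 1]
    events = []
    for _, row in doses.iterrows():
        amt = float(row["AMT"])
        rate = float(row["RATE"])
        if rate <= 0:
            raise DatasetError("dose rows need a positive RATE")
        events.append((float(row["TIME"]), amt, amt / rate))
    return events


def dose_row(sid, time, amt, rate, cov: dict) -> dict:
    row = dict.fromkeys(COLUMNS, np.nan)
    row.update(ID=sid, TIME=time, AMT=amt, RATE=rate, EVID=1, **cov)
    return row


def obs_row(sid, time, dv, dvid, cov: dict, istart=np.nan, iend=np.nan,
            cath=np.nan, perf=np.nan) -> dict:
    row = dict.fromkeys(COLUMNS, np.nan)
    row.update(
        ID=sid, TIME=time, EVID=0, DV=dv, DVID=dvid,
        ISTART=istart, IEND=iend, CATH=cath, PERF=perf, **cov,
    )
    return row
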