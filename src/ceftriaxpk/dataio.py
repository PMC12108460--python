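"""NONMEM-style dataset reader/writer.

One CSV row per event. Dosing rows have ``MDV = 1``, ``AMT`` (mg) and
``RATE`` (mg/h); ``II`` (h) and ``ADDL`` describe additional identical
doses and are expanded to explicit events on read. Observation rows have
``MDV = 0`` and ``DV`` (free concentration, mg/L) or an empty ``DV`` with
``BLQ = 1``. Covariates (CRCL, BMI, AGE, WT, SEX) are constant within an
ID. Times are hours since the first dose of the episode.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import EpisodeRecord
from .population import Covariates

__all__ = ["COLUMNS", "read_dataset", "write_dataset"]

COLUMNS = [
    "ID", "TIME", "DV", "MDV", "AMT", "RATE", "II", "ADDL", "BLQ",
    "CRCL", "BMI", "AGE", "WT", "SEX",
]


class DatasetError(ValueError):
    """Schema or consistency violation in a dataset file."""


def _fail(row: int, column: str, msg: str) -> None:
    raise DatasetError(f"row {row}, column {column}: {msg}")


def read_dataset(path: str | Path) -> list[EpisodeRecord]:
    """Read and validate a NONMEM-style CSV into episode records.

    ``ADDL``/``II`` are expanded into explicit dosing events; infusion
    duration is derived as ``AMT / RATE``. Raises :class:`DatasetError`
    naming the offending row and column on schema violations.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing columns: {missing}")

    records = []
    for eid, g in df.groupby("ID", sort=False):
        g = g.reset_index()
        times = g["TIME"].to_numpy(dtype=float)
        if np.any(times < 0):
            _fail(int(g["index"][np.argmax(times < 0)]) + 2, "TIME", "negative time")
        if np.any(np.diff(times) < 0):
            bad = int(np.argmax(np.diff(times) < 0)) + 1
            _fail(int(g["index"][bad]) + 2, "TIME", "times decrease within ID")
        for col in ("CRCL", "BMI", "AGE", "WT", "SEX"):
            vals = g[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                _fail(int(g["index"][int(np.argmax(np.isnan(vals)))]) + 2, col,
                      "missing covariate")
            if np.unique(vals).size > 1:
                _fail(int(g["index"][0]) + 2, col, "covariate varies within ID")
        cov = Covariates(
            crcl=float(g["CRCL"].iloc[0]),
            bmi=float(g["BMI"].iloc[0]),
            age=float(g["AGE"].iloc[0]),
            weight=float(g["WT"].iloc[0]),
            sex=int(g["SEX"].iloc[0]),
        )

        dose_t, dose_amt, dose_rate = [], [], []
        obs_t, obs_dv, obs_blq = [], [], []
        for _, r in g.iterrows():
            csv_row = int(r["index"]) + 2  # header + 1-based
            mdv = int(r["MDV"])
            if mdv == 1:
                amt, rate = float(r["AMT"]), float(r["RATE"])
                if not amt > 0:
                    _fail(csv_row, "AMT", "dosing row needs AMT > 0")
                if not rate > 0:
                    _fail(csv_row, "RATE", "dosing row needs RATE > 0")
                addl = int(r["ADDL"]) if np.isfinite(r["ADDL"]) else 0
                ii = float(r["II"]) if np.isfinite(r["II"]) else 0.0
                if addl > 0 and ii <= 0:
                    _fail(csv_row, "II", "ADDL > 0 requires II > 0")
                for k in range(addl + 1):
                    dose_t.append(float(r["TIME"]) + k * ii)
                    dose_amt.append(amt)
                    dose_rate.append(rate)
            elif mdv == 0:
                blq = int(r["BLQ"]) if np.isfinite(r["BLQ"]) else 0
                dv = float(r["DV"])
                if np.isnan(dv) and blq != 1:
                    _fail(csv_row, "DV", "observation row needs DV or BLQ = 1")
                obs_t.append(float(r["TIME"]))
                obs_dv.append(np.nan if blq == 1 else dv)
                obs_blq.append(bool(blq))
            else:
                _fail(csv_row, "MDV", f"MDV must be 0 or 1, got {mdv}")
        if not obs_t:
            raise DatasetError(f"ID {eid}: no observation rows")
        if not dose_t:
            raise DatasetError(f"ID {eid}: no dosing rows")

        order = np.argsort(dose_t, kind="stable")
        dt = np.asarray(dose_t)[order]
        dur = np.asarray(dose_amt)[order] / np.asarray(dose_rate)[order]
        if np.any(dt[:-1] + dur[:-1] > dt[1:] + 1e-9):
            import warnings

            warnings.warn(f"ID {eid}: overlapping infusions", stacklevel=2)
        records.append(
            EpisodeRecord(
                episode_id=str(eid),
                covariates=cov,
                dose_times=dt,
                dose_amounts=np.asarray(dose_amt)[order],
                dose_rates=np.asarray(dose_rate)[order],
                obs_times=np.asarray(obs_t),
                obs_conc=np.asarray(obs_dv),
                obs_blq=np.asarray(obs_blq),
            )
        )
    return records


def write_dataset(records: list[EpisodeRecord], path: str | Path) -> None:
    """Write episode records as canonical NONMEM-style CSV.

    Explicit dosing events (no ADDL compression), canonical column order,
    6-decimal formatting, rows sorted by time within episode with dose
    rows before observation rows at equal times.
    """
    rows = []
    for rec in records:
        c = rec.covariates
        covs = {"CRCL": c.crcl, "BMI": c.bmi, "AGE": c.age, "WT": c.weight, "SEX": c.sex}
        for t, amt, rate in zip(rec.dose_times, rec.dose_amounts, rec.dose_rates):
            rows.append({"ID": rec.episode_id, "TIME": t, "DV": np.nan, "MDV": 1,
                         "AMT": amt, "RATE": rate, "II": 0.0, "ADDL": 0, "BLQ": 0,
                         "_k": 0, **covs})
        for t, dv, blq in zip(rec.obs_times, rec.obs_conc, rec.obs_blq):
            rows.append({"ID": rec.episode_id, "TIME": t,
                         "DV": np.nan if blq else dv, "MDV": 0,
                         "AMT": 0.0, "RATE": 0.0, "II": 0.0, "ADDL": 0,
                         "BLQ": int(blq), "_k": 1, **covs})
    df = pd.DataFrame(rows)
    df = df.sort_values(["ID", "TIME", "_k"], kind="stable").drop(columns="_k")
    df = df[COLUMNS]
    df.to_csv(path, index=False, float_format="%.6f")
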