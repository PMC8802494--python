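"""Delimited-text readers and writers.

IPD files carry columns ``time,status,group`` (comma or tab, autodetected).
Digitized-curve files carry ``time,survival``; risk tables carry
``time,n_risk`` — the output shape of common plot digitizers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import SurvivalSample
from .reconstruct import ArmDigitization, DigitizedInput

__all__ = ["read_ipd", "write_ipd", "read_digitized_arm", "read_digitized"]


def _read_table(path) -> pd.DataFrame:
    # sniff comma vs tab from the header, then parse with the C engine's
    # round-trip float conversion (the default parsers lose the last bits)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_ipd(path) -> SurvivalSample:
    """Read subject-level data with header columns time,status,group."""
    df = _read_table(path)
    missing = {"time", "status", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return SurvivalSample(df["time"].to_numpy(float),
                          df["status"].to_numpy(),
                          df["group"].to_numpy())


def write_ipd(sample: SurvivalSample, path) -> None:
    # %.17g keeps the round trip bit-exact for double-precision times
    pd.DataFrame({"time": sample.time,
                  "status": sample.status,
                  "group": sample.group}).to_csv(path, index=False,
                                                 float_format="%.17g")


def read_digitized_arm(curve_path, risk_path, total_events: int | None = None) -> ArmDigitization:
    """Read one arm's digitized curve (time,survival) and risk table (time,n_risk)."""
    curve = _read_table(curve_path)
    risk = _read_table(risk_path)
    for col in ("time", "survival"):
        if col not in curve.columns:
            raise ValueError(f"curve file missing column {col!r}")
    for col in ("time", "n_risk"):
        if col not in risk.columns:
            raise ValueError(f"risk table missing column {col!r}")
    return ArmDigitization(
        curve_times=curve["time"].to_numpy(float),
        curve_surv=curve["survival"].to_numpy(float),
        risk_times=risk["time"].to_numpy(float),
        risk_counts=risk["n_risk"].to_numpy(int),
        total_events=total_events,
    )


def read_digitized(curve1, risk1, curve2, risk2,
                   total_events1: int | None = None,
                   total_events2: int | None = None) -> DigitizedInput:
    """Read a two-arm digitized input from two file pairs."""
    return DigitizedInput(
        arm1=read_digitized_arm(curve1, risk1, total_events1),
        arm2=read_digitized_arm(curve2, risk2, total_events2),
    )
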