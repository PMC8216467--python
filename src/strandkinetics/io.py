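"""CSV / YAML interfaces.

Trace files are plain CSV with a ``time_s`` column and one column per
well role (``reaction``, ``pre_activated``, ``negative``,
``background``); melt files have ``temp_C``, ``f_melt``, ``f_pos``,
``f_bkgnd``. Experiment structure (which files belong together, their
concentrations in nM, replicate groups, condition labels) lives in a
YAML manifest; simulation ground truth goes into a YAML sidecar so that
round-trip recovery tests can read it back.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .melt import MeltCurve
from .traces import ROLES, FluorescenceTrace

TRACE_TIME_COL = "time_s"
MELT_COLS = ("temp_C", "f_melt", "f_pos", "f_bkgnd")


def write_well_csv(path, wells: dict) -> None:
    """Write one experiment's wells (dict role -> FluorescenceTrace) as CSV."""
    path = Path(path)
    roles = [r for r in ROLES if r in wells]
    times = wells[roles[0]].times
    for r in roles[1:]:
        if not np.array_equal(wells[r].times, times):
            raise ValueError(f"well {r!r} is not on the shared time grid")
    df = pd.DataFrame({TRACE_TIME_COL: times})
    for r in roles:
        df[r] = wells[r].values
    df.to_csv(path, index=False)


def read_well_csv(path) -> dict:
    """Read an experiment CSV back into a dict role -> FluorescenceTrace."""
    path = Path(path)
    df = pd.read_csv(path)
    if TRACE_TIME_COL not in df.columns:
        raise ValueError(f"{path}: missing required column {TRACE_TIME_COL!r}")
    times = df[TRACE_TIME_COL].to_numpy(float)
    wells = {}
    for role in ROLES:
        if role in df.columns:
            wells[role] = FluorescenceTrace(times, df[role].to_numpy(float),
                                            role=role, label=f"{path.stem}:{role}")
    missing = {"reaction", "pre_activated", "negative"} - set(wells)
    if missing:
        raise ValueError(f"{path}: missing well columns {sorted(missing)}")
    return wells


def write_melt_csv(path, curve: MeltCurve) -> None:
    pd.DataFrame({
        "temp_C": curve.temps, "f_melt": curve.f_melt,
        "f_pos": curve.f_pos, "f_bkgnd": curve.f_bkgnd,
    }).to_csv(path, index=False)


def read_melt_csv(path, ct: float) -> MeltCurve:
    """Read a melt CSV; ``ct`` (molar) comes from the manifest."""
    df = pd.read_csv(path)
    missing = set(MELT_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing melt columns {sorted(missing)}")
    return MeltCurve(temps=df["temp_C"].to_numpy(float),
                     f_melt=df["f_melt"].to_numpy(float),
                     f_pos=df["f_pos"].to_numpy(float),
                     f_bkgnd=df["f_bkgnd"].to_numpy(float), ct=ct)


def save_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=True))


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())
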