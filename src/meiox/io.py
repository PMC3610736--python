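"""CSV/JSON/YAML readers and writers and table-style report rendering.

Trace CSV dialect: comma separator, "." decimal, UTF-8, mandatory header
``time_h,o2_umol_l,chamber_id,is_blank``. Readers validate hard (missing
columns, negative O2 and non-monotone times are data errors naming the
offending rows); rows may arrive in any order and are sorted by time
within each chamber.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    ChamberConfig,
    ChamberTrace,
    MonodFit,
    SaturationRates,
    TraceDataError,
)

__all__ = [
    "read_traces",
    "write_traces",
    "render_table1",
    "fit_report_row",
    "load_yaml_config",
]

TRACE_COLUMNS = ["time_h", "o2_umol_l", "chamber_id", "is_blank"]


def read_traces(path: Union[str, Path]) -> List[ChamberTrace]:
    """Read chamber traces from CSV, grouped by chamber, blanks flagged."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceDataError(f"{path}: missing required columns {missing}")
    bad = df.index[df["o2_umol_l"] < 0].tolist()
    if bad:
        raise TraceDataError(
            f"{path}: negative O2 at data rows {[i + 2 for i in bad]}"
        )
    traces = []
    for cid, grp in df.groupby("chamber_id", sort=True):
        grp = grp.sort_values("time_h")
        times = grp["time_h"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(times) <= 0)
        if dup.size:
            rows = [int(grp.index[i + 1]) + 2 for i in dup]
            raise TraceDataError(
                f"{path}: chamber {cid!r} has duplicate/non-increasing "
                f"times at data rows {rows}"
            )
        traces.append(
            ChamberTrace(
                times_h=times,
                o2_umol_l=grp["o2_umol_l"].to_numpy(dtype=float),
                chamber_id=str(cid),
                is_blank=bool(grp["is_blank"].iloc[0]),
            )
        )
    return traces


def write_traces(traces: Sequence[ChamberTrace], path: Union[str, Path]) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_h": tr.times_h,
                "o2_umol_l": tr.o2_umol_l,
                "chamber_id": tr.chamber_id,
                "is_blank": tr.is_blank,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def fit_report_row(
    label: str,
    fit: MonodFit,
    rates: SaturationRates,
    biomass_ugC: Optional[float] = None,
) -> Dict[str, float]:
    """One report row mirroring the coefficient-table layout."""
    p = fit.params
    return {
        "treatment": label,
        "k_s": p.k_s,
        "o2_init": p.o2_init,
        "o2_min": p.o2_min,
        "biomass_ugC": biomass_ugC,
        "r_100": rates.r_100,
        "r_10": rates.r_10,
        "r_1": rates.r_1,
    }


def render_table1(rows: Sequence[Dict[str, float]]) -> pd.DataFrame:
    """Coefficient-table report: 2-decimal coefficients, 3-decimal rates.

    Accepts rows from :func:`fit_report_row` (or equivalent dicts) and
    returns a formatted string DataFrame; an empty input yields a
    header-only frame.
    """
    cols = ["treatment", "k_s", "o2_init", "o2_min", "biomass_ugC", "r_100", "r_10", "r_1"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(list(rows))[cols]
    out = df.copy()
    for c in ("k_s", "o2_init", "o2_min", "biomass_ugC"):
        out[c] = df[c].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.2f}")
    for c in ("r_100", "r_10", "r_1"):
        out[c] = df[c].map(lambda v: "" if v is None or pd.isna(v) else f"{v:.3f}")
    return out


def load_yaml_config(path: Union[str, Path]) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return cfg
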