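"""CSV/JSON readers and writers and the monitoring run report.

Interval-valued cells are stored as two plain columns (``*_lo``, ``*_hi``)
rather than packed strings, so every file round-trips through pandas with no
delimiter ambiguity.  Reports print 2 decimals to match the usual tabular
presentation; machine-readable JSON keeps full precision.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from typing import Optional

import numpy as np
import pandas as pd

from .chart import MonitorResult, MovingAverageChart
from .datasets import SubgroupSeries

__all__ = [
    "read_subgroup_csv",
    "write_subgroup_csv",
    "write_profile_csv",
    "RunReport",
    "build_report",
]


def _library_version() -> str:
    try:
        return _pkg_version("nmachart")
    except Exception:  # pragma: no cover - not installed
        return "unknown"


def subgroups_to_frame(series: SubgroupSeries) -> pd.DataFrame:
    if series.lower.shape != series.upper.shape:
        raise ValueError("CSV dialect requires equal subgroup sizes per endpoint")
    m, n = series.lower.shape
    data: dict[str, np.ndarray] = {"sr": np.arange(1, m + 1)}
    for j in range(n):
        data[f"obs{j + 1}_lo"] = series.lower[:, j]
        data[f"obs{j + 1}_hi"] = series.upper[:, j]
    return pd.DataFrame(data)


def write_subgroup_csv(series: SubgroupSeries, path) -> None:
    subgroups_to_frame(series).to_csv(path, index=False)


def read_subgroup_csv(path) -> SubgroupSeries:
    """Read paired-endpoint subgroup data (columns sr, obs1_lo, obs1_hi, ...)."""
    frame = pd.read_csv(path)
    lo_cols = [c for c in frame.columns if c.endswith("_lo")]
    hi_cols = [c for c in frame.columns if c.endswith("_hi")]
    if not lo_cols or len(lo_cols) != len(hi_cols):
        raise ValueError(
            f"{path}: expected paired obs<i>_lo / obs<i>_hi columns, "
            f"got {list(frame.columns)}"
        )
    for cols in (lo_cols, hi_cols):
        block = frame[cols]
        bad = block.isna().any(axis=1) | ~block.map(np.isfinite).all(axis=1)
        if bad.any():
            row = int(frame.index[bad][0]) + 2  # 1-based + header line
            raise ValueError(f"{path}: malformed or missing value in row {row}")
    return SubgroupSeries(
        lower=frame[lo_cols].to_numpy(float), upper=frame[hi_cols].to_numpy(float)
    )


def write_profile_csv(
    lower: pd.DataFrame, upper: pd.DataFrame, path
) -> pd.DataFrame:
    """Merge per-endpoint shift profiles into the published CSV dialect.

    Columns: c, arl_lower, sdrl_lower, arl_upper, sdrl_upper, se_lower,
    se_upper, censored (summed over endpoints).
    """
    merged = pd.DataFrame(
        {
            "c": lower["c"],
            "arl_lower": lower["arl"],
            "sdrl_lower": lower["sdrl"],
            "arl_upper": upper["arl"],
            "sdrl_upper": upper["sdrl"],
            "se_lower": lower["se"],
            "se_upper": upper["se"],
            "censored": lower["censored"] + upper["censored"],
        }
    )
    merged.to_csv(path, index=False)
    return merged


@dataclass
class RunReport:
    """Reproducible record of one paired-endpoint monitoring run."""

    config: dict
    table: pd.DataFrame
    first_signal_lower: Optional[int]
    first_signal_upper: Optional[int]
    seed: Optional[int] = None
    version: str = field(default_factory=_library_version)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_text(self) -> str:
        lines = [
            f"nmachart {self.version} monitoring report ({self.timestamp})",
            f"config: {json.dumps(self.config, sort_keys=True)}",
            "",
            self.table.round(2).to_string(index=False),
            "",
            f"first signal (lower endpoint): {self.first_signal_lower}",
            f"first signal (upper endpoint): {self.first_signal_upper}",
        ]
        return "\n".join(lines)

    def to_json(self) -> str:
        payload = {
            "config": self.config,
            "version": self.version,
            "timestamp": self.timestamp,
            "first_signal_lower": self.first_signal_lower,
            "first_signal_upper": self.first_signal_upper,
            "table": self.table.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=2)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.2f")


def build_report(
    series: SubgroupSeries,
    lower_chart: MovingAverageChart,
    upper_chart: MovingAverageChart,
    seed: Optional[int] = None,
) -> RunReport:
    """Monitor both endpoints of ``series`` with fitted charts and tabulate."""
    res_lo: MonitorResult = lower_chart.monitor(series.lower)
    res_hi: MonitorResult = upper_chart.monitor(series.upper)
    m = series.m
    table = pd.DataFrame(
        {
            "sr": np.arange(1, m + 1),
            "ma_lower": res_lo.ma_values,
            "ma_upper": res_hi.ma_values,
            "lcl_lower": lower_chart.limits_.lcl,
            "ucl_lower": lower_chart.limits_.ucl,
            "lcl_upper": upper_chart.limits_.lcl,
            "ucl_upper": upper_chart.limits_.ucl,
            "flag_lower": res_lo.flags,
            "flag_upper": res_hi.flags,
        }
    )
    config = {
        "lower": {k: v for k, v in lower_chart.get_params().items()},
        "upper": {k: v for k, v in upper_chart.get_params().items()},
        "theta0_lower": lower_chart.theta0_,
        "theta0_upper": upper_chart.theta0_,
        "m": m,
    }
    return RunReport(
        config=config,
        table=table,
        first_signal_lower=res_lo.first_signal,
        first_signal_upper=res_hi.first_signal,
        seed=seed,
    )
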