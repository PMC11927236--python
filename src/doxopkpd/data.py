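"""Reading, cleaning and averaging of replicate cell-count time series.

The in vitro design exposes MM1R cultures to a doxorubicin bolus (one arm per
dose, including an untreated control), then measures CFDA-SE fluorescence per
well every 24 h; a standard curve converts fluorescence to living-cell
counts. Conversion of low fluorescence signals can produce negative or
spurious zero counts, so cleaned series are obtained by an explicit exclusion
rule before per-time averaging with Student-t confidence intervals.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REQUIRED_COLUMNS",
    "StandardCurve",
    "ExclusionReport",
    "read_experiment",
    "fit_standard_curve",
    "fluorescence_to_count",
    "filter_unrealistic",
    "average_series",
]

logger = logging.getLogger(__name__)

#: Column schema of a replicate-level experiment table.
REQUIRED_COLUMNS = ("arm_nM", "time_h", "replicate", "count")


@dataclass(frozen=True)
class StandardCurve:
    """Linear fluorescence-to-cell-count conversion: count = slope·fluor + intercept."""

    slope: float  # cells per fluorescence unit
    intercept: float  # cells

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("StandardCurve.slope must be strictly positive")


def fit_standard_curve(calibration: pd.DataFrame) -> StandardCurve:
    """Least-squares line through (fluorescence, cells) calibration pairs.

    Parameters
    ----------
    calibration : DataFrame
        Columns ``fluorescence`` and ``cells``; at least two distinct
        fluorescence values are required.
    """
    x = np.asarray(calibration["fluorescence"], dtype=float)
    y = np.asarray(calibration["cells"], dtype=float)
    if x.size < 2:
        raise ValueError("calibration needs at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all fluorescence values equal")
    res = stats.linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept))


def fluorescence_to_count(fluor, curve: StandardCurve):
    """Convert fluorescence signal(s) to cell counts.

    The conversion does not censor: low signals may map to negative counts,
    which the exclusion filter removes downstream.
    """
    out = curve.slope * np.asarray(fluor, dtype=float) + curve.intercept
    return float(out) if np.isscalar(fluor) else out


def read_experiment(path: str | Path, calibration: str | Path | None = None) -> pd.DataFrame:
    """Read a replicate-level CSV of cell counts (or fluorescence signals).

    Expects columns ``arm_nM, time_h, replicate, count``; alternatively
    ``fluorescence`` instead of ``count`` together with a ``calibration`` CSV
    of (fluorescence, cells) pairs, in which case counts are derived via the
    fitted standard curve. Rows with unparseable numeric fields are dropped
    with a logged warning naming the row numbers.
    """
    path = Path(path)
    df = pd.read_csv(path)
    has_fluor = "fluorescence" in df.columns and "count" not in df.columns
    needed = ("arm_nM", "time_h", "replicate", "fluorescence" if has_fluor else "count")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s): {', '.join(missing)}")
    if has_fluor:
        if calibration is None:
            raise ValueError("fluorescence input requires a calibration file")
        curve = fit_standard_curve(pd.read_csv(calibration))
        df["count"] = fluorescence_to_count(df["fluorescence"].to_numpy(float), curve)
        value_col = "fluorescence"
    else:
        value_col = "count"
    for col in ("arm_nM", "time_h", value_col):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["arm_nM", "time_h", value_col]].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # +2: header + 1-based file rows
        logger.warning("%s: dropped %d unparseable row(s) at file line(s) %s", path.name, bad.sum(), rows)
        df = df.loc[~bad]
    out = df[["arm_nM", "time_h", "replicate", "count"]].reset_index(drop=True)
    out["count"] = out["count"].astype(float)
    return out


@dataclass
class ExclusionReport:
    """What the unrealistic-record filter removed and why."""

    excluded: pd.DataFrame  # dropped rows with a 'reason' column
    per_arm_pct: dict[float, float]  # % of the arm's records excluded

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)

    def summary(self) -> dict:
        return {
            "n_excluded": int(self.n_excluded),
            "per_arm_pct": {str(k): float(v) for k, v in self.per_arm_pct.items()},
        }

    def to_csv(self, path: str | Path) -> None:
        self.excluded.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


def filter_unrealistic(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop physically implausible counts from replicate series.

    Two rules, applied per (arm, replicate) series sorted by time:

    1. any negative count is excluded;
    2. any zero count measured earlier than some later nonzero count in the
       same series is excluded (a well cannot be empty and later repopulate;
       such zeros are conversion artifacts of low fluorescence).

    Trailing zeros (no later nonzero measurement) are kept. The operation is
    idempotent.
    """
    records = records.sort_values(["arm_nM", "replicate", "time_h"], kind="stable").reset_index(
        drop=True
    )
    counts = records["count"].to_numpy(float)
    drop = counts < 0
    reason = np.where(drop, "negative count", "").astype(object)
    for _, idx in records.groupby(["arm_nM", "replicate"], sort=False).indices.items():
        c = counts[idx]
        later_nonzero = np.zeros(c.size, dtype=bool)
        # later_nonzero[i]: does any strictly later sample have a nonzero count?
        later_nonzero[:-1] = (c[::-1] != 0).cumsum()[::-1][1:] > 0
        early_zero = (c == 0) & later_nonzero
        drop[idx] |= early_zero
        reason[idx] = np.where(
            early_zero & (reason[idx] == ""), "zero before nonzero", reason[idx]
        )
    excluded = records.loc[drop].copy()
    excluded["reason"] = reason[drop]
    kept = records.loc[~drop].reset_index(drop=True)
    pct = {
        float(arm): 100.0 * drop[grp.index.to_numpy()].mean()
        for arm, grp in records.groupby("arm_nM")
    }
    report = ExclusionReport(excluded=excluded.reset_index(drop=True), per_arm_pct=pct)
    return kept, report


def average_series(records: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Per-(arm, time) mean counts with Student-t confidence intervals.

    Returns a tidy frame with columns ``arm_nM, time_h, n, mean, sd, sem,
    ci_low, ci_high``. The interval is the symmetric t-interval on the mean,
    ``mean ± t_{n−1, 1−α/2}·sd/√n``. Time points with a single retained
    replicate are kept but flagged by NaN interval bounds (a t-quantile needs
    n ≥ 2); time points with no retained records are simply absent.
    """
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    grouped = records.groupby(["arm_nM", "time_h"])["count"]
    out = grouped.agg(n="size", mean="mean", sd="std").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    tq = stats.t.ppf(0.5 + confidence / 2.0, out["n"] - 1)
    half = tq * out["sem"]
    out["ci_low"] = out["mean"] - half
    out["ci_high"] = out["mean"] + half
    return out.sort_values(["arm_nM", "time_h"]).reset_index(drop=True)
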