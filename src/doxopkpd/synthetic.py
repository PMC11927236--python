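"""Synthetic replicate-level datasets with the structure of the in vitro study.

Each experimental arm receives a single 3 h doxorubicin bolus ending at the
pharmacodynamic time origin (t = 0), after which fluorescence-derived cell
counts are taken every 24 h out to 456 h. The generator simulates the PK/PD
model per arm, then draws replicate counts with multiplicative lognormal
noise (positive counts, spread roughly proportional to scale, as in the real
fluorescence-converted data). Control wells carry ~3× as many replicates as
treated wells. Optional "artifact" records — negative counts and spurious
early zeros from low-signal conversion — exercise the exclusion filter, and
first-sample noise can be inflated to mimic the unreliable initial
measurement seen in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import StandardCurve
from .model import predict_arm_counts
from .params import PDParams, PKParams

__all__ = ["DesignSpec", "NoiseSpec", "generate_dataset", "generate_calibration"]

#: (arm_nM, time_h) pairs absent from the real design (external measurement failures).
DEFAULT_MISSING = frozenset({(20.0, 120.0), (20.0, 288.0), (50.0, 120.0), (50.0, 288.0)})


@dataclass(frozen=True)
class DesignSpec:
    """Layout of the dosing/sampling design to emulate."""

    arms: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 50.0, 200.0, 450.0, 900.0)
    exposure_h: float = 3.0
    sample_interval_h: float = 24.0
    horizon_h: float = 456.0
    replicates_control: int = 12
    replicates_treated: int = 4
    missing: frozenset[tuple[float, float]] = DEFAULT_MISSING
    artifact_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.horizon_h % self.sample_interval_h:
            raise ValueError("horizon must be a multiple of the sampling interval")
        if min(self.replicates_control, self.replicates_treated) < 1:
            raise ValueError("replicate counts must be >= 1")
        if not 0.0 <= self.artifact_rate < 1.0:
            raise ValueError("artifact_rate must be in [0, 1)")

    @property
    def sample_times(self) -> np.ndarray:
        return np.arange(0.0, self.horizon_h + 0.5 * self.sample_interval_h, self.sample_interval_h)

    def replicates_for(self, arm: float) -> int:
        return self.replicates_control if arm == 0.0 else self.replicates_treated


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: multiplicative lognormal with unit mean.

    ``cv`` is the coefficient of variation of the multiplier; ``cv = 0``
    reproduces the model trajectory exactly. ``first_sample_factor`` inflates
    the cv of the t = 0 sample (the initial measurement is unreliable in the
    real assay); set it to 1 to disable.
    """

    cv: float = 0.2
    first_sample_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.first_sample_factor < 1:
            raise ValueError("first_sample_factor must be >= 1")


def _lognormal_multiplier(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=size)


def _arm_trajectory(
    pk: PKParams, pd_: PDParams, design: DesignSpec, arm: float, times: np.ndarray
) -> np.ndarray:
    """Noise-free mean counts for one arm at the sampling times."""
    return predict_arm_counts(
        pk, pd_, dose=arm, times=times, n0=pd_.n0_for(arm), exposure_h=design.exposure_h
    )


def generate_dataset(
    pk: PKParams | None = None,
    pd_: PDParams | None = None,
    design: DesignSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    return_artifacts: bool = False,
):
    """Draw a replicate-level dataset from the PK/PD model.

    Per arm, the model is simulated from the start of exposure (t = −3 h,
    bolus at the arm's dose, washout at t = 0) and the living-cell count is
    read at every retained sampling time; each replicate observation is the
    model count times a unit-mean lognormal multiplier. With
    ``design.artifact_rate > 0``, records are independently corrupted: the
    count is sign-flipped, or — when a later sample of the same replicate
    series exists — zeroed, so both exclusion rules fire.

    Returns a DataFrame with columns ``arm_nM, time_h, replicate, count``
    (the :mod:`~doxopkpd.data` input schema); with ``return_artifacts=True``
    also the corrupted rows, for checking the exclusion report.
    Deterministic given ``seed``.
    """
    pk = pk or PKParams()
    pd_ = pd_ or PDParams()
    design = design or DesignSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)

    frames = []
    for arm in design.arms:
        all_times = design.sample_times
        times = np.array([t for t in all_times if (float(arm), float(t)) not in design.missing])
        mean_counts = _arm_trajectory(pk, pd_, design, float(arm), times)
        n_rep = design.replicates_for(float(arm))
        for rep in range(n_rep):
            cv = np.full(times.size, noise.cv)
            if times.size and times[0] == 0.0:
                cv[0] *= noise.first_sample_factor
            mult = np.array([_lognormal_multiplier(rng, c, 1)[0] for c in cv])
            frames.append(
                pd.DataFrame(
                    {
                        "arm_nM": float(arm),
                        "time_h": times,
                        "replicate": rep,
                        "count": mean_counts * mult,
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)

    artifact_rows = []
    if design.artifact_rate > 0:
        hit = rng.random(len(df)) < design.artifact_rate
        hit_idx = set(np.flatnonzero(hit).tolist())
        count_col = df.columns.get_loc("count")
        for i in sorted(hit_idx):
            row = df.iloc[i]
            series = df[(df["arm_nM"] == row["arm_nM"]) & (df["replicate"] == row["replicate"])]
            # a zero is only "unrealistic" if a later, untouched (hence
            # nonzero) sample of the same series witnesses it
            later_clean = series.index[
                (series["time_h"] > row["time_h"]) & ~series.index.isin(hit_idx)
            ]
            if rng.random() < 0.5 and len(later_clean):
                df.iat[i, count_col] = 0.0
            else:
                df.iat[i, count_col] = -abs(row["count"])
            artifact_rows.append(i)
    if return_artifacts:
        return df, df.iloc[artifact_rows].copy()
    return df


def generate_calibration(
    curve: StandardCurve,
    n: int = 10,
    noise_sd: float = 0.0,
    seed: int = 0,
    fluor_max: float = 100.0,
) -> pd.DataFrame:
    """Standard-curve calibration pairs: fluorescence vs seeded cell number.

    Produces ``n`` fluorescence values evenly spaced on [0, fluor_max] and
    cell counts on the line plus Gaussian noise of standard deviation
    ``noise_sd`` (in cells). Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 calibration points")
    rng = np.random.default_rng(seed)
    fluor = np.linspace(0.0, fluor_max, n)
    cells = curve.slope * fluor + curve.intercept + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"fluorescence": fluor, "cells": cells})
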