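"""Diagnostic plots for fits and in-silico trials."""

from __future__ import annotations

import math

import numpy as np

from .model import DoxoPKPDResults
from .trials import TrialReport


def plot_fit(results: DoxoPKPDResults, axes=None):
    """Per-arm panels: averaged data with CIs, fitted curve, bootstrap band."""
    import matplotlib.pyplot as plt

    model = results.model
    arms = model.arms
    if axes is None:
        ncol = 4
        nrow = math.ceil(len(arms) / ncol)
        fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
        axes = axes.ravel()
    boot = results.bootstrap_result
    for ax, arm in zip(axes, arms):
        obs = model._obs[arm]
        avg = model.averaged[model.averaged["arm_nM"] == arm]
        ax.errorbar(
            avg["time_h"], avg["mean"],
            yerr=np.vstack([avg["mean"] - avg["ci_low"], avg["ci_high"] - avg["mean"]]),
            fmt="o", ms=3, color="crimson", ecolor="salmon", label="data (95% CI)",
        )
        dense = np.linspace(0.0, obs["times"].max(), 200)
        ax.plot(dense, results.predict(arm, times=dense), "k-", lw=1.2, label="fit")
        if boot is not None and arm in boot.bands:
            band = boot.bands[arm]
            ax.fill_between(band["time_h"], band["lo"], band["hi"], color="green", alpha=0.2)
        ax.set_title(f"{arm:g} nM")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("cells")
    for ax in axes[len(arms):]:
        ax.set_visible(False)
    return axes


def plot_trial(report: TrialReport, fig=None):
    """Three stacked panels: total intracellular drug, bound drug vs threshold, cells."""
    import matplotlib.pyplot as plt

    if fig is None:
        fig, axs = plt.subplots(3, 1, figsize=(8, 9), sharex=True)
    else:
        axs = fig.subplots(3, 1, sharex=True)
    for name, m in report.regimens.items():
        t = m.trajectory.times
        axs[0].plot(t, m.trajectory.xi, label=name)
        axs[1].plot(t, m.trajectory.xb, label=name)
        axs[2].plot(t, m.trajectory.n, label=name)
    if np.isfinite(report.threshold_nM):
        axs[1].axhline(report.threshold_nM, ls="--", c="gray", label="efficacy threshold")
    axs[0].set_ylabel("total intracellular DOXO (nM)")
    axs[1].set_ylabel("DNA-bound DOXO (nM)")
    axs[2].set_ylabel("living cells")
    axs[2].set_xlabel("time (h)")
    for ax in axs:
        ax.legend(fontsize=8)
    return fig
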