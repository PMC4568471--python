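"""Optional figures: monthly hormone profile and age-specific reproduction."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .senescence import decline_rates

__all__ = ["plot_monthly_gcm", "plot_reproduction_by_age"]


def plot_monthly_gcm(samples: pd.DataFrame, season_def, path) -> None:
    g = samples.groupby("month")["concentration_ng_g"]
    mean, se = g.mean(), g.sem()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(mean.index, mean, yerr=se, fmt="o-", capsize=3)
    for m in season_def.months:
        ax.axvspan(m - 0.5, m + 0.5, alpha=0.15, color="tab:red")
    ax.set_xlabel("calendar month")
    ax.set_ylabel("GCM concentration (ng/g dry faeces)")
    ax.set_xticks(range(1, 13))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_reproduction_by_age(table: pd.DataFrame, fits, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for gval, color, lab in ((0, "tab:blue", "other-born"), (1, "tab:red", "high-stress-born")):
        sub = table[table["high_stress_born"] == gval]
        g = sub.groupby("bin_mid_age")["reproduced"]
        ax.errorbar(g.mean().index, g.mean(), yerr=g.sem(), fmt="o", color=color, label=lab)
    sen = table[table["bin_mid_age"] >= fits.peak_age]
    d = decline_rates(fits, sen)
    ages = np.asarray(d["ages"])
    ax.plot(ages, d["other"]["predicted"], "-", color="tab:blue")
    ax.plot(ages, d["high_stress"]["predicted"], "-", color="tab:red")
    ax.set_xlabel("age-bin mid (years)")
    ax.set_ylabel("P(reproduced in 3-year bin)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
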