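"""Built-in trajectory plots (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_trajectory(df, ax=None):
    """Mean assembly length and CD proxy against time.

    ``df`` is a trajectory or ensemble-summary DataFrame containing
    ``time_days`` plus either ``mean_length_all``/``active_fraction`` or
    their ``_mean`` ensemble columns.  Returns the matplotlib axes pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    t = df["time_days"]
    ml = df["mean_length_all_mean"] if "mean_length_all_mean" in df else df["mean_length_all"]
    af = df["active_fraction_mean"] if "active_fraction_mean" in df else df["active_fraction"]
    ax.plot(t, ml, "o-", color="tab:blue", label="mean length (toroid units)")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("mean assembly length (toroid units)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(t, af, "s--", color="tab:red", label="active fraction (CD proxy)")
    ax2.set_ylabel("active fraction", color="tab:red")
    ax2.set_ylim(-0.02, 1.05)
    return ax, ax2


def plot_length_histograms(cryotem, times=None, ax=None, bins=20):
    """Stacked per-time-point histograms of sampled assembly lengths (nm),
    the package's rendering of the micrograph length counts."""
    import matplotlib.pyplot as plt

    if times is None:
        times = sorted(cryotem["time_days"].unique())
    if ax is None:
        _, ax = plt.subplots(len(times), 1, sharex=True,
                             figsize=(5, 1.2 * len(times)))
    axes = np.atleast_1d(ax)
    for a, t in zip(axes, times):
        vals = cryotem.loc[cryotem["time_days"] == t, "length_nm"]
        a.hist(vals, bins=bins, color="tab:gray")
        a.set_ylabel(f"day {t:g}", fontsize=8)
    axes[-1].set_xlabel("measured length (nm)")
    return axes


def plot_fit(results, ax=None):
    """Overlay a calibration dataset with the fitted mean-field curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    data = results.model.data
    dense = np.linspace(data["time_days"].min(), data["time_days"].max(), 200)
    pred = results.predict(times=dense)
    if results.model.has_length:
        yerr = data.get("mean_length_se")
        ax.errorbar(data["time_days"], data["mean_length_nm"], yerr=yerr,
                    fmt="o", color="tab:blue", label="data")
        ax.plot(pred["time_days"], pred["mean_length_nm"], "-",
                color="tab:orange", label="fitted model")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("mean length (nm)")
    ax.legend()
    return ax
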