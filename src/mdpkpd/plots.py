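"""Diagnostic plots: concentration-time curves and hysteresis loops."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .link import LinkFit  # noqa: E402
from .series import EffectSeries, SampleSeries  # noqa: E402

__all__ = ["plot_concentration_time", "plot_hysteresis_loop"]


def plot_concentration_time(series: SampleSeries, predicted=None, ax=None):
    """Observed (and optionally model-predicted) concentration vs time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(series.times, series.concentrations, "o", label="observed")
    if predicted is not None:
        ax.plot(predicted.times, predicted.concentrations, "-",
                label="fitted")
        ax.legend(frameon=False)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(f"{series.analyte} (ng/mL)")
    return ax


def plot_hysteresis_loop(conc, effect, times=None, *, label: str = "",
                         ax=None):
    """Effect vs concentration trajectory in time order, loop closed
    last-to-first; arrows mark the traversal direction."""
    c = np.asarray(conc, dtype=float)
    e = np.asarray(effect, dtype=float)
    if times is not None:
        order = np.argsort(np.asarray(times, dtype=float), kind="stable")
        c, e = c[order], e[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(4.2, 4.2))
    cc = np.append(c, c[0])
    ee = np.append(e, e[0])
    ax.plot(cc, ee, "-o", ms=3, lw=1)
    k = max(len(c) // 6, 1)
    for i in range(0, len(c) - 1, k):
        ax.annotate("", xy=(c[i + 1], e[i + 1]), xytext=(c[i], e[i]),
                    arrowprops=dict(arrowstyle="->", color="tab:red", lw=1))
    ax.set_xlabel("concentration (ng/mL)")
    ax.set_ylabel("effect (% of baseline)")
    if label:
        ax.set_title(label, fontsize=10)
    return ax
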