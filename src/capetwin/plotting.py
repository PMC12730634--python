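"""Figure-style plotting helpers: per-dose time courses of one variable.

Optional output only; nothing in the analysis pipeline depends on these.
"""

from __future__ import annotations

from typing import Mapping

from .simulate import Trajectory

__all__ = ["plot_dose_scan"]


def plot_dose_scan(
    scan: Mapping[float, Trajectory],
    variable: str,
    ax=None,
    *,
    relative: bool = False,
):
    """Overlay the time course of *variable* for every dose in *scan*.

    With ``relative=True`` each curve is divided by the dose-0 control at
    the same time (undefined points are masked).
    """
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    control = scan.get(0.0)
    for dose in sorted(scan):
        traj = scan[dose]
        y = traj.column(variable)
        if relative:
            if control is None:
                raise ValueError("relative plotting needs the dose-0 control")
            ref = control.column(variable)
            y = np.where(ref > 0, y / np.where(ref > 0, ref, 1.0), np.nan)
        ax.plot(traj.times, y, label=f"{dose:g} uM")
    ax.set_xlabel("time (h)")
    ax.set_ylabel(f"{variable} (relative to control)" if relative
                  else variable)
    ax.legend(title="CAPE dose", fontsize="small")
    return ax
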