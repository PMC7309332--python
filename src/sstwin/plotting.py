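"""Optional rendering: squeezed-plane heat map with the ridge overlaid."""

from __future__ import annotations

import numpy as np

from .pipeline import AnalysisProducts


def plot_sst(products: AnalysisProducts, ax=None, db_floor: float = -60.0):
    """Heat map of |SST| (dB, log-frequency axis) with the SSTIF curve on top.

    The dominant dark curve is the instantaneous frequency; its intensity
    carries the amplitude modulation.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    sst = products.sst
    mag = np.abs(sst.coefficients)
    ref = mag.max()
    if ref <= 0:
        raise ValueError("all-zero SST matrix cannot be rendered")
    db = 20.0 * np.log10(np.maximum(mag / ref, 10 ** (db_floor / 20.0)))
    ax.pcolormesh(
        sst.time_axis, sst.frequency_grid.bin_centers, db, shading="nearest", cmap="magma"
    )
    iff = products.sstif
    shown = np.where(iff.boundary_mask, np.nan, iff.values)
    ax.plot(iff.time_axis, shown, "c--", lw=1.2, label="SSTIF")
    ax.set_yscale("log")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    ax.legend(loc="upper right")
    return ax
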