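"""Matplotlib views of profiles, window correlations and motif scans."""

from __future__ import annotations

import numpy as np

_BASE_COLORS = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}


def plot_flank_profile(profile, ax=None, title: str | None = None):
    """Grouped o/e bars per flank position, one colour per base."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.2))
    positions = profile.positions
    xs = np.arange(len(positions))
    width = 0.2
    for off, base in zip((-1.5, -0.5, 0.5, 1.5), "ACGT"):
        ax.bar(xs + off * width, profile.oe[base].to_numpy(), width,
               label=base, color=_BASE_COLORS[base])
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(xs, [str(p) for p in positions])
    ax.set_xlabel("flank position")
    ax.set_ylabel("o/e")
    ax.legend(ncols=4, frameon=False)
    if title:
        ax.set_title(title)
    return ax


def plot_local_correlation(wc, ax=None):
    """Window r values along the chromosome, positive blue / negative orange."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    r = wc.windows.r.to_numpy()
    pos = wc.windows.start_pos.to_numpy()
    ax.vlines(pos[r > 0], 0, r[r > 0], color="#1f78b4", lw=0.5)
    ax.vlines(pos[r < 0], 0, r[r < 0], color="#ff7f00", lw=0.5)
    ax.set_xlabel("position of window start")
    ax.set_ylabel(f"r ({wc.window}-site window)")
    return ax


def plot_window_oe(profile_frame, motif_class: str = "CCCG+CGGG", ax=None):
    """Tile-averaged motif o/e along one element."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    sub = profile_frame[profile_frame.motif_class == motif_class]
    mid = (sub.start + sub.end) / 2
    ax.plot(mid, sub.oe, drawstyle="steps-mid")
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(f"o/e {motif_class}")
    return ax
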