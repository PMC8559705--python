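"""Dot-plot rendering of split-mapped reads (read offset vs unit position)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .refmodel import ReferenceModel
from .splitmap import ReadAlignmentMap


def dot_plot(amap: ReadAlignmentMap, ref: ReferenceModel, path: str | Path,
             profile=None, qualities=None) -> None:
    """Render one read's split map: forward blue, reverse red, unmapped lane.

    Optionally adds a binned methylation bar track (``profile``) and a
    binned quality trace below the main panel.
    """
    n_panels = 1 + (profile is not None) + (qualities is not None)
    fig, axes = plt.subplots(
        n_panels, 1, figsize=(10, 4 + 1.4 * (n_panels - 1)), sharex=True,
        gridspec_kw={"height_ratios": [4] + [1] * (n_panels - 1)}, squeeze=False)
    ax = axes[0][0]
    um_lane = -0.06 * ref.unit_length
    for s in amap.splits:
        if s.mapped:
            color = "tab:blue" if s.strand == "+" else "tab:red"
            ax.plot([s.read_offset, s.read_offset + s.length],
                    [s.ref_pos, s.ref_pos + (s.length if s.strand == "+"
                                             else -s.length)],
                    color=color, lw=1.2)
        else:
            ax.plot([s.read_offset, s.read_offset + s.length],
                    [um_lane, um_lane], color="0.6", lw=1.2)
    for y, style in ((0, ":"), (ref.unit_length, ":"),
                     (ref.coding_interval[1], "--")):
        ax.axhline(y, color="0.7", ls=style, lw=0.8)
    ax.set_ylabel("unit position (nt)")
    ax.set_title(f"{amap.read_id} ({amap.read_length:,} nt)")
    ax.set_ylim(um_lane * 2, ref.unit_length * 1.02)

    row = 1
    if profile is not None:
        axp = axes[row][0]
        axp.bar(profile.bin_start, profile.avg_freq, width=profile.bin_size,
                align="edge", color="magenta")
        axp.set_ylim(0, 1)
        axp.set_ylabel("mCpG")
        row += 1
    if qualities is not None:
        axq = axes[row][0]
        q = np.asarray(qualities, dtype=float)
        nb = len(q) // 200
        if nb:
            means = q[: nb * 200].reshape(nb, 200).mean(axis=1)
            axq.plot(np.arange(nb) * 200, means, color="0.3", lw=0.8)
        axq.set_ylabel("Q")
    axes[-1][0].set_xlabel("read position (nt)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
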