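"""Figure panels summarising a workflow run (orthogonal mid-slices)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def _triplanar(ax_row, volume, mask, title, unit, vmin=None, vmax=None):
    vol = np.where(mask, volume, np.nan)
    cx, cy, cz = (s // 2 for s in vol.shape)
    slices = [vol[cx, :, :].T, vol[:, cy, :].T, vol[:, :, cz].T]
    for ax, sl in zip(ax_row, slices):
        im = ax.imshow(sl, origin="lower", cmap="viridis", vmin=vmin, vmax=vmax)
        ax.set_xticks([])
        ax.set_yticks([])
    ax_row[0].set_ylabel(f"{title}\n[{unit}]", fontsize=9)
    return im


def save_panels(artifacts: dict, outdir) -> Path:
    """Write field- and flip-angle-homogenisation panels as one PNG.

    ``artifacts`` is the in-memory artefact dictionary produced by
    :func:`ptxh.workflow.run_workflow` (pre/post-shim fields, CP-mode
    combination, designed flip map).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = artifacts["mask"].data
    rows = []
    b0_pre = artifacts["b0_measured"].values
    b0_post = artifacts["b0_post"].values
    lim = np.nanpercentile(np.abs(b0_pre[mask]), 99)
    rows.append(("B0 before shim", "Hz", b0_pre, -lim, lim))
    rows.append(("B0 after shim", "Hz", b0_post, -lim, lim))
    b1 = artifacts.get("b1_measured", artifacts.get("b1_true"))
    if b1 is not None:
        cp = np.abs(b1.cp_combined())
        rows.append(("CP-mode |B1+|", "uT/V", cp, 0, np.nanpercentile(cp[mask], 99)))
    if "designed_fa" in artifacts:
        fa = artifacts["designed_fa"].values
        rows.append(("kT-points flip", "deg", fa, 0, np.nanpercentile(fa[mask], 99)))

    fig, axes = plt.subplots(len(rows), 3, figsize=(7, 2.2 * len(rows)))
    axes = np.atleast_2d(axes)
    for ax_row, (title, unit, vol, vmin, vmax) in zip(axes, rows):
        im = _triplanar(ax_row, vol, mask, title, unit, vmin, vmax)
        fig.colorbar(im, ax=ax_row[-1], shrink=0.8)
    fig.suptitle("B0 and flip-angle homogenisation summary", fontsize=11)
    fig.tight_layout()
    path = outdir / "summary_panels.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
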