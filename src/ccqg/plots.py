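"""Basic diagnostic plots: genome scan profiles and mosaic paintings."""

from __future__ import annotations

import numpy as np

from .scan import ScanResult
from .simulate import MosaicGenome


def plot_scan(scan: ScanResult, thresholds: dict | None = None, ax=None):
    """LogP along the genome, chromosomes concatenated, with optional
    horizontal permutation-threshold lines keyed by alpha."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    t = scan.table
    offset = 0.0
    ticks, labels = [], []
    for chrom in dict.fromkeys(t["chrom"]):
        sub = t[t["chrom"] == chrom]
        x = sub["cm"].to_numpy() + offset
        ax.plot(x, sub["logp"], lw=0.9)
        ticks.append(offset + sub["cm"].to_numpy().mean())
        labels.append(str(chrom))
        offset = x[-1] + 5.0
    for alpha, thr in (thresholds or {}).items():
        ax.axhline(thr, ls="--", lw=0.7, color="grey")
        ax.annotate(f"P<{alpha}", (offset, thr), fontsize=7, color="grey")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("LogP")
    ax.set_title(scan.trait)
    return ax


def plot_mosaic(mosaic: MosaicGenome, ax=None, cmap_name: str = "tab10"):
    """Founder-colored segment painting of one line's two haplotypes."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(mosaic.chrom_lengths)))
    cmap = colormaps[cmap_name]
    y = 0
    for chrom in mosaic.chrom_lengths:
        for h, haps in enumerate((mosaic.hap1, mosaic.hap2)):
            for a, b, f in haps[chrom]:
                ax.barh(
                    y + 0.4 * h, b - a, left=a, height=0.35,
                    color=cmap(f % 10), edgecolor="none",
                )
        y += 1
    ax.set_yticks(np.arange(len(mosaic.chrom_lengths)) + 0.2,
                  list(mosaic.chrom_lengths))
    ax.set_xlabel("cM")
    ax.set_title(mosaic.line_id)
    return ax
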