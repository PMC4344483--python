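"""Plots: genome-wide ratio tracks, per-region ASCN detail, and QC tracks.

Color convention: losses blue, gains red, normal green.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .counts_io import ChromCounts, SampleTotals
from .event_calling import classify_segment, NORMAL
from .mixture_model import observed_ascn_arrays
from .segmentation import SegmentationResult

LOSS_COLOR = "tab:blue"
GAIN_COLOR = "tab:red"
NORMAL_COLOR = "tab:green"


def _ratio_color(ratio: float, delta: float = 0.2) -> str:
    if ratio < 1.0 - delta:
        return LOSS_COLOR
    if ratio > 1.0 + delta:
        return GAIN_COLOR
    return NORMAL_COLOR


def plot_genome(results, path, delta: float = 0.2, ymax: float = 3.0) -> None:
    """Step plot of minor and major allelic ratios versus genome position.

    ``results`` is one mapping chrom -> SegmentationResult per sample; pass a
    list of such mappings for stacked panels (e.g. pre-malignant above
    malignant).
    """
    if isinstance(results, dict):
        results = [results]
    if not results or not any(r for r in results):
        raise ValueError("empty segmentation results")
    fig, axes = plt.subplots(len(results), 1, figsize=(12, 3 * len(results)),
                             squeeze=False, sharex=True)
    for ax_row, sample in zip(axes, results):
        ax = ax_row[0]
        offset = 0
        for chrom, res in sample.items():
            for seg in res.segments:
                x = [offset + seg.start_pos, offset + seg.end_pos]
                for ratio in (seg.ratios.minor, seg.ratios.major):
                    ax.plot(x, [min(ratio, ymax)] * 2,
                            color=_ratio_color(ratio, delta), lw=2)
            last = res.segments[-1].end_pos
            offset += last
            ax.axvline(offset, color="0.8", lw=0.5)
        ax.axhline(1.0, color="0.5", lw=0.5, ls=":")
        ax.set_ylim(0, ymax)
        ax.set_ylabel("allelic ratio")
    axes[-1][0].set_xlabel("genome position (bp, chromosomes concatenated)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_region(loci: ChromCounts, result: SegmentationResult,
                totals: SampleTotals, path, start_pos: int | None = None,
                end_pos: int | None = None, ymax: float = 3.0) -> None:
    """Observed per-locus ASCN (solid markers) with the fitted segment-level
    minor/major ratios overlaid as lines."""
    lo = start_pos if start_pos is not None else int(loci.pos[0])
    hi = end_pos if end_pos is not None else int(loci.pos[-1])
    mask = (loci.pos >= lo) & (loci.pos <= hi)
    if not mask.any():
        raise ValueError("empty region")
    cA, cB = observed_ascn_arrays(loci, totals)
    fig, ax = plt.subplots(figsize=(10, 4))
    ax.plot(loci.pos[mask], np.minimum(cA[mask], ymax), "v", ms=3,
            color="0.4", label="observed ASCN (A)")
    ax.plot(loci.pos[mask], np.minimum(cB[mask], ymax), "^", ms=3,
            color="0.7", label="observed ASCN (B)")
    for seg in result.segments:
        if seg.end_pos < lo or seg.start_pos > hi:
            continue
        x = [max(seg.start_pos, lo), min(seg.end_pos, hi)]
        for ratio in (seg.ratios.minor, seg.ratios.major):
            ax.plot(x, [min(ratio, ymax)] * 2, color=_ratio_color(ratio), lw=2)
    ax.axhline(1.0, color="0.5", lw=0.5, ls=":")
    ax.set_ylim(0, ymax)
    ax.set_xlabel(f"{loci.chrom} position (bp)")
    ax.set_ylabel("relative ASCN")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_qc(loci: ChromCounts, path) -> None:
    """Normal-sample QC: total coverage and log allelic ratio per locus."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    total = loci.yA + loci.yB
    ax1.plot(loci.pos, total, ".", ms=2, color="0.3")
    ax1.set_ylabel("normal coverage")
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.log(np.maximum(loci.yB, 0.5) / np.maximum(loci.yA, 0.5))
    ax2.plot(loci.pos, logratio, ".", ms=2, color="0.3")
    ax2.axhline(0.0, color="0.5", lw=0.5, ls=":")
    ax2.set_ylabel("log allelic ratio (B/A)")
    ax2.set_xlabel(f"{loci.chrom} position (bp)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
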