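"""Classification of segments into copy-number aberration types.

Each segment's minor/major allelic ratios are compared to 1 (no change).
A haplotype is lost when its ratio falls below 1 - delta and gained when it
exceeds 1 + delta, giving six aberration types plus "normal":

    gain/normal            one haplotype gained, the other unchanged
    gain/gain              both haplotypes gained
    normal/loss            one haplotype lost (heterozygous deletion)
    loss/loss              both haplotypes lost (homozygous deletion)
    balanced gain/loss     copy-neutral LOH: gain of one haplotype offset by
                           an equal loss of the other
    unbalanced gain/loss   gain of one haplotype with an unequal loss
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .mixture_model import AllelicRatios
from .segmentation import SegmentationResult

GAIN_NORMAL = "gain/normal"
GAIN_GAIN = "gain/gain"
NORMAL_LOSS = "normal/loss"
LOSS_LOSS = "loss/loss"
BALANCED_GAIN_LOSS = "balanced gain/loss"
UNBALANCED_GAIN_LOSS = "unbalanced gain/loss"
NORMAL = "normal"

EVENT_TYPES = (
    GAIN_NORMAL, GAIN_GAIN, NORMAL_LOSS, LOSS_LOSS,
    BALANCED_GAIN_LOSS, UNBALANCED_GAIN_LOSS,
)

#: events smaller than this many bases are annotated "focal"
FOCAL_MAX_BP = 1_000_000


@dataclass(frozen=True)
class CNEvent:
    """A called copy-number aberration with its supporting statistics."""

    chrom: str
    start_pos: int
    end_pos: int
    length_bp: int
    n_snvs: int
    minor_ratio: float
    major_ratio: float
    type: str
    focal: bool
    start_idx: int = -1
    end_idx: int = -1

    @property
    def total_copy(self) -> float:
        """Relative total copy number (2 x this = diploid-scale copies)."""
        return self.minor_ratio + self.major_ratio


def _state(ratio: float, delta: float) -> str:
    if ratio < 1.0 - delta:
        return "loss"
    if ratio > 1.0 + delta:
        return "gain"
    return "normal"


def classify_segment(ratios: AllelicRatios, delta: float = 0.2,
                     balance_tol: float = 0.1) -> str:
    """Map (minor, major) allelic ratios to an aberration type.

    ``delta`` is the no-change band half-width around ratio 1; the default
    0.2 matches the high-confidence filter "change in allelic ratio from 1
    larger than 0.2". ``balance_tol`` separates balanced from unbalanced
    gain/loss by comparing the magnitudes of the loss (1 - minor) and the
    gain (major - 1).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    lo = _state(ratios.minor, delta)
    hi = _state(ratios.major, delta)
    if lo == "normal" and hi == "normal":
        return NORMAL
    if lo == "normal" and hi == "gain":
        return GAIN_NORMAL
    if lo == "gain":  # minor > 1 + delta implies major > 1 + delta
        return GAIN_GAIN
    if hi == "normal":
        return NORMAL_LOSS
    if hi == "loss":
        return LOSS_LOSS
    # loss of one haplotype with gain of the other
    if abs((1.0 - ratios.minor) - (ratios.major - 1.0)) <= balance_tol:
        return BALANCED_GAIN_LOSS
    return UNBALANCED_GAIN_LOSS


def call_events(result: SegmentationResult, delta: float = 0.2,
                balance_tol: float = 0.1, min_snvs: int = 4) -> list[CNEvent]:
    """One event per non-normal segment with at least ``min_snvs`` loci.

    Adjacent same-type segments are not merged: the segmentation itself
    defines event boundaries.
    """
    events: list[CNEvent] = []
    for seg in result.segments:
        etype = classify_segment(seg.ratios, delta, balance_tol)
        if etype == NORMAL or seg.n_snvs < min_snvs:
            continue
        length = seg.end_pos - seg.start_pos + 1
        events.append(
            CNEvent(
                chrom=seg.chrom,
                start_pos=seg.start_pos,
                end_pos=seg.end_pos,
                length_bp=length,
                n_snvs=seg.n_snvs,
                minor_ratio=seg.ratios.minor,
                major_ratio=seg.ratios.major,
                type=etype,
                focal=length < FOCAL_MAX_BP,
                start_idx=seg.start_idx,
                end_idx=seg.end_idx,
            )
        )
    return events


def events_table(events: list[CNEvent]) -> pd.DataFrame:
    """Tabular event list: Chr, Start, Length, Type, Num. SNVs, ratios."""
    return pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "start_bp": e.start_pos,
                "length_bp": e.length_bp,
                "type": e.type,
                "n_snvs": e.n_snvs,
                "minor_ratio": e.minor_ratio,
                "major_ratio": e.major_ratio,
                "total_copy": e.total_copy,
                "focal": e.focal,
            }
            for e in events
        ],
        columns=["chrom", "start_bp", "length_bp", "type", "n_snvs",
                 "minor_ratio", "major_ratio", "total_copy", "focal"],
    )
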