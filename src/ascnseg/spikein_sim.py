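"""Synthetic tumor/normal allele-specific counts with spiked-in aberrations.

The generator mirrors the Poisson coverage model that motivates the binomial
mixture: per locus, haplotype-specific read counts in both samples are
independent Poissons whose means share a lognormal site bias h(t), lognormal
allele biases b_A(t), b_B(t) and, in the tumor, a haplotype-specific relative
copy number. A tumor sample of purity f whose aberrant cells carry c copies
of a haplotype has relative ratio f*c + (1-f) for that haplotype. A latent
Bernoulli(1/2) phase assigns alleles to haplotypes, which is what makes the
observed allele-specific counts a two-component mixture.

Defaults follow the sensitivity-study design: a 10,000-locus chromosome at
44x per-sample coverage, 1000-locus spiked events, lower coverages produced
by binomial thinning (site bias sd 0.3 and allelic bias sd 0.2 give a
normal-sample coverage range and allelic-ratio spread comparable to real
whole-genome data at this depth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import ChromCounts, SampleTotals, compute_totals
from .event_calling import (BALANCED_GAIN_LOSS, GAIN_GAIN, GAIN_NORMAL,
                            LOSS_LOSS, NORMAL, NORMAL_LOSS,
                            UNBALANCED_GAIN_LOSS, call_events)
from .segmentation import SegmentationConfig, segment_chromosome

#: tumor-cell haplotype copy numbers per aberration type, (minor, major)
TYPE_COPIES: dict[str, tuple[int, int]] = {
    LOSS_LOSS: (0, 0),
    NORMAL_LOSS: (0, 1),
    BALANCED_GAIN_LOSS: (0, 2),
    UNBALANCED_GAIN_LOSS: (0, 3),
    GAIN_NORMAL: (1, 2),
    GAIN_GAIN: (2, 2),
}

NOT_DETECTED = -1  # sentinel for detection_threshold


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic chromosome."""

    T: int = 10_000
    mean_cov: float = 44.0  # per-sample total coverage per locus
    site_bias_sd: float = 0.3  # lognormal sd of h(t)
    allelic_bias_sd: float = 0.2  # lognormal sd of b_A(t), b_B(t)
    seed: int = 0
    chrom: str = "sim1"
    pos_spacing: int = 1000  # bp between consecutive loci

    def __post_init__(self) -> None:
        if self.mean_cov <= 0:
            raise ValueError("mean_cov must be positive")
        if self.site_bias_sd < 0 or self.allelic_bias_sd < 0:
            raise ValueError("bias sds must be non-negative")


@dataclass(frozen=True)
class SpikeEvent:
    """A spiked aberration over a locus-index half-open span [start, end)."""

    start: int
    end: int
    c_a: int  # haplotype-a copies per aberrant cell
    c_b: int
    purity: float  # fraction f of aberrant cells

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty spike span")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0, 1]")
        if self.c_a < 0 or self.c_b < 0:
            raise ValueError("haplotype copies must be non-negative")

    @property
    def ratios(self) -> tuple[float, float]:
        """Effective relative haplotype ratios f*c + (1-f), minor first."""
        f = self.purity
        r = sorted((f * self.c_a + 1.0 - f, f * self.c_b + 1.0 - f))
        return (r[0], r[1])

    @property
    def type(self) -> str:
        lo, hi = sorted((self.c_a, self.c_b))
        for name, copies in TYPE_COPIES.items():
            if (lo, hi) == copies:
                return name
        if lo == hi == 1:
            return NORMAL
        if lo < 1 and hi > 1:
            return (BALANCED_GAIN_LOSS if (1 - lo) == (hi - 1)
                    else UNBALANCED_GAIN_LOSS)
        if lo >= 1 and hi > 1:
            return GAIN_NORMAL if lo == 1 else GAIN_GAIN
        return NORMAL_LOSS if hi == 1 else LOSS_LOSS


def spike_for_type(event_type: str, purity: float, start: int = 4500,
                   end: int = 5500) -> SpikeEvent:
    """Convenience constructor: canonical haplotype copies for a type."""
    c_a, c_b = TYPE_COPIES[event_type]
    return SpikeEvent(start=start, end=end, c_a=c_a, c_b=c_b, purity=purity)


def simulate_pair(config: SimConfig, spikes: Sequence[SpikeEvent] = ()
                  ) -> tuple[ChromCounts, pd.DataFrame]:
    """Draw one synthetic tumor/normal chromosome plus a truth table.

    Returns the counts and a DataFrame with one row per spike (start/end
    locus indices, haplotype copies, purity, effective ratios, type).
    """
    spans = sorted((s.start, s.end) for s in spikes)
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 < b1:
            raise ValueError("overlapping spike spans")
    for s in spikes:
        if not (0 <= s.start < s.end <= config.T):
            raise ValueError("spike span outside the chromosome")

    rng = np.random.default_rng(config.seed)
    T = config.T
    h = rng.lognormal(0.0, config.site_bias_sd, T) if config.site_bias_sd > 0 \
        else np.ones(T)
    bA = rng.lognormal(0.0, config.allelic_bias_sd, T) \
        if config.allelic_bias_sd > 0 else np.ones(T)
    bB = rng.lognormal(0.0, config.allelic_bias_sd, T) \
        if config.allelic_bias_sd > 0 else np.ones(T)
    phase = rng.integers(0, 2, T).astype(bool)  # True: allele A on haplotype a

    r_a = np.ones(T)
    r_b = np.ones(T)
    for s in spikes:
        f = s.purity
        r_a[s.start:s.end] = f * s.c_a + 1.0 - f
        r_b[s.start:s.end] = f * s.c_b + 1.0 - f

    half = config.mean_cov / 2.0
    rA = np.where(phase, r_a, r_b)  # tumor copy ratio of the haplotype holding A
    rB = np.where(phase, r_b, r_a)
    yA = rng.poisson(half * h * bA)
    yB = rng.poisson(half * h * bB)
    xA = rng.poisson(half * h * bA * rA)
    xB = rng.poisson(half * h * bB * rB)

    pos = (np.arange(T) + 1) * config.pos_spacing
    counts = ChromCounts(config.chrom, pos, xA, xB, yA, yB)
    truth = pd.DataFrame(
        [
            {
                "start_idx": s.start,
                "end_idx": s.end,
                "c_a": s.c_a,
                "c_b": s.c_b,
                "purity": s.purity,
                "minor_ratio": s.ratios[0],
                "major_ratio": s.ratios[1],
                "type": s.type,
            }
            for s in spikes
        ],
        columns=["start_idx", "end_idx", "c_a", "c_b", "purity",
                 "minor_ratio", "major_ratio", "type"],
    )
    return counts, truth


def six_event_layout(purity: float, T: int = 10_000, span: int = 1000,
                     gap: int = 500) -> list[SpikeEvent]:
    """Six spiked events, one per aberration type, evenly laid out."""
    spikes = []
    start = gap
    for etype in (LOSS_LOSS, NORMAL_LOSS, BALANCED_GAIN_LOSS,
                  UNBALANCED_GAIN_LOSS, GAIN_NORMAL, GAIN_GAIN):
        c_a, c_b = TYPE_COPIES[etype]
        spikes.append(SpikeEvent(start, start + span, c_a, c_b, purity))
        start += span + gap
    if start - gap > T:
        raise ValueError("layout does not fit on the chromosome")
    return spikes


def downsample(counts: ChromCounts, fraction: float,
               rng: np.random.Generator | None = None,
               seed: int | None = None) -> ChromCounts:
    """Binomial thinning of all four counts; preserves the Poisson form
    with mean scaled by ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return counts
    if rng is None:
        rng = np.random.default_rng(seed)
    return ChromCounts(
        counts.chrom,
        counts.pos,
        rng.binomial(counts.xA, fraction),
        rng.binomial(counts.xB, fraction),
        rng.binomial(counts.yA, fraction),
        rng.binomial(counts.yB, fraction),
    )


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def detect_event(counts: ChromCounts, truth_span: tuple[int, int],
                 truth_type: str, seg_config: SegmentationConfig | None = None,
                 detect_delta: float = 0.1, balance_tol: float = 0.1,
                 min_overlap: float = 0.5) -> bool:
    """Run segmentation + classification; the spike counts as detected only
    if a called event reciprocally overlaps the true span by at least
    ``min_overlap`` AND carries the true aberration type.

    ``detect_delta`` is the classification band used for detection scoring;
    it is narrower than the 0.2 reporting filter so that near-threshold
    purities, which the segmentation can localize, are typed by the sign of
    the estimated ratios rather than suppressed.
    """
    chroms = {counts.chrom: counts}
    totals = compute_totals(chroms)
    result = segment_chromosome(counts, totals, seg_config)
    events = call_events(result, delta=detect_delta, balance_tol=balance_tol)
    for ev in events:
        if ev.type != truth_type:
            continue
        if _reciprocal_overlap((ev.start_idx, ev.end_idx), truth_span) >= min_overlap:
            return True
    return False


def detection_threshold(aberration_type: str, coverage_fraction: float = 1.0,
                        purity_grid: Sequence[float] | None = None,
                        replicates: int = 3,
                        config: SimConfig | None = None,
                        seg_config: SegmentationConfig | None = None,
                        detect_delta: float = 0.1,
                        min_overlap: float = 0.5,
                        seed: int = 0) -> float:
    """Smallest grid purity at which an aberration type is detected.

    For each purity (ascending), ``replicates`` seeded chromosomes are
    simulated with a single 1000-locus spiked event, optionally thinned to a
    lower coverage, then segmented and classified; the purity counts as
    detected when at least half the replicates detect the event with the
    correct type. Returns the detected purity in percent, or NOT_DETECTED.
    """
    cfg = config or SimConfig()
    grid = list(purity_grid) if purity_grid is not None \
        else [p / 100 for p in range(5, 101, 5)]
    need = (replicates + 1) // 2
    ss = np.random.SeedSequence(entropy=seed)
    # one independent seed stream per (purity, replicate) cell
    child_seeds = ss.generate_state(2 * len(grid) * replicates) % (2**31)

    for gi, purity in enumerate(grid):
        hits = 0
        for rep in range(replicates):
            k = 2 * (gi * replicates + rep)
            sim_seed = int(child_seeds[k])
            thin_seed = int(child_seeds[k + 1])
            spike = spike_for_type(aberration_type, purity)
            counts, truth = simulate_pair(replace(cfg, seed=sim_seed), [spike])
            if coverage_fraction < 1.0:
                counts = downsample(counts, coverage_fraction, seed=thin_seed)
            if detect_event(counts, (spike.start, spike.end), spike.type,
                            seg_config, detect_delta=detect_delta,
                            min_overlap=min_overlap):
                hits += 1
            # early exit when the vote is already decided
            if hits >= need or hits + (replicates - rep - 1) < need:
                break
        if hits >= need:
            return 100.0 * purity
    return NOT_DETECTED


def sensitivity_grid(types: Sequence[str] = tuple(TYPE_COPIES),
                     coverage_fractions: Sequence[float] = (1.0, 0.5, 0.25),
                     seed: int = 0, **kwargs) -> pd.DataFrame:
    """Detection-threshold table: aberration type x coverage level.

    Column labels report the nominal coverage implied by the thinning
    fraction relative to the 44x baseline.
    """
    cfg = kwargs.pop("config", None) or SimConfig()
    rows = []
    for i, etype in enumerate(types):
        row = {"type": etype}
        for j, frac in enumerate(coverage_fractions):
            label = f"{cfg.mean_cov * frac:g}x"
            row[label] = detection_threshold(
                etype, coverage_fraction=frac, config=cfg,
                seed=seed + 1000 * i + j, **kwargs,
            )
        rows.append(row)
    return pd.DataFrame(rows)
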