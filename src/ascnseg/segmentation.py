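"""Change-point detection on the bivariate binomial success probabilities.

The haplotype copy numbers, hence the success probabilities (p_a, p_b), are
piecewise constant along each chromosome. Candidate change-points are grown
by greedy binary segmentation (linear-time in the number of loci) and the
number of change-points K is chosen with a modified BIC that penalizes both
the number and the configuration of the change-points.

Scanning every admissible split with a full EM fit on both sides is
quadratic, so the scan uses a folded surrogate: at every locus the allele
with the higher pooled success frequency is assigned to a "high" stream and
the other to a "low" stream, giving two binomial streams whose interval MLEs
and log-likelihoods reduce to cumulative sums. The surrogate locates the
split; the accepted gain and all model-selection scores are then computed
with genuine EM fits, so the surrogate only ever chooses *where* to look.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .counts_io import ChromCounts, SampleTotals
from .mixture_model import (AllelicRatios, MixtureFit, fit_arrays,
                            fit_segment, lchoose_terms, segment_ratios)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tuning knobs of the segmentation stage.

    min_seg
        Smallest admissible segment, in loci.
    max_K
        Cap on the number of change-points per chromosome.
    mbic_multiplier
        Scale factor on the modified-BIC penalty (1 = the default penalty).
    em_tol, em_max_iter
        EM convergence controls, passed through to the mixture fits.
    exact_scan_limit
        Intervals with at most this many admissible splits are scanned with
        full EM fits at every split; larger intervals use the folded
        surrogate plus local EM refinement.
    refine_halfwidth
        Half-width (in loci) of the EM refinement window around the
        surrogate's best split.
    stop_gain_factor
        Candidate growth stops once the best available split gains less
        than stop_gain_factor * log(T) * mbic_multiplier; such splits sit
        well below the minimum penalty increment and cannot be selected.
        Set to 0 to always grow to max_K.
    """

    min_seg: int = 5
    max_K: int = 15
    mbic_multiplier: float = 1.0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    exact_scan_limit: int = 128
    refine_halfwidth: int = 10
    stop_gain_factor: float = 0.5
    #: EM iteration cap for split-scan fits; truncation only underestimates
    #: gains (conservative), final segments are refit at em_max_iter
    scan_em_max_iter: int = 40


@dataclass(frozen=True)
class ChangePointSet:
    """Strictly increasing interior change-point indices in (0, T)."""

    tau: tuple[int, ...]
    T: int

    def __post_init__(self) -> None:
        if any(not (0 < t < self.T) for t in self.tau):
            raise ValueError("change-points must lie strictly inside (0, T)")
        if any(b <= a for a, b in zip(self.tau, self.tau[1:])):
            raise ValueError("change-points must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.tau)

    def boundaries(self) -> list[int]:
        return [0, *self.tau, self.T]


@dataclass
class Segment:
    """One homogeneous-ASCN segment (locus-index half-open span)."""

    chrom: str
    start_idx: int
    end_idx: int
    start_pos: int
    end_pos: int
    n_snvs: int
    fit: MixtureFit
    ratios: AllelicRatios


@dataclass
class SegmentationResult:
    segments: list[Segment]
    total_loglik: float
    K: int
    mbic_trace: list[float]
    totals: SampleTotals
    chrom: str = ""


class _ChromArrays:
    """Float views of one chromosome's counts plus the cumulative sum of the
    parameter-free binomial-coefficient terms (for O(1) interval constants)."""

    def __init__(self, cc: ChromCounts):
        self.xA = cc.xA.astype(float)
        self.xB = cc.xB.astype(float)
        self.nA = (cc.xA + cc.yA).astype(float)
        self.nB = (cc.xB + cc.yB).astype(float)
        self.clch = np.concatenate(
            [np.zeros(1),
             np.cumsum(lchoose_terms(self.xA, self.nA, self.xB, self.nB))]
        )

    def em_ll(self, lo: int, hi: int, tol: float, max_iter: int) -> float:
        """Maximized mixture log-likelihood of [lo, hi), constants included."""
        sl = slice(lo, hi)
        _, _, kll, _, _, _ = fit_arrays(
            self.xA[sl], self.nA[sl], self.xB[sl], self.nB[sl],
            tol=tol, max_iter=max_iter, single_start=True)
        return kll + float(self.clch[hi] - self.clch[lo])


class _FoldedScan:
    """Cumulative-sum machinery for the folded two-stream surrogate."""

    def __init__(self, cc: ChromCounts):
        xA = cc.xA.astype(float)
        xB = cc.xB.astype(float)
        nA = (cc.xA + cc.yA).astype(float)
        nB = (cc.xB + cc.yB).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            fA = np.where(nA > 0, xA / np.maximum(nA, 1.0), 0.5)
            fB = np.where(nB > 0, xB / np.maximum(nB, 1.0), 0.5)
        # same swap-invariant tie-break as the EM moment start
        a_low = (fA < fB) | ((fA == fB) & ((xA < xB) | ((xA == xB) & (nA <= nB))))
        lo_x = np.where(a_low, xA, xB)
        lo_n = np.where(a_low, nA, nB)
        hi_x = np.where(a_low, xB, xA)
        hi_n = np.where(a_low, nB, nA)
        z = np.zeros(1)
        self.clx = np.concatenate([z, np.cumsum(lo_x)])
        self.cln = np.concatenate([z, np.cumsum(lo_n)])
        self.chx = np.concatenate([z, np.cumsum(hi_x)])
        self.chn = np.concatenate([z, np.cumsum(hi_n)])

    @staticmethod
    def _binom_ll(x, n):
        # profile log-likelihood of a binomial interval at its MLE,
        # dropping the data-only combinatorial terms (they cancel in gains)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, x / np.maximum(n, 1.0), 0.0)
            t1 = np.where(x > 0, x * np.log(np.maximum(p, 1e-300)), 0.0)
            t2 = np.where(n - x > 0, (n - x) * np.log(np.maximum(1.0 - p, 1e-300)), 0.0)
        return t1 + t2

    def interval_ll(self, i, j):
        """Surrogate profile loglik of [i, j); i, j may be arrays."""
        i = np.asarray(i)
        j = np.asarray(j)
        ll = self._binom_ll(self.clx[j] - self.clx[i], self.cln[j] - self.cln[i])
        ll = ll + self._binom_ll(self.chx[j] - self.chx[i], self.chn[j] - self.chn[i])
        return ll


def _em_ll(arrays: _ChromArrays, lo: int, hi: int, cfg: SegmentationConfig,
           cache: dict | None = None) -> float:
    if cache is not None and (lo, hi) in cache:
        return cache[(lo, hi)]
    ll = arrays.em_ll(lo, hi, cfg.em_tol, cfg.scan_em_max_iter)
    if cache is not None:
        cache[(lo, hi)] = ll
    return ll


def best_split(cc: ChromCounts, lo: int, hi: int, min_seg: int,
               config: SegmentationConfig | None = None,
               scan: _FoldedScan | None = None,
               cache: dict | None = None,
               arrays: _ChromArrays | None = None) -> tuple[int, float]:
    """Best single change-point of [lo, hi) and its log-likelihood gain.

    The gain is loglik(lo,s) + loglik(s,hi) - loglik(lo,hi) under the EM
    fits. Ties break to the smallest index. Small intervals are scanned
    exhaustively with EM; large ones via the folded surrogate with an EM
    refinement window around the surrogate optimum.
    """
    cfg = config or SegmentationConfig(min_seg=min_seg)
    if hi - lo < 2 * min_seg:
        raise ValueError("no admissible split: interval shorter than 2*min_seg")
    if arrays is None:
        arrays = _ChromArrays(cc)
    candidates = np.arange(lo + min_seg, hi - min_seg + 1)
    base = _em_ll(arrays, lo, hi, cfg, cache)

    if candidates.size <= cfg.exact_scan_limit:
        window = candidates
    else:
        if scan is None:
            scan = _FoldedScan(cc)
        sur = (scan.interval_ll(np.full(candidates.size, lo), candidates)
               + scan.interval_ll(candidates, np.full(candidates.size, hi)))
        s_star = int(candidates[int(np.argmax(sur))])
        w = cfg.refine_halfwidth
        window = candidates[(candidates >= s_star - w) & (candidates <= s_star + w)]

    best_s, best_gain = int(window[0]), -np.inf
    for s in window:
        gain = (_em_ll(arrays, lo, int(s), cfg, cache)
                + _em_ll(arrays, int(s), hi, cfg, cache) - base)
        if gain > best_gain + 1e-12:
            best_s, best_gain = int(s), float(gain)
    return best_s, max(best_gain, 0.0)


def recursive_segment(cc: ChromCounts, min_seg: int = 5, max_K: int = 15,
                      config: SegmentationConfig | None = None
                      ) -> list[tuple[ChangePointSet, float]]:
    """Greedy binary segmentation: nested candidates for K = 0..K_max.

    Returns (change-point set, total EM log-likelihood) per candidate K,
    each candidate's change-points a superset of the previous one's.
    """
    cfg = config or SegmentationConfig(min_seg=min_seg, max_K=max_K)
    T = len(cc)
    scan = _FoldedScan(cc)
    arrays = _ChromArrays(cc)
    cache: dict = {}

    base_ll = _em_ll(arrays, 0, T, cfg, cache)
    candidates: list[tuple[ChangePointSet, float]] = [
        (ChangePointSet(tau=(), T=T), base_ll)
    ]
    # each open segment carries its best admissible split (or None)
    splits: dict[tuple[int, int], tuple[int, float] | None] = {}

    def propose(lo, hi):
        if hi - lo >= 2 * cfg.min_seg:
            splits[(lo, hi)] = best_split(cc, lo, hi, cfg.min_seg, cfg, scan,
                                          cache, arrays)
        else:
            splits[(lo, hi)] = None

    propose(0, T)
    tau: list[int] = []
    total_ll = base_ll
    stop_gain = cfg.stop_gain_factor * np.log(max(T, 2)) * cfg.mbic_multiplier
    while len(tau) < cfg.max_K:
        open_splits = [(seg, sp) for seg, sp in splits.items() if sp is not None]
        if not open_splits:
            break
        (lo, hi), (s, gain) = max(
            open_splits, key=lambda item: (item[1][1], -item[1][0])
        )
        if gain < stop_gain:
            break
        del splits[(lo, hi)]
        tau.append(s)
        tau.sort()
        total_ll += gain
        propose(lo, s)
        propose(s, hi)
        candidates.append((ChangePointSet(tau=tuple(tau), T=T), total_ll))
    return candidates


def mbic_penalty(tau: ChangePointSet, T: int, multiplier: float = 1.0) -> float:
    """Modified-BIC penalty for a change-point configuration.

    penalty = (3K/2) log T + (1/2) sum_k log(l_k / T), floored at K log T,
    where l_k are the segment lengths; zero when K = 0. The floor keeps
    short-segment configurations from being under-penalized.
    """
    K = tau.K
    if K == 0:
        return 0.0
    bounds = tau.boundaries()
    lengths = np.diff(bounds).astype(float)
    pen = 1.5 * K * np.log(T) + 0.5 * float(np.sum(np.log(lengths / T)))
    return multiplier * max(pen, K * np.log(T))


def mbic_score(candidate: ChangePointSet, loglik: float, T: int,
               multiplier: float = 1.0) -> float:
    """Modified-BIC score (larger is better): loglik minus the penalty."""
    return loglik - mbic_penalty(candidate, T, multiplier)


def segment_chromosome(cc: ChromCounts, totals: SampleTotals,
                       config: SegmentationConfig | None = None
                       ) -> SegmentationResult:
    """Segment one chromosome and attach per-segment ratios."""
    cfg = config or SegmentationConfig()
    T = len(cc)
    if T < 2 * cfg.min_seg:
        logger.warning("%s has %d loci (< 2*min_seg); kept as one segment",
                       cc.chrom, T)
        candidates = [(ChangePointSet(tau=(), T=T),
                       fit_segment(cc, tol=cfg.em_tol, max_iter=cfg.em_max_iter).loglik)]
    else:
        candidates = recursive_segment(cc, cfg.min_seg, cfg.max_K, cfg)

    scores = [mbic_score(cp, ll, T, cfg.mbic_multiplier) for cp, ll in candidates]
    best_k = int(np.argmax(scores))
    chosen, _ = candidates[best_k]

    segments: list[Segment] = []
    total_ll = 0.0
    bounds = chosen.boundaries()
    for lo, hi in zip(bounds, bounds[1:]):
        fit = fit_segment(cc.subset(slice(lo, hi)), tol=cfg.em_tol,
                          max_iter=cfg.em_max_iter)
        segments.append(
            Segment(
                chrom=cc.chrom,
                start_idx=lo,
                end_idx=hi,
                start_pos=int(cc.pos[lo]),
                end_pos=int(cc.pos[hi - 1]),
                n_snvs=hi - lo,
                fit=fit,
                ratios=segment_ratios(fit, totals),
            )
        )
        total_ll += fit.loglik
    return SegmentationResult(
        segments=segments,
        total_loglik=total_ll,
        K=chosen.K,
        mbic_trace=scores,
        totals=totals,
        chrom=cc.chrom,
    )


def segment_genome(chroms: Mapping[str, ChromCounts], totals: SampleTotals,
                   config: SegmentationConfig | None = None
                   ) -> dict[str, SegmentationResult]:
    """Segment every chromosome independently (embarrassingly parallel)."""
    return {
        chrom: segment_chromosome(cc, totals, config)
        for chrom, cc in chroms.items()
    }
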