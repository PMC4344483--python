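"""Bivariate two-component binomial mixture for allele-specific coverage.

At a heterozygous locus the tumor's allele-specific coverages, conditional on
the pooled tumor+normal coverages (n_A, n_B), follow a half/half mixture

    (X_A, X_B) | (n_A, n_B) ~ 1/2 (Bin(n_A, p_a), Bin(n_B, p_b))
                             + 1/2 (Bin(n_A, p_b), Bin(n_B, p_a)),

where the mixture arises from the unknown phase: each allele sits on one of
the two parental haplotypes with probability 1/2 by Mendelian segregation.
Site- and allele-specific coverage biases multiply tumor and normal means
identically and therefore cancel in the success probabilities, which relate
to the relative haplotype copy number c through p = N c / (N c + M).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .counts_io import ChromCounts, SampleTotals

_LOG_HALF = math.log(0.5)
_P_CLIP = 1e-6  # keep success probabilities off the degenerate boundary


@dataclass(frozen=True)
class SegmentParams:
    """Per-segment mixture success probabilities, ordered p_a <= p_b.

    ``p_a`` belongs to the minor (lower copy number) haplotype component and
    ``p_b`` to the major one; ties mean allelic balance.
    """

    p_a: float
    p_b: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_a <= self.p_b < 1.0):
            raise ValueError(f"require 0 < p_a <= p_b < 1, got ({self.p_a}, {self.p_b})")


@dataclass
class MixtureFit:
    """EM result for one segment."""

    params: SegmentParams
    loglik: float
    phase_post: np.ndarray  # P(allele A on the minor haplotype) per locus
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class AllelicRatios:
    """Relative haplotype copy numbers: minor <= major; (1, 1) = no change."""

    minor: float
    major: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.minor <= self.major):
            raise ValueError(f"require 0 <= minor <= major, got ({self.minor}, {self.major})")


@dataclass(frozen=True)
class ObservedASCN:
    """Per-locus observed relative allele-specific copy numbers.

    A component is NaN (undefined) when the matching normal count is zero.
    """

    cA: float
    cB: float


def _binom_logpmf(x, n, p):
    """log Binomial(x; n, p), vectorized; exact for x=n=0 (returns 0)."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return (
        gammaln(n + 1.0) - gammaln(x + 1.0) - gammaln(n - x + 1.0)
        + x * np.log(p) + (n - x) * np.log1p(-p)
    )


def _component_logliks(xA, nA, xB, nB, p_a, p_b):
    """Log-likelihood of each phase assignment per locus.

    Component 1: allele A on the p_a haplotype; component 2: the swap.
    """
    l1 = _binom_logpmf(xA, nA, p_a) + _binom_logpmf(xB, nB, p_b)
    l2 = _binom_logpmf(xA, nA, p_b) + _binom_logpmf(xB, nB, p_a)
    return l1, l2


def locus_mixture_loglik(locus, params: SegmentParams) -> float:
    """Mixture log-likelihood of one locus (log-sum-exp over the two phases).

    ``locus`` may be a LocusCounts or any object with xA, xB, yA, yB.
    """
    if not (0.0 < params.p_a < 1.0 and 0.0 < params.p_b < 1.0):
        raise ValueError("success probabilities must lie in (0, 1)")
    nA = locus.xA + locus.yA
    nB = locus.xB + locus.yB
    if nA == 0 and nB == 0:
        return 0.0
    l1, l2 = _component_logliks(locus.xA, nA, locus.xB, nB, params.p_a, params.p_b)
    return float(np.logaddexp(l1, l2) + _LOG_HALF)


def mixture_loglik_arrays(xA, nA, xB, nB, p_a: float, p_b: float) -> float:
    """Total mixture log-likelihood of a segment given fixed parameters."""
    l1, l2 = _component_logliks(xA, nA, xB, nB, p_a, p_b)
    return float(np.sum(np.logaddexp(l1, l2) + _LOG_HALF))


def _kernel_logliks(xA, nA, xB, nB, p_a, p_b):
    """Per-phase log-likelihood kernels without the binomial coefficients.

    The coefficients are parameter-free, so they cancel in EM posteriors and
    only shift the total log-likelihood by a data-only constant that is
    added back once per fit.
    """
    la, l1a = math.log(p_a), math.log1p(-p_a)
    lb, l1b = math.log(p_b), math.log1p(-p_b)
    # grouped per allele so that a label swap permutes whole summands and the
    # result is bit-identical under relabeling
    tA_a = xA * la + (nA - xA) * l1a
    tA_b = xA * lb + (nA - xA) * l1b
    tB_a = xB * la + (nB - xB) * l1a
    tB_b = xB * lb + (nB - xB) * l1b
    k1 = tA_a + tB_b
    k2 = tB_a + tA_b
    return k1, k2


def _em_run(xA, nA, xB, nB, p_a, p_b, tol, max_iter):
    """One EM run from a given start; returns (p_a, p_b, kll, w, n_iter, conv).

    ``kll`` excludes the constant binomial-coefficient terms. The E-step
    weight w is the posterior of 'allele A on the p_a haplotype'; the fixed
    1/2 mixture weights are never re-estimated.
    """
    ll_prev = -np.inf
    n_iter = 0
    converged = False
    # both posteriors are carried explicitly (w1 + w2 = 1 analytically) so
    # that swapping the allele labels permutes, bit-for-bit, the floating
    # point operations instead of rerouting them through 1 - w
    for n_iter in range(1, max_iter + 1):
        k1, k2 = _kernel_logliks(xA, nA, xB, nB, p_a, p_b)
        mix = np.logaddexp(k1, k2)
        ll = float(np.sum(mix)) + mix.size * _LOG_HALF
        w1 = np.exp(k1 - mix)
        w2 = np.exp(k2 - mix)
        p_a_new = np.sum(w1 * xA + w2 * xB) / np.sum(w1 * nA + w2 * nB)
        p_b_new = np.sum(w2 * xA + w1 * xB) / np.sum(w2 * nA + w1 * nB)
        p_a = float(np.clip(p_a_new, _P_CLIP, 1.0 - _P_CLIP))
        p_b = float(np.clip(p_b_new, _P_CLIP, 1.0 - _P_CLIP))
        if ll - ll_prev < tol:
            converged = True
            break
        ll_prev = ll
    # evaluate at the final parameters so the reported loglik matches them
    k1, k2 = _kernel_logliks(xA, nA, xB, nB, p_a, p_b)
    mix = np.logaddexp(k1, k2)
    ll = float(np.sum(mix)) + mix.size * _LOG_HALF
    w = np.exp(k1 - mix)
    return p_a, p_b, ll, w, n_iter, converged


def _initial_starts(xA, nA, xB, nB):
    """Two deterministic EM starts: a hard-phase moment start and a
    symmetric perturbation of the pooled frequency."""
    n_tot = nA + nB
    pooled = float(np.sum(xA + xB) / max(np.sum(n_tot), 1))
    pooled = min(max(pooled, _P_CLIP), 1.0 - _P_CLIP)
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = np.where(nA > 0, xA / np.maximum(nA, 1), pooled)
        fB = np.where(nB > 0, xB / np.maximum(nB, 1), pooled)
    # lexicographic tie-break keeps the fold invariant to allele-label swaps
    a_is_low = (fA < fB) | ((fA == fB) & ((xA < xB) | ((xA == xB) & (nA <= nB))))
    lo_x = np.where(a_is_low, xA, xB)
    lo_n = np.where(a_is_low, nA, nB)
    hi_x = np.where(a_is_low, xB, xA)
    hi_n = np.where(a_is_low, nB, nA)
    p_lo = float(lo_x.sum() / max(lo_n.sum(), 1))
    p_hi = float(hi_x.sum() / max(hi_n.sum(), 1))
    clip = lambda p: min(max(p, _P_CLIP), 1.0 - _P_CLIP)
    starts = [
        (clip(p_lo), clip(p_hi)),
        (clip(pooled - 0.05), clip(pooled + 0.05)),
    ]
    return starts


def fit_arrays(xA, nA, xB, nB, tol: float = 1e-6, max_iter: int = 200,
               init: SegmentParams | None = None, single_start: bool = False):
    """EM on raw count arrays; the returned loglik EXCLUDES the data-only
    binomial-coefficient constant (see :func:`lchoose_terms`).

    Returns (p_a, p_b, kernel_loglik, phase_post, n_iter, converged) with
    p_a <= p_b and phase_post the posterior of allele A on the minor
    haplotype. ``single_start`` keeps only the hard-phase moment start
    (used by the segmentation scan, where speed matters more than the rare
    tie between starts).
    """
    if np.sum(nA + nB) == 0:
        raise ValueError("degenerate segment: all-zero counts")
    starts = _initial_starts(xA, nA, xB, nB)
    if single_start:
        starts = starts[:1]
    if init is not None:
        starts.append((init.p_a, init.p_b))
    best = None
    for p_a0, p_b0 in starts:
        run = _em_run(xA, nA, xB, nB, p_a0, p_b0, tol, max_iter)
        if best is None or run[2] > best[2]:
            best = run
    p_a, p_b, ll, w, n_iter, converged = best
    if p_a > p_b:
        p_a, p_b = p_b, p_a
        w = 1.0 - w
    return p_a, p_b, ll, w, n_iter, converged


def lchoose_terms(xA, nA, xB, nB) -> np.ndarray:
    """Per-locus log binomial coefficients (parameter-free loglik part)."""
    return (
        gammaln(nA + 1.0) - gammaln(xA + 1.0) - gammaln(nA - xA + 1.0)
        + gammaln(nB + 1.0) - gammaln(xB + 1.0) - gammaln(nB - xB + 1.0)
    )


def fit_segment(loci, init: SegmentParams | None = None, tol: float = 1e-6,
                max_iter: int = 200, separation_test: bool = True) -> MixtureFit:
    """Fit the per-segment mixture by EM with fixed 1/2 weights.

    ``loci`` is a ChromCounts (or any object exposing xA, xB, yA, yB arrays).
    Two deterministic starts are tried and the higher-likelihood fit kept;
    an explicit ``init`` adds a third start.

    When ``separation_test`` is on (the default), the two-parameter mixture
    is compared against the one-parameter model p_a = p_b by BIC. Fitting a
    mixture to a segment whose haplotypes are actually balanced inflates the
    estimated separation (the larger per-locus frequency is always assigned
    to the larger component), so without this test homozygous deletions and
    double gains — whose two ratios are truly equal — are systematically
    reported as asymmetric. If the mixture does not improve the constrained
    log-likelihood by more than 0.5*log(T), the pooled estimate is reported
    for both parameters and the phase posterior is the uninformative 1/2.
    """
    xA = np.asarray(loci.xA, dtype=float)
    xB = np.asarray(loci.xB, dtype=float)
    nA = xA + np.asarray(loci.yA, dtype=float)
    nB = xB + np.asarray(loci.yB, dtype=float)
    p_a, p_b, ll, w, n_iter, converged = fit_arrays(
        xA, nA, xB, nB, tol=tol, max_iter=max_iter, init=init)
    if separation_test:
        p0 = float(np.sum(xA + xB) / max(np.sum(nA + nB), 1.0))
        p0 = min(max(p0, _P_CLIP), 1.0 - _P_CLIP)
        # constrained (p_a = p_b = p0) kernel loglik: the mixture collapses
        # to independent binomials, so the log(1/2) terms cancel exactly
        ll0 = float(np.sum((xA + xB) * math.log(p0)
                           + (nA - xA + nB - xB) * math.log1p(-p0)))
        if ll - ll0 <= 0.5 * math.log(max(xA.size, 2)):
            p_a = p_b = p0
            ll = ll0
            w = np.full(xA.size, 0.5)
    # add back the parameter-free binomial coefficients (once per fit)
    ll += float(np.sum(lchoose_terms(xA, nA, xB, nB)))
    return MixtureFit(
        params=SegmentParams(p_a=p_a, p_b=p_b),
        loglik=ll,
        phase_post=w,
        n_iter=n_iter,
        converged=converged,
    )


def segment_loglik(loci, tol: float = 1e-6, max_iter: int = 200) -> float:
    """Maximized mixture log-likelihood of a segment (convenience)."""
    return fit_segment(loci, tol=tol, max_iter=max_iter).loglik


def prob_to_ratio(p: float, totals: SampleTotals) -> float:
    """Invert p = N c / (N c + M): relative copy number c = p/(1-p) * M/N."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"success probability out of range: {p}")
    if p == 1.0:
        warnings.warn("p = 1 maps to infinite relative copy number")
        return math.inf
    return (p / (1.0 - p)) * (totals.M / totals.N)


def ratio_to_prob(c: float, totals: SampleTotals) -> float:
    """Forward map from relative copy number to success probability."""
    if c < 0:
        raise ValueError(f"relative copy number must be >= 0, got {c}")
    return totals.N * c / (totals.N * c + totals.M)


def observed_ascn(locus, totals: SampleTotals) -> ObservedASCN:
    """Per-locus observed relative ASCN: (x/y) * (M/N) per allele.

    Equivalent to mapping the raw per-locus success frequency x/(x+y)
    through the same odds transform used for the fitted parameters. A
    component with zero normal coverage is undefined (NaN), not an error.
    """
    ratio = totals.M / totals.N
    cA = (locus.xA / locus.yA) * ratio if locus.yA > 0 else math.nan
    cB = (locus.xB / locus.yB) * ratio if locus.yB > 0 else math.nan
    return ObservedASCN(cA=cA, cB=cB)


def observed_ascn_arrays(loci: ChromCounts, totals: SampleTotals):
    """Vectorized observed ASCN for plotting; NaN where normal count is 0."""
    ratio = totals.M / totals.N
    with np.errstate(divide="ignore", invalid="ignore"):
        cA = np.where(loci.yA > 0, loci.xA / np.maximum(loci.yA, 1) * ratio, np.nan)
        cB = np.where(loci.yB > 0, loci.xB / np.maximum(loci.yB, 1) * ratio, np.nan)
    return cA, cB


def segment_ratios(fit: MixtureFit, totals: SampleTotals) -> AllelicRatios:
    """Convert fitted success probabilities to minor/major allelic ratios."""
    return AllelicRatios(
        minor=prob_to_ratio(fit.params.p_a, totals),
        major=prob_to_ratio(fit.params.p_b, totals),
    )
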