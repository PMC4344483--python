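"""Event-specific purity and simple clonal-ordering checks.

For a mutation carried by a fraction f of the cells in a sample, a haplotype
present in c copies per aberrant cell has relative ratio f*c + (1-f). Two
event types make f directly identifiable from the allelic ratios:

    normal/loss          aberrant cells carry (0, 1):  minor = 1 - f
    balanced gain/loss   aberrant cells carry (0, 2):  minor = 1 - f,
                                                       major = 1 + f

Gain-type events confound f with the (integer) number of gained copies and
are excluded. Events sharing a purity across one or two samples are grouped
by single-linkage clustering; pairwise clonal nesting G contains H is
admissible only if f_H <= f_G (pigeonhole on cell fractions) within error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .counts_io import ChromCounts, SampleTotals
from .event_calling import (BALANCED_GAIN_LOSS, NORMAL, NORMAL_LOSS, CNEvent,
                            classify_segment)
from .mixture_model import fit_segment, segment_ratios


@dataclass
class PurityEstimate:
    """Fraction of cells carrying one event's mutation."""

    event: CNEvent
    f: float
    se: float | None = None
    #: for balanced gain/loss: |f_from_loss - f_from_gain|
    discrepancy: float | None = None


@dataclass
class EventGroup:
    label: str
    members: list[int]  # indices into the input purity list(s)
    mean_purity: tuple[float, ...] = ()


def _clip_unit(f: float) -> float:
    if f < 0.0 or f > 1.0:
        warnings.warn(f"purity estimate {f:.3f} outside [0, 1]; clipped")
    return float(min(max(f, 0.0), 1.0))


def normal_baseline(results, delta: float = 0.2,
                    balance_tol: float = 0.1) -> float:
    """Locus-weighted mean ratio of segments classified "normal".

    Allelic ratios are relative to the average ploidy through the library
    totals, so large aberrations compress or inflate every ratio by a common
    factor. Anchoring on the unaberrated segments removes that factor before
    purity is computed. ``results`` is one SegmentationResult or an iterable
    of them; returns 1.0 when no normal segment exists.
    """
    if hasattr(results, "segments"):
        results = [results]
    num = den = 0.0
    for res in results:
        for seg in res.segments:
            if classify_segment(seg.ratios, delta, balance_tol) == NORMAL:
                num += seg.n_snvs * 0.5 * (seg.ratios.minor + seg.ratios.major)
                den += seg.n_snvs
    return num / den if den > 0 else 1.0


def event_purity(event: CNEvent, loci: ChromCounts | None = None,
                 totals: SampleTotals | None = None, n_boot: int = 200,
                 seed: int = 0, baseline: float = 1.0) -> PurityEstimate:
    """Point estimate of the event-specific purity, optionally with a
    bootstrap standard error.

    When ``loci`` (the full chromosome's counts) and ``totals`` are given,
    the SE is estimated by resampling the event's loci with replacement and
    refitting the mixture (the M/N normalization is held fixed).
    ``baseline`` is the estimated ratio of unaberrated regions (see
    :func:`normal_baseline`); event ratios are divided by it so the purity
    is unaffected by the common normalization factor the aberrations
    themselves impose on the library totals.
    """
    if baseline <= 0:
        raise ValueError("baseline ratio must be positive")
    if event.type == NORMAL_LOSS:
        point = _clip_unit(1.0 - event.minor_ratio / baseline)
        discrepancy = None
    elif event.type == BALANCED_GAIN_LOSS:
        f_loss = 1.0 - event.minor_ratio / baseline
        f_gain = event.major_ratio / baseline - 1.0
        point = _clip_unit(0.5 * (f_loss + f_gain))
        discrepancy = abs(f_loss - f_gain)
    else:
        raise ValueError(
            f"purity not identifiable from event type {event.type!r}"
        )

    se = None
    if loci is not None and totals is not None and event.start_idx >= 0:
        rng = np.random.default_rng(seed)
        span = loci.subset(slice(event.start_idx, event.end_idx))
        n = len(span)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = np.sort(rng.integers(0, n, size=n))
            boot = ChromCounts(span.chrom, np.arange(1, n + 1),
                               span.xA[idx], span.xB[idx],
                               span.yA[idx], span.yB[idx])
            ratios = segment_ratios(fit_segment(boot), totals)
            if event.type == NORMAL_LOSS:
                reps[b] = 1.0 - ratios.minor / baseline
            else:
                reps[b] = 0.5 * ((1.0 - ratios.minor / baseline)
                                 + (ratios.major / baseline - 1.0))
        se = float(np.std(reps, ddof=1))
    return PurityEstimate(event=event, f=point, se=se, discrepancy=discrepancy)


def group_by_purity(purities, linkage_threshold: float = 0.05
                    ) -> list[EventGroup]:
    """Single-linkage clustering of events in purity space.

    ``purities`` is a sequence whose elements are either PurityEstimate
    (one sample) or tuples/lists of PurityEstimate (the same event measured
    in several samples); clustering then runs in 1-D or k-D accordingly.
    Groups are labeled G1, G2, ... by descending mean purity in sample 1
    and are invariant to the input order of the events.
    """
    pts = []
    for p in purities:
        if isinstance(p, PurityEstimate):
            pts.append([p.f])
        else:
            pts.append([q.f for q in p])
    X = np.asarray(pts, dtype=float)
    if X.size == 0:
        raise ValueError("need at least one purity estimate")
    if X.shape[0] == 1:
        labels = np.array([1])
    else:
        Z = linkage(X, method="single", metric="euclidean")
        labels = fcluster(Z, t=linkage_threshold, criterion="distance")

    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    out = []
    for members in groups.values():
        means = tuple(float(np.mean(X[members, j])) for j in range(X.shape[1]))
        out.append(EventGroup(label="", members=sorted(members), mean_purity=means))
    out.sort(key=lambda g: -g.mean_purity[0])
    for i, g in enumerate(out):
        g.label = f"G{i + 1}"
    return out


@dataclass(frozen=True)
class NestingRelation:
    """Whether 'cells carrying H are a subset of cells carrying G' is
    consistent with the per-sample purities."""

    ancestor: str  # group G
    descendant: str  # group H
    admissible: bool
    margins: tuple[float, ...]  # f_G - f_H per sample (>= -2 se if admissible)


def check_subclonal_consistency(groups: list[EventGroup],
                                purities_by_sample: np.ndarray,
                                se_by_sample: np.ndarray | None = None
                                ) -> list[NestingRelation]:
    """Flag admissible ancestry relations between purity groups.

    ``purities_by_sample`` has shape (n_groups, n_samples): the mean event
    purity of each group in each sample. H nested in G requires
    f_H <= f_G in every sample, allowing a 2-SE slack per comparison.
    Full clonal-tree enumeration is deliberately left to the user.
    """
    P = np.asarray(purities_by_sample, dtype=float)
    if se_by_sample is None:
        SE = np.zeros_like(P)
    else:
        SE = np.asarray(se_by_sample, dtype=float)
    relations = []
    for i, g in enumerate(groups):
        for j, h in enumerate(groups):
            if i == j:
                continue
            margins = P[i] - P[j]
            slack = 2.0 * np.sqrt(SE[i] ** 2 + SE[j] ** 2)
            admissible = bool(np.all(margins >= -slack))
            relations.append(
                NestingRelation(
                    ancestor=g.label,
                    descendant=h.label,
                    admissible=admissible,
                    margins=tuple(float(m) for m in margins),
                )
            )
    return relations
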