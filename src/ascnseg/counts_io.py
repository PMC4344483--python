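"""Reading, validation, filtering and writing of per-locus allele-specific counts.

The central container is :class:`ChromCounts`, a column-oriented view of the
allele-specific read counts at inherited heterozygous SNV loci for one
chromosome: tumor counts ``(xA, xB)`` and matched-normal counts ``(yA, yB)``
per locus. Coordinates are 1-based on input (VCF convention); segment/event
output is written 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default column names of the tabular locus format
DEFAULT_DIALECT: dict[str, str] = {
    "chrom": "chrom",
    "pos": "pos",
    "tumor_ref": "tumor_ref",
    "tumor_alt": "tumor_alt",
    "normal_ref": "normal_ref",
    "normal_alt": "normal_alt",
}


class CountsValidationError(ValueError):
    """Raised when a locus table violates the count/ordering contract."""


class ConfigurationError(ValueError):
    """Raised when required columns are missing or a dialect is malformed."""


class LocusCounts(NamedTuple):
    """Allele-specific read counts at one heterozygous locus.

    ``A`` is the reference allele and ``B`` the alternate allele when counts
    come from VCF allelic-depth fields; the model is label-symmetric so the
    assignment is only a bookkeeping convention.
    """

    chrom: str
    pos: int
    xA: int  # tumor, allele A
    xB: int  # tumor, allele B
    yA: int  # normal, allele A
    yB: int  # normal, allele B


@dataclass(frozen=True)
class SampleTotals:
    """Total read counts used for normalization: M (normal), N (tumor).

    Only the ratio M/N enters the conversion between success probabilities
    and relative copy numbers, so totals over the retained heterozygous loci
    are a self-consistent default; library-wide totals may be supplied
    instead.
    """

    M: float
    N: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and self.N > 0):
            raise CountsValidationError("sample totals M and N must be positive")


@dataclass
class ChromCounts:
    """Counts for all retained loci of one chromosome, sorted by position."""

    chrom: str
    pos: np.ndarray  # 1-based, strictly increasing
    xA: np.ndarray
    xB: np.ndarray
    yA: np.ndarray
    yB: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        for name in ("xA", "xB", "yA", "yB"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if arr.shape != self.pos.shape:
                raise CountsValidationError(f"{name} length does not match pos")
            if np.any(arr < 0):
                raise CountsValidationError(f"negative counts in {name}")
            setattr(self, name, arr)
        if np.any(np.diff(self.pos) <= 0):
            raise CountsValidationError(
                f"positions on {self.chrom} not strictly increasing"
            )

    def __len__(self) -> int:
        return self.pos.size

    @property
    def nA(self) -> np.ndarray:
        """Pooled tumor+normal coverage of allele A, n_t = x_t + y_t."""
        return self.xA + self.yA

    @property
    def nB(self) -> np.ndarray:
        return self.xB + self.yB

    def subset(self, idx) -> "ChromCounts":
        return ChromCounts(
            self.chrom, self.pos[idx], self.xA[idx], self.xB[idx],
            self.yA[idx], self.yB[idx],
        )

    def loci(self) -> Iterable[LocusCounts]:
        for i in range(len(self)):
            yield LocusCounts(
                self.chrom, int(self.pos[i]), int(self.xA[i]), int(self.xB[i]),
                int(self.yA[i]), int(self.yB[i]),
            )

    def to_frame(self, dialect: Mapping[str, str] = DEFAULT_DIALECT) -> pd.DataFrame:
        return pd.DataFrame(
            {
                dialect["chrom"]: self.chrom,
                dialect["pos"]: self.pos,
                dialect["tumor_ref"]: self.xA,
                dialect["tumor_alt"]: self.xB,
                dialect["normal_ref"]: self.yA,
                dialect["normal_alt"]: self.yB,
            }
        )


@dataclass
class QCReport:
    """Per-reason removal counts from :func:`qc_filter`."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)


def _frame_to_chroms(df: pd.DataFrame, dialect: Mapping[str, str],
                     source: str) -> dict[str, ChromCounts]:
    count_cols = ["tumor_ref", "tumor_alt", "normal_ref", "normal_alt"]
    for key in count_cols + ["pos"]:
        col = dialect[key]
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (np.mod(numeric, 1) != 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CountsValidationError(
                f"{source}: non-integer value in column '{col}' at data row {row + 1}"
            )
        if key != "pos" and (numeric < 0).any():
            row = int(np.flatnonzero((numeric < 0).to_numpy())[0])
            raise CountsValidationError(
                f"{source}: negative count in column '{col}' at data row {row + 1}"
            )
        df[col] = numeric.astype(np.int64)

    dup = df.duplicated(subset=[dialect["chrom"], dialect["pos"]])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CountsValidationError(f"{source}: duplicate (chrom, pos) at data row {row + 1}")

    out: dict[str, ChromCounts] = {}
    for chrom, grp in df.groupby(dialect["chrom"], sort=False):
        if not grp[dialect["pos"]].is_monotonic_increasing:
            logger.warning("loci on %s were unsorted; sorting by position", chrom)
            grp = grp.sort_values(dialect["pos"])
        out[str(chrom)] = ChromCounts(
            str(chrom),
            grp[dialect["pos"]].to_numpy(),
            grp[dialect["tumor_ref"]].to_numpy(),
            grp[dialect["tumor_alt"]].to_numpy(),
            grp[dialect["normal_ref"]].to_numpy(),
            grp[dialect["normal_alt"]].to_numpy(),
        )
    return out


def read_counts_table(path, dialect: Mapping[str, str] | None = None
                      ) -> dict[str, ChromCounts]:
    """Read a TSV locus table into per-chromosome count collections.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    dialect
        Mapping from the canonical keys (``chrom``, ``pos``, ``tumor_ref``,
        ``tumor_alt``, ``normal_ref``, ``normal_alt``) to the column names
        actually present in the file.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [col for col in d.values() if col not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: missing required columns {missing}")
    return _frame_to_chroms(df, d, str(path))


def read_vcf_pair(tumor_vcf, normal_vcf, *, normal_sample: str | None = None,
                  tumor_sample: str | None = None) -> dict[str, ChromCounts]:
    """Extract allele-specific counts from a tumor/normal VCF pair.

    Loci are taken where the normal genotype is heterozygous (0/1) and the
    site is bi-allelic; counts come from the AD (allelic depth) FORMAT field.
    Multi-allelic sites are dropped with a logged count. Allele "A" is the
    reference allele, "B" the alternate.
    """
    import pysam

    def _load(path, sample):
        vf = pysam.VariantFile(str(path))
        name = sample or list(vf.header.samples)[0]
        records = {}
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ad = rec.samples[name].get("AD")
            if ad is None or len(ad) < 2 or ad[0] is None:
                continue
            records[(rec.chrom, rec.pos)] = (int(ad[0]), int(ad[1]))
        gts = {}
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            gts[(rec.chrom, rec.pos)] = rec.samples[name].get("GT")
        return records, gts

    normal_ad, normal_gt = _load(normal_vcf, normal_sample)
    tumor_ad, _ = _load(tumor_vcf, tumor_sample)

    n_multi_or_missing = 0
    rows = []
    for key, (yA, yB) in normal_ad.items():
        gt = normal_gt.get(key)
        if gt is None or set(gt) != {0, 1}:
            continue
        if key not in tumor_ad:
            n_multi_or_missing += 1
            continue
        xA, xB = tumor_ad[key]
        rows.append((key[0], key[1], xA, xB, yA, yB))
    if n_multi_or_missing:
        logger.info("dropped %d het loci without usable tumor AD", n_multi_or_missing)
    rows.sort(key=lambda r: (r[0], r[1]))
    df = pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values()))
    return _frame_to_chroms(df.astype({"pos": np.int64}), DEFAULT_DIALECT, "vcf pair")


def write_counts_table(chroms: Mapping[str, ChromCounts], path,
                       dialect: Mapping[str, str] | None = None) -> None:
    """Write per-chromosome counts back to the TSV locus format (lossless)."""
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    frames = [cc.to_frame(d) for cc in chroms.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def qc_filter(chroms: Mapping[str, ChromCounts], *, min_total: int = 1,
              max_total: float = np.inf,
              mask: Sequence[tuple[str, int, int]] = ()
              ) -> tuple[dict[str, ChromCounts], QCReport]:
    """Remove loci with out-of-range normal coverage or inside masked regions.

    ``mask`` holds (chrom, start, end) intervals, 1-based inclusive — intended
    for centromeres/telomeres where mapping artifacts inflate false calls.
    """
    if not (1 <= min_total <= max_total):
        raise ConfigurationError("require 1 <= min_total <= max_total")
    report = QCReport(removed={"low_coverage": 0, "high_coverage": 0, "mask": 0})
    out: dict[str, ChromCounts] = {}
    for chrom, cc in chroms.items():
        total = cc.yA + cc.yB
        low = total < min_total
        high = total > max_total
        masked = np.zeros(len(cc), dtype=bool)
        for mchrom, start, end in mask:
            if mchrom == chrom:
                masked |= (cc.pos >= start) & (cc.pos <= end)
        keep = ~(low | high | masked)
        report.n_input += len(cc)
        report.removed["low_coverage"] += int((low & ~masked).sum())
        report.removed["high_coverage"] += int((high & ~low & ~masked).sum())
        report.removed["mask"] += int(masked.sum())
        if keep.any():
            out[chrom] = cc.subset(keep)
            report.n_retained += int(keep.sum())
    if report.n_retained == 0:
        raise CountsValidationError("no usable loci after QC filtering")
    return out, report


def compute_totals(chroms: Mapping[str, ChromCounts], mode: str = "at-loci",
                   supplied: SampleTotals | None = None) -> SampleTotals:
    """Sample totals M (normal) and N (tumor).

    ``at-loci`` sums the retained heterozygous-locus counts genome-wide;
    ``supplied`` passes library-wide totals through.
    """
    if mode == "supplied":
        if supplied is None:
            raise ConfigurationError("mode='supplied' requires totals")
        return supplied
    if mode != "at-loci":
        raise ConfigurationError(f"unknown totals mode {mode!r}")
    if not chroms:
        raise CountsValidationError("no loci to compute totals from")
    M = sum(int(cc.yA.sum() + cc.yB.sum()) for cc in chroms.values())
    N = sum(int(cc.xA.sum() + cc.xB.sum()) for cc in chroms.values())
    if M == 0 or N == 0:
        raise CountsValidationError("zero total read count")
    return SampleTotals(M=float(M), N=float(N))


SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_snvs", "minor_ratio", "major_ratio", "type",
]


def write_segments(result, path) -> None:
    """Write a segmentation as a BED-like TSV (0-based half-open coordinates)."""
    from .event_calling import classify_segment

    rows = []
    for seg in result.segments:
        rows.append(
            {
                "chrom": seg.chrom,
                "start": seg.start_pos - 1,
                "end": seg.end_pos,
                "n_snvs": seg.n_snvs,
                "minor_ratio": round(seg.ratios.minor, 6),
                "major_ratio": round(seg.ratios.major, 6),
                "type": classify_segment(seg.ratios),
            }
        )
    if not rows:
        raise CountsValidationError("empty segmentation result")
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_segments` output."""
    return pd.read_csv(path, sep="\t")
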