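"""Alignment filtering, per-window unique-read counting and the coverage QC gate.

Retains a read iff it is not a PCR duplicate, not secondary/supplementary,
not unmapped, at least 35 bp long, and has MAPQ >= 60; surviving reads are
"uniquely mapped reads" (UMRs).  Each UMR increments the single window
containing its leftmost aligned base.  Mean genome coverage of UMRs must
reach 0.16X for a sample to enter analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .genome_model import GenomeWindows, locate_window

__all__ = [
    "MIN_READ_LENGTH",
    "MIN_MAPQ",
    "QC_COVERAGE_THRESHOLD",
    "DEFAULT_READ_LENGTH",
    "AlignmentRecord",
    "FilterTally",
    "WindowCounts",
    "QcResult",
    "filter_alignments",
    "iter_sam",
    "count_windows",
    "count_sam",
    "qc_coverage",
    "read_counts_tsv",
    "write_counts_tsv",
]

MIN_READ_LENGTH = 35
MIN_MAPQ = 60
QC_COVERAGE_THRESHOLD = 0.16
#: Nominal read length for coverage; single-end 160-cycle chemistry yields
#: variable lengths, so this is configurable.
DEFAULT_READ_LENGTH = 150


@dataclass(frozen=True)
class AlignmentRecord:
    """Minimal view of one aligned read."""

    chrom: str
    pos: int          # 0-based leftmost aligned base
    length: int       # aligned read length in bp
    mapq: int
    is_duplicate: bool = False
    is_secondary: bool = False   # secondary or supplementary alignment
    is_unmapped: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0 or self.length < 0:
            raise ValueError("pos and length must be nonnegative")

    @classmethod
    def from_pysam(cls, rec: pysam.AlignedSegment) -> "AlignmentRecord":
        # unmapped records carry reference_start == -1; clamp so the
        # dataclass invariant holds (they are removed by the filter anyway)
        return cls(
            chrom=rec.reference_name or "*",
            pos=max(rec.reference_start if rec.reference_start is not None else 0, 0),
            length=rec.query_length or (rec.infer_query_length() or 0),
            mapq=rec.mapping_quality,
            is_duplicate=rec.is_duplicate,
            is_secondary=rec.is_secondary or rec.is_supplementary,
            is_unmapped=rec.is_unmapped,
        )


@dataclass
class FilterTally:
    """Counts of reads removed per filter reason, plus retained."""

    retained: int = 0
    duplicate: int = 0
    multimapped: int = 0
    unmapped: int = 0
    short: int = 0
    low_mapq: int = 0

    @property
    def total(self) -> int:
        return (self.retained + self.duplicate + self.multimapped
                + self.unmapped + self.short + self.low_mapq)

    def as_dict(self) -> dict[str, int]:
        return {
            "retained": self.retained, "duplicate": self.duplicate,
            "multimapped": self.multimapped, "unmapped": self.unmapped,
            "short": self.short, "low_mapq": self.low_mapq,
        }


def _classify(rec: AlignmentRecord) -> str | None:
    """Removal reason for a record, or None if retained.

    The first matching reason in the fixed order unmapped > duplicate >
    multimapped > short > low_mapq is reported, so tallies are deterministic
    for reads failing several filters.
    """
    if rec.is_unmapped:
        return "unmapped"
    if rec.is_duplicate:
        return "duplicate"
    if rec.is_secondary:
        return "multimapped"
    if rec.length < MIN_READ_LENGTH:
        return "short"
    if rec.mapq < MIN_MAPQ:
        return "low_mapq"
    return None


def filter_alignments(records: Iterable[AlignmentRecord],
                      tally: FilterTally | None = None) -> Iterator[AlignmentRecord]:
    """Yield retained records; removal reasons accumulate in ``tally``.

    Idempotent: records that survive once survive again unchanged.
    """
    if tally is None:
        tally = FilterTally()
    for rec in records:
        reason = _classify(rec)
        if reason is None:
            tally.retained += 1
            yield rec
        else:
            setattr(tally, reason, getattr(tally, reason) + 1)


def iter_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a plain-text SAM file."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for rec in fh:
            yield AlignmentRecord.from_pysam(rec)


@dataclass
class WindowCounts:
    """Per-sample unique-read counts, one per window of a GenomeWindows tiling."""

    sample_id: str
    windows: GenomeWindows
    counts: np.ndarray                  # int, len == len(windows)
    other: int = 0                      # reads on chromosomes outside the tiling
    tally: FilterTally | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.windows),):
            raise ValueError("counts length must equal number of windows")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total_umr(self) -> int:
        """Total unique reads counted on the tiled chromosomes."""
        return int(self.counts.sum())

    def chrom_total(self, chrom: str) -> int:
        return int(self.counts[self.windows.chrom_slice(chrom)].sum())


def count_windows(records: Iterable[AlignmentRecord], windows: GenomeWindows,
                  sample_id: str = "sample") -> WindowCounts:
    """Count retained reads into windows by leftmost aligned base.

    Reads on chromosomes absent from the tiling go to the ``other`` bucket
    and are excluded from ``total_umr``.
    """
    counts = np.zeros(len(windows), dtype=np.int64)
    other = 0
    known = set(windows.chrom_names)
    for rec in records:
        if rec.chrom not in known:
            other += 1
            continue
        idx = locate_window(windows, rec.chrom, rec.pos)
        counts[windows.global_index(rec.chrom, idx)] += 1
    return WindowCounts(sample_id, windows, counts, other=other)


def count_sam(path: str | Path, windows: GenomeWindows,
              sample_id: str | None = None) -> WindowCounts:
    """Filter and count a SAM file in one pass; tally attached to the result."""
    tally = FilterTally()
    wc = count_windows(filter_alignments(iter_sam(path), tally), windows,
                       sample_id=sample_id or Path(path).stem)
    wc.tally = tally
    return wc


@dataclass(frozen=True)
class QcResult:
    """Coverage QC gate outcome: coverage = UMRs x read_length / genome_length."""

    coverage: float
    threshold: float

    @property
    def passed(self) -> bool:
        return self.coverage >= self.threshold

    def as_dict(self) -> dict:
        return {"coverage": self.coverage, "threshold": self.threshold,
                "pass": self.passed}


def qc_coverage(counts: WindowCounts, read_length: int = DEFAULT_READ_LENGTH,
                genome_length: int | None = None,
                threshold: float = QC_COVERAGE_THRESHOLD) -> QcResult:
    """Mean genome coverage of unique reads; pass iff >= threshold (inclusive)."""
    if read_length <= 0:
        raise ValueError("read_length must be > 0")
    if genome_length is None:
        genome_length = counts.windows.total_length()
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    coverage = counts.total_umr * read_length / genome_length
    return QcResult(coverage=coverage, threshold=threshold)


def write_counts_tsv(counts: WindowCounts, path: str | Path) -> None:
    """One row per window: chrom, start, end, count; sample id in the header."""
    with open(path, "w") as fh:
        fh.write(f"#sample_id={counts.sample_id}\n")
        fh.write("chrom\tstart\tend\tcount\n")
        for w, c in zip(counts.windows, counts.counts):
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{int(c)}\n")


def read_counts_tsv(path: str | Path, windows: GenomeWindows,
                    sample_id: str | None = None) -> WindowCounts:
    """Load a counts TSV; rows must match the tiling exactly, in order."""
    rows: list[tuple[str, int, int, int]] = []
    sid = sample_id
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                if line.startswith("#sample_id=") and sid is None:
                    sid = line.split("=", 1)[1]
                continue
            if not line or line.startswith("chrom\t"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
    if len(rows) != len(windows):
        raise ValueError(
            f"{path}: {len(rows)} rows but tiling has {len(windows)} windows")
    counts = np.empty(len(windows), dtype=np.int64)
    for i, ((chrom, start, end, c), w) in enumerate(zip(rows, windows)):
        if (chrom, start, end) != (w.chrom, w.start, w.end):
            raise ValueError(f"{path}: row {i} ({chrom}:{start}-{end}) does not "
                             f"match window {w.chrom}:{w.start}-{w.end}")
        counts[i] = c
    return WindowCounts(sid or Path(path).stem, windows, counts)
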