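"""Genome coordinate model: chromosomes, the 2 Mb window tiling, and syndrome regions.

All coordinates are 0-based, half-open, throughout the package.  The analysis
set is the 22 autosomes; sex chromosomes may be present in inputs but are
never scored.  Chromosome lengths default to hg19 but any genome (including
the miniature test genome used by the simulator) can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "WINDOW_SIZE",
    "ANALYSIS_CHROMOSOMES",
    "HG19_SIZES",
    "Chromosome",
    "Window",
    "GenomeWindows",
    "SyndromeRegion",
    "build_windows",
    "locate_window",
    "load_chrom_sizes",
    "load_syndrome_regions",
]

#: Default window size: 2 Mb, the unit of all window-level analysis.
WINDOW_SIZE = 2_000_000

#: Chromosomes entering z-score and CNV calling (autosomes only).
ANALYSIS_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))

#: hg19 (GRCh37) autosome lengths in bp.
HG19_SIZES = {
    "chr1": 249_250_621, "chr2": 243_199_373, "chr3": 198_022_430,
    "chr4": 191_154_276, "chr5": 180_915_260, "chr6": 171_115_067,
    "chr7": 159_138_663, "chr8": 146_364_022, "chr9": 141_213_431,
    "chr10": 135_534_747, "chr11": 135_006_516, "chr12": 133_851_895,
    "chr13": 115_169_878, "chr14": 107_349_540, "chr15": 102_531_392,
    "chr16": 90_354_753, "chr17": 81_195_210, "chr18": 78_077_248,
    "chr19": 59_128_983, "chr20": 63_025_520, "chr21": 48_129_895,
    "chr22": 51_304_566,
}


@dataclass(frozen=True)
class Chromosome:
    """A chromosome with its length in bp."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name!r}: length must be > 0")


@dataclass(frozen=True)
class Window:
    """One tile of the genome, 0-based half-open [start, end).

    ``index`` is the ordinal within the chromosome; ``partial`` marks the
    trailing window of a chromosome whose length is not a multiple of the
    window size.  ``gc`` is filled in by :mod:`gnipt.gc_normalize`.
    """

    chrom: str
    start: int
    end: int
    index: int
    partial: bool = False
    gc: float | None = None

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class GenomeWindows:
    """Ordered window tiling of a genome.

    Windows are contiguous, non-overlapping and cover each chromosome's
    [0, length).  Iteration order is (chromosome order, start).
    """

    def __init__(self, chromosomes: Sequence[Chromosome], windows: Sequence[Window],
                 window_size: int) -> None:
        self.chromosomes = list(chromosomes)
        self.windows = list(windows)
        self.window_size = window_size
        self._chrom_length = {c.name: c.length for c in self.chromosomes}
        self._chrom_offset: dict[str, int] = {}
        self._chrom_nwin: dict[str, int] = {}
        for gi, w in enumerate(self.windows):
            if w.chrom not in self._chrom_offset:
                self._chrom_offset[w.chrom] = gi
            self._chrom_nwin[w.chrom] = self._chrom_nwin.get(w.chrom, 0) + 1

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, gi: int) -> Window:
        return self.windows[gi]

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def analysis_chroms(self) -> list[str]:
        """Chromosome names entering z-score / CNV analysis (autosomes)."""
        return [c.name for c in self.chromosomes if c.name in ANALYSIS_CHROMOSOMES]

    def chrom_length(self, chrom: str) -> int:
        return self._chrom_length[chrom]

    def total_length(self, chroms: Iterable[str] | None = None) -> int:
        names = list(chroms) if chroms is not None else self.chrom_names
        return sum(self._chrom_length[c] for c in names)

    def n_windows(self, chrom: str) -> int:
        return self._chrom_nwin.get(chrom, 0)

    def global_index(self, chrom: str, index: int) -> int:
        """Flat index of window ``index`` of ``chrom`` across the genome."""
        if chrom not in self._chrom_offset:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= index < self._chrom_nwin[chrom]:
            raise IndexError(f"{chrom} has no window {index}")
        return self._chrom_offset[chrom] + index

    def chrom_slice(self, chrom: str) -> slice:
        """Slice of the flat window arrays covering ``chrom``."""
        if chrom not in self._chrom_offset:
            raise KeyError(f"unknown chromosome {chrom!r}")
        off = self._chrom_offset[chrom]
        return slice(off, off + self._chrom_nwin[chrom])

    def chrom_windows(self, chrom: str) -> list[Window]:
        return self.windows[self.chrom_slice(chrom)]


@dataclass(frozen=True)
class SyndromeRegion:
    """A genomic interval associated with a named, clinically known syndrome."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.name}: start must be < end")
        if not self.name:
            raise ValueError("syndrome region requires a nonempty name")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) on chrom intersects this region by >= 1 bp."""
        return chrom == self.chrom and start < self.end and self.start < end


def build_windows(chromosomes: Sequence[Chromosome] | dict[str, int],
                  window_size: int = WINDOW_SIZE) -> GenomeWindows:
    """Tile each chromosome into half-open windows of ``window_size`` bp.

    The trailing window of a chromosome whose length is not a multiple of
    ``window_size`` is retained (shorter, flagged ``partial``); downstream
    z-scores compare it against the same window of the reference, so the
    partial width cancels out.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if isinstance(chromosomes, dict):
        chromosomes = [Chromosome(n, l) for n, l in chromosomes.items()]
    names = [c.name for c in chromosomes]
    if len(set(names)) != len(names):
        raise ValueError("chromosome names must be unique")
    windows: list[Window] = []
    for chrom in chromosomes:
        idx = 0
        for start in range(0, chrom.length, window_size):
            end = min(start + window_size, chrom.length)
            windows.append(Window(chrom.name, start, end, idx,
                                  partial=(end - start) < window_size))
            idx += 1
    return GenomeWindows(chromosomes, windows, window_size)


def locate_window(windows: GenomeWindows, chrom: str, pos: int) -> int:
    """Within-chromosome index of the window containing position ``pos``.

    Equals floor(pos / window_size) for full-size windows.  Raises
    ``KeyError`` for an unknown chromosome and ``ValueError`` for an
    out-of-range position.
    """
    if chrom not in windows._chrom_length:
        raise KeyError(f"unknown chromosome {chrom!r}")
    length = windows.chrom_length(chrom)
    if not 0 <= pos < length:
        raise ValueError(f"position {pos} outside [0, {length}) on {chrom}")
    idx = pos // windows.window_size
    return min(idx, windows.n_windows(chrom) - 1)


def load_chrom_sizes(path: str | Path) -> list[Chromosome]:
    """Read chromosome sizes from a 2-column TSV or a FASTA index (.fai).

    Only the first two columns (name, length) are used, so samtools-style
    .fai files parse directly.
    """
    out: list[Chromosome] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 tab-separated columns")
            try:
                length = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: length {parts[1]!r} is not an integer") from exc
            out.append(Chromosome(parts[0], length))
    return out


def load_syndrome_regions(path: str | Path) -> list[SyndromeRegion]:
    """Read known-syndrome regions from a BED file (>= 4 columns, 0-based half-open)."""
    regions: list[SyndromeRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 4 columns (chrom, start, end, name)")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must be > start")
            if not parts[3]:
                raise ValueError(f"{path}:{lineno}: empty syndrome name")
            regions.append(SyndromeRegion(parts[0], start, end, parts[3]))
    return regions
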