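"""LOESS GC-bias correction of window read counts.

Shallow cfDNA sequencing shows a systematic dependence of read yield on
window GC content.  Before any fraction or z-score is computed, window
counts are corrected by a locally-linear LOESS fit of count against GC:
each count is scaled by the ratio of the global mean count to the fitted
count at its GC value, so the correction is multiplicative (nonnegativity
preserved) and mean-conserving.

Windows dominated by ambiguous (N) sequence — centromeric and telomeric
gaps — are masked: they take no part in the fit and carry no corrected
value, and downstream z-scores and segmentations skip them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_model import GenomeWindows
from .read_ingest import WindowCounts

__all__ = [
    "DEFAULT_LOESS_SPAN",
    "DEFAULT_N_MASK_THRESHOLD",
    "MIN_USABLE_WINDOWS",
    "GcProfile",
    "CorrectedCounts",
    "window_gc",
    "loess_correct",
    "read_gc_tsv",
    "write_gc_tsv",
]

DEFAULT_LOESS_SPAN = 0.75
#: Windows with more than this fraction of N bases are masked.
DEFAULT_N_MASK_THRESHOLD = 0.2
#: LOESS is refused below this many usable windows.
MIN_USABLE_WINDOWS = 30


@dataclass
class GcProfile:
    """Per-window GC fraction and ambiguous-base fraction."""

    windows: GenomeWindows
    gc: np.ndarray          # float in [0, 1]
    n_fraction: np.ndarray  # float in [0, 1]

    def __post_init__(self) -> None:
        self.gc = np.asarray(self.gc, dtype=float)
        self.n_fraction = np.asarray(self.n_fraction, dtype=float)
        n = len(self.windows)
        if self.gc.shape != (n,) or self.n_fraction.shape != (n,):
            raise ValueError("gc and n_fraction must have one value per window")
        ok = np.isnan(self.gc) | ((self.gc >= 0) & (self.gc <= 1))
        if not ok.all():
            raise ValueError("gc fractions must lie in [0, 1]")

    def usable(self, n_mask_threshold: float = DEFAULT_N_MASK_THRESHOLD) -> np.ndarray:
        """Boolean mask of windows usable for fitting and analysis."""
        return (~np.isnan(self.gc)) & (self.n_fraction <= n_mask_threshold)


@dataclass
class CorrectedCounts:
    """GC-corrected window counts; masked windows carry NaN."""

    sample_id: str
    windows: GenomeWindows
    values: np.ndarray   # float, NaN on masked windows
    mask: np.ndarray     # bool, True = usable

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = len(self.windows)
        if self.values.shape != (n,) or self.mask.shape != (n,):
            raise ValueError("values and mask must have one entry per window")
        if np.nanmin(self.values, initial=0.0) < 0:
            raise ValueError("corrected counts must be nonnegative")


def window_gc(genome, windows: GenomeWindows) -> GcProfile:
    """GC and N fractions per window from a FASTA (pyfaidx) or a mapping.

    ``genome`` may be a path to a FASTA file, an open :class:`pyfaidx.Fasta`,
    or any mapping of chromosome name to sequence string.  GC is computed
    over unambiguous bases only: gc = (G+C)/(A+C+G+T).  A window of pure N
    has undefined GC (NaN) and n_fraction 1.
    """
    if isinstance(genome, (str, Path)):
        import pyfaidx
        genome = pyfaidx.Fasta(str(genome))
    gc = np.empty(len(windows))
    n_frac = np.empty(len(windows))
    for gi, w in enumerate(windows):
        try:
            seq = str(genome[w.chrom][w.start:w.end]).upper()
        except KeyError as exc:
            raise KeyError(f"no sequence for window {w.chrom}:{w.start}-{w.end}") from exc
        if len(seq) != w.width:
            raise ValueError(f"sequence for {w.chrom}:{w.start}-{w.end} is truncated")
        g = seq.count("G") + seq.count("C")
        a = seq.count("A") + seq.count("T")
        n_frac[gi] = 1.0 - (g + a) / w.width
        gc[gi] = g / (g + a) if (g + a) > 0 else np.nan
    return GcProfile(windows, gc, n_frac)


def loess_correct(counts: WindowCounts, gc: GcProfile,
                  span: float = DEFAULT_LOESS_SPAN,
                  n_mask_threshold: float = DEFAULT_N_MASK_THRESHOLD) -> CorrectedCounts:
    """Remove GC bias from window counts by locally-linear LOESS.

    corrected_i = count_i * M / m(gc_i) with m the LOESS fit of count on GC
    over usable windows and M the mean usable count, then rescaled so the
    usable mean is conserved exactly.  Windows where the fit is
    nonpositive are masked with a warning rather than corrected.
    """
    if counts.windows is not gc.windows and len(counts.windows) != len(gc.windows):
        raise ValueError("counts and GC profile use different tilings")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    usable = gc.usable(n_mask_threshold)
    n_usable = int(usable.sum())
    if n_usable < MIN_USABLE_WINDOWS:
        raise ValueError(
            f"only {n_usable} usable windows; >= {MIN_USABLE_WINDOWS} required for LOESS")
    raw = counts.counts.astype(float)
    x = gc.gc[usable]
    y = raw[usable]
    mean_count = y.mean()
    # lowess with return_sorted=False returns the fit at each input point.
    fitted = lowess(y, x, frac=span, it=2, return_sorted=False)
    bad = ~(fitted > 0)
    if bad.any():
        import warnings
        warnings.warn(f"{int(bad.sum())} windows had nonpositive LOESS fit; masked")
    mask = usable.copy()
    usable_idx = np.flatnonzero(usable)
    mask[usable_idx[bad]] = False
    values = np.full(len(counts.windows), np.nan)
    good = usable_idx[~bad]
    values[good] = raw[good] * mean_count / fitted[~bad]
    # enforce exact mean conservation over the final usable set
    conserved_mean = raw[mask].mean()
    cur = values[mask].mean()
    if cur > 0:
        values[mask] *= conserved_mean / cur
    values[mask] = np.clip(values[mask], 0.0, None)
    return CorrectedCounts(counts.sample_id, counts.windows, values, mask)


def write_gc_tsv(gc: GcProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgc\tn_fraction\n")
        for w, g, nf in zip(gc.windows, gc.gc, gc.n_fraction):
            gtxt = "NA" if np.isnan(g) else f"{g:.6f}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{gtxt}\t{nf:.6f}\n")


def read_gc_tsv(path: str | Path, windows: GenomeWindows) -> GcProfile:
    gcv = np.empty(len(windows))
    nfv = np.empty(len(windows))
    i = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "chrom\t")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            if i >= len(windows):
                raise ValueError(f"{path}: more rows than windows")
            w = windows[i]
            if (parts[0], int(parts[1]), int(parts[2])) != (w.chrom, w.start, w.end):
                raise ValueError(f"{path}:{lineno}: row does not match window "
                                 f"{w.chrom}:{w.start}-{w.end}")
            gcv[i] = np.nan if parts[3] == "NA" else float(parts[3])
            nfv[i] = float(parts[4])
            i += 1
    if i != len(windows):
        raise ValueError(f"{path}: {i} rows but tiling has {len(windows)} windows")
    return GcProfile(windows, gcv, nfv)
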