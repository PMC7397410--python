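"""Euploid reference baseline: mean/SD of read fractions per chromosome and window.

The z-score machinery compares a sample's read fractions against a panel of
euploid pregnancies.  This module turns GC-corrected counts into fractions
(denominator: all usable autosome windows) and summarizes a cohort into
per-chromosome and per-window means and sample standard deviations.

A small relative floor is applied to every SD so that a degenerate cohort
(tiny n, near-identical samples) cannot produce divide-by-near-zero z
explosions; the floor is far below the counting-noise CV of shallow
sequencing, so it is inert on realistic panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gc_normalize import CorrectedCounts
from .genome_model import GenomeWindows

__all__ = [
    "DEFAULT_SD_FLOOR",
    "ReferenceBaseline",
    "sample_fractions",
    "build_reference",
    "save_reference",
    "load_reference",
]

REFERENCE_FORMAT_VERSION = 1
#: SD floor coefficient: sd >= DEFAULT_SD_FLOOR * mean.
DEFAULT_SD_FLOOR = 0.01


def sample_fractions(corrected: CorrectedCounts) -> tuple[dict[str, float], np.ndarray]:
    """Read fractions of one sample at chromosome and window resolution.

    The denominator is the sum of corrected counts over all usable windows
    of the analysis (autosome) chromosomes; chromosome fractions therefore
    sum to 1 and window fractions sum to the containing chromosome's
    fraction.  Masked windows carry NaN.
    """
    windows = corrected.windows
    analysis = windows.analysis_chroms
    usable = corrected.mask.copy()
    for chrom in windows.chrom_names:
        if chrom not in analysis:
            usable[windows.chrom_slice(chrom)] = False
    denom = np.nansum(corrected.values[usable])
    if denom <= 0:
        raise ValueError("total usable corrected count is zero")
    window_fraction = np.full(len(windows), np.nan)
    window_fraction[usable] = corrected.values[usable] / denom
    chrom_fraction = {
        chrom: float(np.nansum(window_fraction[windows.chrom_slice(chrom)]))
        for chrom in analysis
    }
    return chrom_fraction, window_fraction


@dataclass
class ReferenceBaseline:
    """Cohort summary statistics the z-scores are computed against."""

    windows: GenomeWindows
    n_samples: int
    chrom_mean: dict[str, float]
    chrom_sd: dict[str, float]
    window_mean: np.ndarray   # NaN on masked windows
    window_sd: np.ndarray     # NaN on masked windows
    mask: np.ndarray          # True = usable
    sd_floor: float = DEFAULT_SD_FLOOR

    def usable_indices(self, chrom: str) -> np.ndarray:
        sl = self.windows.chrom_slice(chrom)
        return np.flatnonzero(self.mask[sl]) + sl.start


def build_reference(cohort: list[CorrectedCounts],
                    sd_floor: float = DEFAULT_SD_FLOOR) -> ReferenceBaseline:
    """Mean and sample SD (n-1) of fractions over a euploid cohort.

    The usable-window mask is the intersection of the samples' masks, so
    every statistic is computed over an identical window set.  SDs are
    floored at ``sd_floor * mean``.  Order of the cohort does not matter.
    """
    if len(cohort) < 2:
        raise ValueError("reference cohort needs >= 2 samples")
    windows = cohort[0].windows
    for s in cohort[1:]:
        if len(s.windows) != len(windows) or [
            (w.chrom, w.start, w.end) for w in s.windows
        ] != [(w.chrom, w.start, w.end) for w in windows]:
            raise ValueError("cohort samples use inconsistent window sets")
    mask = np.logical_and.reduce([s.mask for s in cohort])
    harmonized = []
    for s in cohort:
        v = np.where(mask, s.values, np.nan)
        harmonized.append(CorrectedCounts(s.sample_id, windows, v, mask))
    n = len(cohort)
    chrom_names = windows.analysis_chroms
    chrom_fr = np.empty((n, len(chrom_names)))
    window_fr = np.empty((n, len(windows)))
    for i, s in enumerate(harmonized):
        cfr, wfr = sample_fractions(s)
        chrom_fr[i] = [cfr[c] for c in chrom_names]
        window_fr[i] = wfr
    cmean = chrom_fr.mean(axis=0)
    csd = chrom_fr.std(axis=0, ddof=1)
    csd = np.maximum(csd, sd_floor * cmean)
    wmean = np.full(len(windows), np.nan)
    wsd = np.full(len(windows), np.nan)
    wmean[mask] = window_fr[:, mask].mean(axis=0)
    wsd[mask] = window_fr[:, mask].std(axis=0, ddof=1)
    wsd[mask] = np.maximum(wsd[mask], sd_floor * wmean[mask])
    return ReferenceBaseline(
        windows=windows, n_samples=n,
        chrom_mean=dict(zip(chrom_names, cmean.tolist())),
        chrom_sd=dict(zip(chrom_names, csd.tolist())),
        window_mean=wmean, window_sd=wsd, mask=mask, sd_floor=sd_floor,
    )


def loo_window_z(cohort: list[CorrectedCounts],
                 sd_floor: float = DEFAULT_SD_FLOOR) -> np.ndarray:
    """Leave-one-out window z-scores across a euploid cohort.

    For each sample, a baseline is built from the remaining samples and
    the held-out sample's window z-scores are computed against it.  The
    result is an (n_samples, n_windows) array, NaN on masked windows —
    the standard panel-calibration diagnostic (values should look roughly
    standard normal if the panel is homogeneous).
    """
    from .zscore_engine import window_z_track  # local import to avoid a cycle

    if len(cohort) < 3:
        raise ValueError("leave-one-out calibration needs >= 3 samples")
    out = np.full((len(cohort), len(cohort[0].windows)), np.nan)
    for i, held_out in enumerate(cohort):
        baseline = build_reference(cohort[:i] + cohort[i + 1:], sd_floor=sd_floor)
        _, wfr = sample_fractions(held_out)
        for chrom in baseline.windows.analysis_chroms:
            sl = baseline.windows.chrom_slice(chrom)
            out[i, sl] = window_z_track(wfr, baseline, chrom)
    return out


def save_reference(baseline: ReferenceBaseline, path: str | Path) -> None:
    """Versioned TSV: chromosome-level rows then window-level rows."""
    with open(path, "w") as fh:
        fh.write(f"#version={REFERENCE_FORMAT_VERSION}\n")
        fh.write(f"#n_samples={baseline.n_samples}\n")
        fh.write(f"#window_size={baseline.windows.window_size}\n")
        fh.write(f"#sd_floor={baseline.sd_floor!r}\n")
        fh.write("level\tchrom\tstart\tend\tmean\tsd\tusable\n")
        for chrom in baseline.windows.analysis_chroms:
            fh.write(f"chromosome\t{chrom}\t0\t{baseline.windows.chrom_length(chrom)}\t"
                     f"{baseline.chrom_mean[chrom]!r}\t{baseline.chrom_sd[chrom]!r}\t1\n")
        for gi, w in enumerate(baseline.windows):
            m, s = baseline.window_mean[gi], baseline.window_sd[gi]
            ok = bool(baseline.mask[gi])
            mtxt = "NA" if np.isnan(m) else repr(float(m))
            stxt = "NA" if np.isnan(s) else repr(float(s))
            fh.write(f"window\t{w.chrom}\t{w.start}\t{w.end}\t{mtxt}\t{stxt}\t{int(ok)}\n")


def load_reference(path: str | Path, windows: GenomeWindows) -> ReferenceBaseline:
    """Lossless counterpart of :func:`save_reference`."""
    header: dict[str, str] = {}
    chrom_mean: dict[str, float] = {}
    chrom_sd: dict[str, float] = {}
    wmean = np.full(len(windows), np.nan)
    wsd = np.full(len(windows), np.nan)
    mask = np.zeros(len(windows), dtype=bool)
    wi = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    header[k] = v
                continue
            if not line or line.startswith("level\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            level, chrom, start, end, mean, sd, ok = parts
            if level == "chromosome":
                chrom_mean[chrom] = float(mean)
                chrom_sd[chrom] = float(sd)
            elif level == "window":
                if wi >= len(windows):
                    raise ValueError(f"{path}: more window rows than windows")
                w = windows[wi]
                if (chrom, int(start), int(end)) != (w.chrom, w.start, w.end):
                    raise ValueError(f"{path}:{lineno}: window row mismatch")
                wmean[wi] = np.nan if mean == "NA" else float(mean)
                wsd[wi] = np.nan if sd == "NA" else float(sd)
                mask[wi] = ok == "1"
                wi += 1
            else:
                raise ValueError(f"{path}:{lineno}: unknown level {level!r}")
    if "version" not in header:
        raise ValueError(f"{path}: missing version header")
    if int(header["version"]) != REFERENCE_FORMAT_VERSION:
        raise ValueError(f"{path}: reference format version {header['version']} "
                         f"!= supported {REFERENCE_FORMAT_VERSION}")
    if wi != len(windows):
        raise ValueError(f"{path}: truncated file ({wi}/{len(windows)} window rows)")
    return ReferenceBaseline(
        windows=windows, n_samples=int(header["n_samples"]),
        chrom_mean=chrom_mean, chrom_sd=chrom_sd,
        window_mean=wmean, window_sd=wsd, mask=mask,
        sd_floor=float(header.get("sd_floor", DEFAULT_SD_FLOOR)),
    )
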