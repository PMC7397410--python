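"""Chromosome- and window-level z-scores and the |z| >= 3.00 classification.

The whole-chromosome z-score (the standard NIPT statistic, "nNIPT" here)
standardizes a sample's chromosome read fraction against the euploid
reference panel; the window z-score does the same per 2 Mb window:

    z = (fraction_sample - mean_reference) / SD_reference

A chromosome with |z| >= 3.00 (inclusive) is classified "affected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reference_baseline import ReferenceBaseline, sample_fractions
from .gc_normalize import CorrectedCounts

__all__ = [
    "Z_THRESHOLD",
    "TARGET_CHROMOSOMES",
    "ZTrack",
    "chromosome_z",
    "window_z",
    "window_z_track",
    "classify_chromosome",
    "nnipt_call",
    "NniptResult",
]

Z_THRESHOLD = 3.00
#: The clinically reported trisomies: T21, T18, T13.
TARGET_CHROMOSOMES = {"T21": "chr21", "T18": "chr18", "T13": "chr13"}


def chromosome_z(sample_fraction: float, baseline: ReferenceBaseline, chrom: str) -> float:
    """Whole-chromosome z of a sample fraction against the reference panel."""
    if chrom not in baseline.chrom_mean:
        raise KeyError(f"reference has no chromosome {chrom!r}")
    sd = baseline.chrom_sd[chrom]
    if not sd > 0:
        raise ValueError(f"{chrom}: reference SD must be > 0")
    return (sample_fraction - baseline.chrom_mean[chrom]) / sd


def window_z(window_fraction: float, baseline: ReferenceBaseline, global_index: int) -> float:
    """z of one window's fraction; raises on a masked window (never silent 0)."""
    if not baseline.mask[global_index]:
        raise ValueError(f"window {global_index} is masked; no z-score defined")
    sd = baseline.window_sd[global_index]
    if not sd > 0:
        raise ValueError(f"window {global_index}: reference SD must be > 0")
    return (window_fraction - baseline.window_mean[global_index]) / sd


def classify_chromosome(z: float) -> str:
    """'affected' iff |z| >= 3.00 (boundary inclusive), else 'unaffected'."""
    if not math.isfinite(z):
        raise ValueError("z-score must be finite")
    return "affected" if abs(z) >= Z_THRESHOLD else "unaffected"


@dataclass
class ZTrack:
    """All z information for one chromosome of one sample.

    ``window_z`` is aligned to the chromosome's windows; masked windows are
    NaN.  ``call`` applies the whole-chromosome |z| >= 3.00 rule only; the
    window-level evidence feeds the graphic-aided caller separately.
    """

    chrom: str
    chrom_z: float
    window_z: np.ndarray
    mask: np.ndarray   # per-window usability, aligned with window_z

    @property
    def call(self) -> str:
        return classify_chromosome(self.chrom_z)

    @property
    def direction(self) -> str:
        return "loss" if self.chrom_z <= -Z_THRESHOLD else "gain" if self.chrom_z >= Z_THRESHOLD else "none"


def window_z_track(window_fraction: np.ndarray, baseline: ReferenceBaseline,
                   chrom: str) -> np.ndarray:
    """Vector of window z for one chromosome; NaN where masked."""
    sl = baseline.windows.chrom_slice(chrom)
    out = np.full(sl.stop - sl.start, np.nan)
    for local, gi in enumerate(range(sl.start, sl.stop)):
        if baseline.mask[gi]:
            out[local] = window_z(window_fraction[gi], baseline, gi)
    return out


@dataclass
class NniptResult:
    """Whole-chromosome screen: per-chromosome z-tracks plus trisomy verdicts."""

    sample_id: str
    tracks: dict[str, ZTrack]
    verdicts: dict[str, str] = field(default_factory=dict)  # e.g. {"T21": "unaffected"}

    def z(self, chrom: str) -> float:
        return self.tracks[chrom].chrom_z


def nnipt_call(sample: CorrectedCounts, baseline: ReferenceBaseline) -> NniptResult:
    """Score all autosomes and issue T21/T18/T13 verdicts by the |z| >= 3 rule."""
    chrom_fr, window_fr = sample_fractions(sample)
    tracks: dict[str, ZTrack] = {}
    for chrom in baseline.windows.analysis_chroms:
        sl = baseline.windows.chrom_slice(chrom)
        tracks[chrom] = ZTrack(
            chrom=chrom,
            chrom_z=chromosome_z(chrom_fr[chrom], baseline, chrom),
            window_z=window_z_track(window_fr, baseline, chrom),
            mask=baseline.mask[sl].copy(),
        )
    verdicts = {
        target: classify_chromosome(tracks[chrom].chrom_z)
        for target, chrom in TARGET_CHROMOSOMES.items()
        if chrom in tracks
    }
    return NniptResult(sample.sample_id, tracks, verdicts)
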