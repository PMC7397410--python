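"""End-to-end per-sample analysis: counts -> GC correction -> z -> segmentation.

Thin glue over the module surface so the CLI, tests and scripted studies
share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cnv_segment import GniptStatus, gnipt_call, segment_chromosome
from .gc_normalize import CorrectedCounts, GcProfile, loess_correct
from .genome_model import SyndromeRegion
from .read_ingest import WindowCounts
from .reference_baseline import ReferenceBaseline
from .zscore_engine import TARGET_CHROMOSOMES, NniptResult, nnipt_call

__all__ = ["SampleAnalysis", "analyze_sample", "correct_sample"]


@dataclass
class SampleAnalysis:
    """Everything computed for one sample."""

    sample_id: str
    nnipt: NniptResult
    statuses: dict[str, GniptStatus]
    fits: dict = field(default_factory=dict)
    blocks: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)

    @property
    def gnipt_verdicts(self) -> dict[str, str]:
        """T21/T18/T13 verdicts under the graphic-aided rules."""
        return {
            target: self.statuses[chrom].status
            for target, chrom in TARGET_CHROMOSOMES.items()
            if chrom in self.statuses
        }

    @property
    def nnipt_verdicts(self) -> dict[str, str]:
        return self.nnipt.verdicts


def correct_sample(counts: WindowCounts, gc: GcProfile, **loess_kwargs) -> CorrectedCounts:
    return loess_correct(counts, gc, **loess_kwargs)


def analyze_sample(corrected: CorrectedCounts, baseline: ReferenceBaseline,
                   syndromes: list[SyndromeRegion] | None = None,
                   mode: str = "gnipt", **segment_kwargs) -> SampleAnalysis:
    """Run the whole-chromosome screen and, in gnipt mode, the window-level analysis."""
    if mode not in ("nnipt", "gnipt"):
        raise ValueError("mode must be 'nnipt' or 'gnipt'")
    result = nnipt_call(corrected, baseline)
    statuses: dict[str, GniptStatus] = {}
    fits, blocks_d, warns = {}, {}, {}
    if mode == "gnipt":
        for chrom, track in result.tracks.items():
            fit, blocks, _dots, warnings = segment_chromosome(
                track, baseline.windows, syndromes, **segment_kwargs)
            statuses[chrom] = gnipt_call(track, blocks, warnings)
            fits[chrom] = fit
            blocks_d[chrom] = blocks
            warns[chrom] = warnings
    return SampleAnalysis(corrected.sample_id, result, statuses, fits, blocks_d, warns)
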