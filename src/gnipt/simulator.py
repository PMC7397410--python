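"""Synthetic cfDNA window-count generator with known ground truth.

Models maternal plasma cfDNA as a mixture of maternal (euploid) and fetal
genomes at fetal fraction f.  With c_w the fetal copy number over window w
(2 when unaffected) and p_w the window's euploid share of the genome, the
expected read fraction of window w is

    F_w = [(1 - f) p_w + f (c_w / 2) p_w] / [(1 - f) + f G],
    G   = sum_w (c_w / 2) p_w,

where G accounts for the changed fetal genome size; the F_w sum to 1.
Window counts are drawn negative-binomially around total_reads * F_w times
a mean-normalized GC-bias factor (quadratic in GC, centered at 0.40), with
a dispersion ("size") parameter making the counts mildly overdispersed
relative to Poisson.  Defaults emulate the shallow-sequencing regime the
method operates in: ~0.16X unique-read coverage, fetal fraction 0.10,
near-Poisson dispersion (size 1000).

The default genome is a miniature 6-autosome genome (~320 Mb) so full
pipelines run in seconds; chr18 keeps its real ~78 Mb length so that
offsetting loss+gain scenarios have realistic window-level signal.  A
deterministic synthetic GC profile covers the 0.28-0.55 range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gc_normalize import GcProfile
from .genome_model import Chromosome, GenomeWindows, build_windows
from .read_ingest import (DEFAULT_READ_LENGTH, QC_COVERAGE_THRESHOLD,
                          WindowCounts)

__all__ = [
    "MINI_GENOME_SIZES",
    "SimEvent",
    "SimConfig",
    "SimTruth",
    "mini_genome_windows",
    "synthetic_gc_profile",
    "trisomy",
    "monosomy",
    "segmental",
    "offsetting_event_pair",
    "expected_fraction",
    "simulate_sample",
    "simulate_cohort",
    "write_sam_fixture",
]

#: Default simulated mean coverage.  The analysis QC floor is 0.16X; real
#: cohorts sequence with some headroom above it so that sampling noise does
#: not push samples under the gate, hence a 0.18X default target.
DEFAULT_COVERAGE_TARGET = 0.18

#: Miniature test genome: 6 autosomes, 161 windows at 2 Mb.  chr18 keeps
#: its hg19-scale length; the others are scaled down for speed.
MINI_GENOME_SIZES = {
    "chr1": 70_000_000,
    "chr2": 60_000_000,
    "chr3": 50_000_000,
    "chr13": 40_000_000,
    "chr18": 78_000_000,
    "chr21": 24_000_000,
}


def mini_genome_windows(window_size: int = 2_000_000) -> GenomeWindows:
    return build_windows(MINI_GENOME_SIZES, window_size)


def synthetic_gc_profile(windows: GenomeWindows) -> GcProfile:
    """Deterministic smooth GC landscape covering ~0.28-0.55, no N gaps."""
    i = np.arange(len(windows), dtype=float)
    gc = 0.42 + 0.10 * np.sin(2 * np.pi * i / 37.0) + 0.03 * np.cos(2 * np.pi * i / 11.0)
    return GcProfile(windows, gc, np.zeros(len(windows)))


@dataclass(frozen=True)
class SimEvent:
    """A planted fetal copy-number event.

    ``fetal_copies`` is the fetal copy number over the event region:
    1 = onefold loss, 3 = single gain (trisomy when whole-chromosome),
    4 = threefold gain.  ``start``/``end`` are bp for segmental events and
    ignored (whole chromosome) otherwise.
    """

    kind: str              # "trisomy" | "monosomy" | "segmental"
    chrom: str
    fetal_copies: int
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.fetal_copies < 0 or self.fetal_copies == 2:
            raise ValueError("fetal_copies must be >= 0 and != 2")
        if self.kind == "segmental":
            if self.start is None or self.end is None or self.start >= self.end:
                raise ValueError("segmental event requires start < end")
        elif self.kind not in ("trisomy", "monosomy"):
            raise ValueError(f"unknown event kind {self.kind!r}")


def trisomy(chrom: str) -> SimEvent:
    return SimEvent("trisomy", chrom, 3)


def monosomy(chrom: str) -> SimEvent:
    return SimEvent("monosomy", chrom, 1)


def segmental(chrom: str, start: int, end: int, fetal_copies: int) -> SimEvent:
    return SimEvent("segmental", chrom, fetal_copies, start, end)


def offsetting_event_pair(windows: GenomeWindows, chrom: str = "chr18") -> list[SimEvent]:
    """Loss + gain pair that cancels exactly in the chromosome fraction.

    A onefold loss (copies 1, effect -f/2 per bp) over the first two thirds
    of the chromosome and a threefold gain (copies 4, effect +f per bp)
    over the last third: 2/3 * (-1/2) + 1/3 * (+1) = 0, so the chromosome
    z stays near zero while every window is shifted — the canonical case
    invisible to whole-chromosome screening.
    """
    length = windows.chrom_length(chrom)
    split = round(length * 2 / 3)
    return [segmental(chrom, 0, split, 1), segmental(chrom, split, length, 4)]


def _fetal_copies_per_window(windows: GenomeWindows, events: list[SimEvent]) -> np.ndarray:
    """Length-weighted mean fetal copy number per window (2 where untouched)."""
    c = np.full(len(windows), 2.0)
    for ev in events:
        sl = windows.chrom_slice(ev.chrom)
        for gi in range(sl.start, sl.stop):
            w = windows[gi]
            if ev.kind == "segmental":
                ov = min(ev.end, w.end) - max(ev.start, w.start)
                if ov > 0:
                    c[gi] += (ev.fetal_copies - 2) * ov / w.width
            else:
                c[gi] += ev.fetal_copies - 2
    return c


def _euploid_share(windows: GenomeWindows) -> np.ndarray:
    widths = np.array([w.width for w in windows], dtype=float)
    return widths / widths.sum()


def expected_fraction(windows: GenomeWindows, events: list[SimEvent],
                      fetal_fraction: float) -> np.ndarray:
    """Expected read fraction per window under the maternal-fetal mixture."""
    if not 0 <= fetal_fraction <= 1:
        raise ValueError("fetal_fraction must lie in [0, 1]")
    f = fetal_fraction
    p = _euploid_share(windows)
    c = _fetal_copies_per_window(windows, events)
    G = float(np.sum((c / 2.0) * p))
    num = (1 - f) * p + f * (c / 2.0) * p
    return num / ((1 - f) + f * G)


@dataclass
class SimConfig:
    """Study conditions of a simulation run."""

    windows: GenomeWindows
    fetal_fraction: float = 0.10
    total_reads: int | None = None        # default: DEFAULT_COVERAGE_TARGET depth
    read_length: int = DEFAULT_READ_LENGTH
    gc_bias: tuple[float, float] = (1.0, -8.0)   # (linear, quadratic) in (gc - 0.40)
    dispersion: float | None = 1000.0     # NB size; None = Poisson
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads is None:
            self.total_reads = round(
                DEFAULT_COVERAGE_TARGET * self.windows.total_length() / self.read_length)
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if not 0 <= self.fetal_fraction <= 1:
            raise ValueError("fetal_fraction must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SimTruth:
    """Ground truth emitted alongside each simulated sample."""

    sample_id: str
    events: list[SimEvent]
    fetal_fraction: float
    expected_fraction: np.ndarray
    seed: int


def _bias_factor(gc: np.ndarray, coeffs: tuple[float, float],
                 weights: np.ndarray) -> np.ndarray:
    b1, b2 = coeffs
    x = gc - 0.40
    bias = 1.0 + b1 * x + b2 * x ** 2
    bias = np.clip(bias, 0.05, None)
    return bias / float(np.sum(weights * bias))   # weighted mean normalized to 1


def simulate_sample(config: SimConfig, events: list[SimEvent],
                    rng: np.random.Generator,
                    gc: GcProfile | None = None,
                    sample_id: str = "sim") -> tuple[WindowCounts, SimTruth]:
    """Draw one sample's window counts; reproducible from the generator state."""
    windows = config.windows
    F = expected_fraction(windows, events, config.fetal_fraction)
    if gc is None:
        gc = synthetic_gc_profile(windows)
    bias = _bias_factor(gc.gc, config.gc_bias, F)
    mu = config.total_reads * F * bias
    if config.dispersion is None or math.isinf(config.dispersion):
        counts = rng.poisson(mu)
    else:
        size = config.dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    wc = WindowCounts(sample_id, windows, counts.astype(np.int64))
    truth = SimTruth(sample_id, list(events), config.fetal_fraction, F, config.seed)
    return wc, truth


#: Scenario factories usable in cohort mixes.
def _scenario_events(name: str, windows: GenomeWindows) -> list[SimEvent]:
    if name == "euploid":
        return []
    if name.startswith("T") and name[1:].isdigit():
        return [trisomy(f"chr{name[1:]}")]
    if name == "offsetting_chr18":
        return offsetting_event_pair(windows, "chr18")
    raise ValueError(f"unknown scenario {name!r}")


def simulate_cohort(config: SimConfig, scenario_mix: dict[str, float],
                    n_samples: int) -> tuple[list[WindowCounts], list[SimTruth]]:
    """Simulate a cohort with a deterministic scenario assignment.

    ``scenario_mix`` maps scenario names ("euploid", "T21", "T18", "T13",
    "offsetting_chr18") to proportions summing to 1.  Per-scenario counts
    are floor(n * proportion) topped up by largest remainder, assigned in
    declaration order before any noise is drawn, so the planted composition
    is exact and reproducible.
    """
    total = sum(scenario_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"scenario proportions sum to {total}, expected 1")
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    names = list(scenario_mix)
    quotas = {k: n_samples * v for k, v in scenario_mix.items()}
    alloc = {k: int(math.floor(q)) for k, q in quotas.items()}
    short = n_samples - sum(alloc.values())
    for k in sorted(names, key=lambda k: quotas[k] - alloc[k], reverse=True)[:short]:
        alloc[k] += 1
    rng = config.rng()
    counts_list: list[WindowCounts] = []
    truths: list[SimTruth] = []
    i = 0
    for name in names:
        events = _scenario_events(name, config.windows)
        for _ in range(alloc[name]):
            sid = f"{name}_{i:04d}"
            wc, truth = simulate_sample(config, events, rng, sample_id=sid)
            counts_list.append(wc)
            truths.append(truth)
            i += 1
    return counts_list, truths


def write_sam_fixture(windows: GenomeWindows, rng: np.random.Generator,
                      path, n_pass: int = 60, n_duplicate: int = 10,
                      n_multimapped: int = 10, n_unmapped: int = 10,
                      n_short: int = 10, n_low_mapq: int = 0,
                      read_length: int = 50) -> dict[str, int]:
    """Write a small plain-text SAM file with planted filter-failure classes.

    Failure classes are disjoint by construction; returns the planted
    tally so round-trip tests can compare against the ingest filter.
    """
    chroms = windows.chrom_names
    lengths = {c: windows.chrom_length(c) for c in chroms}

    def random_locus():
        c = chroms[rng.integers(len(chroms))]
        return c, int(rng.integers(0, lengths[c] - read_length))

    def record(qname, flag, chrom, pos0, mapq, length):
        seq = "A" * length
        qual = "I" * length
        return (f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{length}M\t*\t0\t0\t"
                f"{seq}\t{qual}")

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{c}\tLN:{lengths[c]}" for c in chroms]
    qid = 0
    classes = [("pass", n_pass, 0, 60, read_length),
               ("dup", n_duplicate, 0x400, 60, read_length),
               ("multi", n_multimapped, 0x100, 60, read_length),
               ("unmapped", n_unmapped, 0x4, 0, read_length),
               ("short", n_short, 0, 60, 20),
               ("lowq", n_low_mapq, 0, 30, read_length)]
    for tag, n, flag, mapq, length in classes:
        for _ in range(n):
            if flag & 0x4:
                lines.append(f"r{qid:05d}_{tag}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                             f"{'A' * length}\t{'I' * length}")
            else:
                chrom, pos = random_locus()
                lines.append(record(f"r{qid:05d}_{tag}", flag, chrom, pos, mapq, length))
            qid += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return {"retained": n_pass, "duplicate": n_duplicate,
            "multimapped": n_multimapped, "unmapped": n_unmapped,
            "short": n_short, "low_mapq": n_low_mapq}
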