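# Methods

## The screening problem

Noninvasive prenatal testing (NIPT) screens for fetal aneuploidy from
cell-free DNA (cfDNA) in maternal plasma. Fetal (placental) DNA is a
minority component of the plasma at fetal fraction *f* (typically
0.04–0.2), so a trisomic fetal chromosome shifts that chromosome's share
of sequenced reads by only ~*f*/2. The standard statistic ("nNIPT" in
this package) standardizes the sample's per-chromosome read fraction
against a reference panel of euploid pregnancies:

    z_chrN = (%chrN_sample − mean %chrN_reference) / SD %chrN_reference

and classifies a chromosome *affected* when |z| ≥ 3.00 (inclusive on the
boundary, in both directions).

The whole-chromosome statistic is blind to a specific failure mode: a
chromosome carrying both a copy-number loss and a copy-number gain whose
contributions cancel in the chromosome-wide read fraction. The
window-resolved extension implemented here ("gNIPT") divides every
autosome into 2 Mb windows, computes the same z statistic per window
against the window-level reference, fits a piecewise-constant
segmentation to the z-track, and combines three sources of evidence into
the per-chromosome verdict.

## Pipeline

1. **Read ingest.** Aligned reads (SAM) are filtered: PCR duplicates,
   unmapped reads, secondary/supplementary alignments, reads < 35 bp and
   reads with MAPQ < 60 are removed; survivors are uniquely mapped reads
   (UMRs). Each UMR increments the single 2 Mb window containing its
   leftmost aligned base. Samples must reach 0.16X mean UMR coverage
   (`UMRs × read_length / genome_length`, nominal read length 150 bp,
   configurable) to enter analysis; the gate is inclusive at 0.16.
2. **GC correction.** Window counts are corrected by a locally-linear
   LOESS fit of count against window GC fraction (span 0.75 default),
   multiplicatively: `corrected = count × M / m(gc)` with `M` the mean
   usable count, then rescaled so the usable mean is conserved exactly.
   Windows with > 20% ambiguous (N) bases are masked from the fit and
   from all downstream analysis. The correction is applied at the 2 Mb
   window level, the unit of every downstream computation.
3. **Reference baseline.** Fractions are corrected counts divided by the
   sum of corrected counts over all usable autosome windows (the
   denominator excludes chrX/chrY throughout). A euploid cohort yields
   per-chromosome and per-window means and sample SDs (n−1). Every SD
   is floored at `0.01 × mean`: a guard against degenerate cohorts only,
   deliberately far below the ~3–4% counting-noise CV of 2 Mb windows at
   0.16X so that realistic panels are never affected.
4. **z-scores and segmentation.** Window z-tracks are fitted with the
   fused-lasso signal approximator

       β = argmin ½Σ(zᵢ−βᵢ)² + λ₁Σ|βᵢ| + λ₂Σ|βᵢ−βᵢ₋₁|

   solved exactly: 1-D total-variation denoising via the dual
   box-constrained least-squares problem (BVLS), then elementwise
   soft-thresholding by λ₁ — the known exact decomposition of this
   objective. Masked windows split the problem, so centromere-like gaps
   never fuse across arms. Maximal same-sign nonzero runs of β are
   *blocks*; each is scored with the equal-weight Stouffer combination
   of its member raw window z-scores, `z_block = Σzᵢ/√k`, and flagged
   at |z_block| ≥ 3.00 (red dots). Windows with |z| ≥ 3 get black dots.
5. **Warnings.** On the raw z-track: ≥ 5 consecutive usable windows with
   |z| ≥ 5 raise an *unknown anomaly* (≥ 10 Mb); ≥ 2 such windows whose
   span intersects a user-supplied known-syndrome BED region by ≥ 1 bp
   raise a *known syndrome anomaly* (≥ 4 Mb). One run can raise both;
   masked windows break consecutiveness.
6. **Combined verdict.** A chromosome is *affected* when |chromosome z|
   ≥ 3.00, or any warning fired, or flagged gain *and* loss blocks
   jointly cover ≥ 80% of its usable windows (the offsetting-whole-
   chromosome rule). Flagged blocks on an otherwise negative chromosome
   are reported as segmental CNV findings without changing the trisomy
   verdict.

## Penalty selection

The segmentation penalties are chosen deterministically per chromosome
by minimizing `RSS + 2·log(n)·df` over a fixed grid (λ₁ ∈ {0.1, 0.2,
0.5, 1, 2}, λ₂ ∈ {0.5, 1, 2, 4, 8, 16, 32}), where `df` is the number of
distinct constant nonzero levels of β — the standard unbiased df
estimate for the fused lasso. Ties prefer the smoother, then sparser,
fit. The df-penalty multiplier (2.0) controls the family-wise spurious-
block rate on pure-noise tracks of ~100 windows at roughly 5%, while a
10-window shift of 6 SD is recovered with block boundaries within ±1
window. Chromosomes with fewer than 5 usable windows skip segmentation
and report per-window dots only. Because block scores use the raw
window z-scores, not the shrunken β, verdicts are insensitive to the
exact penalty level once the block support is right.

Choices the underlying method leaves open, decided here: the block
weighting is the equal-weight Stouffer sum (2 Mb windows are
interchangeable units; other weightings are pluggable); every window of
a flagged block is red-dotted; syndrome overlap requires ≥ 1 bp.

## The simulator

`gnipt.simulator` generates window counts with known truth under a
maternal–fetal mixture: with c_w the fetal copy number over window w
(2 if unaffected; length-weighted within boundary windows) and p_w the
window's euploid share of the genome,

    F_w = [(1−f)·p_w + f·(c_w/2)·p_w] / [(1−f) + f·G],  G = Σ (c_w/2)·p_w,

so fractions sum to 1 and the fetal genome-size change is accounted for.
Counts are negative-binomial with mean `total_reads × F_w × bias(gc_w)`
and size 1000 (mildly overdispersed relative to Poisson; size=None gives
Poisson). The GC-bias factor is quadratic in (gc − 0.40) with default
coefficients (1.0, −8.0), mean-normalized to 1 — strong enough that the
LOESS step has something real to remove (raw count–GC correlation
≈ 0.7–0.9 on the default genome).

Defaults define the study conditions: fetal fraction 0.10, target
coverage 0.18X (the analysis floor is 0.16X; the simulated depth carries
headroom so sampling noise does not push samples under the inclusive
gate — studies that need exactly floor depth pass `total_reads`
explicitly), read length 150 bp. The default genome is a miniature
6-autosome genome (chr1 70, chr2 60, chr3 50, chr13 40, chr18 78,
chr21 24 Mb; 161 windows, ~2100–2400 reads per window at default depth)
so that full pipeline studies run in seconds; chr18 keeps its real
~78 Mb length so offsetting scenarios have realistic per-window
signal-to-noise. A deterministic smooth GC landscape spans ~0.28–0.55.

The canonical offsetting scenario plants a onefold loss (fetal copies 1,
per-bp effect −f/2) over the first two thirds of chr18 and a threefold
gain (fetal copies 4, per-bp effect +f) over the last third; the spans
are chosen in the 2:1 ratio that makes the two events cancel exactly in
the chromosome fraction, so the chromosome z stays near zero while the
p-side windows shift by about −1.3 SD and the q-side windows by +2.6 SD
at f = 0.10 and floor depth. The corresponding Stouffer block scores
(≈ −6.6 and +9.4 in expectation) make both blocks reliably flagged, and
the offsetting rule calls the chromosome.

What the simulator does *not* model: placental mosaicism (a real
offsetting case may show attenuated, region-dependent effective fetal
fraction), fragment-length biology, mappability structure, maternal
CNVs, or sequencing error. Passing the simulation studies therefore
demonstrates the algorithm's behavior under its own stated model, not
clinical performance.

## Calibration behavior and known limitations

- Leave-one-out window z-scores against an n-sample panel are
  `sqrt(n/(n−1))·t_{n−2}` distributed rather than standard normal; at
  n = 50 the |z| ≥ 3 exceedance rate is ≈ 0.0046 versus the normal
  2Φ(−3) ≈ 0.0027. Panel-calibration checks at small n should use
  t-based expectations; the package reports the empirical rate and
  leaves the interpretation to the panel size at hand.
- The chromosome-level SD of a small panel is likewise noisy; clinical
  deployments use panels of hundreds of samples.
- Percentages in reports are rounded half-up to 2 decimals; z-scores
  print at 3 decimals; all raw values are retained in JSON.
- Published comparison figures reproduced by the metrics module are the
  ones computable from the 2x2 method-agreement counts (53, 2, 18,
  13464 of 13537): coincidence rate 99.85%, Cohen's κ 0.84, positive
  rate 0.39%. The printed per-method PPV table of the source cohort is
  not consistent with those marginals (e.g. an overall PPV printed as
  88.14% where the marginals imply 53/55 = 96.4%), so PPV/NPV are
  implemented as general operations but not asserted against those
  printed values.
- Coordinates are 0-based half-open everywhere; BED input is consumed
  natively; 1-based conventions are not accepted.
- Coverage QC uses post-filter unique reads (the quantity the 0.16X
  floor is defined on).

## Problem sizes used in the shipped studies

The acceptance script and test suite run: a 50-sample euploid reference
panel; 100 offsetting-scenario and 100 euploid replicates at
0.16X-equivalent depth for the detection/false-flag rates; 50 instances
of length ≤ 12 for solver–oracle equivalence (objective gap ≤ 1e-5
required, ~1e-11 observed); 50-sample leave-one-out calibration (8050
window z values); and 5 replicates for the GC-correlation-reduction
study. These sizes keep the full suite within a few minutes on one CPU
while leaving the binomial/stochastic tolerances meaningful.
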