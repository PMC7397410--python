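"""Mixture-model fractions, count noise, scenarios and SAM fixtures."""

import numpy as np
import pytest

from gnipt.genome_model import build_windows
from gnipt.simulator import (SimConfig, SimEvent, expected_fraction,
                             offsetting_event_pair, segmental, simulate_cohort,
                             simulate_sample, trisomy)


@pytest.fixture(scope="module")
def toy():
    # chr21 carries 1.3% of a 1000-unit genome (unit windows)
    return build_windows({"chr1": 987, "chr21": 13}, 1)


class TestExpectedFraction:
    def test_zero_fetal_fraction_is_euploid_share(self, toy):
        F = expected_fraction(toy, [trisomy("chr21")], 0.0)
        widths = np.ones(1000) / 1000
        assert np.allclose(F, widths)

    def test_pure_fetal_trisomy_closed_form(self, toy):
        F = expected_fraction(toy, [trisomy("chr21")], 1.0)
        chr21 = F[toy.chrom_slice("chr21")].sum()
        assert chr21 == pytest.approx(1.5 * 0.013 / (1 + 0.5 * 0.013), abs=1e-12)

    def test_ten_percent_fetal_trisomy_closed_form(self, toy):
        F = expected_fraction(toy, [trisomy("chr21")], 0.1)
        chr21 = F[toy.chrom_slice("chr21")].sum()
        expected = (0.9 * 0.013 + 0.1 * 1.5 * 0.013) / (0.9 + 0.1 * 1.0065)
        assert chr21 == pytest.approx(expected, abs=1e-12)

    def test_fractions_normalize_for_arbitrary_events(self, toy):
        rng = np.random.default_rng(0)
        for _ in range(20):
            events = []
            if rng.random() < 0.5:
                events.append(trisomy("chr21"))
            if rng.random() < 0.5:
                s = int(rng.integers(0, 900))
                events.append(segmental("chr1", s, s + int(rng.integers(1, 80)),
                                        int(rng.choice([0, 1, 3, 4]))))
            f = float(rng.uniform(0, 1))
            F = expected_fraction(toy, events, f)
            assert F.sum() == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_fetal_fraction(self, toy):
        gained = [segmental("chr1", 0, 100, 4)]
        lost = [segmental("chr1", 0, 100, 1)]
        fs = [0.02, 0.05, 0.1, 0.2]
        gain_fr = [expected_fraction(toy, gained, f)[:100].sum() for f in fs]
        loss_fr = [expected_fraction(toy, lost, f)[:100].sum() for f in fs]
        assert np.all(np.diff(gain_fr) > 0)
        assert np.all(np.diff(loss_fr) < 0)

    def test_invalid_inputs(self, toy):
        with pytest.raises(ValueError):
            expected_fraction(toy, [], 1.5)
        with pytest.raises(ValueError):
            SimEvent("segmental", "chr1", 3, 10, 10)
        with pytest.raises(ValueError):
            SimEvent("trisomy", "chr1", 2)


class TestSimulateSample:
    def test_same_seed_identical_counts(self, windows):
        cfg = SimConfig(windows=windows, seed=99)
        a, _ = simulate_sample(cfg, [trisomy("chr21")], cfg.rng())
        b, _ = simulate_sample(cfg, [trisomy("chr21")], cfg.rng())
        assert np.array_equal(a.counts, b.counts)

    def test_poisson_means_match_expectation(self, windows):
        cfg = SimConfig(windows=windows, seed=5, dispersion=None,
                        gc_bias=(0.0, 0.0), total_reads=100_000)
        rng = cfg.rng()
        F = expected_fraction(windows, [], cfg.fetal_fraction)
        acc = np.zeros(len(windows))
        n_rep = 200
        for _ in range(n_rep):
            wc, _ = simulate_sample(cfg, [], rng)
            acc += wc.counts
        mean = acc / n_rep
        mu = cfg.total_reads * F
        se = np.sqrt(mu / n_rep)
        assert np.all(np.abs(mean - mu) < 4 * se + 1e-9)

    def test_offsetting_scenario_shape(self, windows, gc_profile, baseline):
        """Window z negative on the lost arm, positive on the gained arm,
        chromosome z near zero."""
        from gnipt.gc_normalize import loess_correct
        from gnipt.zscore_engine import nnipt_call

        events = offsetting_event_pair(windows, "chr18")
        sl = windows.chrom_slice("chr18")
        n18 = sl.stop - sl.start
        split = 26   # 52 Mb of 78 Mb
        zsum = np.zeros(n18)
        chrom_zs = []
        for seed in range(400, 410):
            cfg = SimConfig(windows=windows, seed=seed)
            wc, _ = simulate_sample(cfg, events, cfg.rng())
            res = nnipt_call(loess_correct(wc, gc_profile), baseline)
            zsum += res.tracks["chr18"].window_z
            chrom_zs.append(res.tracks["chr18"].chrom_z)
        zmean = zsum / 10
        assert np.all(zmean[:split] < 0)
        assert np.all(zmean[split:] > 0)
        assert abs(np.mean(chrom_zs)) < 1.0

    def test_truth_records_events_and_fraction(self, windows):
        cfg = SimConfig(windows=windows, seed=1, fetal_fraction=0.07)
        events = [trisomy("chr13")]
        _, truth = simulate_sample(cfg, events, cfg.rng(), sample_id="x")
        assert truth.events == events
        assert truth.fetal_fraction == 0.07
        assert truth.expected_fraction.sum() == pytest.approx(1.0, abs=1e-12)


class TestSimulateCohort:
    def test_pure_euploid_mix(self, windows):
        cfg = SimConfig(windows=windows, seed=2)
        counts, truths = simulate_cohort(cfg, {"euploid": 1.0}, 5)
        assert len(counts) == 5
        assert all(t.events == [] for t in truths)

    def test_exact_deterministic_allocation(self, windows):
        cfg = SimConfig(windows=windows, seed=3)
        _, truths = simulate_cohort(cfg, {"euploid": 0.95, "T21": 0.05}, 200)
        planted = sum(1 for t in truths if t.events)
        assert planted == 10

    def test_invalid_mix_rejected(self, windows):
        cfg = SimConfig(windows=windows, seed=4)
        with pytest.raises(ValueError, match="sum"):
            simulate_cohort(cfg, {"euploid": 0.5}, 10)
        with pytest.raises(ValueError, match="unknown scenario"):
            simulate_cohort(cfg, {"klingon": 1.0}, 10)

    def test_cohort_reusable_as_reference_panel(self, euploid_cohort, baseline):
        # structural check: full usable coverage, positive SDs
        assert baseline.n_samples == 50
        assert baseline.mask.all()
        assert np.all(baseline.window_sd[baseline.mask] > 0)
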