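"""Fused-lasso solver, penalty selection, blocks, dots, warnings, combined call."""

import math

import numpy as np
import pytest

from conftest import fused_lasso_oracle
from gnipt.cnv_segment import (GniptStatus, RegionWarning, block_z, detect_blocks,
                               fire_warnings, fused_lasso_fit, gnipt_call,
                               mark_window_dots, select_lambdas, soft_threshold,
                               tv_denoise)
from gnipt.genome_model import Chromosome, SyndromeRegion, build_windows
from gnipt.zscore_engine import ZTrack


def objective(beta, z, l1, l2):
    return (0.5 * np.sum((z - beta) ** 2) + l1 * np.sum(np.abs(beta))
            + l2 * np.sum(np.abs(np.diff(beta))))


class TestFusedLassoSolver:
    def test_zero_penalties_return_input(self):
        z = np.array([1.0, -2.0, 0.5, 3.0])
        fit = fused_lasso_fit(z, 0.0, 0.0)
        assert np.array_equal(fit.beta, z)

    def test_constant_signal_soft_threshold_closed_form(self):
        for c, t in [(2.5, 1.0), (-1.2, 0.5), (0.3, 0.4)]:
            z = np.full(9, c)
            fit = fused_lasso_fit(z, t, 7.3)   # fusion penalty vanishes
            expected = math.copysign(max(abs(c) - t, 0.0), c)
            assert np.allclose(fit.beta, expected)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            fused_lasso_fit(np.zeros(3), -0.1, 0.0)

    def test_oracle_equivalence_small_vectors(self):
        """Objective matches a generic convex solver to 1e-5 on random
        instances of length <= 12 with random penalties."""
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(50):
            n = int(rng.integers(2, 13))
            z = rng.normal(0, 3, n)
            l1 = float(rng.uniform(0, 2))
            l2 = float(rng.uniform(0, 3))
            fit = fused_lasso_fit(z, l1, l2)
            _, obj_oracle = fused_lasso_oracle(z, l1, l2)
            gap = objective(fit.beta, z, l1, l2) - obj_oracle
            worst = max(worst, abs(gap))
        assert worst <= 1e-5

    def test_translation_consistency_without_sparsity_penalty(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0, 1, 40)
        c = 2.7
        a = fused_lasso_fit(z, 0.0, 1.5).beta
        b = fused_lasso_fit(z + c, 0.0, 1.5).beta
        assert np.allclose(b, a + c, atol=1e-8)

    def test_masked_windows_split_the_problem(self):
        z = np.array([5.0, 5.0, np.nan, -5.0, -5.0])
        fit = fused_lasso_fit(z, 0.0, 100.0)   # huge fusion within segments
        assert np.allclose(fit.beta[:2], 5.0)
        assert np.isnan(fit.beta[2])
        assert np.allclose(fit.beta[3:], -5.0)  # gap prevents fusing to 0

    def test_tv_denoise_interior_averaging(self):
        # strong fusion pulls a two-point segment to its mean
        out = tv_denoise(np.array([0.0, 4.0]), 10.0)
        assert np.allclose(out, 2.0)


class TestSelectLambdas:
    def test_pure_noise_yields_empty_fit(self):
        rng = np.random.default_rng(0)
        empty = 0
        for _ in range(100):
            z = rng.normal(0, 1, 100)
            l1, l2 = select_lambdas(z)
            if np.all(fused_lasso_fit(z, l1, l2).beta == 0):
                empty += 1
        assert empty >= 95

    def test_planted_shift_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(1)
        recovered = 0
        for _ in range(50):
            z = rng.normal(0, 1, 100)
            z[40:50] += 6.0
            l1, l2 = select_lambdas(z)
            beta = fused_lasso_fit(z, l1, l2).beta
            core = np.flatnonzero(beta > 3.0)
            if (core.size and abs(core[0] - 40) <= 1 and abs(core[-1] - 49) <= 1
                    and np.all(np.diff(core) == 1)):
                recovered += 1
        assert recovered >= 48

    def test_too_few_windows_falls_back(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="gnipt.cnv_segment"):
            assert select_lambdas(np.array([1.0, 2.0, 3.0])) is None
        assert "per-window dots" in caplog.text

    def test_deterministic(self):
        z = np.random.default_rng(5).normal(0, 1, 80)
        assert select_lambdas(z) == select_lambdas(z.copy())


class TestBlocksAndDots:
    def test_run_extraction(self):
        beta = np.array([0, 0, 2, 2, 2, 0, -1, -1], dtype=float)
        z = np.array([0, 0, 4, 4, 4, 0, -2, -2], dtype=float)
        fit = fused_lasso_fit(beta, 0, 0)   # identity fit
        blocks = detect_blocks(fit, z, "chrT")
        assert [(b.first, b.last, b.direction) for b in blocks] == [
            (2, 4, "gain"), (6, 7, "loss")]

    def test_no_blocks_on_zero_fit(self):
        fit = fused_lasso_fit(np.zeros(6), 0, 0)
        assert detect_blocks(fit, np.zeros(6), "chrT") == []

    @pytest.mark.parametrize("zvals,expected,flagged", [
        ([4.0], 4.0, True),
        ([3.0, 3.0, 3.0, 3.0], 6.0, True),
        ([2.0, -2.0], 0.0, False),
    ])
    def test_block_z_stouffer(self, zvals, expected, flagged):
        zb = block_z(np.array(zvals))
        assert zb == pytest.approx(expected)
        assert (abs(zb) >= 3.0) is flagged

    def test_block_z_empty_rejected(self):
        with pytest.raises(ValueError):
            block_z(np.array([]))

    @pytest.mark.parametrize("z,dot", [
        (3.0, True), (-2.99, False), (-5.1, True), (2.999, False), (-3.0, True),
    ])
    def test_black_dots(self, z, dot):
        assert mark_window_dots(np.array([z]))[0] == dot

    def test_dots_false_on_masked(self):
        assert not mark_window_dots(np.array([np.nan]))[0]


@pytest.fixture(scope="module")
def warn_windows():
    return build_windows([Chromosome("chrW", 40_000_000)], 2_000_000)


class TestWarnings:
    def _z(self, spec, n=20):
        z = np.zeros(n)
        for i, v in spec:
            z[i] = v
        return z

    def test_five_consecutive_extreme_bins_fire_unknown_anomaly(self, warn_windows):
        z = self._z([(i, 5.5) for i in range(3, 8)])
        (w,) = fire_warnings(z, "chrW", warn_windows)
        assert w.kind == "unknown_anomaly"
        assert w.span == 10_000_000
        assert (w.first, w.last) == (3, 7)

    def test_four_consecutive_bins_do_not_fire(self, warn_windows):
        z = self._z([(i, 6.0) for i in range(3, 7)])
        assert fire_warnings(z, "chrW", warn_windows) == []

    def test_two_bins_over_syndrome_fire_known_anomaly(self, warn_windows):
        syn = [SyndromeRegion("chrW", 0, 15_000_000, "test_syndrome")]
        z = self._z([(5, -6.0), (6, -6.0)])
        (w,) = fire_warnings(z, "chrW", warn_windows, syn)
        assert w.kind == "known_syndrome_anomaly"
        assert w.syndrome == "test_syndrome"
        assert w.span == 4_000_000

    def test_two_bins_without_overlap_do_not_fire(self, warn_windows):
        syn = [SyndromeRegion("chrW", 20_000_000, 30_000_000, "far_syndrome")]
        z = self._z([(1, 6.0), (2, 6.0)])
        assert fire_warnings(z, "chrW", warn_windows, syn) == []

    def test_single_bin_never_fires_even_on_syndrome(self, warn_windows):
        syn = [SyndromeRegion("chrW", 0, 40_000_000, "whole")]
        z = self._z([(5, 9.0)])
        assert fire_warnings(z, "chrW", warn_windows, syn) == []

    def test_long_run_over_syndrome_fires_both_kinds(self, warn_windows):
        syn = [SyndromeRegion("chrW", 6_000_001, 7_000_000, "mid")]
        z = self._z([(i, 5.2) for i in range(0, 6)])
        kinds = {w.kind for w in fire_warnings(z, "chrW", warn_windows, syn)}
        assert kinds == {"unknown_anomaly", "known_syndrome_anomaly"}

    def test_masked_window_breaks_consecutiveness(self, warn_windows):
        z = self._z([(i, 6.0) for i in range(0, 6)])
        z[2] = np.nan
        assert fire_warnings(z, "chrW", warn_windows) == []

    def test_warnings_monotone_in_z(self, warn_windows):
        z = self._z([(i, 5.1) for i in range(3, 8)])
        base = fire_warnings(z, "chrW", warn_windows)
        z[5] = 9.9
        boosted = fire_warnings(z, "chrW", warn_windows)
        assert len(boosted) >= len(base) == 1


def _track(chrom_z, window_z):
    window_z = np.asarray(window_z, dtype=float)
    return ZTrack(chrom="chrT", chrom_z=chrom_z, window_z=window_z,
                  mask=np.isfinite(window_z))


class TestGniptCall:
    def test_offsetting_blocks_flag_normal_chromosome(self):
        # chrom z in the normal range, but loss + gain blocks covering all windows
        z = np.concatenate([np.full(10, -2.2), np.full(10, 2.2)])
        track = _track(1.783, z)
        fit = fused_lasso_fit(z, 0.1, 4.0)
        blocks = detect_blocks(fit, z, "chrT")
        flagged = [b for b in blocks if b.flagged]
        assert {b.direction for b in flagged} == {"gain", "loss"}
        status = gnipt_call(track, blocks, [])
        assert status.status == "affected"
        assert "offsetting_blocks" in status.reasons
        assert track.call == "unaffected"

    def test_single_segmental_finding_keeps_chromosome_unaffected(self):
        z = np.zeros(30)
        z[12] = 4.0
        track = _track(0.677, z)
        fit = fused_lasso_fit(z, 0.1, 0.5)
        blocks = detect_blocks(fit, z, "chrT")
        status = gnipt_call(track, blocks, [])
        assert status.status == "unaffected"
        assert len(status.findings) == 1
        assert status.findings[0].direction == "gain"

    def test_clean_chromosome(self):
        track = _track(0.0, np.zeros(25))
        status = gnipt_call(track, [], [])
        assert status.status == "unaffected"
        assert status.findings == [] and status.reasons == []

    def test_high_chromosome_z_alone_suffices(self):
        track = _track(5.2, np.full(25, 1.0))
        status = gnipt_call(track, [], [])
        assert status.status == "affected"
        assert status.reasons == ["chromosome_z"]

    def test_warning_alone_suffices(self, warn_windows):
        z = np.zeros(20)
        z[3:8] = 6.0
        warnings = fire_warnings(z, "chrW", warn_windows)
        track = _track(0.5, z)
        status = gnipt_call(track, [], warnings)
        assert status.status == "affected"
        assert "warning" in status.reasons
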