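"""Shared fixtures: miniature genome, synthetic GC landscape, euploid panel."""

import numpy as np
import pytest

from gnipt.gc_normalize import loess_correct
from gnipt.reference_baseline import build_reference
from gnipt.simulator import (SimConfig, mini_genome_windows, simulate_sample,
                             synthetic_gc_profile)

#: Seed of the shared euploid panel; independent of per-test seeds.
PANEL_SEED = 11


@pytest.fixture(scope="session")
def windows():
    return mini_genome_windows()


@pytest.fixture(scope="session")
def gc_profile(windows):
    return synthetic_gc_profile(windows)


@pytest.fixture(scope="session")
def euploid_cohort(windows, gc_profile):
    """50 GC-corrected euploid samples at default study conditions."""
    cfg = SimConfig(windows=windows, seed=PANEL_SEED)
    rng = cfg.rng()
    return [
        loess_correct(simulate_sample(cfg, [], rng, sample_id=f"eu{i:02d}")[0],
                      gc_profile)
        for i in range(50)
    ]


@pytest.fixture(scope="session")
def baseline(euploid_cohort):
    return build_reference(euploid_cohort)


def fused_lasso_oracle(y, lambda1, lambda2):
    """Generic convex-optimization solve of the fused-lasso objective.

    Smooth reformulation with slack variables for both absolute-value
    penalties, solved by SLSQP: an independent route from the production
    TV-denoise + soft-threshold solver.  Returns (beta, objective).
    """
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    n = y.size

    def f(v):
        b, t, s = v[:n], v[n:2 * n], v[2 * n:]
        return (0.5 * np.sum((y - b) ** 2) + lambda1 * np.sum(t)
                + lambda2 * np.sum(s))

    cons = []
    for i in range(n):
        cons.append({"type": "ineq", "fun": lambda v, i=i: v[n + i] - v[i]})
        cons.append({"type": "ineq", "fun": lambda v, i=i: v[n + i] + v[i]})
    for i in range(n - 1):
        cons.append({"type": "ineq", "fun": lambda v, i=i: v[2 * n + i] - (v[i + 1] - v[i])})
        cons.append({"type": "ineq", "fun": lambda v, i=i: v[2 * n + i] + (v[i + 1] - v[i])})
    v0 = np.concatenate([y, np.abs(y), np.abs(np.diff(y))])
    res = minimize(f, v0, method="SLSQP", constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    return res.x[:n], f(res.x)
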