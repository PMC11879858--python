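"""Shared fixtures and independent oracles for the test-suite."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from scipy.stats import binom

from egocontagion import experiments as exp
from egocontagion.forest import RFProtocol


def exact_misclassification_dp(
    k: int, beta: float, phi: float, r: float, horizon: int = 4000
) -> float:
    """Exact P(classified Cx | true Sm) for one ego star, by dynamic
    programming over the Markov chain (infected-leaf count, threshold-history
    flag).  Independent of the likelihood engine: it enumerates the
    generative process directly.  The misclassification event is a trajectory
    whose complex-contagion likelihood equals one — the count stayed at or
    below k*phi until the step before adoption and exceeded it at that step.
    """
    thr = k * phi
    P = np.zeros((k + 1, 2))
    P[0, 1] = 1.0
    p_mis = 0.0
    for _ in range(horizon):
        newP = np.zeros_like(P)
        for n in range(k + 1):
            b_n = 1.0 - (1.0 - beta) ** n
            for g in (0, 1):
                pr = P[n, g]
                if pr == 0.0:
                    continue
                if b_n > 0 and g == 1 and n > thr:
                    p_mis += pr * b_n
                surv = pr * (1.0 - b_n)
                if surv == 0.0:
                    continue
                g_new = 1 if (g == 1 and n <= thr) else 0
                for j in range(k - n + 1):
                    newP[n + j, g_new] += surv * binom.pmf(j, k - n, r)
        P = newP
        if P.sum() < 1e-13:
            break
    return p_mis


@pytest.fixture(scope="session")
def exp1_surface():
    """Ego-star accuracy surface at 10,000 replicates per cell, with the
    matching closed-form surface (shared across acceptance tests)."""
    rng = np.random.default_rng(20260901)
    surface = exp.run_experiment1(10_000, rng)
    theory = exp.analytic_surface()
    return surface, theory


@pytest.fixture(scope="session")
def exp2_results():
    """Experiment 2/3 sweep at 5 network realisations per cell with the
    scaled-down random-forest protocol (shared across acceptance tests)."""
    rng = np.random.default_rng(20260902)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return exp.run_experiment2_grid(
            5,
            rng,
            rf_protocol=RFProtocol(train_per_class=3000, test_per_class=1000),
            rf_realisations=2,
        )


@pytest.fixture(scope="session")
def exp4_results():
    """Activity-driven experiment on a reduced synthetic network."""
    rng = np.random.default_rng(20260903)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, records, clf = exp.run_experiment4(
            rng,
            n_big=4000,
            target_size=1500,
            n_runs=3,
            rf_protocol=RFProtocol(train_per_class=2000, test_per_class=700),
        )
    return out, records, clf
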