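import math

import numpy as np
import pandas as pd
import pytest

from rhythmfit import GeneTruth, SyntheticDesign, simulate_expression

CLOCK_GENES = ("CLOCK", "BMAL1", "PER1", "PER2", "PER3", "CRY1", "CRY2")
CONDITIONS = ("K", "BJ17", "BJ23")


@pytest.fixture
def study_design():
    """2-h sampling over 24 h, two experiments, 24-h period."""
    return SyntheticDesign(genes=("PER3",), conditions=("K", "BJ17"), seed=11)


@pytest.fixture
def noiseless_sine():
    """Times and values of y = 5 + 2*sin(2*pi*t/24) at 2-h spacing."""
    t = np.arange(0.0, 24.0, 2.0)
    return t, 5.0 + 2.0 * np.sin(2.0 * np.pi * t / 24.0)


@pytest.fixture
def multigene_series():
    """Noisy 7-gene x 3-condition series mirroring a co-culture experiment."""
    rng = np.random.default_rng(42)
    design = SyntheticDesign(genes=CLOCK_GENES, conditions=CONDITIONS, seed=42)
    truths = {
        g: GeneTruth(mesor=5.0, amplitude=1.5, acrophase=-2 * math.pi * i / 7 - 0.1,
                     amplitude_scale={"BJ17": 1.5}, phase_shift={"BJ23": 2.0},
                     noise_sd=0.2)
        for i, g in enumerate(CLOCK_GENES)
    }
    return simulate_expression(design, truths)


def cosinor_normal_equations(times, values, period=24.0):
    """Independent brute-force oracle: solve the normal equations directly."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    w = 2.0 * np.pi * t / period
    X = np.column_stack([np.sin(w), np.cos(w), np.ones_like(t)])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    rss_full = float(np.sum((y - X @ coef) ** 2))
    rss_reduced = float(np.sum((y - y.mean()) ** 2))
    return coef, rss_full, rss_reduced


def bh_stepup(pvalues):
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m*p_(j)/j."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = math.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * p[idx] / rank)
        q[idx] = min(running, 1.0)
    return q
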