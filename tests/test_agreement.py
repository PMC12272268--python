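"""Bland-Altman agreement, JZS Bayes factor, repeatability SD."""

import math

import numpy as np
import pytest
from scipy import stats

from synt1w import (
    CohortSpec,
    bland_altman,
    interpret_bf,
    jzs_bayes_factor,
    repeatability_sd,
    simulate_cohort,
    subject_mean_differences,
)
from synt1w.agreement import _jzs_integrand


def test_identical_pairs_zero_bias_and_loa():
    a = np.array([60.0, 61.0, 62.0])
    ba = bland_altman(a, a.copy())
    assert ba.bias == 0.0
    assert ba.loa_lower == 0.0
    assert ba.loa_upper == 0.0


def test_hand_computed_loa():
    """Differences {1,2,3}: bias 2, sample SD exactly 1, LoA (0.04, 3.96)."""
    a = np.array([10.0, 20.0, 30.0])
    b = a + np.array([1.0, 2.0, 3.0])
    ba = bland_altman(a, b)
    assert ba.bias == pytest.approx(2.0)
    assert ba.sd_diff == pytest.approx(1.0)
    assert ba.loa_lower == pytest.approx(0.04)
    assert ba.loa_upper == pytest.approx(3.96)


def test_bias_percent_against_method_means():
    """A -0.31 mm^2 bias between method means 63.02 and 62.71 reads as -0.5%."""
    rng = np.random.default_rng(0)
    a = 63.02 + rng.normal(0, 1e-9, 40)
    b = a - 0.31
    ba = bland_altman(a, b)
    assert ba.mean_a == pytest.approx(63.02, abs=1e-6)
    assert ba.mean_b == pytest.approx(62.71, abs=1e-6)
    assert round(ba.bias_pct, 1) == -0.5


def test_two_pairs_minimum():
    with pytest.raises(ValueError):
        bland_altman([1.0], [2.0])


def test_loa_covers_95_percent_of_large_sample():
    df = simulate_cohort(CohortSpec(n_controls=500, n_patients=500, seed=5))
    pairs = subject_mean_differences(df)
    ba = bland_altman(pairs["a"], pairs["b"])
    d = pairs["b"].values - pairs["a"].values
    coverage = np.mean((d >= ba.loa_lower) & (d <= ba.loa_upper))
    assert ba.n >= 1000
    assert coverage == pytest.approx(0.95, abs=0.02)


def test_bf_null_favored_at_t_zero():
    x = np.concatenate([np.arange(50) * 0.1, -np.arange(50) * 0.1])
    bf = jzs_bayes_factor(x, x.copy())
    assert bf < 1.0
    assert interpret_bf(bf) == "evidence for equivalence"


def test_bf_scale_invariance():
    rng = np.random.default_rng(3)
    x, y = rng.normal(0, 1, 25), rng.normal(0.4, 1, 25)
    assert jzs_bayes_factor(x, y) == pytest.approx(
        jzs_bayes_factor(10 * x, 10 * y), rel=1e-9
    )


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_bf_matches_fine_grid_quadrature_oracle(seed):
    """Adaptive-quadrature BF10 equals a dense fixed-grid Simpson evaluation."""
    rng = np.random.default_rng(seed)
    x, y = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
    bf = jzs_bayes_factor(x, y)

    n1 = n2 = 20
    nu = n1 + n2 - 2
    N = n1 * n2 / (n1 + n2)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / nu
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    # substitute g = u/(1-u) to integrate over (0, 1) on a dense Simpson grid
    u = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
    g = u / (1.0 - u)
    vals = _jzs_integrand(g, t, N, nu, math.sqrt(2) / 2) / (1.0 - u) ** 2
    from scipy.integrate import simpson

    alt = simpson(vals, x=u)
    null = (1.0 + t * t / nu) ** (-(nu + 1.0) / 2.0)
    assert bf == pytest.approx(alt / null, rel=1e-6)


def test_bf_matches_pingouin():
    """Independent cross-check against pingouin's published implementation."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 24)
    t, _ = stats.ttest_ind(x, y)
    theirs = float(pg.bayesfactor_ttest(t, 30, 24, paired=False, r=math.sqrt(2) / 2))
    assert jzs_bayes_factor(x, y) == pytest.approx(theirs, rel=1e-8)


def test_bf_decreases_with_n_under_null():
    """Under H0 the Bayes factor concentrates toward 0 as n grows."""
    medians = []
    for n in (20, 80, 320):
        bfs = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            bfs.append(jzs_bayes_factor(rng.normal(0, 1, n), rng.normal(0, 1, n)))
        medians.append(np.median(bfs))
    assert medians[0] > medians[1] > medians[2]


def test_bf_degenerate_samples_warn():
    with pytest.warns(UserWarning, match="degenerate"):
        bf = jzs_bayes_factor([1.0, 1.0, 1.0], [1.0, 1.0])
    assert bf == 0.0


def test_repeatability_hand_values():
    import pandas as pd

    rows = []
    for t, v in zip((0, 2, 6), (60.0, 62.0, 64.0)):
        rows.append(dict(subject_id="s1", group="control", modality="synthetic",
                         time_months=t, level="C1", csa_mm2=v))
        rows.append(dict(subject_id="s2", group="control", modality="synthetic",
                         time_months=t, level="C1", csa_mm2=55.0))
    rep = repeatability_sd(pd.DataFrame(rows))
    assert rep.per_subject_sd["s1"] == pytest.approx(2.0)
    assert rep.per_subject_sd["s2"] == pytest.approx(0.0)


def test_repeatability_recovers_residual_sd():
    """Stable controls with residual SD 1.4: cohort mean SD lands near 1.4."""
    spec = CohortSpec(
        n_controls=50, n_patients=5, seed=17,
        control_rate=0.0, control_quad=0.0, sd_slope=0.0, sd_quad=0.0,
        residual_sd=1.4,
        modality_noise_sd={"reference": 0.0, "synthetic": 0.0},
    )
    df = simulate_cohort(spec)
    rep = repeatability_sd(df, modality="synthetic", group="control")
    assert rep.mean_sd == pytest.approx(1.4, abs=0.2)
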