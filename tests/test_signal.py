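"""Closed-form MPRAGE signal model: timing, relaxation factors, synthesis."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synt1w import (
    PhantomSpec,
    QuantitativeMaps,
    SequenceParams,
    TissueVoxel,
    compute_Q,
    compute_t1star,
    derive_timing,
    make_cord_phantom,
    signal_components,
    synthesize_volume,
    synthesize_voxel,
)
from synt1w.signal import TissueVoxel as TV


@pytest.mark.parametrize(
    "alpha,te,tr,ti,es,n,tau_ms,td_ms,feasible",
    [
        (14, 0, 1400, 900, 14, 176, 2464, -732, False),
        (10, 0, 1500, 1000, 10, 100, 1000, 0, True),
        (10, 0, 1000, 500, 10, 1, 10, 495, True),
    ],
)
def test_timing_identities(alpha, te, tr, ti, es, n, tau_ms, td_ms, feasible):
    """tau = n*ES and TD = TR - (TI - tau/2) - tau, exact in milliseconds."""
    params = SequenceParams.from_ms(alpha, te, tr, ti, es, n)
    t = derive_timing(params)
    assert round(t.tau * 1e3) == tau_ms
    assert abs(t.tau * 1e3 - tau_ms) < 1e-9
    assert round(t.TD * 1e3) == td_ms
    assert abs(t.TD * 1e3 - td_ms) < 1e-9
    assert t.feasible == feasible


@settings(max_examples=100, deadline=None)
@given(
    alpha=st.floats(1.0, 89.0),
    tr=st.floats(0.5, 5.0),
    ti=st.floats(0.1, 2.0),
    es=st.floats(0.002, 0.02),
    n=st.integers(1, 300),
)
def test_timing_identity_property(alpha, tr, ti, es, n):
    params = SequenceParams(alpha, 0.0, tr, ti, es, n)
    t = derive_timing(params)
    assert t.tau == n * es
    assert t.TD == tr - (ti - t.tau / 2.0) - t.tau


def test_t1star_examples():
    assert compute_t1star(1.0, 0.0, 0.014) == pytest.approx(1.0)
    # -ln(cos 14 deg)/0.014 s = 2.1538 1/s, so T1* = 1/3.1538 = 0.3171 s
    assert compute_t1star(1.0, 14.0, 0.014) == pytest.approx(0.3171, abs=2e-4)
    # alpha -> 90: T1* -> 0
    assert compute_t1star(1.0, 89.99, 0.014) < 2e-3
    assert compute_t1star(1.0, 89.9999, 0.014) < compute_t1star(1.0, 89.99, 0.014)
    with pytest.raises(ValueError):
        compute_t1star(1.0, 90.0, 0.014)
    with pytest.raises(ValueError):
        compute_t1star(1.0, 14.0, 0.0)


def test_fully_relaxed_limit(mprage_params):
    """With R1 -> infinity all relaxation completes within the cycle: Q -> 1."""
    assert compute_Q(mprage_params, 1.0e4) == pytest.approx(1.0, abs=1e-3)


def test_components_in_unit_interval_for_feasible_timing(mprage_params):
    comps = signal_components(mprage_params, 1.0)
    for val in (comps.E1, comps.E2, comps.E3, comps.E4):
        assert 0.0 < val <= 1.0


def test_negative_td_warns_and_e2_exceeds_one(optimized_params):
    with pytest.warns(UserWarning, match="not feasible"):
        comps = signal_components(optimized_params, 1.0)
    assert comps.E2 > 1.0


def test_voxel_zero_signal_cases(mprage_params):
    assert synthesize_voxel(TissueVoxel(0.0, 1.0, 30.0), mprage_params) == 0.0
    zero_alpha = SequenceParams.from_ms(0.0, 4.18, 2420.0, 960.0, 10.0, 176)
    assert synthesize_voxel(TissueVoxel(0.8, 1.0, 30.0), zero_alpha) == 0.0


def test_invalid_voxel_synthesizes_to_zero(mprage_params):
    assert synthesize_voxel(TissueVoxel(math.nan, 1.0, 30.0), mprage_params) == 0.0
    assert synthesize_voxel(TissueVoxel(0.8, -1.0, 30.0), mprage_params) == 0.0


def test_linearity_in_pd(mprage_params):
    base = synthesize_voxel(TissueVoxel(0.37, 0.9, 25.0), mprage_params)
    for c in (0.1, 2.0, 17.5):
        scaled = synthesize_voxel(TissueVoxel(0.37 * c, 0.9, 25.0), mprage_params)
        assert scaled == pytest.approx(c * base, rel=1e-12)


def test_te_decay_factorization(mprage_params):
    """S factorizes as exp(-TE*R2*): the TE=0 / TE=5ms ratio is exp(0.005*30)."""
    v0 = TissueVoxel(0.8, 1.0, 30.0)
    p0 = SequenceParams(9.0, 0.0, 2.42, 0.96, 0.010, 176)
    p5 = SequenceParams(9.0, 0.005, 2.42, 0.96, 0.010, 176)
    s0 = synthesize_voxel(v0, p0)
    s5 = synthesize_voxel(v0, p5)
    assert s0 / s5 == pytest.approx(math.exp(0.15), rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(te_us=st.lists(st.integers(0, 20000), min_size=2, max_size=6, unique=True))
def test_monotonic_te_decay(te_us):
    """For R2* > 0 the signal strictly decreases with TE, all else fixed."""
    voxel = TissueVoxel(0.8, 1.0, 30.0)
    te_sorted = [t * 1e-6 for t in sorted(te_us)]
    signals = [
        synthesize_voxel(voxel, SequenceParams(9.0, t, 2.42, 0.96, 0.010, 176))
        for t in te_sorted
    ]
    assert all(a > b for a, b in zip(signals, signals[1:]))


def test_volume_matches_voxelwise(straight_phantom, mprage_params):
    maps = straight_phantom.maps
    vol = synthesize_volume(maps, mprage_params)
    rng = np.random.default_rng(0)
    for _ in range(100):
        i, j, k = (rng.integers(0, s) for s in maps.shape)
        expected = synthesize_voxel(
            TV(maps.PD[i, j, k], maps.R1[i, j, k], maps.R2star[i, j, k]),
            mprage_params,
        )
        assert vol[i, j, k] == pytest.approx(expected, rel=1e-12, abs=1e-15)


def test_all_zero_pd_volume(mprage_params):
    maps = QuantitativeMaps(
        PD=np.zeros((4, 4, 4)),
        R1=np.ones((4, 4, 4)),
        R2star=np.full((4, 4, 4), 30.0),
        voxel_spacing=(1.0, 1.0, 1.0),
    )
    assert np.all(synthesize_volume(maps, mprage_params) == 0.0)


def test_volume_shape_mismatch_errors():
    with pytest.raises(ValueError, match="shapes differ"):
        QuantitativeMaps(
            PD=np.zeros((4, 4, 4)),
            R1=np.zeros((4, 4, 3)),
            R2star=np.zeros((4, 4, 4)),
            voxel_spacing=(1.0, 1.0, 1.0),
        )


def test_invalid_voxels_masked_in_volume(mprage_params):
    pd = np.ones((4, 4, 4))
    pd[1, 2, 3] = np.nan
    maps = QuantitativeMaps(
        PD=pd, R1=np.ones((4, 4, 4)), R2star=np.full((4, 4, 4), 30.0),
        voxel_spacing=(1.0, 1.0, 1.0),
    )
    vol = synthesize_volume(maps, mprage_params)
    assert vol[1, 2, 3] == 0.0
    assert np.all(np.isfinite(vol))


def test_two_class_phantom_gives_two_intensities(mprage_params):
    """Piecewise-constant maps synthesize to piecewise-constant signal."""
    tissues = {
        "cord": TissueVoxel(0.9, 1.0, 30.0),
        "csf": TissueVoxel(0.5, 0.5, 20.0),
        "background": TissueVoxel(0.5, 0.5, 20.0),
    }
    ph = make_cord_phantom(
        PhantomSpec(grid_shape=(24, 24, 8), cord_radius=5.0, tissue_params=tissues,
                    subsample=1)
    )
    vol = synthesize_volume(ph.maps, mprage_params)
    values = np.unique(np.round(vol, 12))
    assert len(values) == 2
    assert np.all(values > 0)
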