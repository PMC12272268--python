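"""Segmentation and CSA measurement: geometry recovery, angle correction."""

import numpy as np
import pytest

from synt1w import (
    CordMask,
    PhantomSpec,
    SegmentationConfig,
    TissueVoxel,
    batch_csa,
    make_cord_phantom,
    measure_csa,
    segment_cord,
    synthesize_volume,
)
from synt1w.phantom import PD_CONTRAST_TISSUES

PI16 = np.pi * 16.0


def test_mask_equals_majority_mask_on_two_intensity_phantom(mprage_params):
    """Noiseless two-class phantom without partial volume segments exactly."""
    tissues = {
        "cord": TissueVoxel(0.9, 1.0, 30.0),
        "csf": TissueVoxel(0.5, 0.5, 20.0),
        "background": TissueVoxel(0.5, 0.5, 20.0),
    }
    ph = make_cord_phantom(
        PhantomSpec(grid_shape=(32, 32, 8), cord_radius=4.0,
                    tissue_params=tissues, subsample=1)
    )
    vol = synthesize_volume(ph.maps, mprage_params)
    mask = segment_cord(vol, (1.0, 1.0, 1.0))
    assert np.array_equal(mask.mask, ph.cord_fraction > 0.5)


def test_untilted_phantom_area_within_digitization_bound(straight_volume):
    mask = segment_cord(straight_volume, (1.0, 1.0, 1.0))
    meas = measure_csa(mask)
    bound = 2.0 * 2.0 * np.pi * 4.0 * 1.0  # 2 * perimeter * voxel size
    raw = meas.slice_area_raw[np.isfinite(meas.slice_area_raw)]
    assert np.all(np.abs(raw - PI16) < bound)
    # straight cylinder: no angle, corrected equals raw
    assert np.nanmax(meas.slice_angle_deg) == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(meas.slice_area_corrected, meas.slice_area_raw)


def test_tilted_cylinder_angle_correction(tilted_pd_phantom, optimized_params):
    """Corrected area recovers pi*r^2 within 5%; raw is inflated by 1/cos(30)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol = synthesize_volume(tilted_pd_phantom.maps, optimized_params)
    mask = segment_cord(vol, (1.0, 1.0, 1.0))
    meas = measure_csa(mask)
    assert meas.overall_mean == pytest.approx(PI16, rel=0.05)
    raw_mean = np.nanmean(meas.slice_area_raw)
    assert raw_mean == pytest.approx(PI16 / np.cos(np.radians(30.0)), rel=0.05)
    interior = meas.slice_angle_deg[6:-6]
    assert np.nanmean(interior) == pytest.approx(30.0, abs=3.0)


def test_segmentation_scale_invariance(straight_volume):
    m1 = segment_cord(straight_volume, (1.0, 1.0, 1.0))
    m2 = segment_cord(10.0 * straight_volume, (1.0, 1.0, 1.0))
    assert np.array_equal(m1.mask, m2.mask)


def test_segmentation_with_noise_snr20(optimized_params):
    """Pipeline recovers phantom CSA within the digitization bound at SNR ~20."""
    import warnings

    spec = PhantomSpec(
        grid_shape=(48, 48, 16), cord_radius=4.0,
        tissue_params=dict(PD_CONTRAST_TISSUES), noise_sd=0.025, seed=21,
    )
    ph = make_cord_phantom(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol = synthesize_volume(ph.maps, optimized_params)
    meas = measure_csa(segment_cord(vol, (1.0, 1.0, 1.0)))
    bound = 2.0 * 2.0 * np.pi * 4.0 * 1.0
    assert abs(meas.overall_mean - PI16) < bound


def test_constant_image_raises():
    with pytest.raises(ValueError, match="no cord found"):
        segment_cord(np.ones((8, 8, 4)), (1.0, 1.0, 1.0))


def test_fixed_threshold_config_requires_value():
    with pytest.raises(ValueError, match="fixed_threshold"):
        SegmentationConfig(method="fixed")


def _handmade_mask(counts, shape=(16, 16)):
    """Straight mask whose slice s contains counts[s] foreground voxels."""
    nz = len(counts)
    mask = np.zeros(shape + (nz,), dtype=bool)
    centroids = np.zeros((nz, 2))
    for s, c in enumerate(counts):
        side = int(np.ceil(np.sqrt(c)))
        flat = np.zeros(shape[0] * shape[1], dtype=bool)
        flat[:c] = True
        mask[:, :, s] = flat.reshape(shape)
        cx, cy = np.argwhere(mask[:, :, s]).mean(axis=0)
        centroids[s] = (cx, cy)
    # use identical centroids to keep the centerline perfectly straight
    centroids[:] = centroids.mean(axis=0)
    return CordMask(mask=mask, spacing=(1.0, 1.0, 1.0), centroids=centroids,
                    empty_slices=np.zeros(nz, dtype=bool))


def test_level_means_arithmetic():
    mask = _handmade_mask([50, 50, 52, 52])
    meas = measure_csa(mask, levels={"A": (0, 2), "B": (2, 4)})
    assert meas.level_means == pytest.approx({"A": 50.0, "B": 52.0})
    assert meas.overall_mean == pytest.approx(51.0)


def test_measure_requires_three_slices():
    mask = _handmade_mask([50, 50])
    with pytest.raises(ValueError, match="3 non-empty"):
        measure_csa(mask)


def test_level_range_outside_volume_errors():
    mask = _handmade_mask([50, 50, 52, 52])
    with pytest.raises(ValueError, match="outside"):
        measure_csa(mask, levels={"A": (0, 9)})


def test_batch_csa_known_radii(optimized_params):
    """Levels drawn from phantoms of radii 4.0/4.1/4.2 mm give pi*r^2 areas."""
    import warnings

    radii = np.repeat([4.0, 4.1, 4.2], 4)
    ph = make_cord_phantom(
        PhantomSpec(grid_shape=(48, 48, 12), cord_radius=radii,
                    tissue_params=dict(PD_CONTRAST_TISSUES))
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vol = synthesize_volume(ph.maps, optimized_params)
    levels = {"C1": (0, 4), "C2": (4, 8), "C3": (8, 12)}
    df = batch_csa({"s1": vol}, (1.0, 1.0, 1.0), levels, meta={"s1": {"group": "control"}})
    assert len(df) == 3
    got = df.set_index("level")["csa_mm2"]
    for lev, r in zip(("C1", "C2", "C3"), (4.0, 4.1, 4.2)):
        assert got[lev] == pytest.approx(np.pi * r * r, rel=0.08)
    # determinism
    df2 = batch_csa({"s1": vol}, (1.0, 1.0, 1.0), levels, meta={"s1": {"group": "control"}})
    assert df.equals(df2)
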