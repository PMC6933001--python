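import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from ctvlsm.preprocess import (
    AffineTransform,
    SigmoidParams,
    default_sigmoid_params,
    fwhm_to_sigma,
    inverse_transform_intensity,
    make_masks,
    register_affine,
    remove_background_clusters,
    resample,
    reslice_isotropic,
    skull_strip,
    smooth_gaussian,
    transform_intensity,
)
from ctvlsm.synthetic import generate_control_volume
from ctvlsm.volume import Volume, dice

from conftest import tiny_config


def _vol(data, voxel=1.0, origin=None):
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    if origin is not None:
        aff[:3, 3] = origin
    return Volume(np.asarray(data, float), aff)


# ---- background removal ---------------------------------------------


def test_single_blob_retained_unchanged():
    data = np.zeros((20, 20, 20))
    data[5:15, 5:15, 5:15] = 40.0
    out = remove_background_clusters(_vol(data))
    np.testing.assert_array_equal(out.data, data)


def test_disjoint_speck_removed():
    data = np.zeros((24, 24, 24))
    data[2:12, 2:12, 2:12] = 40.0  # 1000-voxel head
    data[20:21, 20:21, 20:25] = 40.0  # disjoint speck
    out = remove_background_clusters(_vol(data))
    labels, n = ndimage.label(out.data > 0, structure=np.ones((3, 3, 3)))
    assert n == 1
    assert (out.data > 0).sum() == 1000


def test_all_zero_input_errors():
    with pytest.raises(ValueError):
        remove_background_clusters(_vol(np.zeros((8, 8, 8))))


def test_uniform_volume_degenerate_rule():
    with pytest.warns(UserWarning):
        out = remove_background_clusters(_vol(np.full((8, 8, 8), 100.0)))
    assert np.all(out.data == 100.0)


# ---- intensity transform --------------------------------------------


def test_sigmoid_round_trip_and_monotonicity():
    params = default_sigmoid_params(10.0, 40.0)
    x = np.linspace(0.0, 80.0, 500).reshape(5, 10, 10)
    v = _vol(x)
    back = inverse_transform_intensity(transform_intensity(v, params), params)
    assert np.max(np.abs(back.data - x)) < 1e-6
    fwd = transform_intensity(v, params).data.ravel()
    assert np.all(np.diff(fwd) > 0)


def test_sigmoid_steepest_between_tissue_modes():
    params = default_sigmoid_params(10.0, 40.0)
    c, s = params.center, 1.0 / params.slope

    def deriv(x, h=1e-4):
        f = lambda z: params.out_max / (1 + np.exp(-params.slope * (z - c)))
        return (f(x + h) - f(x - h)) / (2 * h)

    assert deriv(c) > deriv(c + 3 * s)
    assert deriv(c) > deriv(c - 3 * s)


def test_non_monotone_params_rejected():
    with pytest.raises(ValueError):
        SigmoidParams(center=25.0, slope=-1.0)


@given(
    center=st.floats(5.0, 50.0),
    slope=st.floats(0.05, 1.0),
    x=st.floats(-20.0, 100.0),
)
def test_sigmoid_inverse_property(center, slope, x):
    from hypothesis import assume

    # stay on the float-invertible part of the sigmoid: once the output
    # saturates toward 0 or out_max the inverse loses precision
    assume(abs(slope * (x - center)) < 15.0)
    params = SigmoidParams(center=center, slope=slope)
    v = _vol(np.full((2, 2, 2), x))
    back = inverse_transform_intensity(transform_intensity(v, params), params)
    assert np.max(np.abs(back.data - x)) < 1e-6


# ---- masks and skull strip ------------------------------------------


def test_masks_recover_generator_anatomy():
    cfg = tiny_config()
    v = generate_control_volume(cfg, np.random.default_rng(2))
    brain, vent = make_masks(v)
    assert dice(brain, cfg.brain_mask().astype(np.uint8)) >= 0.95
    assert brain.is_mask() and vent.is_mask()
    # containment: ventricles inside the brain
    assert np.all(brain.data[vent.data > 0] == 1)


def test_masks_error_on_empty_and_flat():
    with pytest.raises(ValueError):
        make_masks(_vol(np.zeros((10, 10, 10))))
    with pytest.raises(ValueError):
        make_masks(_vol(np.full((10, 10, 10), 100.0)))


def test_skull_strip_arithmetic():
    rng = np.random.default_rng(0)
    v = _vol(rng.random((8, 8, 8)))
    ones = _vol(np.ones((8, 8, 8)))
    zeros = _vol(np.zeros((8, 8, 8)))
    np.testing.assert_array_equal(skull_strip(v, ones).data, v.data)
    assert not skull_strip(v, zeros).data.any()
    mask = _vol((rng.random((8, 8, 8)) > 0.5).astype(float))
    out = skull_strip(v, mask)
    assert out.data.sum() == pytest.approx((v.data * mask.data).sum())
    with pytest.raises(ValueError):
        skull_strip(v, _vol(np.ones((4, 4, 4))))


# ---- reslicing -------------------------------------------------------


def test_reslice_identity_is_exact():
    cfg = tiny_config()
    v = generate_control_volume(cfg, np.random.default_rng(4))
    out = reslice_isotropic(v, AffineTransform.identity(), resolution_mm=1.0)
    assert out.shape == v.shape
    assert np.max(np.abs(out.data - v.data)) < 1e-6
    assert out.space == "template"


def test_reslice_integer_shift_of_mask_preserves_counts():
    data = np.zeros((16, 16, 16))
    data[5:9, 5:9, 5:9] = 1.0
    v = _vol(data, origin=(-8, -8, -8))
    t = AffineTransform(translation=[3.0, -2.0, 1.0])
    out = reslice_isotropic(v, t, resolution_mm=1.0,
                            bounding_box=((-8, -8, -8), (7, 7, 7)), is_mask=True)
    assert out.data.sum() == data.sum()
    np.testing.assert_array_equal(out.data, np.roll(data, (3, -2, 1), axis=(0, 1, 2)))


def test_reslice_downsample_constant_region():
    cfg = tiny_config(parenchyma_sd=0.0, csf_sd=0.0, ventricle_centers_mm=())
    v = generate_control_volume(cfg, np.random.default_rng(0))
    out = reslice_isotropic(v, AffineTransform.identity(), resolution_mm=2.0)
    center = tuple(s // 2 for s in out.shape)
    assert out.data[center] == pytest.approx(cfg.parenchyma_mean)


def test_reslice_warns_when_bbox_misses_brain():
    data = np.zeros((10, 10, 10))
    data[4:6, 4:6, 4:6] = 10.0
    v = _vol(data, origin=(-5, -5, -5))
    with pytest.warns(UserWarning):
        reslice_isotropic(v, None, 1.0, bounding_box=((50, 50, 50), (60, 60, 60)))


# ---- smoothing -------------------------------------------------------


def test_smoothing_contracts():
    assert fwhm_to_sigma(4.0) == pytest.approx(1.6986, abs=1e-3)
    rng = np.random.default_rng(1)
    v = _vol(rng.random((12, 12, 12)))
    np.testing.assert_array_equal(smooth_gaussian(v, 0.0).data, v.data)
    with pytest.raises(ValueError):
        smooth_gaussian(v, -1.0)
    # interior mass conservation
    data = np.zeros((32, 32, 32))
    data[12:20, 12:20, 12:20] = 7.0
    sm = smooth_gaussian(_vol(data), 4.0)
    assert sm.data.sum() == pytest.approx(data.sum(), rel=1e-6)


# ---- affine transform / registration --------------------------------


def test_identity_parameters_compose_to_identity_matrix():
    t = AffineTransform.identity()
    np.testing.assert_allclose(t.matrix, np.eye(4), atol=1e-15)
    vec = t.to_vector()
    np.testing.assert_allclose(AffineTransform.from_vector(vec).matrix, np.eye(4))


def test_transform_matrix_inverse():
    t = AffineTransform(translation=[1, 2, 3], rotation=[0.1, -0.05, 0.2],
                        scale=[1.1, 0.9, 1.05], shear=[0.02, -0.01, 0.03])
    np.testing.assert_allclose(t.matrix @ t.inverse_matrix, np.eye(4), atol=1e-12)


def _registration_phantom(seed=0):
    cfg = tiny_config(
        grid_shape=(32, 32, 32),
        brain_radii_mm=(9.0, 10.0, 9.0),
        ventricle_centers_mm=((-3.5, 1.5, 2.5), (2.5, -3.0, -0.5)),
        parenchyma_sd=4.0,
        noise_smoothness_mm=3.0,
    )
    return generate_control_volume(cfg, np.random.default_rng(seed))


def test_register_identity():
    v = _registration_phantom()
    est = register_affine(v, v)
    assert np.abs(est.translation).max() < 0.5  # < 0.5 voxel at 1 mm
    assert np.abs(est.scale - 1.0).max() < 0.01


def test_register_recovers_known_translation():
    v = _registration_phantom(1)
    true = AffineTransform(translation=[5.0, -3.0, 2.0])
    template = resample(v, true, v)
    est = register_affine(v, template)
    assert np.abs(est.translation - true.translation).max() < 1.0


def test_register_rejects_flat_images():
    flat = _vol(np.full((16, 16, 16), 3.0))
    with pytest.raises(ValueError):
        register_affine(flat, flat)
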