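import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from ctvlsm.vlsm import (
    extract_clusters,
    fdr_threshold,
    fit_voxel_model,
    permutation_null_fdp,
    run_vlsm,
    voxel_inclusion_mask,
)
from ctvlsm.volume import Volume


def _vol(data, voxel=1.0, origin=None):
    aff = np.eye(4)
    aff[:3, :3] *= voxel
    if origin is not None:
        aff[:3, 3] = origin
    return Volume(np.asarray(data, float), aff)


def bh_oracle(p, q):
    """Brute-force Benjamini-Hochberg step-up (independent reference)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    thresh = (np.arange(1, m + 1) * q) / m
    below = np.nonzero(ps <= thresh)[0]
    reject = np.zeros(m, bool)
    if len(below):
        reject[order[: below[-1] + 1]] = True
    q_sorted = ps * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_adj = np.empty(m)
    q_adj[order] = np.minimum(q_sorted, 1.0)
    return reject, q_adj


# ---- voxel inclusion -------------------------------------------------


def _lesion_stack(n, shape=(6, 6, 6)):
    rng = np.random.default_rng(0)
    return [_vol((rng.random(shape) > 0.5).astype(float)) for _ in range(n)]


def test_inclusion_mask_union_and_empty():
    lesions = _lesion_stack(5)
    union, counts = voxel_inclusion_mask(lesions, min_count=1)
    manual = np.any([l.data > 0 for l in lesions], axis=0)
    np.testing.assert_array_equal(union.data.astype(bool), manual)
    empty, _ = voxel_inclusion_mask(lesions, min_count=6)
    assert not empty.data.any()
    with pytest.raises(ValueError):
        voxel_inclusion_mask([], 1)


def test_inclusion_threshold_at_ten_patients():
    shape = (4, 4, 4)
    lesions = [_vol(np.zeros(shape)) for _ in range(12)]
    for l in lesions:
        l.data[2, 2, 2] = 1  # all 12 share one voxel
    mask, counts = voxel_inclusion_mask(lesions, min_count=10)
    assert mask.data[2, 2, 2] == 1
    assert mask.data.sum() == 1
    assert counts.data[2, 2, 2] == 12


# ---- per-voxel model -------------------------------------------------


def test_fit_matches_two_sample_t_without_covariates():
    rng = np.random.default_rng(1)
    lesion = np.repeat([0, 1], 10)
    y = rng.normal(10, 2, 20) - 3 * lesion
    beta, t, p = fit_voxel_model(y, lesion)
    t_ref, p_ref = stats.ttest_ind(y[lesion == 1], y[lesion == 0], equal_var=True)
    assert beta == pytest.approx(y[lesion == 1].mean() - y[lesion == 0].mean(), abs=1e-12)
    assert t == pytest.approx(t_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)


def test_fit_exact_group_separation_is_infinite_t():
    y = np.array([10.0, 10, 10, 10, 2, 2, 2, 2])
    lesion = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    beta, t, p = fit_voxel_model(y, lesion)
    assert beta == pytest.approx(-8.0)
    # residual variance is zero up to floating-point noise
    assert t < -1e6
    assert p < 1e-12


def test_fit_identical_groups_is_null():
    y = np.array([1.0, 2, 3, 1, 2, 3])
    lesion = np.array([0, 0, 0, 1, 1, 1])
    beta, t, _ = fit_voxel_model(y, lesion)
    assert beta == pytest.approx(0.0, abs=1e-12)
    assert t == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_statsmodels_with_covariates():
    rng = np.random.default_rng(2)
    n = 40
    lesion = (rng.random(n) > 0.5).astype(float)
    covs = rng.normal(size=(n, 2))
    y = 5 - 2 * lesion + covs @ [0.5, -1.0] + rng.normal(0, 1, n)
    beta, t, p = fit_voxel_model(y, lesion, covs)
    X = sm.add_constant(np.column_stack([lesion, covs]))
    fit = sm.OLS(y, X).fit()
    assert beta == pytest.approx(fit.params[1], abs=1e-10)
    assert t == pytest.approx(fit.tvalues[1], abs=1e-10)
    assert p == pytest.approx(fit.pvalues[1], abs=1e-10)


def test_orthogonal_covariate_leaves_beta_unchanged():
    rng = np.random.default_rng(3)
    n = 30
    lesion = np.repeat([0.0, 1.0], n // 2)
    y = rng.normal(0, 1, n)
    beta0, _, _ = fit_voxel_model(y, lesion)
    cov = rng.normal(size=n)
    # orthogonalize against both intercept and lesion columns
    X = np.column_stack([np.ones(n), lesion])
    cov = cov - X @ np.linalg.lstsq(X, cov, rcond=None)[0]
    beta1, _, _ = fit_voxel_model(y, lesion, cov)
    assert beta1 == pytest.approx(beta0, abs=1e-10)


def test_fit_rejects_degenerate_designs():
    y = np.arange(6.0)
    with pytest.raises(ValueError):
        fit_voxel_model(y, np.ones(6))  # constant lesion column
    with pytest.raises(ValueError):
        lesion = np.array([0, 0, 0, 1.0, 1, 1])
        fit_voxel_model(y, lesion, covariates=lesion)  # collinear covariate


# ---- FDR -------------------------------------------------------------


def test_bh_hand_examples():
    reject, q_adj, cutoff = fdr_threshold([0.01, 0.02, 0.03, 0.04], q=0.05)
    assert reject.all()
    assert cutoff == pytest.approx(0.04)
    reject, _, cutoff = fdr_threshold(np.ones(10), q=0.05)
    assert not reject.any() and cutoff == 0.0
    reject, _, _ = fdr_threshold([0.04], q=0.05)
    assert reject.all()
    flags, q_adj, _ = fdr_threshold(np.zeros(0), q=0.05)
    assert flags.size == 0 and q_adj.size == 0


def test_bh_matches_bruteforce_on_random_vectors():
    from test_vlsm import bh_oracle  # explicit: same module oracle

    rng = np.random.default_rng(4)
    for _ in range(50):
        m = rng.integers(1, 40)
        p = np.round(rng.random(m), 3)
        reject, q_adj, _ = fdr_threshold(p, q=0.05)
        o_reject, o_q = bh_oracle(p, 0.05)
        np.testing.assert_array_equal(reject, o_reject)
        np.testing.assert_allclose(q_adj, o_q, atol=1e-12)
        assert np.all(q_adj >= p - 1e-15)  # adjusted q >= raw p


def test_bh_rejects_invalid_input():
    with pytest.raises(ValueError):
        fdr_threshold([0.5, 1.5], q=0.05)
    with pytest.raises(ValueError):
        fdr_threshold([0.5], q=1.5)


# ---- clusters --------------------------------------------------------


def test_single_voxel_cluster_world_coordinates():
    shape = (32, 32, 32)
    sig = np.zeros(shape)
    sig[10, 10, 10] = 1
    t = np.zeros(shape)
    t[10, 10, 10] = 5.0
    table = extract_clusters(
        _vol(sig, origin=(-32, -32, -32)), _vol(t, origin=(-32, -32, -32))
    )
    assert len(table) == 1
    row = table.iloc[0]
    assert (row["x_mm"], row["y_mm"], row["z_mm"]) == (-22.0, -22.0, -22.0)
    assert row["peak_t"] == 5.0
    assert row["volume_mm3"] == 1.0


def test_two_blobs_sorted_by_volume():
    shape = (20, 20, 20)
    sig = np.zeros(shape)
    sig[2:6, 2:6, 2:6] = 1  # 64 voxels
    sig[12:14, 12:14, 12:14] = 1  # 8 voxels
    t = np.where(sig > 0, 4.0, 0.0)
    t[3, 3, 3] = 6.0
    table = extract_clusters(_vol(sig), _vol(t))
    assert list(table["n_voxels"]) == [64, 8]
    assert table.iloc[0]["peak_t"] == 6.0
    assert list(table["cluster_id"]) == [1, 2]


def test_empty_mask_empty_table():
    table = extract_clusters(_vol(np.zeros((5, 5, 5))), _vol(np.zeros((5, 5, 5))))
    assert len(table) == 0
    assert "peak_t" in table.columns


# ---- run_vlsm --------------------------------------------------------


def _toy_vlsm_inputs(n=20, seed=0):
    rng = np.random.default_rng(seed)
    shape = (8, 8, 8)
    lesions = []
    status = []
    for _ in range(n):
        les = np.zeros(shape)
        hit = rng.random() > 0.5
        if hit:
            # variable extent so total lesion volume is not collinear
            # with lesion status at the shared voxels
            ext = int(rng.integers(3, 6))
            les[2:ext + 2, 2:5, 2:5] = 1
        # private voxel so no lesion map is empty
        les[7, 7, int(rng.integers(0, 8))] = 1
        lesions.append(_vol(les))
        status.append(hit)
    status = np.array(status, float)
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age_years": rng.normal(70, 10, n),
            "handedness": rng.choice(["R", "L"], n),
            "orientation_score": rng.normal(12, 2, n),
            "gesture_production": np.clip(10 - 5 * status + rng.normal(0, 1, n), 0, 12),
        }
    )
    return lesions, table


def test_run_vlsm_recovers_toy_effect_and_is_deterministic():
    lesions, table = _toy_vlsm_inputs()
    res = run_vlsm(lesions, table, "gesture_production", min_count=5, q=0.05)
    assert res.metadata["n_significant"] > 0
    assert len(res.clusters) >= 1
    # q >= p voxelwise on tested voxels
    tested = ~np.isnan(res.p.data)
    assert np.all(res.q.data[tested] >= res.p.data[tested] - 1e-12)
    # cluster volumes sum to total significant volume
    assert res.clusters["volume_mm3"].sum() == pytest.approx(
        res.sig_mask.data.sum() * res.sig_mask.voxel_volume_mm3
    )
    again = run_vlsm(lesions, table, "gesture_production", min_count=5, q=0.05)
    assert res.clusters.to_csv() == again.clusters.to_csv()


def test_run_vlsm_empty_when_min_count_exceeds_n():
    lesions, table = _toy_vlsm_inputs()
    res = run_vlsm(lesions, table, "gesture_production", min_count=len(table) + 1)
    assert not res.tested_mask.data.any()
    assert len(res.clusters) == 0
    assert res.metadata["n_tested"] == 0


def test_run_vlsm_unknown_task_lists_available():
    lesions, table = _toy_vlsm_inputs()
    with pytest.raises(ValueError, match="gesture_production"):
        run_vlsm(lesions, table, "no_such_task", min_count=5)


def test_permutation_null_fdp_shape_and_range():
    lesions, table = _toy_vlsm_inputs()
    fdps = permutation_null_fdp(
        lesions, table, "gesture_production",
        covariates=("age_years", "handedness", "orientation_score"),
        min_count=5, n_perm=20, seed=1,
    )
    assert fdps.shape == (20,)
    assert np.all((fdps >= 0) & (fdps <= 1))
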