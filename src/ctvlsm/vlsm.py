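"""Mass-univariate voxel-based lesion-symptom mapping (VLSM).

At every voxel lesioned in at least ``min_count`` patients, an ordinary
least-squares model relates the continuous behavioral score to lesion
status (0/1) plus covariates of no interest (age, handedness, total
lesion volume, orientation score).  The per-voxel p values are
corrected with Benjamini-Hochberg FDR over exactly the tested voxels,
and significant voxels are grouped into 26-connected clusters reported
with volume, peak t, and peak world (template-space) coordinates.

Sign convention: the stored t map is oriented for the *deficit*
direction (positive t = lesion lowers the score), matching the
convention that all scores are "higher = better"; a two-sided option
is exposed.

The per-voxel fits are vectorized by Frisch-Waugh residualization:
score and each voxel's lesion column are residualized against the
covariates once, reducing every voxel to a simple regression whose
coefficient, t and p equal the full OLS fit's exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .delineate import lesion_volume
from .volume import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COVARIATES",
    "VlsmResult",
    "voxel_inclusion_mask",
    "fit_voxel_model",
    "fdr_threshold",
    "extract_clusters",
    "run_vlsm",
    "permutation_null_fdp",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)

DEFAULT_COVARIATES = ("age_years", "handedness", "lesion_volume_mm3", "orientation_score")

CLUSTER_COLUMNS = ["cluster_id", "n_voxels", "volume_mm3", "peak_t", "x_mm", "y_mm", "z_mm"]


# ---- voxel inclusion -------------------------------------------------


def voxel_inclusion_mask(lesions, min_count: int = 10) -> tuple[Volume, Volume]:
    """Mask of voxels lesioned in >= ``min_count`` patients, plus the count map."""
    lesions = list(lesions)
    if not lesions:
        raise ValueError("empty patient list")
    ref = lesions[0]
    for l in lesions[1:]:
        if not l.same_grid(ref):
            raise ValueError("lesion maps are on different grids")
    counts = np.zeros(ref.shape, dtype=np.int32)
    for l in lesions:
        counts += (np.asarray(l.data) > 0).astype(np.int32)
    mask = (counts >= min_count).astype(np.uint8)
    return ref.with_data(mask), ref.with_data(counts)


# ---- per-voxel model -------------------------------------------------


def fit_voxel_model(score, lesion_status, covariates=None) -> tuple[float, float, float]:
    """OLS of score on [intercept, lesion, covariates] at a single voxel.

    Returns the lesion coefficient, its t statistic (sign of the raw
    coefficient: negative = lesion lowers the score) and the two-sided
    p value.  With no covariates this is algebraically identical to a
    pooled two-sample t-test between lesioned and intact patients.
    """
    y = np.asarray(score, dtype=float)
    l = np.asarray(lesion_status, dtype=float)
    n = len(y)
    if len(l) != n:
        raise ValueError("score and lesion_status lengths differ")
    if np.ptp(l) == 0:
        raise ValueError("constant lesion column: model not identifiable")
    cols = [np.ones(n), l]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariate matrix shape mismatch")
        cols.extend(C.T)
    X = np.column_stack(cols)
    p_cols = X.shape[1]
    if n <= p_cols:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p_cols:
        raise ValueError("rank-deficient design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p_cols
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0:
        # zero residual variance: the group difference is exact
        t = 0.0 if beta[1] == 0 else float(np.copysign(np.inf, beta[1]))
    else:
        t = float(beta[1] / se)
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(beta[1]), t, p


def _residualizer(X: np.ndarray):
    """Return a function projecting vectors/matrices off the column space of X."""
    Q, _ = np.linalg.qr(X)

    def project_out(Z):
        return Z - Q @ (Q.T @ Z)

    return project_out


def _fit_lesion_columns(y: np.ndarray, L: np.ndarray, X_cov: np.ndarray):
    """Vectorized OLS lesion-coefficient stats across voxels.

    ``y``: (n,) scores; ``L``: (n, V) lesion indicators; ``X_cov``:
    (n, c) nuisance design including the intercept.  Returns
    (beta, t, df, valid) where ``valid`` marks voxels whose lesion
    column is not collinear with the covariates.
    """
    n, V = L.shape
    project_out = _residualizer(X_cov)
    ytil = project_out(y)
    Ltil = project_out(L)
    denom = np.einsum("ij,ij->j", Ltil, Ltil)
    valid = denom > 1e-8
    df = n - X_cov.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough patients for the requested model")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Ltil.T @ ytil) / denom
        rss = float(ytil @ ytil) - beta**2 * denom
        sigma2 = np.clip(rss, 0.0, None) / df
        t = beta / np.sqrt(sigma2 / denom)
    beta[~valid] = np.nan
    t[~valid] = np.nan
    return beta, t, df, valid


# ---- FDR -------------------------------------------------------------


def fdr_threshold(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up over the tested voxels.

    Returns (significance flags, adjusted q values, p cutoff) where the
    cutoff is the largest p(i) <= i*q/m (0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    cutoff = float(p[reject].max()) if reject.any() else 0.0
    return reject, q_adj, cutoff


# ---- clusters --------------------------------------------------------


def extract_clusters(sig_mask: Volume, t_map: Volume) -> pd.DataFrame:
    """26-connected clusters of significant voxels with peak statistics.

    Peak = highest |t| voxel (first in lexicographic voxel order on
    ties); coordinates are world mm via the affine.  Rows sorted by
    volume descending with a deterministic lexicographic tie-break.
    """
    if not sig_mask.same_grid(t_map):
        raise ValueError("significance mask and t map are on different grids")
    sig = np.asarray(sig_mask.data) > 0
    if not sig.any():
        return pd.DataFrame(columns=CLUSTER_COLUMNS)
    labels, n = ndimage.label(sig, structure=_CONN26)
    abs_t = np.abs(np.nan_to_num(np.asarray(t_map.data, float), nan=-np.inf))
    abs_t[~sig] = -np.inf
    voxvol = sig_mask.voxel_volume_mm3
    rows = []
    peaks = ndimage.maximum_position(abs_t, labels, index=range(1, n + 1))
    for lab, peak in zip(range(1, n + 1), peaks):
        size = int((labels == lab).sum())
        world = t_map.voxel_to_world(peak)
        rows.append(
            {
                "n_voxels": size,
                "volume_mm3": size * voxvol,
                "peak_t": float(t_map.data[peak]),
                "x_mm": float(world[0]),
                "y_mm": float(world[1]),
                "z_mm": float(world[2]),
                "_peak_idx": tuple(int(i) for i in peak),
            }
        )
    rows.sort(key=lambda r: (-r["volume_mm3"], r["_peak_idx"]))
    for i, r in enumerate(rows):
        r["cluster_id"] = i + 1
        del r["_peak_idx"]
    return pd.DataFrame(rows, columns=CLUSTER_COLUMNS)


# ---- orchestration ---------------------------------------------------


@dataclass
class VlsmResult:
    """Maps, tested-voxel bookkeeping and the cluster table for one task."""

    task: str
    beta: Volume
    t: Volume  # deficit-direction t (positive = lesion lowers score)
    p: Volume
    q: Volume
    tested_mask: Volume
    count_map: Volume
    sig_mask: Volume
    clusters: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _covariate_matrix(table: pd.DataFrame, covariates, lesions) -> np.ndarray:
    n = len(table)
    cols = [np.ones(n)]
    for name in covariates:
        if name == "handedness":
            vals = table["handedness"].map({"R": 0.0, "L": 1.0})
            if vals.isna().any():
                raise ValueError("handedness must be coded 'R' or 'L'")
            cols.append(vals.to_numpy(dtype=float))
        elif name == "lesion_volume_mm3" and name not in table.columns:
            cols.append(np.array([lesion_volume(l) for l in lesions]))
        else:
            if name not in table.columns:
                raise ValueError(f"covariate {name!r} not in behavior table")
            cols.append(table[name].to_numpy(dtype=float))
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        raise ValueError("covariates contain missing/non-finite values")
    return X


def run_vlsm(
    lesions,
    table: pd.DataFrame,
    task: str,
    covariates=DEFAULT_COVARIATES,
    min_count: int = 10,
    q: float = 0.05,
    sided: str = "one",
    min_patients: int = 10,
) -> VlsmResult:
    """Full VLSM for one task: inclusion mask -> voxel fits -> FDR -> clusters."""
    lesions = list(lesions)
    n = len(table)
    if n != len(lesions):
        raise ValueError("behavior table and lesion list lengths differ")
    if n < min_patients:
        raise ValueError(f"need at least {min_patients} patients, got {n}")
    if task not in table.columns:
        numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
        raise ValueError(f"task {task!r} not in behavior table; available: {numeric}")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")

    mask, counts = voxel_inclusion_mask(lesions, min_count)
    tested_idx = np.flatnonzero(mask.data.ravel() > 0)
    shape = mask.shape
    y = table[task].to_numpy(dtype=float)
    X_cov = _covariate_matrix(table, covariates, lesions)

    nan_map = np.full(np.prod(shape), np.nan)
    result_maps = {k: nan_map.copy() for k in ("beta", "t", "p", "q")}
    sig_flat = np.zeros(np.prod(shape), dtype=np.uint8)
    df = None
    n_valid = n_sig = 0

    if tested_idx.size:
        L = np.stack(
            [(np.asarray(l.data) > 0).ravel()[tested_idx] for l in lesions]
        ).astype(float)
        beta, t_ols, df, valid = _fit_lesion_columns(y, L, X_cov)
        n_valid = int(valid.sum())
        if n_valid < tested_idx.size:
            logger.info(
                "%s: %d of %d tested voxels skipped (lesion column collinear with covariates)",
                task,
                tested_idx.size - n_valid,
                tested_idx.size,
            )
        t_def = -t_ols  # positive = lesion lowers score
        with np.errstate(invalid="ignore"):
            if sided == "one":
                p = stats.t.sf(t_def, df)
            else:
                p = 2.0 * stats.t.sf(np.abs(t_def), df)
        vidx = tested_idx[valid]
        reject, q_adj, _ = fdr_threshold(p[valid], q)
        n_sig = int(reject.sum())
        result_maps["beta"][vidx] = beta[valid]
        result_maps["t"][vidx] = t_def[valid]
        result_maps["p"][vidx] = p[valid]
        result_maps["q"][vidx] = q_adj
        sig_flat[vidx[reject]] = 1

    t_vol = mask.with_data(result_maps["t"].reshape(shape))
    sig_vol = mask.with_data(sig_flat.reshape(shape))
    clusters = extract_clusters(sig_vol, t_vol)
    meta = {
        "task": task,
        "n_patients": n,
        "covariates": list(covariates),
        "min_count": min_count,
        "q": q,
        "sided": sided,
        "df": df,
        "n_tested": int(tested_idx.size),
        "n_valid": n_valid,
        "n_significant": n_sig,
    }
    logger.info("VLSM %s: %d tested, %d valid, %d significant voxels", task, tested_idx.size, n_valid, n_sig)
    return VlsmResult(
        task=task,
        beta=mask.with_data(result_maps["beta"].reshape(shape)),
        t=t_vol,
        p=mask.with_data(result_maps["p"].reshape(shape)),
        q=mask.with_data(result_maps["q"].reshape(shape)),
        tested_mask=mask,
        count_map=counts,
        sig_mask=sig_vol,
        clusters=clusters,
        metadata=meta,
    )


# ---- permutation null ------------------------------------------------


def permutation_null_fdp(
    lesions,
    table: pd.DataFrame,
    task: str,
    covariates=DEFAULT_COVARIATES,
    min_count: int = 10,
    q: float = 0.05,
    sided: str = "one",
    n_perm: int = 200,
    seed: int = 0,
    chunk: int = 50,
) -> np.ndarray:
    """False-discovery proportion per seeded score permutation.

    Scores are permuted across patients (covariates and lesions fixed),
    destroying any lesion-behavior association, so every rejection is a
    false discovery: FDP = 1 if any voxel is significant, else 0.
    Returns the FDP of each replicate.
    """
    lesions = list(lesions)
    rng = np.random.default_rng(seed)
    mask, _ = voxel_inclusion_mask(lesions, min_count)
    tested_idx = np.flatnonzero(mask.data.ravel() > 0)
    if tested_idx.size == 0:
        return np.zeros(n_perm)
    y = table[task].to_numpy(dtype=float)
    X_cov = _covariate_matrix(table, covariates, lesions)
    L = np.stack([(np.asarray(l.data) > 0).ravel()[tested_idx] for l in lesions]).astype(float)

    n = len(y)
    project_out = _residualizer(X_cov)
    Ltil = project_out(L)
    denom = np.einsum("ij,ij->j", Ltil, Ltil)
    valid = denom > 1e-8
    Ltil = Ltil[:, valid]
    denom = denom[valid]
    df = n - X_cov.shape[1] - 1

    fdps = np.zeros(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(y) for _ in range(b)], axis=1)  # (n, b)
        Ytil = project_out(perms)
        num = Ltil.T @ Ytil  # (V, b)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = num / denom[:, None]
            yss = np.einsum("ij,ij->j", Ytil, Ytil)  # (b,)
            rss = np.clip(yss[None, :] - beta**2 * denom[:, None], 0.0, None)
            t = beta / np.sqrt(rss / df / denom[:, None])
        t_def = -t
        if sided == "one":
            p = stats.t.sf(t_def, df)
        else:
            p = 2.0 * stats.t.sf(np.abs(t_def), df)
        for j in range(b):
            reject, _, _ = fdr_threshold(p[:, j], q)
            fdps[done + j] = 1.0 if reject.any() else 0.0
        done += b
    return fdps
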