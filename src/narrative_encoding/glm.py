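"""Two-stage mass-univariate inference.

First level: per-participant, per-voxel ordinary least squares on the
assembled design (after per-run grand-mean scaling to 100). Second level:
one-sample t-tests across participants on each interest beta, Cohen's d
(mean over sample SD, n-1 denominator), Benjamini-Hochberg FDR flags at a
stated q, cross-modal conjunction (significant with the same sign in both
maps, displayed as the average t), and scalar map-comparison statistics
(spatial Pearson r, point-biserial r against a binary mask, overlap
fraction).
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import ConjunctionMap, DesignMatrix, FirstLevelResult, GroupStatMap, VoxelDataset
from .errors import (
    EstimationError,
    InsufficientDataError,
    InvalidParameterError,
    MalformedInputError,
    ShapeMismatchError,
    UndefinedStatisticError,
)

__all__ = [
    "grand_mean_scale",
    "fit_first_level",
    "group_onesample",
    "fdr_bh",
    "conjunction_map",
    "map_similarity",
]


def grand_mean_scale(data: VoxelDataset, target: float = 100.0) -> VoxelDataset:
    """Rescale each run to a grand mean of ``target`` over all volumes and voxels."""
    scaled = data.data.astype(float).copy()
    for r in data.runs():
        mask = data.run_id == r
        gm = scaled[:, mask].mean()
        if gm <= 0:
            raise InvalidParameterError(f"nonpositive grand mean in run {r!r}")
        scaled[:, mask] *= target / gm
    return VoxelDataset(
        data=scaled,
        tr=data.tr,
        run_id=data.run_id,
        shape3d=data.shape3d,
        affine=data.affine,
        voxel_index=data.voxel_index,
    )


def _name_collinear(matrix: np.ndarray, names: list) -> list:
    """Identify columns involved in a rank deficiency via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    bad = piv[diag <= tol] if (diag <= tol).any() else piv[np.argsort(diag)[:1]]
    return [names[i] for i in np.atleast_1d(bad)]


def fit_first_level(
    data: VoxelDataset, design: DesignMatrix, participant_id: object = None
) -> FirstLevelResult:
    """Per-voxel OLS of the BOLD matrix on the full design."""
    x = design.matrix
    if x.shape[0] != data.n_timepoints:
        raise ShapeMismatchError(
            f"design rows ({x.shape[0]}) != data timepoints ({data.n_timepoints})"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        culprits = _name_collinear(x, design.names)
        raise EstimationError(f"rank-deficient design; offending columns: {culprits}")
    betas, ss, _, _ = np.linalg.lstsq(x, data.data.T, rcond=None)
    resid = data.data.T - x @ betas
    dof = x.shape[0] - x.shape[1]
    resid_var = (resid**2).sum(axis=0) / dof
    return FirstLevelResult(
        participant_id=participant_id,
        betas=betas,
        names=list(design.names),
        roles=list(design.roles),
        resid_var=resid_var,
        dof=dof,
    )


def group_onesample(betas: np.ndarray, q: float | None = None) -> GroupStatMap:
    """One-sample t-test across participants at every voxel.

    ``betas`` is participants x voxels. t = mean / (SD / sqrt(n)) with the
    sample SD (n-1); two-sided p from the t distribution with n-1 df;
    Cohen's d = mean / SD. Zero-variance voxels are flagged as undefined.
    When ``q`` is given, BH-FDR flags at that rate are attached.
    """
    betas = np.asarray(betas, float)
    if betas.ndim != 2 or betas.shape[0] < 3:
        raise InsufficientDataError("need >= 3 participants (rows)")
    n = betas.shape[0]
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    undefined = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        d = mean / sd
    t[undefined] = np.nan
    d[undefined] = np.nan
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    sig = fdr_bh(p, q) if q is not None else np.zeros(t.size, dtype=bool)
    return GroupStatMap(
        beta_mean=mean, t=t, p=p, d=d, df=n - 1, sig=sig, q=q, undefined=undefined
    )


def fdr_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags.

    Flags all p <= p_(k) where k = max{i : p_(i) <= i * q / m}; equal
    p-values share a flag. NaN entries are excluded from m and never
    flagged.
    """
    p = np.asarray(p, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise InvalidParameterError("p-values must lie in [0, 1]")
    flags = np.zeros(p.shape, dtype=bool)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return flags
    order = np.argsort(pf, kind="stable")
    passed = pf[order] <= (np.arange(1, m + 1) * q / m)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        flags[finite] = pf <= pf[order][k]
    return flags


def conjunction_map(map_a: GroupStatMap, map_b: GroupStatMap) -> ConjunctionMap:
    """Voxels significant in both maps with the same t sign.

    The display value at flagged voxels is the mean of the two t
    statistics; unflagged voxels carry NaN.
    """
    if map_a.t.size != map_b.t.size:
        raise ShapeMismatchError("maps are on different voxel grids")
    sig = map_a.sig & map_b.sig & (np.sign(map_a.t) == np.sign(map_b.t))
    value = np.full(map_a.t.size, np.nan)
    value[sig] = (map_a.t[sig] + map_b.t[sig]) / 2.0
    return ConjunctionMap(sig=sig, value=value)


def map_similarity(map_values: np.ndarray, reference: np.ndarray, mode: str = "pearson") -> float:
    """Scalar comparison between a voxel map and a reference map or mask.

    ``pearson``: spatial correlation between two continuous maps.
    ``point_biserial``: Pearson r between a continuous map and a 0/1 mask.
    ``overlap_fraction``: fraction of flagged voxels lying inside the mask.
    """
    a = np.asarray(map_values, float)
    b = np.asarray(reference, float)
    if a.size != b.size:
        raise ShapeMismatchError("map and reference differ in voxel count")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if mode == "pearson":
        if a.std() == 0 or b.std() == 0:
            raise UndefinedStatisticError("spatial correlation undefined for constant map")
        return float(np.corrcoef(a, b)[0, 1])
    if mode == "point_biserial":
        if not np.isin(b, (0.0, 1.0)).all():
            raise MalformedInputError("point-biserial reference must be binary")
        if a.std() == 0 or b.std() == 0:
            raise UndefinedStatisticError("point-biserial undefined for constant input")
        return float(np.corrcoef(a, b)[0, 1])
    if mode == "overlap_fraction":
        flagged = a.astype(bool)
        if not flagged.any():
            raise UndefinedStatisticError("no flagged voxels; overlap undefined")
        return float(np.mean(b.astype(bool)[flagged]))
    raise InvalidParameterError(f"unknown mode {mode!r}")
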