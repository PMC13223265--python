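"""First-level GLM design construction.

Interest regressors are the group-median rating time courses mapped from
[0, 100] to [-1, 1], convolved with the canonical double-gamma HRF at the
behavioral grid resolution (230 ms) and decimated to the scanner TR.
Nuisance structure follows the standard fMRI denoising recipe: a
discrete-cosine high-pass basis (1/128 Hz), the 24-parameter motion
expansion, a CSF mean-signal regressor, per-volume outlier indicators
(|z| > 3 on the run's global signal or framewise displacement), indicator
columns for volumes without a valid group rating, per-run intercepts, and
the first six volumes of every run discarded.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .containers import AnnotationSet, DesignMatrix, GroupTimecourse, HRFKernel, NuisanceBundle
from .errors import (
    EstimationError,
    InvalidParameterError,
    MalformedInputError,
    ShapeMismatchError,
)

__all__ = [
    "canonical_hrf",
    "build_interest_regressor",
    "build_tom_demand_regressors",
    "dct_basis",
    "build_nuisance",
    "assemble_design",
    "compute_vif",
]

HRF_LENGTH_S = 32.0


def canonical_hrf(
    step: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    length_s: float = HRF_LENGTH_S,
) -> HRFKernel:
    """Canonical double-gamma hemodynamic response, peak-normalized.

    Difference of two gamma densities with peak delay 6 s, undershoot delay
    16 s, unit dispersions and a peak:undershoot ratio of 1/6 (the community
    default); the analytic mode sits at (6 - 1) s = 5 s.
    """
    if not (0 < step <= 1.0):
        raise InvalidParameterError("step must be in (0, 1] seconds")
    t = np.arange(int(round(length_s / step)) + 1) * step
    peak = stats.gamma.pdf(t, a=peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, a=undershoot_delay / undershoot_disp, scale=undershoot_disp)
    values = peak - ratio * under
    values = values / values.max()
    return HRFKernel(
        step=step,
        values=values,
        parameters={
            "peak_delay_s": peak_delay,
            "undershoot_delay_s": undershoot_delay,
            "peak_dispersion": peak_disp,
            "undershoot_dispersion": undershoot_disp,
            "ratio": ratio,
            "length_s": length_s,
        },
    )


def _decim_factor(tr: float, step: float) -> int:
    k = tr / step
    if abs(k - round(k)) > 1e-6:
        raise ShapeMismatchError(f"TR ({tr}s) is not an integer multiple of the grid step ({step}s)")
    return int(round(k))


def rating_to_regressor_scale(values: np.ndarray) -> np.ndarray:
    """Affine map of the rating scale [0, 100] onto [-1, 1]: v/50 - 1."""
    return np.asarray(values, float) / 50.0 - 1.0


def build_interest_regressor(
    course: GroupTimecourse,
    hrf: HRFKernel,
    tr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """HRF-convolved interest regressor at TR resolution.

    Returns ``(regressor, missing_volumes)``. The group median is mapped by
    v/50 - 1; grid points with ``valid_flag`` False (or an undefined median)
    are zero-filled before convolution and reported as missing volumes:
    every volume whose acquisition window covers an invalid grid point.
    Convolution runs at the behavioral grid resolution, then the series is
    decimated to one sample per TR aligned to volume onsets.
    """
    step = course.grid_step
    if step is None:
        raise InvalidParameterError("course must carry its grid step")
    if abs(step - hrf.step) > 1e-9:
        raise ShapeMismatchError("HRF kernel step must match the course grid step")
    k = _decim_factor(tr, step)
    mapped = rating_to_regressor_scale(course.median)
    invalid = ~course.valid_flag | ~np.isfinite(mapped)
    mapped[invalid] = 0.0
    conv = np.convolve(mapped, hrf.values)[: mapped.size]
    regressor = conv[::k]
    n_vol = regressor.size
    win_invalid = np.add.reduceat(
        invalid.astype(int), np.arange(0, invalid.size, k)
    )[:n_vol]
    missing_volumes = np.flatnonzero(win_invalid > 0)
    return regressor, missing_volumes


def build_tom_demand_regressors(
    consensus: AnnotationSet,
    timing: Sequence[tuple],
    hrf: HRFKernel,
    tr: float,
    n_volumes: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Demand / no-demand boxcar pair convolved with the HRF.

    ``timing`` holds one (onset_s, duration_s) per sentence part, on the
    same clock as the volumes; parts must not overlap. The two boxcars are
    mutually exclusive and jointly cover narrative time. Returns
    ``(demand, no_demand, contrast)`` with contrast (+1, -1); the contrast
    applied to the two betas is their difference.
    """
    if len(timing) != consensus.consensus.size:
        raise ShapeMismatchError("timing entries must match the number of sentence parts")
    step = hrf.step
    k = _decim_factor(tr, step)
    n_grid = n_volumes * k
    demand = np.zeros(n_grid)
    nodemand = np.zeros(n_grid)
    occupied = np.zeros(n_grid, dtype=bool)
    for label, (onset, duration) in zip(consensus.consensus, timing):
        i0 = int(round(onset / step))
        i1 = int(round((onset + duration) / step))
        i1 = min(i1, n_grid)
        if i0 >= i1:
            continue
        if occupied[i0:i1].any():
            raise MalformedInputError("overlapping sentence parts in timing")
        occupied[i0:i1] = True
        (demand if label == 1 else nodemand)[i0:i1] = 1.0
    if not demand.any() or not nodemand.any():
        warnings.warn("degenerate annotation boxcar: one class never occurs", stacklevel=2)
    d = np.convolve(demand, hrf.values)[:n_grid][::k]
    nd = np.convolve(nodemand, hrf.values)[:n_grid][::k]
    return d, nd, np.array([1.0, -1.0])


def dct_basis(n_volumes: int, tr: float, cutoff: float = 1.0 / 128.0) -> np.ndarray:
    """Discrete-cosine high-pass basis (constant term excluded).

    K = floor(2 * n * TR * cutoff) columns; the k-th column is
    cos(pi * k * (2t + 1) / (2n)). Every retained column has period
    >= 1/cutoff seconds. Returns an (n_volumes, K) array; K may be 0 for
    short runs (a warning is emitted).
    """
    if n_volumes < 8:
        raise InvalidParameterError("n_volumes must be >= 8")
    if cutoff <= 0:
        raise InvalidParameterError("cutoff must be positive")
    k_max = int(np.floor(2.0 * n_volumes * tr * cutoff))
    if k_max == 0:
        warnings.warn("run too short for the requested high-pass cutoff; empty DCT basis",
                      stacklevel=2)
        return np.empty((n_volumes, 0))
    t = np.arange(n_volumes)
    ks = np.arange(1, k_max + 1)
    return np.cos(np.pi * np.outer(2 * t + 1, ks) / (2.0 * n_volumes))


def build_nuisance(bundle: NuisanceBundle, z_thresh: float = 3.0) -> dict:
    """Expand confound series into regressor blocks, one entry per run.

    Motion is expanded to 24 columns (6 parameters, backward-difference
    derivatives with a leading zero, and the squares of both). Outlier
    volumes are flagged where |z| of the run's global signal or framewise
    displacement exceeds ``z_thresh`` (strict inequality; z uses the run
    mean/SD computed once), yielding one unit-indicator column each.
    """
    if z_thresh <= 0:
        raise InvalidParameterError("z_thresh must be positive")
    bundle.validate()
    out = {"motion24": [], "csf": [], "outlier_volumes": []}
    for r in range(bundle.n_runs()):
        m = np.asarray(bundle.motion[r], float)
        dm = np.vstack([np.zeros((1, 6)), np.diff(m, axis=0)])
        out["motion24"].append(np.hstack([m, dm, m**2, dm**2]))
        out["csf"].append(np.asarray(bundle.csf[r], float))

        flagged = np.zeros(m.shape[0], dtype=bool)
        for series in (bundle.global_signal[r], bundle.fd[r]):
            s = np.asarray(series, float)
            sd = s.std()
            if sd > 0:
                flagged |= np.abs((s - s.mean()) / sd) > z_thresh
        out["outlier_volumes"].append(np.flatnonzero(flagged))
    return out


def assemble_design(
    run_lengths: Sequence[int],
    tr: float,
    interest: dict,
    rating_period: Optional[Sequence[np.ndarray]] = None,
    tom_demand: Optional[dict] = None,
    missing_volumes: Optional[dict] = None,
    nuisance: Optional[dict] = None,
    dct: Optional[Sequence[np.ndarray]] = None,
    n_discard: int = 6,
) -> DesignMatrix:
    """Concatenate per-run components into one labeled design matrix.

    The first ``n_discard`` volumes of every run are dropped from all
    components before assembly. Interest, rating-period, demand-pair and
    missing-volume columns are global (a single beta across runs); DCT,
    motion, CSF, outlier and intercept columns live in per-run blocks that
    are exactly zero outside their run.

    ``interest``/``tom_demand`` map column name -> list of per-run arrays;
    ``missing_volumes`` maps column-group name -> list of per-run volume
    index arrays (pre-discard indices); ``nuisance`` is the output of
    :func:`build_nuisance`.
    """
    run_lengths = [int(n) for n in run_lengths]
    n_runs = len(run_lengths)
    if n_runs == 0:
        raise InvalidParameterError("need at least one run")
    if any(n <= n_discard for n in run_lengths):
        raise InvalidParameterError("every run must be longer than the discard count")
    kept = [n - n_discard for n in run_lengths]
    total = int(np.sum(kept))
    run_id = np.repeat(np.arange(n_runs), kept)

    def _global_column(per_run: Sequence[np.ndarray]) -> np.ndarray:
        if len(per_run) != n_runs:
            raise ShapeMismatchError("per-run component count != number of runs")
        pieces = []
        for r, arr in enumerate(per_run):
            arr = np.asarray(arr, float)
            if arr.shape[0] != run_lengths[r]:
                raise ShapeMismatchError(f"component length != run length in run {r}")
            pieces.append(arr[n_discard:])
        return np.concatenate(pieces)

    names: list = []
    roles: list = []
    cols: list = []

    def _add(name: str, role: str, col: np.ndarray) -> None:
        if name in names:
            raise MalformedInputError(f"duplicate column label {name!r}")
        if not np.any(col != 0):
            raise EstimationError(f"all-zero design column {name!r}")
        names.append(name)
        roles.append(role)
        cols.append(col)

    for name, per_run in interest.items():
        _add(name, "interest", _global_column(per_run))
    if tom_demand:
        for name, per_run in tom_demand.items():
            _add(name, "tom_demand_pair", _global_column(per_run))
    if rating_period is not None:
        _add("rating_period", "rating_period", _global_column(rating_period))
    if missing_volumes:
        for group, per_run in missing_volumes.items():
            if len(per_run) != n_runs:
                raise ShapeMismatchError("missing-volume lists must cover every run")
            offsets = np.concatenate([[0], np.cumsum(kept)[:-1]])
            for r, vols in enumerate(per_run):
                for v in np.asarray(vols, int):
                    if v < n_discard:
                        continue  # the volume is already discarded
                    col = np.zeros(total)
                    col[offsets[r] + v - n_discard] = 1.0
                    _add(f"missing_{group}_run{r}_vol{v}", "missing_indicator", col)

    def _block(role: str, name: str, r: int, arr: np.ndarray) -> None:
        arr = np.atleast_2d(np.asarray(arr, float).T).T
        if arr.shape[0] != run_lengths[r]:
            raise ShapeMismatchError(f"{role} length != run length in run {r}")
        trimmed = arr[n_discard:]
        for j in range(trimmed.shape[1]):
            col = np.zeros(total)
            col[run_id == r] = trimmed[:, j]
            if not np.any(col != 0):
                continue  # e.g. an outlier indicator inside the discarded head
            _add(f"{name}{j}_run{r}" if trimmed.shape[1] > 1 else f"{name}_run{r}", role, col)

    if dct is not None:
        for r, basis in enumerate(dct):
            if basis.size:
                _block("dct", "dct", r, basis)
    if nuisance is not None:
        for r, m24 in enumerate(nuisance["motion24"]):
            _block("motion24", "motion", r, m24)
        for r, csf in enumerate(nuisance["csf"]):
            _block("csf", "csf", r, csf[:, None])
        for r, vols in enumerate(nuisance["outlier_volumes"]):
            for v in np.asarray(vols, int):
                if v < n_discard:
                    continue
                col = np.zeros(total)
                offsets = np.concatenate([[0], np.cumsum(kept)[:-1]])
                col[offsets[r] + v - n_discard] = 1.0
                _add(f"outlier_run{r}_vol{v}", "outlier", col)
    for r in range(n_runs):
        col = (run_id == r).astype(float)
        _add(f"intercept_run{r}", "intercept", col)

    matrix = np.column_stack(cols)
    return DesignMatrix(matrix=matrix, names=names, roles=roles, run_id=run_id, tr=tr)


def compute_vif(design: DesignMatrix, labels: Sequence[str]) -> dict:
    """Variance inflation factors for a subset of design columns.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the other selected
    columns plus an intercept. Rank deficiency among the selected columns
    raises rather than returning infinities silently.
    """
    labels = list(labels)
    for name in labels:
        if name not in design.names:
            raise InvalidParameterError(f"no design column named {name!r}")
    sub = design.subset(labels)
    out = {}
    for j, name in enumerate(labels):
        others = np.delete(sub, j, axis=1)
        x = np.column_stack([np.ones(sub.shape[0]), others])
        y = sub[:, j]
        beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            raise EstimationError(f"column {name!r} is constant; VIF undefined")
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if r2 > 1.0 - 1e-10:
            raise EstimationError(f"column {name!r} is collinear with the others (infinite VIF)")
        out[name] = float(1.0 / (1.0 - r2))
    return out
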