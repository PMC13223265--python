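"""Mask construction and ROI-level effect-size statistics.

Masks come from thresholded meta-analytic z maps (z >= 3), unions of
parcellation labels, or group stat maps. Within each mask: per-participant
mean betas, group Cohen's d with Bonferroni-corrected one-sample tests,
paired participant-bootstrap comparison of two effect sizes (two-sided p
as twice the proportion of bootstrap differences at zero or of opposite
sign, floored at 2/n_boot), and Fisher-z spatial pattern similarity against
a meta-analytic map with paired t-tests.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FirstLevelResult, MaskSet
from .errors import (
    DegenerateMaskError,
    InsufficientDataError,
    InvalidParameterError,
    ShapeMismatchError,
    UndefinedStatisticError,
)

__all__ = [
    "threshold_meta_map",
    "label_parcels",
    "roi_effect_sizes",
    "bootstrap_effect_diff",
    "pattern_similarity_test",
    "cohens_d",
]


def cohens_d(values: np.ndarray) -> float:
    """Group effect size vs zero: mean / sample SD (n-1 denominator)."""
    values = np.asarray(values, float)
    sd = values.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("Cohen's d undefined for zero variance")
    return float(values.mean() / sd)


def threshold_meta_map(zmap: np.ndarray, z_min: float = 3.0) -> np.ndarray:
    """Binary mask of voxels with z >= z_min (boundary inclusive)."""
    zmap = np.asarray(zmap, float)
    mask = zmap >= z_min
    if not mask.any():
        raise DegenerateMaskError(f"no voxel reaches z >= {z_min}")
    return mask


def label_parcels(
    sig_map: np.ndarray, parcellation: np.ndarray, min_fraction: float = 0.25
) -> pd.DataFrame:
    """Parcels whose significant-voxel fraction exceeds ``min_fraction``.

    The inequality is strict (25/100 exactly is not flagged). Parcel label
    0 denotes background; empty parcels are skipped with a warning.
    Returns a frame with parcel, size, n_sig, fraction, flagged.
    """
    sig = np.asarray(sig_map).astype(bool)
    parc = np.asarray(parcellation).astype(int)
    if sig.size != parc.size:
        raise ShapeMismatchError("parcellation does not cover the significance map")
    rows = []
    for pid in np.unique(parc):
        if pid == 0:
            continue
        in_parcel = parc == pid
        size = int(in_parcel.sum())
        if size == 0:
            warnings.warn(f"empty parcel {pid}; skipped", stacklevel=2)
            continue
        n_sig = int(sig[in_parcel].sum())
        frac = n_sig / size
        rows.append(
            {
                "parcel": int(pid),
                "size": size,
                "n_sig": n_sig,
                "fraction": frac,
                "flagged": frac > min_fraction,
            }
        )
    return pd.DataFrame(rows, columns=["parcel", "size", "n_sig", "fraction", "flagged"])


def roi_effect_sizes(
    first_levels: Sequence[FirstLevelResult],
    masks: MaskSet,
    conditions: Sequence[str],
    family_size: Optional[int] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group effect sizes of mean betas inside each mask.

    For every participant, condition beta maps are averaged over mask
    voxels; across participants a one-sample t-test, Cohen's d and a 95%
    CI of the mean are computed. ``family_size`` sets the Bonferroni
    correction recorded alongside the raw p (defaults to masks x
    conditions).
    """
    if len(first_levels) < 3:
        raise InsufficientDataError("need >= 3 participants")
    n_vox = first_levels[0].betas.shape[1]
    masks.validate(n_voxels=n_vox)
    if family_size is None:
        family_size = len(masks.masks) * len(conditions)
    rows = []
    for mask_name, mask in masks.masks.items():
        for cond in conditions:
            means = np.array([fl.beta(cond)[mask].mean() for fl in first_levels])
            n = means.size
            sd = means.std(ddof=1)
            se = sd / np.sqrt(n)
            tval = means.mean() / se if se > 0 else np.nan
            p = 2.0 * stats.t.sf(abs(tval), df=n - 1) if np.isfinite(tval) else np.nan
            tcrit = stats.t.ppf(0.975, df=n - 1)
            rows.append(
                {
                    "mask": mask_name,
                    "condition": cond,
                    "n": n,
                    "mean_beta": means.mean(),
                    "d": means.mean() / sd if sd > 0 else np.nan,
                    "t": tval,
                    "p": p,
                    "ci_low": means.mean() - tcrit * se,
                    "ci_high": means.mean() + tcrit * se,
                    "family_size": family_size,
                    "sig_bonferroni": bool(np.isfinite(p) and p < alpha / family_size),
                }
            )
    return pd.DataFrame(rows)


def participant_mask_means(
    first_levels: Sequence[FirstLevelResult], mask: np.ndarray, condition: str
) -> np.ndarray:
    """Per-participant mean beta inside a mask, one value per participant."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise DegenerateMaskError("empty mask")
    return np.array([fl.beta(condition)[mask].mean() for fl in first_levels])


def bootstrap_effect_diff(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Paired participant bootstrap for a difference of two Cohen's d.

    Participants (the exchangeable unit) are resampled with replacement;
    both effect sizes are recomputed per sample. The two-sided p is twice
    the proportion of bootstrap differences that are zero or of the
    opposite sign to the observed difference, clamped to [2/n_boot, 1] —
    the smallest reportable nonzero p with 10,000 resamples is 2e-4.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size != b.size:
        raise ShapeMismatchError("paired samples must have equal length")
    n = a.size
    if n < 5:
        raise InsufficientDataError("need >= 5 paired observations")
    obs = cohens_d(a) - cohens_d(b)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab, bb = a[idx], b[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        d_a = ab.mean(axis=1) / ab.std(axis=1, ddof=1)
        d_b = bb.mean(axis=1) / bb.std(axis=1, ddof=1)
    diffs = d_a - d_b
    if obs == 0:
        p = 1.0
    else:
        exceed = (diffs == 0) | (np.sign(diffs) != np.sign(obs))
        p = float(np.clip(2.0 * np.mean(exceed), 2.0 / n_boot, 1.0))
    lo, hi = np.nanpercentile(diffs, [2.5, 97.5])
    return {
        "diff": float(obs),
        "p": p,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_boot": n_boot,
        "seed": seed,
    }


def _fisher_z(r: np.ndarray) -> np.ndarray:
    clipped = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    if np.any(np.abs(r) >= 1.0 - 1e-12):
        warnings.warn("|r| at or above 1 - 1e-12 clipped before Fisher z", stacklevel=2)
    return np.arctanh(clipped)


def pattern_similarity_test(
    betas_a: np.ndarray,
    betas_b: np.ndarray,
    meta: np.ndarray,
    family_size: int = 1,
    alpha: float = 0.05,
) -> dict:
    """Fisher-z pattern similarity of two conditions against a reference map.

    ``betas_a``/``betas_b`` are participants x voxels (within one mask);
    ``meta`` is the within-mask reference vector. Per participant and
    condition the Pearson correlation with the reference is transformed to
    Fisher z; the paired t-test (df n-1) compares the two z sets.
    Identical z sets are flagged as no-difference rather than producing an
    undefined t.
    """
    a = np.asarray(betas_a, float)
    b = np.asarray(betas_b, float)
    meta = np.asarray(meta, float)
    if a.shape != b.shape or a.shape[1] != meta.size:
        raise ShapeMismatchError("betas_a, betas_b and meta must share the voxel set")
    if meta.size < 10:
        raise InsufficientDataError("need >= 10 voxels in the mask")
    if a.shape[0] < 3:
        raise InsufficientDataError("need >= 3 participants")
    if meta.std() == 0:
        raise UndefinedStatisticError("constant reference vector")

    def _corrs(mat: np.ndarray) -> np.ndarray:
        out = np.empty(mat.shape[0])
        mc = meta - meta.mean()
        for i, row in enumerate(mat):
            if row.std() == 0:
                raise UndefinedStatisticError(f"constant beta vector for participant {i}")
            rc = row - row.mean()
            out[i] = (rc @ mc) / (np.linalg.norm(rc) * np.linalg.norm(mc))
        return out

    z_a = _fisher_z(_corrs(a))
    z_b = _fisher_z(_corrs(b))
    dz = z_a - z_b
    n = dz.size
    if np.allclose(dz, 0.0):
        return {
            "z_a": z_a,
            "z_b": z_b,
            "t": np.nan,
            "p": 1.0,
            "df": n - 1,
            "no_difference": True,
            "family_size": family_size,
            "sig_bonferroni": False,
        }
    tval, p = stats.ttest_rel(z_a, z_b)
    return {
        "z_a": z_a,
        "z_b": z_b,
        "t": float(tval),
        "p": float(p),
        "df": n - 1,
        "no_difference": False,
        "family_size": family_size,
        "sig_bonferroni": bool(p < alpha / family_size),
    }
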