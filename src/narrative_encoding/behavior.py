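"""Behavioral rating preprocessing, reliability, and surrogate testing.

Continuous visual-analog ratings (0-100) from many online raters are
cleaned (attention checks, constant raters, leave-one-out similarity),
masked before each rater's first mouse move, resampled to a uniform grid
(230 ms by default), and summarized as group medians with raw-MAD error
bands. Reliability is quantified by Spearman-Brown-corrected split-half
correlations over random half-splits and by pairwise inter-rater
correlations. Binary sentence-part annotations are combined into consensus
labels with Fleiss' kappa, and rating-annotation correspondence is tested
against a phase-randomization surrogate null that preserves the amplitude
spectrum exactly.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

from .containers import AnnotationSet, GroupTimecourse, RatingPanel, ReliabilityReport
from .errors import (
    EmptyCohortError,
    InsufficientDataError,
    InvalidParameterError,
    MalformedInputError,
    UndefinedStatisticError,
)

__all__ = [
    "apply_exclusions",
    "preprocess_ratings",
    "group_timecourse",
    "rating_similarity",
    "consensus_annotations",
    "phase_randomization_corr",
    "spearman_brown",
    "phase_randomize",
]


def spearman_brown(r: float) -> float:
    """Split-half correlation corrected to full-cohort length: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def _pairwise_valid_corr(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def apply_exclusions(
    panel: RatingPanel,
    question: str,
    loo_threshold: float,
    max_failed_checks: int = 2,
) -> tuple[RatingPanel, pd.DataFrame]:
    """Remove unusable raters and log the rule that fired for each.

    Three rules, applied in order: (1) attention — more than
    ``max_failed_checks`` failed checks (more than half of the four checks);
    (2) constant — the same rating at every non-missing sample; (3)
    loo_similarity — correlation with the leave-one-out median time course
    below ``loo_threshold`` (0.3 for the social question, 0.2 for the
    theory-of-mind question in the reference analysis).
    """
    sub = panel.ratings[panel.ratings["question"] == question]
    if sub.empty:
        raise EmptyCohortError(f"no ratings for question {question!r}")
    participants = list(sub["participant"].unique())
    log = []

    excluded = set()
    if panel.attention is not None:
        failed = (
            panel.attention[~panel.attention["passed"].astype(bool)]
            .groupby("participant")
            .size()
        )
        for pid in participants:
            if failed.get(pid, 0) > max_failed_checks:
                excluded.add(pid)
                log.append({"participant": pid, "reason": "attention"})

    for pid in participants:
        if pid in excluded:
            continue
        vals = sub.loc[sub["participant"] == pid, "value"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if vals.size and np.all(vals == vals[0]):
            excluded.add(pid)
            log.append({"participant": pid, "reason": "constant"})

    survivors = [p for p in participants if p not in excluded]
    if len(survivors) >= 2:
        wide = RatingPanel(ratings=sub[sub["participant"].isin(survivors)]).to_wide(question)
        mat = wide.to_numpy(float)  # time x participant
        cols = list(wide.columns)
        for j, pid in enumerate(cols):
            others = np.delete(mat, j, axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN leading samples
                loo_median = np.nanmedian(others, axis=1)
            r = _pairwise_valid_corr(mat[:, j], loo_median)
            if np.isfinite(r) and r < loo_threshold:
                excluded.add(pid)
                log.append({"participant": pid, "reason": "loo_similarity", "loo_r": r})

    kept = [p for p in participants if p not in excluded]
    if not kept:
        raise EmptyCohortError("all participants excluded")
    keep_mask = ~panel.ratings["participant"].isin(excluded) | (
        panel.ratings["question"] != question
    )
    filtered = RatingPanel(
        ratings=panel.ratings[keep_mask].reset_index(drop=True),
        attention=panel.attention,
        first_move=panel.first_move,
        trials=panel.trials,
        grid_step=panel.grid_step,
    )
    log_df = pd.DataFrame(log, columns=["participant", "reason", "loo_r"])
    return filtered, log_df


def preprocess_ratings(panel: RatingPanel, grid_step: float = 0.23) -> RatingPanel:
    """Mask pre-first-move samples and resample to a uniform grid.

    Per participant and trial: samples before the participant's first mouse
    move are set missing; the remaining samples are linearly interpolated
    onto a grid 0, step, ..., floor(T/step)*step within the trial window
    (raw recordings extend ~1.5 s past the trial end and support
    interpolation at the boundary). Grid points outside the valid raw range
    stay missing; no extrapolation.
    """
    if grid_step <= 0:
        raise InvalidParameterError("grid_step must be positive")
    fm = {}
    if panel.first_move is not None:
        fm = {
            (row.participant, row.trial): row.first_move_s
            for row in panel.first_move.itertuples()
        }
    durations = {}
    if panel.trials is not None:
        durations = dict(zip(panel.trials["trial"], panel.trials["duration_s"]))

    out = []
    for (pid, q, tid), grp in panel.ratings.groupby(
        ["participant", "question", "trial"], sort=True
    ):
        t_raw = grp["time_s"].to_numpy(float)
        v_raw = grp["value"].to_numpy(float)
        if np.any(np.diff(t_raw) <= 0):
            raise MalformedInputError(f"non-monotone timestamps for {pid}/{tid}")
        duration = durations.get(tid, t_raw[-1])
        first_move = fm.get((pid, tid), 0.0)
        valid = np.isfinite(v_raw) & (t_raw >= first_move)
        n_grid = int(np.floor(duration / grid_step + 1e-9)) + 1
        t_grid = np.arange(n_grid) * grid_step
        v_grid = np.full(n_grid, np.nan)
        if valid.any():
            tv, vv = t_raw[valid], v_raw[valid]
            inside = (t_grid >= tv[0]) & (t_grid <= tv[-1]) & (t_grid >= first_move)
            v_grid[inside] = np.interp(t_grid[inside], tv, vv)
        out.append(
            pd.DataFrame(
                {
                    "participant": pid,
                    "question": q,
                    "trial": tid,
                    "time_s": t_grid,
                    "value": v_grid,
                }
            )
        )
    return RatingPanel(
        ratings=pd.concat(out, ignore_index=True),
        attention=panel.attention,
        first_move=panel.first_move,
        trials=panel.trials,
        grid_step=grid_step,
    ).validate()


def group_timecourse(
    panel: RatingPanel,
    question: Optional[str] = None,
    min_trial_coverage: float = 0.4,
    min_timepoint_coverage: float = 0.5,
) -> GroupTimecourse:
    """Group median/MAD/valid-count summary on the common grid.

    Per trial, participants with less than ``min_trial_coverage`` of
    non-missing samples are dropped. Per timepoint the median (mean of the
    two central values for even counts), the raw MAD (no 1.4826 factor),
    and the count of non-missing raters are computed; the timepoint is
    marked invalid where fewer than ``min_timepoint_coverage`` of the
    retained participants have a value.
    """
    ratings = panel.ratings
    if question is not None:
        ratings = ratings[ratings["question"] == question]
    if ratings.empty:
        raise EmptyCohortError("no ratings to summarize")

    time_s, med, mad, n_valid, flags, trial_ids = [], [], [], [], [], []
    for tid in sorted(ratings["trial"].unique()):
        wide = RatingPanel(ratings=ratings[ratings["trial"] == tid]).to_wide(
            ratings["question"].iloc[0], trial=tid
        )
        mat = wide.to_numpy(float)
        coverage = np.isfinite(mat).mean(axis=0)
        keep = coverage >= min_trial_coverage
        if not keep.any():
            raise EmptyCohortError(f"no participant meets trial coverage in {tid}")
        mat = mat[:, keep]
        total = mat.shape[1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN leading samples
            m = np.nanmedian(mat, axis=1)
            a = np.nanmedian(np.abs(mat - m[:, None]), axis=1)
        nv = np.isfinite(mat).sum(axis=1)
        m[nv == 0] = np.nan
        a[nv == 0] = np.nan
        time_s.append(wide.index.to_numpy(float))
        med.append(m)
        mad.append(a)
        n_valid.append(nv)
        flags.append(nv / total >= min_timepoint_coverage)
        trial_ids.append(np.full(m.size, tid, dtype=object))

    nv_all = np.concatenate(n_valid)
    if (nv_all == 0).all():
        raise EmptyCohortError("no valid participants at any timepoint")
    return GroupTimecourse(
        time_s=np.concatenate(time_s),
        median=np.concatenate(med),
        mad=np.concatenate(mad),
        n_valid=nv_all,
        valid_flag=np.concatenate(flags),
        trial_id=np.concatenate(trial_ids),
        grid_step=panel.grid_step,
    )


def rating_similarity(
    panel: RatingPanel,
    question: Optional[str] = None,
    n_permutations: int = 2000,
    seed: int = 0,
) -> ReliabilityReport:
    """Split-half reliability and pairwise inter-rater similarity.

    For each permutation, participants are randomly split into two equal
    halves (odd cohorts drop one participant at random), the Pearson
    correlation between the two half-mean time courses is corrected by
    Spearman-Brown. Timepoints with any missing value are removed listwise
    before all correlations.
    """
    ratings = panel.ratings
    if question is not None:
        ratings = ratings[ratings["question"] == question]
    if ratings.empty:
        raise EmptyCohortError("no ratings")
    wide = RatingPanel(ratings=ratings).to_wide(ratings["question"].iloc[0])
    mat = wide.to_numpy(float).T  # participant x time
    n_p = mat.shape[0]
    if n_p < 4:
        raise InsufficientDataError("need >= 4 participants for split-half reliability")
    complete = np.isfinite(mat).all(axis=0)
    mat = mat[:, complete]
    if mat.shape[1] < 3:
        raise InsufficientDataError("too few listwise-complete timepoints")

    rng = np.random.default_rng(seed)
    half = n_p // 2
    corrected = np.empty(n_permutations)
    for i in range(n_permutations):
        order = rng.permutation(n_p)
        a = mat[order[:half]].mean(axis=0)
        b = mat[order[half : 2 * half]].mean(axis=0)
        r = np.corrcoef(a, b)[0, 1]
        corrected[i] = np.clip(spearman_brown(r), -1.0, 1.0)

    pair_r = np.corrcoef(mat)[np.triu_indices(n_p, k=1)]
    pair_r = pair_r[np.isfinite(pair_r)]
    p_med = float(np.median(pair_r))
    p_mad = float(np.median(np.abs(pair_r - p_med)))
    return ReliabilityReport(
        corrected=corrected,
        pairwise_median=p_med,
        pairwise_mad=p_mad,
        n_permutations=n_permutations,
        seed=seed,
    )


def consensus_annotations(
    labels: np.ndarray, resolution: Optional[np.ndarray] = None
) -> AnnotationSet:
    """Majority-vote consensus over binary rater labels, with Fleiss' kappa.

    Unanimous and majority (e.g. 3-1) parts take the majority label; exact
    ties are marked unresolved (-1) unless ``resolution`` supplies a label
    (mirroring tie resolution by discussion).
    """
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[1] < 2:
        raise MalformedInputError("labels must be n_parts x n_raters with >= 2 raters")
    if not np.isin(labels, (0, 1)).all():
        raise MalformedInputError("labels must be binary (0/1)")
    n_parts, n_raters = labels.shape
    votes = labels.sum(axis=1)
    consensus = np.where(votes * 2 > n_raters, 1, np.where(votes * 2 < n_raters, 0, -1))
    ties = consensus == -1
    if resolution is not None:
        resolution = np.asarray(resolution)
        if resolution.size != n_parts:
            raise MalformedInputError("resolution length must equal n_parts")
        consensus = np.where(ties, resolution, consensus)

    counts, _ = aggregate_raters(labels, n_cat=2)
    # degenerate case: a single category used everywhere -> perfect agreement
    if (counts[:, 0] == n_raters).all() or (counts[:, 1] == n_raters).all():
        kappa = 1.0
    else:
        kappa = float(fleiss_kappa(counts))
    return AnnotationSet(
        labels=labels, consensus=consensus, kappa=kappa, part_id=np.arange(n_parts)
    )


def phase_randomize(y: np.ndarray, rng: np.random.Generator, n_surrogates: int) -> np.ndarray:
    """Surrogate series with the amplitude spectrum of ``y`` and random phases.

    DC and (for even length) Nyquist Fourier components are left untouched,
    so the mean and power spectrum are preserved exactly.
    """
    n = y.size
    spec = np.fft.rfft(y)
    n_bins = spec.size
    free = np.arange(1, n_bins - 1 if n % 2 == 0 else n_bins)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n_surrogates, free.size))
    sur_spec = np.tile(spec, (n_surrogates, 1))
    sur_spec[:, free] = np.abs(spec[free]) * np.exp(1j * phases)
    return np.fft.irfft(sur_spec, n=n, axis=1)


def phase_randomization_corr(
    x: np.ndarray,
    y: np.ndarray,
    n_surrogates: int = 10000,
    seed: int = 0,
) -> dict:
    """Pearson correlation with a phase-randomization surrogate null.

    ``y`` (the annotation/second series) is phase-randomized; the two-sided
    p-value is the proportion of surrogates whose |r| reaches |r_obs|,
    floored at 1/n_surrogates; the null CI is the 2.5/97.5 percentile of
    the surrogate correlations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise MalformedInputError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 32:
        raise InsufficientDataError("need >= 32 valid timepoints")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for constant series")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    surrogates = phase_randomize(y, rng, n_surrogates)
    xc = x - x.mean()
    sc = surrogates - surrogates.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(xc) * np.linalg.norm(sc, axis=1)
    r_null = (sc @ xc) / denom
    p = max(float(np.mean(np.abs(r_null) >= abs(r_obs))), 1.0 / n_surrogates)
    lo, hi = np.percentile(r_null, [2.5, 97.5])
    return {
        "r": r_obs,
        "p": p,
        "null_ci": (float(lo), float(hi)),
        "n_surrogates": n_surrogates,
        "n_timepoints": int(x.size),
    }
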