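"""Ground-truth simulators for ratings, annotations, and BOLD voxel data.

The generator emulates the structure of a two-question naturalistic rating
study: two latent group time courses (perceived social interaction and
theory-of-mind engagement) with a controlled correlation near 0.32, noisy
raters whose traces start missing until their first mouse move, binary
sentence-part annotations from a small rater panel, and voxel time series
belonging to known response classes (both / social_only / tom_only / null)
with AR(1) noise, slow drift, motion- and CSF-coupled artifacts, and
injected outlier volumes.

All randomness flows through one ``numpy.random.Generator`` per call;
identical (parameters, seed) pairs give bit-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d

from .containers import (
    DesignMatrix,
    NuisanceBundle,
    RatingPanel,
    SyntheticTruth,
    VoxelDataset,
)
from .errors import InvalidParameterError, MalformedInputError, ShapeMismatchError

__all__ = [
    "make_latent_pair",
    "simulate_raters",
    "simulate_annotations",
    "make_truth",
    "simulate_bold",
    "simulate_cohort",
    "SimulatedBold",
]

#: default behavioral grid step (half of the scanner TR), seconds
DEFAULT_GRID_STEP = 0.23
#: default latent correlation-time, in grid samples (~2.3 s)
DEFAULT_SMOOTHNESS = 10.0

CLASS_ORDER = ("both", "social_only", "tom_only", "null")


def _smooth_standard_series(rng: np.random.Generator, length: int, smoothness: float) -> np.ndarray:
    """Temporally smooth Gaussian series, empirically standardized."""
    pad = int(np.ceil(4 * smoothness))
    z = rng.standard_normal(length + 2 * pad)
    z = gaussian_filter1d(z, sigma=smoothness, mode="reflect")[pad : pad + length]
    z = z - z.mean()
    sd = z.std()
    if sd == 0:
        raise InvalidParameterError("degenerate latent (zero variance); increase length")
    return z / sd


def make_latent_pair(
    target_r: float,
    length: int,
    smoothness: float = DEFAULT_SMOOTHNESS,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two bounded, temporally smooth latent time courses with correlation
    close to ``target_r``.

    Smoothed Gaussian processes are built first; the second is orthogonalized
    against the first and recombined so the pre-squash sample correlation is
    exact. Each series is then pushed through the probit squash
    ``x = 100 * Phi(z)``, which maps to (0, 100). The squash attenuates the
    Gaussian correlation rho to (6/pi) * arcsin(rho / 2), so the pre-squash
    correlation is set to the inverse, ``2 sin(pi * target_r / 6)``, leaving
    the post-squash correlation centered on ``target_r``.
    """
    if not np.isfinite(target_r) or abs(target_r) >= 1:
        raise InvalidParameterError("|target_r| must be < 1")
    if length < 100:
        raise InvalidParameterError("length must be >= 100")
    if smoothness <= 0:
        raise InvalidParameterError("smoothness must be positive")
    rng = np.random.default_rng(seed)
    z1 = _smooth_standard_series(rng, length, smoothness)
    z2 = _smooth_standard_series(rng, length, smoothness)
    # exact empirical orthogonalization, then recombination at the target
    z2 = z2 - (z2 @ z1) / (z1 @ z1) * z1
    z2 = (z2 - z2.mean()) / z2.std()
    rho_pre = 2.0 * np.sin(np.pi * target_r / 6.0)
    w = rho_pre * z1 + np.sqrt(1.0 - rho_pre**2) * z2
    x = 100.0 * stats.norm.cdf(z1)
    y = 100.0 * stats.norm.cdf(w)
    return x, y


def _draw_delays(
    rng: np.random.Generator, n: int, model: Optional[dict], grid_step: float
) -> np.ndarray:
    """First-move delays in seconds, one per (rater, trial)."""
    if model is None or model.get("kind", "none") == "none":
        return np.zeros(n)
    kind = model["kind"]
    if kind == "fixed":
        return np.full(n, float(model["delay_s"]))
    if kind == "uniform":
        return rng.uniform(model["low_s"], model["high_s"], size=n)
    if kind == "exponential":
        return rng.exponential(model["mean_s"], size=n)
    raise InvalidParameterError(f"unknown delay model kind: {kind!r}")


def simulate_raters(
    latent: Union[np.ndarray, Sequence[np.ndarray]],
    n_raters: int,
    noise_sd: float,
    first_move_delay_model: Optional[dict] = None,
    seed: int = 0,
    grid_step: float = DEFAULT_GRID_STEP,
    noise_smoothness: float = DEFAULT_SMOOTHNESS,
    question: str = "social",
    attention_fail_prob: float = 0.0,
    n_checks: int = 4,
) -> RatingPanel:
    """Noisy raters tracking a latent time course, with leading missingness.

    Each rater's trace is ``clip(latent + smooth noise, 0, 100)``; samples
    before the rater's first mouse move (drawn from the delay model, per
    trial) are missing. The noise is temporally smoothed to mimic
    mouse-tracking inertia, then rescaled to ``noise_sd``.
    """
    if n_raters < 2:
        raise InvalidParameterError("n_raters must be >= 2")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if len(latent) == 0:
        raise MalformedInputError("empty latent time course")
    trials = [np.asarray(latent)] if np.ndim(latent[0]) == 0 else [np.asarray(t) for t in latent]
    if any(t.size == 0 for t in trials):
        raise MalformedInputError("empty latent time course")

    rng = np.random.default_rng(seed)
    rows = []
    fm_rows = []
    for p in range(n_raters):
        pid = f"sub-{p:03d}"
        delays = _draw_delays(rng, len(trials), first_move_delay_model, grid_step)
        for k, lat in enumerate(trials):
            tid = f"trial-{k:02d}"
            t = np.arange(lat.size) * grid_step
            if noise_sd > 0:
                noise = _smooth_standard_series(rng, lat.size, noise_smoothness) * noise_sd
            else:
                noise = np.zeros(lat.size)
            vals = np.clip(lat + noise, 0.0, 100.0)
            vals = vals.astype(float)
            vals[t < delays[k]] = np.nan
            rows.append(
                pd.DataFrame(
                    {
                        "participant": pid,
                        "question": question,
                        "trial": tid,
                        "time_s": t,
                        "value": vals,
                    }
                )
            )
            fm_rows.append({"participant": pid, "trial": tid, "first_move_s": delays[k]})
    ratings = pd.concat(rows, ignore_index=True)
    fails = rng.random((n_raters, n_checks)) < attention_fail_prob
    attention = pd.DataFrame(
        {
            "participant": np.repeat([f"sub-{p:03d}" for p in range(n_raters)], n_checks),
            "run": np.tile(np.arange(n_checks), n_raters),
            "passed": ~fails.ravel(),
        }
    )
    trials_df = pd.DataFrame(
        {
            "trial": [f"trial-{k:02d}" for k in range(len(trials))],
            "duration_s": [(t.size - 1) * grid_step for t in trials],
        }
    )
    return RatingPanel(
        ratings=ratings,
        attention=attention,
        first_move=pd.DataFrame(fm_rows),
        trials=trials_df,
        grid_step=grid_step,
    ).validate()


def simulate_annotations(
    n_parts: int,
    n_raters: int,
    true_labels: np.ndarray,
    flip_prob: float,
    seed: int = 0,
) -> np.ndarray:
    """Rater label matrix: ``true_labels`` with independent flips.

    Returns an ``n_parts x n_raters`` binary array.
    """
    if n_parts < 1:
        raise MalformedInputError("n_parts must be >= 1")
    if not (0.0 <= flip_prob < 0.5):
        raise InvalidParameterError("flip_prob must be in [0, 0.5)")
    true_labels = np.asarray(true_labels).astype(int)
    if true_labels.size != n_parts or not np.isin(true_labels, (0, 1)).all():
        raise MalformedInputError("true_labels must be binary with length n_parts")
    rng = np.random.default_rng(seed)
    flips = rng.random((n_parts, n_raters)) < flip_prob
    return np.where(flips, 1 - true_labels[:, None], true_labels[:, None])


def make_truth(
    latent_social: np.ndarray,
    latent_tom: np.ndarray,
    n_voxels_per_class: int,
    beta_social: float = 1.0,
    beta_tom: float = 1.0,
    rater_noise_sd: float = 15.0,
    ar1_phi: float = 0.4,
    seed: int = 0,
) -> SyntheticTruth:
    """Assemble a :class:`SyntheticTruth` with balanced voxel classes.

    Voxels are laid out in class blocks (both, social_only, tom_only, null);
    amplitudes are exact (zero where a class has no effect).
    """
    if n_voxels_per_class < 1:
        raise InvalidParameterError("n_voxels_per_class must be >= 1")
    classes = np.repeat(CLASS_ORDER, n_voxels_per_class)
    b_soc = np.where(np.isin(classes, ("both", "social_only")), float(beta_social), 0.0)
    b_tom = np.where(np.isin(classes, ("both", "tom_only")), float(beta_tom), 0.0)
    latent_social = np.asarray(latent_social, float)
    latent_tom = np.asarray(latent_tom, float)
    r = float(np.corrcoef(latent_social, latent_tom)[0, 1])
    return SyntheticTruth(
        latent_social=latent_social,
        latent_tom=latent_tom,
        latent_correlation=r,
        rater_noise_sd=rater_noise_sd,
        ar1_phi=ar1_phi,
        seed=seed,
        voxel_class=classes,
        true_beta_social=b_soc,
        true_beta_tom=b_tom,
    ).validate()


@dataclass
class SimulatedBold:
    """Output bundle of :func:`simulate_bold`."""

    dataset: VoxelDataset
    nuisance: NuisanceBundle
    truth_table: pd.DataFrame
    spike_volumes: np.ndarray  # global indices of injected outlier volumes


def _ar1(rng: np.random.Generator, shape: tuple, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    e = rng.standard_normal(shape) * sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    if phi == 0.0:
        return e
    return signal.lfilter([1.0], [1.0, -phi], e, axis=-1)


def _dct_columns(n: int, k_max: int) -> np.ndarray:
    t = np.arange(n)
    ks = np.arange(1, k_max + 1)
    return np.cos(np.pi * np.outer(2 * t + 1, ks) / (2.0 * n))


def simulate_bold(
    design: DesignMatrix,
    truth: SyntheticTruth,
    noise_sd: float,
    outlier_rate: float = 0.0,
    seed: int = 0,
    participant_betas: Optional[dict] = None,
    baseline: float = 100.0,
    spike_sd: float = 8.0,
    drift_sd_factor: float = 2.0,
    artifact_sd_factor: float = 0.3,
) -> SimulatedBold:
    """Voxel time series driven by the design's interest columns.

    ``y_v = baseline + X_social * b_social,v + X_tom * b_tom,v + drift
    + motion/CSF artifacts + AR(1) noise + spikes``.

    Drift is drawn inside the span of each run's discrete-cosine high-pass
    basis; motion/CSF artifacts couple generated confound traces into every
    voxel with random weights; spikes are global-signal excursions of
    ``spike_sd`` noise units with matching framewise-displacement bumps.
    All non-signal amplitudes scale with ``noise_sd``, so a noiseless call
    yields data that an OLS fit recovers exactly.

    ``participant_betas`` optionally overrides the per-voxel amplitudes
    (keys ``social`` and ``tom``), e.g. to add between-participant
    variation around the group truth.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if not (0.0 <= outlier_rate < 1.0):
        raise InvalidParameterError("outlier_rate must be in [0, 1)")
    if truth.voxel_class is None:
        raise InvalidParameterError("truth must carry per-voxel classes (see make_truth)")
    n_t = design.n_rows
    rng = np.random.default_rng(seed)

    b_soc = np.asarray(
        participant_betas["social"] if participant_betas else truth.true_beta_social, float
    )
    b_tom = np.asarray(
        participant_betas["tom"] if participant_betas else truth.true_beta_tom, float
    )
    if b_soc.size != b_tom.size:
        raise ShapeMismatchError("social/tom amplitude vectors differ in length")
    n_v = b_soc.size

    interest = design.columns_with_role("interest")
    if "social" not in interest or "tom" not in interest:
        raise ShapeMismatchError("design must contain interest columns 'social' and 'tom'")
    x_soc = design.column("social")
    x_tom = design.column("tom")
    if x_soc.size != n_t:
        raise ShapeMismatchError("design rows do not match requested timepoint count")

    data = np.full((n_v, n_t), float(baseline))
    data += np.outer(b_soc, x_soc) + np.outer(b_tom, x_tom)

    run_labels = design.run_id
    runs = [run_labels == r for r in pd.unique(run_labels)]

    motion, csf, gs, fd = [], [], [], []
    spike_global = []
    for run_mask in runs:
        n_r = int(run_mask.sum())
        # slow rigid-body motion: smoothed random walks (mm / rad)
        m = np.cumsum(rng.standard_normal((n_r, 6)) * 0.02, axis=0)
        m = gaussian_filter1d(m, sigma=5.0, axis=0, mode="nearest")
        dm = np.vstack([np.zeros(6), np.abs(np.diff(m, axis=0))])
        fd_run = dm.sum(axis=1) + np.abs(rng.standard_normal(n_r)) * 0.01
        csf_run = _ar1(rng, (n_r,), 0.5, 1.0)

        if noise_sd > 0:
            k_drift = max(int(np.floor(2 * n_r * design.tr / 128.0)), 1)
            dct = _dct_columns(n_r, k_drift)
            drift = dct @ rng.standard_normal((k_drift, n_v)) * (drift_sd_factor * noise_sd)
            art = (
                np.outer(m @ rng.standard_normal(6), np.ones(n_v))
                + np.outer(csf_run, rng.standard_normal(n_v))
            ) * (artifact_sd_factor * noise_sd)
            noise = _ar1(rng, (n_v, n_r), truth.ar1_phi, noise_sd)
            data[:, run_mask] += drift.T + art.T + noise

        spikes = rng.random(n_r) < outlier_rate
        spikes[:1] = False  # keep run starts clean
        if noise_sd > 0 and spikes.any():
            block = data[:, run_mask]
            block[:, spikes] += spike_sd * noise_sd
            data[:, run_mask] = block
            fd_run = fd_run.copy()
            fd_run[spikes] += 10.0 * fd_run.std() + 1.0
        offset = int(np.flatnonzero(run_mask)[0])
        spike_global.extend(offset + np.flatnonzero(spikes))

        motion.append(m)
        csf.append(csf_run)
        gs.append(data[:, run_mask].mean(axis=0))
        fd.append(fd_run)

    dataset = VoxelDataset(data=data, tr=design.tr, run_id=run_labels.copy()).validate()
    nuisance = NuisanceBundle(motion=motion, csf=csf, global_signal=gs, fd=fd).validate()
    table = pd.DataFrame(
        {
            "voxel": np.arange(n_v),
            "voxel_class": truth.voxel_class,
            "true_beta_social": truth.true_beta_social,
            "true_beta_tom": truth.true_beta_tom,
            "participant_beta_social": b_soc,
            "participant_beta_tom": b_tom,
        }
    )
    return SimulatedBold(
        dataset=dataset,
        nuisance=nuisance,
        truth_table=table,
        spike_volumes=np.asarray(spike_global, dtype=int),
    )


def simulate_cohort(
    design: DesignMatrix,
    truth: SyntheticTruth,
    n_participants: int,
    between_sd: float,
    noise_sd: float,
    outlier_rate: float = 0.0,
    seed: int = 0,
):
    """Yield per-participant simulated datasets around the group truth.

    Participant amplitudes are ``group amplitude + N(0, between_sd)`` at
    voxels with a true effect and exactly zero elsewhere, so the group-level
    effect size at an active voxel is d = amplitude / between_sd (before
    first-level estimation noise).
    """
    if n_participants < 1:
        raise InvalidParameterError("n_participants must be >= 1")
    if between_sd < 0:
        raise InvalidParameterError("between_sd must be >= 0")
    seeds = np.random.SeedSequence(seed).spawn(n_participants)
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        b_soc = truth.true_beta_social + np.where(
            truth.true_beta_social != 0,
            rng.standard_normal(truth.true_beta_social.size) * between_sd,
            0.0,
        )
        b_tom = truth.true_beta_tom + np.where(
            truth.true_beta_tom != 0,
            rng.standard_normal(truth.true_beta_tom.size) * between_sd,
            0.0,
        )
        sim = simulate_bold(
            design,
            truth,
            noise_sd=noise_sd,
            outlier_rate=outlier_rate,
            seed=int(rng.integers(2**31 - 1)),
            participant_betas={"social": b_soc, "tom": b_tom},
        )
        yield f"sub-{i:03d}", sim
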