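"""Core in-memory containers shared across the pipeline.

The containers are deliberately thin: plain dataclasses wrapping numpy
arrays and pandas frames, with validation helpers where an invariant is
cheap to check. Time is always seconds; ratings live on a visual-analog
scale in [0, 100]; BOLD values are arbitrary units (grand-mean scaled to
100 before model fitting).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ShapeMismatchError

RATING_MIN = 0.0
RATING_MAX = 100.0

#: integer codes used for voxel classification maps (and their NIfTI export)
CLASS_CODES = {"none": 0, "social_only": 1, "tom_only": 2, "both": 3}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}


@dataclass
class RatingPanel:
    """Long-format continuous ratings plus per-participant metadata.

    ``ratings`` columns: participant, question, trial, time_s, value
    (NaN = missing). ``attention`` columns: participant, run, passed.
    ``first_move`` columns: participant, trial, first_move_s.
    ``trials`` columns: trial, duration_s.
    """

    ratings: pd.DataFrame
    attention: Optional[pd.DataFrame] = None
    first_move: Optional[pd.DataFrame] = None
    trials: Optional[pd.DataFrame] = None
    grid_step: Optional[float] = None  # set once resampled to a uniform grid

    def validate(self) -> "RatingPanel":
        required = {"participant", "question", "trial", "time_s", "value"}
        missing = required - set(self.ratings.columns)
        if missing:
            raise FormatError(f"rating table missing columns: {sorted(missing)}")
        vals = self.ratings["value"].to_numpy(float)
        finite = np.isfinite(vals)
        if finite.any() and (
            (vals[finite] < RATING_MIN).any() or (vals[finite] > RATING_MAX).any()
        ):
            raise FormatError("rating values outside [0, 100]")
        return self

    def participants(self) -> np.ndarray:
        return np.asarray(sorted(self.ratings["participant"].unique()))

    def to_wide(self, question: str, trial=None) -> pd.DataFrame:
        """time_s x participant matrix for one question (one trial or all,
        concatenated in trial order)."""
        sub = self.ratings[self.ratings["question"] == question]
        if trial is not None:
            sub = sub[sub["trial"] == trial]
            return sub.pivot_table(
                index="time_s", columns="participant", values="value", dropna=False
            ).sort_index()
        blocks = []
        for tr_id in sorted(sub["trial"].unique()):
            w = (
                sub[sub["trial"] == tr_id]
                .pivot_table(index="time_s", columns="participant", values="value", dropna=False)
                .sort_index()
            )
            w.index = pd.MultiIndex.from_product([[tr_id], w.index], names=["trial", "time_s"])
            blocks.append(w)
        return pd.concat(blocks, axis=0)


@dataclass
class GroupTimecourse:
    """Median/MAD/valid-count summary of a rating cohort on a uniform grid."""

    time_s: np.ndarray
    median: np.ndarray
    mad: np.ndarray  # raw MAD, no consistency factor
    n_valid: np.ndarray
    valid_flag: np.ndarray  # False where < 50% of retained participants rated
    trial_id: Optional[np.ndarray] = None
    grid_step: Optional[float] = None

    def error_band(self) -> tuple[np.ndarray, np.ndarray]:
        """median +/- 1.96 * MAD / sqrt(n_valid), the display band for group plots."""
        with np.errstate(divide="ignore", invalid="ignore"):
            half = 1.96 * self.mad / np.sqrt(self.n_valid)
        return self.median - half, self.median + half


@dataclass
class AnnotationSet:
    """Binary sentence-part annotations, their consensus, and rater agreement."""

    labels: np.ndarray  # n_parts x n_raters, values in {0, 1}
    consensus: np.ndarray  # per part: 0, 1, or -1 (unresolved tie)
    kappa: float  # Fleiss' kappa over the rater matrix
    part_id: Optional[np.ndarray] = None

    @property
    def unresolved(self) -> np.ndarray:
        return self.consensus == -1


@dataclass
class ReliabilityReport:
    """Split-half (Spearman-Brown corrected) and pairwise rating similarity."""

    corrected: np.ndarray  # per permutation
    pairwise_median: float
    pairwise_mad: float
    n_permutations: int
    seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.corrected))

    @property
    def sd(self) -> float:
        return float(np.std(self.corrected, ddof=1))

    @property
    def range(self) -> tuple[float, float]:
        return float(np.min(self.corrected)), float(np.max(self.corrected))

    def to_dict(self) -> dict:
        return {
            "split_half_corrected_mean": self.mean,
            "split_half_corrected_sd": self.sd,
            "split_half_corrected_min": self.range[0],
            "split_half_corrected_max": self.range[1],
            "pairwise_median": self.pairwise_median,
            "pairwise_mad": self.pairwise_mad,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class HRFKernel:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""

    step: float  # seconds between samples
    values: np.ndarray
    parameters: dict = field(default_factory=dict)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.values.size) * self.step


@dataclass
class DesignMatrix:
    """Labeled time x regressor matrix with run structure.

    Roles: interest, rating_period, tom_demand_pair, dct, motion24, csf,
    outlier, missing_indicator, intercept. Interest-class columns span all
    runs (one beta per variable); nuisance columns are zero outside their run.
    """

    matrix: np.ndarray
    names: list
    roles: list
    run_id: np.ndarray
    tr: float

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def columns_with_role(self, role: str) -> list:
        return [n for n, r in zip(self.names, self.roles) if r == role]

    def subset(self, names: Sequence[str]) -> np.ndarray:
        idx = [self.names.index(n) for n in names]
        return self.matrix[:, idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


@dataclass
class NuisanceBundle:
    """Per-run confound series: 6 rigid-body motion params, CSF mean signal,
    whole-brain global signal, and framewise displacement."""

    motion: list  # one (n_volumes x 6) array per run
    csf: list  # one (n_volumes,) array per run
    global_signal: list
    fd: list

    def n_runs(self) -> int:
        return len(self.motion)

    def validate(self) -> "NuisanceBundle":
        for series in (self.csf, self.global_signal, self.fd):
            if len(series) != len(self.motion):
                raise ShapeMismatchError("nuisance bundle run counts differ")
        for r, m in enumerate(self.motion):
            n = m.shape[0]
            if m.shape[1] != 6:
                raise ShapeMismatchError("motion must have 6 columns per run")
            for series in (self.csf, self.global_signal, self.fd):
                if len(series[r]) != n:
                    raise ShapeMismatchError(f"nuisance lengths differ in run {r}")
        return self


@dataclass
class VoxelDataset:
    """voxel x timepoint BOLD matrix plus grid metadata."""

    data: np.ndarray  # n_voxels x n_timepoints
    tr: float
    run_id: np.ndarray  # per timepoint
    shape3d: Optional[tuple] = None
    affine: Optional[np.ndarray] = None
    voxel_index: Optional[np.ndarray] = None  # flat indices into shape3d

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def validate(self) -> "VoxelDataset":
        if not np.isfinite(self.data).all():
            raise FormatError("voxel data contain non-finite values")
        if len(self.run_id) != self.n_timepoints:
            raise ShapeMismatchError("run_id length != timepoint count")
        return self

    def runs(self) -> np.ndarray:
        # preserve temporal order of runs
        _, first = np.unique(self.run_id, return_index=True)
        return self.run_id[np.sort(first)]


@dataclass
class FirstLevelResult:
    """Per-participant OLS betas for every design column."""

    participant_id: object
    betas: np.ndarray  # n_columns x n_voxels
    names: list
    roles: list
    resid_var: np.ndarray  # per voxel, SSR / (n - p)
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.names.index(name)]

    def interest_betas(self) -> dict:
        return {
            n: self.betas[i]
            for i, (n, r) in enumerate(zip(self.names, self.roles))
            if r in ("interest", "tom_demand_pair")
        }


@dataclass
class GroupStatMap:
    """Group one-sample statistics per voxel."""

    beta_mean: np.ndarray
    t: np.ndarray
    p: np.ndarray
    d: np.ndarray  # Cohen's d = mean / sample SD
    df: int
    sig: np.ndarray  # FDR flag at q
    q: Optional[float] = None
    undefined: Optional[np.ndarray] = None  # zero-variance voxels

    @property
    def n_voxels(self) -> int:
        return self.t.size


@dataclass
class ConjunctionMap:
    """Voxels significant with the same sign in two maps; display value is
    the mean of the two t statistics at flagged voxels."""

    sig: np.ndarray
    value: np.ndarray


@dataclass
class ClassificationMap:
    """Per-voxel evidence class (none / social_only / tom_only / both)."""

    labels: np.ndarray  # integer codes, see CLASS_CODES
    bf_social: Optional[np.ndarray] = None
    t_social: Optional[np.ndarray] = None
    bf_tom: Optional[np.ndarray] = None
    t_tom: Optional[np.ndarray] = None
    alt_thresh: float = 5.0
    null_thresh: float = 0.2

    def proportions(self) -> dict:
        total = self.labels.size
        return {
            name: float(np.sum(self.labels == code) / total)
            for name, code in CLASS_CODES.items()
            if name != "none"
        }


@dataclass
class MaskSet:
    """Named binary masks on the analysis grid."""

    masks: dict  # name -> boolean array over voxels
    provenance: dict = field(default_factory=dict)  # name -> how it was built

    def validate(self, n_voxels: Optional[int] = None) -> "MaskSet":
        from .errors import DegenerateMaskError

        for name, m in self.masks.items():
            arr = np.asarray(m)
            if arr.dtype != bool:
                raise FormatError(f"mask {name!r} is not boolean")
            if not arr.any():
                raise DegenerateMaskError(f"mask {name!r} is empty")
            if n_voxels is not None and arr.size != n_voxels:
                raise ShapeMismatchError(f"mask {name!r} size != voxel count")
        return self


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated study.

    Group-level latents drive the regressors; per-voxel classes and signal
    amplitudes drive the BOLD simulator. Null voxels carry exactly zero
    amplitude in both conditions; single-condition voxels carry exactly zero
    in the other condition.
    """

    latent_social: np.ndarray  # [0, 100] on the behavioral grid
    latent_tom: np.ndarray
    latent_correlation: float
    rater_noise_sd: float
    ar1_phi: float
    seed: int
    voxel_class: Optional[np.ndarray] = None  # string labels per voxel
    true_beta_social: Optional[np.ndarray] = None
    true_beta_tom: Optional[np.ndarray] = None

    def validate(self) -> "SyntheticTruth":
        for latent in (self.latent_social, self.latent_tom):
            if (latent < RATING_MIN).any() or (latent > RATING_MAX).any():
                raise FormatError("latents must stay in [0, 100]")
        if not (0.0 <= self.ar1_phi < 1.0):
            raise FormatError("ar1_phi must be in [0, 1)")
        if self.voxel_class is not None:
            null = self.voxel_class == "null"
            soc = self.voxel_class == "social_only"
            tom = self.voxel_class == "tom_only"
            if (self.true_beta_social[null] != 0).any() or (self.true_beta_tom[null] != 0).any():
                raise FormatError("null voxels must have zero amplitudes")
            if (self.true_beta_tom[soc] != 0).any() or (self.true_beta_social[tom] != 0).any():
                raise FormatError("single-condition voxels must be zero in the other condition")
        return self

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel": np.arange(self.voxel_class.size),
                "voxel_class": self.voxel_class,
                "true_beta_social": self.true_beta_social,
                "true_beta_tom": self.true_beta_tom,
            }
        )
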