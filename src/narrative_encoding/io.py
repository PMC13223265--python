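"""Readers/writers for on-disk formats and the pipeline configuration.

Conventions: long-format TSV for ratings and tables (empty field =
missing), NIfTI for anything voxelwise, JSON for scalar reports, YAML for
configuration. Loaders validate invariants and reject out-of-range or
non-finite data instead of coercing it. Every numeric output can carry a
provenance sidecar (config hash, seed, package version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import DesignMatrix, MaskSet, RatingPanel, VoxelDataset
from .errors import FormatError, InvalidParameterError, ShapeMismatchError

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_rating_panel",
    "write_rating_panel",
    "read_voxel_dataset",
    "write_voxel_dataset",
    "read_map",
    "write_map",
    "load_mask_set",
    "read_design",
    "write_design",
    "write_json",
    "read_json",
    "provenance_sidecar",
]


@dataclass
class PipelineConfig:
    """All analysis parameters with their reference defaults.

    Analysis defaults mirror the reference settings: 230 ms behavioral
    grid, TR 0.46 s, 1/128 Hz high-pass, FDR q < 0.01, BF thresholds 5 and
    1/5 with prior scale sqrt(2)/2, 2000 split-half permutations, 10,000
    bootstrap/surrogate samples, leave-one-out exclusion thresholds 0.3
    (social) and 0.2 (tom). Simulation sizes default to a desk-scale smoke
    configuration.
    """

    grid_step: float = 0.23
    tr: float = 0.46
    highpass_hz: float = 1.0 / 128.0
    fdr_q: float = 0.01
    bf_alt_thresh: float = 5.0
    bf_null_thresh: float = 0.2
    bf_scale: float = float(np.sqrt(2.0) / 2.0)
    n_permutations: int = 2000
    n_boot: int = 10000
    n_surrogates: int = 10000
    loo_threshold_social: float = 0.3
    loo_threshold_tom: float = 0.2
    outlier_z: float = 3.0
    n_discard: int = 6
    parcel_min_fraction: float = 0.25
    meta_z_min: float = 3.0
    seed: int = 0
    # simulation block (smoke-scale defaults; study structure otherwise)
    target_r: float = 0.32
    n_raters: int = 30
    rater_noise_sd: float = 15.0
    n_participants: int = 6
    n_voxels_per_class: int = 125
    n_runs_per_modality: int = 2
    volumes_per_run: int = 160
    rating_volumes_per_run: int = 12
    effect_d: float = 1.2
    effect_amplitude: float = 1.0
    bold_noise_sd: float = 2.0
    ar1_phi: float = 0.4
    outlier_rate: float = 0.01

    def validate(self) -> "PipelineConfig":
        positive = (
            "grid_step tr highpass_hz fdr_q bf_scale n_permutations n_boot "
            "n_surrogates outlier_z n_raters n_participants n_voxels_per_class "
            "n_runs_per_modality volumes_per_run effect_d effect_amplitude"
        ).split()
        for name in positive:
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"config field {name!r} must be positive (got {v!r})")
        if not (self.bf_alt_thresh > 1.0 > self.bf_null_thresh > 0.0):
            raise InvalidParameterError("need bf_alt_thresh > 1 > bf_null_thresh > 0")
        k = self.tr / self.grid_step
        if abs(k - round(k)) > 1e-6:
            raise InvalidParameterError("tr must be an integer multiple of grid_step")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> PipelineConfig:
    """Build a validated config from a YAML file and/or override mapping."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError("config YAML must be a mapping")
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values).validate()


# --------------------------------------------------------------------------
# rating panels


def write_rating_panel(panel: RatingPanel, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    panel.ratings.to_csv(directory / "ratings.tsv", sep="\t", index=False, na_rep="")
    for name, frame in (
        ("attention", panel.attention),
        ("first_move", panel.first_move),
        ("trials", panel.trials),
    ):
        if frame is not None:
            frame.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
    return directory


def read_rating_panel(directory) -> RatingPanel:
    directory = Path(directory)
    path = directory / "ratings.tsv"
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ratings = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"malformed rating TSV {path}: {exc}") from exc

    def _opt(name):
        p = directory / f"{name}.tsv"
        return pd.read_csv(p, sep="\t") if p.exists() else None

    grid = None
    times = ratings.groupby(["participant", "question", "trial"])["time_s"]
    steps = times.apply(lambda t: np.diff(np.sort(t)).round(9))
    chunks = [s for s in steps if len(s)]
    flat = np.concatenate(chunks) if chunks else np.array([])
    if flat.size and np.allclose(flat, flat[0]):
        grid = float(flat[0])
    return RatingPanel(
        ratings=ratings,
        attention=_opt("attention"),
        first_move=_opt("first_move"),
        trials=_opt("trials"),
        grid_step=grid,
    ).validate()


# --------------------------------------------------------------------------
# voxel data and maps


def _default_grid(n_voxels: int) -> tuple:
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    nz = int(np.ceil(n_voxels / side**2))
    return (side, side, nz)


def write_voxel_dataset(dataset: VoxelDataset, prefix) -> Path:
    """4D NIfTI (.nii.gz) plus a JSON sidecar with TR and run boundaries."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    shape = dataset.shape3d or _default_grid(dataset.n_voxels)
    affine = dataset.affine if dataset.affine is not None else np.diag([2.0, 2.0, 2.0, 1.0])
    index = (
        dataset.voxel_index
        if dataset.voxel_index is not None
        else np.arange(dataset.n_voxels)
    )
    vol = np.zeros((int(np.prod(shape)), dataset.n_timepoints), dtype=np.float32)
    vol[index] = dataset.data
    img = nib.Nifti1Image(vol.reshape(*shape, dataset.n_timepoints), affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], dataset.tr))
    nib.save(img, str(prefix) + ".nii.gz")
    sidecar = {
        "tr": dataset.tr,
        "run_id": [str(r) for r in dataset.run_id],
        "voxel_index": [int(i) for i in index],
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(sidecar, fh)
    return prefix


def read_voxel_dataset(prefix) -> VoxelDataset:
    prefix = Path(prefix)
    img = nib.load(str(prefix) + ".nii.gz")
    with open(str(prefix) + ".json") as fh:
        sidecar = json.load(fh)
    data4d = np.asarray(img.dataobj, dtype=float)
    shape = data4d.shape[:3]
    flat = data4d.reshape(int(np.prod(shape)), data4d.shape[3])
    index = np.asarray(sidecar["voxel_index"], int)
    return VoxelDataset(
        data=flat[index],
        tr=float(sidecar["tr"]),
        run_id=np.asarray(sidecar["run_id"]),
        shape3d=shape,
        affine=img.affine,
        voxel_index=index,
    ).validate()


def write_map(
    values: np.ndarray,
    path,
    shape3d: Optional[tuple] = None,
    affine: Optional[np.ndarray] = None,
    voxel_index: Optional[np.ndarray] = None,
    dtype=np.float32,
) -> Path:
    """One statistic per voxel as a 3D NIfTI volume."""
    values = np.asarray(values)
    shape = shape3d or _default_grid(values.size)
    affine = affine if affine is not None else np.diag([2.0, 2.0, 2.0, 1.0])
    index = voxel_index if voxel_index is not None else np.arange(values.size)
    flat = np.zeros(int(np.prod(shape)), dtype=dtype)
    flat[index] = values.astype(dtype)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(flat.reshape(shape), affine), path)
    return path


def read_map(path, voxel_index: Optional[np.ndarray] = None) -> tuple:
    """Load a 3D map; returns (flat values over voxel_index, affine, shape)."""
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    flat = data.reshape(-1)
    if voxel_index is not None:
        flat = flat[np.asarray(voxel_index, int)]
    return flat, img.affine, data.shape


def load_mask_set(paths: dict, reference_affine: Optional[np.ndarray] = None,
                  voxel_index: Optional[np.ndarray] = None) -> MaskSet:
    """Load named binary NIfTI masks, checking affine compatibility."""
    masks = {}
    prov = {}
    for name, path in paths.items():
        flat, affine, _ = read_map(path, voxel_index=voxel_index)
        if reference_affine is not None and not np.allclose(affine, reference_affine):
            raise ShapeMismatchError(f"mask {name!r} affine differs from the analysis grid")
        uniq = np.unique(flat)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise FormatError(f"mask {name!r} is not binary")
        masks[name] = flat.astype(bool)
        prov[name] = {"path": str(path)}
    return MaskSet(masks=masks, provenance=prov).validate()


# --------------------------------------------------------------------------
# design matrices, reports, provenance


def write_design(design: DesignMatrix, prefix) -> Path:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    design.to_frame().to_csv(str(prefix) + ".tsv", sep="\t", index=False)
    header = {
        "names": list(design.names),
        "roles": list(design.roles),
        "run_id": [str(r) for r in design.run_id],
        "tr": design.tr,
    }
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(header, fh)
    return prefix


def read_design(prefix) -> DesignMatrix:
    prefix = Path(prefix)
    frame = pd.read_csv(str(prefix) + ".tsv", sep="\t")
    with open(str(prefix) + ".json") as fh:
        header = json.load(fh)
    if list(frame.columns) != header["names"]:
        raise FormatError("design TSV columns do not match the JSON header")
    return DesignMatrix(
        matrix=frame.to_numpy(float),
        names=header["names"],
        roles=header["roles"],
        run_id=np.asarray(header["run_id"]),
        tr=float(header["tr"]),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
    return path


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def provenance_sidecar(config: PipelineConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "parameters": config.to_dict(),
    }
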