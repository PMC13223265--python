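"""End-to-end driver: simulate -> behavior -> design -> GLM -> BF -> ROI.

The driver runs the whole analysis on a self-contained synthetic study
with known ground truth: two rating questions (social interaction,
theory-of-mind engagement) with a controlled latent correlation, two
stimulus modalities (text, audio) with independent narrative latents,
per-participant BOLD datasets with planted voxel classes, and the full
two-stage inference with FDR, cross-modal conjunction, JZS Bayes-factor
classification and ROI statistics. Identical config and seed give
bit-identical outputs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bayes, behavior, design, glm, roi, synthetic
from .containers import (
    CLASS_NAMES,
    DesignMatrix,
    GroupTimecourse,
    MaskSet,
    SyntheticTruth,
    VoxelDataset,
)
from .errors import InvalidParameterError
from .io import PipelineConfig, provenance_sidecar, write_design, write_json, write_map

__all__ = ["run_pipeline", "run_study", "balanced_accuracy", "discard_initial_volumes"]

MODALITIES = ("text", "audio")
CONDITIONS = ("social", "tom")


def discard_initial_volumes(dataset: VoxelDataset, n_discard: int) -> VoxelDataset:
    """Drop the first ``n_discard`` volumes of every run from the data."""
    keep = np.ones(dataset.n_timepoints, dtype=bool)
    for r in dataset.runs():
        idx = np.flatnonzero(dataset.run_id == r)
        keep[idx[:n_discard]] = False
    return VoxelDataset(
        data=dataset.data[:, keep],
        tr=dataset.tr,
        run_id=dataset.run_id[keep],
        shape3d=dataset.shape3d,
        affine=dataset.affine,
        voxel_index=dataset.voxel_index,
    )


def balanced_accuracy(true_classes: np.ndarray, predicted_codes: np.ndarray) -> float:
    """Mean per-class recall of the voxel classification against ground truth.

    ``true_classes`` holds the planted class strings (null voxels count as
    correctly recovered when labeled none).
    """
    predicted = np.asarray([CLASS_NAMES[int(c)] for c in predicted_codes])
    truth = np.where(np.asarray(true_classes) == "null", "none", np.asarray(true_classes))
    recalls = []
    for cls in np.unique(truth):
        sel = truth == cls
        recalls.append(np.mean(predicted[sel] == cls))
    return float(np.mean(recalls))


# --------------------------------------------------------------------------
# study construction


@dataclass
class ModalityData:
    """Everything simulated and estimated for one stimulus modality."""

    latents: dict  # condition -> list of per-run latent arrays
    courses: dict  # condition -> list of per-run GroupTimecourse
    signal_design: DesignMatrix
    first_levels: list = field(default_factory=list)
    group: dict = field(default_factory=dict)  # condition -> GroupStatMap
    bf: dict = field(default_factory=dict)  # condition -> BF array
    classification: Optional[object] = None


def _rating_period_column(n_vol: int, n_rate: int, hrf, k: int) -> np.ndarray:
    box = np.zeros(n_vol * k)
    if n_rate > 0:
        box[(n_vol - n_rate) * k :] = 1.0
    return np.convolve(box, hrf.values)[: box.size][::k]


def _course_from_panel(panel, question: str) -> list:
    """Per-trial group time courses, in trial order."""
    course = behavior.group_timecourse(panel, question=question)
    out = []
    for tid in pd.unique(course.trial_id):
        sel = course.trial_id == tid
        out.append(
            GroupTimecourse(
                time_s=course.time_s[sel],
                median=course.median[sel],
                mad=course.mad[sel],
                n_valid=course.n_valid[sel],
                valid_flag=course.valid_flag[sel],
                trial_id=course.trial_id[sel],
                grid_step=course.grid_step,
            )
        )
    return out


def _build_modality(
    config: PipelineConfig,
    modality: str,
    truth_seed_pool,
) -> tuple[ModalityData, dict, SyntheticTruth]:
    """Simulate ratings for one modality and build its stimulus design."""
    k = int(round(config.tr / config.grid_step))
    n_vol = config.volumes_per_run
    n_rate = config.rating_volumes_per_run
    n_narr_grid = (n_vol - n_rate) * k
    hrf = design.canonical_hrf(config.grid_step)

    latents = {"social": [], "tom": []}
    for _ in range(config.n_runs_per_modality):
        ls, lt = synthetic.make_latent_pair(
            config.target_r, n_narr_grid, seed=int(next(truth_seed_pool))
        )
        latents["social"].append(ls)
        latents["tom"].append(lt)

    panels = {}
    courses = {}
    reliability = {}
    for q in CONDITIONS:
        panel = synthetic.simulate_raters(
            latents[q],
            n_raters=config.n_raters,
            noise_sd=config.rater_noise_sd,
            first_move_delay_model={"kind": "uniform", "low_s": 0.0, "high_s": 3.0},
            seed=int(next(truth_seed_pool)),
            grid_step=config.grid_step,
            question=q,
        )
        loo = config.loo_threshold_social if q == "social" else config.loo_threshold_tom
        panel, _ = behavior.apply_exclusions(panel, q, loo_threshold=loo)
        panel = behavior.preprocess_ratings(panel, grid_step=config.grid_step)
        panels[q] = panel
        courses[q] = _course_from_panel(panel, q)
        reliability[q] = behavior.rating_similarity(
            panel, question=q, n_permutations=config.n_permutations,
            seed=int(next(truth_seed_pool)),
        )

    interest = {}
    missing = {}
    for q in CONDITIONS:
        cols, miss = [], []
        for course in courses[q]:
            reg, missing_vols = design.build_interest_regressor(course, hrf, config.tr)
            cols.append(np.concatenate([reg, np.zeros(n_vol - reg.size)]))
            miss.append(missing_vols)
        interest[q] = cols
        missing[q] = miss
    rating_cols = [
        _rating_period_column(n_vol, n_rate, hrf, k)
        for _ in range(config.n_runs_per_modality)
    ]
    signal_design = design.assemble_design(
        run_lengths=[n_vol] * config.n_runs_per_modality,
        tr=config.tr,
        interest=interest,
        rating_period=rating_cols,
        missing_volumes=None,
        n_discard=0,
    )
    behavior_outputs = {
        "panels": panels,
        "reliability": reliability,
        "interest": interest,
        "missing": missing,
        "rating_cols": rating_cols,
    }
    truth = synthetic.make_truth(
        latent_social=np.concatenate(latents["social"]),
        latent_tom=np.concatenate(latents["tom"]),
        n_voxels_per_class=config.n_voxels_per_class,
        beta_social=config.effect_amplitude,
        beta_tom=config.effect_amplitude,
        rater_noise_sd=config.rater_noise_sd,
        ar1_phi=config.ar1_phi,
        seed=config.seed,
    )
    return ModalityData(latents=latents, courses=courses, signal_design=signal_design), behavior_outputs, truth


def _analysis_design(
    config: PipelineConfig,
    behavior_outputs: dict,
    nuisance_bundle,
) -> DesignMatrix:
    n_vol = config.volumes_per_run
    n_runs = config.n_runs_per_modality
    nuis = design.build_nuisance(nuisance_bundle, z_thresh=config.outlier_z)
    dct = [design.dct_basis(n_vol, config.tr, config.highpass_hz) for _ in range(n_runs)]
    return design.assemble_design(
        run_lengths=[n_vol] * n_runs,
        tr=config.tr,
        interest=behavior_outputs["interest"],
        rating_period=behavior_outputs["rating_cols"],
        missing_volumes={
            q: behavior_outputs["missing"][q] for q in CONDITIONS
        },
        nuisance=nuis,
        dct=dct,
        n_discard=config.n_discard,
    )


def run_study(config: PipelineConfig) -> dict:
    """Run the full synthetic study in memory; returns all stage outputs."""
    config.validate()
    master = np.random.SeedSequence(config.seed)
    seed_iter = iter(
        np.random.default_rng(master).integers(0, 2**31 - 1, size=10000).tolist()
    )

    between_sd = config.effect_amplitude / config.effect_d
    results: dict = {"modalities": {}, "behavior": {}, "config": config.to_dict()}
    truth = None

    for modality in MODALITIES:
        mod, behav, truth = _build_modality(config, modality, seed_iter)
        results["behavior"][modality] = behav

        for pid, sim in synthetic.simulate_cohort(
            mod.signal_design,
            truth,
            n_participants=config.n_participants,
            between_sd=between_sd,
            noise_sd=config.bold_noise_sd,
            outlier_rate=config.outlier_rate,
            seed=int(next(seed_iter)),
        ):
            analysis = _analysis_design(config, behav, sim.nuisance)
            data = discard_initial_volumes(sim.dataset, config.n_discard)
            data = glm.grand_mean_scale(data, target=100.0)
            mod.first_levels.append(glm.fit_first_level(data, analysis, participant_id=pid))

        for cond in CONDITIONS:
            betas = np.vstack([fl.beta(cond) for fl in mod.first_levels])
            gmap = glm.group_onesample(betas, q=config.fdr_q)
            mod.group[cond] = gmap
            mod.bf[cond] = bayes.jzs_bf_map(gmap.t, n=config.n_participants, scale=config.bf_scale)
        mod.classification = bayes.classify_voxels(
            mod.bf["social"],
            mod.group["social"].t,
            mod.bf["tom"],
            mod.group["tom"].t,
            alt_thresh=config.bf_alt_thresh,
            null_thresh=config.bf_null_thresh,
        )
        results["modalities"][modality] = mod

    results["truth"] = truth

    # ----- annotations of theory-of-mind demand (text modality narrative)
    rng = np.random.default_rng(int(next(seed_iter)))
    text = results["modalities"]["text"]
    k = int(round(config.tr / config.grid_step))
    grid_len = text.latents["tom"][0].size
    part_len = max(int(round(2.76 / config.grid_step)), 1)  # ~2.8 s sentence parts
    bounds = np.arange(0, grid_len + 1, part_len)
    true_labels = np.array(
        [
            int(text.latents["tom"][0][a:b].mean() > 50.0)
            for a, b in zip(bounds[:-1], bounds[1:])
            if b > a
        ]
    )
    labels = synthetic.simulate_annotations(
        true_labels.size, 4, true_labels, flip_prob=0.1, seed=int(next(seed_iter))
    )
    consensus = behavior.consensus_annotations(labels, resolution=true_labels)
    timing = [
        (a * config.grid_step, (b - a) * config.grid_step)
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]
    demand_grid = np.zeros(grid_len)
    for lab, (onset, dur) in zip(consensus.consensus, timing):
        i0 = int(round(onset / config.grid_step))
        i1 = min(i0 + int(round(dur / config.grid_step)), grid_len)
        demand_grid[i0:i1] = lab
    course0 = text.courses["tom"][0]
    ok = course0.valid_flag
    surrogate = behavior.phase_randomization_corr(
        course0.median[ok], demand_grid[ok], n_surrogates=config.n_surrogates,
        seed=int(next(seed_iter)),
    )
    results["annotations"] = {
        "consensus": consensus,
        "true_labels": true_labels,
        "rating_vs_annotation": surrogate,
    }

    # ----- conjunctions, classification, recovery metrics
    text, audio = (results["modalities"][m] for m in MODALITIES)
    results["conjunction"] = {
        cond: glm.conjunction_map(text.group[cond], audio.group[cond]) for cond in CONDITIONS
    }
    conj_labels, proportions = bayes.cross_modal_labels(
        text.classification, audio.classification
    )
    results["classification"] = {
        "conjunction": conj_labels,
        "proportions": proportions,
        "balanced_accuracy": balanced_accuracy(truth.voxel_class, conj_labels.labels),
    }

    # ----- ROI stage on truth-derived masks and a synthetic meta-analytic map
    n_vox = truth.voxel_class.size
    zmap = 4.0 * np.isin(truth.voxel_class, ("both", "tom_only")) + rng.standard_normal(n_vox)
    meta_mask = roi.threshold_meta_map(zmap, z_min=config.meta_z_min)
    masks = MaskSet(
        masks={
            "both_truth": truth.voxel_class == "both",
            "tom_only_truth": truth.voxel_class == "tom_only",
            "meta_tom": meta_mask,
        },
        provenance={
            "both_truth": {"kind": "group_map"},
            "tom_only_truth": {"kind": "group_map"},
            "meta_tom": {"kind": "meta_threshold", "z_min": config.meta_z_min},
        },
    )
    roi_stats = roi.roi_effect_sizes(
        text.first_levels + audio.first_levels, masks, conditions=list(CONDITIONS)
    )
    both_mask = masks.masks["both_truth"]
    a = np.mean(
        [
            roi.participant_mask_means(m.first_levels, both_mask, "social")
            for m in (text, audio)
        ],
        axis=0,
    )
    b = np.mean(
        [roi.participant_mask_means(m.first_levels, both_mask, "tom") for m in (text, audio)],
        axis=0,
    )
    boot = roi.bootstrap_effect_diff(a, b, n_boot=config.n_boot, seed=int(next(seed_iter)))
    betas_soc = np.vstack([fl.beta("social")[meta_mask] for fl in text.first_levels])
    betas_tom = np.vstack([fl.beta("tom")[meta_mask] for fl in text.first_levels])
    pattern = roi.pattern_similarity_test(
        betas_tom, betas_soc, zmap[meta_mask], family_size=2
    )
    parcellation = 1 + (np.arange(n_vox) // max(n_vox // 8, 1))
    parcels = roi.label_parcels(
        results["conjunction"]["social"].sig, parcellation,
        min_fraction=config.parcel_min_fraction,
    )
    results["roi"] = {
        "masks": masks,
        "stats": roi_stats,
        "bootstrap_social_vs_tom": boot,
        "pattern_similarity": pattern,
        "parcels": parcels,
    }
    return results


# --------------------------------------------------------------------------
# on-disk pipeline


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Run the synthetic study and write all declared outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = run_study(config)
    write_json(provenance_sidecar(config, "pipeline"), outdir / "provenance.json")

    behav_dir = outdir / "behavior"
    for modality in MODALITIES:
        for q in CONDITIONS:
            rel = results["behavior"][modality]["reliability"][q]
            write_json(rel.to_dict(), behav_dir / f"reliability_{modality}_{q}.json")
    ann = results["annotations"]
    write_json(ann["rating_vs_annotation"], behav_dir / "rating_vs_annotation.json")
    pd.DataFrame(
        {
            "part_id": np.arange(ann["true_labels"].size),
            "true_label": ann["true_labels"],
            "consensus": ann["consensus"].consensus,
        }
    ).to_csv(behav_dir / "annotation_consensus.tsv", sep="\t", index=False)

    glm_dir = outdir / "glm"
    truth = results["truth"]
    for modality in MODALITIES:
        mod = results["modalities"][modality]
        table = {"voxel": np.arange(truth.voxel_class.size)}
        for cond in CONDITIONS:
            g = mod.group[cond]
            for stat in ("beta_mean", "t", "p", "d"):
                values = getattr(g, stat)
                write_map(values, glm_dir / f"{modality}_{cond}_{stat}.nii.gz")
                table[f"{cond}_{stat}"] = values
            table[f"{cond}_sig"] = g.sig.astype(int)
            write_map(mod.bf[cond], glm_dir / f"{modality}_{cond}_bf.nii.gz")
            table[f"{cond}_bf"] = mod.bf[cond]
        pd.DataFrame(table).to_csv(
            glm_dir / f"{modality}_voxel_table.tsv", sep="\t", index=False
        )
        write_map(
            mod.classification.labels,
            glm_dir / f"{modality}_labels.nii.gz",
            dtype=np.int16,
        )
    for cond in CONDITIONS:
        conj = results["conjunction"][cond]
        write_map(conj.sig.astype(np.int16), glm_dir / f"conjunction_{cond}_sig.nii.gz",
                  dtype=np.int16)
        write_map(np.nan_to_num(conj.value), glm_dir / f"conjunction_{cond}_t.nii.gz")
    write_map(
        results["classification"]["conjunction"].labels,
        glm_dir / "labels_conjunction.nii.gz",
        dtype=np.int16,
    )
    write_json(
        {
            "proportions": results["classification"]["proportions"],
            "balanced_accuracy": results["classification"]["balanced_accuracy"],
            "alt_thresh": config.bf_alt_thresh,
            "null_thresh": config.bf_null_thresh,
            "scale": config.bf_scale,
            "n": config.n_participants,
        },
        glm_dir / "class_proportions.json",
    )

    roi_dir = outdir / "roi"
    roi_dir.mkdir(parents=True, exist_ok=True)
    results["roi"]["stats"].to_csv(roi_dir / "roi_stats.tsv", sep="\t", index=False)
    results["roi"]["parcels"].to_csv(roi_dir / "parcels.tsv", sep="\t", index=False)
    write_json(results["roi"]["bootstrap_social_vs_tom"], roi_dir / "bootstrap_social_vs_tom.json")
    pattern = {
        k: v for k, v in results["roi"]["pattern_similarity"].items() if k not in ("z_a", "z_b")
    }
    write_json(pattern, roi_dir / "pattern_similarity.json")

    truth.truth_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    example_design = _analysis_design(
        config,
        results["behavior"]["text"],
        _example_nuisance(config, results),
    )
    write_design(example_design, outdir / "design" / "design_text_example")
    return outdir


def _example_nuisance(config: PipelineConfig, results: dict):
    """Regenerate one participant's nuisance bundle for the design export."""
    mod = results["modalities"]["text"]
    truth = results["truth"]
    sim = synthetic.simulate_bold(
        mod.signal_design, truth, noise_sd=config.bold_noise_sd,
        outlier_rate=config.outlier_rate, seed=config.seed,
    )
    return sim.nuisance
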