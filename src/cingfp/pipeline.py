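"""End-to-end phantom pipeline: simulate, map, parcellate, fingerprint,
QC, test, compare.

`run_demo` reproduces the whole analysis on synthetic phantoms of two
"species": both share the anterior-limbic / mid-motor / posterior-
hippocampal gradient, but the insula is wired to the anterior (limbic)
network in species A ("mouse") and to the mid (motor) network in
species B ("human") — so the comparator should single out the insula as
the least-similar homolog pair.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import two_way_rm_anova
from .compare import align_fingerprints, fingerprint_similarity
from .core_io import (
    Fingerprint,
    write_fingerprint_table,
    write_label_atlas,
    write_manifest,
)
from .errors import ConfigError
from .fc import bandpass, extract_roi_timeseries, group_fingerprint, subject_fc
from .ica import is_contiguous_assignment, order_sweep
from .qc import filter_manifest, qc_cohort
from .synthetic import (
    NET_MOTOR,
    build_phantom_atlas,
    default_bold_model,
    default_tracer_rules,
    iter_rsfmri_scans,
    simulate_tracer_experiments,
)
from .tracer import (
    place_seeds,
    projection_similarity,
    sample_density,
    stack_densities,
    tracer_fingerprint,
)

log = logging.getLogger("cingfp")


@dataclass
class PipelineConfig:
    """All knobs of the phantom demo, JSON-serializable."""

    grid_shape: tuple[int, int, int] = (40, 60, 30)
    n_targets: int = 9
    bilateral: bool = True

    n_tracer_experiments: int = 60
    tracer_noise_sd: float = 0.2

    ica_orders: tuple[int, ...] = (4, 5, 6, 7, 8, 9)
    n_parcellation_seeds: int | None = None  # None: min(2000, ROI size)

    mouse_fp_seeds: int = 10
    human_fp_seeds: int = 12
    seed_radius: int = 0

    mouse_n_subjects: int = 8
    human_n_subjects: int = 10
    n_timepoints: int = 200
    tr_s: float = 1.0
    bold_signal_sd: float = 1.0
    bold_noise_sd: float = 1.0
    human_frac_bad: float = 0.2

    mouse_band: tuple[float, float] = (0.01, 0.25)
    human_band: tuple[float, float] = (0.01, 0.1)

    qc_thr_pos: float = 0.1
    qc_thr_neg: float = 0.1

    compare_grid_m: int = 50
    rng_seed: int = 0

    def validate(self) -> None:
        nyq = 1.0 / (2.0 * self.tr_s)
        for name, band in (("mouse_band", self.mouse_band), ("human_band", self.human_band)):
            lo, hi = band
            if not 0 <= lo < hi:
                raise ConfigError(f"{name}: need 0 <= low < high, got {band}")
            if hi > nyq:
                raise ConfigError(
                    f"{name}: high={hi} exceeds Nyquist {nyq} for tr_s={self.tr_s}"
                )
        if self.n_timepoints < 16:
            raise ConfigError("n_timepoints must be >= 16")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        return cfg


def _base_name(name: str) -> str:
    return name.removesuffix("_L").removesuffix("_R")


def _fp_rois(atlas):
    """Left-hemisphere target ROIs, base-named, atlas order."""
    rows = atlas.table[(atlas.table["role"] == "target")]
    rows = rows[rows["hemisphere"].isin(["L", "M"])]
    names = [_base_name(n) for n in rows["name"]]
    ids = [int(i) for i in rows["label_id"]]
    return names, ids


def _fc_fingerprint_for_cohort(
    atlas, scans, seeds, band, target_ids, target_names, species
) -> tuple[Fingerprint, list[np.ndarray]]:
    rois = {f"seed_{i}": vs for i, vs in enumerate(seeds.voxel_sets)}
    for name, lid in zip(target_names, target_ids):
        rois[name] = atlas.voxels_of(lid)
    n_seeds = seeds.n_seeds
    seed_rows = list(range(n_seeds))
    target_rows = list(range(n_seeds, n_seeds + len(target_ids)))
    mats = []
    for scan in scans:
        ts = extract_roi_timeseries(scan, rois)
        ts = bandpass(ts, band[0], band[1])
        mats.append(subject_fc(ts, seed_rows, target_rows))
    fp = group_fingerprint(mats, seeds.u, target_names, species=species)
    return fp, mats


def run_demo(config: PipelineConfig, out_dir) -> Path:
    """Run the full phantom pipeline; returns the report directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "cingfp_version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    config.to_json(out / "config.json")
    seed = int(config.rng_seed)

    # --- simulate ----------------------------------------------------
    stage = "simulate"
    log.info("stage %s", stage)
    atlas_a = build_phantom_atlas(
        config.grid_shape, config.n_targets, config.bilateral, rng_seed=seed
    )
    atlas_b = build_phantom_atlas(
        config.grid_shape, config.n_targets, config.bilateral, rng_seed=seed + 1
    )
    write_label_atlas(atlas_a, out / "atlas_mouse.nii.gz", out / "atlas_mouse.tsv")
    write_label_atlas(atlas_b, out / "atlas_human.nii.gz", out / "atlas_human.tsv")

    rules = default_tracer_rules(noise_sd=config.tracer_noise_sd)
    experiments = simulate_tracer_experiments(
        atlas_a, rules, config.n_tracer_experiments, rng_seed=seed + 10
    )
    write_manifest(
        pd.DataFrame(
            {
                "experiment_id": [e.experiment_id for e in experiments],
                "injection_u": [e.injection_u for e in experiments],
                "off_strip": [e.off_strip for e in experiments],
            }
        ),
        out / "tracer_manifest.tsv",
    )

    model_a = default_bold_model(
        atlas_a, config.bold_signal_sd, config.bold_noise_sd, frac_bad=0.0
    )
    # species B: insula participates in the mid-cingulate/motor network
    model_b = default_bold_model(
        atlas_b,
        config.bold_signal_sd,
        config.bold_noise_sd,
        frac_bad=config.human_frac_bad,
        rewire={"insula": NET_MOTOR},
    )
    scans_a = []
    rows_a = []
    for scan, bad in iter_rsfmri_scans(
        atlas_a, model_a, config.mouse_n_subjects, config.n_timepoints,
        config.tr_s, rng_seed=seed + 20,
    ):
        scans_a.append(scan)
        rows_a.append((scan.subject_id, bad, config.tr_s))
    scans_b = []
    rows_b = []
    for scan, bad in iter_rsfmri_scans(
        atlas_b, model_b, config.human_n_subjects, config.n_timepoints,
        config.tr_s, rng_seed=seed + 21,
    ):
        scans_b.append(scan)
        rows_b.append((scan.subject_id, bad, config.tr_s))
    manifest_a = pd.DataFrame(rows_a, columns=["subject_id", "bad_flag", "tr_s"])
    manifest_b = pd.DataFrame(rows_b, columns=["subject_id", "bad_flag", "tr_s"])
    write_manifest(manifest_a, out / "scans_mouse.tsv")
    write_manifest(manifest_b, out / "scans_human.tsv")
    run_log["stages"][stage] = {
        "n_experiments": len(experiments),
        "n_scans": [len(scans_a), len(scans_b)],
    }

    # --- tracer-map --------------------------------------------------
    stage = "tracer-map"
    log.info("stage %s", stage)
    strip_ids = atlas_a.ids_with_role("seed_roi")
    roi_size = int(sum(len(atlas_a.voxels_of(i)) for i in strip_ids))
    n_parc = config.n_parcellation_seeds or min(2000, roi_size)
    parc_seeds = place_seeds(atlas_a, strip_ids, n_parc)
    seed_pm = sample_density(experiments, parc_seeds.voxel_sets, list(range(n_parc)))
    brain_pm = stack_densities(experiments)
    sim = projection_similarity(seed_pm, brain_pm, atlas_a.shape)
    run_log["stages"][stage] = {"n_parcellation_seeds": n_parc}

    # --- parcellate --------------------------------------------------
    stage = "parcellate"
    log.info("stage %s", stage)
    solutions, matching = order_sweep(sim, config.ica_orders, rng_seed=seed + 30)
    matching.to_csv(out / "ica_matching.tsv", sep="\t", index=False)
    assign_rows = []
    for order, sol in solutions.items():
        for i, (comp, u) in enumerate(zip(sol.seed_assignment, parc_seeds.u)):
            assign_rows.append((order, i, u, int(comp)))
    pd.DataFrame(
        assign_rows, columns=["order", "seed_index", "u", "component"]
    ).to_csv(out / "seed_assignment.tsv", sep="\t", index=False)
    run_log["stages"][stage] = {
        "orders": list(config.ica_orders),
        "contiguous": {
            int(k): bool(is_contiguous_assignment(sol.seed_assignment))
            for k, sol in solutions.items()
        },
    }

    # --- fingerprint (tracer + rsfMRI, both species) -----------------
    stage = "fingerprint"
    log.info("stage %s", stage)
    target_names, target_ids = _fp_rois(atlas_a)
    fp_seeds_a = place_seeds(
        atlas_a, strip_ids, config.mouse_fp_seeds, radius=config.seed_radius
    )
    seed_fp_pm = sample_density(
        experiments, fp_seeds_a.voxel_sets, list(range(config.mouse_fp_seeds))
    )
    target_locs = [atlas_a.voxels_of(i) for i in target_ids]
    target_pm = sample_density(experiments, target_locs, target_names)
    sim_fp_seeds = projection_similarity(seed_fp_pm, brain_pm, atlas_a.shape)
    sim_fp_targets = projection_similarity(target_pm, brain_pm, atlas_a.shape)
    exclusion = atlas_a.mask_of(strip_ids + atlas_a.ids_with_role("target"))
    fp_tracer = tracer_fingerprint(
        sim_fp_seeds, sim_fp_targets, exclusion, fp_seeds_a.u, target_names,
        species="mouse",
    )
    write_fingerprint_table(fp_tracer, out / "fingerprint_mouse_tracer.tsv")

    fp_mouse, mats_a = _fc_fingerprint_for_cohort(
        atlas_a, scans_a, fp_seeds_a, config.mouse_band, target_ids,
        target_names, "mouse",
    )
    write_fingerprint_table(fp_mouse, out / "fingerprint_mouse_rsfmri.tsv")

    # --- qc (species B cohort) ---------------------------------------
    stage = "qc"
    log.info("stage %s", stage)
    report = qc_cohort(
        scans_b,
        atlas_b.voxels_of(atlas_b.id_of("sensory_L")),
        atlas_b.voxels_of(atlas_b.id_of("sensory_R")),
        atlas_b.voxels_of(atlas_b.id_of("dmn_L")),
        thr_pos=config.qc_thr_pos,
        thr_neg=config.qc_thr_neg,
    )
    report.to_frame().to_csv(out / "qc_human.tsv", sep="\t", index=False)
    kept = filter_manifest(manifest_b, report)
    write_manifest(kept, out / "scans_human_qc.tsv")
    kept_ids = set(kept["subject_id"])
    scans_b_kept = [s for s in scans_b if s.subject_id in kept_ids]
    run_log["stages"][stage] = {
        "n_in": len(scans_b),
        "n_pass": len(scans_b_kept),
    }
    if not scans_b_kept:
        raise ConfigError("no species-B scan passed QC")

    target_names_b, target_ids_b = _fp_rois(atlas_b)
    fp_seeds_b = place_seeds(
        atlas_b, atlas_b.ids_with_role("seed_roi"), config.human_fp_seeds,
        radius=config.seed_radius,
    )
    fp_human, mats_b = _fc_fingerprint_for_cohort(
        atlas_b, scans_b_kept, fp_seeds_b, config.human_band, target_ids_b,
        target_names_b, "human",
    )
    write_fingerprint_table(fp_human, out / "fingerprint_human_rsfmri.tsv")
    run_log["stages"]["fingerprint"] = {
        "targets": target_names,
        "n_mouse_subjects": len(mats_a),
        "n_human_subjects": len(mats_b),
    }

    # --- anova -------------------------------------------------------
    stage = "anova"
    log.info("stage %s", stage)
    anova_rows = []
    for species, mats in (("mouse", mats_a), ("human", mats_b)):
        if len(mats) >= 2:
            res = two_way_rm_anova(np.stack(mats))
            anova_rows.append(
                (
                    species,
                    res.F_interaction,
                    res.df1,
                    res.df2,
                    res.epsilon_gg,
                    res.epsilon_hf,
                    res.p_unadjusted,
                    res.p_hf,
                )
            )
    anova_df = pd.DataFrame(
        anova_rows,
        columns=[
            "species", "F_interaction", "df1", "df2",
            "epsilon_gg", "epsilon_hf", "p_unadjusted", "p_hf",
        ],
    )
    anova_df.to_csv(out / "anova.tsv", sep="\t", index=False, na_rep="NA")
    run_log["stages"][stage] = {"rows": len(anova_df)}

    # --- compare -----------------------------------------------------
    stage = "compare"
    log.info("stage %s", stage)
    homologs = [(n, n) for n in target_names]
    pair = align_fingerprints(fp_mouse, fp_human, homologs, m=config.compare_grid_m)
    scores = fingerprint_similarity(pair)
    df = scores.to_frame()
    df.to_csv(out / "compare.tsv", sep="\t", index=False, na_rep="NA")
    summary = pd.DataFrame(
        {
            "metric": ["cosine_overall", "manhattan_overall"],
            "value": [scores.cosine_overall, scores.manhattan_overall],
        }
    )
    summary.to_csv(out / "compare_overall.tsv", sep="\t", index=False)
    run_log["stages"][stage] = {
        "cosine_overall": scores.cosine_overall,
        "manhattan_overall": scores.manhattan_overall,
        "min_r_target": str(scores.per_target_r.idxmin()),
    }

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return out
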