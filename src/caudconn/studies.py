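"""Cohort-level simulation studies.

These drive the full generator -> preprocessing -> parcellation ->
connectivity -> statistics chain at toy-grid scale and measure how well the
analysis recovers the planted structure: winner-take-all assignment
accuracy, the direction of FPN/DMN allocation change across age groups, the
rest differentiation-on-age slope, lag and load-gain recovery in task runs,
SRTM parameter recovery, and the calibration of the inferential layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import connectivity, parcellation, pet_srtm, preprocess, stats, synthgen

GROUPS = ("young", "middle", "old")


def child_seed(seed: int, i: int) -> int:
    """Deterministic sub-seed derivation, kept below 2**31."""
    return int((seed * 1_000_003 + 7919 * i + 1) % (2**31 - 1))


def toy_roi_voxels(atlas: synthgen.ToyAtlas):
    """Seed and target voxel sets for the toy grid."""
    labels = atlas.labels
    seed_vox = None
    fpn, dmn = {}, {}
    for spec in synthgen.toy_roi_table(atlas):
        restrict = spec.pop("restrict", None)
        roi = connectivity.RoiSpec(**spec)
        if restrict == "striatum_seed_box":
            mask = atlas.seed_box_mask()
        elif restrict and restrict.startswith("label_"):
            mask = labels == int(restrict.split("_")[1])
        else:
            mask = None
        vox = connectivity.make_sphere_roi(roi, atlas.affine, atlas.shape, mask=mask)
        if roi.network == "seed":
            seed_vox = vox
        elif roi.network == "FPN":
            fpn[roi.name] = vox
        else:
            dmn[roi.name] = vox
    return seed_vox, fpn, dmn


# ---------------------------------------------------------------------------
# rest cohort: parcellation recovery + differentiation slope


@dataclass
class RestCohortResult:
    subjects: pd.DataFrame
    accuracy_pct: float
    fractions: pd.DataFrame  # rows = age group, cols = network label
    records: pd.DataFrame
    slope: float
    slope_se: float
    planted_slope: float
    fpn_decreasing: bool
    dmn_increasing: bool
    overlap_young_vs_old: dict


def run_rest_cohort(
    seed: int,
    n_subjects: int = 60,
    noiseless: bool = False,
    apply_qc: bool = True,
    fwhm_mm: float = 0.0,
    n_volumes: int = synthgen.REST_VOLUMES,
    top_k: int = 25,
) -> RestCohortResult:
    """Generate a rest cohort, clean it, parcellate per age group, and
    measure recovery of the planted structure.

    Spatial smoothing defaults to off: at toy-grid scale (3 mm voxels,
    two-voxel network strips) a 6 mm kernel mixes neighbouring strips,
    which tests the smoother rather than the parcellation.
    """
    atlas = synthgen.make_toy_atlas()
    profile = synthgen.default_coupling_profile(atlas)
    if noiseless:
        profile = profile.noiseless()
    subjects = synthgen.generate_subject_table(n=n_subjects, seed=seed)
    if apply_qc and not noiseless:
        subjects, _ = preprocess.qc_exclude(subjects)

    seed_vox, fpn_rois, dmn_rois = toy_roi_voxels(atlas)
    zmaps: dict[str, list] = {g: [] for g in GROUPS}
    group_rows: dict[str, list[int]] = {g: [] for g in GROUPS}
    records = []
    for i, (idx, subj) in enumerate(subjects.iterrows()):
        run, motion, truth = synthgen.generate_rest_bold(
            subj, atlas, profile, n_volumes=n_volumes, seed=child_seed(seed, i)
        )
        if noiseless:
            cleaned = run
        else:
            cleaned, _ = preprocess.clean_run(
                run, motion, atlas.csf_mask, atlas.wm_mask, fwhm=fwhm_mm
            )
        zmaps[subj["age_group"]].append(
            parcellation.voxelwise_zmap(cleaned, atlas.striatal_mask, atlas.cortical_mask)
        )
        group_rows[subj["age_group"]].append(idx)
        records.append(
            connectivity.connectivity_record(
                cleaned, seed_vox, fpn_rois, dmn_rois,
                condition="rest", subject_id=subj["subject_id"],
            )
        )
    records = pd.DataFrame(records)

    frac_rows, correct, total = [], 0, 0
    pmaps = {}
    for g in GROUPS:
        if not zmaps[g]:
            continue
        gmap = parcellation.group_average(zmaps[g], tag=g)
        pmap = parcellation.winner_take_all(gmap, atlas.labels, k=top_k)
        pmaps[g] = pmap
        rows = subjects.loc[group_rows[g]]
        truth_labels = synthgen.planted_labels(
            profile, rows["age"].to_numpy(), rows["diff_rest_true"].to_numpy()
        )
        correct += int(np.sum(pmap.labels == truth_labels))
        total += len(truth_labels)
        frac = parcellation.allocation_fractions(pmap)
        frac_rows.append(pd.Series(frac.to_dict(), name=g))
    fractions = pd.DataFrame(frac_rows)

    fpn_dec = bool(fractions[1].is_monotonic_decreasing and fractions[1].nunique() == len(fractions))
    dmn_inc = bool(fractions[2].is_monotonic_increasing and fractions[2].nunique() == len(fractions))

    merged = records.merge(subjects, on="subject_id")
    x = sm.add_constant(merged["age"])
    fit = sm.OLS(merged["differentiation"], x).fit()
    planted = sm.OLS(merged["diff_rest_true"], x).fit()

    overlap = {}
    if "young" in pmaps and "old" in pmaps:
        overlap = parcellation.label_overlap(pmaps["young"], pmaps["old"], network=1)

    return RestCohortResult(
        subjects=subjects,
        accuracy_pct=100.0 * correct / total,
        fractions=fractions,
        records=records,
        slope=float(fit.params["age"]),
        slope_se=float(fit.bse["age"]),
        planted_slope=float(planted.params["age"]),
        fpn_decreasing=fpn_dec,
        dmn_increasing=dmn_inc,
        overlap_young_vs_old=overlap,
    )


def parcellation_recovery_study(
    n_seeds: int = 20, n_subjects: int = 60, base_seed: int = 1
) -> pd.DataFrame:
    """Accuracy, dedifferentiation direction, and slope recovery per seed."""
    rows = []
    for s in range(n_seeds):
        res = run_rest_cohort(seed=child_seed(base_seed, 1000 + s), n_subjects=n_subjects)
        rows.append(
            {
                "seed_index": s,
                "accuracy_pct": res.accuracy_pct,
                "fpn_decreasing": res.fpn_decreasing,
                "dmn_increasing": res.dmn_increasing,
                "slope": res.slope,
                "slope_se": res.slope_se,
                "planted_slope": res.planted_slope,
                "fpn_young": res.fractions.loc["young", 1],
                "fpn_old": res.fractions.loc["old", 1],
                "dmn_young": res.fractions.loc["young", 2],
                "dmn_old": res.fractions.loc["old", 2],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# task runs: lag and load-gain recovery


def run_lag_gain_study(
    seed: int,
    n_subjects: int = 48,
    shifts_volumes: tuple[int, ...] = (0, 2, 4),
) -> pd.DataFrame:
    """Noiseless task cohort: mean seed-FPN z per load at several analysis
    lags.  The generator plants a 4 s delay at TR 2 s, so the 2-volume
    shift is the aligned one."""
    atlas = synthgen.make_toy_atlas()
    profile = synthgen.default_coupling_profile(atlas).noiseless()
    design = synthgen.TaskDesign()
    subjects = synthgen.generate_subject_table(n=n_subjects, seed=seed)
    seed_vox, fpn_rois, dmn_rois = toy_roi_voxels(atlas)

    rows = []
    for i, (_, subj) in enumerate(subjects.iterrows()):
        run, labels_df, motion, truth = synthgen.generate_task_bold(
            subj, atlas, profile, design, seed=child_seed(seed, i)
        )
        for shift in shifts_volumes:
            rec = connectivity.task_connectivity(
                run, labels_df["condition"], seed_vox, fpn_rois, dmn_rois,
                lag_s=shift * design.tr, subject_id=subj["subject_id"],
            )
            rec["shift_volumes"] = shift
            rows.append(rec)
    df = pd.concat(rows, ignore_index=True)
    return df.groupby(["shift_volumes", "condition"], as_index=False)[
        ["z_fpn", "z_dmn", "differentiation"]
    ].mean()


# ---------------------------------------------------------------------------
# SRTM recovery


def srtm_grid_recovery(
    r1_grid=(0.7, 1.0, 1.3),
    k2_grid=(0.08, 0.15, 0.30),
    bp_grid=(0.5, 2.0, 5.0),
) -> pd.DataFrame:
    """Noiseless forward/fit round trip over a 27-point parameter grid."""
    rows = []
    for r1 in r1_grid:
        for k2 in k2_grid:
            for bp in bp_grid:
                tac = synthgen.generate_tac({"R1": r1, "k2": k2, "BP_ND": bp})
                fit = pet_srtm.fit_srtm(tac)
                rows.append(
                    {
                        "R1": r1, "k2": k2, "BP_ND": bp,
                        "R1_hat": fit.R1, "k2_hat": fit.k2, "BP_hat": fit.BP_ND,
                        "err_R1": abs(fit.R1 - r1) / r1,
                        "err_k2": abs(fit.k2 - k2) / k2,
                        "err_BP": abs(fit.BP_ND - bp) / bp,
                        "converged": fit.converged,
                    }
                )
    return pd.DataFrame(rows)


def srtm_noise_recovery(
    n_replicates: int = 100,
    seed: int = 1,
    params: dict | None = None,
    noise_scale: float = 0.15,
) -> pd.DataFrame:
    """Monte-Carlo recovery of BP_ND under frame-level noise."""
    params = params or {"R1": 1.0, "k2": 0.15, "BP_ND": 2.0}
    rows = []
    for i in range(n_replicates):
        tac = synthgen.generate_tac(
            params, noise_scale=noise_scale, seed=child_seed(seed, i)
        )
        fit = pet_srtm.fit_srtm(tac)
        rows.append(
            {"BP_hat": fit.BP_ND,
             "rel_err_BP": abs(fit.BP_ND - params["BP_ND"]) / params["BP_ND"],
             "converged": fit.converged}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical calibration


def lrt_null_calibration(n_replicates: int = 1000, n: int = 180, seed: int = 1) -> float:
    """False-positive rate of LRT model selection when the added term is null."""
    rng = np.random.default_rng(seed)
    false_pos = 0
    for _ in range(n_replicates):
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        y = 0.5 * x1 + rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        nested = smf.ols("y ~ x1", df).fit()
        full = smf.ols("y ~ x1 + x2", df).fit()
        if stats.lrt_select(nested, full)["keep_full"]:
            false_pos += 1
    return false_pos / n_replicates


def mediation_null_coverage(
    n_replicates: int = 300,
    n: int = 500,
    n_boot: int = 2000,
    seed: int = 1,
    a: float = -0.5,
    b: float = 0.0,
    c_prime: float = -0.2,
) -> float:
    """Share of BCa indirect-effect intervals covering the true indirect
    effect (a*b = 0 with the default null b path)."""
    rng = np.random.default_rng(seed)
    truth = a * b
    covered = 0
    for i in range(n_replicates):
        x = rng.standard_normal(n)
        m = a * x + rng.standard_normal(n)
        y = c_prime * x + b * m + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = stats.mediate_bca(
            df, "x", "m", "y", n_boot=n_boot, seed=child_seed(seed, i),
            standardize=False,
        )
        lo, hi = res.ci["indirect"]
        if lo <= truth <= hi:
            covered += 1
    return covered / n_replicates


# ---------------------------------------------------------------------------
# full model battery on a generated cohort


def run_battery_cohort(seed: int, n_subjects: int = 60, n_boot: int = 2000) -> dict:
    """Generate rest + task runs for a cohort, clean them, extract ROI
    connectivity, and run the full model battery on the measured records."""
    atlas = synthgen.make_toy_atlas()
    profile = synthgen.default_coupling_profile(atlas)
    subjects = synthgen.generate_subject_table(n=n_subjects, seed=seed)
    subjects = synthgen.generate_behavior(subjects, seed=child_seed(seed, 999))
    subjects, _ = preprocess.qc_exclude(subjects)
    seed_vox, fpn_rois, dmn_rois = toy_roi_voxels(atlas)
    design = synthgen.TaskDesign()
    rows = []
    for i, (_, subj) in enumerate(subjects.iterrows()):
        run, motion, _ = synthgen.generate_rest_bold(
            subj, atlas, profile, seed=child_seed(seed, 2 * i)
        )
        clean, _ = preprocess.clean_run(run, motion, atlas.csf_mask, atlas.wm_mask, fwhm=0)
        rows.append(pd.DataFrame([
            connectivity.connectivity_record(
                clean, seed_vox, fpn_rois, dmn_rois,
                condition="rest", subject_id=subj["subject_id"],
            )
        ]))
        trun, labels_df, tmotion, _ = synthgen.generate_task_bold(
            subj, atlas, profile, design, seed=child_seed(seed, 2 * i + 1)
        )
        tclean, _ = preprocess.clean_run(trun, tmotion, atlas.csf_mask, atlas.wm_mask, fwhm=0)
        rows.append(connectivity.task_connectivity(
            tclean, labels_df["condition"], seed_vox, fpn_rois, dmn_rois,
            subject_id=subj["subject_id"],
        ))
    records = pd.concat(rows, ignore_index=True)
    bundle = stats.run_paper_models(
        records, subjects, n_boot=n_boot, seed=child_seed(seed, 31)
    )
    bundle["records"] = records
    bundle["subjects"] = subjects
    return bundle
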