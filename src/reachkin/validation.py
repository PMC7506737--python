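"""Study-level validation runs: recovery of ground truth by the full pipeline.

These routines drive the synthetic generator through the complete analysis
chain and measure how well each stage recovers what was scripted: sensor
orientations, sensor-to-segment frames, joint angles, phase events and the
factor effects injected into the trial metrics.  They are used by the
validation test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .conventions import BLOCKS, TARGETS
from .core_io import TrialCondition
from .kinematics import JointAngleSeries
from .metrics_stats import (
    aggregate_conditions,
    compute_trial_metrics,
    load_subject_table,
    metrics_table,
    summarize_subjects,
)
from .pipeline import (
    PipelineConfig,
    _trial_seed,
    default_conditions,
    joint_angle_rmse_deg,
    make_subject,
    orientation_errors_deg,
    process_trial,
    run_study,
    simulate_trial,
    study_metrics_frame,
)
from .synthetic import _ARM_EFFECT, _HEIGHT_EFFECT, SUBJECT_SD, NoiseConfig, script_reach_trial

#: subject discarded from the published kinematic analysis (defective
#: calibration data); the clinical table still lists all ten rows
DISCARDED_SUBJECTS = ("S02",)


def in_paper_statistics() -> dict[str, float]:
    """Descriptive statistics recomputed from the bundled clinical table and
    the experimental protocol (12 conditions x 3 repetitions per arm)."""
    table = load_subject_table()
    s = summarize_subjects(table)
    conditions_per_arm = len(BLOCKS) * len(TARGETS)
    trials_per_arm = conditions_per_arm * 3
    analyzed = len(table) - len(DISCARDED_SUBJECTS)
    return {
        "fma_total_median": s["columns"]["fma_total"]["median"],
        "fma_total_mean": s["columns"]["fma_total"]["mean"],
        "fma_total_sd": s["columns"]["fma_total"]["sd"],
        "age_median_years": s["columns"]["age_years"]["median"],
        "months_since_stroke_median": s["columns"]["months_since_stroke"]["median"],
        "fma_mca_pca_mean": s["territory_groups"]["mca_pca"]["fma_total_mean"],
        "fma_aca_mean": s["territory_groups"]["aca"]["fma_total_mean"],
        "trials_per_subject_per_arm": float(trials_per_arm),
        "total_datasets": float(analyzed * trials_per_arm),
    }


def orientation_recovery(seed: int, n_trials: int = 36) -> dict[str, float]:
    """Noise-free per-sensor orientation error over the full condition grid."""
    cfg = PipelineConfig(seed=seed)
    subj = make_subject(seed, noise=NoiseConfig.zero(seed))
    conds = default_conditions("AF")[:n_trials]
    worst = []
    for cond in conds:
        truth, sset = simulate_trial(subj, cond, _trial_seed(seed, cond), cfg)
        errs = orientation_errors_deg(subj, truth, sset, cfg)
        worst.append(max(errs.values()))
    return {
        "orientation_rmse_mean_deg": float(np.mean(worst)),
        "orientation_rmse_max_deg": float(np.max(worst)),
        "n_trials": n_trials,
    }


def calibration_recovery(seed: int, n_mountings: int = 20) -> dict[str, float]:
    """Frame recovery and joint-angle stability across random sensor mountings."""
    cfg = PipelineConfig(seed=seed)
    cond = TrialCondition("AF", "BW", "Top3")
    frame_errs = []
    rmses = []
    for k in range(n_mountings):
        subj = make_subject(seed + 1000 * k, noise=NoiseConfig.zero(seed + 1000 * k))
        frame_errs.extend(
            np.degrees((fr.rotation * subj.chain.mountings[site].inv()).magnitude())
            for site, fr in subj.calibration.frames.items()
        )
        truth, sset = simulate_trial(subj, cond, 17, cfg)
        pt = process_trial(sset, subj.calibration, cfg, subj.biases, truth=truth)
        rmses.append(max(joint_angle_rmse_deg(pt.angles, truth).values()))
    return {
        "calibration_frame_error_max_deg": float(np.max(frame_errs)),
        "joint_rmse_spread_over_mountings_deg": float(np.ptp(rmses)),
        "n_mountings": n_mountings,
    }


def joint_angle_recovery(seed: int, n_noise_seeds: int = 10) -> dict[str, float]:
    """Per-DOF RMSE of reconstructed joint angles, noise-free and noisy."""
    cfg = PipelineConfig(seed=seed)
    clean = make_subject(seed, noise=NoiseConfig.zero(seed))
    clean_rmse = []
    for cond in (
        TrialCondition("AF", "BH", "Top3"),
        TrialCondition("AF", "BL", "Tab2"),
        TrialCondition("NAF", "BW", "Top4"),
        TrialCondition("NAF", "BH", "Tab1"),
    ):
        truth, sset = simulate_trial(clean, cond, _trial_seed(seed, cond), cfg)
        pt = process_trial(sset, clean.calibration, cfg, clean.biases, truth=truth)
        clean_rmse.append(max(joint_angle_rmse_deg(pt.angles, truth).values()))
    noisy_rmse = []
    for k in range(n_noise_seeds):
        subj = make_subject(seed + 71 * k + 1)
        cond = TrialCondition("AF" if k % 2 else "NAF", BLOCKS[k % 3], TARGETS[k % 4])
        truth, sset = simulate_trial(subj, cond, seed + k, cfg)
        pt = process_trial(sset, subj.calibration, cfg, subj.biases, truth=truth)
        noisy_rmse.append(max(joint_angle_rmse_deg(pt.angles, truth).values()))
    return {
        "joint_rmse_noise_free_max_deg": float(np.max(clean_rmse)),
        "joint_rmse_noisy_mean_deg": float(np.mean(noisy_rmse)),
        "n_noise_seeds": n_noise_seeds,
    }


def segmentation_recovery(seed: int, n_trials: int = 50) -> dict[str, float]:
    """Event-timing recovery over seeded clean trials, both detection routes."""
    cfg = PipelineConfig(seed=seed)
    subj = make_subject(seed, noise=NoiseConfig.zero(seed))
    force_errs, kin_errs = [], []
    ordered = 0
    for k in range(n_trials):
        cond = TrialCondition(
            "AF" if k % 2 else "NAF", BLOCKS[k % 3], TARGETS[k % 4], repetition=k % 3 + 1
        )
        truth, sset = simulate_trial(subj, cond, seed + 13 * k, cfg)
        pt = process_trial(sset, subj.calibration, cfg, subj.biases, truth=truth)
        tv = (truth.events.t_start, truth.events.t_grasp, truth.events.t_release, truth.events.t_end)
        ev = (pt.events.t_start, pt.events.t_grasp, pt.events.t_release, pt.events.t_end)
        force_errs.append(max(abs(a - b) for a, b in zip(ev, tv)))
        ordered += pt.events.t_start < pt.events.t_grasp < pt.events.t_release < pt.events.t_end
        nf = dataclasses.replace(sset, forces={})
        ptk = process_trial(nf, subj.calibration, cfg, subj.biases, truth=truth)
        evk = (ptk.events.t_start, ptk.events.t_grasp, ptk.events.t_release, ptk.events.t_end)
        kin_errs.append(max(abs(a - b) for a, b in zip(evk, tv)))
    return {
        "segmentation_force_max_error_s": float(np.max(force_errs)),
        "segmentation_kinematic_max_error_s": float(np.max(kin_errs)),
        "segmentation_ordering_fraction": ordered / n_trials,
        "n_trials": n_trials,
    }


def ground_truth_metrics_frame(seed: int, n_subjects: int = 4, rate: float = 100.0):
    """Trial-metric table computed from scripted trajectories and true events.

    No sensors are rendered: this isolates the metric and aggregation stages
    from the reconstruction chain.
    """
    rng = np.random.default_rng(seed)
    metrics = []
    for s in range(n_subjects):
        offsets = {m: rng.normal(0.0, sd) for m, sd in SUBJECT_SD.items()}
        for arm in ("AF", "NAF"):
            for cond in default_conditions(arm):
                truth = script_reach_trial(
                    cond,
                    seed=rng,
                    subject_offsets=offsets,
                    rate=rate,
                )
                angles = JointAngleSeries(
                    t=truth.trajectory.t, angles=dict(truth.trajectory.angles)
                )
                metrics.append(
                    compute_trial_metrics(
                        angles, truth.events, cond, subject=f"S{s + 1:02d}"
                    )
                )
    return metrics_table(metrics)


def effect_recovery(seed: int, n_seeds: int = 20, n_subjects: int = 4) -> dict:
    """Recovery of the generator-injected arm and target-height shifts.

    For each seed a small cohort is scripted, its metric table aggregated,
    and the AF-NAF and Top-Tab mean differences compared with the injected
    effects (twice the half-effects of the additive generator model).
    """
    arm_err = {m: [] for m in _ARM_EFFECT}
    height_err = {m: [] for m in _HEIGHT_EFFECT}
    for k in range(n_seeds):
        df = ground_truth_metrics_frame(seed + 101 * k, n_subjects=n_subjects)
        agg = aggregate_conditions(df)
        for m in arm_err:
            means = agg.factor_means["arm"][m]["mean"]
            arm_err[m].append((means["AF"] - means["NAF"]) - 2 * _ARM_EFFECT[m])
            hmeans = agg.factor_means["height"][m]["mean"]
            height_err[m].append((hmeans["Top"] - hmeans["Tab"]) - 2 * _HEIGHT_EFFECT[m])
    out = {}
    for name, errs in (("arm", arm_err), ("height", height_err)):
        for m, e in errs.items():
            e = np.asarray(e)
            out[f"{name}_{m}_mean_error_deg"] = float(np.mean(e))
            out[f"{name}_{m}_sd_deg"] = float(np.std(e, ddof=1))
    out["n_seeds"] = n_seeds
    return out


def simulated_group_means(seed: int) -> dict[str, float]:
    """Group means of the primary metrics after full-pipeline analysis of one
    simulated subject's 36 trials per arm (default noise)."""
    cfg = PipelineConfig(seed=seed)
    frames = []
    for arm in ("AF", "NAF"):
        subj = make_subject(seed, noise=NoiseConfig(seed=seed))
        frames.append(study_metrics_frame(run_study(subj, arm, cfg)))
    import pandas as pd

    df = pd.concat(frames, ignore_index=True)
    out = {}
    for metric in ("trunk_comp", "elbow_rom", "wrist_rom", "finger_rom", "movement_time"):
        g = df.groupby("arm")[metric].mean()
        out[f"{metric}_af_mean"] = float(g["AF"])
        out[f"{metric}_naf_mean"] = float(g["NAF"])
    h = df.groupby("height")["elbow_rom"].mean()
    out["elbow_rom_top_mean"] = float(h["Top"])
    out["elbow_rom_tab_mean"] = float(h["Tab"])
    b = df.groupby("block")["trunk_comp"].mean()
    out["trunk_comp_bh_mean"] = float(b["BH"])
    out["trunk_comp_bl_mean"] = float(b["BL"])
    out["n_trials"] = int(len(df))
    return out
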