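"""End-to-end orchestration: simulate -> clean -> extract -> decode -> tune -> test.

``run_subject`` executes all stages for one simulated subject and session;
``run_study`` loops over groups, subjects and conditions, assembles the
tidy long-format results table (the direct input for downstream
mixed-model software) and runs the built-in group tests. All stage seeds
derive from the config's master seed, so outputs are fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bold import VoxelTuningSpec, clean_signal, generate_tuned_bold
from .config import StudyConfig, stage_seed
from .decode import (
    CHANCE_LEVEL,
    ClassifierSpec,
    PermutationNull,
    cross_validate,
    group_null_of_means,
    make_folds,
    permutation_null,
)
from .events import (
    DirectionBinning,
    check_class_distribution,
    events_to_examples,
    events_to_tsv,
    extract_events,
)
from .stats import holm_correct, paired_contrast, permutation_p, t_test_vs_chance
from .task import (
    ArenaSpec,
    ObjectSet,
    simulate_feedback_phase,
    simulate_trajectory,
    summarize_behavior,
)
from .tuning import confusion_function, fit_tuning

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class SubjectResult:
    """Everything one simulated session produced."""

    subject_id: str
    group: str
    condition: str
    session_index: int
    excluded: bool
    exclusion_reason: str = ""
    n_examples: int = 0
    n_events_dropped: int = 0
    balanced_accuracy: float = float("nan")
    per_fold_scores: np.ndarray | None = None
    tau: float = float("nan")
    tuning_sse: float = float("nan")
    tuning_converged: bool = False
    confusion: np.ndarray | None = None
    null: PermutationNull | None = None
    p_perm: float = float("nan")
    learning_change: float = float("nan")
    last_trial_error: float = float("nan")
    mean_fd: float = float("nan")


def run_subject(
    config: StudyConfig,
    subject_index: int,
    group: str,
    condition: str,
    outdir: Path | None = None,
) -> SubjectResult:
    """Run all stages for one subject and session (= one condition).

    A session failing the class-distribution gate is marked excluded and
    carries NaN statistics; this mirrors participant exclusion for
    insufficient direction coverage and is not an error.
    """
    session_index = sorted(config.conditions).index(condition)
    subject_id = f"sub-{group}-{subject_index:02d}"
    arena = ArenaSpec(config.arena.radius_vm, config.arena.unreal_units_per_vm)
    bold_cfg = config.bold_for(group, condition)
    binning = DirectionBinning(config.events.n_bins)

    traj = simulate_trajectory(
        arena,
        duration=config.trajectory.duration_s,
        dt=config.trajectory.dt_s,
        turn_volatility=config.trajectory.turn_volatility,
        mean_speed=config.trajectory.mean_speed,
        seed=stage_seed(config.seed, subject_index, "trajectory", session_index),
    )
    # the voxel population (preferences, tuned subset) is a subject-level
    # property shared across sessions; gain/noise/trajectory vary per session
    voxel_spec = VoxelTuningSpec(
        n_voxels=bold_cfg.n_voxels,
        tuning_sd=bold_cfg.tuning_sd,
        gain=bold_cfg.gain,
        baseline=bold_cfg.baseline,
        noise_sd=bold_cfg.noise_sd,
        fraction_tuned=bold_cfg.fraction_tuned,
    ).sample_population(seed=stage_seed(config.seed, subject_index, "voxels"))
    run = generate_tuned_bold(
        traj,
        voxel_spec,
        TR=bold_cfg.tr_s,
        lag=bold_cfg.lag_trs * bold_cfg.tr_s,
        drift_amplitude=bold_cfg.drift_amplitude,
        seed=stage_seed(config.seed, subject_index, "bold", session_index),
    )
    mean_fd = float(run.confounds["framewise_displacement"].mean())
    cleaned = clean_signal(run)
    events = extract_events(
        traj, binning, config.events.min_duration_s, config.events.min_speed
    )
    es = events_to_examples(
        events, cleaned, TR=bold_cfg.tr_s, lag_TRs=bold_cfg.lag_trs,
        binning=binning, session_id=f"{subject_id}_{condition}",
    )

    # behavior: feedback phase of this session
    objects = ObjectSet.random(
        arena, seed=stage_seed(config.seed, subject_index, "objects", session_index)
    )
    trials = simulate_feedback_phase(
        arena,
        objects,
        memory_noise_sd=config.task.memory_noise_sd,
        n_repetitions=config.task.n_repetitions,
        seed=stage_seed(config.seed, subject_index, "feedback", session_index),
        noise_decay=config.task.noise_decay,
        omission_prob=config.task.omission_prob,
    )
    behavior = summarize_behavior(trials)

    result = SubjectResult(
        subject_id, group, condition, session_index,
        excluded=False,
        n_examples=len(es.X),
        n_events_dropped=es.n_dropped,
        learning_change=behavior.learning_change,
        last_trial_error=float(behavior.trial_errors[-1]),
        mean_fd=mean_fd,
    )

    ok, diagnostic = check_class_distribution(
        es, config.decode.min_per_class, config.decode.k_folds
    )
    if not ok:
        result.excluded = True
        result.exclusion_reason = diagnostic["reason"]
        logger.info("%s %s excluded: %s", subject_id, condition, diagnostic["reason"])
        return result

    spec = ClassifierSpec(config.decode.C, config.decode.tol, config.decode.max_iter)
    folds = make_folds(es, config.decode.k_folds)
    decoding = cross_validate(
        es, spec, folds,
        seed=stage_seed(config.seed, subject_index, "decode", session_index),
    )
    cf = confusion_function(decoding.prob, decoding.y_true, decoding.classes)
    fit = fit_tuning(cf)
    result.balanced_accuracy = decoding.balanced_accuracy
    result.per_fold_scores = decoding.per_fold_scores
    result.tau = fit.tau
    result.tuning_sse = fit.sse
    result.tuning_converged = fit.converged
    result.confusion = cf.mean_prob

    if config.permutation.n_iterations > 0:
        result.null = permutation_null(
            es, spec, folds, n=config.permutation.n_iterations,
            seed=stage_seed(config.seed, subject_index, "permutation", session_index),
        )
        result.p_perm = permutation_p(decoding.balanced_accuracy, result.null.scores)

    if outdir is not None:
        subdir = Path(outdir) / subject_id / condition
        subdir.mkdir(parents=True, exist_ok=True)
        traj.to_tsv(subdir / "trajectory.tsv")
        events_to_tsv(events, subdir / "events.tsv")
        es.save(subdir / "examples")
        pd.DataFrame(
            {"offset_deg": cf.offsets, "mean_prob": cf.mean_prob}
        ).to_csv(subdir / "confusion_function.tsv", sep="\t", index=False)
        (subdir / "decoding.json").write_text(
            json.dumps(
                {
                    "balanced_accuracy": result.balanced_accuracy,
                    "per_fold_scores": decoding.per_fold_scores.tolist(),
                    "tau": result.tau,
                    "p_perm": result.p_perm if np.isfinite(result.p_perm) else None,
                },
                indent=1,
            )
        )
    return result


def tidy_table(results: list[SubjectResult], config: StudyConfig) -> pd.DataFrame:
    """Long-format per-session table, one row per subject x condition.

    Designed as the direct input of downstream mixed-model software
    (intervention x age group x ROI x session order, random intercept and
    intervention slope per subject).
    """
    rows = []
    for r in results:
        rows.append(
            {
                "subject": r.subject_id,
                "age_group": r.group,
                "session": r.session_index + 1,
                "order": "-".join(sorted(config.conditions)),
                "intervention": r.condition,
                "roi": config.roi,
                "excluded": r.excluded,
                "n_examples": r.n_examples,
                "balanced_accuracy": r.balanced_accuracy,
                "tau": r.tau,
                "p_perm": r.p_perm,
                "learning_change": r.learning_change,
                "last_trial_error": r.last_trial_error,
                "fd": r.mean_fd,
                "dosage_per_kg": np.nan,  # placeholder column for real studies
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class StudyResult:
    table: pd.DataFrame
    group_tests: dict
    manifest: dict
    subject_results: list


def run_study(config: StudyConfig, outdir: Path | None = None) -> StudyResult:
    """Simulate and analyze the whole study described by ``config``.

    Per group x condition cell: ``n_subjects`` sessions. Group tests:
    one-sided t-tests of balanced accuracy against chance per condition
    (Holm-corrected across conditions), a paired contrast between the two
    conditions (within subjects), and — when per-subject permutation nulls
    were computed — a permutation test of the group-mean accuracy against
    the iteration-wise group null.
    """
    results: list[SubjectResult] = []
    global_index = 0  # unique per subject across groups, keys all stage seeds
    for group in sorted(config.groups):
        for _ in range(config.n_subjects):
            for condition in sorted(config.conditions):
                results.append(
                    run_subject(config, global_index, group, condition, outdir)
                )
            global_index += 1
    table = tidy_table(results, config)

    included = table[~table.excluded]
    if included.empty:
        raise RuntimeError(
            "all subjects were excluded by the class-distribution check; "
            "sessions are too short or walking too erratic for decoding"
        )

    conditions = sorted(config.conditions)
    tests: dict = {"vs_chance": {}, "paired": {}, "permutation": {}}
    raw_ps = []
    for condition in conditions:
        scores = included[included.intervention == condition].balanced_accuracy
        res = t_test_vs_chance(scores.to_numpy())
        tests["vs_chance"][condition] = dataclasses.asdict(res)
        raw_ps.append(res.p_one_sided)
    adjusted = holm_correct(raw_ps)
    for condition, adj in zip(conditions, adjusted):
        tests["vs_chance"][condition]["p_adjusted"] = float(adj)

    if len(conditions) == 2:
        a, b = conditions
        wide = included.pivot_table(
            index="subject", columns="intervention", values="balanced_accuracy"
        ).dropna()
        if len(wide) >= 2:
            contrast = paired_contrast(wide[b].to_numpy(), wide[a].to_numpy())
            tests["paired"] = {
                "contrast": f"{b} - {a}",
                "mean_difference": float((wide[b] - wide[a]).mean()),
                **dataclasses.asdict(contrast),
            }

    nulls = [r.null for r in results if r.null is not None and not r.excluded]
    if nulls:
        group_null = group_null_of_means(nulls)
        observed = float(
            np.mean([r.balanced_accuracy for r in results if r.null is not None and not r.excluded])
        )
        tests["permutation"] = {
            "observed_group_mean": observed,
            "null_mean": float(group_null.mean()),
            "p": permutation_p(observed, group_null),
        }

    manifest = {
        "config_hash": config.content_hash(),
        "version": __version__,
        "master_seed": config.seed,
        "n_sessions": len(results),
        "n_excluded": int(table.excluded.sum()),
        "chance_level": CHANCE_LEVEL,
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "tidy_table.tsv", sep="\t", index=False)
        (out / "group_tests.json").write_text(json.dumps(tests, indent=1, default=float))
        config.to_yaml(out / "config.yaml")
        manifest["outputs"] = sorted(
            str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return StudyResult(table, tests, manifest, results)


def behavioral_chance(config: StudyConfig, results_trials, n_locations=100_000, n_sims=1000):
    """Convenience wrapper: group chance distribution for simulated sessions."""
    from .task import chance_distribution

    arena = ArenaSpec(config.arena.radius_vm, config.arena.unreal_units_per_vm)
    return chance_distribution(
        arena, results_trials, n_locations=n_locations, n_sims=n_sims,
        seed=stage_seed(config.seed, 0, "chance"),
    )
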