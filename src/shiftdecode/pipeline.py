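"""End-to-end study orchestration: simulate -> GLM -> ROI -> decode -> infer.

``run_full_study`` produces, for a configured cohort, the condition x
accuracy tables for the feedback and feedforward ROIs, group bootstrap
inference, pairwise permutation tests against the unshifted condition, a
QC report, and a provenance record; ``recover_tuning_width`` reduces the
group table to the headline quantity — the largest spatial shift with
significant cross-decoding.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .glm import single_trial_betas
from .inference import (
    group_table,
    permutation_diff_test,
    pool_experiments,
    qc_exclude_subjects,
)
from .mvpa import results_to_frame, shift_profile
from .roi import select_rois
from .simulate import SimulatedSession, derive_seed, simulate_cohort
from .inference import bootstrap_subject_mean

logger = logging.getLogger("shiftdecode")

__all__ = ["StudyResult", "run_full_study", "process_subject", "recover_tuning_width"]


@dataclass
class StudyResult:
    """Bundle of every artefact a study run produces."""

    fold_df: pd.DataFrame
    subject_means: pd.DataFrame
    group_df: pd.DataFrame
    comparisons: pd.DataFrame
    qc: dict
    precision: dict
    provenance: dict

    def save(self, out_dir, fmt: str = "csv") -> None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            self.fold_df.to_csv(out / "fold_accuracies.csv", index=False)
            self.subject_means.to_csv(out / "subject_means.csv", index=False)
            self.group_df.to_csv(out / "group_results.csv", index=False)
            self.comparisons.to_csv(out / "comparisons.csv", index=False)
        else:
            self.fold_df.to_json(out / "fold_accuracies.json", orient="records")
            self.subject_means.to_json(out / "subject_means.json", orient="records")
            self.group_df.to_json(out / "group_results.json", orient="records")
            self.comparisons.to_json(out / "comparisons.json", orient="records")
        with open(out / "qc_report.json", "w") as fh:
            json.dump(self.qc, fh, indent=2)
        with open(out / "run_log.json", "w") as fh:
            json.dump({"provenance": self.provenance, "precision": self.precision}, fh, indent=2)


def process_subject(session: SimulatedSession, config: PipelineConfig) -> pd.DataFrame:
    """One subject through GLM, ROI selection and decoding."""
    betas = single_trial_betas(session, cutoff_hz=config.highpass_hz)
    rois = select_rois(
        session,
        threshold=config.roi_threshold,
        use_ground_truth=config.use_ground_truth_rois,
    )
    for name, mask in rois.items():
        if len(mask) == 0:
            logger.warning("subject %s: empty %s ROI", session.subject_id, name)
    results = shift_profile(
        betas,
        rois,
        session.design,
        C=config.svm_c,
        subject_id=session.subject_id,
    )
    return results_to_frame(results, session.subject_id, session.experiment)


def _subject_mean_frame(fold_df: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """First-level bootstrap: one mean accuracy per subject and condition."""
    rows = []
    keys = ["subject", "experiment", "roi", "train_shift", "test_shift", "delta", "within", "mode"]
    grouped = sorted(fold_df.groupby(keys), key=lambda kv: kv[0])
    for i, (key, sub) in enumerate(grouped):
        est = bootstrap_subject_mean(
            sub["accuracy"].to_numpy(),
            B=config.n_boot,
            seed=derive_seed(config.seed, 100, i),
        )
        rows.append(dict(zip(keys, key)) | {"accuracy": est})
    return pd.DataFrame(rows)


def _comparisons(
    pooled: dict, config: PipelineConfig
) -> pd.DataFrame:
    """Permutation tests of each shifted condition against delta 0."""
    rows = []
    conditions = sorted(pooled)
    for i, (roi, delta, mode) in enumerate(conditions):
        if delta == 0:
            continue
        ref = (roi, 0.0, mode)
        if ref not in pooled:
            continue
        test = permutation_diff_test(
            pooled[ref],
            pooled[(roi, delta, mode)],
            n_perm=config.n_perm,
            seed=derive_seed(config.seed, 200, i),
        )
        rows.append(
            {
                "roi": roi,
                "mode": mode,
                "comparison": f"0 vs {delta:g} deg",
                "observed_diff": test.observed_diff,
                "p_value": test.p_value,
                "significant": test.significant,
            }
        )
    return pd.DataFrame(rows)


def run_full_study(
    config: PipelineConfig,
    out_dir=None,
    n_jobs: int = 1,
    fmt: str = "csv",
) -> StudyResult:
    """Run the whole pipeline on a simulated cohort.

    Stages: cohort simulation, per-subject single-trial GLM + ROI selection
    + shift-profile decoding (parallelisable over subjects; results are
    independent of ``n_jobs``), QC exclusion of subjects with chance-level
    feedforward decoding, pooling across experiments sharing shift sets,
    two-level bootstrap per condition, and permutation comparisons against
    the unshifted condition.
    """
    logger.info("simulating cohort: %d subjects, seed %d", config.n_subjects, config.seed)
    sessions = simulate_cohort(
        config.n_subjects,
        config.designs(),
        config.tuning,
        config.noise,
        config.seed,
        cohort_sizes=config.cohort_sizes,
        layout=config.layout,
    )
    if n_jobs != 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=n_jobs)(
            delayed(process_subject)(s, config) for s in sessions
        )
    else:
        frames = [process_subject(s, config) for s in sessions]
    fold_df = pd.concat(frames, ignore_index=True)

    # QC: drop subjects whose stimulated-ROI decoding is at chance
    from .mvpa import DecodingResult, DecodingSpec

    qc_results = []
    for (sub, roi, s1, s2, mode), g in fold_df.groupby(
        ["subject", "roi", "train_shift", "test_shift", "mode"]
    ):
        qc_results.append(
            DecodingResult(
                DecodingSpec(roi, s1, s2, mode),
                g.sort_values("fold")["accuracy"].tolist(),
                g.sort_values("fold")["n_test"].tolist(),
                subject_id=sub,
            )
        )
    if config.qc_enabled:
        kept, excluded = qc_exclude_subjects(qc_results, alpha=config.qc_alpha)
    else:
        kept, excluded = sorted(fold_df["subject"].unique()), []
    if excluded:
        logger.warning("QC excluded subjects: %s", ", ".join(excluded))
    if not kept:
        raise RuntimeError(
            "QC excluded every subject (chance-level feedforward decoding across "
            "the cohort); nothing to pool. Disable QC for null cohorts."
        )
    fold_kept = fold_df[fold_df["subject"].isin(kept)]

    subject_means = _subject_mean_frame(fold_kept, config)
    pooled = pool_experiments(subject_means, pooling=config.effective_pooling())
    group_df = group_table(
        pooled, B=config.n_boot, coverage=config.ci_coverage, seed=config.seed
    )
    comparisons = _comparisons(pooled, config)

    precision = {
        roi: {
            mode: recover_tuning_width(group_df, roi=roi, mode=mode)
            for mode in ("ST", "AB")
        }
        for roi in ("feedback", "feedforward")
    }
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    provenance = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "n_subjects_simulated": config.n_subjects,
        "n_subjects_kept": len(kept),
    }
    result = StudyResult(
        fold_df=fold_df,
        subject_means=subject_means,
        group_df=group_df,
        comparisons=comparisons,
        qc={"kept": kept, "excluded": excluded, "criterion": f"binomial one-sided alpha={config.qc_alpha}"},
        precision=precision,
        provenance=provenance,
    )
    if out_dir is not None:
        result.save(out_dir, fmt=fmt)
    return result


def recover_tuning_width(
    group_df: pd.DataFrame, roi: str = "feedback", mode: str = "ST"
) -> float:
    """Largest shift delta with significant cross-decoding (degrees).

    Returns 0 if no cross-shift condition's CI excludes chance.  Delta-0
    (within-condition) decoding does not count toward the precision.
    """
    sub = group_df[
        (group_df["roi"] == roi)
        & (group_df["mode"] == mode)
        & (group_df["delta_deg"] > 0)
        & group_df["significant_vs_chance"]
    ]
    return float(sub["delta_deg"].max()) if len(sub) else 0.0
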