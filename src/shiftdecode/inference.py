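"""Group-level statistics: two-level bootstrap, permutation tests, QC.

Group means and confidence intervals follow a two-level percentile
bootstrap: fold accuracies are resampled within subject (1000 samples) to
estimate subject means, then subject means are resampled (1000 samples) to
estimate the group mean and its middle-95% interval, reported as a pair of
non-negative offsets below/above the mean.  Accuracy is deemed above
chance only if the interval excludes 0.5.  Differences between conditions
use a label-shuffling permutation test on absolute group-mean differences
with a top-5% criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy.stats import binomtest

from .mvpa import DecodingResult

__all__ = [
    "GroupInference",
    "PermutationTest",
    "bootstrap_subject_mean",
    "bootstrap_group",
    "permutation_diff_test",
    "qc_exclude_subjects",
    "pool_experiments",
    "group_table",
]

CHANCE = 0.5


@dataclass
class GroupInference:
    """Group mean with bootstrap CI offsets for one decoding condition.

    ``ci_excludes_chance`` records the raw two-sided interval check;
    ``significant_vs_chance`` additionally requires the mean to lie above
    chance, matching how above-chance decoding is reported.
    """

    condition: tuple
    group_mean: float
    ci_offsets: tuple[float, float]
    significant_vs_chance: bool
    ci_excludes_chance: bool
    n_subjects: int

    @property
    def ci(self) -> tuple[float, float]:
        lo, up = self.ci_offsets
        return self.group_mean - lo, self.group_mean + up

    def format_result(self) -> str:
        """Reporting format: mean % with bracketed CI offsets."""
        lo, up = self.ci_offsets
        return f"{100 * self.group_mean:.2f}%, CI [{lo:.4f}, {up:.4f}]"


@dataclass
class PermutationTest:
    """Permutation test of a group-mean difference."""

    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    significant: bool


def bootstrap_subject_mean(fold_accuracies, B: int = 1000, seed=None) -> float:
    """Bootstrap estimate of one subject's mean classifier performance.

    Mean of ``B`` with-replacement resample means of the fold accuracies.
    """
    vals = np.asarray(fold_accuracies, dtype=float)
    if vals.size == 0:
        raise ValueError("no accuracy values to bootstrap")
    if vals.size == 1 or np.ptp(vals) == 0:
        return float(vals[0])
    rng = default_rng(seed)
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    return float(vals[idx].mean(axis=1).mean())


def bootstrap_group(
    subject_means,
    B: int = 1000,
    coverage: float = 0.95,
    seed=None,
    condition: tuple = (),
    return_samples: bool = False,
):
    """Second-level bootstrap of the group mean with percentile CI.

    The CI spans the middle ``coverage`` fraction of the ``B`` bootstrap
    group means and is stored as offsets (mean - lower, upper - mean).
    """
    vals = np.asarray(subject_means, dtype=float)
    if vals.size < 2:
        raise ValueError("group bootstrap needs at least 2 subjects")
    rng = default_rng(seed)
    idx = rng.integers(0, vals.size, size=(B, vals.size))
    boot_means = vals[idx].mean(axis=1)
    group_mean = float(boot_means.mean())
    alpha = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    offsets = (max(group_mean - lo, 0.0), max(hi - group_mean, 0.0))
    excludes = not (group_mean - offsets[0] <= CHANCE <= group_mean + offsets[1])
    gi = GroupInference(
        condition=condition,
        group_mean=group_mean,
        ci_offsets=offsets,
        significant_vs_chance=excludes and group_mean > CHANCE,
        ci_excludes_chance=excludes,
        n_subjects=int(vals.size),
    )
    return (gi, boot_means) if return_samples else gi


def permutation_diff_test(
    vals_a,
    vals_b,
    n_perm: int = 1000,
    seed=None,
) -> PermutationTest:
    """Permutation test of the absolute difference between group means.

    Condition labels are shuffled across the pooled values ``n_perm``
    times; the difference is significant if the observed absolute
    difference falls in the top 5% of the null distribution.  The p-value
    uses the add-one convention so it can never be exactly zero.
    """
    a = np.asarray(vals_a, dtype=float)
    b = np.asarray(vals_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions must be non-empty")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is too small for a stable top-5% criterion")
    rng = default_rng(seed)
    observed = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    null = np.abs(perms[:, : a.size].mean(axis=1) - perms[:, a.size :].mean(axis=1))
    p = (1 + np.sum(null >= observed - 1e-12)) / (n_perm + 1)
    return PermutationTest(
        observed_diff=float(observed),
        null_diffs=null,
        p_value=float(p),
        significant=p <= 0.05,
    )


def qc_exclude_subjects(
    results: list[DecodingResult],
    alpha: float = 0.05,
    roi: str = "feedforward",
) -> tuple[list[str], list[str]]:
    """Exclude subjects whose feedforward decoding is at chance.

    A subject is excluded if their within-condition (delta = 0, unshifted,
    single-trial) feedforward accuracy is not significantly above 0.5 by a
    one-sided binomial test over the pooled test trials — i.e. subjects in
    whom even directly stimulated V1 carries no decodable scene signal.
    Returns ``(kept, excluded)`` subject id lists.
    """
    per_subject: dict[str, DecodingResult] = {}
    for res in results:
        s = res.spec
        if s.roi == roi and s.mode == "ST" and s.within and s.train_shift == 0:
            per_subject[res.subject_id] = res
    if not per_subject:
        raise ValueError(f"no within-condition delta=0 {roi} results to apply QC to")
    kept, excluded = [], []
    for sub, res in sorted(per_subject.items()):
        test = binomtest(res.n_correct_total, res.n_test_total, CHANCE, alternative="greater")
        (kept if test.pvalue <= alpha else excluded).append(sub)
    return kept, excluded


def _delta_sets(df: pd.DataFrame) -> dict[str, frozenset]:
    out = {}
    for exp, sub in df[~df["within"]].groupby("experiment"):
        out[exp] = frozenset(sub["delta"].round(6))
    return out


def pool_experiments(
    subject_means: pd.DataFrame,
    pooling: dict[str, tuple[str, ...]] | None = None,
) -> dict[tuple, np.ndarray]:
    """Pool per-subject condition means across experiments.

    ``subject_means`` is tidy with columns (subject, experiment, roi,
    delta, within, train_shift, mode, accuracy).  Experiments inside one
    pool must share identical cross-shift delta sets (pooling e.g. a
    2-degree with a 3-degree design would mix incomparable conditions).
    Returns ``{(roi, delta, mode): subject-mean array}`` for the reported
    conditions: delta 0 from the unshifted within-condition CV (pooled over
    every experiment), cross-shift deltas from all experiments that tested
    them.
    """
    df = subject_means
    if pooling is not None:
        sets = _delta_sets(df)
        for name, exps in pooling.items():
            present = [e for e in exps if e in sets]
            if len({sets[e] for e in present}) > 1:
                raise ValueError(
                    f"pool '{name}' mixes experiments with different shift deltas: "
                    f"{ {e: sorted(sets[e]) for e in present} }"
                )
    reported = df[(df["within"] & (df["train_shift"] == 0)) | (~df["within"])]
    out: dict[tuple, np.ndarray] = {}
    for (roi, delta, mode), sub in reported.groupby(["roi", "delta", "mode"]):
        sub = sub.sort_values("subject")
        out[(roi, float(delta), mode)] = sub["accuracy"].to_numpy()
    return out


def group_table(
    pooled: dict[tuple, np.ndarray],
    B: int = 1000,
    coverage: float = 0.95,
    seed=None,
) -> pd.DataFrame:
    """Bootstrap every pooled condition into a results table.

    Columns mirror the reporting format: accuracies in percent, CI offsets
    as fractions, a significance flag, and the contributing sample size.
    Deterministic in ``seed`` and invariant to dict ordering.
    """
    rows = []
    for i, key in enumerate(sorted(pooled)):
        roi, delta, mode = key
        # sub-seed by rank in the sorted condition list: stable across runs
        sub_seed = None if seed is None else np.random.SeedSequence((int(seed), i))
        gi = bootstrap_group(pooled[key], B=B, coverage=coverage, seed=sub_seed, condition=key)
        rows.append(
            {
                "roi": roi,
                "delta_deg": delta,
                "mode": mode,
                "group_mean_pct": 100 * gi.group_mean,
                "ci_lower_offset": gi.ci_offsets[0],
                "ci_upper_offset": gi.ci_offsets[1],
                "significant_vs_chance": gi.significant_vs_chance,
                "ci_excludes_chance": gi.ci_excludes_chance,
                "n_subjects": gi.n_subjects,
            }
        )
    return pd.DataFrame(rows)
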