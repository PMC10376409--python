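"""Localiser-based ROI selection.

The non-stimulated "feedback" ROI is the set of voxels responding to the
target checkerboard (the cortical representation of the occluded image
quadrant) more than to the near surround checkerboard, with voxels that
respond to either surround checkerboard excluded to minimise lateral
spillover.  The stimulated "feedforward+" ROI is the conjunction of voxels
responding to every one of the six image conditions against the fixation
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import canonical_hrf, dct_highpass_basis, DEFAULT_HIGHPASS_HZ
from .simulate import SimulatedSession
from . import glm as _glm

__all__ = [
    "ROIMask",
    "ConditionGLM",
    "fit_condition_glm",
    "contrast_t",
    "select_feedback_roi",
    "select_feedforward_roi",
    "select_rois",
]

DEFAULT_T_THRESHOLD = 3.0
NEAR_SURROUND = "surround1"  # the ring adjacent to the target representation


@dataclass
class ROIMask:
    """Boolean voxel selection with provenance."""

    voxel_indices: np.ndarray
    source_contrast: str
    threshold: float

    def __post_init__(self) -> None:
        self.voxel_indices = np.unique(np.asarray(self.voxel_indices, dtype=int))

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    def __len__(self) -> int:
        return self.n_voxels


@dataclass
class ConditionGLM:
    """Condition-level OLS fit across concatenated runs.

    Holds everything needed for t-contrasts: coefficients (condition x
    voxel), the unscaled covariance factor ``(X'X)^-1`` restricted to the
    condition columns, per-voxel residual variance and residual degrees of
    freedom.  The implicit baseline is the unmodelled fixation periods.
    """

    conditions: list[str]
    coef: np.ndarray
    cov_factor: np.ndarray
    sigma2: np.ndarray
    dof: int

    def _contrast_vec(self, cond_a: str, cond_b: str | None) -> np.ndarray:
        c = np.zeros(len(self.conditions))
        try:
            c[self.conditions.index(cond_a)] = 1.0
            if cond_b is not None:
                c[self.conditions.index(cond_b)] -= 1.0
        except ValueError as err:
            raise KeyError(f"condition not in fit: {err}") from None
        return c

    def t_contrast(self, cond_a: str, cond_b: str | None = None) -> np.ndarray:
        """Per-voxel t statistic for ``cond_a - cond_b`` (baseline if None)."""
        c = self._contrast_vec(cond_a, cond_b)
        est = c @ self.coef
        se = np.sqrt(self.sigma2 * (c @ self.cov_factor @ c))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(se > 0, est / se, 0.0)


def fit_condition_glm(
    session: SimulatedSession,
    cutoff_hz: float | None = DEFAULT_HIGHPASS_HZ,
) -> ConditionGLM:
    """Fit one regressor per condition over all runs.

    Runs are concatenated; condition regressors are shared across runs while
    the intercept/trend/DCT confounds are run-specific, matching standard
    localiser practice.
    """
    runs, events = _glm.trim_dummy_volumes(session)
    tr = session.design.tr_s
    conditions = sorted(events["condition"].unique())
    hrf = canonical_hrf(tr)
    task_blocks, conf_blocks, data = [], [], []
    for r, ts in enumerate(runs):
        ev = events[events["run"] == r]
        n_vols = ts.shape[1]
        Xt = np.zeros((n_vols, len(conditions)))
        for j, cond in enumerate(conditions):
            u = np.zeros(n_vols)
            for _, row in ev[ev["condition"] == cond].iterrows():
                i0 = int(round(row["onset_s"] / tr))
                i1 = int(round((row["onset_s"] + row["duration_s"]) / tr))
                u[i0:i1] = 1.0
            Xt[:, j] = np.convolve(u, hrf)[:n_vols]
        t = np.arange(n_vols)
        conf = np.column_stack([np.ones(n_vols), (t - t.mean()) / n_vols])
        if cutoff_hz is not None:
            conf = np.column_stack([conf, dct_highpass_basis(n_vols, tr, cutoff_hz)])
        task_blocks.append(Xt)
        conf_blocks.append(conf)
        data.append(ts.T)
    n_runs = len(runs)
    X_task = np.vstack(task_blocks)
    n_conf = conf_blocks[0].shape[1]
    X_conf = np.zeros((X_task.shape[0], n_runs * n_conf))
    row = 0
    for r, conf in enumerate(conf_blocks):
        X_conf[row : row + conf.shape[0], r * n_conf : (r + 1) * n_conf] = conf
        row += conf.shape[0]
    X = np.column_stack([X_task, X_conf])
    Y = np.vstack(data)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    dof = X.shape[0] - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    k = len(conditions)
    return ConditionGLM(
        conditions=conditions,
        coef=coef[:k],
        cov_factor=xtx_inv[:k, :k],
        sigma2=sigma2,
        dof=dof,
    )


def contrast_t(fit: ConditionGLM, cond_a: str, cond_b: str | None = None) -> np.ndarray:
    """Per-voxel t statistic for the contrast ``cond_a > cond_b``.

    With ``cond_b=None`` the contrast is against the implicit fixation
    baseline.  Antisymmetric: ``contrast_t(f, a, b) == -contrast_t(f, b, a)``.
    """
    return fit.t_contrast(cond_a, cond_b)


def select_feedback_roi(
    fit: ConditionGLM,
    threshold: float = DEFAULT_T_THRESHOLD,
    near_surround: str = NEAR_SURROUND,
) -> ROIMask:
    """Voxels with target > near-surround, excluding surround responders.

    Selection: ``t(target - near_surround) > threshold`` minus any voxel
    whose response to either surround checkerboard versus baseline exceeds
    the same threshold.
    """
    t_sel = fit.t_contrast("target", near_surround)
    keep = t_sel > threshold
    for surround in ("surround1", "surround2"):
        if surround in fit.conditions:
            keep &= ~(fit.t_contrast(surround) > threshold)
    return ROIMask(
        np.flatnonzero(keep),
        source_contrast=f"target>{near_surround}, excl. surround responders",
        threshold=threshold,
    )


def select_feedforward_roi(
    fit: ConditionGLM,
    threshold: float = DEFAULT_T_THRESHOLD,
    image_conditions: list[str] | None = None,
    exclude_mapping_responders: bool = True,
) -> ROIMask:
    """Conjunction of responses to all six image conditions vs baseline.

    Voxels responding to any occluder-mapping checkerboard are excluded by
    default: the mapping stimuli localise the occluded quadrant's cortical
    representation, so responders sit in or around the non-stimulated
    region rather than in the directly stimulated cortex.  (The original
    analysis achieves this separation anatomically, via the contralateral
    hemisphere; this exclusion is the simulator's stand-in.)
    """
    if image_conditions is None:
        image_conditions = [c for c in fit.conditions if c.startswith("im")]
    if not image_conditions:
        raise ValueError("no image conditions in fit")
    keep = np.ones(fit.coef.shape[1], dtype=bool)
    for cond in image_conditions:
        keep &= fit.t_contrast(cond) > threshold
    if exclude_mapping_responders:
        for cond in ("target", "surround1", "surround2"):
            if cond in fit.conditions:
                keep &= ~(fit.t_contrast(cond) > threshold)
    return ROIMask(
        np.flatnonzero(keep),
        source_contrast="conjunction: all image conditions > baseline, excl. mapping responders",
        threshold=threshold,
    )


def select_rois(
    session: SimulatedSession,
    threshold: float = DEFAULT_T_THRESHOLD,
    use_ground_truth: bool = False,
) -> dict[str, ROIMask]:
    """Feedback + feedforward masks for one session.

    With ``use_ground_truth`` the generator's known voxel populations are
    returned instead of the localiser estimate (useful for null
    calibrations where no localiser signal is simulated).
    """
    if use_ground_truth:
        return {
            roi: ROIMask(session.rois[roi], source_contrast="ground truth", threshold=np.nan)
            for roi in ("feedback", "feedforward")
        }
    fit = fit_condition_glm(session)
    return {
        "feedback": select_feedback_roi(fit, threshold),
        "feedforward": select_feedforward_roi(fit, threshold),
    }
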