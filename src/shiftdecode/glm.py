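"""Single-trial design matrices, temporal filtering and OLS beta estimation.

The estimation model mirrors a standard block-design beta-series analysis:
one boxcar regressor per trial convolved with the canonical double-gamma
HRF, confounds consisting of an intercept, a linear trend and a
discrete-cosine high-pass set (cutoff 0.006 Hz), and ordinary least squares
per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import qr as _pivoted_qr
from scipy.stats import gamma as gamma_dist

from .simulate import SimulatedSession, parse_condition

__all__ = [
    "DesignMatrix",
    "TrialBetaMatrix",
    "canonical_hrf",
    "dct_highpass_basis",
    "highpass_and_detrend",
    "build_single_trial_design",
    "estimate_betas",
    "single_trial_betas",
    "trim_dummy_volumes",
]

DEFAULT_HIGHPASS_HZ = 0.006


def canonical_hrf(
    tr_s: float,
    duration_s: float = 32.0,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at the TR, normalised to peak 1.

    Difference of two unit-dispersion gamma densities whose modes sit at
    ``peak_delay_s`` and ``undershoot_delay_s`` (a gamma with shape k and
    scale 1 peaks at k - 1); the undershoot is attenuated by
    ``undershoot_ratio``.  ``h(0) = 0`` and the kernel spans at least 30 s.
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    t = np.arange(0.0, max(duration_s, 30.0) + tr_s / 2, tr_s)
    h = (
        gamma_dist.pdf(t, peak_delay_s + 1.0)
        - gamma_dist.pdf(t, undershoot_delay_s + 1.0) / undershoot_ratio
    )
    return h / h.max()


def dct_highpass_basis(n_vols: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine regressors spanning frequencies below ``cutoff_hz``.

    Component ``k`` has frequency ``k / (2 n TR)``; all components with
    frequency strictly below the cutoff are returned (possibly zero
    columns).  The constant term is excluded.
    """
    if cutoff_hz >= 0.5 / tr_s:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist {0.5 / tr_s} Hz")
    k_max = int(np.floor(2 * n_vols * tr_s * cutoff_hz))
    t = np.arange(n_vols)
    cols = [np.cos(np.pi * k * (t + 0.5) / n_vols) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_vols, 0))


def highpass_and_detrend(
    ts: np.ndarray,
    tr_s: float = 1.0,
    cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    keep_mean: bool = True,
) -> np.ndarray:
    """Remove the linear trend and frequency content below ``cutoff_hz``.

    Implemented as least-squares projection of each voxel time course
    (``ts`` is voxel x time) onto the complement of an intercept + linear
    trend + discrete-cosine nuisance space.  With ``keep_mean`` the voxel
    mean is added back after projection.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n = ts.shape[1]
    if n < 2:
        raise ValueError("need at least 2 time points")
    t = np.arange(n)
    nuis = np.column_stack(
        [np.ones(n), t - t.mean(), dct_highpass_basis(n, tr_s, cutoff_hz)]
    )
    coef, *_ = np.linalg.lstsq(nuis, ts.T, rcond=None)
    clean = ts - (nuis @ coef).T
    if keep_mean:
        clean += ts.mean(axis=1, keepdims=True)
    return clean


@dataclass
class DesignMatrix:
    """Time x regressor matrix with one task column per trial."""

    matrix: np.ndarray
    task_labels: list[str]
    confound_labels: list[str]
    tr_s: float

    @property
    def n_task(self) -> int:
        return len(self.task_labels)

    @property
    def labels(self) -> list[str]:
        return self.task_labels + self.confound_labels


@dataclass
class TrialBetaMatrix:
    """Trial x voxel single-trial amplitude estimates with aligned labels.

    ``labels`` carries one row per beta row: run, condition, onset_s and the
    parsed scene / shift (NaN for mapping trials).
    """

    betas: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.labels):
            raise ValueError("betas and labels disagree on trial count")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def image_trials(self) -> "TrialBetaMatrix":
        keep = (self.labels["kind"] == "image").to_numpy()
        return TrialBetaMatrix(self.betas[keep], self.labels.loc[keep].reset_index(drop=True))


def build_single_trial_design(
    events: pd.DataFrame,
    n_vols: int,
    tr_s: float,
    hrf: np.ndarray | None = None,
    cutoff_hz: float | None = DEFAULT_HIGHPASS_HZ,
) -> DesignMatrix:
    """One HRF-convolved boxcar regressor per trial, plus confounds.

    ``events`` needs columns ``onset_s``, ``duration_s``, ``condition`` for
    a single run; onsets are on the (already trimmed) acquisition axis.
    Confounds: intercept, linear trend, and a DCT high-pass set when
    ``cutoff_hz`` is given.
    """
    if len(events) and (events["onset_s"] + events["duration_s"]).max() > n_vols * tr_s + 1e-9:
        raise ValueError("events extend past the end of the run")
    onsets = events["onset_s"].to_numpy() if len(events) else np.empty(0)
    if len(np.unique(onsets)) != len(onsets):
        raise ValueError("trials with identical onsets are not identifiable")
    if hrf is None:
        hrf = canonical_hrf(tr_s)
    cols, labels = [], []
    for i, row in events.reset_index(drop=True).iterrows():
        u = np.zeros(n_vols)
        i0 = int(round(row["onset_s"] / tr_s))
        i1 = int(round((row["onset_s"] + row["duration_s"]) / tr_s))
        u[i0:i1] = 1.0
        cols.append(np.convolve(u, hrf)[:n_vols])
        labels.append(f"trial{i:03d}_{row['condition']}")
    t = np.arange(n_vols)
    conf = [np.ones(n_vols), (t - t.mean()) / n_vols]
    conf_labels = ["intercept", "trend"]
    if cutoff_hz is not None:
        dct = dct_highpass_basis(n_vols, tr_s, cutoff_hz)
        conf.extend(dct.T)
        conf_labels.extend(f"dct{k + 1:02d}" for k in range(dct.shape[1]))
    matrix = np.column_stack(cols + conf) if cols else np.column_stack(conf)
    return DesignMatrix(matrix, labels, conf_labels, tr_s)


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the culprits via pivoted QR
        _, _, piv = _pivoted_qr(X, mode="economic", pivoting=True)
        bad = [labels[j] for j in piv[rank:]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}"
        )


def estimate_betas(ts: np.ndarray, X: DesignMatrix, events: pd.DataFrame | None = None) -> TrialBetaMatrix:
    """Per-voxel OLS fit of a single-trial design.

    ``ts`` is voxel x time.  Returns only the task (trial) rows of the
    coefficient matrix; the residuals are orthogonal to every design column.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if ts.shape[1] != X.matrix.shape[0]:
        raise ValueError(
            f"time axis mismatch: data has {ts.shape[1]} volumes, design {X.matrix.shape[0]}"
        )
    _check_rank(X.matrix, X.labels)
    coef, *_ = np.linalg.lstsq(X.matrix, ts.T, rcond=None)
    betas = coef[: X.n_task].T  # voxel x trial -> transpose below
    if events is not None:
        labels = events.reset_index(drop=True).copy()
    else:
        conds = [lbl.split("_", 1)[1] for lbl in X.task_labels]
        labels = pd.DataFrame({"condition": conds})
    parsed = [parse_condition(c) for c in labels["condition"]]
    labels["kind"] = [p[0] for p in parsed]
    labels["scene"] = [p[1] for p in parsed]
    labels["shift_deg"] = [p[2] for p in parsed]
    return TrialBetaMatrix(betas.T, labels)


def trim_dummy_volumes(session: SimulatedSession) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Drop the initial dummy volumes and shift onsets accordingly."""
    nd = session.n_dummy
    tr = session.design.tr_s
    runs = [r[:, nd:] for r in session.runs]
    events = session.events.copy()
    events["onset_s"] = events["onset_s"] - nd * tr
    if (events["onset_s"] < -1e-9).any():
        raise ValueError("an event starts inside the discarded dummy volumes")
    return runs, events


def single_trial_betas(
    session: SimulatedSession,
    cutoff_hz: float | None = DEFAULT_HIGHPASS_HZ,
) -> TrialBetaMatrix:
    """Run-wise single-trial GLM for a whole session.

    The first dummy volumes of each run are discarded, each run is fitted
    with its own design (trial regressors + intercept/trend/DCT confounds),
    and the per-run beta matrices are stacked in acquisition order.
    """
    runs, events = trim_dummy_volumes(session)
    tr = session.design.tr_s
    blocks, frames = [], []
    for r, ts in enumerate(runs):
        ev = events[events["run"] == r].reset_index(drop=True)
        X = build_single_trial_design(ev, ts.shape[1], tr, cutoff_hz=cutoff_hz)
        bm = estimate_betas(ts, X, events=ev)
        blocks.append(bm.betas)
        frames.append(bm.labels)
    return TrialBetaMatrix(np.vstack(blocks), pd.concat(frames, ignore_index=True))
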