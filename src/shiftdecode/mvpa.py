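"""Linear-SVM scene decoding with leave-one-run-out cross-classification.

A linear support vector machine is trained to discriminate the two scenes
from single-trial beta patterns at one spatial shift and tested — on
single trials (ST) or on the per-condition average of the held-out run's
trials (AB) — at the same or a different shift.  The shift difference
``delta = |train - test|`` indexes the generalisation distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .glm import TrialBetaMatrix
from .roi import ROIMask
from .simulate import ExperimentDesign

__all__ = [
    "DecodingSpec",
    "DecodingResult",
    "FittedDecoder",
    "train_linear_svm",
    "loro_crossclassify",
    "shift_profile",
    "results_to_frame",
]

MODES = ("ST", "AB")


@dataclass(frozen=True)
class DecodingSpec:
    """One decoding condition: ROI, train/test shifts and test mode."""

    roi: str
    train_shift: float
    test_shift: float
    mode: str = "ST"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @property
    def delta(self) -> float:
        return abs(self.train_shift - self.test_shift)

    @property
    def within(self) -> bool:
        return self.train_shift == self.test_shift


@dataclass
class DecodingResult:
    """Per-fold accuracies for one subject and decoding condition."""

    spec: DecodingSpec
    fold_accuracies: list[float]
    fold_n_test: list[int]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.fold_accuracies):
            raise ValueError("fold accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def n_correct_total(self) -> int:
        return int(round(sum(a * n for a, n in zip(self.fold_accuracies, self.fold_n_test))))

    @property
    def n_test_total(self) -> int:
        return int(sum(self.fold_n_test))


class FittedDecoder:
    """Linear SVM with training-fold z-scoring baked in.

    Decision-boundary ties are broken toward the lower class label so that
    predictions are deterministic.
    """

    def __init__(self, svc: SVC, mean: np.ndarray, sd: np.ndarray, classes: np.ndarray):
        self._svc = svc
        self._mean = mean
        self._sd = sd
        self.classes_ = classes

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self._mean) / self._sd
        return self._svc.decision_function(Z)

    def predict(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_function(X)
        return np.where(d > 0, self.classes_[1], self.classes_[0])


def train_linear_svm(
    train_betas: np.ndarray, labels, C: float = 1.0, standardize: bool = True
) -> FittedDecoder:
    """Fit a linear SVM on z-scored features.

    Feature means and SDs are computed on the training set only and are
    applied unchanged at test time (no leakage).  Constant features get
    unit scale.  ``standardize=False`` fits in the raw feature space
    (useful when comparing against geometric margin solvers).
    """
    X = np.atleast_2d(np.asarray(train_betas, dtype=float))
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    if X.shape[1] == 0:
        raise ValueError("empty feature set (no voxels selected)")
    if standardize:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mean = np.zeros(X.shape[1])
        sd = np.ones(X.shape[1])
    svc = SVC(kernel="linear", C=C)
    svc.fit((X - mean) / sd, y)
    return FittedDecoder(svc, mean, sd, classes)


def _fold_sets(labels: pd.DataFrame, run: int, shift: float, train: bool) -> np.ndarray:
    m = (labels["kind"] == "image") & np.isclose(labels["shift_deg"].astype(float), shift)
    m &= (labels["run"] != run) if train else (labels["run"] == run)
    return m.to_numpy()


def _score_direction(
    betas: np.ndarray,
    labels: pd.DataFrame,
    run: int,
    train_shift: float,
    test_shift: float,
    C: float,
) -> dict[str, tuple[float, int]]:
    """Train once on one fold/direction; score both ST and AB test modes."""
    tr = _fold_sets(labels, run, train_shift, train=True)
    te = _fold_sets(labels, run, test_shift, train=False)
    if tr.sum() == 0 or te.sum() == 0:
        raise ValueError(
            f"no trials for fold: run {run}, train shift {train_shift}, test shift {test_shift}"
        )
    clf = train_linear_svm(betas[tr], labels.loc[tr, "scene"].to_numpy().astype(int), C=C)
    X_te = betas[te]
    y_te = labels.loc[te, "scene"].to_numpy().astype(int)
    scenes = np.unique(y_te)
    X_ab = np.vstack([X_te[y_te == s].mean(axis=0) for s in scenes])
    return {
        "ST": (float(np.mean(clf.predict(X_te) == y_te)), len(y_te)),
        "AB": (float(np.mean(clf.predict(X_ab) == scenes)), len(scenes)),
    }


def loro_crossclassify(
    betas: TrialBetaMatrix,
    spec: DecodingSpec,
    roi_mask: ROIMask | np.ndarray | None = None,
    C: float = 1.0,
    subject_id: str = "",
) -> DecodingResult:
    """Leave-one-run-out (cross-)classification for one decoding condition.

    Per fold, the classifier is trained on the ``train_shift`` trials of the
    remaining runs and tested on the ``test_shift`` trials of the held-out
    run.  For cross-shift conditions the fold accuracy is the average of
    the two train/test directions, since the analysis reports a single
    number per shift difference.
    """
    both = _crossclassify_both(
        betas, spec.roi, spec.train_shift, spec.test_shift, roi_mask, C, subject_id
    )
    return both[spec.mode]


def _crossclassify_both(
    betas: TrialBetaMatrix,
    roi: str,
    train_shift: float,
    test_shift: float,
    roi_mask,
    C: float,
    subject_id: str,
) -> dict[str, DecodingResult]:
    """ST and AB results for one train/test shift pair, sharing SVM fits."""
    mat = betas.betas
    if roi_mask is not None:
        idx = roi_mask.voxel_indices if isinstance(roi_mask, ROIMask) else np.asarray(roi_mask)
        if len(idx) == 0:
            raise ValueError(f"empty ROI mask for {roi}")
        mat = mat[:, idx]
    labels = betas.labels
    runs = sorted(labels["run"].unique())
    accs = {m: [] for m in MODES}
    ns = {m: [] for m in MODES}
    within = train_shift == test_shift
    for run in runs:
        fwd = _score_direction(mat, labels, run, train_shift, test_shift, C)
        if within:
            for m in MODES:
                accs[m].append(fwd[m][0])
                ns[m].append(fwd[m][1])
        else:
            rev = _score_direction(mat, labels, run, test_shift, train_shift, C)
            for m in MODES:
                accs[m].append(0.5 * (fwd[m][0] + rev[m][0]))
                ns[m].append(fwd[m][1] + rev[m][1])
    return {
        m: DecodingResult(
            DecodingSpec(roi, train_shift, test_shift, m), accs[m], ns[m], subject_id=subject_id
        )
        for m in MODES
    }


def shift_profile(
    betas: TrialBetaMatrix,
    rois: dict[str, ROIMask],
    design: ExperimentDesign,
    modes: tuple[str, ...] = MODES,
    C: float = 1.0,
    subject_id: str = "",
    include_within_shifted: bool = True,
) -> list[DecodingResult]:
    """All decoding conditions of one subject.

    For a shift set {0, a, b} the cross-classification pairs are 0<->a,
    a<->b and 0<->b (deltas a, b - a and b) plus the within-condition CV of
    the unshifted images (delta 0).  Within-condition CV of the shifted
    conditions is computed too (flagged by ``train_shift == test_shift``)
    but reported separately downstream.
    """
    for name, mask in rois.items():
        if len(mask) == 0:
            raise ValueError(f"ROI '{name}' is empty; cannot decode")
    shifts = sorted(design.shift_levels_deg)
    pairs = [(shifts[0], shifts[0])]
    pairs += [(s1, s2) for i, s1 in enumerate(shifts) for s2 in shifts[i + 1 :]]
    if include_within_shifted:
        pairs += [(s, s) for s in shifts[1:]]
    results = []
    for roi_name, mask in rois.items():
        for s1, s2 in pairs:
            both = _crossclassify_both(betas, roi_name, s1, s2, mask, C, subject_id)
            results.extend(both[m] for m in modes)
    return results


def results_to_frame(
    results: list[DecodingResult],
    subject_id: str | None = None,
    experiment: str = "",
) -> pd.DataFrame:
    """Tidy long-format table: one row per fold."""
    rows = []
    for res in results:
        for fold, (acc, n) in enumerate(zip(res.fold_accuracies, res.fold_n_test)):
            rows.append(
                {
                    "subject": subject_id or res.subject_id,
                    "experiment": experiment,
                    "roi": res.spec.roi,
                    "train_shift": res.spec.train_shift,
                    "test_shift": res.spec.test_shift,
                    "delta": res.spec.delta,
                    "within": res.spec.within,
                    "mode": res.spec.mode,
                    "fold": fold,
                    "accuracy": acc,
                    "n_test": n,
                }
            )
    return pd.DataFrame(rows)
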