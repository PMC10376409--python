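"""Synthetic multi-run BOLD datasets with controlled cross-shift pattern similarity.

The generator emulates the statistical structure of an occluder fMRI
experiment: each subject sees two natural scenes at three spatial shifts
(six image conditions) plus three checkerboard mapping conditions, in four
runs of 12 s block trials at TR = 1 s.  Scene-specific multivoxel patterns
are drawn so that the expected correlation between the patterns of the same
scene at shifts ``s1`` and ``s2`` equals a Gaussian similarity kernel
``rho(|s1 - s2|) = exp(-delta^2 / (2 sigma^2))`` — the generator's
operationalisation of the spatial precision of the contextual signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.signal import lfilter

__all__ = [
    "TuningModel",
    "ExperimentDesign",
    "NoiseModel",
    "VoxelLayout",
    "SimulatedSession",
    "make_patterns",
    "simulate_timeseries",
    "simulate_cohort",
    "derive_seed",
    "image_condition",
    "parse_condition",
    "MAPPING_CONDITIONS",
    "DEFAULT_SHIFT_SETS",
    "DEFAULT_COHORT_SIZES",
]

MAPPING_CONDITIONS = ("target", "surround1", "surround2")

#: Shift triplets of the four experiments: {0, 2, 8} deg for experiments one
#: and two, {0, 3, 7} deg for experiments three and four.
DEFAULT_SHIFT_SETS = ((0.0, 2.0, 8.0), (0.0, 2.0, 8.0), (0.0, 3.0, 7.0), (0.0, 3.0, 7.0))

#: Analysed cohort: 8 + 7 + 6 + 5 = 26 subjects after QC exclusions.
DEFAULT_COHORT_SIZES = (8, 7, 6, 5)

# Mean block response amplitude (BOLD units) of each ground-truth voxel
# population to each class of condition.  The feedback ROI responds to the
# target checkerboard (that is how it is localised) and carries only a weak
# mean image response on top of the scene-specific pattern; the feedforward
# ROI responds to every image condition; surround voxels respond to their
# checkerboards and non-specifically to the image edge.
MEAN_AMPLITUDE = {
    "feedback": {"target": 1.0, "image": 0.3},
    "feedforward": {"image": 1.0},
    "surround": {"surround1": 1.0, "surround2": 1.0, "image": 0.5},
    "noise": {},
}


def image_condition(scene: int, shift_deg: float) -> str:
    """Canonical label for scene ``scene`` displaced by ``shift_deg``."""
    return f"im{scene}_s{shift_deg:g}"


def parse_condition(label: str) -> tuple[str, int | None, float | None]:
    """Split a condition label into ``(kind, scene, shift_deg)``.

    ``kind`` is ``"image"`` or ``"mapping"``; scene/shift are ``None`` for
    mapping conditions.
    """
    if label in MAPPING_CONDITIONS:
        return "mapping", None, None
    stem, _, shift = label.partition("_s")
    return "image", int(stem.removeprefix("im")), float(shift)


def derive_seed(master_seed: int, *keys: int) -> SeedSequence:
    """Deterministic sub-seed: master seed followed by integer stage keys.

    Every stochastic stage draws from ``SeedSequence((master, k1, k2, ...))``
    so that any stage can be regenerated independently of execution order.
    """
    return SeedSequence((int(master_seed),) + tuple(int(k) for k in keys))


@dataclass(frozen=True)
class TuningModel:
    """Spatial tuning of the fed-back scene pattern.

    Parameters
    ----------
    sigma_deg:
        Width (degrees of visual angle) of the Gaussian similarity kernel
        ``rho(delta) = exp(-delta^2 / (2 sigma_deg^2))``.  Must be > 0.
    snr:
        Scene-pattern amplitude in the feedback ROI relative to the noise
        standard deviation (dimensionless, >= 0).
    feedforward_gain:
        Multiplier on ``snr`` for the feedforward ROI, whose stimulated
        patterns are far more decodable than the fed-back ones.
    """

    sigma_deg: float
    snr: float
    feedforward_gain: float = 3.0

    def __post_init__(self) -> None:
        if not self.sigma_deg > 0:
            raise ValueError(f"sigma_deg must be > 0, got {self.sigma_deg}")
        if self.snr < 0:
            raise ValueError(f"snr must be >= 0, got {self.snr}")
        if self.feedforward_gain < 0:
            raise ValueError("feedforward_gain must be >= 0")

    def rho(self, delta_deg) -> np.ndarray | float:
        """Similarity kernel value at shift difference ``delta_deg``."""
        d = np.asarray(delta_deg, dtype=float)
        out = np.exp(-(d**2) / (2.0 * self.sigma_deg**2))
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExperimentDesign:
    """Block-design timing of one experiment.

    Defaults give 12 s trials (30 flashes of 200 ms on / 200 ms off), six
    randomised 72 s sequences of the six image conditions per run, one
    mapping sequence, 12 s fixation between sequences, TR = 1 s, four runs.
    """

    shift_levels_deg: tuple[float, ...] = (0.0, 2.0, 8.0)
    n_runs: int = 4
    sequences_per_run: int = 6
    trial_duration_s: float = 12.0
    n_flashes: int = 30
    flash_on_ms: float = 200.0
    flash_off_ms: float = 200.0
    fixation_s: float = 12.0
    tr_s: float = 1.0
    n_images: int = 2
    mapping_conditions: tuple[str, ...] = MAPPING_CONDITIONS
    mapping_repeats: int = 2
    n_dummy: int = 2

    def __post_init__(self) -> None:
        flicker_s = self.n_flashes * (self.flash_on_ms + self.flash_off_ms) / 1000.0
        if not math.isclose(self.trial_duration_s, flicker_s):
            raise ValueError(
                f"trial_duration_s ({self.trial_duration_s}) inconsistent with "
                f"{self.n_flashes} x ({self.flash_on_ms}+{self.flash_off_ms}) ms "
                f"= {flicker_s} s of flicker"
            )
        if len(set(self.shift_levels_deg)) != len(self.shift_levels_deg):
            raise ValueError("shift levels must be distinct")
        if any(s < 0 for s in self.shift_levels_deg):
            raise ValueError("shift levels must be non-negative")
        if self.n_runs < 1 or self.sequences_per_run < 1 or self.n_images < 1:
            raise ValueError("counts must be positive")

    @property
    def n_shifts(self) -> int:
        return len(self.shift_levels_deg)

    @property
    def image_conditions(self) -> tuple[str, ...]:
        return tuple(
            image_condition(i + 1, s)
            for i in range(self.n_images)
            for s in self.shift_levels_deg
        )

    @property
    def sequence_duration_s(self) -> float:
        """One image sequence: every image condition once (72 s by default)."""
        return self.n_images * self.n_shifts * self.trial_duration_s

    @property
    def mapping_sequence_duration_s(self) -> float:
        return self.mapping_repeats * len(self.mapping_conditions) * self.trial_duration_s

    @property
    def run_duration_s(self) -> float:
        """Task duration of one run, dummy volumes excluded."""
        n_seq = self.sequences_per_run
        return (
            self.fixation_s * (n_seq + 2)
            + n_seq * self.sequence_duration_s
            + self.mapping_sequence_duration_s
        )

    @property
    def n_volumes(self) -> int:
        """Volumes generated per run, including the discarded dummies."""
        return int(round((self.run_duration_s + self.n_dummy * self.tr_s) / self.tr_s))


@dataclass(frozen=True)
class NoiseModel:
    """Stationary AR(1) scanner noise plus slow drift and trial jitter.

    ``noise_sd`` is the stationary standard deviation (BOLD units) of the
    AR(1) process with lag-1 autocorrelation ``ar1_coef``; ``drift_amp``
    scales per-voxel linear + half-cosine drift; ``trial_jitter_sd`` is the
    SD of a per-trial scalar amplitude fluctuation shared across voxels.
    """

    ar1_coef: float = 0.3
    noise_sd: float = 1.0
    drift_amp: float = 0.5
    trial_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.trial_jitter_sd < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class VoxelLayout:
    """Ground-truth voxel populations of the simulated slab."""

    feedback: int = 150
    feedforward: int = 150
    surround: int = 150
    noise: int = 150

    def __post_init__(self) -> None:
        if min(self.feedback, self.feedforward) < 2:
            raise ValueError("decoded ROIs need at least 2 voxels")
        if min(self.surround, self.noise) < 0:
            raise ValueError("voxel counts must be non-negative")

    @property
    def total(self) -> int:
        return self.feedback + self.feedforward + self.surround + self.noise

    def indices(self) -> dict[str, np.ndarray]:
        out, start = {}, 0
        for name in ("feedback", "feedforward", "surround", "noise"):
            n = getattr(self, name)
            out[name] = np.arange(start, start + n)
            start += n
        return out


@dataclass
class SimulatedSession:
    """One subject's simulated acquisition.

    ``runs`` are voxel x time matrices (dummy volumes included); ``events``
    holds (run, onset_s, duration_s, condition) with onsets on the full,
    untrimmed time axis of each run.
    """

    runs: list[np.ndarray]
    events: pd.DataFrame
    rois: dict[str, np.ndarray]
    truth: dict
    design: ExperimentDesign
    seed: int
    subject_id: str = "sub-01"
    experiment: str = "exp1"

    @property
    def n_voxels(self) -> int:
        return self.runs[0].shape[0]

    @property
    def n_dummy(self) -> int:
        return self.design.n_dummy


def _kernel_cholesky(shifts: np.ndarray, tuning: TuningModel) -> np.ndarray:
    """Cholesky factor of the shift-level similarity kernel matrix."""
    K = tuning.rho(np.abs(shifts[:, None] - shifts[None, :]))
    K = np.asarray(K, dtype=float)
    # Gaussian kernel matrices are PSD; jitter guards near-singular cases
    # (e.g. two nearly identical shift levels).
    return np.linalg.cholesky(K + 1e-12 * np.eye(len(shifts)))


def make_patterns(
    n_voxels: int,
    n_images: int,
    shifts,
    tuning: TuningModel,
    seed,
) -> np.ndarray:
    """Draw scene patterns with Gaussian cross-shift similarity.

    Returns an ``(n_images, n_shifts, n_voxels)`` array of zero-mean,
    unit-variance voxel patterns.  For each image the shift-level patterns
    are jointly Gaussian with ``Cov[pattern(s1), pattern(s2)] =
    rho(|s1 - s2|)``, so the expected sample correlation between any two
    shifted versions of the same image equals the tuning kernel at their
    shift difference; patterns of different images are independent.
    """
    if n_voxels < 2:
        raise ValueError("n_voxels must be >= 2")
    shifts = np.asarray(shifts, dtype=float)
    if np.any(shifts < 0):
        raise ValueError("shifts must be non-negative")
    rng = default_rng(seed)
    L = _kernel_cholesky(shifts, tuning)
    z = rng.standard_normal((n_images, len(shifts), n_voxels))
    return L @ z


def _run_events(design: ExperimentDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Randomised trial order of one run (onsets include dummy volumes)."""
    rows = []
    t = design.n_dummy * design.tr_s + design.fixation_s
    for _ in range(design.sequences_per_run):
        for cond in rng.permutation(design.image_conditions):
            rows.append((t, design.trial_duration_s, str(cond)))
            t += design.trial_duration_s
        t += design.fixation_s
    mapping = list(design.mapping_conditions) * design.mapping_repeats
    for cond in rng.permutation(mapping):
        rows.append((t, design.trial_duration_s, str(cond)))
        t += design.trial_duration_s
    return pd.DataFrame(rows, columns=["onset_s", "duration_s", "condition"])


def _trial_amplitudes(
    events: pd.DataFrame,
    patterns: dict[str, np.ndarray],
    roi_idx: dict[str, np.ndarray],
    design: ExperimentDesign,
    tuning: TuningModel,
    noise: NoiseModel,
    n_voxels: int,
    rng: np.random.Generator,
    mean_amplitude: float = 1.0,
) -> np.ndarray:
    """Per-trial, per-voxel neural amplitude matrix (n_trials x n_voxels)."""
    shift_index = {s: j for j, s in enumerate(design.shift_levels_deg)}
    amps = np.zeros((len(events), n_voxels))
    jitter = rng.normal(0.0, noise.trial_jitter_sd, size=len(events))
    pattern_scale = {
        "feedback": tuning.snr * noise.noise_sd,
        "feedforward": tuning.snr * tuning.feedforward_gain * noise.noise_sd,
    }
    for t, cond in enumerate(events["condition"]):
        kind, scene, shift = parse_condition(cond)
        for roi, idx in roi_idx.items():
            if len(idx) == 0:
                continue
            means = MEAN_AMPLITUDE[roi]
            base = means.get("image", 0.0) if kind == "image" else means.get(cond, 0.0)
            base *= mean_amplitude
            a = np.full(len(idx), base + jitter[t])
            if kind == "image" and roi in patterns:
                a += pattern_scale[roi] * patterns[roi][scene - 1, shift_index[shift]]
            amps[t, idx] = a
    return amps


def _ar1_noise(
    shape: tuple[int, int], noise: NoiseModel, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) noise, time on the first axis."""
    if noise.noise_sd == 0:
        return np.zeros(shape)
    phi = noise.ar1_coef
    innov_sd = noise.noise_sd * math.sqrt(1.0 - phi**2)
    eps = rng.normal(0.0, innov_sd, size=shape)
    x = lfilter([1.0], [1.0, -phi], eps, axis=0)
    # stationary start: add the decayed contribution of a stationary draw
    x0 = rng.normal(0.0, noise.noise_sd, size=shape[1])
    decay = phi ** np.arange(1, shape[0] + 1)
    return x + decay[:, None] * x0[None, :]


def simulate_timeseries(
    design: ExperimentDesign,
    patterns: dict[str, np.ndarray],
    noise: NoiseModel,
    tuning: TuningModel,
    seed: int,
    layout: VoxelLayout | None = None,
    subject_id: str = "sub-01",
    experiment: str = "exp1",
    mean_amplitude: float = 1.0,
) -> SimulatedSession:
    """Simulate one subject's multi-run session.

    Each trial contributes a ``trial_duration_s`` boxcar convolved with the
    canonical double-gamma HRF, scaled per voxel by the condition's mean
    amplitude plus ``snr``-scaled scene pattern and trial jitter, summed
    with AR(1) noise and slow drift.  ``patterns`` maps ROI name
    (``feedback``/``feedforward``) to a pattern array from
    :func:`make_patterns` over ``design.shift_levels_deg``.
    """
    from .glm import canonical_hrf  # local import; glm does not import simulate

    layout = layout or VoxelLayout()
    for roi in ("feedback", "feedforward"):
        if roi in patterns:
            pat = patterns[roi]
            if pat.shape[:2] != (design.n_images, design.n_shifts):
                raise ValueError(
                    f"{roi} patterns cover {pat.shape[:2]} (images, shifts); design "
                    f"needs {(design.n_images, design.n_shifts)}"
                )
    roi_idx = layout.indices()
    n_vox = layout.total
    n_vols = design.n_volumes
    hrf = canonical_hrf(design.tr_s)
    master = derive_seed(seed, 0)
    run_rngs = [default_rng(derive_seed(seed, 1, r)) for r in range(design.n_runs)]
    order_rng = default_rng(master)

    local_patterns = {
        roi: patterns[roi][:, :, : len(roi_idx[roi])] for roi in patterns
    }
    # patterns are indexed within each ROI's local voxel block
    runs, ev_frames = [], []
    tvec = np.arange(n_vols) * design.tr_s
    for r, rng in enumerate(run_rngs):
        ev = _run_events(design, order_rng)
        if (ev["onset_s"] + ev["duration_s"]).max() > n_vols * design.tr_s:
            raise ValueError("events overrun the run duration")
        onsets = ev["onset_s"].to_numpy()
        if len(np.unique(onsets)) != len(onsets):
            raise ValueError("overlapping trials in generated design")
        amps = _trial_amplitudes(
            ev, local_patterns, roi_idx, design, tuning, noise, n_vox, rng,
            mean_amplitude=mean_amplitude,
        )
        X = np.zeros((n_vols, len(ev)))
        for t, (onset, dur) in enumerate(zip(onsets, ev["duration_s"])):
            u = np.zeros(n_vols)
            i0 = int(round(onset / design.tr_s))
            i1 = int(round((onset + dur) / design.tr_s))
            u[i0:i1] = 1.0
            X[:, t] = np.convolve(u, hrf)[:n_vols]
        signal = X @ amps  # time x voxel
        eta = _ar1_noise((n_vols, n_vox), noise, rng)
        if noise.drift_amp > 0:
            lin = np.linspace(-0.5, 0.5, n_vols)
            cos = np.cos(np.pi * tvec / tvec[-1])
            c = rng.normal(0.0, 1.0, size=(2, n_vox))
            drift = noise.drift_amp * (np.outer(lin, c[0]) + np.outer(cos, c[1]))
        else:
            drift = 0.0
        runs.append((signal + eta + drift).T)  # voxel x time
        ev = ev.copy()
        ev.insert(0, "run", r)
        ev_frames.append(ev)

    events = pd.concat(ev_frames, ignore_index=True)
    truth = {
        "patterns": {k: v.copy() for k, v in local_patterns.items()},
        "tuning": tuning,
        "noise": noise,
        "layout": layout,
    }
    return SimulatedSession(
        runs=runs,
        events=events,
        rois={k: v for k, v in roi_idx.items() if k != "noise"},
        truth=truth,
        design=design,
        seed=seed,
        subject_id=subject_id,
        experiment=experiment,
    )


def simulate_subject(
    design: ExperimentDesign,
    tuning: TuningModel,
    noise: NoiseModel,
    seed: int,
    layout: VoxelLayout | None = None,
    subject_id: str = "sub-01",
    experiment: str = "exp1",
    mean_amplitude: float = 1.0,
) -> SimulatedSession:
    """Convenience wrapper: draw patterns then simulate the session."""
    layout = layout or VoxelLayout()
    pat = {
        "feedback": make_patterns(
            layout.feedback, design.n_images, design.shift_levels_deg, tuning,
            derive_seed(seed, 2, 0),
        ),
        "feedforward": make_patterns(
            layout.feedforward, design.n_images, design.shift_levels_deg, tuning,
            derive_seed(seed, 2, 1),
        ),
    }
    return simulate_timeseries(
        design, pat, noise, tuning, seed,
        layout=layout, subject_id=subject_id, experiment=experiment,
        mean_amplitude=mean_amplitude,
    )


def simulate_cohort(
    n_subjects: int,
    experiments: list[ExperimentDesign],
    tuning: TuningModel,
    noise: NoiseModel,
    seed: int,
    cohort_sizes=None,
    layout: VoxelLayout | None = None,
) -> list[SimulatedSession]:
    """Simulate a multi-experiment cohort.

    Subjects are assigned to ``experiments`` according to ``cohort_sizes``
    (defaults to a near-even split); subject-level seeds derive
    deterministically from the master ``seed`` and the subject index, so a
    single subject can be regenerated in isolation.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    n_exp = len(experiments)
    if cohort_sizes is None:
        base = n_subjects // n_exp
        cohort_sizes = [base + (1 if i < n_subjects % n_exp else 0) for i in range(n_exp)]
    if len(cohort_sizes) != n_exp or sum(cohort_sizes) != n_subjects:
        raise ValueError("cohort_sizes must have one entry per experiment and sum to n_subjects")
    sessions = []
    s = 0
    for e, (design, size) in enumerate(zip(experiments, cohort_sizes)):
        for _ in range(size):
            sub_seed = int(derive_seed(seed, 3, s).generate_state(1)[0] % (2**31))
            sessions.append(
                simulate_subject(
                    design, tuning, noise, sub_seed,
                    layout=layout,
                    subject_id=f"sub-{s + 1:02d}",
                    experiment=f"exp{e + 1}",
                )
            )
            s += 1
    return sessions
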