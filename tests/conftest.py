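import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import shiftdecode as sd
from shiftdecode.glm import TrialBetaMatrix
from shiftdecode.simulate import image_condition, parse_condition

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design() -> sd.ExperimentDesign:
    """Reduced design (2 sequences/run) for fast unit tests."""
    return sd.ExperimentDesign(shift_levels_deg=(0.0, 2.0, 8.0), sequences_per_run=2)


@pytest.fixture(scope="session")
def small_design34() -> sd.ExperimentDesign:
    return sd.ExperimentDesign(shift_levels_deg=(0.0, 3.0, 7.0), sequences_per_run=2)


@pytest.fixture(scope="session")
def small_layout() -> sd.VoxelLayout:
    return sd.VoxelLayout(feedback=40, feedforward=40, surround=30, noise=30)


@pytest.fixture(scope="session")
def strong_tuning() -> sd.TuningModel:
    """High per-voxel snr: delta-0 decoding is essentially perfect."""
    return sd.TuningModel(sigma_deg=2.4, snr=0.3)


@pytest.fixture(scope="session")
def small_session(small_design, small_layout, strong_tuning) -> sd.SimulatedSession:
    return sd.simulate_subject(
        small_design, strong_tuning, sd.NoiseModel(), seed=42, layout=small_layout
    )


@pytest.fixture(scope="session")
def small_betas(small_session) -> TrialBetaMatrix:
    return sd.single_trial_betas(small_session)


@pytest.fixture(scope="session")
def toy_betas():
    """Factory for synthetic TrialBetaMatrix objects that bypass the BOLD
    simulation: trial betas are scene patterns plus iid Gaussian beta noise.

    Useful for decoder-level tests where the GLM stage is irrelevant.
    """

    def _make(
        tuning: sd.TuningModel,
        shifts=(0.0, 2.0, 8.0),
        n_runs: int = 4,
        trials_per_cond: int = 6,
        n_voxels: int = 60,
        amp: float = 1.0,
        beta_noise_sd: float = 1.0,
        seed: int = 0,
    ) -> TrialBetaMatrix:
        rng = np.random.default_rng(seed)
        patterns = sd.make_patterns(n_voxels, 2, shifts, tuning, rng)
        rows, mats = [], []
        for run in range(n_runs):
            for scene in (1, 2):
                for j, shift in enumerate(shifts):
                    for _ in range(trials_per_cond):
                        mats.append(
                            amp * patterns[scene - 1, j]
                            + beta_noise_sd * rng.standard_normal(n_voxels)
                        )
                        rows.append((run, image_condition(scene, shift)))
        labels = pd.DataFrame(rows, columns=["run", "condition"])
        parsed = [parse_condition(c) for c in labels["condition"]]
        labels["kind"] = [p[0] for p in parsed]
        labels["scene"] = [p[1] for p in parsed]
        labels["shift_deg"] = [p[2] for p in parsed]
        return TrialBetaMatrix(np.vstack(mats), labels)

    return _make
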