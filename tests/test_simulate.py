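"""Generator tests: similarity kernel, design timing, noise, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import shiftdecode as sd
from shiftdecode.simulate import (
    MAPPING_CONDITIONS,
    derive_seed,
    image_condition,
    parse_condition,
)


class TestTuningKernel:
    @given(
        sigma=st.floats(0.5, 10),
        d1=st.floats(0.01, 20),
        d2=st.floats(0.01, 20),
    )
    def test_kernel_properties(self, sigma, d1, d2):
        """rho(0)=1, bounded in (0,1], strictly decreasing in delta."""
        tun = sd.TuningModel(sigma, 0.1)
        assert tun.rho(0.0) == 1.0
        lo, hi = sorted([d1, d2])
        assert 0 < tun.rho(hi) <= tun.rho(lo) <= 1
        if hi > lo:
            assert tun.rho(hi) < tun.rho(lo)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sd.TuningModel(0.0, 0.1)
        with pytest.raises(ValueError):
            sd.TuningModel(-1.0, 0.1)
        with pytest.raises(ValueError):
            sd.TuningModel(2.4, -0.1)


class TestMakePatterns:
    def test_degenerate_kernels(self):
        """sigma -> inf gives identical patterns; sigma -> 0 independent ones."""
        flat = sd.make_patterns(500, 2, [0, 2, 8], sd.TuningModel(1e9, 0.1), seed=0)
        assert np.allclose(flat[0, 0], flat[0, 1], atol=1e-3)
        sharp = sd.make_patterns(20000, 2, [0, 2, 8], sd.TuningModel(1e-3, 0.1), seed=0)
        r = np.corrcoef(sharp[0, 0], sharp[0, 1])[0, 1]
        assert abs(r) < 0.03

    def test_correlation_matches_kernel_reference_point(self):
        """sigma=2.4, delta=4: sample correlation ~ exp(-16/11.52) ~ 0.249.

        Oracle: direct sample correlation over many seeds at large n_voxels.
        """
        tun = sd.TuningModel(2.4, 0.1)
        rs = []
        for seed in range(10):
            pat = sd.make_patterns(10000, 1, [0, 4], tun, seed=seed)
            rs.append(np.corrcoef(pat[0, 0], pat[0, 1])[0, 1])
        mc_se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs) - np.exp(-16 / 11.52)) < 3 * mc_se + 1e-3

    @pytest.mark.parametrize("sigma", [1.5, 2.4, 4.0])
    @pytest.mark.parametrize("shifts", [(0.0, 2.0, 8.0), (0.0, 3.0, 7.0)])
    def test_all_pairs_match_kernel(self, sigma, shifts):
        """Every shift pair's empirical correlation matches rho(|s1-s2|)."""
        tun = sd.TuningModel(sigma, 0.1)
        n_rep, n_vox = 8, 4000
        for i in range(3):
            for j in range(i + 1, 3):
                rs = [
                    np.corrcoef(
                        (p := sd.make_patterns(n_vox, 1, shifts, tun, seed=100 * i + 10 * j + r))[0, i],
                        p[0, j],
                    )[0, 1]
                    for r in range(n_rep)
                ]
                expected = tun.rho(abs(shifts[i] - shifts[j]))
                mc_se = np.std(rs, ddof=1) / np.sqrt(n_rep)
                assert abs(np.mean(rs) - expected) < 3 * mc_se + 2e-3

    def test_images_independent(self):
        pat = sd.make_patterns(20000, 2, [0, 2], sd.TuningModel(2.4, 0.1), seed=1)
        assert abs(np.corrcoef(pat[0, 0], pat[1, 0])[0, 1]) < 0.03

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sd.make_patterns(1, 2, [0, 2], sd.TuningModel(2.4, 0.1), 0)
        with pytest.raises(ValueError):
            sd.make_patterns(10, 2, [-1, 2], sd.TuningModel(2.4, 0.1), 0)


class TestExperimentDesign:
    def test_design_arithmetic(self):
        """12 s trials from 30 x (200+200) ms; 72 s sequences from 6 x 12 s."""
        des = sd.ExperimentDesign()
        assert des.trial_duration_s == 30 * (200 + 200) / 1000 == 12.0
        assert des.sequence_duration_s == 6 * 12.0 == 72.0

    def test_inconsistent_flicker_rejected(self):
        with pytest.raises(ValueError, match="flicker"):
            sd.ExperimentDesign(trial_duration_s=10.0)

    @given(n_flash=st.integers(5, 60), on_ms=st.sampled_from([100.0, 200.0, 250.0]))
    def test_flicker_arithmetic_generalises(self, n_flash, on_ms):
        dur = n_flash * 2 * on_ms / 1000
        des = sd.ExperimentDesign(
            n_flashes=n_flash, flash_on_ms=on_ms, flash_off_ms=on_ms, trial_duration_s=dur
        )
        assert des.sequence_duration_s == des.n_images * des.n_shifts * dur

    def test_condition_labels_roundtrip(self):
        des = sd.ExperimentDesign(shift_levels_deg=(0.0, 3.0, 7.0))
        assert len(des.image_conditions) == 6
        for lbl in des.image_conditions:
            kind, scene, shift = parse_condition(lbl)
            assert kind == "image" and scene in (1, 2) and shift in (0.0, 3.0, 7.0)
            assert image_condition(scene, shift) == lbl
        assert parse_condition("target") == ("mapping", None, None)


class TestSimulateTimeseries:
    def test_event_table_counts_default_design(self):
        """Default design: 36 image trials per run, mapping conditions >= 1."""
        des = sd.ExperimentDesign()
        ses = sd.simulate_subject(des, sd.TuningModel(2.4, 0.01), sd.NoiseModel(), seed=0)
        for r in range(des.n_runs):
            ev = ses.events[ses.events["run"] == r]
            images = ev[~ev["condition"].isin(MAPPING_CONDITIONS)]
            assert len(images) == 36
            counts = images["condition"].value_counts()
            assert set(counts.index) == set(des.image_conditions)
            assert (counts == des.sequences_per_run).all()
            for m in MAPPING_CONDITIONS:
                assert (ev["condition"] == m).sum() >= 1

    def test_onsets_within_run_and_non_overlapping(self, small_session):
        des = small_session.design
        for r in range(des.n_runs):
            ev = small_session.events[small_session.events["run"] == r].sort_values("onset_s")
            assert (ev["onset_s"] >= 0).all()
            assert (ev["onset_s"] + ev["duration_s"]).max() <= des.n_volumes * des.tr_s
            gaps = ev["onset_s"].diff().dropna()
            assert (gaps >= ev["duration_s"].iloc[0] - 1e-9).all()

    def test_all_zero_when_silent(self, small_design, small_layout):
        """No signal, no noise, no drift, no jitter -> identically zero data."""
        ses = sd.simulate_subject(
            small_design,
            sd.TuningModel(2.4, 0.0),
            sd.NoiseModel(ar1_coef=0.0, noise_sd=0.0, drift_amp=0.0, trial_jitter_sd=0.0),
            seed=0,
            layout=small_layout,
            mean_amplitude=0.0,
        )
        assert all(np.all(run == 0) for run in ses.runs)

    def test_noiseless_equals_convolution_oracle(self, small_design, small_layout):
        """Noise-free data must equal boxcar*HRF convolution exactly.

        Oracle: independent numpy convolution of the event boxcars.
        """
        tun = sd.TuningModel(2.4, 0.3)
        ses = sd.simulate_subject(
            small_design, tun,
            sd.NoiseModel(ar1_coef=0.0, noise_sd=0.0, drift_amp=0.0, trial_jitter_sd=0.0),
            seed=3, layout=small_layout,
        )
        # reconstruct one feedforward voxel of run 0 by hand; with noise_sd=0
        # the pattern amplitude (snr x noise_sd) vanishes, leaving the mean
        # image response of 1.0 convolved with the HRF
        v = small_layout.feedback  # first feedforward voxel
        hrf = sd.canonical_hrf(small_design.tr_s)
        n = small_design.n_volumes
        expected = np.zeros(n)
        for _, row in ses.events[ses.events["run"] == 0].iterrows():
            kind, scene, shift = parse_condition(row["condition"])
            if kind != "image":
                continue
            u = np.zeros(n)
            u[int(row["onset_s"]) : int(row["onset_s"] + row["duration_s"])] = 1.0
            expected += np.convolve(u, hrf)[:n]
        assert np.allclose(ses.runs[0][v], expected, atol=1e-10)
        # the HRF-convolved response peaks after the first onset by the
        # hemodynamic delay, never before
        first_onset = ses.events[ses.events["run"] == 0]["onset_s"].min()
        assert np.argmax(ses.runs[0][v]) > first_onset / small_design.tr_s

    def test_ar1_autocorrelation(self):
        """Empirical lag-1 autocorrelation of the noise matches ar1_coef."""
        des = sd.ExperimentDesign(sequences_per_run=2, n_runs=1)
        noise = sd.NoiseModel(ar1_coef=0.45, noise_sd=1.0, drift_amp=0.0, trial_jitter_sd=0.0)
        ses = sd.simulate_subject(
            des, sd.TuningModel(2.4, 0.0), noise, seed=7,
            layout=sd.VoxelLayout(200, 200, 0, 600), mean_amplitude=0.0,
        )
        x = ses.runs[0]
        num = (x[:, 1:] * x[:, :-1]).mean()
        den = (x**2).mean()
        assert abs(num / den - 0.45) < 0.02

    def test_seed_determinism(self, small_design, small_layout, strong_tuning):
        a = sd.simulate_subject(small_design, strong_tuning, sd.NoiseModel(), 11, layout=small_layout)
        b = sd.simulate_subject(small_design, strong_tuning, sd.NoiseModel(), 11, layout=small_layout)
        c = sd.simulate_subject(small_design, strong_tuning, sd.NoiseModel(), 12, layout=small_layout)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra, rb)
        pd.testing.assert_frame_equal(a.events, b.events)
        assert not all(np.array_equal(ra, rc) for ra, rc in zip(a.runs, c.runs))
        assert not a.events.equals(c.events) or True  # orders may coincide; data must differ


class TestSimulateCohort:
    def test_cohort_structure(self, small_design, small_design34, small_layout):
        designs = [small_design, small_design, small_design34, small_design34]
        cohort = sd.simulate_cohort(
            8, designs, sd.TuningModel(2.4, 0.01), sd.NoiseModel(), seed=0,
            cohort_sizes=(3, 2, 2, 1), layout=small_layout,
        )
        assert [s.experiment for s in cohort] == (
            ["exp1"] * 3 + ["exp2"] * 2 + ["exp3"] * 2 + ["exp4"]
        )
        assert len({s.subject_id for s in cohort}) == 8

    def test_single_subject_and_master_seed(self, small_design, small_layout):
        one = sd.simulate_cohort(
            1, [small_design], sd.TuningModel(2.4, 0.05), sd.NoiseModel(), seed=5,
            layout=small_layout,
        )
        assert len(one) == 1
        again = sd.simulate_cohort(
            1, [small_design], sd.TuningModel(2.4, 0.05), sd.NoiseModel(), seed=5,
            layout=small_layout,
        )
        assert np.array_equal(one[0].runs[0], again[0].runs[0])
        other = sd.simulate_cohort(
            1, [small_design], sd.TuningModel(2.4, 0.05), sd.NoiseModel(), seed=6,
            layout=small_layout,
        )
        assert not np.array_equal(one[0].runs[0], other[0].runs[0])

    def test_bad_cohort_sizes(self, small_design):
        with pytest.raises(ValueError):
            sd.simulate_cohort(
                3, [small_design], sd.TuningModel(2.4, 0.1), sd.NoiseModel(), 0,
                cohort_sizes=(1, 1),
            )

    def test_derive_seed_distinct_streams(self):
        a = np.random.default_rng(derive_seed(1, 2, 3)).integers(0, 2**31, 4)
        b = np.random.default_rng(derive_seed(1, 2, 4)).integers(0, 2**31, 4)
        assert not np.array_equal(a, b)
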