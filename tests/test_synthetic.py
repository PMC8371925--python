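import numpy as np
import pytest

import stimtrack as st
from stimtrack.synthetic import (
    generate_cohort,
    generate_eeg,
    generate_motion_trace,
    generate_triggers,
    generate_video,
    resample_trace,
)
from tests.conftest import crossed_design

class TestMockLayout:
    def test_structure(self, layout):
        assert layout.n_sensors == 32
        assert set(layout.groups) >= {"frontal", "occipital", "mastoids"}
        assert np.allclose(np.linalg.norm(layout.positions, axis=1), 1.0)
        # frontal sensors are anterior (y > 0), occipital posterior
        for lab in layout.groups["frontal"]:
            assert layout.positions[layout.labels.index(lab), 1] > 0
        for lab in layout.groups["occipital"]:
            assert layout.positions[layout.labels.index(lab), 1] < 0

class TestGenerateMotionTrace:
    def test_seeded_determinism(self):
        a = generate_motion_trace(30, 30, seed=4)
        b = generate_motion_trace(30, 30, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_non_negative(self):
        tr = generate_motion_trace(60, 30, seed=1, periodic_peak=(4.4, 0.29))
        assert np.all(tr.values >= 0)

    def test_peak_recovered_near_requested_center(self):
        tr = generate_motion_trace(900, 30, periodic_peak=(4.4, 0.3), seed=0)
        fit = st.parameterize_spectrum(st.welch_psd(st.normalize_ivc(tr), 64, 32))
        pk = np.asarray(fit.peaks).reshape(-1, 3)
        sel = pk[(pk[:, 0] > 3) & (pk[:, 0] < 6)]
        assert len(sel) >= 1
        assert abs(sel[np.argmax(sel[:, 1]), 0] - 4.4) < 0.5

    def test_parameter_errors(self):
        with pytest.raises(st.ParameterError):
            generate_motion_trace(-1, 30)
        with pytest.raises(st.ParameterError):
            generate_motion_trace(10, 30, burst_rate_hz=20.0)

class TestGenerateVideo:
    def test_zero_trace_gives_identical_frames(self):
        tr = st.MotionTrace(np.zeros(20), rate_hz=30.0)
        vid = generate_video(tr, seed=0)
        assert np.all(vid.frames == vid.frames[0])
        assert np.all(st.compute_ivc(vid).values == 0.0)

    def test_round_trip_correlation(self):
        for seed in range(3):
            tr = generate_motion_trace(20, 30, seed=seed)
            vid = generate_video(tr, seed=seed)
            ivc = st.compute_ivc(vid)
            r = np.corrcoef(ivc.values, tr.values)[0, 1]
            assert r > 0.95

    def test_seeded_determinism(self):
        tr = generate_motion_trace(5, 30, seed=0)
        a = generate_video(tr, seed=1)
        b = generate_video(tr, seed=1)
        assert np.array_equal(a.frames, b.frames)

    def test_frame_too_small_rejected(self):
        tr = generate_motion_trace(5, 30, seed=0)
        with pytest.raises(st.ParameterError):
            generate_video(tr, frame_shape=(8, 8))

class TestGenerateEeg:
    def test_seeded_determinism(self, layout):
        tr = generate_motion_trace(20, 30, seed=0)
        spec = st.CouplingSpec(["Cz"], (0.5, 2.0), 1.0)
        a = generate_eeg(tr, layout, spec, seed=5, eeg_rate_hz=125.0)
        b = generate_eeg(tr, layout, spec, seed=5, eeg_rate_hz=125.0)
        assert np.array_equal(a.data, b.data)

    def test_unknown_target_channel_rejected(self, layout):
        tr = generate_motion_trace(10, 30, seed=0)
        with pytest.raises(st.ParameterError):
            generate_eeg(tr, layout, st.CouplingSpec(["XX"], (0.5, 2), 1.0))

    def test_rate_below_band_rejected(self, layout):
        tr = generate_motion_trace(10, 30, seed=0)
        with pytest.raises(st.ParameterError):
            generate_eeg(
                tr, layout, st.CouplingSpec(["Cz"], (0.5, 30.0), 1.0),
                eeg_rate_hz=50.0,
            )

    def test_coupled_channels_beat_others(self, layout):
        """Strong frontal coupling: target-channel z beats every
        non-target channel in the coupled band, across seeds."""
        targets = ["Fz", "F3", "F4"]
        wins = 0
        n_runs = 5
        for seed in range(n_runs):
            tr = generate_motion_trace(120, 30, seed=seed)
            eeg = generate_eeg(
                tr, layout, st.CouplingSpec(targets, (0.5, 2.0), 2.0),
                eeg_rate_hz=125.0, seed=seed + 50,
            )
            stim = st.MotionTrace(resample_trace(tr, 125.0), 125.0)
            emp, null = st.empirical_and_null(eeg, stim, n_shifts=40, seed=seed)
            z = st.zscore_map(emp, null)
            # bins whose pass band lies fully inside the coupling band
            band = (0.8 * z.bin_centers_hz >= 0.5) & (1.25 * z.bin_centers_hz <= 2.0)
            t_idx = [z.channel_labels.index(t) for t in targets]
            o_idx = [i for i in range(len(z.channel_labels)) if i not in t_idx]
            if z.values[np.ix_(t_idx, np.flatnonzero(band))].min() > \
               z.values[np.ix_(o_idx, np.flatnonzero(band))].max():
                wins += 1
        assert wins >= n_runs - 1

class TestGenerateTriggers:
    def test_count(self):
        trig = generate_triggers(900, 30, 30.0, 250.0, seed=0)
        assert trig.n_triggers == 30

    def test_no_drift_no_jitter_is_exact_rescaling(self):
        trig = generate_triggers(900, 30, 30.0, 250.0, 0.0, 0.0, seed=0)
        want = np.round(trig.video_frame_idx / 30.0 * 250.0).astype(int)
        assert np.array_equal(trig.eeg_sample_idx, want)

    def test_drift_offset_closed_form(self):
        """100 ppm over 10 min: the last trigger lands ~60 ms late."""
        video, eeg = 30.0, 250.0
        n_frames = int(600 * video)
        trig = generate_triggers(n_frames, 30, video, eeg, 100.0, 0.0, seed=0)
        nominal = trig.video_frame_idx[-1] / video
        actual_s = trig.eeg_sample_idx[-1] / eeg
        offset_ms = (actual_s - nominal) * 1000
        assert offset_ms == pytest.approx(nominal * 100e-6 * 1000, abs=3)

    def test_too_few_triggers_rejected(self):
        with pytest.raises(st.ParameterError):
            generate_triggers(40, 30, 30.0, 250.0)

class TestGenerateCohort:
    def test_study_like_group_sizes(self):
        design = crossed_design(0, n_per_group=(12, 19))
        assert design.group_sizes == (12, 19)
        # don't generate 62 recordings here; a tiny cohort checks structure
        small = crossed_design(0, n_per_group=2)
        recs = generate_cohort(small, duration_s=5.0, eeg_rate_hz=60.0)
        assert len(recs) == 2 * 2 * 2
        groups = {r.group for r in recs}
        stims = {r.stimulus for r in recs}
        assert groups == {"signers", "dancers"} and stims == {"sign", "dance"}

    def test_subject_multiplier_scales_coupling(self):
        recs = generate_cohort(
            crossed_design(3, n_per_group=2), duration_s=5.0, eeg_rate_hz=60.0
        )
        by_subj = {}
        for r in recs:
            by_subj.setdefault(r.subject, []).append(r)
        for subj, rr in by_subj.items():
            mults = {r.subject_multiplier for r in rr}
            assert len(mults) == 1  # shared within subject
            for r in rr:
                base = crossed_design(3).coupling_table[(r.group, r.stimulus)]
                assert r.coupling.coupling_strength == pytest.approx(
                    base.coupling_strength * r.subject_multiplier
                )

    def test_coupling_table_must_cover_cells(self):
        good = crossed_design(0)
        bad_table = dict(good.coupling_table)
        bad_table.pop(("signers", "sign"))
        with pytest.raises(st.ParameterError):
            st.CohortDesign(4, good.groups, good.stimuli, bad_table)

    def test_seeded_determinism(self):
        a = generate_cohort(crossed_design(7, n_per_group=1), duration_s=5.0,
                            eeg_rate_hz=60.0)
        b = generate_cohort(crossed_design(7, n_per_group=1), duration_s=5.0,
                            eeg_rate_hz=60.0)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.eeg.data, rb.eeg.data)
            assert np.array_equal(ra.trace.values, rb.trace.values)

class TestCouplingSpec:
    def test_invariants(self):
        with pytest.raises(st.ParameterError):
            st.CouplingSpec([], (0.5, 2.0), 1.0)  # coupled but no targets
        with pytest.raises(st.ParameterError):
            st.CouplingSpec(["a"], (2.0, 0.5), 1.0)
        with pytest.raises(st.ParameterError):
            st.CouplingSpec(["a"], (0.5, 2.0), -1.0)
        st.CouplingSpec([], (0.5, 2.0), 0.0)  # uncoupled needs no targets
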