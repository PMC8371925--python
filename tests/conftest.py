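import numpy as np
import pytest

import stimtrack as st


@pytest.fixture(scope="session")
def layout():
    return st.mock_layout()


@pytest.fixture(scope="session")
def bank():
    return st.make_filter_bank()


@pytest.fixture(scope="session")
def grid20():
    """A 4 x 5 planar sensor grid used for reduced-scale calibration."""
    pos = np.column_stack(
        [
            np.repeat(np.arange(4), 5),
            np.tile(np.arange(5), 4),
            np.zeros(20),
        ]
    ).astype(float)
    labels = [f"ch{i:02d}" for i in range(20)]
    return labels, pos


def uncoupled_zmap(seed, labels, pos, dur=60.0, fs=100.0, n_shifts=40):
    """Z-scored coherence map of one stimulus-uncoupled subject."""
    from stimtrack.synthetic import powerlaw_noise, resample_trace

    trace = st.generate_motion_trace(dur, 30.0, seed=seed)
    stim = st.MotionTrace(resample_trace(trace, fs), fs)
    rng = np.random.default_rng(seed)
    data = powerlaw_noise(int(dur * fs), len(labels), 1.0, fs, rng)
    eeg = st.EEGRecording(data, fs, labels, pos)
    emp, null = st.empirical_and_null(
        eeg, stim, n_shifts=n_shifts, min_shift_s=10.0, seed=seed + 1
    )
    return st.zscore_map(emp, null).values


def crossed_design(seed, matched=1.0, mismatched=0.2, n_per_group=10,
                   main_effect_only=False):
    """2x2 cohort design: crossed expertise coupling or group main effect."""
    front = ["Fz", "F3", "F4", "FC1", "FC2"]
    if main_effect_only:
        strengths = {
            ("signers", "sign"): 1.0,
            ("signers", "dance"): 1.0,
            ("dancers", "sign"): 0.3,
            ("dancers", "dance"): 0.3,
        }
    else:
        strengths = {
            ("signers", "sign"): matched,
            ("signers", "dance"): mismatched,
            ("dancers", "sign"): mismatched,
            ("dancers", "dance"): matched,
        }
    table = {
        k: st.CouplingSpec(front, (0.5, 2.0), v) for k, v in strengths.items()
    }
    return st.CohortDesign(
        n_per_group, ("signers", "dancers"), ("sign", "dance"), table, seed=seed
    )
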