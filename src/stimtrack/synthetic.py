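"""Synthetic stimuli, videos, triggers, and coupled EEG with known ground truth.

The generators emulate the measurement situation of an expertise-by-stimulus
EEG study: quasi-periodic visual motion traces (burst trains with gamma
inter-burst intervals, optionally carrying a weak narrowband theta peak as
in dance-like movement), toy videos whose frame-difference energy (IVC)
reproduces a target trace, photodiode-style trigger pairs with clock drift
and jitter, and multichannel EEG built from 1/f background noise plus a
band-limited component phase-locked to the stimulus at chosen channels.

Cohorts are organized as 2 subject groups x 2 stimulus types with a
configurable coupling table, so the ground-truth expertise interaction
(each group tracking "its" stimulus more strongly) is known exactly.
All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import (
    EEGRecording,
    FrameSequence,
    InputError,
    MotionTrace,
    ParameterError,
    SensorLayout,
    TriggerSeries,
)
from .spectral import welch_psd

#: dance-like periodic component: (center_hz, relative log10-power height)
DEFAULT_DANCE_PEAK = (4.4, 0.29)

# approximate 10-20 positions as (azimuth_deg from anterior, clockwise
# positive to the right; inclination_deg from the vertex)
_MOCK_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (-18, 90), "Fp2": (18, 90),
    "F7": (-54, 90), "F3": (-39, 60), "Fz": (0, 45), "F4": (39, 60), "F8": (54, 90),
    "FC5": (-69, 64), "FC1": (-21, 41), "FC2": (21, 41), "FC6": (69, 64),
    "T7": (-90, 90), "C3": (-63, 45), "Cz": (0, 0), "C4": (63, 45), "T8": (90, 90),
    "M1": (-100, 115), "M2": (100, 115),
    "CP5": (-111, 64), "CP1": (-159, 41), "CP2": (159, 41), "CP6": (111, 64),
    "P7": (-126, 90), "P3": (-141, 60), "Pz": (180, 45), "P4": (141, 60),
    "P8": (126, 90),
    "PO3": (-157, 72), "PO4": (157, 72),
    "O1": (-162, 90), "Oz": (180, 90), "O2": (162, 90),
}

FRONTAL_GROUP = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC1", "FC2"]
OCCIPITAL_GROUP = ["PO3", "PO4", "O1", "Oz", "O2"]
MASTOID_GROUP = ["M1", "M2"]


def mock_layout() -> SensorLayout:
    """A 32-position spherical sensor layout with named ROI groups.

    A stand-in for a real high-density net: labels follow 10-20
    conventions and the "frontal"/"occipital" groups play the role of the
    a-priori ROIs.  Coordinates are unit-sphere (x right, y anterior,
    z up).
    """
    labels = list(_MOCK_ANGLES)
    pos = np.empty((len(labels), 3))
    for i, lab in enumerate(labels):
        az, incl = np.deg2rad(_MOCK_ANGLES[lab][0]), np.deg2rad(_MOCK_ANGLES[lab][1])
        pos[i] = (
            math.sin(incl) * math.sin(az),
            math.sin(incl) * math.cos(az),
            math.cos(incl),
        )
    return SensorLayout(
        labels=labels,
        positions=pos,
        groups={
            "frontal": FRONTAL_GROUP,
            "occipital": OCCIPITAL_GROUP,
            "mastoids": MASTOID_GROUP,
        },
    )


@dataclass
class CouplingSpec:
    """Ground-truth stimulus-EEG coupling at chosen channels.

    coupling_strength is the amplitude ratio of the stimulus-locked
    band-limited component to the background noise in the same band at the
    target channels; lag_s delays the neural response behind the stimulus.
    """

    target_channels: list[str] = field(default_factory=list)
    band_hz: tuple[float, float] = (0.5, 2.0)
    coupling_strength: float = 0.0
    lag_s: float = 0.1

    def __post_init__(self) -> None:
        if self.coupling_strength < 0:
            raise ParameterError("coupling_strength must be >= 0")
        lo, hi = self.band_hz
        if not lo < hi:
            raise ParameterError("band low edge must be below high edge")
        if self.coupling_strength > 0 and not self.target_channels:
            raise ParameterError(
                "target_channels required when coupling_strength > 0"
            )


@dataclass
class CohortDesign:
    """A 2 x 2 cohort: two groups, two stimuli, coupling per cell."""

    n_per_group: int | tuple[int, int]
    groups: tuple[str, str]
    stimuli: tuple[str, str]
    coupling_table: dict[tuple[str, str], CouplingSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 2 or len(set(self.groups)) != 2:
            raise ParameterError("exactly 2 distinct groups required")
        if len(self.stimuli) != 2 or len(set(self.stimuli)) != 2:
            raise ParameterError("exactly 2 distinct stimuli required")
        cells = {(g, s) for g in self.groups for s in self.stimuli}
        if set(self.coupling_table) != cells:
            raise ParameterError(
                "coupling_table must cover all 4 (group, stimulus) cells"
            )

    @property
    def group_sizes(self) -> tuple[int, int]:
        n = self.n_per_group
        return (n, n) if isinstance(n, int) else (n[0], n[1])


@dataclass
class SubjectRecording:
    """One subject watching one stimulus, with its ground truth attached."""

    subject: str
    group: str
    stimulus: str
    eeg: EEGRecording
    trace: MotionTrace
    triggers: TriggerSeries
    coupling: CouplingSpec
    subject_multiplier: float = 1.0


def generate_motion_trace(
    duration_s: float,
    rate_hz: float = 30.0,
    burst_rate_hz: float = 2.2,
    periodic_peak: tuple[float, float] | None = None,
    seed: int | None = None,
    burst_shape: float = 3.0,
    kernel_tau_s: float = 0.06,
) -> MotionTrace:
    """Quasi-periodic, non-negative motion trace.

    A jittered burst train — gamma-distributed inter-burst intervals
    (shape ``burst_shape``, mean 1/burst_rate_hz) with lognormal burst
    amplitudes — convolved with a causal exponential kernel
    ``exp(-t / kernel_tau_s)``.  The exponential kernel gives the trace a
    Lorentzian (1 / (k + f^2)) spectral roll-off, which lies exactly in
    the family the knee-aperiodic model represents, so a trace without an
    injected component parameterizes as peak-free.  If ``periodic_peak =
    (center_hz, relative_height)`` is given, a weak frequency-jittered
    sinusoidal component is added, calibrated so the Welch spectrum shows
    a peak of approximately ``relative_height`` (log10-power units) above
    the aperiodic trend at ``center_hz``.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    if rate_hz <= 2 * burst_rate_hz:
        raise ParameterError("rate_hz must exceed 2 * burst_rate_hz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))

    # burst times: gamma renewal process with mean interval 1/burst_rate
    mean_iv = 1.0 / burst_rate_hz
    n_iv = int(duration_s / mean_iv * 2) + 20
    intervals = rng.gamma(burst_shape, mean_iv / burst_shape, size=n_iv)
    times = np.cumsum(intervals)
    times = times[times < duration_s]
    train = np.zeros(n)
    idx = np.minimum((times * rate_hz).astype(int), n - 1)
    np.add.at(train, idx, rng.lognormal(0.0, 0.5, size=idx.size))

    # smooth with a causal exponential kernel
    kt = np.arange(0, int(8 * kernel_tau_s * rate_hz) + 1) / rate_hz
    kernel = np.exp(-kt / kernel_tau_s)
    kernel /= kernel.sum()
    trace = np.convolve(train, kernel, mode="same")

    if periodic_peak is not None:
        center_hz, rel_height = periodic_peak
        if not 0 < center_hz < rate_hz / 2:
            raise ParameterError("periodic peak center must be below Nyquist")
        # background power near the peak, from the trace's own spectrum
        spec = welch_psd(trace, 64, 32, rate_hz=rate_hz)
        near = (np.abs(spec.freqs_hz - center_hz) < 3.0) & (
            np.abs(spec.freqs_hz - center_hz) > 1.0
        )
        p_bg = float(np.median(spec.power[near]))
        # frequency-jittered sinusoid: spreads A^2/2 of power over a
        # roughly Gaussian spectral profile of sd sigma_f
        sigma_f = 0.55
        p_target = p_bg * (10.0**rel_height - 1.0)
        amp = math.sqrt(2.0 * p_target * math.sqrt(2 * math.pi) * sigma_f)
        slow = rng.standard_normal(n)
        sos = signal.butter(2, 0.2, btype="lowpass", fs=rate_hz, output="sos")
        slow = signal.sosfiltfilt(sos, slow)
        slow /= max(slow.std(), 1e-12)
        inst_freq = center_hz + sigma_f * slow
        phase = 2 * np.pi * np.cumsum(inst_freq) / rate_hz
        phase = phase + rng.uniform(0, 2 * np.pi)
        # 1 + cos keeps the trace non-negative; the DC term is removed by
        # per-segment detrending in the Welch estimator
        trace = trace + amp * (1.0 + np.cos(phase))

    return MotionTrace(values=trace, rate_hz=rate_hz, normalized=False)


def generate_video(
    trace: MotionTrace,
    frame_shape: tuple[int, int] = (48, 64),
    seed: int | None = None,
    blob_sd_px: float = 2.0,
    max_step_px: float = 0.4,
) -> FrameSequence:
    """Frames of a moving Gaussian blob realizing a target IVC.

    The blob moves horizontally with per-frame displacement proportional
    to sqrt(trace): for small sub-pixel steps the frame-difference energy
    is quadratic in displacement, so ``compute_ivc`` of the output
    correlates > 0.95 with the input trace (after normalization).  The
    blob bounces between margins; a constant-zero trace yields identical
    frames.
    """
    h, w = frame_shape
    margin = 4.0 * blob_sd_px
    if w < 2 * margin + 4 or h < 2 * margin + 1:
        raise ParameterError(
            f"frame shape {frame_shape} too small for blob sd {blob_sd_px}"
        )
    vals = np.asarray(trace.values, dtype=float)
    if np.any(vals < 0):
        raise InputError("target trace must be non-negative")
    peak = vals.max()
    steps = (
        np.zeros_like(vals)
        if peak == 0
        else max_step_px * np.sqrt(vals / peak)
    )
    rng = np.random.default_rng(seed)
    x = float(rng.uniform(margin, w - 1 - margin))
    y = (h - 1) / 2.0
    direction = 1.0 if rng.random() < 0.5 else -1.0

    yy, xx = np.mgrid[0:h, 0:w]
    n_frames = vals.size + 1
    frames = np.empty((n_frames, h, w))

    def render(px: float) -> np.ndarray:
        return 255.0 * np.exp(
            -((xx - px) ** 2 + (yy - y) ** 2) / (2.0 * blob_sd_px**2)
        )

    frames[0] = render(x)
    for t, step in enumerate(steps):
        nx = x + direction * step
        if nx > w - 1 - margin or nx < margin:
            direction = -direction
            nx = x + direction * step
        x = nx
        frames[t + 1] = render(x)
    return FrameSequence(frames=frames, rate_hz=trace.rate_hz)


def powerlaw_noise(
    n_samples: int,
    n_channels: int,
    exponent: float,
    rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with power spectrum 1/f**exponent, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * scale[None, :]
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def resample_trace(trace: MotionTrace, new_rate_hz: float) -> np.ndarray:
    """Cubic-interpolated resampling of a trace onto a new rate's grid."""
    from scipy.interpolate import CubicSpline

    t_old = np.arange(trace.n_samples) / trace.rate_hz
    n_new = int(round(trace.duration_s * new_rate_hz))
    t_new = np.arange(n_new) / new_rate_hz
    t_new = np.clip(t_new, t_old[0], t_old[-1])
    return CubicSpline(t_old, trace.values)(t_new)


def generate_eeg(
    trace: MotionTrace,
    layout: SensorLayout,
    coupling: CouplingSpec,
    noise_exponent: float = 1.0,
    eeg_rate_hz: float = 250.0,
    seed: int | None = None,
) -> EEGRecording:
    """Multichannel EEG: 1/f noise plus a stimulus-locked band component.

    Every channel receives independent 1/f**noise_exponent noise.  At the
    coupling's target channels, a band-pass-filtered, lag-shifted copy of
    the stimulus trace is added, scaled to ``coupling_strength`` times the
    channel's own background RMS within the coupling band — so true
    coherence is high in that band at target channels and at chance
    elsewhere.
    """
    lo, hi = coupling.band_hz
    if eeg_rate_hz < 2 * hi:
        raise ParameterError("eeg_rate_hz must be >= 2 x band high edge")
    unknown = set(coupling.target_channels) - set(layout.labels)
    if unknown:
        raise ParameterError(f"unknown target channels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = int(round(trace.duration_s * eeg_rate_hz))
    data = powerlaw_noise(n, layout.n_sensors, noise_exponent, eeg_rate_hz, rng)

    if coupling.coupling_strength > 0:
        stim = resample_trace(trace, eeg_rate_hz)
        sos = signal.butter(3, [lo, hi], btype="bandpass", fs=eeg_rate_hz, output="sos")
        locked = signal.sosfiltfilt(sos, stim - stim.mean())
        lag = int(round(coupling.lag_s * eeg_rate_hz))
        locked = np.roll(locked, lag)
        rms = locked.std()
        if rms == 0:
            raise ParameterError("stimulus has no energy in the coupling band")
        locked = locked / rms
        for lab in coupling.target_channels:
            i = layout.labels.index(lab)
            bg_rms = signal.sosfiltfilt(sos, data[i]).std()
            data[i] = data[i] + coupling.coupling_strength * bg_rms * locked

    return EEGRecording(
        data=data,
        rate_hz=eeg_rate_hz,
        labels=list(layout.labels),
        positions=layout.positions.copy(),
    )


def generate_triggers(
    n_frames: int,
    frames_per_trigger: int = 30,
    video_rate_hz: float = 30.0,
    eeg_rate_hz: float = 250.0,
    clock_drift_ppm: float = 0.0,
    jitter_s: float = 0.0,
    seed: int | None = None,
) -> TriggerSeries:
    """Paired (video frame, EEG sample) trigger events with drift + jitter.

    EEG-side times are stretched by ``clock_drift_ppm`` parts per million
    and perturbed by bounded uniform jitter before rounding to samples.
    """
    if frames_per_trigger < 1 or n_frames < 2 * frames_per_trigger:
        raise ParameterError(
            "frames_per_trigger must fit into n_frames at least twice"
        )
    rng = np.random.default_rng(seed)
    frame_idx = np.arange(0, n_frames, frames_per_trigger)
    if frame_idx.size < 2:
        raise ParameterError("fewer than 2 triggers")
    t_video = frame_idx / video_rate_hz
    t_eeg = t_video * (1.0 + clock_drift_ppm * 1e-6)
    if jitter_s > 0:
        t_eeg = t_eeg + rng.uniform(-jitter_s, jitter_s, size=t_eeg.size)
    samples = np.round(t_eeg * eeg_rate_hz).astype(int)
    samples = np.maximum.accumulate(samples)  # enforce monotonicity
    bump = np.flatnonzero(np.diff(samples) == 0)
    for b in bump:
        samples[b + 1 :] += 1
    return TriggerSeries(
        video_frame_idx=frame_idx,
        eeg_sample_idx=samples,
        video_rate_hz=video_rate_hz,
        eeg_rate_hz=eeg_rate_hz,
    )


def generate_cohort(
    design: CohortDesign,
    duration_s: float = 120.0,
    video_rate_hz: float = 30.0,
    eeg_rate_hz: float = 250.0,
    layout: SensorLayout | None = None,
    noise_exponent: float = 1.0,
    subject_sd: float = 0.2,
    periodic_peaks: dict[str, tuple[float, float]] | None = None,
    clock_drift_ppm: float = 50.0,
    jitter_s: float = 0.001,
    burst_rate_hz: float = 2.2,
) -> list[SubjectRecording]:
    """Generate one recording per subject x stimulus for a 2 x 2 cohort.

    Each stimulus type gets a single motion trace shared by all subjects
    (as when everyone watches the same videos); a dance-like theta peak
    (4.4 Hz, height 0.29) is injected into any stimulus labeled "dance"
    unless ``periodic_peaks`` overrides it.  Per-subject variation in
    coupling strength is a lognormal multiplier with log-sd
    ``subject_sd``, shared across that subject's recordings.
    """
    layout = layout or mock_layout()
    if periodic_peaks is None:
        periodic_peaks = {
            s: DEFAULT_DANCE_PEAK for s in design.stimuli if "dance" in s.lower()
        }
    ss = np.random.SeedSequence(design.seed)
    trace_seeds = ss.spawn(len(design.stimuli))
    traces = {
        s: generate_motion_trace(
            duration_s,
            video_rate_hz,
            burst_rate_hz=burst_rate_hz,
            periodic_peak=periodic_peaks.get(s),
            seed=int(sd.generate_state(1)[0] % (2**31)),
        )
        for s, sd in zip(design.stimuli, trace_seeds)
    }
    n_frames = traces[design.stimuli[0]].n_samples

    records: list[SubjectRecording] = []
    n1, n2 = design.group_sizes
    subj_ss = ss.spawn(n1 + n2)
    counter = 0
    for group, n_grp in zip(design.groups, (n1, n2)):
        for j in range(n_grp):
            sseq = subj_ss[counter]
            counter += 1
            subject = f"{group}_{j:02d}"
            rng = np.random.default_rng(sseq.generate_state(1)[0] % (2**31))
            multiplier = float(rng.lognormal(0.0, subject_sd)) if subject_sd > 0 else 1.0
            for stim in design.stimuli:
                spec = design.coupling_table[(group, stim)]
                eff = CouplingSpec(
                    target_channels=list(spec.target_channels),
                    band_hz=spec.band_hz,
                    coupling_strength=spec.coupling_strength * multiplier,
                    lag_s=spec.lag_s,
                )
                eeg_seed = int(rng.integers(0, 2**31))
                trg_seed = int(rng.integers(0, 2**31))
                eeg = generate_eeg(
                    traces[stim], layout, eff, noise_exponent, eeg_rate_hz,
                    seed=eeg_seed,
                )
                triggers = generate_triggers(
                    n_frames,
                    frames_per_trigger=30,
                    video_rate_hz=video_rate_hz,
                    eeg_rate_hz=eeg_rate_hz,
                    clock_drift_ppm=clock_drift_ppm,
                    jitter_s=jitter_s,
                    seed=trg_seed,
                )
                records.append(
                    SubjectRecording(
                        subject=subject,
                        group=group,
                        stimulus=stim,
                        eeg=eeg,
                        trace=traces[stim],
                        triggers=triggers,
                        coupling=eff,
                        subject_multiplier=multiplier,
                    )
                )
    return records
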