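"""Shared in-memory containers for stimulus-tracking analysis.

These are plain dataclasses around numpy arrays; every analysis module
consumes and returns them.  Conventions:

* time series are float64, channels-by-samples for EEG;
* a :class:`MotionTrace` is the one-dimensional stimulus signal (the IVC,
  instantaneous visual change) that the brain is hypothesized to track;
* a :class:`TriggerSeries` links the video clock to the EEG clock via
  photodiode-style paired events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class StimtrackError(Exception):
    """Base class for all package errors."""


class ParameterError(StimtrackError, ValueError):
    """A parameter value is outside its documented domain."""


class InputError(StimtrackError, ValueError):
    """An input object violates a precondition (shape, monotonicity, ...)."""


class DegenerateInputError(StimtrackError, ValueError):
    """Input is formally valid but the operation is undefined on it
    (constant trace, all-zero weights, zero surrogate spread, ...)."""


class FitError(StimtrackError, RuntimeError):
    """A numerical fit failed to converge; carries diagnostics in args."""


@dataclass
class FrameSequence:
    """Ordered grayscale frames.

    frames : (n_frames, height, width) float array, finite and >= 0
    rate_hz : frames per second
    """

    frames: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InputError(
                f"frames must be (n, h, w); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise InputError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise InputError("frames contain non-finite values")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class MotionTrace:
    """A one-dimensional stimulus motion signal.

    values : 1-D float array.  Raw IVC values are sums of squared pixel
        differences (hence >= 0); after normalization they are in SD units.
    rate_hz : sampling rate.
    normalized : True once divided by the population SD.
    frame_offset : index of the video frame carrying values[0].  Raw IVC
        assigns each value to the *later* frame of its pair, so
        ``compute_ivc`` sets this to 1; synthetic frame-locked traces use 0.
    """

    values: np.ndarray
    rate_hz: float
    normalized: bool = False
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise InputError("empty motion trace")
        if not np.all(np.isfinite(self.values)):
            raise InputError("motion trace contains non-finite values")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.rate_hz

    def copy_with(self, **kwargs) -> "MotionTrace":
        return replace(self, **kwargs)


@dataclass
class EEGRecording:
    """Multichannel EEG with sensor metadata and a per-sample validity mask.

    data : (n_channels, n_samples) array
    labels : unique channel names, one per row of ``data``
    positions : (n_channels, 3) sensor coordinates
    valid_mask : per-sample weight in [0, 1]; 1 = clean, 0 = rejected.
        Artifact masking writes taper ramps into it so downstream
        estimators can weight samples by how much signal survives.
    """

    data: np.ndarray
    rate_hz: float
    labels: list[str]
    positions: np.ndarray
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        n_ch, n_samp = self.data.shape
        if len(self.labels) != n_ch:
            raise InputError(
                f"{len(self.labels)} labels for {n_ch} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise InputError("channel labels must be unique")
        if self.positions.shape != (n_ch, 3):
            raise InputError(
                f"positions must be ({n_ch}, 3); got {self.positions.shape}"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(n_samp)
        self.valid_mask = np.asarray(self.valid_mask, dtype=float).ravel()
        if self.valid_mask.size != n_samp:
            raise InputError("valid_mask length must equal sample count")
        if np.any((self.valid_mask < 0) | (self.valid_mask > 1)):
            raise InputError("valid_mask values must lie in [0, 1]")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(f"unknown channel label {label!r}") from None

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            data=self.data.copy(),
            rate_hz=self.rate_hz,
            labels=list(self.labels),
            positions=self.positions.copy(),
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class TriggerSeries:
    """Paired trigger events on the video and EEG clocks.

    Both index lists are strictly increasing and equally long (>= 2).
    """

    video_frame_idx: np.ndarray
    eeg_sample_idx: np.ndarray
    video_rate_hz: float
    eeg_rate_hz: float

    def __post_init__(self) -> None:
        self.video_frame_idx = np.asarray(self.video_frame_idx, dtype=int)
        self.eeg_sample_idx = np.asarray(self.eeg_sample_idx, dtype=int)
        if self.video_frame_idx.size != self.eeg_sample_idx.size:
            raise InputError("trigger lists must have equal length")
        if self.video_frame_idx.size < 2:
            raise InputError("need at least 2 triggers")
        for name, idx in (
            ("video_frame_idx", self.video_frame_idx),
            ("eeg_sample_idx", self.eeg_sample_idx),
        ):
            if np.any(np.diff(idx) <= 0):
                raise InputError(f"{name} must be strictly increasing")
        if self.video_rate_hz <= 0 or self.eeg_rate_hz <= 0:
            raise ParameterError("rates must be positive")

    @property
    def n_triggers(self) -> int:
        return self.video_frame_idx.size


@dataclass
class SensorLayout:
    """Labeled sensor positions with optional named groups (ROI seeds)."""

    labels: list[str]
    positions: np.ndarray
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise InputError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("layout labels must be unique")
        for name, members in self.groups.items():
            unknown = set(members) - set(self.labels)
            if unknown:
                raise InputError(f"group {name!r} has unknown labels {unknown}")

    @property
    def n_sensors(self) -> int:
        return len(self.labels)
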