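"""Instantaneous visual change (IVC): a scalar motion-energy time series.

The IVC quantifies frame-to-frame visual change as the sum of squared
pixel-intensity differences between consecutive grayscale frames,

    IVC(t) = sum_i [x_i(t) - x_i(t-1)]^2,

where x_i(t) is the grayscale value of pixel i in frame t.  It is the
stimulus-side signal in all coherence analyses.
"""

from __future__ import annotations

import numpy as np

from .containers import DegenerateInputError, FrameSequence, InputError, MotionTrace

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_601 = (0.299, 0.587, 0.114)


def to_grayscale(frames: np.ndarray) -> np.ndarray:
    """Convert (n, h, w, 3) RGB frames to grayscale using BT.601 luma.

    Grayscale input (3-D) passes through unchanged.  Arithmetic is done in
    float regardless of input dtype so unsigned-integer differences cannot
    wrap around.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 3:
        return frames
    if frames.ndim == 4 and frames.shape[-1] == 3:
        r, g, b = LUMA_601
        return r * frames[..., 0] + g * frames[..., 1] + b * frames[..., 2]
    raise InputError(
        f"expected (n, h, w) grayscale or (n, h, w, 3) RGB; got {frames.shape}"
    )


def compute_ivc(
    frames: FrameSequence | np.ndarray,
    rate_hz: float | None = None,
    crop: tuple[slice, slice] | None = None,
) -> MotionTrace:
    """Compute the IVC of a frame sequence.

    Parameters
    ----------
    frames
        A :class:`FrameSequence`, or a raw (n, h, w) / (n, h, w, 3) array
        (RGB input is converted with BT.601 luma), in which case ``rate_hz``
        must be given.
    crop
        Optional (row_slice, col_slice) restricting the computation to a
        sub-region of every frame (e.g. to exclude a photodiode patch).

    Returns
    -------
    MotionTrace
        ``values[t] = sum((frame[t+1] - frame[t])**2)``, length
        ``n_frames - 1``; each value is stamped on the *later* frame
        (``frame_offset = 1``).
    """
    if isinstance(frames, FrameSequence):
        arr = frames.frames
        rate = frames.rate_hz
    else:
        if rate_hz is None:
            raise InputError("rate_hz is required for raw frame arrays")
        arr = to_grayscale(frames)
        rate = rate_hz
        if arr.shape[0] < 2:
            raise InputError("need at least 2 frames")
    if crop is not None:
        arr = arr[:, crop[0], crop[1]]
    diffs = np.diff(arr, axis=0)
    sq = (diffs * diffs).reshape(diffs.shape[0], -1)
    # sequential (left-to-right) accumulation in row-major pixel order, so
    # the result is reproducible against a plain double-loop summation
    values = np.cumsum(sq, axis=1)[:, -1]
    return MotionTrace(values=values, rate_hz=rate, normalized=False, frame_offset=1)


def normalize_ivc(trace: MotionTrace) -> MotionTrace:
    """Divide a trace by its population standard deviation (output SD = 1)."""
    sd = float(np.std(trace.values))
    if sd == 0.0:
        raise DegenerateInputError("cannot normalize a constant trace")
    return trace.copy_with(values=trace.values / sd, normalized=True)
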