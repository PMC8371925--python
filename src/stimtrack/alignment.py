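"""Warp a video-rate motion trace onto the EEG clock using paired triggers.

Video and EEG run on independent hardware clocks that drift relative to one
another.  Periodic photodiode triggers give paired anchor points (video
frame index, EEG sample index).  Between consecutive anchors, EEG sample
times are mapped linearly into frame positions and a cubic spline through
the span's trace samples is evaluated there — warping and resampling (e.g.
30 Hz video to 250 Hz EEG) in one step, absorbing slow non-linear drift
span by span.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .containers import InputError, MotionTrace, TriggerSeries


def align_ivc_to_eeg(trace: MotionTrace, triggers: TriggerSeries) -> MotionTrace:
    """Resample ``trace`` onto the EEG clock, anchored at the triggers.

    The output covers EEG samples ``eeg_sample_idx[0] .. eeg_sample_idx[-1]``
    inclusive, sampled at ``triggers.eeg_rate_hz``.  Within each
    inter-trigger span, a cubic spline is fit through the trace samples of
    that span (frame positions on the x-axis) and evaluated at the EEG
    sample times mapped linearly between the span's two anchors.  Adjacent
    spans share their boundary sample, so the concatenation is continuous.

    Samples before the first or after the last trigger are not represented
    (no extrapolation); exclude them from coherence via the span itself.
    """
    frames = triggers.video_frame_idx.astype(float)
    samples = triggers.eeg_sample_idx.astype(float)

    # Trace sample i sits at frame position i + frame_offset.
    trace_frames = np.arange(trace.n_samples, dtype=float) + trace.frame_offset
    if trace_frames[0] > frames[0] or trace_frames[-1] < frames[-1]:
        raise InputError(
            "trace does not cover the trigger span "
            f"(trace frames {trace_frames[0]:g}..{trace_frames[-1]:g}, "
            f"triggers {frames[0]:g}..{frames[-1]:g})"
        )

    n_out = int(samples[-1] - samples[0]) + 1
    out = np.empty(n_out)
    for j in range(triggers.n_triggers - 1):
        f0, f1 = frames[j], frames[j + 1]
        s0, s1 = samples[j], samples[j + 1]
        # Span's trace samples, with one extra sample of context on each
        # side when available so the local spline is well conditioned.
        lo = int(np.searchsorted(trace_frames, f0, side="right")) - 1
        hi = int(np.searchsorted(trace_frames, f1, side="left")) + 1
        lo = max(lo - 1, 0)
        hi = min(hi + 1, trace.n_samples - 1)
        if hi - lo < 3:  # cubic needs 4 points; widen symmetrically
            lo = max(0, min(lo, trace.n_samples - 4))
            hi = min(trace.n_samples - 1, lo + 3)
        spline = CubicSpline(trace_frames[lo : hi + 1], trace.values[lo : hi + 1])
        # EEG samples in [s0, s1]; last span includes its right edge.
        a = int(s0 - samples[0])
        b = int(s1 - samples[0]) + (1 if j == triggers.n_triggers - 2 else 0)
        s = np.arange(a, b) + samples[0]
        warped_frames = f0 + (s - s0) * (f1 - f0) / (s1 - s0)
        out[a:b] = spline(warped_frames)

    return MotionTrace(
        values=out,
        rate_hz=triggers.eeg_rate_hz,
        normalized=trace.normalized,
        frame_offset=0,
    )


def detect_rising_edges(
    analog: np.ndarray, threshold: float, min_gap_samples: int = 1
) -> np.ndarray:
    """Simple threshold-crossing trigger detector for a photodiode channel.

    Returns sample indices where ``analog`` crosses ``threshold`` upward,
    keeping only crossings at least ``min_gap_samples`` apart.  Provided as
    a convenience for real recordings; hardware-specific tuning is the
    caller's job.
    """
    analog = np.asarray(analog, dtype=float).ravel()
    above = analog >= threshold
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if edges.size == 0 or min_gap_samples <= 1:
        return edges
    keep = [edges[0]]
    for e in edges[1:]:
        if e - keep[-1] >= min_gap_samples:
            keep.append(e)
    return np.asarray(keep)
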