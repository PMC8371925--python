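"""EEG preprocessing: channel exclusion, artifact masking, re-referencing.

Artifact masking zeroes tagged intervals and ramps the flanking data down
with half-Hanning tapers, mirroring the common practice of excising
movement artifacts without introducing step discontinuities.  The same
weights are written into the recording's ``valid_mask`` so the coherence
estimator can down-weight tapered samples instead of treating zero-filled
stretches as signal.
"""

from __future__ import annotations

import numpy as np

from .containers import DegenerateInputError, EEGRecording, InputError, ParameterError


def exclude_channels(eeg: EEGRecording, labels_to_drop: list[str]) -> EEGRecording:
    """Drop the listed channels, keeping labels/positions consistent."""
    drop = set(labels_to_drop)
    unknown = drop - set(eeg.labels)
    if unknown:
        raise InputError(f"unknown channel labels: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(eeg.labels) if lab not in drop]
    if not keep:
        raise DegenerateInputError("cannot drop every channel")
    return EEGRecording(
        data=eeg.data[keep],
        rate_hz=eeg.rate_hz,
        labels=[eeg.labels[i] for i in keep],
        positions=eeg.positions[keep],
        valid_mask=eeg.valid_mask.copy(),
    )


def _half_hann_rising(n: int) -> np.ndarray:
    """Rising half-Hanning ramp of length n: 0 -> 1, sin^2 shape.

    The midpoint of the ramp has weight 0.5.
    """
    if n <= 0:
        return np.empty(0)
    x = np.arange(1, n + 1) / (n + 1)
    return np.sin(0.5 * np.pi * x) ** 2


def mask_artifacts(
    eeg: EEGRecording,
    intervals: list[tuple[float, float]],
    taper_ms: float = 4000.0,
    zero_fill: bool = True,
) -> EEGRecording:
    """Zero out artifact intervals and taper their flanks.

    Parameters
    ----------
    intervals
        (start_s, end_s) pairs in recording time; end exclusive-ish at
        sample resolution.  Overlapping weight profiles combine by
        pointwise minimum.
    taper_ms
        Length of the half-Hanning ramp applied on each side of every
        interval (default 4000 ms).
    zero_fill
        If True (default) the data are multiplied by the weight profile,
        reproducing literal zero-fill-plus-taper behaviour; either way the
        weights are recorded in ``valid_mask`` for downstream weighting.
    """
    if taper_ms < 0:
        raise ParameterError("taper_ms must be >= 0")
    n = eeg.n_samples
    rate = eeg.rate_hz
    taper_n = int(round(taper_ms / 1000.0 * rate))
    weights = np.ones(n)
    for start_s, end_s in intervals:
        i0 = int(round(start_s * rate))
        i1 = int(round(end_s * rate))
        if not (0 <= i0 < i1 <= n):
            raise InputError(
                f"interval ({start_s}, {end_s}) s outside recording of "
                f"{n / rate:g} s"
            )
        w = np.ones(n)
        w[i0:i1] = 0.0
        if taper_n > 0:
            ramp = _half_hann_rising(taper_n)
            left = max(0, i0 - taper_n)
            if i0 > left:
                # falling toward the interval from the left
                w[left:i0] = ramp[::-1][-(i0 - left):]
            right = min(n, i1 + taper_n)
            if right > i1:
                w[i1:right] = ramp[: right - i1]
        weights = np.minimum(weights, w)
    out = eeg.copy()
    new_mask = np.minimum(out.valid_mask, weights)
    if zero_fill:
        # Maintain data == clean_data * valid_mask: scale by the ratio of
        # the combined mask to the mask already applied, so re-masking with
        # the same intervals is a no-op (idempotency).
        old = out.valid_mask
        ratio = np.divide(new_mask, old, out=np.zeros_like(new_mask), where=old > 0)
        out.data = out.data * ratio[None, :]
    out.valid_mask = new_mask
    return out


def rereference(eeg: EEGRecording, ref_labels: list[str]) -> EEGRecording:
    """Subtract the mean of the reference channels from every channel.

    With e.g. the two mastoid channels as references this implements
    average-mastoid re-referencing; afterwards the mean of the reference
    channels is identically zero, so the operation is idempotent.
    """
    if not ref_labels:
        raise InputError("ref_labels must be non-empty")
    idx = [eeg.channel_index(lab) for lab in ref_labels]
    ref = eeg.data[idx].mean(axis=0)
    out = eeg.copy()
    out.data = out.data - ref[None, :]
    return out
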