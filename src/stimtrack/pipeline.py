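"""End-to-end convenience wrappers tying the analysis stages together.

``subject_zscored_map`` runs one subject's recording through alignment,
coherence, surrogates and z-scoring; ``analyze_cohort`` maps a synthetic
(or loaded) 2x2 cohort to per-cell z-map stacks ready for the cluster and
ROI statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len

from .alignment import align_ivc_to_eeg
from .coherence import (
    CoherenceMap,
    FilterBank,
    empirical_and_null,
    make_filter_bank,
    zscore_map,
)
from .containers import EEGRecording, InputError, MotionTrace, TriggerSeries
from .synthetic import SubjectRecording


def _prev_fast_len(n: int) -> int:
    """Largest FFT-friendly (5-smooth) length <= n."""
    m = n
    while next_fast_len(m) != m:
        m -= 1
    return m


def subject_zscored_map(
    eeg: EEGRecording,
    trace: MotionTrace,
    triggers: TriggerSeries | None = None,
    bank: FilterBank | None = None,
    n_shifts: int = 100,
    min_shift_s: float = 10.0,
    seed: int | None = None,
    trim_to_fast_len: bool = True,
) -> CoherenceMap:
    """Empirical coherence z-scored against its circular-shift null.

    If ``triggers`` is given the trace is first warped onto the EEG clock
    and both signals are restricted to the trigger-anchored span;
    otherwise the trace must already be on the EEG clock.  With
    ``trim_to_fast_len`` (default) the analysis span is shortened to the
    nearest FFT-friendly length — dropping at most a fraction of a
    percent of the samples — so the filter-bank and surrogate transforms
    avoid slow large-prime FFT sizes.
    """
    bank = bank or make_filter_bank()
    if triggers is not None:
        aligned = align_ivc_to_eeg(trace, triggers)
        s0 = int(triggers.eeg_sample_idx[0])
        s1 = int(triggers.eeg_sample_idx[-1])
        eeg = EEGRecording(
            data=eeg.data[:, s0 : s1 + 1],
            rate_hz=eeg.rate_hz,
            labels=list(eeg.labels),
            positions=eeg.positions,
            valid_mask=eeg.valid_mask[s0 : s1 + 1],
        )
        trace = aligned
    if trace.n_samples != eeg.n_samples:
        raise InputError("trace and EEG are not on a common clock")
    if trim_to_fast_len:
        n = _prev_fast_len(eeg.n_samples)
        if n != eeg.n_samples:
            eeg = EEGRecording(
                data=eeg.data[:, :n],
                rate_hz=eeg.rate_hz,
                labels=list(eeg.labels),
                positions=eeg.positions,
                valid_mask=eeg.valid_mask[:n],
            )
            trace = trace.copy_with(values=trace.values[:n])
    empirical, null = empirical_and_null(
        eeg, trace, bank, n_shifts=n_shifts, min_shift_s=min_shift_s, seed=seed
    )
    return zscore_map(empirical, null)


@dataclass
class CohortMaps:
    """Per-cell stacks of z-scored maps for a 2x2 cohort."""

    maps: dict[tuple[str, str], np.ndarray]  # (group, stim) -> (n, ch, bins)
    subjects: dict[tuple[str, str], list[str]]
    channel_labels: list[str]
    bin_centers_hz: np.ndarray

    def cell(self, group: str, stimulus: str) -> np.ndarray:
        return self.maps[(group, stimulus)]


def analyze_cohort(
    records: list[SubjectRecording],
    bank: FilterBank | None = None,
    n_shifts: int = 100,
    min_shift_s: float = 10.0,
    seed: int | None = None,
    use_triggers: bool = True,
) -> CohortMaps:
    """Z-scored coherence maps for every recording, grouped by cell.

    Subject order within each (group, stimulus) cell is preserved across
    the two stimuli, so stacks are paired by subject for dependent
    contrasts.
    """
    bank = bank or make_filter_bank()
    cells: dict[tuple[str, str], list[np.ndarray]] = {}
    subjects: dict[tuple[str, str], list[str]] = {}
    labels: list[str] | None = None
    rng = np.random.default_rng(seed)
    for rec in records:
        zmap = subject_zscored_map(
            rec.eeg,
            rec.trace,
            rec.triggers if use_triggers else None,
            bank=bank,
            n_shifts=n_shifts,
            min_shift_s=min_shift_s,
            seed=int(rng.integers(0, 2**31)),
        )
        key = (rec.group, rec.stimulus)
        cells.setdefault(key, []).append(zmap.values)
        subjects.setdefault(key, []).append(rec.subject)
        labels = zmap.channel_labels
    return CohortMaps(
        maps={k: np.stack(v) for k, v in cells.items()},
        subjects=subjects,
        channel_labels=labels or [],
        bin_centers_hz=bank.center_freqs_hz,
    )
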