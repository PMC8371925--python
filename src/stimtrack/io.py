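"""On-disk formats: flat-binary EEG with a JSON sidecar, CSV traces and
triggers, NPY frame stacks, and cohort directories.

The EEG format is deliberately minimal: a float64 little-endian
channels-by-samples binary next to a ``.json`` sidecar holding the rate,
labels and positions.  Readers for standard EEG containers can be layered
on via an adapter without touching the analysis modules.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EEGRecording, FrameSequence, InputError, MotionTrace, TriggerSeries
from .synthetic import CouplingSpec, SubjectRecording


def write_eeg(eeg: EEGRecording, path: str | Path) -> None:
    """Write ``path`` (raw float64 binary) and ``path.with_suffix('.json')``."""
    path = Path(path)
    eeg.data.astype("<f8").tofile(path)
    sidecar = {
        "rate_hz": eeg.rate_hz,
        "labels": eeg.labels,
        "positions": eeg.positions.tolist(),
        "n_channels": eeg.n_channels,
        "n_samples": eeg.n_samples,
        "valid_mask_nontrivial": bool(np.any(eeg.valid_mask != 1.0)),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if sidecar["valid_mask_nontrivial"]:
        eeg.valid_mask.astype("<f8").tofile(path.with_suffix(".mask"))


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    data = np.fromfile(path, dtype="<f8").reshape(
        meta["n_channels"], meta["n_samples"]
    )
    mask = None
    mask_path = path.with_suffix(".mask")
    if meta.get("valid_mask_nontrivial") and mask_path.exists():
        mask = np.fromfile(mask_path, dtype="<f8")
    return EEGRecording(
        data=data,
        rate_hz=meta["rate_hz"],
        labels=meta["labels"],
        positions=np.asarray(meta["positions"]),
        valid_mask=mask,
    )


def write_trace(trace: MotionTrace, path: str | Path) -> None:
    """Two-column CSV: time_s, ivc."""
    t = np.arange(trace.n_samples) / trace.rate_hz
    pd.DataFrame({"time_s": t, "ivc": trace.values}).to_csv(path, index=False)


def read_trace(path: str | Path, normalized: bool = False) -> MotionTrace:
    df = pd.read_csv(path)
    if not {"time_s", "ivc"} <= set(df.columns):
        raise InputError("trace CSV needs columns time_s, ivc")
    t = df["time_s"].to_numpy()
    if t.size < 2:
        raise InputError("trace CSV too short")
    rate = 1.0 / np.median(np.diff(t))
    return MotionTrace(values=df["ivc"].to_numpy(), rate_hz=rate, normalized=normalized)


def write_triggers(triggers: TriggerSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "video_frame_idx": triggers.video_frame_idx,
            "eeg_sample_idx": triggers.eeg_sample_idx,
        }
    ).to_csv(path, index=False)


def read_triggers(
    path: str | Path, video_rate_hz: float, eeg_rate_hz: float
) -> TriggerSeries:
    df = pd.read_csv(path)
    return TriggerSeries(
        video_frame_idx=df["video_frame_idx"].to_numpy(),
        eeg_sample_idx=df["eeg_sample_idx"].to_numpy(),
        video_rate_hz=video_rate_hz,
        eeg_rate_hz=eeg_rate_hz,
    )


def write_frames(frames: FrameSequence, path: str | Path) -> None:
    np.save(path, frames.frames)


def read_frames(path: str | Path, rate_hz: float) -> FrameSequence:
    return FrameSequence(frames=np.load(path), rate_hz=rate_hz)


def read_video(path: str | Path, rate_hz: float | None = None) -> FrameSequence:
    """Decode a standard video container to grayscale frames (via imageio)."""
    try:
        import imageio.v3 as iio
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading video containers requires imageio") from err
    from .motion import to_grayscale

    frames = np.asarray(iio.imread(path))
    if frames.ndim == 4:
        frames = to_grayscale(frames)
    if rate_hz is None:
        meta = iio.immeta(path)
        rate_hz = float(meta.get("fps", 0)) or 30.0
    return FrameSequence(frames=frames, rate_hz=rate_hz)


def write_cohort(records: list[SubjectRecording], out_dir: str | Path) -> None:
    """One directory per subject-stimulus recording, plus ground truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        d = out_dir / f"{rec.subject}__{rec.stimulus}"
        d.mkdir(exist_ok=True)
        write_eeg(rec.eeg, d / "eeg.dat")
        write_trace(rec.trace, d / "trace.csv")
        write_triggers(rec.triggers, d / "triggers.csv")
        truth = {
            "subject": rec.subject,
            "group": rec.group,
            "stimulus": rec.stimulus,
            "subject_multiplier": rec.subject_multiplier,
            "coupling": {
                "target_channels": rec.coupling.target_channels,
                "band_hz": list(rec.coupling.band_hz),
                "coupling_strength": rec.coupling.coupling_strength,
                "lag_s": rec.coupling.lag_s,
            },
        }
        (d / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def read_cohort(out_dir: str | Path) -> list[SubjectRecording]:
    out_dir = Path(out_dir)
    records = []
    for d in sorted(p for p in out_dir.iterdir() if p.is_dir()):
        truth = json.loads((d / "ground_truth.json").read_text())
        eeg = read_eeg(d / "eeg.dat")
        trace = read_trace(d / "trace.csv")
        triggers = read_triggers(
            d / "triggers.csv", trace.rate_hz, eeg.rate_hz
        )
        records.append(
            SubjectRecording(
                subject=truth["subject"],
                group=truth["group"],
                stimulus=truth["stimulus"],
                eeg=eeg,
                trace=trace,
                triggers=triggers,
                coupling=CouplingSpec(
                    target_channels=truth["coupling"]["target_channels"],
                    band_hz=tuple(truth["coupling"]["band_hz"]),
                    coupling_strength=truth["coupling"]["coupling_strength"],
                    lag_s=truth["coupling"]["lag_s"],
                ),
                subject_multiplier=truth["subject_multiplier"],
            )
        )
    return records
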