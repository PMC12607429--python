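"""Reading and writing collar-sensor CSV exports and annotation tracks.

The sensor dialect follows the Consensys-style export: a header row
``Timestamp, Accel_LN_X, Accel_LN_Y, Accel_LN_Z, Gyro_X, Gyro_Y, Gyro_Z``
with one row per sample at a nominally uniform rate (50 Hz in the study
configuration).  Annotations are interval tables
``subject_id, start_s, end_s, label`` with times in seconds relative to the
start of the recording; intervals are half-open ``[start, end)``.

Units are carried as declared metadata and never converted implicitly:
the simulator emits accelerations in m/s^2 and angular velocities in deg/s,
but a reader of third-party exports may declare whatever the logger used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("spinsense")

#: Canonical channel order used throughout the package.
CHANNELS = ("Accel_LN_X", "Accel_LN_Y", "Accel_LN_Z", "Gyro_X", "Gyro_Y", "Gyro_Z")
ACCEL_CHANNELS = CHANNELS[:3]
GYRO_CHANNELS = CHANNELS[3:]

DEFAULT_UNITS = {"accel_unit": "m/s^2", "gyro_unit": "deg/s"}

#: Allowed deviation of successive timestamp deltas from the nominal
#: sampling period (real loggers drift a little).
TIMESTAMP_JITTER_TOLERANCE = 0.02

#: Decimal places written to CSV; round-trips are bit-exact at this precision.
CSV_DECIMALS = 6


class FormatError(ValueError):
    """A file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Structurally valid data violates a domain invariant."""


@dataclass
class ImuRecording:
    """One subject's continuous 6-channel inertial stream at a fixed rate.

    ``data`` is an ``(n_samples, 6)`` float array in :data:`CHANNELS` order.
    """

    subject_id: str
    sampling_rate: float
    data: np.ndarray
    t0: float = 0.0
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise ValidationError(
                f"data must be (n_samples, {len(CHANNELS)}), got shape {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds (samples / rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds, relative to t0 = start."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]

    @property
    def accel(self) -> np.ndarray:
        return self.data[:, :3]

    @property
    def gyro(self) -> np.ndarray:
        return self.data[:, 3:]

    def gyro_magnitude(self) -> np.ndarray:
        """Per-sample Euclidean norm of the three angular-velocity axes."""
        return np.linalg.norm(self.gyro, axis=1)

    def accel_magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.accel, axis=1)


@dataclass
class AnnotationTrack:
    """Ground-truth behaviour intervals over one recording.

    ``intervals`` is a list of ``(start_s, end_s, label)`` tuples, sorted and
    non-overlapping, with half-open ``[start, end)`` semantics in seconds.
    """

    subject_id: str
    intervals: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs = [(float(s), float(e), str(lab)) for s, e, lab in self.intervals]
        for s, e, lab in ivs:
            if not s < e:
                raise ValidationError(f"interval start must precede end, got [{s}, {e})")
        ivs.sort(key=lambda iv: iv[0])
        for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValidationError(
                    f"overlapping intervals [{s0}, {e0}) and [{s1}, {e1})"
                )
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def labelled(self, label: str) -> list:
        return [iv for iv in self.intervals if iv[2] == label]

    def total_seconds(self, label: str | None = None) -> float:
        ivs = self.intervals if label is None else self.labelled(label)
        return float(sum(e - s for s, e, _ in ivs))


# ---------------------------------------------------------------------------
# Sensor CSV
# ---------------------------------------------------------------------------

def write_recording(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording in the Consensys-style CSV dialect."""
    path = Path(path)
    frame = pd.DataFrame(rec.data, columns=list(CHANNELS))
    frame.insert(0, "Timestamp", rec.times)
    frame.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f")
    return path


def read_recording(
    path: str | Path,
    sampling_rate: float | None = None,
    units: dict | None = None,
    subject_id: str | None = None,
    column_map: dict | None = None,
) -> ImuRecording:
    """Read a sensor CSV into a validated :class:`ImuRecording`.

    Parameters
    ----------
    sampling_rate:
        Declared rate in Hz; inferred from the timestamp column when omitted.
    column_map:
        Optional mapping from canonical channel names to the names used in
        the file, absorbing export-dialect differences.
    units:
        Declared units; defaults to the simulator's (m/s^2, deg/s).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    colmap = column_map or {}
    resolved = {name: colmap.get(name, name) for name in ("Timestamp",) + CHANNELS}
    missing = [src for src in resolved.values() if src not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    extra = [c for c in frame.columns if c not in resolved.values()]
    if extra:
        logger.info("%s: ignoring extra columns %s", path.name, extra)

    t = frame[resolved["Timestamp"]].to_numpy(dtype=float)
    if len(t) < 1:
        raise FormatError(f"{path.name}: no samples")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{path.name}: timestamps are not strictly increasing")
        period = np.median(dt)
        if np.any(np.abs(dt - period) > TIMESTAMP_JITTER_TOLERANCE * period):
            raise ValidationError(
                f"{path.name}: sampling is not uniform within "
                f"{TIMESTAMP_JITTER_TOLERANCE:.0%} period jitter"
            )
        inferred_rate = 1.0 / period
    else:
        inferred_rate = sampling_rate
        if inferred_rate is None:
            raise FormatError(f"{path.name}: single-sample file needs an explicit sampling_rate")
    rate = float(sampling_rate) if sampling_rate is not None else float(inferred_rate)

    data = frame[[resolved[c] for c in CHANNELS]].to_numpy(dtype=float)
    return ImuRecording(
        subject_id=subject_id or path.stem,
        sampling_rate=rate,
        data=data,
        t0=float(t[0]),
        units=dict(units or DEFAULT_UNITS),
    )


# ---------------------------------------------------------------------------
# Annotation CSV
# ---------------------------------------------------------------------------

def write_annotations(tracks: AnnotationTrack | Sequence[AnnotationTrack], path: str | Path) -> Path:
    """Write one or several annotation tracks to a shared interval CSV."""
    if isinstance(tracks, AnnotationTrack):
        tracks = [tracks]
    rows = [
        {"subject_id": tr.subject_id, "start_s": s, "end_s": e, "label": lab}
        for tr in tracks
        for s, e, lab in tr.intervals
    ]
    frame = pd.DataFrame(rows, columns=["subject_id", "start_s", "end_s", "label"])
    path = Path(path)
    frame.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f")
    return path


def read_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read an annotation CSV, returning one track per subject (sorted)."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = ["subject_id", "start_s", "end_s", "label"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    tracks = []
    for subject, grp in frame.groupby("subject_id", sort=True):
        intervals = list(zip(grp["start_s"], grp["end_s"], grp["label"]))
        tracks.append(AnnotationTrack(subject_id=str(subject), intervals=intervals))
    return tracks


# ---------------------------------------------------------------------------
# Annotation -> per-sample mask
# ---------------------------------------------------------------------------

def annotations_to_sample_mask(
    rec: ImuRecording, ann: AnnotationTrack, label: str | None = None
) -> np.ndarray:
    """Binary per-sample mask: 1 iff the sample's timestamp lies in some
    annotated ``[start, end)`` interval (optionally restricted to ``label``).
    """
    span_end = rec.t0 + rec.duration
    mask = np.zeros(rec.n_samples, dtype=bool)
    times = rec.times
    for s, e, lab in ann.intervals:
        if label is not None and lab != label:
            continue
        if s < rec.t0 - 1e-9 or e > span_end + 1e-9:
            raise ValidationError(
                f"interval [{s}, {e}) outside recording span [{rec.t0}, {span_end})"
            )
        mask |= (times >= s) & (times < e)
    return mask
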