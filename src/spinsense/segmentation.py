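"""Sliding-window segmentation, window labelling and event curation.

The continuous 6-channel stream is cut into fixed-length overlapping
windows (2.6 s / 130 samples at 50 Hz by default, stride 1.3 s for 50%
overlap).  A window is labelled ``spinning`` when at least 50% of its
samples fall inside an annotated spin interval — the threshold is
inclusive.  Trailing partial windows are dropped rather than padded so
every window yields a fixed-dimension feature vector.

For leakage-safe evaluation the stream is additionally partitioned into
behaviourally *pure* curated events of fixed length (7.8 s by default,
i.e. five constituent windows): a spin event fully contains one or more
complete spin intervals and never clips one at its boundary; a non-spin
event overlaps no spin interval at all.  Splits are made at the event
level so no behavioural occurrence spans both train and test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationTrack, ImuRecording, ValidationError

logger = logging.getLogger("spinsense")

SPINNING = "spinning"
NON_SPINNING = "non_spinning"

EVENT_CLASS_SPIN = "spin"
EVENT_CLASS_NON_SPIN = "non_spin"


@dataclass
class WindowingParams:
    """Sliding-window geometry and the labelling threshold."""

    window_size: float = 2.6  # seconds
    stride: float = 1.3  # seconds
    label_fraction: float = 0.5  # inclusive threshold on positive samples

    def __post_init__(self) -> None:
        if not 0 < self.stride <= self.window_size:
            raise ValidationError(
                f"stride must satisfy 0 < stride <= window_size, "
                f"got stride={self.stride}, window={self.window_size}"
            )
        if not 0 < self.label_fraction <= 1:
            raise ValidationError(
                f"label_fraction must be in (0, 1], got {self.label_fraction}"
            )

    def _samples(self, seconds: float, rate: float, what: str) -> int:
        n = seconds * rate
        if abs(n - round(n)) > 1e-6:
            raise ValidationError(
                f"{what} of {seconds}s is not a whole number of samples at {rate} Hz"
            )
        return int(round(n))

    def window_samples(self, rate: float) -> int:
        return self._samples(self.window_size, rate, "window_size")

    def stride_samples(self, rate: float) -> int:
        return self._samples(self.stride, rate, "stride")


@dataclass
class Segment:
    """One fixed-length window with its label and provenance."""

    subject_id: str
    start_sample: int
    data: np.ndarray  # (window_samples, 6)
    label: str  # SPINNING | NON_SPINNING
    event_id: str | None = None

    @property
    def is_spin(self) -> bool:
        return self.label == SPINNING


@dataclass
class CuratedEvent:
    """A behaviourally pure fixed-length stretch used for event-level splits."""

    subject_id: str
    span: tuple  # (start_s, end_s)
    klass: str  # EVENT_CLASS_SPIN | EVENT_CLASS_NON_SPIN
    event_id: str
    purity: bool = True


def segment_stream(
    rec: ImuRecording,
    mask: np.ndarray,
    params: WindowingParams,
    event_id: str | None = None,
    start_offset: int = 0,
) -> list[Segment]:
    """Cut a stream into labelled windows.

    Windows start at sample 0 and advance by the stride while fully inside
    the stream; the trailing partial window is dropped.  ``start_offset``
    shifts recorded ``start_sample`` provenance when segmenting a slice of
    a longer recording.
    """
    w = params.window_samples(rec.sampling_rate)
    s = params.stride_samples(rec.sampling_rate)
    n = rec.n_samples
    if mask.shape != (n,):
        raise ValidationError(f"mask length {mask.shape} does not match stream length {n}")
    if n < w:
        logger.warning(
            "%s: stream of %d samples shorter than one %d-sample window",
            rec.subject_id, n, w,
        )
        return []
    segments = []
    for start in range(0, n - w + 1, s):
        positives = int(mask[start : start + w].sum())
        label = SPINNING if positives / w >= params.label_fraction else NON_SPINNING
        segments.append(
            Segment(
                subject_id=rec.subject_id,
                start_sample=start_offset + start,
                data=rec.data[start : start + w],
                label=label,
                event_id=event_id,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Event curation
# ---------------------------------------------------------------------------

def _window_is_pure(
    start: float, end: float, intervals: list[tuple[float, float]]
) -> tuple[bool, bool]:
    """(pure, contains_spin) for a candidate event window [start, end]."""
    contains = False
    for s, e in intervals:
        overlaps = s < end and e > start
        if not overlaps:
            continue
        if s >= start and e <= end:
            contains = True
        else:
            return False, False  # partially clipped spin -> impure
    return True, contains


def curate_events(
    rec: ImuRecording,
    ann: AnnotationTrack,
    event_length: float = 7.8,
    params: WindowingParams | None = None,
    seed: int = 0,
) -> list[CuratedEvent]:
    """Partition a labelled stream into pure, non-overlapping curated events.

    Spin events are centred on their annotated interval and shifted when
    centring would clip a neighbouring spin; candidates that cannot be made
    pure (or spin intervals longer than ``event_length``) are dropped with a
    log message.  Non-spin events tile the spin-free stretches with a seeded
    random offset.
    """
    params = params or WindowingParams()
    if event_length < params.window_size:
        raise ValidationError(
            f"event_length {event_length}s is shorter than one window "
            f"({params.window_size}s)"
        )
    duration = rec.duration
    L = float(event_length)
    spans = [(s, e) for s, e, _ in ann.intervals]
    rng = np.random.default_rng(seed)
    events: list[CuratedEvent] = []
    occupied: list[tuple[float, float]] = []
    n_spin_events = 0

    # Walk the sorted spin intervals left to right, greedily grouping
    # neighbours whose joint span fits into one event, and place each event
    # inside its feasible start interval: it must contain the group, start
    # after the previous placed event and the previous spin, and end before
    # the next spin (so no spin is ever clipped).
    i = 0
    while i < len(spans):
        if spans[i][1] - spans[i][0] > L:
            logger.warning(
                "%s: spin [%0.2f, %0.2f)s longer than event_length %.1fs; excluded",
                rec.subject_id, spans[i][0], spans[i][1], L,
            )
            i += 1
            continue
        j_max = i
        while j_max + 1 < len(spans) and spans[j_max + 1][1] - spans[i][0] <= L:
            j_max += 1
        placed = False
        for j in range(j_max, i - 1, -1):
            cs, ce = spans[i][0], spans[j][1]
            prev_event_end = occupied[-1][1] if occupied else 0.0
            prev_span_end = spans[i - 1][1] if i > 0 else 0.0
            next_start = spans[j + 1][0] if j + 1 < len(spans) else duration
            lo = max(ce - L, prev_event_end, prev_span_end, 0.0)
            hi = min(cs, next_start - L, duration - L)
            if lo > hi + 1e-9:
                continue
            preferred = (cs + ce) / 2 - L / 2  # centre the spin group
            start = float(np.clip(preferred, lo, hi))
            pure, contains = _window_is_pure(start, start + L, spans)
            assert pure and contains, "feasible-interval placement must be pure"
            eid = f"{rec.subject_id}_spin{n_spin_events:03d}"
            events.append(CuratedEvent(rec.subject_id, (start, start + L), EVENT_CLASS_SPIN, eid))
            occupied.append((start, start + L))
            n_spin_events += 1
            i = j + 1
            placed = True
            break
        if not placed:
            logger.info(
                "%s: no pure %.1fs placement for spin [%0.2f, %0.2f)s; dropped",
                rec.subject_id, L, spans[i][0], spans[i][1],
            )
            i += 1

    # Non-spin events: tile spin-free gaps, avoiding already-placed events.
    blocked = sorted(occupied + spans)
    gaps = []
    cursor = 0.0
    for s, e in blocked:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    if duration > cursor:
        gaps.append((cursor, duration))
    n_non = 0
    for gs, ge in gaps:
        slack = (ge - gs) - event_length
        if slack < 0:
            continue
        offset = float(rng.uniform(0, min(event_length, slack + 1e-12)))
        start = gs + offset
        while start + event_length <= ge + 1e-9:
            eid = f"{rec.subject_id}_bg{n_non:03d}"
            events.append(
                CuratedEvent(rec.subject_id, (start, start + event_length), EVENT_CLASS_NON_SPIN, eid)
            )
            n_non += 1
            start += event_length
    events.sort(key=lambda ev: ev.span[0])
    return events


def split_events(
    events: list[CuratedEvent],
    ratio: float = 0.8,
    stratify: bool = True,
    seed: int = 0,
) -> tuple[list[CuratedEvent], list[CuratedEvent]]:
    """Event-disjoint train/test partition, stratified by event class.

    Class proportions are preserved to within one event per class; the
    split is deterministic per seed.
    """
    if not 0 < ratio < 1:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    train: list[CuratedEvent] = []
    test: list[CuratedEvent] = []
    if stratify:
        classes = sorted({ev.klass for ev in events})
        for klass in classes:
            members = [ev for ev in events if ev.klass == klass]
            if len(members) < 2:
                raise ValidationError(
                    f"class {klass!r} has {len(members)} event(s); "
                    "need >= 2 to stratify (use stratify=False)"
                )
            order = rng.permutation(len(members))
            n_train = int(round(ratio * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train.extend(members[i] for i in order[:n_train])
            test.extend(members[i] for i in order[n_train:])
    else:
        order = rng.permutation(len(events))
        n_train = int(round(ratio * len(events)))
        train = [events[i] for i in order[:n_train]]
        test = [events[i] for i in order[n_train:]]
    assert {ev.event_id for ev in train}.isdisjoint(ev.event_id for ev in test)
    return train, test


def segments_from_events(
    rec: ImuRecording,
    mask: np.ndarray,
    events: list[CuratedEvent],
    params: WindowingParams,
) -> list[Segment]:
    """Windows drawn from within curated events only, tagged with event ids."""
    rate = rec.sampling_rate
    out: list[Segment] = []
    for ev in events:
        if ev.subject_id != rec.subject_id:
            continue
        a = int(round(ev.span[0] * rate))
        # slice length from the span duration so float jitter in the start
        # position cannot eat a sample (and with it a whole window)
        b = min(a + int(round((ev.span[1] - ev.span[0]) * rate)), rec.n_samples)
        sub = ImuRecording(
            subject_id=rec.subject_id,
            sampling_rate=rate,
            data=rec.data[a:b],
            units=rec.units,
        )
        out.extend(
            segment_stream(sub, mask[a:b], params, event_id=ev.event_id, start_offset=a)
        )
    return out
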