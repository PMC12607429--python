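"""Per-window feature engineering and the three-stage selection pipeline.

Each window contributes 8 traces — the six raw channels plus the
accelerometer- and gyroscope-magnitude traces (per-sample Euclidean norm
of the respective 3 axes) — and each trace contributes six features:

* ``mean``, ``std`` (population), ``range`` (max - min);
* ``dom_freq``: frequency of the largest non-DC periodogram bin, Hz;
* ``spec_energy``: sum of squared spectral magnitudes over non-DC bins;
* ``spec_entropy``: Shannon entropy (base 2) of the non-DC power spectrum
  normalised to unit sum.

Spectra come from a single untapered periodogram of the window (no Welch
averaging); the DC bin is excluded so the spectral features are not
redundant with the mean.  A constant trace degenerates gracefully:
dominant frequency, energy and entropy are all 0, never NaN.

Selection is fitted on training rows only and applied statelessly:

1. drop features with variance below ``var_thresh`` (default 0.1, on raw
   unstandardised values);
2. among survivors, for each pair with |Pearson r| above ``corr_thresh``
   (default 0.95) drop the feature that comes later in schema order;
3. rank survivors by one-way ANOVA F-statistic against the binary label
   and keep the top ``k`` (default 20).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif

from .io import ValidationError
from .segmentation import Segment, SPINNING

logger = logging.getLogger("spinsense")

TRACE_NAMES = (
    "Accel_LN_X", "Accel_LN_Y", "Accel_LN_Z",
    "Gyro_X", "Gyro_Y", "Gyro_Z",
    "Accel_Mag", "Gyro_Mag",
)
STAT_NAMES = ("mean", "std", "range", "dom_freq", "spec_energy", "spec_entropy")

#: Stable, ordered feature schema (8 traces x 6 statistics = 48 features).
FEATURE_SCHEMA = tuple(f"{trace}__{stat}" for trace in TRACE_NAMES for stat in STAT_NAMES)

SCHEMA_VERSION = 1


class SchemaError(ValidationError):
    """A feature matrix does not carry the columns a transform requires."""


def _trace_features(x: np.ndarray, sampling_rate: float) -> tuple[float, ...]:
    mean = float(np.mean(x))
    std = float(np.std(x))  # population sd
    rng = float(np.ptp(x))
    if rng == 0.0:  # constant trace: degenerate spectrum, not FFT leakage
        return mean, std, rng, 0.0, 0.0, 0.0
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    power = spectrum[1:]  # DC excluded
    total = float(power.sum())
    if total <= 0.0:
        return mean, std, rng, 0.0, 0.0, 0.0
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sampling_rate)[1:]
    dom_freq = float(freqs[int(np.argmax(power))])
    p = power / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return mean, std, rng, dom_freq, total, entropy


def extract_features(seg: Segment, sampling_rate: float) -> dict[str, float]:
    """Compute the 48-feature vector for one window, keyed by schema name."""
    data = np.asarray(seg.data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 6:
        raise ValidationError(f"segment data must be (n, 6), got {data.shape}")
    traces = {name: data[:, i] for i, name in enumerate(TRACE_NAMES[:6])}
    traces["Accel_Mag"] = np.linalg.norm(data[:, :3], axis=1)
    traces["Gyro_Mag"] = np.linalg.norm(data[:, 3:], axis=1)
    out: dict[str, float] = {}
    for trace_name in TRACE_NAMES:
        values = _trace_features(traces[trace_name], sampling_rate)
        for stat_name, value in zip(STAT_NAMES, values):
            out[f"{trace_name}__{stat_name}"] = value
    return out


def extract_feature_matrix(
    segments: list[Segment], sampling_rate: float
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Feature matrix, binary labels (1 = spinning) and provenance table."""
    rows = [extract_features(seg, sampling_rate) for seg in segments]
    X = pd.DataFrame(rows, columns=list(FEATURE_SCHEMA))
    y = np.array([1 if seg.label == SPINNING else 0 for seg in segments], dtype=int)
    meta = pd.DataFrame(
        {
            "subject_id": [seg.subject_id for seg in segments],
            "event_id": [seg.event_id for seg in segments],
            "start_sample": [seg.start_sample for seg in segments],
            "label": [seg.label for seg in segments],
        }
    )
    return X, y, meta


# ---------------------------------------------------------------------------
# Three-stage selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    """Fitted state of the three-stage pipeline; sufficient on its own to
    transform any new feature matrix (stateless apply)."""

    variance_threshold: float
    dropped_low_variance: list[str]
    correlation_threshold: float
    dropped_collinear: list[tuple[str, str]]  # (dropped, retained partner)
    k: int
    selected: list[str]
    f_statistic: dict[str, float] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema_version": self.schema_version,
            "variance_threshold": self.variance_threshold,
            "dropped_low_variance": self.dropped_low_variance,
            "correlation_threshold": self.correlation_threshold,
            "dropped_collinear": [list(pair) for pair in self.dropped_collinear],
            "k": self.k,
            "selected": self.selected,
            "f_statistic": self.f_statistic,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SelectionReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            variance_threshold=payload["variance_threshold"],
            dropped_low_variance=list(payload["dropped_low_variance"]),
            correlation_threshold=payload["correlation_threshold"],
            dropped_collinear=[tuple(p) for p in payload["dropped_collinear"]],
            k=payload["k"],
            selected=list(payload["selected"]),
            f_statistic=dict(payload["f_statistic"]),
            schema_version=payload.get("schema_version", SCHEMA_VERSION),
        )


def fit_selection(
    train: pd.DataFrame,
    labels: np.ndarray,
    var_thresh: float = 0.1,
    corr_thresh: float = 0.95,
    k: int = 20,
) -> SelectionReport:
    """Fit the three-stage pipeline on training rows only."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValidationError("selection needs both classes in the training labels")
    counts = pd.Series(y).value_counts()
    if counts.min() < 2:
        raise ValidationError("selection needs >= 2 training rows per class")

    names = list(train.columns)
    values = train.to_numpy(dtype=float)

    # Stage 1: low-variance filter (population variance, raw values).
    variances = values.var(axis=0)
    dropped_low = [n for n, v in zip(names, variances) if v < var_thresh]
    survivors = [n for n in names if n not in set(dropped_low)]

    # Stage 2: collinearity reduction, keeping the earlier feature in schema order.
    dropped_collinear: list[tuple[str, str]] = []
    if survivors:
        corr = np.corrcoef(train[survivors].to_numpy(dtype=float), rowvar=False)
        corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
        alive = [True] * len(survivors)
        for i in range(len(survivors)):
            if not alive[i]:
                continue
            for j in range(i + 1, len(survivors)):
                if alive[j] and abs(corr[i, j]) > corr_thresh:
                    alive[j] = False
                    dropped_collinear.append((survivors[j], survivors[i]))
        survivors = [n for n, keep in zip(survivors, alive) if keep]

    if not survivors:
        raise ValidationError(
            "all features eliminated before univariate ranking "
            f"(stage 1 dropped {len(dropped_low)}, stage 2 dropped {len(dropped_collinear)})"
        )

    # Stage 3: univariate ANOVA F ranking, top k.
    f_values, _ = f_classif(train[survivors].to_numpy(dtype=float), y)
    f_values = np.nan_to_num(f_values, nan=0.0)
    order = np.argsort(-f_values, kind="stable")[: min(k, len(survivors))]
    selected = [survivors[i] for i in order]
    f_map = {n: float(f) for n, f in zip(survivors, f_values)}

    return SelectionReport(
        variance_threshold=var_thresh,
        dropped_low_variance=dropped_low,
        correlation_threshold=corr_thresh,
        dropped_collinear=dropped_collinear,
        k=k,
        selected=selected,
        f_statistic=f_map,
    )


def apply_selection(report: SelectionReport, x: pd.DataFrame) -> pd.DataFrame:
    """Restrict and order columns per the fitted report; never refits."""
    missing = [n for n in report.selected if n not in x.columns]
    if missing:
        raise SchemaError(f"feature matrix lacks selected column(s) {missing}")
    return x[report.selected]
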