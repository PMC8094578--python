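"""Heart-rate-variability features of short (~1 min) RR-interval series.

A tachogram — the sequence of times between consecutive R waves of the ECG —
is turned into a fixed 32-entry feature vector:

* 22 derivative moments: the mean ``m_d`` and sample standard deviation
  ``sd_d`` of the successive difference of order ``d`` for d = 0..10,
  computed on the *seconds* scale;
* 10 classic time-domain measures (SDANN, SDNNidx, SDSD, SDNN, RMSSD, pNN50,
  IRRR, HRV.index, TINN, MADRR), computed on the *milliseconds* scale.

The split of scales matches the conventional reporting of these quantities
(mean RR near 0.8 s; SDNN tens of ms).

Quality control follows the usual short-recording rules: an interval below
200 ms flags a misdetected R peak, above 3 s an undetected one; such series
are excluded, never repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "RRSeries",
    "FEATURE_NAMES",
    "quality_filter",
    "successive_derivative",
    "derivative_moments",
    "time_domain_measures",
    "extract_feature_vector",
    "features_from_series",
]

#: fixed, versioned feature order (schema version 1)
FEATURE_NAMES: tuple = tuple(
    [f"m_{d}" for d in range(11)]
    + [f"sd_{d}" for d in range(11)]
    + ["SDANN", "SDNNidx", "SDSD", "SDNN", "RMSSD", "pNN50",
       "IRRR", "HRV.index", "TINN", "MADRR"]
)

RHYTHM_LABELS = ("NSR", "AF", "unknown")

MIN_RR_MS = 200.0   # below: misdetected R peak
MAX_RR_MS = 3000.0  # above: undetected R peak

#: histogram bin width (ms) for the geometric measures; 1/128 s is the
#: standard sampling-grid convention of HRV analysis software
HIST_BIN_MS = 7.8125

WINDOW_S = 5.0      # short-window length for SDANN / SDNNidx on 1-min records


@dataclass(frozen=True)
class RRSeries:
    """One RR-interval time series with its rhythm annotation.

    intervals are in milliseconds, one per heartbeat.
    """

    intervals: np.ndarray
    rhythm_label: str = "unknown"
    series_id: str = ""

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", iv)
        if iv.ndim != 1:
            raise ValidationError("intervals must be a 1-D sequence")
        if iv.size and (not np.all(np.isfinite(iv)) or np.any(iv <= 0)):
            raise ValidationError("intervals must be positive and finite")
        if self.rhythm_label not in RHYTHM_LABELS:
            raise ValidationError(
                f"rhythm_label must be one of {RHYTHM_LABELS}, got {self.rhythm_label!r}"
            )

    def __len__(self) -> int:
        return self.intervals.size


@dataclass(frozen=True)
class QualityVerdict:
    valid: bool
    reasons: list = field(default_factory=list)


def quality_filter(series: RRSeries) -> QualityVerdict:
    """Flag misdetected (< 200 ms) and undetected (> 3 s) R peaks.

    Always returns a verdict; ``reasons`` lists each violated rule with the
    index of the offending interval.
    """
    iv = series.intervals
    reasons = []
    for i in np.nonzero(iv < MIN_RR_MS)[0]:
        reasons.append(f"misdetected R peak: RR interval < 200ms at index {i}")
    for i in np.nonzero(iv > MAX_RR_MS)[0]:
        reasons.append(f"undetected R peak: RR interval > 3s at index {i}")
    return QualityVerdict(valid=not reasons, reasons=reasons)


def successive_derivative(series, order: int):
    """Successive difference of a sequence.

    Order 0 returns the input unchanged; order ``d`` applies ``d`` first
    differences, shrinking the length by one per order.
    """
    if not isinstance(order, (int, np.integer)) or isinstance(order, bool):
        raise ValidationError("order must be an integer")
    if order < 0 or order > 10:
        raise ValidationError(f"derivative order must be in 0..10, got {order}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValidationError("series must be 1-D")
    if x.size <= order:
        raise ValidationError(
            f"series of length {x.size} too short for derivative order {order}"
        )
    if order == 0:
        return x.copy()
    return np.diff(x, n=order)


def _check_quality(series: RRSeries):
    verdict = quality_filter(series)
    if not verdict.valid:
        raise ValidationError(
            "series failed quality filter: " + "; ".join(verdict.reasons)
        )


def derivative_moments(series: RRSeries) -> dict:
    """Means ``m_0..m_10`` and sample SDs ``sd_0..sd_10`` of the successive
    derivatives, on the seconds scale.

    Requires at least 12 intervals so the order-10 derivative still has two
    points (sample SD needs ``n - 1 >= 1``).
    """
    _check_quality(series)
    if len(series) < 12:
        raise ValidationError(
            f"need at least 12 intervals for derivative moments, got {len(series)}"
        )
    x = series.intervals / 1000.0  # seconds
    out = {}
    for d in range(11):
        der = successive_derivative(x, d)
        out[f"m_{d}"] = float(der.mean())
        out[f"sd_{d}"] = float(der.std(ddof=1))
    return out


def _windows_5s(iv_ms: np.ndarray):
    """Split a tachogram into consecutive windows of >= 5 s cumulative time.

    A window closes as soon as its cumulative time reaches 5 s.  The final
    partial window is kept if it has at least 2 intervals, else dropped.
    """
    windows, current, acc = [], [], 0.0
    for v in iv_ms:
        current.append(v)
        acc += v
        if acc >= WINDOW_S * 1000.0:
            windows.append(np.asarray(current))
            current, acc = [], 0.0
    if len(current) >= 2:
        windows.append(np.asarray(current))
    return windows


def _triangular_fit_width(edges: np.ndarray, counts: np.ndarray) -> float:
    """Base width M - N of the best least-squares triangular fit to a histogram.

    The triangle is zero at N and M, peaks at the modal bin centre with the
    modal height, and N/M are grid-searched over bin edges on either side of
    the mode.
    """
    if counts.sum() == 0:
        return 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak = int(np.argmax(counts))
    xc, yc = centers[peak], counts[peak]
    best = (np.inf, 0.0)
    left_edges = edges[: peak + 1]          # candidate N, <= left edge of mode
    right_edges = edges[peak + 1:]          # candidate M, >= right edge of mode
    for n_edge in left_edges:
        for m_edge in right_edges:
            tri = np.zeros_like(counts, dtype=float)
            rising = (centers > n_edge) & (centers <= xc)
            falling = (centers > xc) & (centers < m_edge)
            if xc > n_edge:
                tri[rising] = yc * (centers[rising] - n_edge) / (xc - n_edge)
            tri[centers == xc] = yc
            if m_edge > xc:
                tri[falling] = yc * (m_edge - centers[falling]) / (m_edge - xc)
            err = float(np.sum((tri - counts) ** 2))
            if err < best[0] - 1e-12:
                best = (err, float(m_edge - n_edge))
    return best[1]


def time_domain_measures(series: RRSeries) -> dict:
    """The ten classic time-domain HRV measures, on the milliseconds scale.

    SDANN / SDNNidx use 5-s windows (appropriate for 1-min records); a series
    yielding a single window gets SDANN = 0 with a warning.  The histogram
    for HRV.index / TINN uses 7.8125 ms bins aligned at 0; IRRR uses
    linearly-interpolated quantiles.
    """
    _check_quality(series)
    iv = series.intervals
    if iv.size < 2:
        raise ValidationError("need at least 2 intervals for time-domain measures")
    diffs = np.diff(iv)
    out = {}

    windows = _windows_5s(iv)
    if len(windows) <= 1:
        warnings.warn(
            "series spans a single 5-s window; SDANN is 0 by convention",
            stacklevel=2,
        )
        out["SDANN"] = 0.0
        out["SDNNidx"] = float(windows[0].std(ddof=1)) if windows else 0.0
    else:
        means = np.array([w.mean() for w in windows])
        sds = np.array([w.std(ddof=1) for w in windows])
        out["SDANN"] = float(means.std(ddof=1))
        out["SDNNidx"] = float(sds.mean())

    out["SDSD"] = float(diffs.std(ddof=1)) if diffs.size >= 2 else 0.0
    out["SDNN"] = float(iv.std(ddof=1))
    out["RMSSD"] = float(np.sqrt(np.mean(diffs ** 2)))
    out["pNN50"] = float(100.0 * np.mean(np.abs(diffs) > 50.0))
    q1, q3 = np.quantile(iv, [0.25, 0.75])  # linear interpolation (type 7)
    out["IRRR"] = float(q3 - q1)

    lo = np.floor(iv.min() / HIST_BIN_MS) * HIST_BIN_MS
    hi = np.ceil(iv.max() / HIST_BIN_MS) * HIST_BIN_MS
    if hi <= lo:
        hi = lo + HIST_BIN_MS
    edges = np.arange(lo, hi + HIST_BIN_MS / 2, HIST_BIN_MS)
    counts, edges = np.histogram(iv, bins=edges)
    out["HRV.index"] = float(iv.size / counts.max())
    out["TINN"] = _triangular_fit_width(edges, counts.astype(float))

    out["MADRR"] = float(np.median(np.abs(diffs)))
    return out


def extract_feature_vector(series: RRSeries) -> pd.Series:
    """Full 32-entry feature vector in the fixed :data:`FEATURE_NAMES` order."""
    values = {}
    values.update(derivative_moments(series))
    values.update(time_domain_measures(series))
    return pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES))


def features_from_series(series_list, skip_invalid: bool = True):
    """Feature table for a collection of series.

    Returns ``(features, labels)``: a DataFrame indexed by series_id with the
    32 feature columns, and a Series of rhythm labels encoded 0 = NSR,
    1 = AF (``unknown`` labels become NA).  Series failing the quality filter
    are dropped when ``skip_invalid`` (default), else raise.
    """
    rows, labels, ids = [], [], []
    for i, s in enumerate(series_list):
        verdict = quality_filter(s)
        if not verdict.valid:
            if skip_invalid:
                continue
            raise ValidationError(
                f"series {s.series_id or i} failed quality filter: "
                + "; ".join(verdict.reasons)
            )
        rows.append(extract_feature_vector(s))
        labels.append({"NSR": 0, "AF": 1}.get(s.rhythm_label, pd.NA))
        ids.append(s.series_id or f"series_{i}")
    if not rows:
        raise ValidationError("no valid series to extract features from")
    features = pd.DataFrame(rows)
    features.index = pd.Index(ids, name="series_id")
    return features, pd.Series(labels, index=features.index, name="label")
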