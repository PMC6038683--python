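"""Peak-count features per component and two-group comparison.

The per-subject feature is the number of prominent oscillation peaks in each
decomposed component: interior positive local maxima whose topographic
prominence is at least a configurable fraction of the signal's RMS. Feature
distributions of the two groups are compared with a two-sided two-sample
Student's t-test (pooled variance by default, Welch behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.ndimage import median_filter
from scipy.signal import peak_prominences

from .emd_hht import IMFSet, find_extrema
from .errors import ParameterError

__all__ = ["FeatureVector", "GroupComparison", "count_peaks",
           "features_for_subject", "ttest_two_sample", "compare_cohorts"]


@dataclass(frozen=True)
class FeatureVector:
    """Per-subject peak counts, one per component, plus the group label."""

    subject_id: str
    deltas: tuple[int, ...]
    label: str

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.deltas):
            raise ParameterError("peak counts must be non-negative")
        if self.label not in ("PB", "nPB"):
            raise ParameterError(f"label must be PB or nPB, got {self.label!r}")


@dataclass
class GroupComparison:
    """Per-component-index group means, t statistics and two-sided p-values."""

    rows: list[dict]   # keys: imf_index, mean_pb, mean_npb, t_statistic, p_value
    n_pb: int
    n_npb: int
    variant: str

    def p_value(self, imf_index: int) -> float:
        for row in self.rows:
            if row["imf_index"] == imf_index:
                return row["p_value"]
        raise KeyError(imf_index)


def count_peaks(x: np.ndarray, prominence_frac: float = 0.5,
                detrend: int | None = None) -> int:
    """Count interior positive local maxima with topographic prominence of at
    least ``prominence_frac`` times the RMS of the (optionally detrended)
    signal. ``detrend`` subtracts a moving median of that window length
    first, for use on raw ventilation rather than zero-mean components.
    Plateaus contribute their first sample.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("need at least 3 samples to count peaks")
    if detrend is not None:
        x = x - median_filter(x, size=int(detrend), mode="nearest")
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        return 0
    maxima, _ = find_extrema(x)
    maxima = maxima[x[maxima] > 0]
    if len(maxima) == 0:
        return 0
    prom = peak_prominences(x, maxima)[0]
    return int(np.count_nonzero(prom >= prominence_frac * rms))


def features_for_subject(imfset: IMFSet, subject_id: str = "",
                         label: str = "nPB",
                         prominence_frac: float = 0.5) -> FeatureVector:
    """Peak count of every component, in fast-to-slow order. Components are
    zero-mean by construction, so no detrending is applied."""
    if imfset.n == 0:
        raise ParameterError("empty decomposition: no components to count")
    deltas = tuple(count_peaks(imf, prominence_frac=prominence_frac)
                   for imf in imfset.imfs)
    return FeatureVector(subject_id=subject_id, deltas=deltas, label=label)


def ttest_two_sample(a, b, variant: str = "pooled") -> tuple[float, float]:
    """Two-sided two-sample t-test.

    ``pooled`` is the classical equal-variance Student's t; ``welch`` does
    not pool. Degenerate case: both groups constant with equal means returns
    (0.0, 1.0); both constant with different means returns (inf, 0.0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 values")
    if variant not in ("pooled", "welch"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def compare_cohorts(features: list[FeatureVector],
                    variant: str = "pooled") -> GroupComparison:
    """Per-component t-tests of peak counts between the PB and nPB groups.

    Only component indices present in every subject of both groups are
    compared, so subjects with fewer components truncate the table.
    """
    pb = [f for f in features if f.label == "PB"]
    npb = [f for f in features if f.label == "nPB"]
    if len(pb) < 2 or len(npb) < 2:
        raise ParameterError(
            f"need >= 2 subjects per group, got {len(pb)} PB / {len(npb)} nPB")
    n_common = min(len(f.deltas) for f in features)
    rows = []
    for i in range(n_common):
        a = [f.deltas[i] for f in pb]
        b = [f.deltas[i] for f in npb]
        t, p = ttest_two_sample(a, b, variant=variant)
        rows.append({
            "imf_index": i + 1,
            "mean_pb": float(np.mean(a)),
            "mean_npb": float(np.mean(b)),
            "t_statistic": t,
            "p_value": p,
        })
    return GroupComparison(rows=rows, n_pb=len(pb), n_npb=len(npb), variant=variant)
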