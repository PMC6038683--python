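"""White-noise significance screening of decomposed components.

Each component is summarized by its mean period (samples per oscillation
peak) and mean energy per sample. Components of unit-variance white noise
scatter along a line of slope about -1 in the (log period, log energy)
plane; an observed component is deemed significant when its energy exceeds
the Monte-Carlo upper quantile of that null scatter at its period. The null
is simulated self-contained: many white-noise series of the same length are
decomposed with the very same algorithm, their (log period, log energy)
pairs pooled, binned in log period, and per-bin upper percentiles are
interpolated into confidence curves. The input series is rescaled to unit
variance before the comparison so flags are scale-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .emd_hht import IMFSet, emd, find_extrema
from .errors import ParameterError

__all__ = ["ImfSummary", "NullCurves", "SignificanceResult",
           "summarize_imf", "null_ensemble", "test_imfs"]


@dataclass(frozen=True)
class ImfSummary:
    """Mean period (breaths) and energy per sample of one component."""

    index: int
    mean_period: float
    energy: float

    @property
    def log_period(self) -> float:
        return float(np.log(self.mean_period))

    @property
    def log_energy(self) -> float:
        # all-zero components get -inf, which never clears any curve
        return float(np.log(self.energy)) if self.energy > 0 else -np.inf


@dataclass
class NullCurves:
    """Interpolable null upper quantiles of log energy vs log period."""

    levels: tuple[float, ...]
    bin_centers: np.ndarray
    curve_values: dict[float, np.ndarray]
    n_null: int
    seed: int | None
    scatter_log_period: np.ndarray
    scatter_log_energy: np.ndarray

    def __call__(self, level: float, log_period: np.ndarray | float) -> np.ndarray:
        if level not in self.curve_values:
            raise ParameterError(f"no null curve for level {level}")
        return np.interp(log_period, self.bin_centers, self.curve_values[level])


@dataclass
class SignificanceResult:
    """Per-component summaries and significance flags at each level."""

    summaries: list[ImfSummary]
    null_curves: NullCurves
    flags: dict[float, list[bool]]
    n_null: int
    seed: int | None


def summarize_imf(imf: np.ndarray, index: int = 0) -> ImfSummary:
    """Energy = mean squared value; mean period = N / (number of maxima),
    falling back to N when the component has no interior maxima."""
    imf = np.asarray(imf, dtype=float)
    n = len(imf)
    if n < 4:
        raise ParameterError("component too short to summarize")
    energy = float(np.mean(imf**2))
    maxima, _ = find_extrema(imf)
    mean_period = n / len(maxima) if len(maxima) > 0 else float(n)
    return ImfSummary(index=index, mean_period=float(mean_period), energy=energy)


def null_ensemble(N: int, n_null: int = 1000, seed: int | None = None,
                  levels: tuple[float, ...] = (0.95, 0.99),
                  n_bins: int = 20, min_bin_count: int = 10,
                  max_imfs: int = 10) -> NullCurves:
    """Monte-Carlo null scatter and confidence curves for length-N inputs.

    Decomposes ``n_null`` unit-variance standard-normal series, pools every
    component's (log period, log energy) pair, bins log period into
    ``n_bins`` equal-width bins, and takes per-bin upper percentiles at each
    level. Bins with fewer than ``min_bin_count`` points are dropped before
    interpolation; the curves are made non-increasing in log period (the
    theoretical shape) by a right-to-left running maximum, which only ever
    raises them, keeping the test conservative.
    """
    if N < 32:
        raise ParameterError("N must be >= 32 for a stable null ensemble")
    if n_null < 100:
        warnings.warn("n_null < 100: null curves will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    log_p, log_e = [], []
    for _ in range(n_null):
        x = rng.standard_normal(N)
        x = x / x.std()
        for j, imf in enumerate(emd(x, max_imfs=max_imfs).imfs):
            s = summarize_imf(imf, index=j + 1)
            if np.isfinite(s.log_energy):
                log_p.append(s.log_period)
                log_e.append(s.log_energy)
    log_p = np.asarray(log_p)
    log_e = np.asarray(log_e)

    edges = np.linspace(log_p.min(), log_p.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(log_p, edges) - 1, 0, n_bins - 1)
    centers, values = [], {lv: [] for lv in levels}
    for b in range(n_bins):
        sel = which == b
        if np.count_nonzero(sel) < min_bin_count:
            continue
        centers.append((edges[b] + edges[b + 1]) / 2.0)
        for lv in levels:
            values[lv].append(np.percentile(log_e[sel], 100.0 * lv))
    centers = np.asarray(centers)
    curve_values = {}
    for lv in levels:
        v = np.asarray(values[lv])
        # enforce the theoretical monotone shape conservatively
        curve_values[lv] = np.maximum.accumulate(v[::-1])[::-1]
    return NullCurves(levels=tuple(levels), bin_centers=centers,
                      curve_values=curve_values, n_null=n_null, seed=seed,
                      scatter_log_period=log_p, scatter_log_energy=log_e)


def test_imfs(imfset: IMFSet, levels: tuple[float, ...] = (0.95, 0.99),
              n_null: int = 1000, seed: int | None = None,
              null_curves: NullCurves | None = None) -> SignificanceResult:
    """Flag each component whose log energy exceeds the null curve at its
    log period, after rescaling the reconstructed input to unit variance.

    A precomputed :class:`NullCurves` for the same length may be passed to
    amortize the Monte-Carlo cost across subjects.
    """
    if imfset.n == 0:
        raise ParameterError("empty decomposition")
    x = imfset.reconstruct()
    scale = float(np.std(x))
    if scale == 0:
        raise ParameterError("constant input: significance test undefined")
    summaries = [summarize_imf(imf / scale, index=j + 1)
                 for j, imf in enumerate(imfset.imfs)]
    if null_curves is None and levels:
        null_curves = null_ensemble(len(x), n_null=n_null, seed=seed, levels=levels)
    flags: dict[float, list[bool]] = {}
    for lv in levels:
        flags[lv] = [bool(s.log_energy > null_curves(lv, s.log_period))
                     for s in summaries]
    return SignificanceResult(summaries=summaries, null_curves=null_curves,
                              flags=flags, n_null=n_null, seed=seed)
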