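"""Empirical mode decomposition and per-component analytic-signal analysis.

The decomposition repeatedly sifts the signal: cubic-spline envelopes are
drawn through the maxima and minima (with the two nearest extrema mirrored
across each end to tame boundary swings), their mean is subtracted, and the
process iterates until the candidate satisfies the Cauchy-style stopping
criterion and the oscillatory-mode shape condition (extrema and
zero-crossing counts differing by at most one). Extracted components are
subtracted from the running residue until the residue is monotone or too
extrema-poor to sift. By construction the components plus the residue sum
exactly to the input.

Each component can then be lifted to its analytic signal to obtain
instantaneous amplitude, unwrapped phase and instantaneous frequency in
cycles per breath (the sample axis is breath number, not seconds, because
breath spacing is irregular in time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert

from .errors import ParameterError, ResidueReached

__all__ = ["IMFSet", "AnalyticIMF", "find_extrema", "zero_crossings",
           "sift_once", "extract_imf", "emd", "hilbert_analytic"]


@dataclass
class IMFSet:
    """Oscillatory components C_1..C_n (fast to slow) plus monotone residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray

    @property
    def n(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all components and the residue (equals the input)."""
        out = self.residue.copy()
        for c in self.imfs:
            out += c
        return out

    def __len__(self) -> int:
        return len(self.residue)


@dataclass
class AnalyticIMF:
    """Analytic-signal view of one component."""

    amplitude: np.ndarray   # a(t) >= 0
    phase: np.ndarray       # unwrapped, radians
    inst_freq: np.ndarray   # cycles per breath, length N-1

    @property
    def mean_freq(self) -> float:
        return float(np.mean(self.inst_freq))


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior strict maxima and minima.

    A plateau contributes its first sample; endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("need at least 3 samples to find extrema")
    dx = np.diff(x)
    nz = np.flatnonzero(dx)
    if len(nz) < 2:
        return np.array([], dtype=int), np.array([], dtype=int)
    s = np.sign(dx[nz])
    turn = np.flatnonzero(np.diff(s))
    idx = nz[turn] + 1  # first sample of a plateau, or the extremum itself
    maxima = idx[s[turn] > 0]
    minima = idx[s[turn] < 0]
    return maxima, minima


def zero_crossings(x: np.ndarray) -> int:
    """Number of sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def is_imf_shaped(x: np.ndarray, tol: int = 1) -> bool:
    """Extrema and zero-crossing counts differ by at most ``tol``."""
    maxima, minima = find_extrema(x)
    n_ext = len(maxima) + len(minima)
    return abs(n_ext - zero_crossings(x)) <= tol


def _envelope(pos: np.ndarray, val: np.ndarray, n: int) -> np.ndarray:
    """Natural cubic spline through extrema, the two nearest mirrored across
    each end, evaluated on 0..n-1."""
    left_p = -pos[:2][::-1]
    left_v = val[:2][::-1]
    right_p = 2 * (n - 1) - pos[-2:][::-1]
    right_v = val[-2:][::-1]
    xs = np.concatenate([left_p, pos, right_p])
    ys = np.concatenate([left_v, val, right_v])
    xs, order = np.unique(xs, return_index=True)
    return CubicSpline(xs, ys[order], bc_type="natural")(np.arange(n))


def sift_once(x: np.ndarray) -> np.ndarray:
    """One sifting pass: subtract the mean of the upper/lower envelopes.

    Raises :class:`ResidueReached` when fewer than two maxima or two minima
    remain, i.e. the sequence can no longer support envelopes.
    """
    x = np.asarray(x, dtype=float)
    maxima, minima = find_extrema(x)
    if len(maxima) < 2 or len(minima) < 2:
        raise ResidueReached(
            f"too few extrema to sift ({len(maxima)} maxima, {len(minima)} minima)")
    upper = _envelope(maxima, x[maxima], len(x))
    lower = _envelope(minima, x[minima], len(x))
    return x - (upper + lower) / 2.0


def extract_imf(x: np.ndarray, sd_stop: float = 0.2, max_sift: int = 50) -> np.ndarray:
    """Sift until the component stabilizes.

    Stops when the relative change between consecutive sifts,
    SD = sum((h_prev - h)^2) / sum(h_prev^2), drops below ``sd_stop`` and the
    candidate is oscillatory-mode shaped, or after ``max_sift`` passes. If
    the envelopes collapse mid-way the current candidate is finalized.
    """
    h = sift_once(x)  # first pass: propagate ResidueReached to the caller
    for _ in range(max_sift - 1):
        denom = float(np.sum(h**2))
        if denom == 0:
            break
        try:
            h_next = sift_once(h)
        except ResidueReached:
            break
        sd = float(np.sum((h - h_next) ** 2)) / denom
        h = h_next
        if sd < sd_stop and is_imf_shaped(h):
            break
    return h


def emd(x: np.ndarray, max_imfs: int = 10, sd_stop: float = 0.2,
        max_sift: int = 50) -> IMFSet:
    """Full decomposition into fast-to-slow components plus a residue."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ParameterError("need at least 8 samples to decompose")
    imfs: list[np.ndarray] = []
    residue = x.copy()
    while len(imfs) < max_imfs:
        try:
            imf = extract_imf(residue, sd_stop=sd_stop, max_sift=max_sift)
        except ResidueReached:
            break
        imfs.append(imf)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue)


def hilbert_analytic(imf: np.ndarray) -> AnalyticIMF:
    """Analytic amplitude/phase/instantaneous frequency of one component.

    Uses the discrete analytic-signal construction (negative-frequency
    suppression); instantaneous frequency is the forward first difference of
    the unwrapped phase divided by 2 pi, in cycles per breath.
    """
    imf = np.asarray(imf, dtype=float)
    if len(imf) < 8:
        raise ParameterError("need at least 8 samples for the analytic signal")
    analytic = hilbert(imf)
    amplitude = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_freq = np.diff(phase) / (2.0 * np.pi)
    return AnalyticIMF(amplitude=amplitude, phase=phase, inst_freq=inst_freq)
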