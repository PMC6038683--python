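"""Pre-peak window selection and AR-based removal of aberrant breaths.

The analysis keeps the k breaths immediately before the global ventilation
maximum, fits an autoregressive model with intercept

    y_hat_t = c + phi_1 y_{t-1} + ... + phi_p y_{t-p}

by ordinary least squares on the raw window, predicts each breath one step
ahead from its observed predecessors, and discards every breath whose
measured VE falls below ``threshold * y_hat_t`` — the signature of a gasping
exhalation recorded as spuriously low breaths. The surviving sequence is the
filtered pre-peak ventilation signal passed to the decomposition stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSeriesError, InsufficientHistoryError, ParameterError
from .series import BreathSeries

__all__ = ["ARModel", "MeeVeResult", "select_window", "fit_ar", "predict",
           "apply_filter", "filter_mee"]


@dataclass(frozen=True)
class ARModel:
    """Autoregressive model of order p with intercept c."""

    c: float
    phi: np.ndarray
    p: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        if self.p < 1:
            raise ParameterError("AR order p must be >= 1")
        if len(self.phi) != self.p:
            raise ParameterError(f"len(phi)={len(self.phi)} does not match p={self.p}")


@dataclass
class MeeVeResult:
    """Outcome of the pre-peak filter for one subject."""

    window_start: int
    window_end: int
    kept: np.ndarray
    removed_indices: np.ndarray  # absolute indices into the source series
    predictions: np.ndarray      # y_hat for window positions p .. window_len-1
    model: ARModel
    threshold: float = 0.8
    k: int = 200
    kept_times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start

    @property
    def removed_window_offsets(self) -> np.ndarray:
        return self.removed_indices - self.window_start


def select_window(series: BreathSeries, k: int = 200,
                  allow_short: bool = False) -> tuple[int, int]:
    """Half-open breath-index interval of the k breaths before the VE peak.

    The peak breath itself is excluded; ties on the maximum resolve to the
    first occurrence. With ``allow_short`` a peak earlier than breath k
    yields the truncated interval ``[0, i_max)`` instead of an error.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    i_max = int(np.argmax(series.ve))
    if i_max == 0:
        raise InsufficientHistoryError(
            f"{series.subject_id}: peak at series start, empty pre-peak window")
    if i_max < k:
        if not allow_short:
            raise InsufficientHistoryError(
                f"{series.subject_id}: only {i_max} breaths precede the peak, "
                f"need {k} (pass allow_short to truncate)")
        return 0, i_max
    return i_max - k, i_max


def fit_ar(window: np.ndarray, p: int = 6, method: str = "ols") -> ARModel:
    """Fit c, phi_1..phi_p to a VE sequence.

    ``method="ols"`` (default) minimizes the sum of squared one-step
    prediction errors over t = p..N-1 via least squares on the lag matrix
    with an intercept column; an exact AR(p) relation is recovered exactly.
    ``method="yule_walker"`` uses the Yule-Walker moment equations instead.
    """
    y = np.asarray(window, dtype=float)
    n = len(y)
    if n <= 2 * p + 1:
        raise DegenerateSeriesError(f"window length {n} too short for AR({p}) fit")
    if np.ptp(y) == 0:
        raise DegenerateSeriesError("constant window: AR fit is degenerate")
    if method == "yule_walker":
        from statsmodels.regression.linear_model import yule_walker
        rho, _ = yule_walker(y - y.mean(), order=p, method="mle")
        c = float(y.mean() * (1.0 - rho.sum()))
        return ARModel(c=c, phi=np.asarray(rho, dtype=float), p=p)
    if method != "ols":
        raise ParameterError(f"unknown AR fitting method {method!r}")
    # design matrix: [1, y_{t-1}, ..., y_{t-p}] for t = p..n-1
    lags = np.column_stack([y[p - j - 1:n - j - 1] for j in range(p)])
    design = np.column_stack([np.ones(n - p), lags])
    if np.linalg.matrix_rank(design) < p + 1:
        raise DegenerateSeriesError("rank-deficient lag matrix: AR fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, y[p:], rcond=None)
    return ARModel(c=float(coef[0]), phi=coef[1:], p=p)


def predict(model: ARModel, window: np.ndarray) -> np.ndarray:
    """One-step-ahead predictions y_hat_t for t = p..N-1.

    Each prediction uses the p *observed* predecessors, never previous
    predictions, so every breath is judged against the measured history.
    """
    y = np.asarray(window, dtype=float)
    n, p = len(y), model.p
    if n <= p:
        raise ParameterError(f"window length {n} must exceed AR order {p}")
    lags = np.column_stack([y[p - j - 1:n - j - 1] for j in range(p)])
    return model.c + lags @ model.phi


def apply_filter(window: np.ndarray, model: ARModel, threshold: float = 0.8,
                 history: str = "kept") -> tuple[np.ndarray, np.ndarray]:
    """Apply the low-breath removal rule with a given model.

    Returns ``(predictions, removed_offsets)`` where predictions cover window
    positions p..N-1 and removed offsets are the positions with
    ``y_t < threshold * y_hat_t``. See :func:`filter_mee` for ``history``.
    """
    window = np.asarray(window, dtype=float)
    p = model.p
    if history == "window":
        preds = predict(model, window)
        removed = np.flatnonzero(window[p:] < threshold * preds) + p
        return preds, removed
    preds = np.empty(len(window) - p)
    kept_hist = list(window[:p])
    removed_list: list[int] = []
    for t in range(p, len(window)):
        y_hat = model.c + float(np.dot(model.phi, kept_hist[-1:-p - 1:-1]))
        preds[t - p] = y_hat
        if window[t] < threshold * y_hat:
            removed_list.append(t)
        else:
            kept_hist.append(window[t])
    return preds, np.asarray(removed_list, dtype=int)


def filter_mee(series: BreathSeries, k: int = 200, p: int = 6,
               threshold: float = 0.8, allow_short: bool = False,
               method: str = "ols", history: str = "kept") -> MeeVeResult:
    """Single-pass fit-then-filter of the pre-peak window.

    The AR model is fitted once on the unfiltered window; every breath
    t >= p with ``y_t < threshold * y_hat_t`` is removed. The first p
    breaths have no prediction and are always kept. Removed breaths are
    deleted so the output is re-indexed consecutively.

    ``history`` controls what feeds the one-step-ahead predictions:

    - ``"kept"`` (default): the p most recent breaths *not already removed*
      during the left-to-right pass. An aberrant breath then never poisons
      the predictions of its successors, so runs of consecutive low breaths
      (a gasp recorded as two breaths) are all caught.
    - ``"window"``: the p observed predecessors in the raw window,
      regardless of earlier removals.
    """
    if not 0.0 < threshold < 1.0:
        raise ParameterError("threshold must be in (0, 1)")
    if history not in ("kept", "window"):
        raise ParameterError(f"unknown history mode {history!r}")
    start, end = select_window(series, k=k, allow_short=allow_short)
    window = series.ve[start:end]
    times = series.times[start:end]
    model = fit_ar(window, p=p, method=method)
    preds, removed_rel = apply_filter(window, model, threshold=threshold,
                                      history=history)
    keep_mask = np.ones(len(window), dtype=bool)
    keep_mask[removed_rel] = False
    return MeeVeResult(
        window_start=start,
        window_end=end,
        kept=window[keep_mask],
        removed_indices=removed_rel + start,
        predictions=preds,
        model=model,
        threshold=threshold,
        k=k,
        kept_times=times[keep_mask],
    )
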