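"""Model-quality metrics: percent fit (NRMSE style), maximum absolute
error, and Akaike's Final Prediction Error.

The percent fit is the system-identification convention
fit = 100 * (1 - ||y_pred - y|| / ||y - mean(y)||), with Euclidean norms
taken per output channel over the full time series.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["fit_percent", "max_abs_error", "fpe", "FitReport"]


def fit_percent(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Percent fit of a prediction to a reference series (<= 100).

    Undefined (raises) for a constant reference, whose normalization
    denominator vanishes.
    """
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("fit undefined: reference series is constant")
    return float(100.0 * (1.0 - np.linalg.norm(y_pred - y) / denom))


def max_abs_error(y: np.ndarray, y_pred: np.ndarray) -> float:
    """max over t of |y_pred(t) - y(t)|."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    if len(y) == 0:
        raise ValueError("empty input")
    return float(np.max(np.abs(y_pred - y)))


def fpe(residuals: np.ndarray, n_params: int, n_samples: int | None = None,
        ) -> float:
    """Akaike's Final Prediction Error.

    V = det((1/N) * sum_t eps(t) eps(t)^T) over the (N x p) residual
    matrix, inflated by the parameter count d: FPE = V * (1 + 2 d / N).
    """
    eps = np.atleast_2d(np.asarray(residuals, dtype=float))
    if eps.shape[0] == 1 and eps.shape[1] > 1:
        eps = eps.T
    n = eps.shape[0] if n_samples is None else int(n_samples)
    if n <= 0:
        raise ValueError("n_samples must be positive")
    if n_params < 0:
        raise ValueError("n_params must be non-negative")
    v = float(np.linalg.det(eps.T @ eps / n))
    return v * (1.0 + 2.0 * n_params / n)


@dataclass
class FitReport:
    """Per-output fit quality for one train/validate/test comparison."""

    output_names: tuple[str, ...]
    fit: tuple[float, ...]            # % per output
    max_abs_error: tuple[float, ...]  # same units as y per output
    fpe: float
    n_params: int
    n_samples: int
    residuals: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_series(cls, y: np.ndarray, y_pred: np.ndarray, n_params: int,
                    output_names: tuple[str, ...] = ("T4mm", "T10mm"),
                    ) -> "FitReport":
        y = np.atleast_2d(np.asarray(y, dtype=float))
        y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
        if y.shape != y_pred.shape:
            raise ValueError("y and y_pred shapes differ")
        if y.shape[1] != len(output_names):
            raise ValueError("output_names must match the channel count")
        eps = y_pred - y
        return cls(
            output_names=tuple(output_names),
            fit=tuple(fit_percent(y[:, k], y_pred[:, k])
                      for k in range(y.shape[1])),
            max_abs_error=tuple(max_abs_error(y[:, k], y_pred[:, k])
                                for k in range(y.shape[1])),
            fpe=fpe(eps, n_params, y.shape[0]),
            n_params=n_params, n_samples=y.shape[0], residuals=eps)

    def as_dict(self) -> dict:
        return {
            "fit_percent": dict(zip(self.output_names, self.fit)),
            "max_abs_error": dict(zip(self.output_names, self.max_abs_error)),
            "fpe": self.fpe, "n_params": self.n_params,
            "n_samples": self.n_samples,
        }
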