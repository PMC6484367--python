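"""Bounded sum-of-sines regression for rhythm detection.

Model
-----
``y(t) = d + sum_k a_k * sin(b_k * t + c_k)``

with ``t`` in hours, amplitudes ``a_k >= 0`` in the units of ``y``,
angular frequencies ``b_k`` (rad/h) constrained so each derived period
``2*pi/b_k`` stays inside its configured bound (e.g. 23-25 h for a
daily component, 10-12 h for a semidaily one), and phases ``c_k`` in
radians. The constant offset ``d`` is fitted freely: percent-of-maximum
profiles are far from zero-mean, and without an offset a sum of sines
cannot track them.

Fitting minimizes the residual sum of squares with scipy's trust-region
reflective bounded least squares, restarted from a deterministic grid of
initial phases {0, pi/2, pi, 3*pi/2} x initial periods {lower bound,
midpoint, upper bound} per component (Cartesian product across
components, plus one near-flat start); the best of all starts is kept.
Goodness of fit is reported as SSE, RMSE = sqrt(SSE/n),
R^2 = 1 - SSE/SStot and adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1) with
p = 3K + 1 fitted parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = ["SumOfSinesRegressor", "SineFitResult", "fit_sum_of_sines"]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SineFitResult:
    """Frozen summary of one bounded sum-of-sines fit.

    ``amplitudes``/``angular_freqs``/``phases`` are the fitted
    ``a_k``/``b_k``/``c_k`` in component order (one per period bound);
    ``periods`` are the derived ``2*pi/b_k`` in hours. ``param_ci`` holds
    asymptotic 95% confidence half-widths for the packed parameter vector
    ``[d, a_1, b_1, c_1, ...]`` (NaN when the Jacobian is degenerate).
    """

    amplitudes: tuple[float, ...]
    angular_freqs: tuple[float, ...]
    phases: tuple[float, ...]
    periods: tuple[float, ...]
    offset: float
    sse: float
    rmse: float
    r2: float
    adjusted_r2: float
    n_points: int
    n_params: int
    period_bounds: tuple[tuple[float, float], ...]
    degenerate: bool = False
    param_ci: tuple[float, ...] = ()

    @property
    def dominant_component(self) -> int:
        """Index of the largest-amplitude component."""
        return int(np.argmax(self.amplitudes))

    @property
    def dominant_period(self) -> float:
        return self.periods[self.dominant_component]

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.offset, dtype=float)
        for a, b, c in zip(self.amplitudes, self.angular_freqs, self.phases):
            out += a * np.sin(b * t + c)
        return out

    def acrophase_hours(self, t0: float = 0.0, t1: float = 24.0) -> float:
        """Clock hour of the fitted curve's maximum on [t0, t1), 1-min grid."""
        grid = np.arange(t0, t1, 1.0 / 60.0)
        return float(grid[np.argmax(self.predict(grid))])

    def to_dict(self) -> dict:
        return {
            "amplitudes": list(self.amplitudes),
            "angular_freqs_rad_per_h": list(self.angular_freqs),
            "phases_rad": list(self.phases),
            "periods_h": list(self.periods),
            "offset": self.offset,
            "sse": self.sse,
            "rmse": self.rmse,
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "period_bounds_h": [list(b) for b in self.period_bounds],
            "degenerate": self.degenerate,
            "param_ci95": list(self.param_ci),
        }


class SumOfSinesRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style estimator for period-bounded sum-of-sines fits.

    Parameters
    ----------
    period_bounds : sequence of (low, high) pairs, hours
        One pair per sine component; each fitted period is constrained to
        its pair. Default: a single circadian component bounded to 23-25 h.
    include_offset : bool
        Fit a free constant offset ``d`` (default True).
    phase_starts : sequence of float, radians
        Initial phases of the deterministic multi-start grid.

    Attributes
    ----------
    offset_, amplitudes_, angular_freqs_, phases_, periods_ : fitted model
    sse_, rmse_, r2_, adjusted_r2_ : goodness of fit
    n_points_, n_params_ : problem size
    degenerate_ : bool, True when the input carried no variance
    result_ : SineFitResult with everything above frozen together
    """

    def __init__(
        self,
        period_bounds: Sequence[tuple[float, float]] = ((23.0, 25.0),),
        include_offset: bool = True,
        phase_starts: Sequence[float] = (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi),
    ):
        self.period_bounds = period_bounds
        self.include_offset = include_offset
        self.phase_starts = phase_starts

    # -- model ----------------------------------------------------------
    @staticmethod
    def _model(theta: np.ndarray, t: np.ndarray, k: int, offset: bool) -> np.ndarray:
        i = 1 if offset else 0
        out = np.full_like(t, theta[0] if offset else 0.0, dtype=float)
        for j in range(k):
            a, b, c = theta[i + 3 * j : i + 3 * j + 3]
            out += a * np.sin(b * t + c)
        return out

    def fit(self, X, y):
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            if t.shape[1] != 1:
                raise ValueError("X must be 1-d times in hours (or a single column)")
            t = t[:, 0]
        y = np.asarray(y, dtype=float)
        if t.shape != y.shape:
            raise ValueError("X and y lengths differ")
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(y)):
            raise ValueError("non-finite input")

        bounds = tuple((float(lo), float(hi)) for lo, hi in self.period_bounds)
        for lo, hi in bounds:
            if not (0 < lo < hi):
                raise ValueError(f"invalid period bound ({lo}, {hi})")
        k = len(bounds)
        offset = bool(self.include_offset)
        n = t.size
        p = 3 * k + (1 if offset else 0)
        if n <= p:
            raise ValueError(
                f"need more than {p} points to identify {k} component(s); got {n}"
            )

        ybar = float(np.mean(y))
        sstot = float(np.sum((y - ybar) ** 2))
        if sstot == 0.0:
            self._set_degenerate(bounds, ybar, n, p)
            return self

        lo_vec, hi_vec = [], []
        if offset:
            lo_vec.append(-np.inf)
            hi_vec.append(np.inf)
        for lo, hi in bounds:
            lo_vec += [0.0, _TWO_PI / hi, -np.inf]
            hi_vec += [np.inf, _TWO_PI / lo, np.inf]
        lo_vec = np.array(lo_vec)
        hi_vec = np.array(hi_vec)

        a0 = 0.5 * float(np.ptp(y)) / k
        starts = []
        per_component = []
        for lo, hi in bounds:
            eps = 1e-9 * (hi - lo)
            period_starts = (lo + eps, 0.5 * (lo + hi), hi - eps)
            per_component.append(
                [(P, phi) for P in period_starts for phi in self.phase_starts]
            )
        for combo in itertools.product(*per_component):
            theta0 = [ybar] if offset else []
            for P, phi in combo:
                theta0 += [a0, _TWO_PI / P, phi]
            starts.append(np.array(theta0))
        # near-flat start guarantees the fit is never worse than a constant
        flat = [ybar] if offset else []
        for lo, hi in bounds:
            flat += [1e-9, _TWO_PI / (0.5 * (lo + hi)), 0.0]
        starts.append(np.array(flat))

        def residual(theta: np.ndarray) -> np.ndarray:
            return self._model(theta, t, k, offset) - y

        best = None
        for theta0 in starts:
            res = optimize.least_squares(
                residual, theta0, bounds=(lo_vec, hi_vec), method="trf"
            )
            sse = float(2.0 * res.cost)
            if best is None or sse < best[0]:
                best = (sse, res)
        sse, res = best

        theta = res.x
        i = 1 if offset else 0
        self.offset_ = float(theta[0]) if offset else 0.0
        self.amplitudes_ = tuple(float(theta[i + 3 * j]) for j in range(k))
        self.angular_freqs_ = tuple(float(theta[i + 3 * j + 1]) for j in range(k))
        self.phases_ = tuple(
            float(_wrap_phase(theta[i + 3 * j + 2])) for j in range(k)
        )
        self.periods_ = tuple(_TWO_PI / b for b in self.angular_freqs_)
        self.sse_ = sse
        self.rmse_ = math.sqrt(sse / n)
        self.r2_ = 1.0 - sse / sstot
        self.adjusted_r2_ = 1.0 - (1.0 - self.r2_) * (n - 1) / (n - p - 1)
        self.n_points_ = n
        self.n_params_ = p
        self.degenerate_ = False
        self.param_ci_ = _asymptotic_ci(res.jac, sse, n, p)
        self.result_ = SineFitResult(
            amplitudes=self.amplitudes_,
            angular_freqs=self.angular_freqs_,
            phases=self.phases_,
            periods=self.periods_,
            offset=self.offset_,
            sse=self.sse_,
            rmse=self.rmse_,
            r2=self.r2_,
            adjusted_r2=self.adjusted_r2_,
            n_points=n,
            n_params=p,
            period_bounds=bounds,
            degenerate=False,
            param_ci=self.param_ci_,
        )
        return self

    def _set_degenerate(self, bounds, ybar: float, n: int, p: int) -> None:
        k = len(bounds)
        self.offset_ = ybar
        self.amplitudes_ = tuple(0.0 for _ in range(k))
        self.angular_freqs_ = tuple(_TWO_PI / (0.5 * (lo + hi)) for lo, hi in bounds)
        self.phases_ = tuple(0.0 for _ in range(k))
        self.periods_ = tuple(0.5 * (lo + hi) for lo, hi in bounds)
        self.sse_ = 0.0
        self.rmse_ = 0.0
        self.r2_ = float("nan")
        self.adjusted_r2_ = float("nan")
        self.n_points_ = n
        self.n_params_ = p
        self.degenerate_ = True
        self.param_ci_ = ()
        self.result_ = SineFitResult(
            amplitudes=self.amplitudes_,
            angular_freqs=self.angular_freqs_,
            phases=self.phases_,
            periods=self.periods_,
            offset=self.offset_,
            sse=0.0,
            rmse=0.0,
            r2=float("nan"),
            adjusted_r2=float("nan"),
            n_points=n,
            n_params=p,
            period_bounds=bounds,
            degenerate=True,
        )

    def predict(self, X):
        if not hasattr(self, "result_"):
            raise RuntimeError("estimator is not fitted")
        t = np.asarray(X, dtype=float)
        if t.ndim == 2:
            t = t[:, 0]
        return self.result_.predict(t)


def _wrap_phase(c: float) -> float:
    return float((c + math.pi) % _TWO_PI - math.pi)


def _asymptotic_ci(jac: np.ndarray, sse: float, n: int, p: int) -> tuple[float, ...]:
    """95% asymptotic half-widths from the NLLS Jacobian (NaN if singular)."""
    if n <= p:
        return tuple(float("nan") for _ in range(jac.shape[1]))
    dof = n - p
    try:
        cov = np.linalg.pinv(jac.T @ jac) * (sse / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        return tuple(float("nan") for _ in range(jac.shape[1]))
    tcrit = float(stats.t.ppf(0.975, dof))
    return tuple(float(tcrit * s) for s in se)


def fit_sum_of_sines(
    hours: Sequence[float],
    values: Sequence[float],
    period_bounds: Sequence[tuple[float, float]] = ((23.0, 25.0),),
) -> SineFitResult:
    """Functional wrapper: fit ``values`` over ``hours`` and return the result."""
    est = SumOfSinesRegressor(period_bounds=tuple(period_bounds))
    est.fit(np.asarray(hours, dtype=float), np.asarray(values, dtype=float))
    return est.result_
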