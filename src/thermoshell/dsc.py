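"""Two-state analysis of differential scanning calorimetry (DSC) thermograms.

The model is the reversible two-state transition N <=> D with
Gibbs-Helmholtz free energy

    dG(T) = dHd * (1 - T/Td) + dCp * [(T - Td) - T * ln(T/Td)]

where Td is the temperature of the excess-heat-capacity maximum, dHd the
denaturation enthalpy at Td, and dCp the (temperature-independent) heat
capacity change upon denaturation.  The excess molar heat capacity is the
analytic derivative of f(T) * dH(T):

    Cp_ex(T) = dH(T)^2 * f * (1 - f) / (R * T^2) + f * dCp

with f the denatured fraction and dH(T) = dHd + dCp * (T - Td) (Kirchhoff).

Trace processing follows calorimetric convention: a chemical (instrument)
baseline is removed by fitting straight lines to the pre- and
post-transition windows joined by a sigmoidal progress baseline weighted by
the reaction extent; the calorimetric enthalpy is the trapezoidal area of
the subtracted peak; the van't Hoff enthalpy uses the Privalov peak-height
form 4 * R * Td^2 * Cp_ex(Td) / dHcal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.special import expit

from .constants import R_KJ

__all__ = [
    "TwoStateParams",
    "DSCTrace",
    "DSCResult",
    "BaselineModel",
    "FitError",
    "delta_g",
    "denatured_fraction",
    "excess_cp",
    "suggested_grid",
    "simulate_trace",
    "estimate_baseline",
    "subtract_baseline",
    "find_td",
    "calorimetric_enthalpy",
    "peak_height",
    "vant_hoff_enthalpy",
    "cooperativity_ratio",
    "analyze_trace",
    "fit_two_state",
]


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails or the input is degenerate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class TwoStateParams:
    """Thermodynamic triple (Td [K], dHd(Td) [kJ/mol], dCp [kJ/K/mol])."""

    td: float
    dh: float
    dcp: float = 0.0

    def __post_init__(self):
        if not self.td > 0:
            raise ValueError(f"Td must be positive (got {self.td} K)")
        if not self.dh > 0:
            raise ValueError(f"dHd must be positive (got {self.dh})")
        if self.dcp < 0:
            raise ValueError(f"dCp must be non-negative (got {self.dcp})")

    @property
    def t_s(self) -> float:
        """Temperature of maximal stability (dS = 0); Td itself if dCp = 0."""
        if self.dcp == 0:
            return self.td
        return self.td * math.exp(-self.dh / (self.dcp * self.td))


@dataclass
class DSCTrace:
    """Temperature grid [K] with excess molar heat capacity [kJ/K/mol]."""

    temperatures: np.ndarray
    cp_excess: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.cp_excess = np.asarray(self.cp_excess, dtype=float)
        if self.temperatures.size == 0:
            raise ValueError("empty temperature grid")
        if self.temperatures.shape != self.cp_excess.shape:
            raise ValueError("temperature and cp arrays differ in length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    def __len__(self):
        return self.temperatures.size


@dataclass(frozen=True)
class DSCResult:
    """Summary of a processed thermogram."""

    td: float  # K
    dh_cal: float  # kJ/mol
    dh_vh: float  # kJ/mol
    ratio: float  # dh_cal / dh_vh
    rss: float = float("nan")
    n_points: int = 0


@dataclass(frozen=True)
class BaselineModel:
    """Linear pre/post-transition segments, optionally joined sigmoidally.

    ``pre`` and ``post`` are (intercept, slope) pairs of Cp = a + b*T lines.
    With ``progress=True`` the two lines are interpolated with the reaction
    extent as weight; otherwise only the pre line is used everywhere.
    """

    pre: tuple[float, float] = (0.0, 0.0)
    post: tuple[float, float] = (0.0, 0.0)
    progress: bool = True

    @classmethod
    def null(cls) -> "BaselineModel":
        return cls((0.0, 0.0), (0.0, 0.0), progress=False)

    @classmethod
    def linear(cls, intercept: float, slope: float) -> "BaselineModel":
        return cls((intercept, slope), (intercept, slope), progress=False)

    def evaluate(self, temperatures, extent=None) -> np.ndarray:
        t = np.asarray(temperatures, dtype=float)
        pre = self.pre[0] + self.pre[1] * t
        if not self.progress:
            return pre
        if extent is None:
            raise ValueError("progress baseline requires the reaction extent")
        post = self.post[0] + self.post[1] * t
        a = np.clip(np.asarray(extent, dtype=float), 0.0, 1.0)
        return (1.0 - a) * pre + a * post


# ---------------------------------------------------------------------------
# forward model


def delta_g(temperature, params: TwoStateParams):
    """Gibbs free energy of denaturation [kJ/mol] at ``temperature`` [K]."""
    t = np.asarray(temperature, dtype=float)
    if np.any(t <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    td, dh, dcp = params.td, params.dh, params.dcp
    dg = dh * (1.0 - t / td) + dcp * ((t - td) - t * np.log(t / td))
    return dg if dg.ndim else float(dg)

def denatured_fraction(temperature, params: TwoStateParams):
    """Two-state denatured population f = K/(1+K), K = exp(-dG/RT)."""
    t = np.asarray(temperature, dtype=float)
    f = expit(-delta_g(t, params) / (R_KJ * t))
    return f if f.ndim else float(f)

def excess_cp(temperature, params: TwoStateParams):
    """Excess molar heat capacity, d[f * dH(T)]/dT, in kJ/K/mol."""
    t = np.asarray(temperature, dtype=float)
    f = denatured_fraction(t, params)
    dh_t = params.dh + params.dcp * (t - params.td)
    cp = dh_t**2 * f * (1.0 - f) / (R_KJ * t**2) + f * params.dcp
    return cp if cp.ndim else float(cp)


def suggested_grid(params: TwoStateParams, width_mult: float = 15.0,
                   step: float = 0.1, window_frac: float = 0.15) -> np.ndarray:
    """Analysis-grade temperature grid for a transition.

    Spans Td +/- ``width_mult`` transition widths (RTd^2/dHd).  When dCp > 0
    and cold denaturation would enter the scan, the cold edge is pulled up so
    the pre-transition window straddles the stability maximum T_S, the
    flattest available baseline region (f'(T_S) = 0).
    """
    w = R_KJ * params.td**2 / params.dh
    lo = params.td - width_mult * w
    hi = params.td + width_mult * w
    if params.dcp > 0:
        ts = params.t_s
        if lo < ts:
            span = (hi - ts) / (1.0 - window_frac / 2.0)
            lo = ts - 0.5 * window_frac * span
    return np.arange(lo, hi + step / 2.0, step)


def simulate_trace(params: TwoStateParams, grid, baseline: BaselineModel | None = None,
                   noise_sd: float = 0.0, seed=None, label: str = "") -> DSCTrace:
    """Synthetic thermogram: forward model plus baseline plus Gaussian noise."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(grid <= 0) or np.any(grid >= 2.0 * params.td):
        raise ValueError("grid must lie inside (0, 2*Td)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    cp = excess_cp(grid, params)
    if baseline is not None:
        cp = cp + baseline.evaluate(grid, extent=denatured_fraction(grid, params))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sd, size=grid.size)
    return DSCTrace(grid, cp, label=label)


# ---------------------------------------------------------------------------
# trace processing


def _window_size(n: int, window_frac: float) -> int:
    return max(3, int(round(n * window_frac)))


def _check_windows(trace: DSCTrace, window_frac: float) -> int:
    n = len(trace)
    w = _window_size(n, window_frac)
    if 2 * w >= n:
        raise ValueError("trace too short for baseline windows")
    cp = trace.cp_excess
    i_max = int(np.argmax(cp))
    if i_max < w or i_max >= n - w:
        raise ValueError(
            "transition maximum falls inside a baseline window; the scan "
            "does not bracket the transition")
    # if both edge windows sit on steep transition flanks (slope comparable
    # to the peak prominence over the scan), there is no baseline region
    t = trace.temperatures
    slope_pre = abs(np.polyfit(t[:w], cp[:w], 1)[0])
    slope_post = abs(np.polyfit(t[-w:], cp[-w:], 1)[0])
    prominence = cp[i_max] - max(float(np.median(cp[:w])), float(np.median(cp[-w:])))
    span = t[-1] - t[0]
    if min(slope_pre, slope_post) * span > max(prominence, 0.0):
        raise ValueError("transition covers the whole scan: no flat baseline windows")
    return w


def estimate_baseline(trace: DSCTrace, window_frac: float = 0.15) -> BaselineModel:
    """Fit pre/post-transition lines to the outer windows of the scan."""
    w = _check_windows(trace, window_frac)
    t, cp = trace.temperatures, trace.cp_excess
    b_pre, a_pre = np.polyfit(t[:w], cp[:w], 1)
    b_post, a_post = np.polyfit(t[-w:], cp[-w:], 1)
    return BaselineModel(pre=(a_pre, b_pre), post=(a_post, b_post), progress=True)


def subtract_baseline(trace: DSCTrace, model: BaselineModel | None = None,
                      window_frac: float = 0.15, n_iter: int = 8) -> DSCTrace:
    """Remove the instrument + progress baseline from a thermogram.

    With ``model=None`` the linear segments are estimated from the outer
    ``window_frac`` windows.  The sigmoidal progress weight is computed
    self-consistently as the normalised running integral of the subtracted
    trace (a few fixed-point iterations suffice).
    """
    if model is None:
        model = estimate_baseline(trace, window_frac)
    t, cp = trace.temperatures, trace.cp_excess
    if not model.progress:
        return DSCTrace(t, cp - model.evaluate(t), label=trace.label)
    # progress weight: normalised running area of the subtracted peak (the
    # standard calorimetric convention), found by fixed-point iteration
    alpha = np.zeros_like(t)
    for _ in range(n_iter):
        ex = cp - model.evaluate(t, extent=alpha)
        cum = cumulative_trapezoid(ex, t, initial=0.0)
        total = cum[-1]
        if total <= 0:
            break
        alpha = np.clip(cum / total, 0.0, 1.0)
    ex = cp - model.evaluate(t, extent=alpha)
    return DSCTrace(t, ex, label=trace.label)


def _refine_peak(trace: DSCTrace) -> tuple[float, float]:
    """(Td, peak height) from a local quadratic around the grid maximum.

    The quadratic is fit to the contiguous run of points above 97% of the
    peak (at least three), which averages grid noise without leaving the
    locally parabolic cap of the transition.
    """
    t, cp = trace.temperatures, trace.cp_excess
    i = int(np.argmax(cp))
    if i == 0 or i == len(trace) - 1:
        raise ValueError("maximum at grid boundary: truncated transition")
    floor = cp[i] - 0.03 * (cp[i] - cp.min())
    lo = i
    while lo > 0 and cp[lo - 1] >= floor:
        lo -= 1
    hi = i
    while hi < len(trace) - 1 and cp[hi + 1] >= floor:
        hi += 1
    lo, hi = min(lo, i - 1), max(hi, i + 1)
    c2, c1, c0 = np.polyfit(t[lo:hi + 1], cp[lo:hi + 1], 2)
    if c2 >= 0:  # numerically flat top; keep the grid point
        return float(t[i]), float(cp[i])
    td = float(np.clip(-c1 / (2.0 * c2), t[lo], t[hi]))
    return td, float(np.polyval([c2, c1, c0], td))


def find_td(trace: DSCTrace) -> float:
    """Temperature of the thermogram maximum [K], quadratically refined."""
    return _refine_peak(trace)[0]


def peak_height(trace: DSCTrace) -> float:
    """Refined excess heat capacity at the maximum [kJ/K/mol]."""
    return _refine_peak(trace)[1]


def calorimetric_enthalpy(trace: DSCTrace) -> float:
    """Area under a baseline-subtracted peak (trapezoid, native grid)."""
    dh = float(np.trapezoid(trace.cp_excess, trace.temperatures))
    if dh <= 0:
        raise ValueError("non-positive peak area: baseline subtraction failed")
    return dh


def vant_hoff_enthalpy(trace: DSCTrace, td: float | None = None,
                       dh_cal: float | None = None) -> float:
    """Van't Hoff enthalpy 4*R*Td^2*Cp_ex(Td)/dHcal from a subtracted trace."""
    if td is None:
        td = find_td(trace)
    if dh_cal is None:
        dh_cal = calorimetric_enthalpy(trace)
    if dh_cal <= 0:
        raise ValueError("dHcal must be positive")
    return 4.0 * R_KJ * td**2 * peak_height(trace) / dh_cal


def cooperativity_ratio(dh_cal: float, dh_vh: float) -> float:
    """dHcal / dHvH; close to one for a single cooperative unit."""
    if dh_vh == 0:
        raise ZeroDivisionError("van't Hoff enthalpy is zero")
    if dh_cal <= 0 or dh_vh <= 0:
        raise ValueError("enthalpies must be positive")
    return dh_cal / dh_vh


def analyze_trace(trace: DSCTrace, baseline: BaselineModel | None = None,
                  window_frac: float = 0.15,
                  baseline_subtracted: bool = False) -> DSCResult:
    """Full thermogram workup: baseline, Td, dHcal, dHvH, cooperativity."""
    ex = trace if baseline_subtracted else subtract_baseline(trace, baseline, window_frac)
    td = find_td(ex)
    dh_cal = calorimetric_enthalpy(ex)
    dh_vh = vant_hoff_enthalpy(ex, td=td, dh_cal=dh_cal)
    return DSCResult(td=td, dh_cal=dh_cal, dh_vh=dh_vh,
                     ratio=cooperativity_ratio(dh_cal, dh_vh),
                     n_points=len(trace))


# ---------------------------------------------------------------------------
# nonlinear fit


def fit_two_state(trace: DSCTrace, init: TwoStateParams | None = None
                  ) -> tuple[TwoStateParams, DSCResult]:
    """Least-squares fit of the forward excess-Cp model to a raw trace.

    The trace must contain the transition with no instrument baseline (or a
    previously subtracted one *excluding* the progress step: the model's
    f*dCp term reproduces the step itself).  Initialisation is deterministic:
    Td from the peak, dHd from the raw area, dCp from the edge offset.
    """
    t, cp = trace.temperatures, trace.cp_excess
    span = float(cp.max() - cp.min())
    if span <= 0 or cp.max() <= 0:
        raise FitError("flat trace: no transition to fit")
    if init is None:
        try:
            td0 = find_td(trace)
        except ValueError as err:
            raise FitError(str(err)) from err
        dh0 = max(float(np.trapezoid(cp, t)), 1.0)
        dcp0 = max(float(np.median(cp[-5:]) - np.median(cp[:5])), 0.0)
        init = TwoStateParams(td0, dh0, dcp0)
    def residuals(theta):
        td, dh, dcp = theta
        return excess_cp(t, TwoStateParams(td, dh, dcp)) - cp

    res = least_squares(
        residuals, x0=[init.td, init.dh, init.dcp],
        bounds=([t[0], 1e-6, 0.0], [2.0 * t[-1], np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(f"two-state fit did not converge: {res.message}",
                       last_iterate=res.x)
    params = TwoStateParams(*res.x)
    rss = float(2.0 * res.cost)
    # flat-trace degeneracy shows up as an absurd width/enthalpy combination
    if params.dh < 10.0 * R_KJ * params.td:
        raise FitError("fit collapsed to a near-flat transition",
                       last_iterate=res.x)
    diag = DSCResult(td=params.td, dh_cal=params.dh,
                     dh_vh=params.dh, ratio=1.0, rss=rss, n_points=len(trace))
    return params, diag
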