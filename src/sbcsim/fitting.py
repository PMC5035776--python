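"""Patch-clamp-style trace quantification.

Double-exponential decay fits with the amplitude-weighted time constant

    tau_w = (A_fast * tau_fast + A_slow * tau_slow) / (A_fast + A_slow)

and the r^2 > 0.8 inclusion criterion, single-exponential tail fits,
peak-conductance computation from a peak current and driving force, and
ordinary-least-squares subthreshold current--voltage monitoring of the
resting potential and membrane resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit, minimize

__all__ = [
    "DecayFit",
    "IVMonitorPoint",
    "R2_INCLUSION",
    "fit_double_exp",
    "fit_single_exp",
    "weighted_tau",
    "peak_conductance",
    "fit_subthreshold_iv",
]

R2_INCLUSION = 0.8


@dataclass
class DecayFit:
    """Parameters of A_f exp(-t/tau_f) + A_s exp(-t/tau_s) + baseline.

    Amplitudes are values at t = 0 of the fitted segment (trace units),
    time constants in ms with tau_fast <= tau_slow by relabeling.
    ``included`` mirrors the goodness-of-fit criterion r^2 > 0.8.
    """

    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    baseline: float
    r2: float
    converged: bool = True
    message: str = ""

    def __post_init__(self):
        if self.converged and self.tau_fast > self.tau_slow:
            self.a_fast, self.a_slow = self.a_slow, self.a_fast
            self.tau_fast, self.tau_slow = self.tau_slow, self.tau_fast

    @property
    def included(self) -> bool:
        return self.converged and self.r2 > R2_INCLUSION

    @property
    def tau_w(self) -> float:
        return weighted_tau(self)


@dataclass
class IVMonitorPoint:
    t_min: float
    rmp_mV: float
    r_m_MOhm: float

    def __post_init__(self):
        if self.r_m_MOhm <= 0:
            raise ValueError("membrane resistance must be positive")


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def _linear_amplitudes(t, y, taus):
    """Least-squares amplitudes + baseline for fixed time constants."""
    cols = [np.exp(-t / tau) for tau in taus] + [np.ones_like(t)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef, design @ coef


def fit_double_exp(t_ms: np.ndarray, y: np.ndarray,
                   n_grid: int = 8) -> DecayFit:
    """Least-squares double-exponential decay fit from the peak onward.

    ``t_ms`` starts at the response peak (t = 0 of the segment).  The
    fit uses variable projection -- amplitudes and baseline are linear
    given the two time constants -- with a log-spaced multi-start grid
    over time-constant pairs followed by a Nelder--Mead polish in
    log-tau space.  A non-convergent fit is returned with
    ``converged = False`` and a diagnostic message rather than raising.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 50:
        raise ValueError("need at least 50 samples from the peak onward")
    t = t - t[0]
    span = t[-1] - t[0]
    dt = max(np.median(np.diff(t)), 1e-9)

    try:
        grid = np.geomspace(2.0 * dt, 2.0 * span, n_grid)
        best = None
        for i in range(n_grid):
            for j in range(i + 1, n_grid):
                coef, y_hat = _linear_amplitudes(t, y, (grid[i], grid[j]))
                ss = float(np.sum((y - y_hat) ** 2))
                if best is None or ss < best[0]:
                    best = (ss, (grid[i], grid[j]))

        def objective(log_taus):
            taus = np.exp(log_taus)
            if taus[0] > taus[1]:
                taus = taus[::-1]
            _, y_hat = _linear_amplitudes(t, y, taus)
            return float(np.sum((y - y_hat) ** 2))

        res = minimize(objective, np.log(best[1]), method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-12,
                                "maxiter": 2000})
        taus = np.sort(np.exp(res.x))
        coef, y_hat = _linear_amplitudes(t, y, taus)
        r2 = _r2(y, y_hat)
        return DecayFit(a_fast=float(coef[0]), tau_fast=float(taus[0]),
                        a_slow=float(coef[1]), tau_slow=float(taus[1]),
                        baseline=float(coef[2]), r2=r2)
    except Exception as exc:  # noqa: BLE001 -- fit failure is a data outcome
        return DecayFit(a_fast=np.nan, tau_fast=np.nan, a_slow=np.nan,
                        tau_slow=np.nan, baseline=np.nan, r2=0.0,
                        converged=False, message=f"fit failed: {exc}")


def fit_single_exp(t_ms: np.ndarray, y: np.ndarray
                   ) -> tuple[float, float, float]:
    """Fit A*exp(-t/tau) + c; returns (A, tau_ms, c).

    Initialized from a log-linear regression on the baseline-subtracted
    segment, then refined by nonlinear least squares.
    """
    t = np.asarray(t_ms, dtype=float)
    y = np.asarray(y, dtype=float)
    t = t - t[0]
    c0 = float(y[-max(3, len(y) // 20):].mean())
    amp = y - c0
    sign = 1.0 if amp[0] >= 0 else -1.0
    pos = sign * amp
    mask = pos > max(1e-12, 1e-3 * pos.max())
    slope, intercept = np.polyfit(t[mask], np.log(pos[mask]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    p0 = (sign * math.exp(intercept), tau0, c0)

    def f(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    popt, _ = curve_fit(f, t, y, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def weighted_tau(fit: DecayFit) -> float:
    """Amplitude-weighted mean decay constant (ms)."""
    denom = fit.a_fast + fit.a_slow
    if denom == 0:
        raise ValueError("amplitude sum is zero; tau_w undefined")
    return (fit.a_fast * fit.tau_fast + fit.a_slow * fit.tau_slow) / denom


def peak_conductance(i_peak_pA: float, v_hold_mV: float,
                     e_rev_mV: float) -> float:
    """Peak conductance magnitude (nS) from a peak current.

    g = |i_peak / (v_hold - e_rev)|; pA/mV = nS.
    """
    drive = v_hold_mV - e_rev_mV
    if drive == 0:
        raise ValueError("zero driving force: v_hold equals e_rev")
    return abs(i_peak_pA / drive)


def fit_subthreshold_iv(steps: Sequence[tuple[float, float]]
                        ) -> dict[str, float]:
    """OLS line V = rmp + R*I through subthreshold (I, V) points.

    ``steps`` holds (current_pA, steady_voltage_mV) pairs; returns the
    slope as membrane resistance in MOhm and the intercept as the
    resting potential in mV.
    """
    arr = np.asarray(steps, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (current, voltage) points")
    i_pA, v_mV = arr[:, 0], arr[:, 1]
    if np.ptp(i_pA) == 0:
        raise ValueError("all currents identical; slope undefined")
    slope, intercept = np.polyfit(i_pA, v_mV, 1)  # mV/pA = GOhm
    return {"r_m_MOhm": float(slope * 1e3), "rmp_mV": float(intercept)}
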