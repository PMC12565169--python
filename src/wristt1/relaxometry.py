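"""Variable-flip-angle (VFA) T1 estimation for spoiled gradient-echo data.

Forward model
-------------
The steady-state spoiled gradient-echo (SPGR) magnitude signal at flip angle
``alpha`` with repetition time ``TR`` and longitudinal relaxation time ``T1`` is

    S(alpha) = M0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),
    E1 = exp(-TR / T1),

where M0 absorbs proton density, coil gain and the (fixed-TE) T2* decay.

Estimation
----------
The canonical DESPOT1 linearization rewrites the model as a straight line:

    S / sin(alpha) = E1 * (S / tan(alpha)) + M0 * (1 - E1),

so ordinary least squares of y = S/sin(alpha) on x = S/tan(alpha) gives
slope = E1 — hence T1 = -TR / ln(slope) — and intercept = M0 (1 - E1).
A physically meaningful fit requires slope in (0, 1); anything else is flagged
invalid rather than coerced. A nonlinear least-squares fit of the forward
model itself is provided as a cross-check estimator.

The fitting surface follows the Model/Results convention: build a
:class:`VFAT1Model` from the per-angle signals, call :meth:`~VFAT1Model.fit`,
and read the estimates and diagnostics off the returned :class:`VFAT1Results`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .protocol import AcquisitionProtocol

__all__ = [
    "spgr_signal",
    "ernst_angle_deg",
    "VFAT1Model",
    "VFAT1Results",
    "fit_t1_linear",
    "fit_t1_nls",
    "estimate_all_structures",
]

#: Upper bound on T1 (ms) for the nonlinear fit; generous for any tissue at 1.5 T.
T1_BOUNDS_MS = (1.0, 10_000.0)


def spgr_signal(m0, t1_ms, tr_ms, alpha_deg):
    """Steady-state SPGR magnitude signal. Broadcasts over array inputs.

    Parameters
    ----------
    m0 : array_like
        Equilibrium signal amplitude (arbitrary units), >= 0.
    t1_ms : array_like
        Longitudinal relaxation time in ms, > 0.
    tr_ms : float
        Repetition time in ms, > 0.
    alpha_deg : array_like
        Flip angle in degrees, in [0, 90].
    """
    m0 = np.asarray(m0, dtype=float)
    t1_ms = np.asarray(t1_ms, dtype=float)
    if np.any(t1_ms <= 0):
        raise ValueError("t1_ms must be positive")
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=float))
    e1 = np.exp(-tr_ms / t1_ms)
    out = m0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
    return out if out.ndim else float(out)


def ernst_angle_deg(t1_ms: float, tr_ms: float) -> float:
    """Flip angle (degrees) maximizing the SPGR signal: arccos(exp(-TR/T1))."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise ValueError("t1_ms and tr_ms must be positive")
    return float(np.rad2deg(np.arccos(np.exp(-tr_ms / t1_ms))))


@dataclass(frozen=True)
class VFAT1Results:
    """Fitted T1/M0 with diagnostics.

    Attributes
    ----------
    t1_ms, m0 : float
        Estimates (NaN when the fit is invalid).
    method : str
        ``"linear"`` (DESPOT1 linearization) or ``"nls"``.
    r2 : float
        Coefficient of determination of the linearized regression; for the
        nonlinear fit, of the forward model against the observed signals.
    valid : bool
        False when the fit is non-physical or did not converge.
    reason : str or None
        Reason code for invalid fits (``slope_out_of_range``,
        ``nonpositive_signal``, ``no_convergence``, ``too_few_angles``).
    slope : float
        Linearized slope (the E1 estimate) when available.
    nobs : int
        Number of (angle, signal) pairs used.
    """

    t1_ms: float
    m0: float
    method: str
    r2: float
    valid: bool
    reason: str | None = None
    slope: float = float("nan")
    nobs: int = 0

    def summary(self) -> str:
        lines = [
            "VFA T1 fit",
            "==========",
            f"method:  {self.method}",
            f"nobs:    {self.nobs}",
            f"valid:   {self.valid}" + (f"  ({self.reason})" if self.reason else ""),
            f"T1:      {self.t1_ms:.1f} ms",
            f"M0:      {self.m0:.4g}",
            f"R^2:     {self.r2:.6f}",
        ]
        if np.isfinite(self.slope):
            lines.append(f"E1 (slope): {self.slope:.6f}")
        return "\n".join(lines)


def _invalid(method: str, reason: str, nobs: int, slope: float = float("nan"),
             r2: float = float("nan")) -> VFAT1Results:
    return VFAT1Results(t1_ms=float("nan"), m0=float("nan"), method=method,
                        r2=r2, valid=False, reason=reason, slope=slope, nobs=nobs)


class VFAT1Model:
    """Single-compartment SPGR model for one set of per-angle mean signals.

    Parameters
    ----------
    signals : array_like
        Mean signal intensity per flip angle (arbitrary units).
    flip_angles_deg : array_like
        Flip angles in degrees, matching ``signals``.
    tr_ms : float
        Repetition time in ms.
    """

    def __init__(self, signals, flip_angles_deg, tr_ms: float):
        self.signals = np.asarray(signals, dtype=float)
        self.flip_angles_deg = np.asarray(flip_angles_deg, dtype=float)
        self.tr_ms = float(tr_ms)
        if self.signals.shape != self.flip_angles_deg.shape or self.signals.ndim != 1:
            raise ValueError("signals and flip_angles_deg must be 1-D with equal length")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")

    def fit(self, method: str = "linear", init: VFAT1Results | None = None) -> VFAT1Results:
        if method == "linear":
            return self._fit_linear()
        if method == "nls":
            return self._fit_nls(init)
        raise ValueError(f"unknown method {method!r}")

    # -- DESPOT1 linearization --------------------------------------------

    def _fit_linear(self) -> VFAT1Results:
        s, a = self.signals, np.deg2rad(self.flip_angles_deg)
        n = s.size
        if n < 2 or np.unique(self.flip_angles_deg).size < 2:
            return _invalid("linear", "too_few_angles", n)
        if np.any(s <= 0):
            return _invalid("linear", "nonpositive_signal", n)
        y = s / np.sin(a)
        x = s / np.tan(a)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if not (0.0 < slope < 1.0):
            return _invalid("linear", "slope_out_of_range", n, slope=float(slope), r2=r2)
        t1 = -self.tr_ms / np.log(slope)
        m0 = intercept / (1.0 - slope)
        return VFAT1Results(t1_ms=float(t1), m0=float(m0), method="linear", r2=r2,
                            valid=True, slope=float(slope), nobs=n)

    # -- nonlinear least squares on the forward model ----------------------

    def _fit_nls(self, init: VFAT1Results | None = None) -> VFAT1Results:
        s = self.signals
        n = s.size
        if n < 2 or np.unique(self.flip_angles_deg).size < 2:
            return _invalid("nls", "too_few_angles", n)
        if np.any(s <= 0):
            return _invalid("nls", "nonpositive_signal", n)
        if init is None:
            init = self._fit_linear()
        if init.valid:
            x0 = np.array([init.m0, np.clip(init.t1_ms, *T1_BOUNDS_MS)])
        else:
            # crude start: peak signal at the Ernst angle of a mid-range T1
            t1_guess = 1000.0
            peak = spgr_signal(1.0, t1_guess, self.tr_ms,
                               ernst_angle_deg(t1_guess, self.tr_ms))
            x0 = np.array([float(s.max()) / peak, t1_guess])

        def resid(p):
            return spgr_signal(p[0], p[1], self.tr_ms, self.flip_angles_deg) - s

        sol = least_squares(resid, x0, bounds=([0.0, T1_BOUNDS_MS[0]],
                                               [np.inf, T1_BOUNDS_MS[1]]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not sol.success:
            return _invalid("nls", "no_convergence", n)
        m0, t1 = sol.x
        yhat = spgr_signal(m0, t1, self.tr_ms, self.flip_angles_deg)
        ss_res = float(np.sum((s - yhat) ** 2))
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return VFAT1Results(t1_ms=float(t1), m0=float(m0), method="nls", r2=r2,
                            valid=True, slope=float(np.exp(-self.tr_ms / t1)), nobs=n)


def fit_t1_linear(signals, flip_angles_deg, tr_ms: float) -> VFAT1Results:
    """DESPOT1 linearized T1 fit (convenience wrapper over :class:`VFAT1Model`)."""
    return VFAT1Model(signals, flip_angles_deg, tr_ms).fit("linear")


def fit_t1_nls(signals, flip_angles_deg, tr_ms: float,
               init: VFAT1Results | None = None) -> VFAT1Results:
    """Nonlinear least-squares T1 fit of the SPGR forward model."""
    return VFAT1Model(signals, flip_angles_deg, tr_ms).fit("nls", init=init)


def estimate_all_structures(signal_table, protocol: AcquisitionProtocol,
                            method: str = "linear") -> dict[str, VFAT1Results]:
    """Fit T1 for every structure row of a signal table.

    Invalid fits are carried through per structure; one bad row never aborts
    the rest.

    Parameters
    ----------
    signal_table : SignalTable or pandas.DataFrame
        Rows indexed by structure name, one column per flip angle (ordered as
        ``protocol.flip_angles_deg``).
    """
    means = getattr(signal_table, "means", signal_table)
    out: dict[str, VFAT1Results] = {}
    alphas = np.asarray(protocol.flip_angles_deg)
    for structure in means.index:
        sig = np.asarray(means.loc[structure], dtype=float)
        try:
            out[structure] = VFAT1Model(sig, alphas, protocol.tr_ms).fit(method)
        except ValueError:
            out[structure] = _invalid(method, "nonpositive_signal", sig.size)
    return out
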