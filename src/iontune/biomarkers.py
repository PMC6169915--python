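"""Electrophysiological markers computed from traces and beat series.

Seven constrained markers drive the calibration: APD90 and triangulation at
1 Hz, systolic/diastolic intracellular calcium at 1 Hz and 0.5 Hz, and the
slow time constant of APD rate adaptation after an abrupt cycle-length
change.  The objective integrand is the one-cycle integral of the total
potassium current.

AP onset is defined at stimulus delivery time (robust for slow upstrokes and
consistent across models); the maximum-dV/dt convention is available via
``onset="dvdt"`` where a trace is supplied.  The resting potential is read
1 ms before the stimulus, the peak over the whole cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import CurrentsRecord, ik_tot

__all__ = [
    "MarkerVector",
    "AdaptationFit",
    "RepolarizationFailure",
    "apd",
    "apd_from_arrays",
    "triangulation",
    "ca_levels",
    "iktot_integral",
    "fit_adaptation",
    "MARKER_NAMES",
]

MARKER_NAMES = ("APD90", "triangulation", "Ca_sys_1Hz", "Ca_sys_0.5Hz",
                "Ca_dia_1Hz", "Ca_dia_0.5Hz", "tau_slow")


class RepolarizationFailure(RuntimeError):
    """The membrane never recrossed the repolarization threshold."""


@dataclass
class MarkerVector:
    """The seven constrained markers plus the one-cycle K-current integral.

    Calcium levels are unit-tagged via ``ca_unit`` ('mM' or 'uM'); time-based
    markers are ms except tau_slow (s); the integral is ms*pA/pF.
    """

    apd90: float
    triangulation: float
    ca_sys_1hz: float
    ca_sys_0p5hz: float
    ca_dia_1hz: float
    ca_dia_0p5hz: float
    tau_slow: float
    iktot_integral: float
    ca_unit: str = "mM"

    def as_array(self) -> np.ndarray:
        """Constrained markers in canonical order (objective excluded)."""
        return np.array([
            self.apd90, self.triangulation, self.ca_sys_1hz, self.ca_sys_0p5hz,
            self.ca_dia_1hz, self.ca_dia_0p5hz, self.tau_slow])

    def as_dict(self) -> dict:
        d = dict(zip(MARKER_NAMES, self.as_array()))
        d["iktot_integral"] = self.iktot_integral
        return d


def _onset_time(trace, onset):
    if onset == "stim":
        return float(getattr(trace, "stim_onset", 0.0))
    if onset == "dvdt":
        t, V = np.asarray(trace.t), np.asarray(trace.V)
        dv = np.gradient(V, t)
        return float(t[int(np.argmax(dv))])
    raise ValueError("onset must be 'stim' or 'dvdt'")


def apd_from_arrays(t, V, fraction, onset: float = 0.0, v_rest=None) -> float:
    """Action-potential duration at the given repolarization fraction.

    The repolarization threshold is ``V_peak - fraction * (V_peak - V_rest)``;
    the duration runs from the stimulus onset to the first downward crossing
    of the threshold after the peak, linearly interpolated between samples.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if v_rest is None:
        # resting potential read 1 ms before the stimulus (clamped to range)
        v_rest = float(np.interp(max(onset - 1.0, t[0]), t, V))
    sel = t >= onset
    ts, Vs = t[sel], V[sel]
    ipk = int(np.argmax(Vs))
    v_peak = Vs[ipk]
    thr = v_peak - fraction * (v_peak - v_rest)
    below = Vs[ipk:] <= thr
    if not below.any():
        raise RepolarizationFailure(
            f"no {100 * fraction:.0f}% repolarization crossing before cycle end")
    j = ipk + int(np.argmax(below))
    if j == ipk:
        return float(ts[j] - onset)
    t0, t1 = ts[j - 1], ts[j]
    v0, v1 = Vs[j - 1], Vs[j]
    tc = t0 if v1 == v0 else t0 + (thr - v0) / (v1 - v0) * (t1 - t0)
    return float(tc - onset)


def apd(trace, fraction: float = 0.9, onset: str = "stim") -> float:
    """APD from a trace object with ``t``, ``V`` and ``stim_onset``."""
    return apd_from_arrays(trace.t, trace.V, fraction,
                           onset=_onset_time(trace, onset))


def triangulation(trace, onset: str = "stim") -> float:
    """APD90 - APD50: shape marker of late repolarization."""
    return apd(trace, 0.9, onset) - apd(trace, 0.5, onset)


def ca_levels(trace):
    """(systolic, diastolic) = (max, min) of the calcium transient.

    Returns ``(nan, nan)`` when the trace carries no calcium series (marker
    unavailable rather than an error).
    """
    cai = getattr(trace, "Cai", None)
    if cai is None:
        return (float("nan"), float("nan"))
    cai = np.asarray(cai, dtype=float)
    return float(np.max(cai)), float(np.min(cai))


def iktot_integral(trace) -> float:
    """Trapezoidal one-cycle integral of the total potassium current
    (ms * pA/pF).  The calibration objective is the square of this value."""
    c = trace.currents if isinstance(trace.currents, CurrentsRecord) else trace.currents
    return float(np.trapezoid(ik_tot(c), np.asarray(trace.t, dtype=float)))


@dataclass
class AdaptationFit:
    """Biexponential APD-adaptation fit: y(t) = y_inf + A_fast e^{-t/tau_fast}
    + A_slow e^{-t/tau_slow}, times in seconds, tau_fast < tau_slow."""

    y_inf: float
    A_fast: float
    tau_fast: float
    A_slow: float
    tau_slow: float
    residual_norm: float
    identifiable: bool = True

    def __post_init__(self):
        if not (0 < self.tau_fast < self.tau_slow):
            raise ValueError("require 0 < tau_fast < tau_slow")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (self.y_inf + self.A_fast * np.exp(-t / self.tau_fast)
                + self.A_slow * np.exp(-t / self.tau_slow))


_TAU_FAST_INITS = (2.0, 10.0, 30.0)
_TAU_SLOW_INITS = (60.0, 90.0, 120.0)
_A_SLOW_IDENT_THRESHOLD = 1.0  # ms


def fit_adaptation(t, y, min_points: int = 30) -> AdaptationFit:
    """Fit the biexponential APD-adaptation model by nonlinear least squares.

    ``t``: beat-onset times since the cycle-length switch (seconds); ``y``:
    per-beat APD90 (ms).  Deterministic multi-start over a grid of time
    constants; the best residual wins.  When the slow amplitude is under 1 ms
    the slow time constant is flagged unidentifiable.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < min_points:
        raise ValueError(f"need at least {min_points} post-switch beats, got {len(t)}")

    span = y[0] - y[-1]

    def residual(theta):
        y_inf, af, as_, ltf, lts = theta
        return (y_inf + af * np.exp(-t / np.exp(ltf))
                + as_ * np.exp(-t / np.exp(lts)) - y)

    best = None
    diagnostics = []
    for tf0 in _TAU_FAST_INITS:
        for ts0 in _TAU_SLOW_INITS:
            theta0 = np.array([y[-1], span / 2.0, span / 2.0,
                               np.log(tf0), np.log(ts0)])
            try:
                res = least_squares(residual, theta0, method="lm",
                                    max_nfev=2000)
            except Exception as exc:  # pragma: no cover - solver failure path
                diagnostics.append(f"start ({tf0}, {ts0}): {exc}")
                continue
            if not np.all(np.isfinite(res.x)):
                diagnostics.append(f"start ({tf0}, {ts0}): non-finite solution")
                continue
            rn = float(np.linalg.norm(res.fun))
            # tie-break near-identical residuals toward an identifiable
            # slow component
            y_inf, af, as_, ltf, lts = res.x
            if np.exp(ltf) > np.exp(lts):
                af, as_ = as_, af
                ltf, lts = lts, ltf
            key = (round(rn, 8), abs(as_) < _A_SLOW_IDENT_THRESHOLD)
            if best is None or key < best[0]:
                best = (key, (y_inf, af, as_, ltf, lts), rn)
    if best is None:
        raise RuntimeError(
            "adaptation fit failed from every start: " + "; ".join(diagnostics))
    _, (y_inf, af, as_, ltf, lts), rn = best
    tau_f, tau_s = float(np.exp(ltf)), float(np.exp(lts))
    if tau_f == tau_s:
        tau_s = np.nextafter(tau_s, np.inf)
    return AdaptationFit(
        y_inf=float(y_inf), A_fast=float(af), tau_fast=tau_f,
        A_slow=float(as_), tau_slow=tau_s, residual_norm=rn,
        identifiable=abs(as_) >= _A_SLOW_IDENT_THRESHOLD)
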