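"""Stimulation protocols: steady-state pacing, abrupt cycle-length change
(rate adaptation), restitution across cycle lengths, and the unstimulated
extracellular-potassium step.

All protocols return plain containers (:class:`APTrace`, :class:`BeatSeries`)
that the biomarker module consumes, and are deterministic for a fixed model
and tolerance set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import biomarkers
from .models import CurrentsRecord, IonicModel, ToyVentricularModel, ik_tot
from .simulate import integrate_beat

__all__ = [
    "APTrace",
    "BeatSeries",
    "KoStepResult",
    "steady_state_pacing",
    "rate_adaptation_protocol",
    "ko_step_unstimulated",
    "restitution",
]

# an AP is counted only if V exceeds this level within CAPTURE_WINDOW of the
# stimulus (loss-of-capture rule)
CAPTURE_THRESHOLD = -20.0  # mV
CAPTURE_WINDOW = 50.0      # ms

DT_BEAT = 0.1    # ms, per-beat marker grid
DT_TRACE = 0.02  # ms, exported trace grid


@dataclass
class APTrace:
    """One-cycle record of a paced beat."""

    t: np.ndarray
    V: np.ndarray
    CL: float
    Cai: np.ndarray | None = None
    Ki: np.ndarray | None = None
    currents: CurrentsRecord | None = None
    stim_onset: float = 0.0

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace time grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        cols = {"time_ms": self.t, "V": self.V}
        if self.Cai is not None:
            cols["Cai"] = self.Cai
        if self.Ki is not None:
            cols["Ki"] = self.Ki
        if self.currents is not None:
            for name, val in self.currents.as_dict().items():
                if np.ndim(val) == np.ndim(self.t):
                    cols[name] = val
        return pd.DataFrame(cols)


@dataclass
class BeatSeries:
    """Per-beat marker records of a pacing run (one record per stimulus)."""

    beat: np.ndarray
    onset_s: np.ndarray
    cl: np.ndarray
    apd90: np.ndarray
    apd50: np.ndarray
    ca_sys: np.ndarray
    ca_dia: np.ndarray
    ki_end: np.ndarray
    iktot_integral: np.ndarray
    captured: np.ndarray = field(default=None)

    def __post_init__(self):
        for name in ("beat", "onset_s", "cl", "apd90", "apd50", "ca_sys",
                     "ca_dia", "ki_end", "iktot_integral"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.captured is None:
            self.captured = np.ones(len(self.beat), dtype=bool)
        self.captured = np.asarray(self.captured, dtype=bool)

    def __len__(self) -> int:
        return len(self.beat)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "beat": self.beat.astype(int), "onset_s": self.onset_s,
            "CL_ms": self.cl, "APD90_ms": self.apd90, "APD50_ms": self.apd50,
            "Ca_sys": self.ca_sys, "Ca_dia": self.ca_dia, "Ki_end": self.ki_end,
            "iktot_integral": self.iktot_integral, "captured": self.captured,
        })

    @staticmethod
    def concat(parts):
        return BeatSeries(**{
            name: np.concatenate([getattr(p, name) for p in parts])
            for name in ("beat", "onset_s", "cl", "apd90", "apd50", "ca_sys",
                         "ca_dia", "ki_end", "iktot_integral", "captured")})


def stimulus_waveform(t, amp, dur):
    """Rectangular stimulus sampled so that its trapezoidal integral is exact
    when the pulse edge falls on a grid point (half amplitude at the edge)."""
    t = np.asarray(t, dtype=float)
    w = np.where(t < dur, amp, 0.0)
    w = np.where(np.isclose(t, dur), 0.5 * amp, w)
    return w


def _resolve_stimulus(model, stim_amp, stim_dur):
    if stim_amp is None:
        stim_amp = getattr(model, "stim_amplitude", -40.0)
    if stim_dur is None:
        stim_dur = getattr(model, "stim_duration", 2.0)
    return float(stim_amp), float(stim_dur)


def _beat_arrays(model: IonicModel, t, Y, stim_amp, stim_dur):
    """Voltage/calcium/potassium series plus the K-current time series for one
    integrated beat."""
    names = model.state_names
    V = Y[:, names.index("V")]
    Cai = Y[:, names.index("Cai")] if "Cai" in names else None
    Ki = Y[:, names.index("Ki")] if "Ki" in names else None
    istim = stimulus_waveform(t, stim_amp, stim_dur)
    if isinstance(model, ToyVentricularModel):
        ki_for_currents = Ki if Ki is not None else model.params["Ki"]
        cur = model.currents(V, Y[:, 1], Y[:, 2], ki_for_currents, istim)
    else:
        cur = model.currents_series(t, Y, istim)
    return V, Cai, Ki, cur


def _record_beat(model, t, Y, stim_amp, stim_dur):
    names = model.state_names
    V = Y[:, names.index("V")]
    Cai = Y[:, names.index("Cai")] if "Cai" in names else None
    Ki = Y[:, names.index("Ki")] if "Ki" in names else None
    win = t <= CAPTURE_WINDOW
    captured = bool(np.max(V[win]) > CAPTURE_THRESHOLD)
    if captured:
        v_rest = float(V[0])
        apd90 = biomarkers.apd_from_arrays(t, V, 0.9, onset=0.0, v_rest=v_rest)
        apd50 = biomarkers.apd_from_arrays(t, V, 0.5, onset=0.0, v_rest=v_rest)
    else:
        apd90 = apd50 = float("nan")
    ca_sys = float(np.max(Cai)) if Cai is not None else float("nan")
    ca_dia = float(np.min(Cai)) if Cai is not None else float("nan")
    ki_end = float(Ki[-1]) if Ki is not None else float("nan")
    kappa = _kappa(model)
    if Ki is not None and kappa is not None:
        # the integrator already carries the K budget: d[K+]i/dt is exactly
        # -kappa * I_K,tot, so the one-cycle integral is -delta Ki / kappa
        integral = float(-(Ki[-1] - Ki[0]) / kappa)
    else:
        _, _, _, cur = _beat_arrays(model, t, Y, stim_amp, stim_dur)
        integral = float(np.trapezoid(ik_tot(cur), t))
    return apd90, apd50, ca_sys, ca_dia, ki_end, integral, captured


def _kappa(model):
    """Current-to-concentration factor Cmem/(Vmyo*Frdy), if declared."""
    try:
        return model.Cmem / (model.Vmyo * model.Frdy)
    except (AttributeError, KeyError, ZeroDivisionError):
        return None


def _pace(model, y0, CL, n_beats, stim_amp, stim_dur, beat0=0, t0_s=0.0,
          dt_beat=DT_BEAT, rtol=1e-6):
    """Pace ``n_beats`` from ``y0``; returns (BeatSeries, final state,
    last-beat (t, Y))."""
    rec = {k: [] for k in ("beat", "onset_s", "cl", "apd90", "apd50", "ca_sys",
                           "ca_dia", "ki_end", "iktot_integral", "captured")}
    y = np.asarray(y0, dtype=float).copy()
    last = None
    for b in range(n_beats):
        t, Y = integrate_beat(model, y, CL, stim_amp, stim_dur,
                              dt_out=dt_beat, rtol=rtol)
        y = Y[-1].copy()
        vals = _record_beat(model, t, Y, stim_amp, stim_dur)
        for k, v in zip(("apd90", "apd50", "ca_sys", "ca_dia", "ki_end",
                         "iktot_integral", "captured"), vals):
            rec[k].append(v)
        rec["beat"].append(beat0 + b)
        rec["onset_s"].append(t0_s + b * CL / 1000.0)
        rec["cl"].append(CL)
        last = (t, Y)
    return BeatSeries(**rec), y, last


def _final_trace(model, y_start, CL, stim_amp, stim_dur, rtol=1e-6):
    """Re-run the final beat on the fine marker grid and build an APTrace.

    A tighter step cap keeps the dense-output interpolation error below the
    trapezoidal-integration tolerance of the exported current series.
    """
    t, Y = integrate_beat(model, y_start, CL, stim_amp, stim_dur,
                          dt_out=DT_TRACE, rtol=rtol, max_step=1.0)
    V, Cai, Ki, cur = _beat_arrays(model, t, Y, stim_amp, stim_dur)
    return APTrace(t=t, V=V, CL=CL, Cai=Cai, Ki=Ki, currents=cur,
                   stim_onset=0.0)


def steady_state_pacing(model: IonicModel, CL: float, n_beats: int = 3000,
                        stim_amp=None, stim_dur=None, rtol=1e-6):
    """Deliver a train of stimuli at a fixed cycle length from the model's
    initial state.

    Returns the full per-beat series together with the final beat re-sampled
    on the fine trace grid (0.02 ms) with its current records.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    stim_amp, stim_dur = _resolve_stimulus(model, stim_amp, stim_dur)
    if CL <= stim_dur:
        raise ValueError("CL must exceed the stimulus duration")
    if n_beats > 1:
        series, y_start, _ = _pace(model, model.initial_state, CL,
                                   n_beats - 1, stim_amp, stim_dur, rtol=rtol)
    else:
        series, y_start = None, model.initial_state
    trace = _final_trace(model, y_start, CL, stim_amp, stim_dur, rtol=rtol)
    # final beat record computed from the fine trace for consistency
    apd90, apd50, ca_sys, ca_dia, ki_end, integ, captured = _record_beat_from_trace(trace)
    final = BeatSeries(
        beat=[n_beats - 1], onset_s=[(n_beats - 1) * CL / 1000.0], cl=[CL],
        apd90=[apd90], apd50=[apd50], ca_sys=[ca_sys], ca_dia=[ca_dia],
        ki_end=[ki_end], iktot_integral=[integ], captured=[captured])
    series = final if series is None else BeatSeries.concat([series, final])
    return series, trace


def _record_beat_from_trace(trace: APTrace):
    t, V = trace.t, trace.V
    win = t <= CAPTURE_WINDOW
    captured = bool(np.max(V[win]) > CAPTURE_THRESHOLD)
    if captured:
        v_rest = float(V[0])
        apd90 = biomarkers.apd_from_arrays(t, V, 0.9, onset=0.0, v_rest=v_rest)
        apd50 = biomarkers.apd_from_arrays(t, V, 0.5, onset=0.0, v_rest=v_rest)
    else:
        apd90 = apd50 = float("nan")
    ca_sys = float(np.max(trace.Cai)) if trace.Cai is not None else float("nan")
    ca_dia = float(np.min(trace.Cai)) if trace.Cai is not None else float("nan")
    ki_end = float(trace.Ki[-1]) if trace.Ki is not None else float("nan")
    integ = biomarkers.iktot_integral(trace)
    return apd90, apd50, ca_sys, ca_dia, ki_end, integ, captured


def rate_adaptation_protocol(model: IonicModel, cl_pre: float = 1000.0,
                             cl_post: float = 600.0,
                             duration_pre_ms: float = 480_000.0,
                             duration_post_ms: float = 480_000.0,
                             stim_amp=None, stim_dur=None, rtol=1e-6):
    """Abrupt cycle-length change protocol.

    Paces at ``cl_pre`` for ``duration_pre_ms`` then at ``cl_post`` for
    ``duration_post_ms`` (defaults: 8 min at CL 1000 = 480 beats, then 8 min
    at CL 600 = 800 beats).  Beat onset times are reported relative to the
    switch (negative before it), so the post-switch series feeds the
    adaptation fit directly.
    """
    stim_amp, stim_dur = _resolve_stimulus(model, stim_amp, stim_dur)
    n_pre = int(round(duration_pre_ms / cl_pre))
    n_post = int(round(duration_post_ms / cl_post))
    pre, y, _ = _pace(model, model.initial_state, cl_pre, n_pre, stim_amp,
                      stim_dur, beat0=0, t0_s=-n_pre * cl_pre / 1000.0,
                      rtol=rtol)
    post, _, _ = _pace(model, y, cl_post, n_post, stim_amp, stim_dur,
                       beat0=n_pre, t0_s=0.0, rtol=rtol)
    return BeatSeries.concat([pre, post])


@dataclass
class KoStepResult:
    """Membrane-potential response of an unstimulated cell to a step in
    extracellular potassium."""

    t: np.ndarray
    V: np.ndarray
    t90: float
    V_start: float
    V_ss: float
    Ki_end: float
    warning: bool = False


def ko_step_unstimulated(model: IonicModel, Ko_from: float, Ko_to: float,
                         settle_ms: float = 10_000.0,
                         observe_ms: float = 2_000.0, rtol=1e-6,
                         dt_out: float = 0.1) -> KoStepResult:
    """Let the unstimulated cell settle at ``Ko_from``, step the extracellular
    potassium to ``Ko_to`` at t = 0, and report the time to 90% of the
    membrane-potential transition (steady level taken at ``observe_ms``).
    """
    if Ko_from <= 0 or Ko_to <= 0:
        raise ValueError("Ko values must be positive")
    m0 = model.with_params(Ko=Ko_from)
    _, Y = integrate_beat(m0, m0.initial_state, settle_ms, 0.0, 0.0,
                          dt_out=min(settle_ms, 10.0), rtol=rtol)
    y0 = Y[-1]
    m1 = model.with_params(Ko=Ko_to)
    t, Y = integrate_beat(m1, y0, observe_ms, 0.0, 0.0, dt_out=dt_out,
                          rtol=rtol)
    iv = m1.state_names.index("V")
    V = Y[:, iv]
    V_start, V_ss = float(V[0]), float(V[-1])
    ki_end = float(Y[-1, m1.state_names.index("Ki")]) \
        if "Ki" in m1.state_names else float("nan")
    if Ko_to == Ko_from or abs(V_ss - V_start) < 1e-9:
        warnings.warn("no membrane-potential transition; t90 defined as 0")
        return KoStepResult(t, V, 0.0, V_start, V_ss, ki_end, warning=True)
    target = V_start + 0.9 * (V_ss - V_start)
    if V_ss > V_start:
        crossed = V >= target
    else:
        crossed = V <= target
    if not crossed.any():  # pragma: no cover - degenerate
        return KoStepResult(t, V, float("nan"), V_start, V_ss, ki_end,
                            warning=True)
    j = int(np.argmax(crossed))
    t90 = float(t[j]) if j == 0 else float(np.interp(
        target, [V[j - 1], V[j]][::1 if V[j] > V[j - 1] else -1],
        [t[j - 1], t[j]][::1 if V[j] > V[j - 1] else -1]))
    # flag a non-monotone approach (first crossing reported)
    after = V[j:]
    non_monotone = bool(np.any((after - target) * np.sign(V_ss - V_start)
                               < -0.05 * abs(V_ss - V_start)))
    if non_monotone:
        warnings.warn("non-monotone approach to steady state; "
                      "first 90% crossing reported")
    return KoStepResult(t, V, t90, V_start, V_ss, ki_end,
                        warning=non_monotone)


def restitution(model: IonicModel, cl_list, n_beats: int = 3000,
                stim_amp=None, stim_dur=None, rtol=1e-6) -> pd.DataFrame:
    """Steady-state APD90 across cycle lengths.

    Per CL: last-beat APD90, APD90 normalized to the CL = 1000 ms value, and
    an alternans flag (|APD90(last) - APD90(last-1)| > 1 ms).  A CL where the
    stimulus fails to elicit an AP is marked inexcitable rather than failing.
    """
    cl_list = list(cl_list)
    if not cl_list:
        raise ValueError("cl_list must be nonempty")
    run_cls = list(cl_list) + ([1000.0] if 1000.0 not in cl_list else [])
    rows = {}
    for CL in run_cls:
        series, _ = steady_state_pacing(model, CL, n_beats, stim_amp,
                                        stim_dur, rtol=rtol)
        excitable = bool(series.captured[-1])
        apd_last = float(series.apd90[-1])
        alternans = (len(series) >= 2 and series.captured[-2]
                     and abs(series.apd90[-1] - series.apd90[-2]) > 1.0)
        rows[CL] = dict(CL=CL, apd90=apd_last if excitable else float("nan"),
                        alternans=bool(alternans), excitable=excitable)
    ref = rows[1000.0]["apd90"]
    out = []
    for CL in cl_list:
        r = dict(rows[CL])
        r["apd90_norm"] = r["apd90"] / ref if ref and np.isfinite(ref) else float("nan")
        out.append(r)
    return pd.DataFrame(out, columns=["CL", "apd90", "apd90_norm",
                                      "alternans", "excitable"])
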