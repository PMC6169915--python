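"""Batch evaluators mapping scaled conductance points to the calibration
objective and marker vector.

Each candidate point configures the model's conductances and runs three
protocols: steady-state pacing at CL 1000 ms and CL 2000 ms, and the abrupt
cycle-length-change protocol — the minimal set that yields all seven
constrained markers.  The objective is the squared one-cycle integral of the
total potassium current on the final 1 Hz beat.

Two protocol profiles are provided: ``"paper"`` (3000 pacing beats, 8-minute
adaptation segments) and ``"test"`` (300 beats, 2-minute segments), the
latter sized for desk-scale runs.  Points in a batch are independent; results
are order-stable and, with a worker pool, independent of the worker count.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import biomarkers
from .biomarkers import MARKER_NAMES, MarkerVector
from .models import IonicModel, apply_conductances
from .protocols import rate_adaptation_protocol, steady_state_pacing

__all__ = ["measure_markers", "make_model_evaluator", "PROFILES"]

PROFILES = {
    "paper": dict(n_beats=3000, adapt_pre_ms=480_000.0, adapt_post_ms=480_000.0),
    "test": dict(n_beats=300, adapt_pre_ms=120_000.0, adapt_post_ms=120_000.0),
}


def measure_markers(model: IonicModel, n_beats: int = 300,
                    adapt_pre_ms: float = 120_000.0,
                    adapt_post_ms: float = 120_000.0,
                    rtol: float = 1e-6) -> MarkerVector:
    """Run the marker protocol set on one configured model.

    Raises if the model loses capture or fails to repolarize; callers that
    need soft failure (batch evaluators, sensitivity scans) catch and mark.
    """
    series_1hz, trace_1hz = steady_state_pacing(model, 1000.0, n_beats,
                                                rtol=rtol)
    if not series_1hz.captured[-1]:
        raise RuntimeError("loss of capture at CL 1000 ms")
    _, trace_2hz = steady_state_pacing(model, 2000.0, n_beats, rtol=rtol)
    adapt = rate_adaptation_protocol(model, duration_pre_ms=adapt_pre_ms,
                                     duration_post_ms=adapt_post_ms,
                                     rtol=rtol)
    post = adapt.onset_s >= 0
    fit = biomarkers.fit_adaptation(adapt.onset_s[post], adapt.apd90[post])
    apd90 = biomarkers.apd(trace_1hz, 0.9)
    apd50 = biomarkers.apd(trace_1hz, 0.5)
    ca_sys_1, ca_dia_1 = biomarkers.ca_levels(trace_1hz)
    ca_sys_05, ca_dia_05 = biomarkers.ca_levels(trace_2hz)
    return MarkerVector(
        apd90=apd90, triangulation=apd90 - apd50,
        ca_sys_1hz=ca_sys_1, ca_sys_0p5hz=ca_sys_05,
        ca_dia_1hz=ca_dia_1, ca_dia_0p5hz=ca_dia_05,
        tau_slow=fit.tau_slow,
        iktot_integral=biomarkers.iktot_integral(trace_1hz))


def make_model_evaluator(model: IonicModel, space, constraints=None,
                         profile: str = "test", workers: int = 1,
                         rtol: float = 1e-6, cache: bool = True,
                         **overrides):
    """Evaluator satisfying the optimizer contract for an ionic model.

    Returns a callable ``X (m, n) -> (f (m,), M (m, 7))`` with marker columns
    in :data:`~iontune.biomarkers.MARKER_NAMES` order.  A point whose
    simulation fails yields a NaN row (the optimizer drops it with a
    warning).  Repeated points are served from a cache keyed on the exact
    scaled coordinates, so re-evaluating the trust-region center is free.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; use one of {list(PROFILES)}")
    settings = dict(PROFILES[profile])
    settings.update(overrides)
    memo: dict = {}

    def evaluate_point(x):
        key = np.asarray(x, dtype=float).tobytes()
        if cache and key in memo:
            return memo[key]
        try:
            m = apply_conductances(model, x, space)
            mv = measure_markers(m, rtol=rtol, **settings)
            out = (mv.iktot_integral ** 2, mv.as_array())
        except Exception as exc:
            warnings.warn(f"evaluation failed at x={np.round(x, 4)}: {exc}")
            out = (float("nan"), np.full(len(MARKER_NAMES), np.nan))
        if cache:
            memo[key] = out
        return out

    def evaluator(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if workers > 1 and len(X) > 1:
            # points are independent and order-stable; threads suffice since
            # the heavy lifting happens in compiled integrator kernels
            from joblib import Parallel, delayed
            results = Parallel(n_jobs=workers, backend="threading")(
                delayed(evaluate_point)(x) for x in X)
        else:
            results = [evaluate_point(x) for x in X]
        f = np.array([r[0] for r in results])
        M = np.stack([r[1] for r in results]) if results else \
            np.empty((0, len(MARKER_NAMES)))
        return f, M

    evaluator.profile = profile
    evaluator.settings = settings
    return evaluator
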