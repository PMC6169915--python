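"""Synthetic generators and oracle problems.

Everything the pipeline needs to be exercised end-to-end without external
data: an analytic constrained optimization problem with a brute-force
verifiable optimum, closed-form AP/calcium traces with known marker values,
noisy biexponential adaptation series, and the toy-model calibration
scenario (perturb conductances, then ask the optimizer to restore potassium
balance subject to marker bands).  All generators are deterministic given
their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ConstraintSpec, DecisionSpace, TrustRegionParams, DEFAULT_BOUND
from .evaluator import PROFILES, make_model_evaluator, measure_markers
from .models import CurrentsRecord, ToyVentricularModel
from .optimizer import OptimizationProblem
from .protocols import APTrace, BeatSeries

__all__ = [
    "AnalyticProblem",
    "grid_oracle",
    "make_synthetic_trace",
    "make_adaptation_series",
    "make_toy_scenario",
    "ToyScenario",
]


@dataclass(frozen=True)
class AnalyticProblem:
    """Closed-form constrained problem mirroring the calibration structure.

    The objective is the fourth power of an affine form — like the squared
    squared-integral objective, flat near its zero set — and two quadratic
    "markers" carry band constraints.  Everything is evaluable in closed
    form, so a dense grid provides ground truth.
    """

    bands: ConstraintSpec = field(default_factory=lambda: ConstraintSpec(
        names=("m1", "m2"), mLL=(280.0, 44.0), mUU=(310.0, 112.0)))
    bound: float = DEFAULT_BOUND

    def f(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (1.0 + 0.5 * X[:, 0] - 0.3 * X[:, 1]) ** 4

    def markers(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        x1, x2 = X[:, 0], X[:, 1]
        m1 = 300.0 + 10.0 * x1 + 5.0 * x2 + x1 * x2
        m2 = 80.0 - 4.0 * x1 + 2.0 * x2 ** 2
        return np.stack([m1, m2], axis=1)

    def evaluator(self, X):
        """Optimizer-contract batch evaluator (exact, no simulation)."""
        return self.f(X), self.markers(X)

    def feasible(self, X):
        g = self.bands.g(self.markers(X))
        return np.all(g <= 0.0, axis=1)

    def problem(self, trust_region: TrustRegionParams | None = None,
                x0=None) -> OptimizationProblem:
        space = DecisionSpace(("x1", "x2"), G0=(1.0, 1.0),
                              xL=-self.bound, xU=self.bound)
        return OptimizationProblem(
            space=space, constraints=self.bands,
            trust_region=trust_region or TrustRegionParams(),
            x0=None if x0 is None else np.asarray(x0, dtype=float))


def grid_oracle(problem, resolution: float = 1e-3, chunk: int = 256):
    """Brute-force constrained optimum on a uniform grid over the bounds.

    Exhaustively evaluates the true objective, keeps feasible points, and
    returns ``(x_opt, f_opt)``.  Serves as ground truth for the trust-region
    optimizer; evaluation is chunked row-wise to bound memory.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    b = problem.bound
    axis = np.arange(-b, b + resolution / 2, resolution)
    best_f = np.inf
    best_x = None
    for i0 in range(0, len(axis), chunk):
        x1 = axis[i0:i0 + chunk]
        X1, X2 = np.meshgrid(x1, axis, indexing="ij")
        X = np.stack([X1.ravel(), X2.ravel()], axis=1)
        feas = problem.feasible(X)
        if not feas.any():
            continue
        fv = problem.f(X[feas])
        j = int(np.argmin(fv))
        if fv[j] < best_f:
            best_f = float(fv[j])
            best_x = X[feas][j].copy()
    if best_x is None:
        raise RuntimeError("no feasible grid point at this resolution")
    return best_x, best_f


def make_synthetic_trace(peak: float = 40.0, rest: float = -85.0,
                         fall_ms: float = 300.0, shape: str = "ramp",
                         stim_onset: float = 10.0, tail_ms: float = 100.0,
                         dt: float = 0.5, ca_amp: float = 6e-4,
                         ca_rest: float = 1e-4, ca_tau: float = 50.0,
                         CL: float | None = None) -> APTrace:
    """Deterministic piecewise AP and calcium waveforms with closed-form
    markers.

    ``shape="ramp"``: instant rise to ``peak`` at the stimulus, linear fall
    to ``rest`` over ``fall_ms`` — APD at fraction q is exactly
    ``q * fall_ms``.  ``shape="square"``: flat at ``peak`` until ``fall_ms``
    then an instant drop (triangulation 0 in the square limit).  The calcium
    transient is ``ca_rest + ca_amp * (t/tau) * exp(1 - t/tau)``, peaking at
    ``ca_rest + ca_amp`` exactly at ``t = tau`` after the stimulus.
    """
    if peak <= rest:
        raise ValueError("need peak > rest")
    T = stim_onset + fall_ms + tail_ms
    t = np.arange(0.0, T + dt / 2, dt)
    # make sure the onset and the end of the fall are exact samples
    for special in (stim_onset, stim_onset + fall_ms):
        if not np.any(np.isclose(t, special)):
            t = np.sort(np.append(t, special))
    ts = t - stim_onset
    if shape == "ramp":
        V = np.where(ts < 0, rest,
                     np.maximum(peak - (peak - rest) * ts / fall_ms, rest))
    elif shape == "square":
        V = np.where((ts >= 0) & (ts < fall_ms), peak, rest)
        # the drop must be resolved by consecutive samples
    else:
        raise ValueError("shape must be 'ramp' or 'square'")
    Cai = np.where(ts <= 0, ca_rest,
                   ca_rest + ca_amp * (ts / ca_tau) * np.exp(1.0 - ts / ca_tau))
    zeros = np.zeros_like(t)
    return APTrace(t=t, V=V, CL=CL if CL is not None else T, Cai=Cai,
                   currents=CurrentsRecord(Istim=zeros), stim_onset=stim_onset)


def make_adaptation_series(y_inf: float = 250.0, A_fast: float = 15.0,
                           tau_fast: float = 10.0, A_slow: float = 25.0,
                           tau_slow: float = 90.0, sigma: float = 0.0,
                           seed: int = 0, spacing_s: float = 0.6,
                           duration_s: float = 480.0) -> BeatSeries:
    """Beat series following a biexponential APD-adaptation law with optional
    Gaussian noise; bitwise-reproducible for a fixed seed."""
    if not tau_fast < tau_slow:
        raise ValueError("require tau_fast < tau_slow")
    t = np.arange(0.0, duration_s, spacing_s)
    y = (y_inf + A_fast * np.exp(-t / tau_fast)
         + A_slow * np.exp(-t / tau_slow))
    if sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, sigma, size=len(t))
    nan = np.full(len(t), np.nan)
    return BeatSeries(beat=np.arange(len(t)), onset_s=t,
                      cl=np.full(len(t), spacing_s * 1000.0), apd90=y,
                      apd50=nan, ca_sys=nan, ca_dia=nan, ki_end=nan,
                      iktot_integral=nan)


DEFAULT_PERTURBATION = {"G_K1": 1.3, "G_Ca": 0.85}
TOY_DECISION_NAMES = ("G_Ca", "G_K", "G_K1", "G_NaK")
# relative band half-widths around the baseline markers
_BAND_FRACTION = 0.10
_BAND_FRACTION_CA = 0.15


@dataclass
class ToyScenario:
    """Toy-model calibration scenario: a perturbed model, marker bands built
    from the unperturbed baseline, and the matching optimization problem."""

    problem: OptimizationProblem
    evaluator: object
    model: ToyVentricularModel
    baseline_markers: dict
    perturbation: dict
    profile: str

    def fit(self, **kw):
        from .optimizer import ConductanceCalibration
        return ConductanceCalibration(self.problem, self.evaluator).fit(**kw)


def make_toy_scenario(perturbation: dict | None = None,
                      profile: str = "test",
                      trust_region: TrustRegionParams | None = None,
                      rtol: float = 1e-6) -> ToyScenario:
    """Build the end-to-end calibration scenario on the toy model.

    The unperturbed toy baseline markers are measured once; constraint bands
    are set to baseline +/-10% (+/-15% for the calcium levels).  The model's
    conductances are then perturbed (default: G_K1 x1.3, G_Ca x0.85),
    breaking the one-cycle potassium balance; the returned problem asks the
    optimizer to re-balance the squared K-current integral subject to the
    bands, with decision variables G_Ca, G_K, G_K1, G_NaK.
    """
    perturbation = dict(DEFAULT_PERTURBATION if perturbation is None
                        else perturbation)
    if any(v <= 0 for v in perturbation.values()):
        raise ValueError("perturbation multipliers must be positive")
    settings = PROFILES[profile]
    baseline_model = ToyVentricularModel()
    base = measure_markers(baseline_model, rtol=rtol, **settings)
    mvec = base.as_array()
    frac = np.array([_BAND_FRACTION, _BAND_FRACTION, _BAND_FRACTION_CA,
                     _BAND_FRACTION_CA, _BAND_FRACTION_CA, _BAND_FRACTION_CA,
                     _BAND_FRACTION])
    half = frac * np.abs(mvec)
    from .biomarkers import MARKER_NAMES
    bands = ConstraintSpec(MARKER_NAMES, mvec - half, mvec + half)

    perturbed = baseline_model.with_params(**{
        k: baseline_model.params[k] * v for k, v in perturbation.items()})
    # sanity: the perturbed model must still produce an AP
    from .protocols import steady_state_pacing
    s, _ = steady_state_pacing(perturbed, 1000.0, 2, rtol=rtol)
    if not s.captured[-1]:
        raise RuntimeError("perturbed toy model is inexcitable")

    space = DecisionSpace(TOY_DECISION_NAMES,
                          [perturbed.params[n] for n in TOY_DECISION_NAMES])
    problem = OptimizationProblem(
        space=space, constraints=bands,
        trust_region=trust_region or TrustRegionParams())
    evaluator = make_model_evaluator(perturbed, space, bands, profile=profile,
                                     rtol=rtol)
    return ToyScenario(problem=problem, evaluator=evaluator, model=perturbed,
                       baseline_markers=base.as_dict(),
                       perturbation=perturbation, profile=profile)
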