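"""Trust-region, response-surface constrained minimization.

The algorithm calibrates a small set of scaled conductances against an
expensive evaluator (typically a paced cell model).  Each iteration:

1. sample the evaluator on a full factorial grid over the trust-region box
   (the *database*; one parallelizable batch),
2. fit quadratic response surfaces to the objective and to every marker,
3. solve the surrogate problem: minimize the objective surface subject to the
   marker-band constraints, the trust-region box and the global bounds,
4. evaluate the true objective/markers at the candidate (a second batch) and
   compare true vs. predicted improvement through trust-region ratios,
5. accept or reject the candidate and update the radius (shrink x0.25 on
   rejection, keep on an interior accepted step, double — capped — on an
   accepted boundary step),
6. stop when an accepted step is tiny, the Lagrangian gradient is tiny, the
   radius collapses, or the iteration budget runs out.

The marker constraints enter the surrogate problem as two-sided bands on the
marker surfaces, which is equivalent to the canonical ``|m - mCR|/mRR - 1 <= 0``
transform but keeps the surrogate constraints smooth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .design import (ConstraintSpec, Database, DecisionSpace,
                     TrustRegionParams, full_factorial)
from .surface import FittingError, ResponseSurface, fit_quadratic_rsa

__all__ = [
    "OptimizationProblem",
    "IterationRecord",
    "OptimizationResult",
    "trust_ratio",
    "accept_step",
    "update_radius",
    "lagrangian_gradient",
    "solve_trust_subproblem",
    "run_optimization",
    "ConductanceCalibration",
    "EvaluatorError",
]

_FEAS_TOL = 1e-8
_BOX_TOL = 1e-9


class EvaluatorError(RuntimeError):
    """Raised when the evaluator cannot supply enough valid database points."""


@dataclass(frozen=True)
class OptimizationProblem:
    """Decision space, marker bands and trust-region settings for one run.

    ``equalities`` is carried for generality of the formulation but is empty
    for conductance calibration — no equality constraints are defined there.
    """

    space: DecisionSpace
    constraints: ConstraintSpec
    trust_region: TrustRegionParams = field(default_factory=TrustRegionParams)
    x0: np.ndarray | None = None
    equalities: tuple = ()

    def start_point(self) -> np.ndarray:
        if self.x0 is None:
            return np.zeros(self.space.n)
        x0 = np.asarray(self.x0, dtype=float)
        if x0.shape != (self.space.n,):
            raise ValueError("x0 must match the decision-space dimension")
        return x0


def trust_ratio(true_old, true_new, surr_old, surr_new, guard: float = 1e-12) -> float:
    """Ratio of true to surrogate change between the iterate and the candidate.

    Near-degenerate surrogate changes are guarded: if the predicted change is
    below ``guard`` in magnitude, the ratio is 1 when the true change is also
    below ``guard`` (perfect-surrogate limit) and signed infinity otherwise.
    """
    dt = true_new - true_old
    ds = surr_new - surr_old
    if abs(ds) < guard:
        if abs(dt) < guard:
            return 1.0
        return float(np.sign(dt) * np.inf)
    return dt / ds


def accept_step(rho0: float, rho_constraints, g_true, rho_L: float) -> bool:
    """Candidate acceptance rule.

    Accepted iff the objective ratio is positive and either (i) the true
    transformed constraints are all feasible at the candidate, or (ii) every
    constraint trust ratio lies within ``rho_L`` of 1.
    """
    if not rho0 > 0:
        return False
    g_true = np.asarray(g_true, dtype=float)
    if g_true.size == 0 or np.all(g_true <= _FEAS_TOL):
        return True
    rho = np.asarray(rho_constraints, dtype=float)
    return bool(np.all(np.abs(rho - 1.0) <= rho_L))


def update_radius(delta: float, accepted: bool, step_on_boundary: bool,
                  delta_max: float) -> float:
    """Radius update: 0.25x on rejection, keep on an interior accepted step,
    2x (capped at ``delta_max``) on an accepted boundary step."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not accepted:
        return 0.25 * delta
    if step_on_boundary:
        return min(2.0 * delta, delta_max)
    return delta


def lagrangian_gradient(f_rsa: ResponseSurface, constraint_rsa, lam, x) -> np.ndarray:
    """Analytic gradient of ``phi(x) = f~(x) + sum_j lam_j * s_j(x)`` where the
    ``s_j`` are the constraint (marker) surfaces.  No numerical differentiation:
    surface gradients are evaluated from the polynomial coefficients."""
    lam = np.asarray(lam, dtype=float)
    if len(lam) != len(constraint_rsa):
        raise ValueError("multiplier count must match constraint surfaces")
    g = f_rsa.gradient(x)
    for lj, sj in zip(lam, constraint_rsa):
        if lj != 0.0:
            g = g + lj * sj.gradient(x)
    return g


def _corner_starts(lo: np.ndarray, hi: np.ndarray):
    """Center plus four deterministic box corners (all-low, all-high, and the
    two alternating patterns)."""
    n = len(lo)
    mid = 0.5 * (lo + hi)
    alt = np.array([(i % 2) for i in range(n)], dtype=float)
    corners = [
        lo, hi,
        lo + (hi - lo) * alt,
        hi - (hi - lo) * alt,
    ]
    return [mid] + [np.asarray(c, dtype=float) for c in corners]


def solve_trust_subproblem(f_rsa: ResponseSurface, g_rsa, center, delta: float,
                           space: DecisionSpace):
    """Minimize the objective surface subject to ``g~_j(x) <= 0`` and the box
    given by the trust region intersected with the global bounds.

    Restarts a gradient-based NLP solve (SLSQP with analytic polynomial
    gradients) from the box center and four deterministic corners and keeps
    the best feasible result; quadratic surfaces can be nonconvex.

    Returns
    -------
    x_star : ndarray
    lam : ndarray
        Non-negative multipliers of the ``g~`` constraints, reconstructed by
        non-negative least squares on the active-constraint gradients.
    feasible : bool
        False when no candidate satisfied every surrogate constraint; in that
        case ``x_star`` minimizes the worst constraint violation.
    """
    center = np.asarray(center, dtype=float)
    lo = np.maximum(space.xL, center - delta)
    hi = np.minimum(space.xU, center + delta)
    bounds = list(zip(lo, hi))
    cons = [
        {"type": "ineq",
         "fun": (lambda x, s=s: -s(x)),
         "jac": (lambda x, s=s: -s.gradient(x))}
        for s in g_rsa
    ]

    def max_violation(x):
        if not g_rsa:
            return 0.0
        return max(s(x) for s in g_rsa)

    best = None
    for x_init in _corner_starts(lo, hi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                lambda x: f_rsa(x), x_init, jac=lambda x: f_rsa.gradient(x),
                bounds=bounds, constraints=cons, method="SLSQP",
                options={"maxiter": 200, "ftol": 1e-12},
            )
        x = np.clip(res.x, lo, hi)
        feas = max_violation(x) <= _FEAS_TOL
        key = (not feas, f_rsa(x) if feas else max_violation(x))
        if best is None or key < best[0]:
            best = (key, x, feas)

    _, x_star, feasible = best
    if not feasible and g_rsa:
        # fall back to minimizing the worst violation (smooth surrogate:
        # sum of squared positive parts), flagged infeasible
        def viol(x):
            return sum(max(s(x), 0.0) ** 2 for s in g_rsa)

        def viol_grad(x):
            g = np.zeros_like(x)
            for s in g_rsa:
                v = s(x)
                if v > 0:
                    g += 2.0 * v * s.gradient(x)
            return g

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(viol, x_star, jac=viol_grad, bounds=bounds,
                           method="L-BFGS-B", options={"maxiter": 500})
        x_star = np.clip(res.x, lo, hi)
        feasible = max_violation(x_star) <= _FEAS_TOL

    lam = _reconstruct_multipliers(f_rsa, g_rsa, x_star, lo, hi)
    return x_star, lam, feasible


def _reconstruct_multipliers(f_rsa, g_rsa, x, lo, hi, active_tol: float = 1e-6):
    """Least-squares KKT multipliers for the active ``g~`` constraints on the
    coordinates not pinned at a box bound."""
    lam = np.zeros(len(g_rsa))
    if not g_rsa:
        return lam
    free = (x - lo > 1e-7) & (hi - x > 1e-7)
    active = [j for j, s in enumerate(g_rsa) if s(x) > -active_tol]
    if not active or not np.any(free):
        return lam
    G = np.stack([g_rsa[j].gradient(x)[free] for j in active], axis=1)
    rhs = -f_rsa.gradient(x)[free]
    sol, _ = nnls(G, rhs)
    for j, v in zip(active, sol):
        lam[j] = v
    return lam


def _band_constraint_surfaces(m_surfaces, constraints: ConstraintSpec,
                              margin: float = 0.0):
    """Two smooth surrogate constraints per marker band, scaled by the band
    half-range so band edges sit at g=0 and the center at g=-1 (the canonical
    transform without the absolute value).  ``margin`` shrinks the surrogate
    band by that fraction of the half-range on each side."""
    g_surfs = []
    for j, s in enumerate(m_surfaces):
        rr = constraints.mRR[j]
        g_surfs.append(s.affine(1.0 / rr,
                                -constraints.mUU[j] / rr + margin))  # m <= mUU
        g_surfs.append(s.affine(-1.0 / rr,
                                constraints.mLL[j] / rr + margin))   # m >= mLL
    return g_surfs


def _marker_multipliers(lam_g, constraints: ConstraintSpec):
    """Fold the paired band multipliers back onto the marker surfaces: the
    upper-edge multiplier enters with +, the lower edge with -, both divided
    by the half-range used to scale the constraint surfaces."""
    n = constraints.n
    lam = np.zeros(n)
    for j in range(n):
        lam[j] = (lam_g[2 * j] - lam_g[2 * j + 1]) / constraints.mRR[j]
    return lam


@dataclass
class IterationRecord:
    k: int
    x_k: np.ndarray
    x_star: np.ndarray
    delta_k: float
    f_k: float
    f_star: float
    m_k: np.ndarray
    m_star: np.ndarray
    rho0: float
    rho_markers: np.ndarray
    accepted: bool
    lam: np.ndarray
    g_star: np.ndarray
    subproblem_feasible: bool
    grad_phi_norm: float
    termination: str = ""

    def __post_init__(self):
        if self.accepted and not self.rho0 > 0:
            raise ValueError("an accepted step requires rho0 > 0")


@dataclass
class OptimizationResult:
    """Outcome of a calibration run, statsmodels-results style."""

    problem: OptimizationProblem
    x_final: np.ndarray
    termination: str
    records: list
    f_final: float
    markers_final: np.ndarray
    n_evaluations: int

    _TERMINATIONS = ("step-size", "gradient", "radius", "max-iter")

    def __post_init__(self):
        if self.termination not in self._TERMINATIONS:
            raise ValueError(f"unknown termination reason {self.termination!r}")

    @property
    def conductances_final(self) -> np.ndarray:
        return self.problem.space.unscale(self.x_final)

    @property
    def percent_change(self) -> np.ndarray:
        return 100.0 * (10.0 ** (self.x_final / 20.0) - 1.0)

    @property
    def n_iterations(self) -> int:
        return len(self.records)

    def iteration_frame(self) -> pd.DataFrame:
        """Per-iteration log as a flat table (CSV-ready)."""
        rows = []
        names = self.problem.space.names
        mnames = self.problem.constraints.names
        for r in self.records:
            row = {"k": r.k, "delta_k": r.delta_k}
            row.update({f"x_{n}": v for n, v in zip(names, r.x_k)})
            row["f"] = r.f_k
            row.update({f"m_{n}": v for n, v in zip(mnames, r.m_k)})
            row["rho0"] = r.rho0
            row.update({f"rho_{n}": v for n, v in zip(mnames, r.rho_markers)})
            row["flgTR"] = r.accepted
            row["termination"] = r.termination
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        space = self.problem.space
        return {
            "termination": self.termination,
            "iterations": self.n_iterations,
            "evaluations": self.n_evaluations,
            "objective": self.f_final,
            "x_scaled": dict(zip(space.names, self.x_final.tolist())),
            "conductances": dict(zip(space.names, self.conductances_final.tolist())),
            "percent_change": dict(zip(space.names, self.percent_change.tolist())),
            "markers": dict(zip(self.problem.constraints.names,
                                np.asarray(self.markers_final).tolist())),
        }

    def to_json(self, path=None, **kw) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        space = self.problem.space
        cons = self.problem.constraints
        lines = []
        lines.append("Conductance calibration (trust-region response surface)")
        lines.append("=" * 62)
        lines.append(f"Termination: {self.termination:<12}  Iterations: "
                     f"{self.n_iterations}   Evaluations: {self.n_evaluations}")
        lines.append(f"Final objective: {self.f_final:.6g}")
        lines.append("-" * 62)
        lines.append(f"{'conductance':<14}{'x (scaled)':>12}{'value':>14}{'% change':>12}")
        for name, x, g, p in zip(space.names, self.x_final,
                                 self.conductances_final, self.percent_change):
            lines.append(f"{name:<14}{x:>12.4f}{g:>14.6g}{p:>+12.2f}")
        lines.append("-" * 62)
        lines.append(f"{'marker':<16}{'value':>14}{'band':>24}{'in':>6}")
        g = cons.g(self.markers_final)
        for j, name in enumerate(cons.names):
            band = f"[{cons.mLL[j]:.4g}, {cons.mUU[j]:.4g}]"
            ok = "yes" if g[j] <= _FEAS_TOL else "NO"
            lines.append(f"{name:<16}{self.markers_final[j]:>14.6g}{band:>24}{ok:>6}")
        lines.append("=" * 62)
        return "\n".join(lines)


def _evaluate_batch(evaluator, X, n_markers):
    """Run the evaluator on a batch and drop failed points (NaN rows)."""
    f, M = evaluator(np.atleast_2d(np.asarray(X, dtype=float)))
    f = np.asarray(f, dtype=float)
    M = np.atleast_2d(np.asarray(M, dtype=float))
    bad = ~np.isfinite(f) | ~np.all(np.isfinite(M), axis=1)
    if np.any(bad):
        warnings.warn(f"dropping {int(bad.sum())} failed evaluator point(s)")
    return f, M, ~bad


def run_optimization(problem: OptimizationProblem, evaluator,
                     log_dir=None, verbose: bool = False) -> OptimizationResult:
    """Execute the trust-region response-surface loop.

    Parameters
    ----------
    problem : OptimizationProblem
    evaluator : callable
        Batch map ``X (m, n) -> (f (m,), M (m, n_markers))``.  Must be
        deterministic for a fixed point.  Database points are submitted as one
        batch, the candidate as a second, separate batch (parallelizable
        contract).  Failed points may be signalled with NaN rows.
    log_dir : path, optional
        If given, per-iteration database dumps and the iteration log are
        written there as CSV.
    """
    space = problem.space
    cons = problem.constraints
    tr = problem.trust_region

    x = space.clip(problem.start_point())
    delta = tr.delta0
    records: list[IterationRecord] = []
    n_eval = 0
    termination = "max-iter"
    f_x = None
    m_x = None

    for k in range(tr.max_iterations):
        # Step 1: database around the current iterate
        X = full_factorial(space, x, delta, tr.levels, shift_into_bounds=True)
        if np.max(np.abs(X - x), axis=1).min() > 1e-9:
            X = np.vstack([x, X])
        f_vals, M_vals, keep = _evaluate_batch(evaluator, X, cons.n)
        n_eval += len(X)
        if np.max(np.abs(X[keep] - x), axis=1).min() > 1e-9:
            raise EvaluatorError("evaluator failed at the trust-region center")
        db = Database(X[keep], f_vals[keep], M_vals[keep], center=x,
                      half_width=delta, marker_names=cons.names)
        from .surface import n_coefficients
        if len(db) < n_coefficients(space.n):
            raise FittingError(
                f"only {len(db)} valid database points; "
                f"{n_coefficients(space.n)} needed for the quadratic fit")
        ci = db.center_index
        f_x, m_x = db.f_values[ci], db.M_values[ci]

        # Step 2: response surfaces for the objective and every marker
        f_rsa = fit_quadratic_rsa(db.X, db.f_values, center=x, scale=delta)
        m_rsa = [fit_quadratic_rsa(db.X, db.M_values[:, j], center=x, scale=delta)
                 for j in range(cons.n)]
        g_rsa = _band_constraint_surfaces(m_rsa, cons, tr.constraint_margin)

        if log_dir is not None:
            import pathlib
            d = pathlib.Path(log_dir)
            d.mkdir(parents=True, exist_ok=True)
            db.to_frame().to_csv(d / f"database_k{k}.csv", index=False)

        # Step 3: surrogate subproblem
        x_star, lam_g, sub_feasible = solve_trust_subproblem(
            f_rsa, g_rsa, x, delta, space)
        lam = _marker_multipliers(lam_g, cons)

        # Step 4: trust-region test at the candidate
        f_cand, M_cand, keep_c = _evaluate_batch(evaluator, x_star[None, :], cons.n)
        n_eval += 1
        if not keep_c[0]:
            accepted = False
            rho0 = -np.inf
            rho_m = np.full(cons.n, np.nan)
            f_star, m_star = np.nan, np.full(cons.n, np.nan)
            g_star = np.full(cons.n, np.nan)
        else:
            f_star, m_star = float(f_cand[0]), M_cand[0]
            rho0 = trust_ratio(f_x, f_star, f_rsa(x), f_rsa(x_star), tr.ratio_guard)
            # marker ratios use a guard on the constraint-band scale: a
            # change much smaller than the band half-range cannot affect
            # feasibility, so the surrogate is adequate there by definition
            rho_m = np.array([
                trust_ratio(m_x[j], m_star[j], m_rsa[j](x), m_rsa[j](x_star),
                            max(tr.ratio_guard,
                                tr.marker_guard_frac * cons.mRR[j]))
                for j in range(cons.n)])
            g_star = cons.g(m_star)
            accepted = accept_step(rho0, rho_m, g_star, tr.rho_L)

        step = float(np.max(np.abs(x_star - x))) if keep_c[0] else 0.0
        on_boundary = step >= delta - 1e-9
        grad_phi = lagrangian_gradient(f_rsa, m_rsa, lam, x_star)
        gp_norm = float(np.linalg.norm(grad_phi))

        rec = IterationRecord(
            k=k, x_k=x.copy(), x_star=x_star.copy(), delta_k=delta,
            f_k=float(f_x), f_star=float(f_star), m_k=np.asarray(m_x).copy(),
            m_star=np.asarray(m_star).copy(), rho0=float(rho0),
            rho_markers=rho_m, accepted=accepted, lam=lam, g_star=g_star,
            subproblem_feasible=sub_feasible, grad_phi_norm=gp_norm)
        records.append(rec)
        if verbose:
            print(f"[k={k}] delta={delta:.3g} f={f_x:.4g} -> {f_star:.4g} "
                  f"rho0={rho0:.3f} accepted={accepted}")

        # Step 5: radius update
        delta_next = update_radius(delta, accepted, on_boundary, tr.delta_max)

        # Step 6: termination
        done = False
        if accepted:
            x_next, f_x, m_x = x_star, f_star, m_star
            if step < tr.delta1:
                termination, done = "step-size", True
            elif gp_norm < tr.delta2:
                termination, done = "gradient", True
        else:
            x_next = x
        if not done and delta_next < tr.delta3:
            termination, done = "radius", True

        x, delta = x_next, delta_next
        rec.termination = termination if done else ""
        if done:
            break

    result = OptimizationResult(
        problem=problem, x_final=x, termination=termination, records=records,
        f_final=float(f_x), markers_final=np.asarray(m_x, dtype=float),
        n_evaluations=n_eval)
    if log_dir is not None:
        import pathlib
        d = pathlib.Path(log_dir)
        d.mkdir(parents=True, exist_ok=True)
        result.iteration_frame().to_csv(d / "iterations.csv", index=False)
        result.to_json(d / "result.json")
    return result


class ConductanceCalibration:
    """Model-object facade over :func:`run_optimization`.

    Construct from an :class:`OptimizationProblem` (decision conductances,
    marker bands, trust-region settings) and an evaluator; :meth:`fit` runs
    the trust-region loop and returns an :class:`OptimizationResult` with the
    iteration history and a ``summary()`` table.
    """

    def __init__(self, problem: OptimizationProblem, evaluator):
        self.problem = problem
        self.evaluator = evaluator

    @classmethod
    def from_model(cls, model, decision_names, constraints: ConstraintSpec,
                   trust_region: TrustRegionParams | None = None,
                   profile: str = "test", **profile_kw):
        """Build a calibration for an ionic cell model: the evaluator paces
        the model at each candidate conductance set and measures the markers
        and the one-cycle potassium-current integral."""
        from .evaluator import make_model_evaluator
        space = DecisionSpace(
            decision_names,
            [model.params[name] for name in decision_names])
        problem = OptimizationProblem(
            space=space, constraints=constraints,
            trust_region=trust_region or TrustRegionParams())
        evaluator = make_model_evaluator(model, space, constraints,
                                         profile=profile, **profile_kw)
        return cls(problem, evaluator)

    def fit(self, log_dir=None, verbose: bool = False) -> OptimizationResult:
        return run_optimization(self.problem, self.evaluator,
                                log_dir=log_dir, verbose=verbose)
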