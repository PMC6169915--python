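"""Ionic cell-model contract, potassium bookkeeping, and a compact toy
ventricular model.

The contract is deliberately small: a model exposes named states (membrane
potential V in mV first), a parameter dictionary that includes per-current
maximal conductances, the membrane/cytosol constants needed for ion
bookkeeping, and a pure right-hand side ``rhs(t, y, istim)`` returning the
state derivatives together with a :class:`CurrentsRecord` of per-current
densities (pA/pF).

Intracellular potassium obeys

    d[K+]i/dt = -I_K,tot * Cmem / (Vmyo * Frdy)

with ``I_K,tot`` the sum of all potassium-carrying currents plus the stimulus
current (whose charge is assigned to K+, preventing artefactual drift):

    I_K,tot = Ito + IKr + IKs + IK1 - 2*INaK + ICaK + IKp + Istim

The Na/K pump enters with a factor -2 because each pump cycle imports two
potassium ions while the pump current itself is carried by the 3:2 Na:K
exchange.

The toy model is a five-state ventricular caricature (V, an L-type-style
calcium current with instantaneous activation and a slow inactivation gate f,
a delayed-rectifier-style potassium current with activation gate n, an inward
rectifier, a Na/K pump, a plateau potassium current, a lumped calcium
transient and dynamic [K+]i).  It is small enough to brute-force yet expresses
every feature the calibration pipeline needs: action potentials with rate
dependence, a calcium transient, potassium homeostasis, and APD adaptation
with a slow time constant carried by [K+]i.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

__all__ = [
    "CurrentsRecord",
    "IonicModel",
    "ToyVentricularModel",
    "ik_tot",
    "ki_derivative",
    "apply_conductances",
    "RT_OVER_F",
]

# RT/F at 37 C, mV
RT_OVER_F = 26.71

_CURRENT_SLOTS = ("Ito", "IKr", "IKs", "IK1", "INaK", "ICaK", "IKp",
                  "Istim", "ICaL", "Incx", "IClbk")


@dataclass
class CurrentsRecord:
    """Per-current densities in pA/pF; absent currents are zero.

    Fields may be scalars or equally shaped arrays (time series).
    """

    Ito: float | np.ndarray = 0.0
    IKr: float | np.ndarray = 0.0
    IKs: float | np.ndarray = 0.0
    IK1: float | np.ndarray = 0.0
    INaK: float | np.ndarray = 0.0
    ICaK: float | np.ndarray = 0.0
    IKp: float | np.ndarray = 0.0
    Istim: float | np.ndarray = 0.0
    ICaL: float | np.ndarray = 0.0
    Incx: float | np.ndarray = 0.0
    IClbk: float | np.ndarray = 0.0
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dc_fields(self)
             if f.name != "extras"}
        d.update(self.extras)
        return d


def ik_tot(currents: CurrentsRecord):
    """Total potassium-carrying current density including the stimulus."""
    c = currents
    return (c.Ito + c.IKr + c.IKs + c.IK1 - 2.0 * c.INaK + c.ICaK + c.IKp
            + c.Istim)


def ki_derivative(iktot, Cmem, Vmyo, Frdy):
    """d[K+]i/dt in mM/ms; a net outward K current (positive) lowers [K+]i."""
    if Vmyo <= 0 or Frdy <= 0:
        raise ValueError("Vmyo and Frdy must be positive")
    return -np.asarray(iktot) * Cmem / (Vmyo * Frdy)


class IonicModel:
    """Base contract for single-cell ionic models.

    Subclasses define ``state_names``, ``state_units``, ``params``,
    ``initial_state`` and ``rhs``.  ``rhs`` must be a pure function of
    ``(t, y, istim)``.  The extracellular potassium level is the settable
    parameter ``params["Ko"]``.
    """

    state_names: tuple = ()
    state_units: tuple = ()
    # membrane capacitance (pF), cytosol volume, Faraday constant; chosen so
    # that Cmem / (Vmyo * Frdy) is the current-to-concentration factor in
    # mM / ((pA/pF) * ms)
    Cmem: float = 1.0
    Frdy: float = 96485.0

    def __init__(self):
        self.params: dict = {}

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def initial_state(self) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def rhs(self, t, y, istim=0.0):  # pragma: no cover - abstract
        raise NotImplementedError

    def copy(self) -> "IonicModel":
        return copy.deepcopy(self)

    def to_snapshot(self) -> dict:
        """JSON-ready snapshot of states, units, parameters and constants."""
        return {
            "model": type(self).__name__,
            "state_names": list(self.state_names),
            "state_units": list(self.state_units),
            "initial_state": np.asarray(self.initial_state).tolist(),
            "params": {k: float(v) for k, v in self.params.items()},
            "constants": {"Cmem": self.Cmem, "Frdy": self.Frdy,
                          "Vmyo": getattr(self, "Vmyo", None)},
        }

    def with_params(self, **updates) -> "IonicModel":
        """Independent instance with updated parameters."""
        unknown = set(updates) - set(self.params)
        if unknown:
            raise KeyError(
                f"unknown parameter(s) {sorted(unknown)}; "
                f"valid names: {sorted(self.params)}")
        m = self.copy()
        m.params.update(updates)
        return m


def apply_conductances(model: IonicModel, x, space) -> IonicModel:
    """Configure a model copy with conductances ``G0 * 10**(x/20)``.

    ``space`` supplies the conductance names and baselines; every other
    parameter is untouched and the original model is not modified.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (space.n,):
        raise ValueError("x must match the decision-space dimension")
    unknown = [n for n in space.names if n not in model.params]
    if unknown:
        raise KeyError(
            f"conductance(s) {unknown} not in model parameters; "
            f"valid names: {sorted(model.params)}")
    G = space.unscale(x)
    return model.with_params(**dict(zip(space.names, np.atleast_1d(G))))


class ToyVentricularModel(IonicModel):
    """Five-state toy ventricular myocyte.

    States: V (mV), f (Ca-channel inactivation gate), n (K-channel activation
    gate), Cai (mM), Ki (mM).  With ``ki_dynamics=False`` the potassium
    concentration is frozen at ``params["Ki"]`` and the model has four states.

    Gating steady states are Boltzmann curves; the calcium current activates
    instantaneously (d_inf) and inactivates through f; the potassium currents
    share the Nernst driving force V - E_K with E_K = (RT/F) ln(Ko/Ki).

    The default stimulus (-40 pA/pF for 2 ms) and the default initial state
    (the model's own unstimulated resting state) were fixed once from the
    model's dynamics: the stimulus comfortably exceeds the ~-25 mV activation
    threshold of the calcium current, and resting initial conditions keep the
    first paced beats free of startup transients.
    """

    Frdy = 96485.0
    Cmem = 1.0

    DEFAULTS = dict(
        G_Ca=0.18,       # pA/pF per mV of Ca driving force
        G_K=0.12,
        G_K1=0.30,
        G_NaK=0.98424320,
        G_Kp=0.010,
        tau_f=150.0,     # ms
        tau_n=250.0,     # ms
        tau_Ca=60.0,     # ms
        k_conv=1.5e-6,   # mM / ((pA/pF) ms)
        kappa_K=5.0e-4,  # mM / ((pA/pF) ms)
        Ko=5.4,          # mM
        Ca_rest=1e-4,    # mM
        E_Ca=60.0,       # mV
        Ki_half=138.0,   # mM, pump regulation midpoint
        k_pump=20.0,     # mM, pump regulation slope
    )

    # default stimulus (see class docstring)
    stim_amplitude = -40.0  # pA/pF
    stim_duration = 2.0     # ms

    # unstimulated resting state at default parameters (V, f, n, Cai, Ki);
    # V solves I_K1 + I_NaK + I_Kp + I_Ca = 0 with gates at steady state.
    # G_NaK is set so that one paced cycle at CL 1000 ms moves no net
    # potassium (the model's own homeostatic baseline).
    _REST = (-87.3015864, 9.99969065e-01, 3.51541817e-05, 1.00006059e-04,
             138.0)

    def __init__(self, ki_dynamics: bool = True, **param_overrides):
        super().__init__()
        self.ki_dynamics = bool(ki_dynamics)
        self.params = dict(self.DEFAULTS)
        if not self.ki_dynamics:
            self.params["Ki"] = 138.0
        unknown = set(param_overrides) - set(self.params)
        if unknown:
            raise KeyError(f"unknown parameter(s) {sorted(unknown)}")
        self.params.update(param_overrides)

    @property
    def state_names(self):
        base = ("V", "f", "n", "Cai")
        return base + ("Ki",) if self.ki_dynamics else base

    @property
    def state_units(self):
        base = ("mV", "1", "1", "mM")
        return base + ("mM",) if self.ki_dynamics else base

    @property
    def Vmyo(self) -> float:
        # volume consistent with kappa_K = Cmem / (Vmyo * Frdy)
        return self.Cmem / (self.params["kappa_K"] * self.Frdy)

    @property
    def initial_state(self) -> np.ndarray:
        y = np.array(self._REST)
        return y if self.ki_dynamics else y[:4]

    # -- gating steady states -------------------------------------------------
    @staticmethod
    def d_inf(V):
        return 1.0 / (1.0 + np.exp(-(V + 10.0) / 6.0))

    @staticmethod
    def f_inf(V):
        return 1.0 / (1.0 + np.exp((V + 25.0) / 6.0))

    @staticmethod
    def n_inf(V):
        return 1.0 / (1.0 + np.exp(-(V - 5.0) / 9.0))

    @staticmethod
    def k1_inf(V, E_K):
        return 1.0 / (1.0 + np.exp((V - E_K - 12.0) / 12.0))

    def currents(self, V, f, n, Ki, istim=0.0) -> CurrentsRecord:
        """Current densities at the given state (scalars or arrays)."""
        p = self.params
        Ko = p["Ko"]
        if np.any(np.asarray(Ki) <= 0) or Ko <= 0:
            raise ValueError("Nernst potential needs positive Ki and Ko")
        E_K = RT_OVER_F * np.log(Ko / Ki)
        I_Ca = p["G_Ca"] * self.d_inf(V) * f * (V - p["E_Ca"])
        I_K = p["G_K"] * n * (V - E_K)
        I_K1 = p["G_K1"] * self.k1_inf(V, E_K) * (V - E_K)
        # pump regulation by intracellular potassium: a rise in Ki throttles
        # the pump's K import, the restoring mechanism behind the slow APD
        # adaptation time constant
        pump_reg = 1.0 / (1.0 + np.exp((Ki - p["Ki_half"]) / p["k_pump"]))
        I_NaK = (p["G_NaK"] * (Ko / (Ko + 1.5)) * pump_reg
                 / (1.0 + np.exp(-(V + 80.0) / 25.0)))
        I_Kp = p["G_Kp"] * (V - E_K) / (1.0 + np.exp((7.488 - V) / 5.98))
        # slot mapping: the delayed rectifier fills the IKr slot, the L-type
        # calcium current the ICaL slot, so ik_tot applies unchanged
        return CurrentsRecord(IKr=I_K, IK1=I_K1, INaK=I_NaK, IKp=I_Kp,
                              ICaL=I_Ca, Istim=istim)

    def rhs(self, t, y, istim=0.0):
        p = self.params
        if self.ki_dynamics:
            V, f, n, Cai, Ki = y
        else:
            V, f, n, Cai = y
            Ki = p["Ki"]
        c = self.currents(V, f, n, Ki, istim)
        dV = -(c.ICaL + c.IKr + c.IK1 + c.INaK + c.IKp + c.Istim)
        df = (self.f_inf(V) - f) / p["tau_f"]
        dn = (self.n_inf(V) - n) / p["tau_n"]
        dCai = -p["k_conv"] * c.ICaL - (Cai - p["Ca_rest"]) / p["tau_Ca"]
        if self.ki_dynamics:
            dKi = -p["kappa_K"] * ik_tot(c)
            return np.array([dV, df, dn, dCai, dKi]), c
        return np.array([dV, df, dn, dCai]), c

    def resting_state(self, Ki: float | None = None) -> np.ndarray:
        """Unstimulated rest: solve dV/dt = 0 with gates at steady state.

        [K+]i is held at the supplied value (default: the initial one); the
        slow potassium drift at rest is not equilibrated here.
        """
        from scipy.optimize import brentq
        p = self.params
        Ki = float(self.initial_state[-1]) if Ki is None and self.ki_dynamics \
            else (Ki if Ki is not None else p["Ki"])

        def dv(V):
            c = self.currents(V, self.f_inf(V), self.n_inf(V), Ki)
            return -(c.ICaL + c.IKr + c.IK1 + c.INaK + c.IKp)

        V = brentq(dv, -120.0, -60.0, xtol=1e-10)
        Cai = p["Ca_rest"] - p["k_conv"] * p["tau_Ca"] * (
            p["G_Ca"] * self.d_inf(V) * self.f_inf(V) * (V - p["E_Ca"]))
        y = [V, self.f_inf(V), self.n_inf(V), Cai]
        if self.ki_dynamics:
            y.append(Ki)
        return np.array(y)

    def param_vector(self) -> np.ndarray:
        """Packed parameters for the compiled fast-integration kernel."""
        p = self.params
        return np.array([
            p["G_Ca"], p["G_K"], p["G_K1"], p["G_NaK"], p["G_Kp"],
            p["tau_f"], p["tau_n"], p["tau_Ca"], p["k_conv"], p["kappa_K"],
            p["Ko"], p["Ca_rest"], p["E_Ca"], p["Ki_half"], p["k_pump"],
        ])
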