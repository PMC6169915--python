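"""Decision space, constraint bands, trust-region parameters and the sampling
database used to fit response surfaces.

The optimizer samples the true (expensive) evaluator on a full factorial grid
spanning the current trust-region box; the set of sampled points together with
their objective and marker responses is the *database* for one iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scaling import constraint_transform, unscale_conductance

# conductance factor 1/2 .. 2 in dB-like scaled units
DEFAULT_BOUND = 20.0 * np.log10(2.0)  # 6.0206...

__all__ = [
    "DecisionSpace",
    "ConstraintSpec",
    "TrustRegionParams",
    "Database",
    "full_factorial",
    "DEFAULT_BOUND",
]


@dataclass(frozen=True)
class DecisionSpace:
    """Named decision conductances with baselines and scaled-unit box bounds."""

    names: tuple
    G0: np.ndarray
    xL: np.ndarray
    xU: np.ndarray

    def __init__(self, names, G0, xL=None, xU=None):
        names = tuple(names)
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate conductance names: {names}")
        G0 = np.atleast_1d(np.asarray(G0, dtype=float))
        n = len(names)
        if G0.shape != (n,):
            raise ValueError("G0 length must match names")
        if np.any(G0 <= 0):
            raise ValueError("baseline conductances G0 must be positive")
        xL = np.full(n, -DEFAULT_BOUND) if xL is None else np.broadcast_to(
            np.asarray(xL, dtype=float), (n,)).copy()
        xU = np.full(n, DEFAULT_BOUND) if xU is None else np.broadcast_to(
            np.asarray(xU, dtype=float), (n,)).copy()
        if not np.all(xL < xU):
            raise ValueError("require xL < xU elementwise")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "G0", G0)
        object.__setattr__(self, "xL", xL)
        object.__setattr__(self, "xU", xU)

    @property
    def n(self) -> int:
        return len(self.names)

    def unscale(self, x):
        """Scaled point -> natural-unit conductance vector."""
        return unscale_conductance(np.asarray(x, dtype=float), self.G0)

    def clip(self, x):
        return np.clip(np.asarray(x, dtype=float), self.xL, self.xU)


@dataclass(frozen=True)
class ConstraintSpec:
    """Admissible bands for the constrained electrophysiological markers."""

    names: tuple
    mLL: np.ndarray
    mUU: np.ndarray

    def __init__(self, names, mLL, mUU):
        names = tuple(names)
        mLL = np.atleast_1d(np.asarray(mLL, dtype=float))
        mUU = np.atleast_1d(np.asarray(mUU, dtype=float))
        if mLL.shape != (len(names),) or mUU.shape != (len(names),):
            raise ValueError("band arrays must match names")
        if not np.all(mLL < mUU):
            raise ValueError("require mLL < mUU elementwise")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "mLL", mLL)
        object.__setattr__(self, "mUU", mUU)

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def mCR(self) -> np.ndarray:
        """Band centers."""
        return 0.5 * (self.mUU + self.mLL)

    @property
    def mRR(self) -> np.ndarray:
        """Band half-ranges (always positive)."""
        return 0.5 * (self.mUU - self.mLL)

    def g(self, m):
        """Transformed constraint values for a marker vector (or matrix)."""
        return constraint_transform(np.asarray(m, dtype=float), self.mCR, self.mRR)


@dataclass(frozen=True)
class TrustRegionParams:
    """Tunables of the trust-region loop.

    delta0/delta_max are in scaled conductance units; rho_L is the half-width
    of the acceptance band around 1 for the constraint trust ratios; delta1,
    delta2, delta3 are the step-size, Lagrangian-gradient and radius
    termination tolerances.
    """

    delta0: float = 2.0
    delta_max: float = 6.0
    rho_L: float = 0.25
    delta1: float = 1e-3
    delta2: float = 1e-3
    delta3: float = 1e-3
    max_iterations: int = 20
    levels: int = 3
    ratio_guard: float = 1e-12
    # marker trust ratios are only meaningful for changes that matter on the
    # constraint scale: changes below this fraction of a band half-range are
    # treated as surrogate-adequate (ratio 1)
    marker_guard_frac: float = 0.1
    # interior safety margin on the surrogate band constraints (fraction of
    # a band half-range): candidates target the slightly shrunken band so
    # that surrogate error does not strand the iterate marginally outside
    # the true band
    constraint_margin: float = 0.01

    def __post_init__(self):
        if not (0 < self.delta0 <= self.delta_max):
            raise ValueError("require 0 < delta0 <= delta_max")
        if not (0 < self.rho_L < 1):
            raise ValueError("require 0 < rho_L < 1")
        if min(self.delta1, self.delta2, self.delta3) <= 0:
            raise ValueError("termination tolerances must be positive")
        if self.levels < 2:
            raise ValueError("factorial design needs >= 2 levels per axis")


def full_factorial(space: DecisionSpace, center, half_width: float,
                   levels: int = 3, shift_into_bounds: bool = False) -> np.ndarray:
    """Full factorial sample of the trust-region box.

    Returns ``levels**n`` points: the Cartesian product of `levels` equally
    spaced values per axis spanning ``center_i +/- half_width``, clipped to the
    global bounds.  With odd `levels` the center itself is one of the points.

    With ``shift_into_bounds=True`` the sampling box is translated (not
    shrunk) so that it lies inside the global bounds whenever it fits; this
    keeps three distinct levels per axis when the iterate sits near a bound,
    which the quadratic fit needs.
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    center = np.broadcast_to(np.asarray(center, dtype=float), (space.n,)).copy()
    lo = center - half_width
    hi = center + half_width
    if shift_into_bounds:
        shift = np.maximum(space.xL - lo, 0.0) - np.maximum(hi - space.xU, 0.0)
        lo = lo + shift
        hi = hi + shift
    axes = [
        np.clip(np.linspace(lo[i], hi[i], levels), space.xL[i], space.xU[i])
        for i in range(space.n)
    ]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=1)


@dataclass
class Database:
    """Sampled evaluator responses for one trust-region iteration."""

    X: np.ndarray
    f_values: np.ndarray
    M_values: np.ndarray
    center: np.ndarray
    half_width: float
    marker_names: tuple = field(default_factory=tuple)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.f_values = np.asarray(self.f_values, dtype=float)
        self.M_values = np.atleast_2d(np.asarray(self.M_values, dtype=float))
        self.center = np.asarray(self.center, dtype=float)
        if not (len(self.X) == len(self.f_values) == len(self.M_values)):
            raise ValueError("X, f_values and M_values must have equal row counts")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def center_index(self) -> int:
        d = np.max(np.abs(self.X - self.center), axis=1)
        i = int(np.argmin(d))
        if d[i] > 1e-9:
            raise ValueError("database does not contain its center point")
        return i

    def to_frame(self) -> pd.DataFrame:
        """Flat table (one row per sample) for CSV audit dumps."""
        cols = {f"x{i}": self.X[:, i] for i in range(self.X.shape[1])}
        cols["f"] = self.f_values
        names = self.marker_names or [f"m{j}" for j in range(self.M_values.shape[1])]
        for j, name in enumerate(names):
            cols[str(name)] = self.M_values[:, j]
        return pd.DataFrame(cols)
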