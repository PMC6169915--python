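"""One-at-a-time conductance sensitivity analysis.

Each conductance is perturbed by +/-a (default 30%) one at a time; for every
property m the percent change relative to control and the centered
sensitivity

    D = (M_perturbed - M_control) / M_control * 100
    S = (D_plus - D_minus) / (2 a)        [a expressed in percent]

are tabulated.  Under this convention a property scaling proportionally with
the conductance (unit elasticity) gives S = 100%.  An alternative literal
scaling carrying an extra factor of 100 is available as
``convention="literal"`` for auditing; the two differ only by that constant
factor.

The matrix supports the heatmap-style per-column normalization (each column
scaled by its maximum absolute sensitivity) and a mechanical
decision-variable selection rule: rank by |S| on the objective, excluding any
conductance that uniquely dominates some marker that no other candidate can
compensate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "percent_change",
    "sensitivity",
    "run_sensitivity",
    "select_decision_variables",
    "SensitivityMatrix",
    "plot_sensitivity",
]


def percent_change(M_pa, M_control):
    """Percent change of a property value relative to control; NaN (undefined
    sensitivity) when the control value is zero."""
    M_pa = np.asarray(M_pa, dtype=float)
    M_control = np.asarray(M_control, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        D = (M_pa - M_control) / M_control * 100.0
    D = np.where(M_control == 0, np.nan, D)
    return D.item() if D.ndim == 0 else D


def sensitivity(D_plus, D_minus, a, convention: str = "elasticity"):
    """Centered sensitivity from the +a and -a percent changes.

    With ``convention="elasticity"`` (default) a is converted to percent so
    that unit elasticity yields S = 100; ``"literal"`` keeps the extra factor
    of 100 (unit elasticity yields S = 10,000).
    """
    if a <= 0:
        raise ValueError("perturbation fraction a must be positive")
    D_plus = np.asarray(D_plus, dtype=float)
    D_minus = np.asarray(D_minus, dtype=float)
    S = (D_plus - D_minus) / (2.0 * a)
    if convention == "literal":
        S = S * 100.0
    elif convention != "elasticity":
        raise ValueError("convention must be 'elasticity' or 'literal'")
    return S.item() if S.ndim == 0 else S


@dataclass
class SensitivityMatrix:
    """D and S tables (rows = conductances, columns = properties)."""

    D_plus: pd.DataFrame
    D_minus: pd.DataFrame
    S: pd.DataFrame
    M_control: pd.Series
    a: float
    convention: str = "elasticity"

    @property
    def conductances(self):
        return list(self.S.index)

    @property
    def properties(self):
        return list(self.S.columns)

    def normalized(self) -> pd.DataFrame:
        """Per-column relative magnitude in [0, 1]: |S| scaled by the column
        maximum, the (first) maximal entry pinned to exactly 1."""
        A = self.S.abs()
        out = pd.DataFrame(0.0, index=A.index, columns=A.columns)
        for col in A.columns:
            m = A[col].max(skipna=True)
            if not np.isfinite(m) or m == 0:
                continue
            v = (A[col] / m).to_numpy()
            top = int(np.nanargmax(v))
            v = np.minimum(v, 1.0 - 1e-12)
            v[top] = 1.0
            out[col] = v
        return out

    def to_csv(self, path):
        self.S.to_csv(path)


def run_sensitivity(model, conductances, marker_fn, a: float = 0.3,
                    convention: str = "elasticity") -> SensitivityMatrix:
    """One-at-a-time scan: 2 * n_conductances + 1 full marker evaluations.

    ``marker_fn(model) -> dict`` maps a configured model to property values
    (e.g. :func:`iontune.evaluator.measure_markers` adapted to a dict).  A
    failing perturbed run marks its row entries NaN and the scan proceeds.
    """
    control = marker_fn(model)
    props = list(control)
    ctrl = pd.Series(control, dtype=float)

    def perturbed(name, factor):
        try:
            m = model.with_params(**{name: model.params[name] * factor})
            return marker_fn(m)
        except Exception as exc:
            warnings.warn(f"sensitivity run failed for {name} x{factor}: {exc}")
            return {p: np.nan for p in props}

    Dp, Dm = {}, {}
    for name in conductances:
        up = perturbed(name, 1.0 + a)
        dn = perturbed(name, 1.0 - a)
        Dp[name] = {p: percent_change(up[p], ctrl[p]) for p in props}
        Dm[name] = {p: percent_change(dn[p], ctrl[p]) for p in props}
    D_plus = pd.DataFrame(Dp).T.reindex(columns=props)
    D_minus = pd.DataFrame(Dm).T.reindex(columns=props)
    S = pd.DataFrame(
        sensitivity(D_plus.to_numpy(), D_minus.to_numpy(), a, convention),
        index=D_plus.index, columns=D_plus.columns)
    return SensitivityMatrix(D_plus=D_plus, D_minus=D_minus, S=S,
                             M_control=ctrl, a=a, convention=convention)


def select_decision_variables(matrix: SensitivityMatrix,
                              objective: str = "iktot_integral",
                              k: int | None = None,
                              dominance_threshold: float = 50.0,
                              compensation_threshold: float = 20.0):
    """Rank conductances by |S| on the objective; exclude dominators.

    A conductance is excluded when it dominates some marker — |S| above the
    dominance threshold — that no other candidate influences above the
    compensation threshold: calibrating with it would distort that marker
    with no way to counterbalance.

    Returns ``(selected, exclusions)`` where ``exclusions`` maps an excluded
    conductance to the marker it uniquely dominates.
    """
    if objective not in matrix.S.columns:
        raise KeyError(f"objective column {objective!r} missing from matrix")
    S = matrix.S.abs()
    ranking = S[objective].sort_values(ascending=False)
    if not np.any(S.to_numpy() > 0):
        warnings.warn("all-zero sensitivity matrix; nothing to select")
        return [], {}
    markers = [c for c in matrix.S.columns if c != objective]
    exclusions = {}
    for p in matrix.conductances:
        for m in markers:
            if S.loc[p, m] > dominance_threshold:
                others = S.loc[[q for q in matrix.conductances if q != p], m]
                if np.all(others.fillna(0.0) < compensation_threshold):
                    exclusions[p] = m
                    break
    selected = [p for p in ranking.index if p not in exclusions]
    if k is not None:
        selected = selected[:k]
    return selected, exclusions


def plot_sensitivity(matrix: SensitivityMatrix, ax=None):
    """Heatmap of the per-column normalized sensitivities with absolute
    percentages annotated (light = maximal relative sensitivity)."""
    import matplotlib.pyplot as plt
    norm = matrix.normalized()
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(norm.columns),
                                      0.5 * len(norm.index) + 1.5))
    im = ax.imshow(norm.to_numpy(), cmap="Blues_r", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(len(norm.columns)), norm.columns, rotation=45,
                  ha="right")
    ax.set_yticks(range(len(norm.index)), norm.index)
    for i, p in enumerate(norm.index):
        for j, c in enumerate(norm.columns):
            s = matrix.S.loc[p, c]
            if np.isfinite(s) and norm.iloc[i, j] > 0.5:
                ax.text(j, i, f"{s:+.1f}%", ha="center", va="center",
                        fontsize=7)
    ax.figure.colorbar(im, ax=ax, label="relative |S|")
    return ax
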