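"""Conductance scaling and marker-band constraint transform.

Decision variables are carried in a logarithmic, dB-like scale so that
conductances differing by orders of magnitude optimize on comparable axes:

    x = 20 * log10(G / G0)

where ``G0`` is the baseline conductance.  A factor-of-two change in a
conductance is therefore ~6.0206 scaled units in either direction.

Marker band constraints ``mLL <= m <= mUU`` are folded into the canonical
inequality form

    g = |m - mCR| / mRR - 1 <= 0

with ``mCR = (mUU + mLL) / 2`` the band center and ``mRR = (mUU - mLL) / 2``
the half-range: g is -1 at the band center, 0 on either edge, and positive
outside.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "scale_conductance",
    "unscale_conductance",
    "constraint_transform",
]


def scale_conductance(G, G0):
    """Map a conductance to its dimensionless dB-like decision variable.

    Parameters
    ----------
    G : float or array_like
        Conductance value(s), model units. Must be positive.
    G0 : float or array_like
        Baseline conductance(s). Must be positive.

    Returns
    -------
    x : float or ndarray
        ``20 * log10(G / G0)``.
    """
    G = np.asarray(G, dtype=float)
    G0 = np.asarray(G0, dtype=float)
    if np.any(G <= 0) or np.any(G0 <= 0):
        raise ValueError("scale_conductance requires positive G and G0")
    out = 20.0 * np.log10(G / G0)
    return out.item() if out.ndim == 0 else out


def unscale_conductance(x, G0):
    """Inverse of :func:`scale_conductance`: ``G = G0 * 10**(x/20)``."""
    x = np.asarray(x, dtype=float)
    G0 = np.asarray(G0, dtype=float)
    if np.any(G0 <= 0):
        raise ValueError("unscale_conductance requires positive G0")
    out = G0 * 10.0 ** (x / 20.0)
    return out.item() if out.ndim == 0 else out


def constraint_transform(m, m_cr, m_rr):
    """Fold a marker value into the canonical inequality ``g <= 0``.

    ``g = |m - m_cr| / m_rr - 1``; non-positive exactly when ``m`` lies inside
    the band ``[m_cr - m_rr, m_cr + m_rr]``.
    """
    m = np.asarray(m, dtype=float)
    m_cr = np.asarray(m_cr, dtype=float)
    m_rr = np.asarray(m_rr, dtype=float)
    if np.any(m_rr <= 0):
        raise ValueError("constraint_transform requires a positive half-range m_rr")
    out = np.abs(m - m_cr) / m_rr - 1.0
    return out.item() if out.ndim == 0 else out
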