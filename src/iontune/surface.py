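"""Full second-order polynomial response surfaces.

A surface over n variables carries 1 + n + n + n(n-1)/2 coefficients
(intercept, linear, pure quadratic, pairwise cross terms).  For conditioning,
regressors are centered on the database center and divided by the trust-region
half-width before ordinary least squares; the affine map is stored with the
coefficients so surfaces evaluate in original coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResponseSurface", "fit_quadratic_rsa", "FittingError", "n_coefficients"]


class FittingError(ValueError):
    """Raised when the design cannot identify the quadratic basis."""


def n_coefficients(n: int) -> int:
    return 1 + 2 * n + n * (n - 1) // 2


def basis_names(n: int):
    names = ["1"]
    names += [f"z{i}" for i in range(n)]
    names += [f"z{i}^2" for i in range(n)]
    names += [f"z{i}*z{j}" for i in range(n) for j in range(i + 1, n)]
    return names


def _design_matrix(Z: np.ndarray) -> np.ndarray:
    n = Z.shape[1]
    cols = [np.ones(len(Z))]
    cols += [Z[:, i] for i in range(n)]
    cols += [Z[:, i] ** 2 for i in range(n)]
    cols += [Z[:, i] * Z[:, j] for i in range(n) for j in range(i + 1, n)]
    return np.stack(cols, axis=1)


@dataclass(frozen=True)
class ResponseSurface:
    """Quadratic surrogate of one scalar response.

    Evaluation, analytic gradient and Hessian are exact polynomial algebra in
    the conditioned coordinates ``z = (x - center) / scale``.
    """

    coef: np.ndarray          # ordered: intercept, linear, pure quad, cross (i<j)
    center: np.ndarray
    scale: float
    n: int

    def _split(self):
        n = self.n
        c0 = self.coef[0]
        a = self.coef[1:1 + n]
        b = self.coef[1 + n:1 + 2 * n]
        c = self.coef[1 + 2 * n:]
        return c0, a, b, c

    def _z(self, x):
        return (np.asarray(x, dtype=float) - self.center) / self.scale

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float((_design_matrix(self._z(x)[None, :]) @ self.coef)[0])
        Z = (x - self.center) / self.scale
        return _design_matrix(Z) @ self.coef

    def gradient(self, x) -> np.ndarray:
        """Analytic gradient with respect to the original coordinates."""
        n = self.n
        z = self._z(np.asarray(x, dtype=float))
        _, a, b, c = self._split()
        g = a + 2.0 * b * z
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                g[i] += c[k] * z[j]
                g[j] += c[k] * z[i]
                k += 1
        return g / self.scale

    def hessian(self) -> np.ndarray:
        """Constant Hessian in original coordinates."""
        n = self.n
        _, _, b, c = self._split()
        H = np.diag(2.0 * b)
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                H[i, j] = H[j, i] = c[k]
                k += 1
        return H / self.scale ** 2

    def affine(self, a: float, b: float = 0.0) -> "ResponseSurface":
        """Surface for ``a * self(x) + b`` (same basis and conditioning)."""
        coef = self.coef * a
        coef = coef.copy()
        coef[0] += b
        return ResponseSurface(coef=coef, center=self.center, scale=self.scale, n=self.n)


def fit_quadratic_rsa(X, y, center=None, scale=None) -> ResponseSurface:
    """Ordinary least-squares fit of the full quadratic basis.

    Parameters
    ----------
    X : (m, n) array
        Sample points (database rows).
    y : (m,) array
        Responses at the samples.
    center, scale : optional
        Conditioning map; defaults to the column means of ``X`` and the
        largest half-extent of the samples (1.0 for a degenerate cloud).

    Raises
    ------
    FittingError
        If the design matrix is rank-deficient; the message names the
        unidentifiable basis terms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    m, n = X.shape
    p = n_coefficients(n)
    if len(y) != m:
        raise ValueError("X and y must have matching lengths")
    if m < p:
        raise FittingError(
            f"need at least {p} samples to fit a quadratic in {n} variables, got {m}")
    center = X.mean(axis=0) if center is None else np.asarray(center, dtype=float)
    if scale is None:
        scale = float(np.max(np.abs(X - center)))
        if scale <= 0:
            scale = 1.0
    Z = (X - center) / scale
    A = _design_matrix(Z)
    rank = np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(A).max()))
    if rank < p:
        # name the basis terms implicated in the null space
        _, s, Vt = np.linalg.svd(A, full_matrices=True)
        null = Vt[rank:]
        bad = sorted({basis_names(n)[j]
                      for row in null for j in np.nonzero(np.abs(row) > 0.3)[0]})
        raise FittingError(
            f"rank-deficient quadratic design (rank {rank} < {p}); "
            f"unidentifiable terms: {', '.join(bad)}")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return ResponseSurface(coef=coef, center=center, scale=scale, n=n)
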