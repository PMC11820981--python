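"""Per-spectrum denoising and baseline removal.

Each row of an MCC-IMS map is one drift spectrum.  High-frequency noise is
removed with a Savitzky–Golay filter (local polynomial least squares, which
preserves peak position and height up to the polynomial order).  The slowly
varying background — dominated by detector drift and the tail of the
reactant-ion peak — is then estimated by asymmetric least squares (AsLS):
the baseline ``b`` minimises

    S(b) = sum_i w_i (y_i - b_i)^2 + lam * sum_i (Delta^2 b_i)^2

where ``Delta^2`` is the second finite difference and the weights switch
asymmetrically, ``w_i = p`` where ``y_i > b_i`` and ``1 - p`` where
``y_i < b_i``.  With ``p`` small the baseline is pushed underneath the
peaks; ``p = 0.5`` recovers an ordinary (symmetric) penalised fit.  The
defaults ``lam = 1e5``, ``p = 5e-3`` suit drift spectra of a few thousand
points with peaks a few hundred points wide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .errors import ParameterError
from .io import IMSMap

__all__ = [
    "SGParams",
    "AsLSParams",
    "BaselineFit",
    "sg_smooth",
    "asls_baseline",
    "asls_solve",
    "correct_map",
]


@dataclass(frozen=True)
class SGParams:
    """Savitzky–Golay settings: polynomial order and odd window length."""

    poly_order: int = 2
    window: int = 9

    def validate(self, n: int | None = None) -> None:
        if self.window % 2 != 1:
            raise ParameterError("SG window must be odd")
        if self.window <= self.poly_order:
            raise ParameterError("SG window must exceed the polynomial order")
        if n is not None and self.window > n:
            raise ParameterError(
                f"SG window {self.window} exceeds spectrum length {n}"
            )


@dataclass(frozen=True)
class AsLSParams:
    """AsLS settings.

    ``w_tol`` is a relative L1 threshold on the weight-vector change for
    early stopping; the default 0.0 demands exactly unchanged weights,
    which the discrete weight update reaches quickly in practice.
    """

    lam: float = 1e5
    p: float = 5e-3
    max_iter: int = 10
    w_tol: float = 0.0

    def validate(self) -> None:
        if not self.lam > 0:
            raise ParameterError("lam must be positive")
        if not 0.0 < self.p < 1.0:
            raise ParameterError("p must lie strictly between 0 and 1")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be at least 1")


@dataclass
class BaselineFit:
    """Result of one AsLS run on a single spectrum."""

    baseline: np.ndarray
    weights: np.ndarray
    n_iter: int
    converged: bool


def _sg_edge_fit(y: np.ndarray, params: SGParams, out: np.ndarray) -> None:
    # Shrink-window fit: at each edge point refit the same-order polynomial
    # on the part of the centred window that lies inside the record.
    half = params.window // 2
    n = y.size
    for i in range(half):
        for idx in (i, n - 1 - i):
            lo = max(0, idx - half)
            hi = min(n, idx + half + 1)
            t = np.arange(lo, hi) - idx
            coeffs = np.polynomial.polynomial.polyfit(t, y[lo:hi],
                                                      params.poly_order)
            out[idx] = coeffs[0]


def sg_smooth(y: np.ndarray, params: SGParams = SGParams()) -> np.ndarray:
    """Smooth one spectrum with a Savitzky–Golay filter.

    Interior points use the standard centred window; the first and last
    ``(window-1)/2`` points are refit on the truncated window so the output
    keeps the input length without mirroring artefacts.  Polynomials of
    degree ``<= poly_order`` pass through unchanged on interior points.
    """
    y = np.asarray(y, dtype=float)
    params.validate(n=y.size)
    out = savgol_filter(y, params.window, params.poly_order, mode="interp")
    _sg_edge_fit(y, params, out)
    return out


def _penalty_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (3 diagonals) of lam * D'D, D the (n-2) x n
    second-difference operator."""
    d0 = np.zeros(n)
    d1 = np.zeros(n)
    d2 = np.zeros(n)
    # D'D row pattern for the second-difference penalty
    d0[:] = 6.0
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1[:] = -4.0
    d1[[1, -1]] = -2.0
    d2[:] = 1.0
    ab = np.zeros((3, n))
    ab[0, 2:] = lam * d2[2:]
    ab[1, 1:] = lam * d1[1:]
    ab[2, :] = lam * d0
    return ab


def asls_solve(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve the penalised weighted least-squares system
    ``(W + lam D'D) b = W y`` for fixed weights, using a symmetric banded
    Cholesky solve (the system is pentadiagonal and positive definite)."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = y.size
    if n < 3:
        raise ParameterError("spectrum must have at least 3 points")
    ab = _penalty_banded(n, lam)
    ab = ab.copy()
    ab[2, :] += w
    return solveh_banded(ab, w * y, lower=False)


def asls_baseline(y: np.ndarray,
                  params: AsLSParams = AsLSParams()) -> BaselineFit:
    """Estimate the baseline of one spectrum by asymmetric least squares.

    Starting from uniform weights, alternate a penalised weighted
    least-squares solve with the asymmetric weight update (``p`` above the
    baseline, ``1 - p`` below, ties assigned ``p``) until the weights stop
    changing or ``max_iter`` passes have run.
    """
    params.validate()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ParameterError("spectrum contains non-finite values")
    n = y.size
    if n < 3:
        raise ParameterError("spectrum must have at least 3 points")

    ab0 = _penalty_banded(n, params.lam)
    w = np.ones(n)
    b = y.copy()
    converged = False
    n_iter = 0
    w_new = w
    for n_iter in range(1, params.max_iter + 1):
        ab = ab0.copy()
        ab[2, :] += w
        b = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > b, params.p, 1.0 - params.p)
        w_new[y == b] = params.p
        delta = np.abs(w_new - w).sum()
        if delta == 0.0 or (params.w_tol > 0
                            and delta <= params.w_tol * np.abs(w).sum()):
            converged = True
            w = w_new
            break
        w = w_new
    return BaselineFit(baseline=b, weights=w_new, n_iter=n_iter,
                       converged=converged)


def asls_cost(y: np.ndarray, b: np.ndarray, w: np.ndarray,
              lam: float) -> float:
    """Evaluate the AsLS objective S(b) at given weights (diagnostics)."""
    y = np.asarray(y, dtype=float)
    b = np.asarray(b, dtype=float)
    resid = float(np.sum(w * (y - b) ** 2))
    d2 = np.diff(b, n=2)
    return resid + lam * float(np.sum(d2**2))


def correct_map(m: IMSMap, sg: SGParams | None = SGParams(),
                asls: AsLSParams | None = AsLSParams()) -> IMSMap:
    """Denoise and baseline-correct every drift spectrum of a map.

    Each row is Savitzky–Golay smoothed, then its AsLS baseline is
    subtracted.  Either stage can be disabled by passing ``None`` (used by
    the preprocessing-ablation experiments).  Axes are untouched.
    """
    out = m.intensity.copy()
    for r in range(out.shape[0]):
        try:
            row = out[r]
            if sg is not None:
                row = sg_smooth(row, sg)
            if asls is not None:
                fit = asls_baseline(row, asls)
                row = row - fit.baseline
            out[r] = row
        except ParameterError as exc:
            raise ParameterError(
                f"retention row {r} (t = {m.retention_time[r]:g} s): {exc}"
            ) from exc
    return m.replace(intensity=out)
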