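"""Genomic breeding-value prediction.

Two routes to a GEBV:

* solve Henderson's mixed model equations with a marker-derived
  relationship matrix (GBLUP when the matrix is G, TABLUP when it is a
  trait-specific TA matrix) -- candidates without records are carried
  by the inverse-relationship block alone;
* direct summation Z @ g_hat of estimated marker effects over an
  individual's genotypes (RRBLUP, BayesB).

The MME

    [ 1'1   1'W            ] [b]   [1'y]
    [ W'1   W'W + G^-1 l   ] [u] = [W'y],      l = sigma_e2 / sigma_a2

are solved by Gauss-Seidel iteration on the explicitly (LU) inverted
relationship matrix, converging when the largest absolute update drops
below ``tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from numba import njit

from .effects import MarkerEffects, VarianceComponents
from .relmat import RelationshipMatrix

__all__ = ["MMEProblem", "GEBVResult", "solve_mme_gauss_seidel", "gebv_from_effects"]


@dataclass
class MMEProblem:
    """One mixed-model prediction problem.

    ``record_individuals[r]`` maps record ``r`` of ``y`` to a row of
    the relationship matrix; individuals absent from it are candidates
    and receive predictions through the relationship structure only.
    """

    y: np.ndarray
    record_individuals: np.ndarray
    relationship: RelationshipMatrix
    vc: VarianceComponents

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.record_individuals = np.asarray(self.record_individuals, dtype=np.int64)
        if self.y.shape != self.record_individuals.shape:
            raise ValueError("y and record_individuals must align")
        if self.y.size == 0:
            raise ValueError("no phenotypic records")
        m = self.relationship.n
        if self.record_individuals.min() < 0 or self.record_individuals.max() >= m:
            raise ValueError("record refers to an individual outside the matrix")
        if self.vc.sigma_a2 <= 0:
            raise ValueError("sigma_a2 must be positive (lambda undefined)")


@dataclass
class GEBVResult:
    gebv: np.ndarray
    method: str
    mu: float = np.nan
    converged: bool = True
    n_iter: int = 0
    max_update: float = 0.0


@njit(cache=True)
def _gauss_seidel(A, b, x, tol, max_iter):
    m = A.shape[0]
    it = 0
    delta = 0.0
    for it in range(1, max_iter + 1):
        delta = 0.0
        for i in range(m):
            s = b[i]
            row = A[i]
            for j in range(m):
                s -= row[j] * x[j]
            s += row[i] * x[i]
            xi = s / row[i]
            d = abs(xi - x[i])
            if d > delta:
                delta = d
            x[i] = xi
        if delta < tol:
            return it, delta, True
    return it, delta, False


def _invert_relationship(G: np.ndarray, scheme: str, psd_floor: float) -> np.ndarray:
    """Numerical inverse of the relationship matrix, with a PSD repair.

    Mean-IBS-corrected matrices subtract a rank-one baseline
    (S_bar * 11') from a PSD similarity matrix, so they carry at most
    one negative eigenvalue, aligned mostly with the all-ones vector
    -- a direction the MME intercept absorbs anyway. When a Cholesky
    factorisation fails, eigenvalues below ``psd_floor * max_eig`` are
    clamped to that floor before inverting, which is equivalent to
    shrinking the breeding-value component along the offending
    direction to zero. Predictions in the well-conditioned subspace
    are unchanged (verified against the inverse-free BLUP form).
    """
    try:
        c, low = scipy.linalg.cho_factor(G)
        return scipy.linalg.cho_solve((c, low), np.eye(G.shape[0]))
    except scipy.linalg.LinAlgError:
        pass
    w, V = scipy.linalg.eigh(G)
    if w[-1] <= 0:
        raise np.linalg.LinAlgError(
            f"relationship matrix (scheme {scheme!r}) is negative "
            "semi-definite; cannot be used as a covariance structure"
        )
    delta = psd_floor * w[-1]
    w = np.maximum(w, delta)
    return (V / w) @ V.T


def solve_mme_gauss_seidel(
    problem: MMEProblem,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    psd_floor: float = 1e-4,
) -> tuple[GEBVResult, float]:
    """Solve the MME by Gauss-Seidel; returns (result, fixed-effect).

    The relationship matrix is inverted numerically (see
    :func:`_invert_relationship` for the rank-one PSD repair applied to
    mean-corrected matrices). A singular matrix raises with the scheme
    name and an estimated condition number. Non-convergence is reported
    via a warning and the ``converged`` flag, together with the last
    maximum update.
    """
    G = problem.relationship.values
    try:
        Ginv = _invert_relationship(G, problem.relationship.scheme, psd_floor)
    except np.linalg.LinAlgError:
        raise
    except scipy.linalg.LinAlgError as err:
        cond = np.linalg.cond(G)
        raise np.linalg.LinAlgError(
            f"relationship matrix (scheme {problem.relationship.scheme!r}) is "
            f"singular; condition number ~{cond:.3g}. A small --jitter ridge "
            "may help with very small marker panels."
        ) from err
    m = G.shape[0]
    lam = problem.vc.sigma_e2 / problem.vc.sigma_a2
    counts = np.bincount(problem.record_individuals, minlength=m).astype(float)
    ysum = np.bincount(
        problem.record_individuals, weights=problem.y, minlength=m
    )

    A = np.empty((m + 1, m + 1))
    A[1:, 1:] = lam * Ginv
    idx = np.diag_indices(m)
    A[1:, 1:][idx] += counts
    A[0, 0] = float(problem.y.size)
    A[0, 1:] = counts
    A[1:, 0] = counts
    b = np.concatenate([[problem.y.sum()], ysum])

    if np.any(np.diag(A) <= 0):
        raise np.linalg.LinAlgError(
            "non-positive diagonal in the MME; Gauss-Seidel cannot proceed "
            f"(scheme {problem.relationship.scheme!r})"
        )
    x = np.zeros(m + 1)
    n_iter, delta, ok = _gauss_seidel(A, b, x, tol, max_iter)
    if not ok:
        warnings.warn(
            f"Gauss-Seidel did not converge in {max_iter} iterations "
            f"(last max update {delta:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
    result = GEBVResult(
        gebv=x[1:],
        method=problem.relationship.scheme,
        mu=float(x[0]),
        converged=ok,
        n_iter=n_iter,
        max_update=float(delta),
    )
    return result, float(x[0])


def gebv_from_effects(genotypes: np.ndarray, effects: MarkerEffects) -> GEBVResult:
    """Direct-summation GEBV: Z @ g_hat over -1/0/1 genotypes."""
    Z = np.asarray(genotypes)
    if Z.ndim != 2 or Z.shape[1] != len(effects.g_hat):
        raise ValueError(
            f"genotype matrix has {Z.shape[-1] if Z.ndim == 2 else '?'} markers "
            f"but effects have {len(effects.g_hat)}"
        )
    return GEBVResult(gebv=Z.astype(float) @ effects.g_hat, method=effects.method)
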