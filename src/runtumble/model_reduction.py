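"""Bayesian model reduction over the product-of-Dirichlets transition prior.

Given the prior counts ``alpha`` accumulated into posterior counts
``phi_alpha``, the change in variational free energy (log model evidence)
incurred by swapping the prior for a *reduced* prior ``alpha'`` can be
evaluated analytically, without refitting:

    delta_F = ln B(phi_alpha) + ln B(alpha') - ln B(alpha)
              - ln B(phi_alpha + alpha' - alpha)

where B is the multivariate beta function. The transition prior is a
product of independent Dirichlets (one per action and previous-state
column), so delta_F is evaluated per column and summed. A positive delta_F
means the reduced model has *less* evidence than the full model; a
parameter is pruned when removing it increases the evidence, i.e. when
delta_F < 0 (ties are not pruned).

"Removing" a prior count means shrinking it to a small epsilon rather than
exactly zero, since ln B diverges at zero counts. The limit is finite
exactly when the pruned entry accrued no posterior count beyond its prior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = ["ReductionResult", "log_beta", "delta_F", "prune_scan", "EPS_PRUNE"]

#: reduced-prior count standing in for an exact zero
EPS_PRUNE = 1e-6


@dataclass
class ReductionResult:
    """Outcome of reducing a single transition-prior count to (near) zero."""

    control: int
    next_state: int
    prev_state: int
    delta_F: float
    pruned: bool


def log_beta(counts: np.ndarray) -> float:
    """Multivariate log-beta of a positive count vector."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("log_beta requires strictly positive counts")
    return float(gammaln(counts).sum() - gammaln(counts.sum()))


def _column_delta_F(
    alpha_col: np.ndarray, phi_col: np.ndarray, reduced_col: np.ndarray
) -> float:
    # associate as reduced + accrual so that a no-learning block (phi ==
    # alpha) cancels bitwise and delta_F is exactly zero, not gammaln noise
    merged = reduced_col + (phi_col - alpha_col)
    if np.any(merged <= 0):
        raise ValueError("phi_alpha + alpha' - alpha must stay strictly positive")
    # pair the differences so both vanish exactly when phi == alpha
    return (log_beta(phi_col) - log_beta(alpha_col)) + (
        log_beta(reduced_col) - log_beta(merged)
    )


def delta_F(alpha: np.ndarray, phi_alpha: np.ndarray, alpha_reduced: np.ndarray) -> float:
    """Evidence change of a reduced Dirichlet prior, summed over columns.

    All three count arrays share the shape ``[u][i, j]`` (or any 2-D/1-D
    shape, treated as a single block per trailing column). Columns whose
    reduced prior equals the full prior contribute exactly zero.
    """
    alpha = np.asarray(alpha, dtype=float)
    phi_alpha = np.asarray(phi_alpha, dtype=float)
    alpha_reduced = np.asarray(alpha_reduced, dtype=float)
    if not (alpha.shape == phi_alpha.shape == alpha_reduced.shape):
        raise ValueError("count arrays must be conformable")
    if alpha.ndim == 1:
        return _column_delta_F(alpha, phi_alpha, alpha_reduced)
    # blocks are the columns of each trailing 2-D matrix
    n, m = alpha.shape[-2:]
    cols = np.moveaxis(alpha.reshape(-1, n, m), 1, 2).reshape(-1, n)
    phis = np.moveaxis(phi_alpha.reshape(-1, n, m), 1, 2).reshape(-1, n)
    reds = np.moveaxis(alpha_reduced.reshape(-1, n, m), 1, 2).reshape(-1, n)
    total = 0.0
    for a_col, p_col, r_col in zip(cols, phis, reds):
        total += _column_delta_F(a_col, p_col, r_col)
    return total


def prune_scan(
    alpha: np.ndarray, phi_alpha: np.ndarray, eps: float = EPS_PRUNE
) -> list[ReductionResult]:
    """One-at-a-time prune scan over every transition-prior count.

    For each entry of the ``[u][i, j]`` tensor, build the reduced prior
    that shrinks that single entry to ``eps``, evaluate ``delta_F`` and
    mark the parameter pruned iff the evidence strictly increases
    (delta_F < 0).
    """
    alpha = np.asarray(alpha, dtype=float)
    phi_alpha = np.asarray(phi_alpha, dtype=float)
    results: list[ReductionResult] = []
    for u in range(alpha.shape[0]):
        for i in range(alpha.shape[1]):
            for j in range(alpha.shape[2]):
                # only the (u, j) column differs from the full prior
                reduced_col = alpha[u][:, j].copy()
                reduced_col[i] = eps
                dF = _column_delta_F(alpha[u][:, j], phi_alpha[u][:, j], reduced_col)
                results.append(
                    ReductionResult(
                        control=u, next_state=i, prev_state=j, delta_F=dF, pruned=dF < 0
                    )
                )
    return results
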