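"""Pairwise maximum-entropy (Ising) models on binary ±1 activity patterns.

The model assigns every activity pattern ``V = (s_1, ..., s_N)`` with
``s_i ∈ {-1, +1}`` an energy

    E(V) = - sum_i h_i s_i - (1/2) sum_ij J_ij s_i s_j

and a Boltzmann probability ``P(V) = exp(-E(V)) / Z``.  ``h_i`` is the basal
activity of node *i* and ``J`` is a symmetric, zero-diagonal coupling matrix.
For N up to 16 the state space (2^N patterns) is enumerated exactly, which
makes gradient-ascent fitting deterministic: model moments are computed by
full summation at every step, so the only stochasticity in a fit comes from
the empirical moments themselves.

State indexing convention: state index ``k`` encodes the pattern through its
bits — bit ``i`` of ``k`` (node 0 at the least-significant bit) is 1 iff
``s_i = +1``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

MAX_ENUM_NODES = 16


class EnumerationError(ValueError):
    """State space too large for exhaustive enumeration."""


class ConvergenceError(RuntimeError):
    """Gradient ascent failed to reach the moment-matching tolerance."""

    def __init__(self, message: str, final_gap: float, iterations: int):
        super().__init__(message)
        self.final_gap = final_gap
        self.iterations = iterations


@dataclass
class MEMParameters:
    """Fields ``h`` (length N) and couplings ``J`` (N x N, symmetric, zero diag)."""

    h: np.ndarray
    J: np.ndarray
    order: Literal["independent", "pairwise"] = "pairwise"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        n = self.h.shape[0]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be {n}x{n}, got {self.J.shape}")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0):
            raise ValueError("J must have zero diagonal")
        if self.order == "independent" and np.any(self.J != 0.0):
            raise ValueError("independent-order parameters require J == 0")

    @property
    def n_nodes(self) -> int:
        return self.h.shape[0]


@dataclass
class EmpiricalMoments:
    """First (⟨s_i⟩) and second (⟨s_i s_j⟩) empirical moments of a ±1 series."""

    first: np.ndarray
    second: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.first = np.asarray(self.first, dtype=float)
        self.second = np.asarray(self.second, dtype=float)
        if np.any(np.abs(self.first) > 1 + 1e-12):
            raise ValueError("first moments must lie in [-1, 1]")
        if not np.allclose(self.second, self.second.T):
            raise ValueError("second moments must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.first.shape[0]


@dataclass
class StateTable:
    """Exhaustive table over all 2^N patterns: energies and probabilities."""

    patterns: np.ndarray  # (2^N, N) of int8 in {-1, +1}
    energies: np.ndarray  # (2^N,)
    probabilities: np.ndarray  # (2^N,), sums to 1
    params: MEMParameters

    @property
    def n_nodes(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_states(self) -> int:
        return self.patterns.shape[0]


@dataclass
class FitAccuracy:
    """KL-based fit accuracy r_D = (D1 - D2) / D1 of the pairwise over the independent model."""

    d1: float
    d2: float
    r_d: float
    defined: bool = True


def state_patterns(n_nodes: int) -> np.ndarray:
    """All 2^N patterns as a (2^N, N) ±1 matrix, row k encoding state index k."""
    if n_nodes > MAX_ENUM_NODES:
        raise EnumerationError(
            f"exhaustive enumeration limited to N <= {MAX_ENUM_NODES}, got N = {n_nodes}"
        )
    k = np.arange(2**n_nodes, dtype=np.int64)
    bits = (k[:, None] >> np.arange(n_nodes)[None, :]) & 1
    return (2 * bits - 1).astype(np.int8)


def pattern_to_index(patterns: np.ndarray) -> np.ndarray:
    """Inverse of :func:`state_patterns` row-encoding (works on a matrix of rows)."""
    p = np.atleast_2d(np.asarray(patterns))
    bits = (p > 0).astype(np.int64)
    weights = 1 << np.arange(p.shape[1], dtype=np.int64)
    return bits @ weights


def _check_pm1(arr: np.ndarray, name: str = "pattern") -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (-1, 1)).all():
        raise ValueError(f"{name} entries must be -1 or +1")
    return a


def state_energy(pattern: np.ndarray, params: MEMParameters) -> float:
    """Energy E(V) = -h·s - (1/2) sᵀ J s of a single ±1 pattern."""
    s = _check_pm1(pattern).astype(float)
    if s.shape != (params.n_nodes,):
        raise ValueError(f"pattern length {s.shape} does not match N = {params.n_nodes}")
    return float(-params.h @ s - 0.5 * s @ params.J @ s)


def all_state_energies(params: MEMParameters, patterns: np.ndarray | None = None) -> np.ndarray:
    """Vectorized energies of every enumerated pattern."""
    S = state_patterns(params.n_nodes).astype(float) if patterns is None else patterns.astype(float)
    return -(S @ params.h) - 0.5 * np.einsum("ki,ij,kj->k", S, params.J, S)


def exact_distribution(params: MEMParameters) -> StateTable:
    """Exhaustive Boltzmann distribution P(V_k) ∝ exp(-E(V_k)) over all 2^N states.

    Normalization is stabilized by subtracting the maximum of -E before
    exponentiation, so arbitrarily strong parameters stay finite.
    """
    S = state_patterns(params.n_nodes)
    E = all_state_energies(params, S)
    log_p = -E - logsumexp(-E)
    return StateTable(patterns=S, energies=E, probabilities=np.exp(log_p), params=params)


def model_moments(table: StateTable) -> tuple[np.ndarray, np.ndarray]:
    """Exact model moments ⟨s_i⟩_m and ⟨s_i s_j⟩_m from a state table."""
    S = table.patterns.astype(float)
    p = table.probabilities
    first = p @ S
    second = (S * p[:, None]).T @ S
    return first, second


def empirical_moments(series: np.ndarray) -> EmpiricalMoments:
    """Time-averaged ⟨s_i⟩ and ⟨s_i s_j⟩ of a T x N ±1 series."""
    X = _check_pm1(np.asarray(series), "series").astype(float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("series must be a non-empty T x N matrix")
    T = X.shape[0]
    first = X.mean(axis=0)
    second = X.T @ X / T
    np.fill_diagonal(second, 1.0)  # s_i^2 == 1 exactly
    return EmpiricalMoments(first=first, second=second, n_samples=T)


def _shrink_boundary_moments(m: EmpiricalMoments) -> EmpiricalMoments:
    """Pull moments at exactly ±1 off the boundary by the factor T/(T+1).

    Moments on the boundary correspond to infinite maximum-likelihood
    parameters; the shrinkage is only applied when the boundary is actually
    hit, and is logged when active.
    """
    off = ~np.eye(m.n_nodes, dtype=bool)
    at_boundary = np.any(np.abs(m.first) >= 1.0) or np.any(np.abs(m.second[off]) >= 1.0)
    if not at_boundary:
        return m
    factor = m.n_samples / (m.n_samples + 1)
    logger.warning("empirical moments at ±1 boundary; shrinking by factor %.6f", factor)
    warnings.warn("empirical moments at ±1 boundary; shrunk toward 0", stacklevel=3)
    second = m.second * factor
    np.fill_diagonal(second, 1.0)
    return EmpiricalMoments(first=m.first * factor, second=second, n_samples=m.n_samples)


def fit_independent(moments: EmpiricalMoments) -> MEMParameters:
    """Closed-form independent (1st-order) model: J = 0, h_i = atanh(⟨s_i⟩)."""
    m = _shrink_boundary_moments(moments)
    h = np.arctanh(m.first)
    n = m.n_nodes
    return MEMParameters(h=h, J=np.zeros((n, n)), order="independent")


def fit_pairwise(
    moments: EmpiricalMoments,
    learning_rate: float = 0.2,
    tol: float = 1e-5,
    max_iter: int = 100_000,
) -> MEMParameters:
    """Fit the pairwise model by gradient ascent on the log-likelihood.

    The ascent direction is the moment gap (⟨s_i⟩ − ⟨s_i⟩_m, ⟨s_i s_j⟩ −
    ⟨s_i s_j⟩_m); model moments are recomputed by exact enumeration at every
    step, and iteration stops when the largest absolute gap falls below
    ``tol`` — i.e. when model moments are approximately equal to the
    empirical ones.  Initialization is h = J = 0 (the maximum-entropy model
    with no constraints).

    Raises :class:`ConvergenceError` (carrying the final gap) if ``max_iter``
    is exhausted.
    """
    m = _shrink_boundary_moments(moments)
    n = m.n_nodes
    S = state_patterns(n).astype(float)
    off_diag = ~np.eye(n, dtype=bool)

    h = np.zeros(n)
    J = np.zeros((n, n))
    emp1 = m.first
    emp2 = m.second

    gap = np.inf
    for it in range(1, max_iter + 1):
        E = -(S @ h) - 0.5 * ((S @ J) * S).sum(axis=1)
        log_p = -E - logsumexp(-E)
        p = np.exp(log_p)
        mod1 = p @ S
        mod2 = (S * p[:, None]).T @ S
        d1 = emp1 - mod1
        d2 = emp2 - mod2
        gap = max(np.abs(d1).max(), np.abs(d2[off_diag]).max() if n > 1 else 0.0)
        if gap <= tol:
            return MEMParameters(
                h=h, J=J, order="pairwise", meta={"iterations": it, "final_gap": float(gap)}
            )
        h = h + learning_rate * d1
        d2s = 0.5 * (d2 + d2.T)
        np.fill_diagonal(d2s, 0.0)
        J = J + learning_rate * d2s

    raise ConvergenceError(
        f"gradient ascent did not converge in {max_iter} iterations "
        f"(final max moment gap {gap:.3e} > tol {tol:.3e})",
        final_gap=float(gap),
        iterations=max_iter,
    )


def empirical_state_distribution(series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Observed state indices and their empirical frequencies from a ±1 series."""
    idx = pattern_to_index(_check_pm1(np.asarray(series), "series"))
    states, counts = np.unique(idx, return_counts=True)
    return states, counts / counts.sum()


def fit_accuracy(
    series: np.ndarray,
    pairwise: MEMParameters,
    independent: MEMParameters,
) -> FitAccuracy:
    """r_D = (D1 − D2)/D1, the fraction of the independent model's KL divergence
    from the empirical distribution that the pairwise model removes.

    D_k = Σ_V P_emp(V) log(P_emp(V)/P_k(V)) in nats, summed over observed
    patterns only (unobserved patterns contribute 0 by the 0·log 0
    convention).  When D1 = 0 the ratio is undefined and flagged.
    """
    states, p_emp = empirical_state_distribution(series)

    def kl(params: MEMParameters) -> float:
        table = exact_distribution(params)
        log_p_model = np.log(table.probabilities[states])
        return float(np.sum(p_emp * (np.log(p_emp) - log_p_model)))

    d1 = kl(independent)
    d2 = kl(pairwise)
    if d1 <= 0.0:
        logger.warning("D1 = 0: empirical distribution already matches the independent model")
        return FitAccuracy(d1=d1, d2=d2, r_d=float("nan"), defined=False)
    return FitAccuracy(d1=d1, d2=d2, r_d=(d1 - d2) / d1, defined=True)
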