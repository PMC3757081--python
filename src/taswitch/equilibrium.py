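"""Fast heteromer-formation equilibrium of a toxin-antitoxin pair.

Antitoxin A and toxin T form two heterocomplexes,

    A + T  <=>  AT      (dissociation constant K1)
    AT + T <=>  ATT     (dissociation constant K2)

with AT the transcriptionally active repressor and ATT an inert sink.
Complex formation is fast compared to production and degradation, so the
distribution of a total pool (A_tot, T_tot) over {A, T, AT, ATT} is an
algebraic mass-action equilibrium:

    [AT]  = [A][T]  / K1
    [ATT] = [AT][T] / K2
    A_tot = [A] + [AT] + [ATT]
    T_tot = [T] + [AT] + 2 [ATT]

The solver reduces the two conservation laws to a single monotone scalar
equation in the free-toxin concentration t: for a trial t the antitoxin
conservation fixes the free antitoxin

    a(t) = A_tot / S_A(t),    S_A(t) = 1 + t/K1 + t^2/(K1 K2),

and the implied total toxin

    Ttot(t) = t + a(t) (t/K1) (1 + 2 t/K2)

is strictly increasing in t, so bisection on t in [0, T_tot] converges to
the unique non-negative equilibrium. A damped 2-D Newton iteration on
(free A, free T) is provided as an independent cross-check.

All quantities are dimensionless (see the package docs for the unit
conventions of the full model).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BindingConstants",
    "TotalPool",
    "EquilibriumState",
    "InvalidInputError",
    "ConvergenceError",
    "solve_equilibrium",
    "solve_equilibrium_newton",
    "at_curve",
    "strong_binding_at",
    "repression_factor",
]

logger = logging.getLogger(__name__)

#: Dissociation constants below this value are clamped (singular limit guard).
K_CLAMP = 1e-15


class InvalidInputError(ValueError):
    """Raised when inputs are negative, non-finite or otherwise out of domain."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative solve fails to reach the requested tolerance."""


@dataclass(frozen=True)
class BindingConstants:
    """Dissociation constants of the two heterocomplexes (dimensionless).

    K1 governs A + T <=> AT, K2 governs AT + T <=> ATT.  Small values mean
    tight binding; the reference toxin-antitoxin pair has K1 = K2 = 0.004.
    """

    K1: float
    K2: float

    def __post_init__(self) -> None:
        for name in ("K1", "K2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{name} must be positive and finite, got {v!r}")

    def clamped(self) -> "BindingConstants":
        """Return constants with values below ``K_CLAMP`` raised to it."""
        k1, k2 = self.K1, self.K2
        if k1 < K_CLAMP or k2 < K_CLAMP:
            warnings.warn(
                f"dissociation constant(s) below {K_CLAMP:g} clamped "
                f"(K1={k1:g}, K2={k2:g})",
                RuntimeWarning,
                stacklevel=2,
            )
            logger.warning("clamping dissociation constants K1=%g K2=%g", k1, k2)
            k1, k2 = max(k1, K_CLAMP), max(k2, K_CLAMP)
            return BindingConstants(k1, k2)
        return self


@dataclass(frozen=True)
class TotalPool:
    """Total (free + complexed) antitoxin and toxin concentrations."""

    A_tot: float
    T_tot: float

    def __post_init__(self) -> None:
        for name in ("A_tot", "T_tot"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be non-negative and finite, got {v!r}")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations of the four species."""

    freeA: float
    freeT: float
    AT: float
    ATT: float

    @property
    def A_tot(self) -> float:
        return self.freeA + self.AT + self.ATT

    @property
    def T_tot(self) -> float:
        return self.freeT + self.AT + 2.0 * self.ATT

    def residuals(self, pool: TotalPool, K: BindingConstants) -> dict[str, float]:
        """Relative residuals of the two mass-action laws and two conservation laws."""
        scale_a = max(pool.A_tot, 1e-300)
        scale_t = max(pool.T_tot, 1e-300)
        mass1 = self.AT * K.K1 - self.freeA * self.freeT
        mass2 = self.ATT * K.K2 - self.AT * self.freeT
        return {
            "mass_action_AT": abs(mass1) / max(self.AT * K.K1, self.freeA * self.freeT, 1e-300),
            "mass_action_ATT": abs(mass2) / max(self.ATT * K.K2, self.AT * self.freeT, 1e-300),
            "conservation_A": abs(self.A_tot - pool.A_tot) / scale_a,
            "conservation_T": abs(self.T_tot - pool.T_tot) / scale_t,
        }


def _species_from_free_t(A_tot: float, t: float, K1: float, K2: float) -> tuple[float, float, float]:
    """Free A and the two complexes implied by total A and trial free toxin t."""
    s_a = 1.0 + t / K1 + t * t / (K1 * K2)
    a = A_tot / s_a
    at = a * t / K1
    att = at * t / K2
    return a, at, att


def _implied_T_tot(A_tot: float, t: float, K1: float, K2: float) -> float:
    a, at, att = _species_from_free_t(A_tot, t, K1, K2)
    return t + at + 2.0 * att


def solve_equilibrium(
    pool: TotalPool,
    K: BindingConstants,
    rel_tol: float = 1e-12,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the heteromer equilibrium by monotone bisection on free toxin.

    Parameters
    ----------
    pool:
        Total antitoxin and toxin.
    K:
        Dissociation constants (clamped at ``K_CLAMP`` if degenerate).
    rel_tol:
        Relative tolerance on the conservation laws, in (0, 1e-6].
    max_iter:
        Bisection iteration budget.

    Returns
    -------
    EquilibriumState satisfying mass action and conservation to ``rel_tol``.
    """
    if not (0.0 < rel_tol <= 1e-6):
        raise InvalidInputError(f"rel_tol must be in (0, 1e-6], got {rel_tol!r}")
    K = K.clamped()
    A_tot, T_tot = pool.A_tot, pool.T_tot

    if T_tot == 0.0:
        return EquilibriumState(freeA=A_tot, freeT=0.0, AT=0.0, ATT=0.0)
    if A_tot == 0.0:
        return EquilibriumState(freeA=0.0, freeT=T_tot, AT=0.0, ATT=0.0)

    lo, hi = 0.0, T_tot
    t = 0.5 * T_tot
    for _ in range(max_iter):
        t = 0.5 * (lo + hi)
        if _implied_T_tot(A_tot, t, K.K1, K.K2) < T_tot:
            lo = t
        else:
            hi = t
        if hi - lo <= rel_tol * max(t, 1e-300):
            break
    t = 0.5 * (lo + hi)
    a, at, att = _species_from_free_t(A_tot, t, K.K1, K.K2)
    state = EquilibriumState(freeA=a, freeT=t, AT=at, ATT=att)

    res = state.residuals(pool, K)
    worst = max(res.values())
    if worst > 10.0 * rel_tol:
        raise ConvergenceError(
            f"equilibrium solve did not reach rel_tol={rel_tol:g} for "
            f"A_tot={A_tot:g}, T_tot={T_tot:g}, K1={K.K1:g}, K2={K.K2:g} "
            f"(worst residual {worst:g})"
        )
    return state


def solve_equilibrium_newton(
    pool: TotalPool,
    K: BindingConstants,
    rel_tol: float = 1e-12,
    max_iter: int = 200,
) -> EquilibriumState:
    """Independent 2-D damped Newton solve on (free A, free T).

    Retained as a cross-check for :func:`solve_equilibrium`; iterates the
    conservation residuals with an analytic Jacobian from several starting
    points and returns the first converged solution.
    """
    K = K.clamped()
    A_tot, T_tot = pool.A_tot, pool.T_tot
    if T_tot == 0.0:
        return EquilibriumState(freeA=A_tot, freeT=0.0, AT=0.0, ATT=0.0)
    if A_tot == 0.0:
        return EquilibriumState(freeA=0.0, freeT=T_tot, AT=0.0, ATT=0.0)

    k1, k2 = K.K1, K.K2
    starts = [
        (0.5 * A_tot, 0.5 * T_tot),
        (A_tot, T_tot),
        (A_tot * 1e-3, T_tot),
        (A_tot, T_tot * 1e-3),
        (A_tot * 1e-6, T_tot * 1e-6),
    ]
    for a0, t0 in starts:
        a, t = a0, t0
        for _ in range(max_iter):
            at = a * t / k1
            att = at * t / k2
            f1 = a + at + att - A_tot
            f2 = t + at + 2.0 * att - T_tot
            scale = max(A_tot, T_tot)
            if abs(f1) <= rel_tol * scale and abs(f2) <= rel_tol * scale:
                break
            # Jacobian wrt (a, t)
            d_at_da, d_at_dt = t / k1, a / k1
            d_att_da, d_att_dt = t * t / (k1 * k2), 2.0 * a * t / (k1 * k2)
            j11 = 1.0 + d_at_da + d_att_da
            j12 = d_at_dt + d_att_dt
            j21 = d_at_da + 2.0 * d_att_da
            j22 = 1.0 + d_at_dt + 2.0 * d_att_dt
            det = j11 * j22 - j12 * j21
            if det == 0.0 or not math.isfinite(det):
                break
            da = (-f1 * j22 + f2 * j12) / det
            dt = (-f2 * j11 + f1 * j21) / det
            # damped positivity-preserving step
            lam = 1.0
            while (a + lam * da <= 0.0 or t + lam * dt <= 0.0) and lam > 1e-12:
                lam *= 0.5
            a += lam * da
            t += lam * dt
        else:
            continue
        at = a * t / k1
        att = at * t / k2
        state = EquilibriumState(freeA=a, freeT=t, AT=at, ATT=att)
        if max(state.residuals(pool, K).values()) <= 1e3 * rel_tol:
            return state
    raise ConvergenceError(
        f"2-D Newton failed for A_tot={A_tot:g}, T_tot={T_tot:g}, "
        f"K1={k1:g}, K2={k2:g}"
    )


def at_curve(
    A_tot: float,
    T_grid: np.ndarray,
    K: BindingConstants,
    rel_tol: float = 1e-12,
) -> list[tuple[float, float]]:
    """Repressor concentration [AT] along a grid of total toxin.

    With tight binding (K1, K2 << A_tot) the curve rises to a single
    interior maximum near T_tot = A_tot and is then titrated to nearly
    zero by ATT formation beyond T_tot = 2 A_tot.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.ndim != 1 or T_grid.size == 0:
        raise InvalidInputError("T_grid must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(T_grid)) or np.any(T_grid < 0):
        raise InvalidInputError("T_grid must be non-negative and finite")
    if T_grid.size > 1 and np.any(np.diff(T_grid) <= 0):
        raise InvalidInputError("T_grid must be strictly increasing")
    out = []
    for T in T_grid:
        st = solve_equilibrium(TotalPool(A_tot, float(T)), K, rel_tol)
        out.append((float(T), st.AT))
    return out


def strong_binding_at(A_tot: float, T_tot: float) -> float:
    """Closed-form [AT] in the infinitely tight binding limit K1 = K2 -> 0.

    Toxin is absorbed first into AT (up to T_tot = A_tot) and then converted
    to ATT, exhausting AT at T_tot = 2 A_tot:

        [AT] = min(T_tot, max(0, 2 A_tot - T_tot))
    """
    if not (math.isfinite(A_tot) and math.isfinite(T_tot)) or A_tot < 0 or T_tot < 0:
        raise InvalidInputError(f"totals must be non-negative, got {A_tot!r}, {T_tot!r}")
    return min(T_tot, max(0.0, 2.0 * A_tot - T_tot))


def repression_factor(AT, K_D: float, n: int = 1):
    """Promoter activity under repression by AT.

    Returns 1 / (1 + (AT/K_D)^n): the fraction of time the promoter is free
    of repressor, with operator dissociation constant K_D and Hill exponent
    n (n = 1, non-cooperative, is the default throughout the package).
    Accepts scalars or arrays.
    """
    if not math.isfinite(K_D) or K_D <= 0:
        raise InvalidInputError(f"K_D must be positive, got {K_D!r}")
    if n < 1 or int(n) != n:
        raise InvalidInputError(f"Hill exponent n must be a positive integer, got {n!r}")
    AT = np.asarray(AT, dtype=float)
    if np.any(AT < 0):
        raise InvalidInputError("AT must be non-negative")
    out = 1.0 / (1.0 + (AT / K_D) ** n)
    return float(out) if out.ndim == 0 else out
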