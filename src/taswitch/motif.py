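"""Single-variable conditional-regulation feedback motif.

Toxin T is produced under repression by the AT heterocomplex while the
total antitoxin pool is held fixed (supplied from an independent promoter),
and is removed by first-order dilution (rate 1 in units of the toxin
lifetime):

    dT_tot/dt = beta_T / (1 + ([AT]/K_D)^n)  -  T_tot

with [AT] the equilibrium repressor concentration at the current totals.
Because [AT] is a non-monotonic function of T_tot (it peaks at T_tot ~
A_tot and is titrated away beyond T_tot ~ 2 A_tot), the production term is
non-monotonic, and the motif can be bistable without any cooperativity in
operator binding.  Concentrations here are measured in units of the mutual
binding strength, K1 = K2 = 1 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .equilibrium import (
    BindingConstants,
    InvalidInputError,
    TotalPool,
    repression_factor,
    solve_equilibrium,
)

__all__ = [
    "MotifParams",
    "SteadyState1D",
    "production_1d",
    "fixed_points_1d",
    "bistable_region_scan",
]


@dataclass(frozen=True)
class MotifParams:
    """Parameters of the one-variable motif."""

    beta_T: float
    A_tot: float
    K_D: float = 1.0
    K: BindingConstants = field(default_factory=lambda: BindingConstants(1.0, 1.0))
    n: int = 1

    def __post_init__(self) -> None:
        if self.beta_T <= 0:
            raise InvalidInputError(f"beta_T must be positive, got {self.beta_T!r}")
        if self.A_tot < 0:
            raise InvalidInputError(f"A_tot must be non-negative, got {self.A_tot!r}")
        if self.K_D <= 0:
            raise InvalidInputError(f"K_D must be positive, got {self.K_D!r}")


@dataclass(frozen=True)
class SteadyState1D:
    """A steady state of the motif; stable iff production - loss is
    decreasing through zero."""

    T_ss: float
    stable: bool


def production_1d(T_tot: float, p: MotifParams) -> float:
    """Production term beta_T * R([AT]) at total toxin ``T_tot``."""
    if T_tot < 0:
        raise InvalidInputError(f"T_tot must be non-negative, got {T_tot!r}")
    st = solve_equilibrium(TotalPool(p.A_tot, float(T_tot)), p.K)
    return p.beta_T * repression_factor(st.AT, p.K_D, p.n)


def _g(T: float, p: MotifParams) -> float:
    return production_1d(T, p) - T


def fixed_points_1d(
    p: MotifParams,
    n_grid: int = 2000,
    abs_tol: float = 1e-10,
) -> list[SteadyState1D]:
    """All steady states of the motif, ordered by T_ss.

    Sign changes of g(T) = production(T) - T are bracketed on a logarithmic
    grid over [1e-6, 10 beta_T] (g(0) > 0 and g(T) < 0 for T > beta_T, so
    the range is exhaustive) and refined by bisection.  Stability is read
    from the sign of g across the bracket: g decreasing through zero means
    the state attracts.
    """
    lo, hi = 1e-6, 10.0 * p.beta_T
    grid = np.concatenate(([0.0], np.logspace(np.log10(lo), np.log10(hi), n_grid)))
    gv = np.array([_g(T, p) for T in grid])
    out: list[SteadyState1D] = []
    for i in range(len(grid) - 1):
        a, b = gv[i], gv[i + 1]
        if a == 0.0:
            continue  # grid point exactly on a root: picked up by the bracket
        if (a > 0) != (b > 0) or b == 0.0:
            x0, x1 = grid[i], grid[i + 1]
            root = brentq(_g, x0, x1, args=(p,), xtol=abs_tol, rtol=1e-14)
            out.append(SteadyState1D(T_ss=float(root), stable=bool(a > 0)))
    return out


def bistable_region_scan(
    beta_T_grid: np.ndarray,
    A_tot_grid: np.ndarray,
    K_D: float = 1.0,
    K: BindingConstants | None = None,
    n: int = 1,
) -> list[dict]:
    """Map the bistable region in the (beta_T, A_tot) plane.

    Returns one record per grid point with the bistability flag, the low-
    and high-T stable steady states, and the contrast ratio T_low/T_high
    (<= 1, absent when monostable).
    """
    K = K or BindingConstants(1.0, 1.0)
    beta_T_grid = np.asarray(beta_T_grid, dtype=float)
    A_tot_grid = np.asarray(A_tot_grid, dtype=float)
    if beta_T_grid.size == 0 or A_tot_grid.size == 0:
        raise InvalidInputError("grids must be non-empty")
    records = []
    for bt in beta_T_grid:
        for a in A_tot_grid:
            p = MotifParams(beta_T=float(bt), A_tot=float(a), K_D=K_D, K=K, n=n)
            fps = fixed_points_1d(p)
            stable = [s.T_ss for s in fps if s.stable]
            rec = {
                "beta_T": float(bt),
                "A_tot": float(a),
                "K_D": float(K_D),
                "n": int(n),
                "bistable": len(stable) >= 2,
                "T_low": min(stable) if len(stable) >= 2 else (stable[0] if stable else None),
                "T_high": max(stable) if len(stable) >= 2 else None,
                "contrast": (min(stable) / max(stable)) if len(stable) >= 2 else None,
            }
            records.append(rec)
    return records
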