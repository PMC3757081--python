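"""Full toxin-antitoxin operon model with growth-rate feedback.

Both proteins are encoded by one operon repressed by the AT heterocomplex.
In units where the toxin dilution rate at normal growth and the maximal
toxin production rate are 1, the totals evolve as

    dA_tot/dt = beta_A * R * phi_p(t)  -  Gamma_A * A_tot
    dT_tot/dt = beta_T * R * phi_p(t)  -  phi_g(t) * T_tot

where R = 1/(1 + ([AT]/K_D)^n) is the promoter activity, t is the free
toxin concentration from the fast complex-formation equilibrium at the
current totals, and the two feedback factors are second-order saturating
inhibition laws

    phi_p(t) = 1 / (1 + k_tl * t)^2      (protein production)
    phi_g(t) = 1 / (1 + k_g  * t)^2      (cell growth = toxin dilution)

k_tl is the per-free-toxin strength of translation/production inhibition
and k_g the per-free-toxin strength of growth inhibition.  Free toxin does
not affect the active degradation of the antitoxin (rate Gamma_A), which
is the asymmetry that lets a toxin-dominated, growth-arrested (dormant)
state coexist with the antitoxin-dominated growing state.  With
k_tl = k_g = 0 the model reduces to the no-feedback operon, which is
monostable.  The rationale for the squared denominator (the lowest-order
saturating law reproducing the dormant branch at the reference feedback
strengths without runaway toxin accumulation) is documented in
docs/methods.md.

Fixed points are enumerated through a one-dimensional reduction: for a
trial free-toxin value t the antitoxin steady-state equation has a unique
positive root in free antitoxin, leaving a single scalar residual in t
whose sign changes are bracketed on a logarithmic grid and refined.  A
multi-start 2-D Newton iteration on the totals is provided as an
independent cross-check.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

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
    "TAParams",
    "REFERENCE",
    "FixedPoint",
    "Trajectory",
    "production_factor",
    "growth_factor",
    "rhs",
    "rhs_no_feedback",
    "nullclines",
    "nullcline_intersections",
    "enumerate_fixed_points",
    "enumerate_fixed_points_newton",
    "classify_stability",
    "simulate_rk4",
    "is_bistable",
    "dilution_rate_ratio",
]

logger = logging.getLogger(__name__)

#: Eigenvalues with |Re| below this are reported as marginal and the point
#: is excluded from bistability counts.
MARGINAL_EIGENVALUE = 1e-9


@dataclass(frozen=True)
class TAParams:
    """Dimensionless parameter vector of the full operon model.

    Defaults are the reference set of the modelled RelBE-like system:
    translation ratio beta_A/beta_T = 100, antitoxin degradation 10x the
    toxin dilution rate, tight complex formation (K1 = K2 = 0.004) and an
    operator constant K_D = 0.015, with feedback strengths
    k_tl = k_g = 11.
    """

    beta_A: float = 100.0
    beta_T: float = 1.0
    Gamma_A: float = 10.0
    K_D: float = 0.015
    K1: float = 0.004
    K2: float = 0.004
    k_tl: float = 11.0
    k_g: float = 11.0
    n: int = 1

    def __post_init__(self) -> None:
        problems = []
        for name in ("beta_A", "beta_T", "Gamma_A", "K_D", "K1", "K2"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                problems.append(f"{name} must be positive, got {v!r}")
        for name in ("k_tl", "k_g"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                problems.append(f"{name} must be non-negative, got {v!r}")
        if self.n < 1 or int(self.n) != self.n:
            problems.append(f"n must be a positive integer, got {self.n!r}")
        if problems:
            raise InvalidInputError("; ".join(problems))

    @property
    def K(self) -> BindingConstants:
        return BindingConstants(self.K1, self.K2)

    def without_feedback(self) -> "TAParams":
        """The same operon with free-toxin activity switched off."""
        return replace(self, k_tl=0.0, k_g=0.0)


#: Table of reference values (dimensionless).
REFERENCE = TAParams()


@dataclass(frozen=True)
class FixedPoint:
    """A steady state in total-concentration coordinates."""

    A_tot: float
    T_tot: float
    freeT: float
    eigenvalues: tuple[complex, complex]
    klass: str  # 'stable' | 'saddle' | 'unstable' | 'marginal'

    @property
    def stable(self) -> bool:
        return self.klass == "stable"


@dataclass(frozen=True)
class Trajectory:
    """An RK4 time course of the totals."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 2): columns A_tot, T_tot


def production_factor(freeT, k_tl: float):
    """Reduction of all protein production by free toxin: 1/(1+k_tl*t)^2."""
    return 1.0 / (1.0 + k_tl * np.asarray(freeT, dtype=float)) ** 2


def growth_factor(freeT, k_g: float):
    """Relative cell growth rate under free toxin: 1/(1+k_g*t)^2."""
    return 1.0 / (1.0 + k_g * np.asarray(freeT, dtype=float)) ** 2


def rhs_terms(state, p: TAParams) -> tuple[np.ndarray, np.ndarray]:
    """Production and loss terms of the two equations: (gains, losses)."""
    A, T = float(state[0]), float(state[1])
    if A < 0 or T < 0:
        raise InvalidInputError(f"state must be non-negative, got ({A!r}, {T!r})")
    eq = solve_equilibrium(TotalPool(A, T), p.K)
    R = repression_factor(eq.AT, p.K_D, p.n)
    pp = float(production_factor(eq.freeT, p.k_tl))
    pg = float(growth_factor(eq.freeT, p.k_g))
    gains = np.array([p.beta_A * R * pp, p.beta_T * R * pp])
    losses = np.array([p.Gamma_A * A, pg * T])
    return gains, losses


def rhs(state, p: TAParams) -> np.ndarray:
    """Right-hand side (dA_tot/dt, dT_tot/dt) at the given totals."""
    gains, losses = rhs_terms(state, p)
    return gains - losses


def rhs_no_feedback(state, p: TAParams) -> np.ndarray:
    """The no-feedback operon (k_tl = k_g = 0) evaluated at the same state."""
    return rhs(state, p.without_feedback())


# ---------------------------------------------------------------------------
# one-dimensional reduction used by the fixed-point enumerator


def _free_antitoxin_at_steady_state(t, p: TAParams):
    """Free antitoxin a(t) solving the A-equation at fixed free toxin t.

    With S_A(t) = 1 + t/K1 + t^2/(K1 K2) and AT = a t / K1 the antitoxin
    steady state beta_A R phi_p = Gamma_A a S_A is, for n = 1, a quadratic
    in a with a unique positive root; for n >= 2 the left side is still
    strictly decreasing in a, and a guarded Newton iteration from the
    repression-free upper bound converges monotonically.
    """
    t = np.asarray(t, dtype=float)
    S = 1.0 + t / p.K1 + t * t / (p.K1 * p.K2)
    P = production_factor(t, p.k_tl)
    upper = p.beta_A * P / (p.Gamma_A * S)  # root with repression ignored
    if p.n == 1:
        c2 = p.Gamma_A * S * t / (p.K1 * p.K_D)
        c1 = p.Gamma_A * S
        rhs_ = p.beta_A * P
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(
                c2 > 0.0,
                (-c1 + np.sqrt(c1 * c1 + 4.0 * c2 * rhs_)) / (2.0 * np.maximum(c2, 1e-300)),
                upper,
            )
        return a
    # general Hill exponent: f(a) = Gamma_A S a (1 + (a t/(K1 K_D))^n) - beta_A P
    a = upper.copy()
    x = t / (p.K1 * p.K_D)
    for _ in range(80):
        h = (a * x) ** p.n
        f = p.Gamma_A * S * a * (1.0 + h) - p.beta_A * P
        df = p.Gamma_A * S * (1.0 + (p.n + 1.0) * h)
        step = f / df
        a = np.clip(a - step, 0.0, upper)
    return a


def _reduction_curves(t, p: TAParams):
    """Totals, repression and residual sign function along a free-toxin grid.

    Returns (A_tot(t), T_tot(t), log-residual s(t)) where s(t) =
    log(beta_T R phi_p) - log(phi_g T_tot(t)); zeros of s are fixed points.
    The log form is overflow-proof across the full scanned range.
    """
    t = np.asarray(t, dtype=float)
    a = _free_antitoxin_at_steady_state(t, p)
    AT = a * t / p.K1
    ATT = AT * t / p.K2
    S = 1.0 + t / p.K1 + t * t / (p.K1 * p.K2)
    A_tot = a * S
    T_tot = t + AT + 2.0 * ATT
    R = 1.0 / (1.0 + (AT / p.K_D) ** p.n)
    s = (
        np.log(p.beta_T * R)
        - 2.0 * np.log1p(p.k_tl * t)
        + 2.0 * np.log1p(p.k_g * t)
        - np.log(np.maximum(T_tot, 1e-300))
    )
    return A_tot, T_tot, s


def _t_grid(p: TAParams, n_points: int) -> np.ndarray:
    ratio = p.k_g / max(p.k_tl, 1e-3)
    tmax = 50.0 * p.beta_T * max(1.0, ratio) ** 2
    tmax = min(max(tmax, 10.0 * p.beta_T), 1e7)
    return np.logspace(-9.0, np.log10(tmax), n_points)


def enumerate_fixed_points(
    p: TAParams,
    n_points: int = 3000,
    classify: bool = True,
) -> list[FixedPoint]:
    """All fixed points of the full model, ordered by total toxin.

    Sign changes of the reduced scalar residual over a logarithmic
    free-toxin grid are refined by Brent's method; the totals are
    reconstructed, near-duplicates merged (relative tolerance 1e-6) and
    each point classified through the Jacobian.
    """
    t = _t_grid(p, n_points)
    _, _, s = _reduction_curves(t, p)
    idx = np.nonzero(np.diff(np.signbit(s)))[0]

    def s_scalar(tt: float) -> float:
        return float(_reduction_curves(np.array([tt]), p)[2][0])

    points: list[tuple[float, float, float, bool]] = []
    for i in idx:
        root = brentq(s_scalar, t[i], t[i + 1], xtol=1e-15, rtol=1e-13)
        A_tot, T_tot, _ = _reduction_curves(np.array([root]), p)
        decreasing = bool(s[i] > 0)  # residual falls through zero => attracting
        cand = (float(A_tot[0]), float(T_tot[0]), float(root), decreasing)
        if any(
            abs(cand[0] - q[0]) <= 1e-6 * max(1e-12, abs(q[0]))
            and abs(cand[1] - q[1]) <= 1e-6 * max(1e-12, abs(q[1]))
            for q in points
        ):
            continue
        points.append(cand)
    points.sort(key=lambda q: q[1])
    if not classify:
        return [
            FixedPoint(A, T, ft, (complex(float("nan")), complex(float("nan"))), "unclassified")
            for A, T, ft, _ in points
        ]
    out = []
    for A, T, ft, decreasing in points:
        fp = classify_stability((A, T), p, freeT=ft)
        if fp.klass == "marginal":
            # A finite-difference Jacobian cannot resolve the slow direction
            # of deeply dormant states (relaxation rate ~ growth rate ~ 0);
            # the exact sign of the reduced residual across the bracket can.
            resolved = "stable" if decreasing else "saddle"
            logger.debug(
                "marginal Jacobian at (%g, %g) resolved as %s via 1-D slope", A, T, resolved
            )
            fp = FixedPoint(fp.A_tot, fp.T_tot, fp.freeT, fp.eigenvalues, resolved)
        out.append(fp)
    return out


def _jacobian(state, p: TAParams, rel_step: float = 1e-6) -> np.ndarray:
    A, T = float(state[0]), float(state[1])
    J = np.empty((2, 2))
    for j, base in enumerate((A, T)):
        h = rel_step * max(abs(base), 1e-8)
        dp = [0.0, 0.0]
        dp[j] = h
        lo0, lo1 = max(A - dp[0], 0.0), max(T - dp[1], 0.0)
        f_hi = rhs((A + dp[0], T + dp[1]), p)
        f_lo = rhs((lo0, lo1), p)
        span = (A + dp[0] - lo0) if j == 0 else (T + dp[1] - lo1)
        J[:, j] = (f_hi - f_lo) / span
    return J


def classify_stability(state, p: TAParams, freeT: float | None = None) -> FixedPoint:
    """Classify a steady state through the finite-difference Jacobian.

    Raises if the right-hand side at ``state`` is not small (the point is
    not a fixed point).  Eigenvalues with both real parts negative mean
    stable, opposite signs a saddle, both positive unstable; |Re| below
    ``MARGINAL_EIGENVALUE`` is reported as 'marginal'.
    """
    A, T = float(state[0]), float(state[1])
    f = rhs((A, T), p)
    scale = max(p.beta_A, p.Gamma_A * A, 1.0)
    if np.max(np.abs(f)) > 1e-5 * scale:
        raise InvalidInputError(
            f"state ({A:g}, {T:g}) is not a fixed point (|rhs| = {np.max(np.abs(f)):g})"
        )
    if freeT is None:
        freeT = solve_equilibrium(TotalPool(A, T), p.K).freeT
    ev = np.linalg.eigvals(_jacobian((A, T), p))
    re = np.sort(ev.real)
    if np.min(np.abs(re)) < MARGINAL_EIGENVALUE:
        klass = "marginal"
        logger.debug("marginal fixed point at (%g, %g): eigenvalues %s", A, T, ev)
    elif re[1] < 0:
        klass = "stable"
    elif re[0] > 0:
        klass = "unstable"
    else:
        klass = "saddle"
    return FixedPoint(A, T, float(freeT), (complex(ev[0]), complex(ev[1])), klass)


def enumerate_fixed_points_newton(
    p: TAParams,
    n_starts: int = 12,
    max_iter: int = 200,
) -> list[FixedPoint]:
    """Independent multi-start 2-D Newton enumeration (cross-check oracle).

    Damped Newton iterations on the totals from a grid of starting points;
    converged points are deduplicated and classified.  Convergence failures
    are logged per start and never fatal.
    """
    A_scale = p.beta_A / p.Gamma_A
    T_scale = max(p.beta_T, 1.0) * max(1.0, (p.k_g / max(p.k_tl, 1e-3)) ** 2)
    starts = []
    for fa in np.logspace(-3, 0.5, n_starts // 3 + 1):
        for ft in np.logspace(-3, 1.0, n_starts // 3 + 1):
            starts.append((A_scale * fa, T_scale * ft))
    found: list[tuple[float, float]] = []
    def balanced(x) -> bool:
        # a true fixed point balances gains against losses component-wise;
        # a relative criterion rejects the flat far field where both vanish
        gains, losses = rhs_terms(x, p)
        scale = np.maximum(np.maximum(gains, losses), 1e-300)
        return bool(np.all(np.abs(gains - losses) <= 1e-9 * scale))

    for a0, t0 in starts:
        x = np.array([a0, t0])
        ok = False
        for _ in range(max_iter):
            f = rhs(x, p)
            if np.max(np.abs(f)) < 1e-13 * max(p.beta_A, 1.0) and balanced(x):
                ok = True
                break
            J = _jacobian(x, p)
            try:
                step = np.linalg.solve(J, -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            while np.any(x + lam * step < 0) and lam > 1e-12:
                lam *= 0.5
            x_new = np.maximum(x + lam * step, 0.0)
            if not np.all(np.isfinite(x_new)):
                break
            if np.max(np.abs(x_new - x)) < 1e-14 * max(1.0, np.max(np.abs(x))):
                x = x_new
                ok = balanced(x)
                break
            x = x_new
        if not ok:
            logger.debug("Newton start (%g, %g) did not converge", a0, t0)
            continue
        if any(
            abs(x[0] - q[0]) <= 1e-5 * max(1e-12, q[0])
            and abs(x[1] - q[1]) <= 1e-5 * max(1e-12, q[1])
            for q in found
        ):
            continue
        found.append((float(x[0]), float(x[1])))
    found.sort(key=lambda q: q[1])
    return [classify_stability(q, p) for q in found]


# ---------------------------------------------------------------------------
# null-clines


def nullclines(
    p: TAParams,
    grid: np.ndarray,
    which: str,
    n_scan: int = 400,
) -> list[tuple[float, float]]:
    """Roots of one RHS component along a grid of total toxin.

    For each T_tot in ``grid`` all roots in A_tot of the selected component
    ('A' for dA_tot/dt, 'T' for dT_tot/dt) are located by sign-change
    bracketing on a logarithmic A_tot scan and refined by Brent's method.
    Returns (T_tot, A_tot) pairs; multivalued branches yield several pairs
    per grid value.
    """
    if which not in ("A", "T"):
        raise InvalidInputError(f"which must be 'A' or 'T', got {which!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise InvalidInputError("grid must be positive")
    comp = 0 if which == "A" else 1
    A_hi = 10.0 * p.beta_A / p.Gamma_A + np.max(grid)
    A_scan = np.concatenate(([0.0], np.logspace(-9, np.log10(A_hi), n_scan)))
    out: list[tuple[float, float]] = []
    for T in grid:
        vals = np.array([rhs((a, T), p)[comp] for a in A_scan])
        sign = np.signbit(vals)
        for i in np.nonzero(np.diff(sign) | (vals[1:] == 0.0))[0]:
            root = brentq(
                lambda a: rhs((a, T), p)[comp],
                A_scan[i],
                A_scan[i + 1],
                xtol=1e-12,
                rtol=1e-12,
            )
            out.append((float(T), float(root)))
    return out


def nullcline_intersections(
    p: TAParams,
    n_grid: int = 80,
) -> list[tuple[float, float]]:
    """Intersections of the two null-clines, polished by 2-D Newton.

    Seeds are cells of a logarithmic (A_tot, T_tot) lattice in which both
    right-hand-side components change sign among the four corners; each
    seed is refined on the full right-hand side.  Used as a consistency
    check against :func:`enumerate_fixed_points`.
    """
    t_hi = max(2.0, 20.0 * p.beta_T * max(1.0, (p.k_g / max(p.k_tl, 1e-3)) ** 2))
    a_hi = 10.0 * p.beta_A / p.Gamma_A
    A_ax = np.logspace(-6, np.log10(a_hi), n_grid)
    T_ax = np.logspace(-6, np.log10(t_hi), n_grid)
    F = np.empty((n_grid, n_grid, 2))
    for i, a in enumerate(A_ax):
        for j, t in enumerate(T_ax):
            F[i, j] = rhs((a, t), p)
    seeds = []
    for i in range(n_grid - 1):
        for j in range(n_grid - 1):
            cell = F[i : i + 2, j : j + 2].reshape(4, 2)
            if (cell[:, 0].min() < 0 < cell[:, 0].max()) and (
                cell[:, 1].min() < 0 < cell[:, 1].max()
            ):
                seeds.append(
                    (np.sqrt(A_ax[i] * A_ax[i + 1]), np.sqrt(T_ax[j] * T_ax[j + 1]))
                )
    found: list[tuple[float, float]] = []
    for a0, t0 in seeds:
        x = np.array([a0, t0])
        for _ in range(100):
            f = rhs(x, p)
            if np.max(np.abs(f)) < 1e-12 * max(p.beta_A, 1.0):
                break
            try:
                step = np.linalg.solve(_jacobian(x, p), -f)
            except np.linalg.LinAlgError:
                break
            lam = 1.0
            while np.any(x + lam * step < 0) and lam > 1e-12:
                lam *= 0.5
            x = x + lam * step
            if not np.all(np.isfinite(x)):
                break
        else:
            continue
        if not np.all(np.isfinite(x)) or np.max(np.abs(rhs(x, p))) > 1e-9 * max(p.beta_A, 1.0):
            continue
        if any(
            abs(x[0] - q[0]) <= 1e-5 * max(1e-12, q[0])
            and abs(x[1] - q[1]) <= 1e-5 * max(1e-12, q[1])
            for q in found
        ):
            continue
        found.append((float(x[0]), float(x[1])))
    found.sort(key=lambda q: q[1])
    return found


# ---------------------------------------------------------------------------
# integration and bistability


class IntegrationError(RuntimeError):
    """Raised when the integrator encounters a non-finite state."""


def simulate_rk4(state0, p: TAParams, dt: float = 1e-3, t_end: float = 50.0) -> Trajectory:
    """Classical fixed-step 4th-order Runge-Kutta time course of the totals.

    Negative overshoots are clamped at zero (with a logged warning);
    non-finite states abort with :class:`IntegrationError`.
    """
    if dt <= 0 or t_end <= dt:
        raise InvalidInputError(f"need 0 < dt < t_end, got dt={dt!r}, t_end={t_end!r}")
    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    states = np.empty((n_steps + 1, 2))
    x = np.asarray(state0, dtype=float)
    if np.any(x < 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError(f"state0 must be finite and non-negative, got {state0!r}")
    states[0] = x
    clamped = False
    for i in range(1, n_steps + 1):
        k1 = rhs(x, p)
        k2 = rhs(np.maximum(x + 0.5 * dt * k1, 0.0), p)
        k3 = rhs(np.maximum(x + 0.5 * dt * k2, 0.0), p)
        k4 = rhs(np.maximum(x + dt * k3, 0.0), p)
        x = x + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.all(np.isfinite(x)):
            raise IntegrationError(f"non-finite state at step {i} (t={times[i]:g})")
        if np.any(x < 0):
            clamped = True
            x = np.maximum(x, 0.0)
        states[i] = x
    if clamped:
        warnings.warn("trajectory clamped at zero after negative overshoot", RuntimeWarning)
        logger.warning("RK4 trajectory clamped at zero")
    return Trajectory(times=times, states=states)


def is_bistable(p: TAParams, n_points: int = 3000) -> bool:
    """True iff the model has at least two stable fixed points.

    Marginal points (eigenvalue real part within ``MARGINAL_EIGENVALUE`` of
    zero) are excluded from the count.
    """
    fps = enumerate_fixed_points(p, n_points=n_points)
    return sum(1 for f in fps if f.klass == "stable") >= 2


def dilution_rate_ratio(p: TAParams, fps: list[FixedPoint] | None = None) -> float:
    """Fold-change of the toxin dilution rate between the two stable states.

    Returns phi_g(freeT at the low-T stable state) / phi_g(freeT at the
    high-T stable state) = ((1 + k_g t_high)/(1 + k_g t_low))^2 >= 1, the
    generation-time contrast between growth and dormancy.  Requires a
    bistable parameter set.
    """
    if fps is None:
        fps = enumerate_fixed_points(p)
    stable = [f for f in fps if f.klass == "stable"]
    if len(stable) < 2:
        raise InvalidInputError("dilution_rate_ratio requires a bistable parameter set")
    # the growing state is the stable point with the fastest growth, i.e.
    # the least free toxin (identical to the low-T_tot state in the
    # physiological regime)
    t_low = min(f.freeT for f in stable)
    t_high = max(f.freeT for f in stable)
    return float(growth_factor(t_low, p.k_g) / growth_factor(t_high, p.k_g))
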