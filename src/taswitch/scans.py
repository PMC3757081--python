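"""Parameter-space exploration of the growth-feedback operon model.

Three kinds of scan reproduce the model's robustness analysis:

* a (k_tl, k_g) state diagram of bistability with the generation-time
  contrast of the dormant state,
* a production-ratio scan (beta_A/beta_T held at various values),
* seeded Monte-Carlo robustness scans in which one parameter is pinned at
  a fold of its reference value while the remaining ones are drawn
  uniformly from a discrete two-fold ladder {reference * 2^k, k = -3..3}.

The ensemble sampler doubles as the package's synthetic-data generator:
the model is purely parameter-driven, so a seeded parameter ensemble plays
the role that simulated reads or counts play in data-driven pipelines.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .equilibrium import InvalidInputError
from .tamodel import TAParams, dilution_rate_ratio, enumerate_fixed_points

__all__ = [
    "SAMPLEABLE",
    "SampleSpec",
    "sample_parameter_sets",
    "state_diagram",
    "sigma_scan",
    "robustness_scan",
    "kd_scan",
]

#: Parameters that may be randomised.  The toxin production and dilution
#: rates are the unit conventions (both 1) and stay fixed.
SAMPLEABLE = ("beta_A", "Gamma_A", "K_D", "K1", "K2", "k_tl", "k_g")


@dataclass(frozen=True)
class SampleSpec:
    """A seeded discrete-fold parameter ensemble.

    Each free parameter is drawn independently and uniformly from
    {reference * 2^k : k in fold_exponents}; the default exponents -3..3
    span 1/8x to 8x.  ``continuous`` switches to log-uniform sampling over
    the same span (a sensitivity-check dialect).
    """

    reference: TAParams = field(default_factory=TAParams)
    free_names: tuple[str, ...] = SAMPLEABLE
    fold_exponents: tuple[int, ...] = (-3, -2, -1, 0, 1, 2, 3)
    n_samples: int = 1000
    seed: int = 0
    continuous: bool = False

    def __post_init__(self) -> None:
        if not self.free_names:
            raise InvalidInputError("free_names must be non-empty")
        unknown = [n for n in self.free_names if n not in SAMPLEABLE]
        if unknown:
            raise InvalidInputError(
                f"unknown parameter name(s) {unknown}; sampleable: {SAMPLEABLE}"
            )
        if self.n_samples < 1:
            raise InvalidInputError("n_samples must be >= 1")


def sample_parameter_sets(spec: SampleSpec) -> list[TAParams]:
    """Draw the parameter ensemble described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    folds = 2.0 ** np.asarray(spec.fold_exponents, dtype=float)
    lo, hi = float(np.min(folds)), float(np.max(folds))
    out = []
    for _ in range(spec.n_samples):
        kw = {}
        for name in spec.free_names:
            ref = getattr(spec.reference, name)
            if spec.continuous:
                f = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                f = float(rng.choice(folds))
            kw[name] = ref * f
        out.append(replace(spec.reference, **kw))
    return out


def _classify(p: TAParams) -> tuple[bool, float | None, int]:
    fps = enumerate_fixed_points(p)
    stable = [f for f in fps if f.klass == "stable"]
    bistable = len(stable) >= 2
    contrast = dilution_rate_ratio(p, fps) if bistable else None
    return bistable, contrast, len(fps)


def state_diagram(
    p_base: TAParams,
    ktl_grid: np.ndarray,
    kg_grid: np.ndarray,
) -> pd.DataFrame:
    """Bistability flag and dilution-rate contrast over a (k_tl, k_g) grid."""
    ktl_grid = np.asarray(ktl_grid, dtype=float)
    kg_grid = np.asarray(kg_grid, dtype=float)
    if np.any(ktl_grid < 0) or np.any(kg_grid < 0):
        raise InvalidInputError("feedback grids must be non-negative")
    rows = []
    for ktl in ktl_grid:
        for kg in kg_grid:
            p = replace(p_base, k_tl=float(ktl), k_g=float(kg))
            bistable, contrast, n_fp = _classify(p)
            rows.append(
                {
                    "k_tl": float(ktl),
                    "k_g": float(kg),
                    "bistable": bistable,
                    "contrast": contrast,
                    "n_fixed_points": n_fp,
                }
            )
    return pd.DataFrame(rows)


def sigma_scan(
    p_base: TAParams,
    ratios,
    ktl_grid: np.ndarray,
    kg_grid: np.ndarray,
) -> dict[float, pd.DataFrame]:
    """State diagrams for several production ratios sigma = beta_A/beta_T.

    beta_A is set to ratio * beta_T with beta_T at its reference value.
    Ratios below 10 are computed but flagged with a warning: the antitoxin
    is degraded ten times faster than the toxin is diluted, so smaller
    ratios cannot sustain an antitoxin-dominated state.
    """
    import warnings

    out = {}
    for ratio in ratios:
        if ratio < 10:
            warnings.warn(
                f"production ratio {ratio} < 10: antitoxin domination is not "
                "expected (antitoxin degradation is 10x the toxin dilution)",
                RuntimeWarning,
                stacklevel=2,
            )
        p = replace(p_base, beta_A=float(ratio) * p_base.beta_T)
        out[float(ratio)] = state_diagram(p, ktl_grid, kg_grid)
    return out


def _cell_seed(seed: int, swept_name: str, fold_exponent: float, extra: str = "") -> int:
    """Deterministic per-cell child seed (stable across processes)."""
    tag = f"{swept_name}:{fold_exponent:.6g}:{extra}".encode()
    return int((seed + zlib.crc32(tag)) % (2**31))


def robustness_scan(
    spec: SampleSpec,
    swept_name: str,
    swept_folds=( -3, -2, -1, 0, 1, 2, 3),
) -> pd.DataFrame:
    """Bistable fraction as one parameter is stepped across two-fold values.

    For each fold 2^j of ``swept_name`` the remaining free parameters are
    sampled per ``spec`` (with a per-cell child seed) and classified; the
    returned table carries the fraction and the sample count so a binomial
    error is computable.
    """
    if swept_name not in SAMPLEABLE:
        raise InvalidInputError(f"unknown swept parameter {swept_name!r}")
    if swept_name in spec.free_names:
        raise InvalidInputError(f"swept parameter {swept_name!r} must not be in free_names")
    rows = []
    for j in swept_folds:
        value = getattr(spec.reference, swept_name) * 2.0 ** float(j)
        cell = replace(
            spec,
            reference=replace(spec.reference, **{swept_name: value}),
            seed=_cell_seed(spec.seed, swept_name, float(j)),
        )
        ensemble = sample_parameter_sets(cell)
        n_bi = sum(_classify(p)[0] for p in ensemble)
        rows.append(
            {
                "swept_name": swept_name,
                "fold_exponent": float(j),
                "value": value,
                "fraction_bistable": n_bi / len(ensemble),
                "n_samples": len(ensemble),
            }
        )
    return pd.DataFrame(rows)


#: Parameters held at reference in the dissociation-constant scan: the two
#: feedback strengths plus the antitoxin production rate (the concentrations
#: interacting with the dissociation constants are pinned).
KD_SCAN_FIXED = ("k_tl", "k_g", "beta_A")


def kd_scan(
    spec: SampleSpec,
    folds=(1, 2, 4, 8, 16, 32, 64),
    fixed_names: tuple[str, ...] = KD_SCAN_FIXED,
) -> pd.DataFrame:
    """Bistable fraction as K1 = K2 are raised together from reference.

    For each fold the binding constants are multiplied jointly; the
    parameters in ``fixed_names`` stay at reference and the rest of the
    sampleable set is drawn as in :func:`robustness_scan`.
    """
    if any(f < 1 for f in folds):
        raise InvalidInputError("folds must be >= 1")
    free = tuple(
        n for n in SAMPLEABLE if n not in fixed_names and n not in ("K1", "K2")
    )
    rows = []
    for fold in folds:
        ref = replace(
            spec.reference,
            K1=spec.reference.K1 * float(fold),
            K2=spec.reference.K2 * float(fold),
        )
        cell = replace(
            spec,
            reference=ref,
            free_names=free,
            seed=_cell_seed(spec.seed, "K1K2", float(fold), "kd"),
        )
        ensemble = sample_parameter_sets(cell)
        n_bi = sum(_classify(p)[0] for p in ensemble)
        rows.append(
            {
                "fold": float(fold),
                "K1": ref.K1,
                "K2": ref.K2,
                "fraction_bistable": n_bi / len(ensemble),
                "n_samples": len(ensemble),
            }
        )
    return pd.DataFrame(rows)
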