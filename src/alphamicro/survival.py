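"""Survival functionals over nucleus dose distributions and the
calibration of the microdosimetric slope alpha_z from the experimental
slope alpha_D.

Survival is purely exponential, S(D) = exp(-alpha D): the quadratic term
of the linear-quadratic model is deliberately omitted, which is adequate
for the high-LET, low-dose regime this package targets.  Because the
exponential is convex, averaging it over a dose distribution with positive
variance always predicts *higher* survival than the mean dose does — hence
alpha_z >= alpha_D (Jensen), with equality only in the q -> 0 limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .microdose import DoseDistribution, analytic_ndd

__all__ = [
    "SurvivalModel",
    "CellCollection",
    "FitProblem",
    "survival_from_ndd",
    "collection_survival",
    "fit_alpha_d",
    "fit_alpha_z",
]

_S_FLOOR = 1e-300  # avoid log underflow for absurdly steep slopes


@dataclass
class SurvivalModel:
    alpha_d: float  # experimental slope per absorbed dose (1/Gy)
    alpha_z: Optional[float] = None  # microdosimetric slope (1/Gy)
    sigma_alpha_d: Optional[float] = None
    sigma_alpha_z: Optional[float] = None


@dataclass
class CellCollection:
    """M cells, each contributing its own single-hit distribution."""

    shndds: Sequence[DoseDistribution]

    def __post_init__(self) -> None:
        self.shndds = list(self.shndds)
        if not self.shndds:
            raise ValueError("collection must contain at least one cell")

    @property
    def m(self) -> int:
        return len(self.shndds)

    @property
    def q_values(self) -> np.ndarray:
        return np.array([f.mean for f in self.shndds])


@dataclass
class FitProblem:
    """Inputs of the alpha_z calibration: the absorbed doses used in the
    survival experiment, the cell collection, and the measured alpha_D."""

    doses: np.ndarray
    collection: CellCollection
    alpha_d: float
    sigma_alpha_d: float = 0.0
    tail_tol: float = 1e-9
    _ndd_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.size == 0 or np.any(~np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("doses must be positive and finite")
        self.doses = d
        if self.alpha_d <= 0:
            raise ValueError("alpha_d must be positive")

    def ndds(self, dose: float):
        """NDD of every cell at this absorbed dose (cached: the NDD does
        not depend on alpha_z)."""
        if dose not in self._ndd_cache:
            self._ndd_cache[dose] = [
                analytic_ndd(f, dose, self.tail_tol) for f in self.collection.shndds
            ]
        return self._ndd_cache[dose]


def survival_from_ndd(ndd: DoseDistribution, alpha_z: float) -> float:
    """S = zero_mass + integral f(z) exp(-alpha_z z) dz over the NDD."""
    if alpha_z < 0:
        raise ValueError("alpha_z must be non-negative")
    return max(ndd.laplace(alpha_z), _S_FLOOR)


def collection_survival(collection: CellCollection, zbar: float, alpha_z: float,
                        tail_tol: float = 1e-9) -> float:
    """Mean survival over the collection, each cell's NDD built from its
    own SHNDD at absorbed dose zbar."""
    vals = [
        survival_from_ndd(analytic_ndd(f, zbar, tail_tol), alpha_z)
        for f in collection.shndds
    ]
    return float(np.mean(vals))


def fit_alpha_d(doses, survival_fractions) -> tuple[float, float]:
    """Least-squares slope of ln S = -alpha_D D through the origin.

    Returns (alpha_d, sigma) with sigma from the fit covariance; sigma is
    nan for a single point.
    """
    d = np.asarray(doses, dtype=float)
    s = np.asarray(survival_fractions, dtype=float)
    if d.shape != s.shape or d.size < 1:
        raise ValueError("need matching, non-empty dose and survival arrays")
    if np.any(s <= 0) or np.any(s > 1 + 1e-9):
        raise ValueError("survival fractions must lie in (0, 1]")
    y = -np.log(s)
    denom = float(np.sum(d * d))
    alpha = float(np.sum(d * y) / denom)
    if d.size < 2:
        return alpha, float("nan")
    resid = y - alpha * d
    sigma = float(np.sqrt(np.sum(resid**2) / (d.size - 1) / denom))
    return alpha, sigma


def _fit_alpha_z_for(problem: FitProblem, alpha_d: float) -> float:
    surv = {}
    for dj in problem.doses:
        surv[dj] = problem.ndds(dj)

    def objective(alpha_z: float) -> float:
        tot = 0.0
        for dj in problem.doses:
            s = np.mean([max(n.laplace(alpha_z), _S_FLOOR) for n in surv[dj]])
            tot += (alpha_d * dj + np.log(s)) ** 2
        return tot

    res = minimize_scalar(
        objective,
        bounds=(alpha_d, 20.0 * alpha_d),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(
            f"alpha_z optimization failed on [{alpha_d:g}, {20 * alpha_d:g}]: "
            f"residual {res.fun:g}"
        )
    return float(res.x)


def fit_alpha_z(problem: FitProblem) -> tuple[float, float]:
    """Solve min_{alpha_z} sum_j (alpha_D D_j + ln S_z^C(D_j))^2 by bounded
    scalar optimization on [alpha_D, 20 alpha_D].

    The uncertainty propagates the alpha_D error through the numerically
    evaluated derivative d(alpha_z)/d(alpha_D) (central difference).
    """
    alpha_z = _fit_alpha_z_for(problem, problem.alpha_d)
    sigma = 0.0
    if problem.sigma_alpha_d:
        h = 1e-3 * problem.alpha_d
        hi = _fit_alpha_z_for(problem, problem.alpha_d + h)
        lo = _fit_alpha_z_for(problem, problem.alpha_d - h)
        sigma = abs((hi - lo) / (2 * h)) * problem.sigma_alpha_d
    return alpha_z, float(sigma)
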