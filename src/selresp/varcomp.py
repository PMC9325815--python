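"""Variance components and derived inference.

Holds REML variance-component estimates with their average-information
(AI) covariance, the long-term ratio

    rho = sigma2_g / (sigma2_g + sigma2_gy),

its delta-method standard error, and asymptotic correlations between
component estimates read off the inverse AI matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "rho_from_components",
    "se_rho_delta",
    "asymptotic_correlation",
]


@dataclass
class VarianceComponents:
    """REML variance-component estimates.

    Attributes
    ----------
    names : list of str
        Component labels (random terms first, residual groups last).
    values : ndarray
        Estimates, all >= 0 (REML non-negativity constraint).
    std_errors : ndarray
        Standard errors from the inverse AI matrix; NaN where the
        component was held fixed or pinned at the zero boundary.
    ai_inverse : DataFrame or None
        Covariance matrix of the *estimated* components (labels = the
        free, non-boundary components).
    fixed : set
        Components held fixed during estimation.
    boundary : set
        Components whose estimate lies at the zero boundary (SE
        unreliable there).
    """

    names: list
    values: np.ndarray
    std_errors: np.ndarray | None = None
    ai_inverse: pd.DataFrame | None = None
    fixed: set = field(default_factory=set)
    boundary: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("variance components must be non-negative")
        if self.std_errors is None:
            self.std_errors = np.full(len(self.names), np.nan)
        self.std_errors = np.asarray(self.std_errors, dtype=float)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name="estimate")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.values,
                "se": self.std_errors,
                "fixed": [n in self.fixed for n in self.names],
                "boundary": [n in self.boundary for n in self.names],
            },
            index=self.names,
        )

    def covariance_block(self, names) -> np.ndarray:
        if self.ai_inverse is None:
            raise ValueError("no AI covariance available (all components fixed?)")
        missing = [n for n in names if n not in self.ai_inverse.index]
        if missing:
            raise KeyError(f"components {missing} have no AI covariance "
                           "(fixed or at the boundary)")
        return self.ai_inverse.loc[list(names), list(names)].to_numpy()


def rho_from_components(sigma2_g: float, sigma2_gy: float) -> float:
    """Fraction of apparent genomic variance due to the GBV main effect."""
    if sigma2_g < 0 or sigma2_gy < 0:
        raise ValueError("variances must be non-negative")
    total = sigma2_g + sigma2_gy
    if total <= 0:
        raise ValueError("rho undefined: sigma2_g + sigma2_gy must be positive")
    return sigma2_g / total


def se_rho_delta(sigma2_g: float, sigma2_gy: float, cov: np.ndarray) -> float:
    """Delta-method standard error of rho.

    ``cov`` is the 2x2 covariance of (sigma2_g, sigma2_gy) estimates.  The
    gradient of rho is d = (sigma2_gy, -sigma2_g) / (sigma2_g + sigma2_gy)^2
    and SE(rho) = sqrt(d' V d).
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("cov must be 2x2")
    if abs(cov[0, 1] - cov[1, 0]) > 1e-8 * (1.0 + np.abs(cov).max()):
        raise ValueError("cov must be symmetric")
    eigmin = np.linalg.eigvalsh(0.5 * (cov + cov.T)).min()
    if eigmin < -1e-10 * max(1.0, np.abs(cov).max()):
        raise ValueError("cov must be positive semidefinite")
    total = sigma2_g + sigma2_gy
    if total <= 0:
        raise ValueError("rho undefined for zero total variance")
    d = np.array([sigma2_gy, -sigma2_g]) / total**2
    var = float(d @ cov @ d)
    return float(np.sqrt(max(var, 0.0)))


def asymptotic_correlation(
    components: VarianceComponents, term_a: str, term_b: str
) -> tuple[float, bool]:
    """Correlation between two component estimates from the inverse AI matrix.

    Returns ``(correlation, reliable)``.  When either estimate sits at the
    zero boundary (or its AI variance is zero) the correlation is reported
    as 0.0 with ``reliable=False``.
    """
    for t in (term_a, term_b):
        if t in components.fixed:
            raise ValueError(f"component {t!r} was held fixed; no sampling correlation")
    at_boundary = {term_a, term_b} & components.boundary
    if at_boundary:
        return 0.0, False
    v = components.covariance_block([term_a, term_b])
    if v[0, 0] <= 0 or v[1, 1] <= 0:
        return 0.0, False
    return float(v[0, 1] / np.sqrt(v[0, 0] * v[1, 1])), True
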