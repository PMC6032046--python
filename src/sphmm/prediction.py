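"""Power and discovery projection for future GWAS.

Given a fitted mixture (pi, g) on a pruned SNP set, the probability that
SNP j reaches significance at two-sided level p_c in a future study is

    P_j = (1 - pi) * Power_j(0) + pi * sum_k p_k * Power_j(b_k),

where Power_j(b) is the two-sided rejection probability of the Wald
statistic with mean b / sqrt(v*_j), and v*_j is the current variance
rescaled by the ratio of summed inverse case/control sizes — the empirical
variance of a log-OR estimate is approximately proportional to
1/n_cases + 1/n_controls.  The predicted count among m* independent SNPs
is K = m* x mean_j P_j.  Because only the sum of inverse sizes matters,
curves are indexed by the effective number of cases
n_e* = 2 / (1/n_r* + 1/n_s*), the balanced-design equivalent size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .core import SphmmFit

__all__ = [
    "PredictionConfig",
    "DiscoveryCurve",
    "rejection_threshold",
    "power",
    "rescale_variance",
    "effective_cases",
    "rejection_probability",
    "predict_num_significant",
    "discovery_curve",
    "required_effective_cases",
]

GENOME_WIDE_SIGNIFICANT = 5e-8
GENOME_WIDE_SUGGESTIVE = 1e-6


@dataclass
class PredictionConfig:
    """Significance level, target SNP count, and current/future sizes."""

    n_r: int
    n_s: int
    n_r_star: int
    n_s_star: int
    p_c: float = GENOME_WIDE_SIGNIFICANT
    m_star: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 < self.p_c < 1.0):
            raise ValueError("p_c must lie in (0, 1)")
        for name in ("n_r", "n_s", "n_r_star", "n_s_star"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.m_star < 1:
            raise ValueError("m_star must be >= 1")


@dataclass
class DiscoveryCurve:
    """Predicted significant-SNP count versus effective number of cases."""

    n_e_star: np.ndarray
    k_hat: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.n_e_star = np.asarray(self.n_e_star, float)
        self.k_hat = np.asarray(self.k_hat, float)
        if np.any(np.diff(self.n_e_star) <= 0):
            raise ValueError("n_e_star must be strictly increasing")
        if np.any(self.k_hat < 0):
            raise ValueError("k_hat must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        d = {"n_e_star": self.n_e_star, "k_hat": self.k_hat}
        if self.ci_low is not None:
            d["ci_low"] = self.ci_low
            d["ci_high"] = self.ci_high
        return pd.DataFrame(d)


def rejection_threshold(p_c: float) -> float:
    """Two-sided rejection threshold z_c = Phi^-1(1 - p_c / 2)."""
    if not (0.0 < p_c <= 1.0):
        raise ValueError("p_c must lie in (0, 1]")
    return float(stats.norm.isf(p_c / 2.0))


def power(beta, v, z_c: float):
    """Two-sided rejection probability of the Wald statistic.

    The statistic y / sqrt(v) is normal with mean beta / sqrt(v) and unit
    variance; the test rejects when it falls outside [-z_c, z_c].  At
    beta = 0 this returns the size of the test.
    """
    beta = np.asarray(beta, float)
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise ValueError("variance must be positive")
    mu = beta / np.sqrt(v)
    out = ndtr(-z_c - mu) + ndtr(mu - z_c)
    return out if out.ndim else float(out)


def rescale_variance(v, n_r: int, n_s: int, n_r_star: int, n_s_star: int):
    """Project an estimate variance to a study of different size.

    v* = v x (1/n_r* + 1/n_s*) / (1/n_r + 1/n_s).
    """
    for n in (n_r, n_s, n_r_star, n_s_star):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise ValueError("variance must be positive")
    out = v * (1.0 / n_r_star + 1.0 / n_s_star) / (1.0 / n_r + 1.0 / n_s)
    return out if out.ndim else float(out)


def effective_cases(n_r_star: int, n_s_star: int) -> float:
    """Effective number of cases n_e* = 2 / (1/n_r* + 1/n_s*).

    Equals N for a balanced n_r* = n_s* = N design; only this combination
    of the two sizes enters the predicted counts.
    """
    if n_r_star < 1 or n_s_star < 1:
        raise ValueError("sample sizes must be >= 1")
    return 2.0 / (1.0 / n_r_star + 1.0 / n_s_star)


def rejection_probability(v_star, fit: SphmmFit, z_c: float):
    """Per-SNP probability of significance under the fitted mixture.

    P = (1 - pi) * power(0) + pi * sum_k p_k * power(b_k); the integral
    over g is an exact finite sum because g is discrete.  Power is even in
    beta, so only unique |b_k| are evaluated.
    """
    v_star = np.atleast_1d(np.asarray(v_star, float))
    if np.any(v_star <= 0):
        raise ValueError("variance must be positive")
    p_null = power(0.0, v_star, z_c)
    pts = fit.g.grid.points
    abs_u, inv = np.unique(np.abs(pts), return_inverse=True)
    mu = abs_u[None, :] / np.sqrt(v_star)[:, None]  # (m, U)
    pow_u = ndtr(-z_c - mu) + ndtr(mu - z_c)
    p_nonnull = pow_u[:, inv] @ fit.g.masses
    out = (1.0 - fit.pi) * p_null + fit.pi * p_nonnull
    return out if out.size > 1 else float(out[0])


def predict_num_significant(fit: SphmmFit, data, cfg: PredictionConfig) -> float:
    """Predicted number of significant SNPs K = m* x mean_j P_j.

    ``data`` supplies the per-SNP variances of the set the model was
    fitted to; each is rescaled to the future sizes in ``cfg``.
    """
    z_c = rejection_threshold(cfg.p_c)
    v_star = rescale_variance(data.v, cfg.n_r, cfg.n_s, cfg.n_r_star, cfg.n_s_star)
    p_bar = float(np.mean(rejection_probability(v_star, fit, z_c)))
    return cfg.m_star * p_bar


def _k_hat_at_ne(fit: SphmmFit, v: np.ndarray, cfg: PredictionConfig, n_e_star) -> np.ndarray:
    """K evaluated on a vector of effective case numbers."""
    z_c = rejection_threshold(cfg.p_c)
    inv_cur = 1.0 / cfg.n_r + 1.0 / cfg.n_s
    out = np.empty(np.size(n_e_star))
    for i, ne in enumerate(np.atleast_1d(n_e_star)):
        v_star = v * (2.0 / ne) / inv_cur
        out[i] = cfg.m_star * float(np.mean(rejection_probability(v_star, fit, z_c)))
    return out


def discovery_curve(
    fit: SphmmFit,
    data,
    cfg: PredictionConfig,
    n_e_grid: Sequence[float],
    ci: tuple[np.ndarray, np.ndarray] | None = None,
) -> DiscoveryCurve:
    """K as a function of the effective number of cases.

    A balanced future design (n_r* = n_s* = n_e*) is assumed; unbalanced
    designs with the same n_e* give identical predictions.  ``ci``
    optionally attaches per-point (low, high) bands, e.g. from the
    parametric bootstrap.
    """
    n_e = np.asarray(list(n_e_grid), float)
    if np.any(np.diff(n_e) <= 0):
        raise ValueError("n_e_grid must be strictly increasing")
    k = _k_hat_at_ne(fit, np.asarray(data.v, float), cfg, n_e)
    low = high = None
    if ci is not None:
        low, high = (np.asarray(a, float) for a in ci)
    return DiscoveryCurve(n_e_star=n_e, k_hat=k, ci_low=low, ci_high=high)


def required_effective_cases(
    fit: SphmmFit,
    data,
    cfg: PredictionConfig,
    k_target: float,
    rounding_unit: int = 1000,
    ceiling: float = 1e7,
) -> int:
    """Smallest effective case number whose predicted count reaches ``k_target``.

    Bisection on the monotone curve to within one effective case, then
    rounded up to ``rounding_unit``.  If the target is unreachable below
    ``ceiling`` a warning is issued and the capped value returned.
    """
    if k_target < 0:
        raise ValueError("k_target must be nonnegative")
    v = np.asarray(data.v, float)
    lo, hi = 1.0, float(ceiling)
    if _k_hat_at_ne(fit, v, cfg, hi)[0] < k_target:
        warnings.warn(
            f"target of {k_target} significant SNPs not reachable below "
            f"n_e* = {ceiling:g}; returning the cap",
            RuntimeWarning,
            stacklevel=2,
        )
        return int(hi)
    if _k_hat_at_ne(fit, v, cfg, lo)[0] >= k_target:
        return int(rounding_unit)
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if _k_hat_at_ne(fit, v, cfg, mid)[0] >= k_target:
            hi = mid
        else:
            lo = mid
    return int(np.ceil(hi / rounding_unit) * rounding_unit)
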