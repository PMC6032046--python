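"""Parametric bootstrap for the fitted mixture.

New summary datasets are simulated from the estimated (pi, g) at the
original per-SNP variances, refitted, and the replicate estimates
summarised: the standard error of pi-hat as the replicate standard
deviation, and percentile confidence intervals for the predicted
significant-SNP count K.  Replicate refits are warm-started at the
original fit — standard practice for a parametric bootstrap and recorded
in the result metadata.  A master seed deterministically spawns one
stream per replicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EmConfig, SphmmFit, fit_em
from .prediction import PredictionConfig, predict_num_significant

__all__ = [
    "BootstrapResult",
    "simulate_from_fit",
    "bootstrap_pi_se",
    "bootstrap_k_ci",
]

log = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Replicate estimates and their summaries."""

    n_boot: int
    pi_replicates: np.ndarray
    pi_se: float
    seed: int
    k_replicates: np.ndarray | None = None
    k_ci: tuple[float, float] | None = None
    level: float | None = None
    n_failed: int = 0
    warm_start: bool = True

    def __post_init__(self) -> None:
        self.pi_replicates = np.asarray(self.pi_replicates, float)
        if self.pi_se < 0:
            raise ValueError("pi_se must be nonnegative")
        if self.k_ci is not None and self.k_ci[0] > self.k_ci[1]:
            raise ValueError("k_ci lower bound exceeds upper bound")

    def to_frame(self) -> pd.DataFrame:
        d = {"replicate": np.arange(1, len(self.pi_replicates) + 1), "pi_hat": self.pi_replicates}
        if self.k_replicates is not None:
            d["k_hat"] = self.k_replicates
        return pd.DataFrame(d)


def simulate_from_fit(
    fit: SphmmFit,
    variances: np.ndarray,
    seed,
    return_labels: bool = False,
):
    """Draw one synthetic estimate vector from the fitted mixture.

    Per SNP: non-null with probability pi; a non-null SNP's true effect is
    drawn from g, a null SNP's is 0; the observed Y is normal around the
    true effect with the SNP's variance.  Deterministic given ``seed``
    (an int or a numpy SeedSequence/Generator).
    """
    v = np.asarray(variances, float)
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    rng = np.random.default_rng(seed)
    m = v.size
    nonnull = rng.random(m) < fit.pi
    beta = np.zeros(m)
    n_nonnull = int(nonnull.sum())
    if n_nonnull:
        beta[nonnull] = rng.choice(fit.g.grid.points, size=n_nonnull, p=fit.g.masses)
    y = beta + np.sqrt(v) * rng.standard_normal(m)
    if return_labels:
        return y, nonnull
    return y


def percentile_ci(x: np.ndarray, level: float) -> tuple[float, float]:
    """Order-statistic percentile interval.

    With n replicates and tail mass a = (1 - level)/2 the bounds are the
    ceil(n a)-th smallest and ceil(n a)-th largest replicates (for
    n = 100, level 0.95: the 3rd and 98th smallest).
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    xs = np.sort(np.asarray(x, float))
    n = xs.size
    k = max(1, math.ceil(n * (1.0 - level) / 2.0))
    return float(xs[k - 1]), float(xs[n - k])


def _run_replicates(
    fit: SphmmFit,
    data,
    em_cfg: EmConfig,
    n_boot: int,
    seed: int,
    pred_cfg: PredictionConfig | None,
    include_count_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray | None, int]:
    v = np.asarray(data.v, float)
    children = np.random.SeedSequence(seed).spawn(n_boot)
    warm = [(fit.pi, fit.g.masses, "warm")]
    pi_reps: list[float] = []
    k_reps: list[float] = []
    n_failed = 0
    for b, child in enumerate(children):
        try:
            rng = np.random.default_rng(child)
            y_b = simulate_from_fit(fit, v, rng)
            refit = fit_em((y_b, v), em_cfg, starts=warm)
            pi_reps.append(refit.pi)
            if pred_cfg is not None:
                k_b = predict_num_significant(refit, data, pred_cfg)
                if include_count_noise:
                    # overlay the count's own sampling noise so the
                    # interval predicts an observed count, not just K
                    k_b = float(rng.poisson(k_b))
                k_reps.append(k_b)
        except (ValueError, FloatingPointError) as exc:  # pragma: no cover
            n_failed += 1
            log.warning("bootstrap replicate %d failed: %s", b, exc)
    if n_failed > 0.2 * n_boot:
        raise RuntimeError(f"{n_failed}/{n_boot} bootstrap replicates failed")
    return (
        np.array(pi_reps),
        np.array(k_reps) if pred_cfg is not None else None,
        n_failed,
    )


def bootstrap_pi_se(
    fit: SphmmFit,
    data,
    em_cfg: EmConfig | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """Standard error of pi-hat from ``n_boot`` simulate-and-refit cycles."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    em_cfg = em_cfg or EmConfig()
    pi_reps, _, n_failed = _run_replicates(fit, data, em_cfg, n_boot, seed, None)
    return BootstrapResult(
        n_boot=n_boot,
        pi_replicates=pi_reps,
        pi_se=float(np.std(pi_reps, ddof=1)),
        seed=seed,
        n_failed=n_failed,
    )


def bootstrap_k_ci(
    fit: SphmmFit,
    data,
    em_cfg: EmConfig | None = None,
    pred_cfg: PredictionConfig | None = None,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    include_count_noise: bool = False,
) -> BootstrapResult:
    """Percentile interval for the predicted count K.

    Each replicate is refitted and K recomputed under ``pred_cfg``; the
    interval is the order-statistic percentile interval at ``level``.
    With ``include_count_noise`` each replicate additionally draws the
    realised significant-SNP count around its K, turning the confidence
    interval for the expectation into a prediction interval for an
    observed count (the right object when comparing against the count
    actually seen in a validation study).
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if pred_cfg is None:
        raise ValueError("pred_cfg is required")
    em_cfg = em_cfg or EmConfig()
    pi_reps, k_reps, n_failed = _run_replicates(
        fit, data, em_cfg, n_boot, seed, pred_cfg, include_count_noise
    )
    return BootstrapResult(
        n_boot=n_boot,
        pi_replicates=pi_reps,
        pi_se=float(np.std(pi_reps, ddof=1)),
        seed=seed,
        k_replicates=k_reps,
        k_ci=percentile_ci(k_reps, level),
        level=level,
        n_failed=n_failed,
    )
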