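"""Bootstrap hypothesis testing, confidence intervals and rank-sum tests.

The central procedure is a mean-shifted bootstrap: the observed sample is
translated so its mean equals the null mean, resampled with replacement N
times (N = sample size) to form one bootstrap mean, and the process repeated
``n_boot`` times.  The p-value is the (add-one corrected) fraction of
bootstrap means at least as extreme as the observed mean, so it is never
exactly zero.  Multiple comparisons are handled by Bonferroni correction of
the significance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BootstrapResult",
    "bootstrap_p",
    "bonferroni_alpha",
    "percentile_ci",
    "ranksum",
    "significance_report",
]

_SIDES = ("two_sided", "greater", "less")


@dataclass(frozen=True)
class BootstrapResult:
    p_value: float
    observed_mean: float
    h0_mean: float
    n_boot: int
    side: str
    degenerate: bool = False


def _boot_means(sample: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    n = sample.size
    idx = rng.integers(0, n, size=(n_boot, n))
    return sample[idx].mean(axis=1)


def bootstrap_p(
    sample,
    h0_mean: float,
    n_boot: int = 10000,
    side: str = "two_sided",
    seed: int = 0,
) -> BootstrapResult:
    """Mean-shifted bootstrap test of ``mean(sample) == h0_mean``.

    ``side`` is ``"two_sided"`` (default), ``"greater"`` (H1: mean > h0) or
    ``"less"``.  The p-value has an add-one correction, so its floor is
    ``1/(n_boot+1)``.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least 2 observations")
    if side not in _SIDES:
        raise ValueError(f"side must be one of {_SIDES}")
    obs = float(sample.mean())
    if np.ptp(sample) == 0.0 and obs == h0_mean:
        return BootstrapResult(1.0, obs, h0_mean, n_boot, side, degenerate=True)
    null_sample = sample - obs + h0_mean
    means = _boot_means(null_sample, n_boot, np.random.default_rng(seed))
    if side == "greater":
        extreme = means >= obs
    elif side == "less":
        extreme = means <= obs
    else:
        extreme = np.abs(means - h0_mean) >= abs(obs - h0_mean)
    p = (1.0 + int(extreme.sum())) / (n_boot + 1.0)
    return BootstrapResult(float(p), obs, float(h0_mean), n_boot, side)


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test significance level ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def percentile_ci(
    sample, level: float = 0.95, n_boot: int = 10000, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of the sample mean."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(sample) == 0.0:
        c = float(sample[0])
        return (c, c)
    means = _boot_means(sample, n_boot, np.random.default_rng(seed))
    lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
    return (float(lo), float(hi))


def ranksum(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (tie-corrected); returns (U of sample_a, p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def significance_report(
    samples: dict,
    h0_means: dict,
    alpha: float = 0.05,
    n_boot: int = 10000,
    side: str = "two_sided",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-element bootstrap tests with a shared Bonferroni-corrected alpha.

    ``samples`` maps element -> 1d sample; ``h0_means`` maps element -> null
    mean (e.g. 0 for Shapley contributions, the intact mean for lesioned
    performance distributions).
    """
    alpha_c = bonferroni_alpha(alpha, len(samples))
    rows = []
    for k, (e, s) in enumerate(samples.items()):
        res = bootstrap_p(s, h0_means[e], n_boot=n_boot, side=side, seed=seed + k)
        rows.append(
            {
                "element": str(e),
                "statistic": res.observed_mean,
                "h0_mean": res.h0_mean,
                "p": res.p_value,
                "alpha_corrected": alpha_c,
                "significant": bool(res.p_value < alpha_c),
            }
        )
    return pd.DataFrame(rows)
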