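"""Small bootstrap helpers shared by the reproducibility and forest analyses."""

from __future__ import annotations

import numpy as np

__all__ = ["bootstrap_mean_ci", "bootstrap_p_mean_less", "cis_overlap"]


def bootstrap_mean_ci(x, n_boot: int = 2000, alpha: float = 0.05,
                      seed: int = 0) -> tuple[float, float, float]:
    """(mean, lo, hi): percentile bootstrap CI of the mean."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(x.mean()), float(lo), float(hi)


def bootstrap_p_mean_less(x, y, n_boot: int = 2000, seed: int = 0) -> float:
    """One-sided paired bootstrap p-value for mean(x) < mean(y).

    Resamples the paired differences d = y - x; the p-value is the fraction
    of bootstrap means that are <= 0 (evidence against mean(d) > 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be non-empty and paired")
    d = y - x
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_boot, d.size))
    means = d[idx].mean(axis=1)
    return float((means <= 0).mean())


def cis_overlap(ci_a: tuple[float, float], ci_b: tuple[float, float]) -> bool:
    """Whether two intervals (lo, hi) intersect."""
    return ci_a[0] <= ci_b[1] and ci_b[0] <= ci_a[1]
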