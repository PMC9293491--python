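"""Independent brute-force oracles used across the test modules.

``naive_threshold`` re-derives the optimal threshold from first
principles: for every admissible split it recomputes class
probabilities, means and variances by direct O(K) summation, forms the
separability criterion eta = sigma_C^2 / sigma_E^2, and averages the
tied argmax set.  It shares no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def naive_class_stats(q: np.ndarray, t: int) -> dict:
    """Direct two-pass class statistics for the split at level t (1-based)."""
    levels = np.arange(1, len(q) + 1, dtype=float)
    w0 = q[:t].sum()
    w1 = q[t:].sum()
    mu0 = float((levels[:t] * q[:t]).sum() / w0)
    mu1 = float((levels[t:] * q[t:]).sum() / w1)
    var0 = float(((levels[:t] - mu0) ** 2 * q[:t]).sum() / w0)
    var1 = float(((levels[t:] - mu1) ** 2 * q[t:]).sum() / w1)
    mu_e = float((levels * q).sum())
    sigma_v2 = w0 * var0 + w1 * var1
    sigma_c2 = w0 * (mu0 - mu_e) ** 2 + w1 * (mu1 - mu_e) ** 2
    sigma_e2 = float(((levels - mu_e) ** 2 * q).sum())
    return dict(
        w0=float(w0), w1=float(w1), mu0=mu0, mu1=mu1, var0=var0, var1=var1,
        mu_e=mu_e, sigma_v2=sigma_v2, sigma_c2=sigma_c2, sigma_e2=sigma_e2,
    )


def naive_threshold(counts) -> tuple[float, dict]:
    """Brute-force argmax of eta over all admissible splits, ties averaged.

    Returns (t_star, {t: sigma_c2}).
    """
    counts = np.asarray(counts, dtype=float)
    q = counts / counts.sum()
    curve = {}
    for t in range(1, len(q)):
        if q[:t].sum() == 0.0 or q[t:].sum() == 0.0:
            continue
        cs = naive_class_stats(q, t)
        curve[t] = cs["sigma_c2"] / cs["sigma_e2"]  # eta; same argmax
    peak = max(curve.values())
    tied = [t for t, v in curve.items() if v >= peak - 1e-12 * abs(peak)]
    return float(np.mean(tied)), curve


def random_histogram(rng: np.random.Generator, k_max: int = 32) -> np.ndarray:
    """Random counts with at least two occupied levels."""
    while True:
        k = int(rng.integers(2, k_max + 1))
        counts = rng.integers(0, 50, size=k)
        if np.count_nonzero(counts) >= 2:
            return counts
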