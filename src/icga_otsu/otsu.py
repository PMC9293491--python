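"""Histogram thresholding by between-class variance maximization (Otsu's method).

The algorithm operates on a grayscale histogram with levels indexed
``1..K``.  A candidate threshold ``t`` splits the levels into a low class
B0 (levels ``1..t``) and a high class B1 (levels ``t+1..K``).  The optimal
threshold maximizes the between-class variance

    sigma_C^2(t) = omega0 (mu0 - mu_E)^2 + omega1 (mu1 - mu_E)^2
                 = (mu_E * omega(t) - mu(t))^2 / (omega(t) (1 - omega(t)))

where ``omega(t)`` and ``mu(t)`` are the zero- and first-order cumulative
sums of the normalized histogram and ``mu_E`` is the global mean level.
Maximizing ``sigma_C^2`` is equivalent to maximizing the separability
criterion ``eta = sigma_C^2 / sigma_E^2`` because the total variance
``sigma_E^2`` does not depend on ``t``.  Exact ties on the maximum are
resolved by averaging the tied thresholds, so the selected threshold is
real-valued.

Levels are 1-based throughout this module; the adapter mapping raster
intensities ``v`` in ``[0, 2^bits - 1]`` to levels ``i = v + 1`` lives in
:mod:`icga_otsu.image`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DegenerateHistogramError",
    "DegenerateSplitError",
    "ConstantImageError",
    "GrayHistogram",
    "NormalizedHistogram",
    "CumulativeMoments",
    "ClassStatistics",
    "VarianceDecomposition",
    "ThresholdResult",
    "normalize_histogram",
    "cumulative_moments",
    "class_statistics",
    "variance_decomposition",
    "between_class_variance_fast",
    "select_threshold",
]

# relative tolerance for declaring two between-class variances an exact tie
_TIE_RTOL = 1e-12


class DegenerateHistogramError(ValueError):
    """Raised for a histogram with no mass (total count zero)."""


class DegenerateSplitError(ValueError):
    """Raised for a threshold that leaves one class empty."""


class ConstantImageError(ValueError):
    """Raised when every pixel shares one gray level, so no split exists.

    Attributes
    ----------
    level : int
        The single occupied 1-based gray level.
    """

    def __init__(self, level: int):
        self.level = int(level)
        super().__init__(
            f"constant image: all mass at gray level {self.level}; no threshold exists"
        )


@dataclass(frozen=True)
class GrayHistogram:
    """Per-level pixel counts ``a_i`` for 1-based gray levels ``i = 1..K``.

    ``counts[0]`` is the count of level 1.  ``K`` must be at least 2; counts
    must be non-negative integers.
    """

    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("histogram needs a 1-D array of counts with K >= 2 levels")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("histogram counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_levels(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        """Total pixel count A."""
        return int(self.counts.sum())


@dataclass(frozen=True)
class NormalizedHistogram:
    """Probability distribution ``q_i = a_i / A`` over gray levels."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=np.float64)
        if q.ndim != 1 or q.size < 2:
            raise ValueError("normalized histogram must be 1-D with K >= 2 levels")
        if np.any(q < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(float(q.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        object.__setattr__(self, "q", q)

    @property
    def n_levels(self) -> int:
        return int(self.q.size)


@dataclass(frozen=True)
class CumulativeMoments:
    """Zero- and first-order cumulative sums of a normalized histogram.

    ``omega[t-1] = sum_{i<=t} q_i`` and ``mu[t-1] = sum_{i<=t} i q_i`` for
    ``t = 1..K``; ``mu_e = mu[K-1]`` is the global mean gray level.
    """

    omega: np.ndarray
    mu: np.ndarray
    mu_e: float

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=np.float64)
        mu = np.asarray(self.mu, dtype=np.float64)
        if omega.shape != mu.shape or omega.ndim != 1:
            raise ValueError("omega and mu must be 1-D arrays of equal length")
        if np.any(np.diff(omega) < -1e-15):
            raise ValueError("omega must be non-decreasing")
        if abs(float(omega[-1]) - 1.0) > 1e-12:
            raise ValueError("omega(K) must equal 1 within 1e-12")
        if abs(float(mu[-1]) - float(self.mu_e)) > 1e-12:
            raise ValueError("mu(K) must equal the global mean within 1e-12")
        object.__setattr__(self, "omega", omega)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "mu_e", float(self.mu_e))


@dataclass(frozen=True)
class ClassStatistics:
    """Probabilities, means and variances of the two classes at threshold t."""

    t: int
    omega0: float
    omega1: float
    mu0: float
    mu1: float
    var0: float
    var1: float


@dataclass(frozen=True)
class VarianceDecomposition:
    """Within/between/total variance at a threshold and the three criteria.

    ``sigma_v2 + sigma_c2 = sigma_e2`` holds identically; the criteria are
    ``lambda_ = sigma_c2/sigma_v2``, ``kappa = sigma_e2/sigma_v2`` and
    ``eta = sigma_c2/sigma_e2``.  When the within-class variance vanishes
    (two point masses) ``lambda_`` and ``kappa`` are reported as ``inf``.
    """

    t: int
    sigma_v2: float
    sigma_c2: float
    sigma_e2: float
    lambda_: float
    kappa: float
    eta: float


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of threshold selection.

    ``t_star`` is the arithmetic mean of all tied maximizers of the
    between-class variance and is therefore real-valued.  ``admissible_t``
    and ``curve`` give sigma_C^2(t) over every admissible split;
    ``eta_at_star`` is the separability criterion evaluated at the
    admissible integer threshold nearest to ``t_star``.
    """

    t_star: float
    admissible_t: np.ndarray
    curve: np.ndarray
    tied_levels: np.ndarray
    eta_at_star: float
    sigma_e2: float


def normalize_histogram(h: GrayHistogram) -> NormalizedHistogram:
    """Convert raw counts to the probability distribution q_i = a_i / A."""
    total = h.total
    if total <= 0:
        raise DegenerateHistogramError("histogram is empty (total count A = 0)")
    return NormalizedHistogram(h.counts / total)


def cumulative_moments(q: NormalizedHistogram) -> CumulativeMoments:
    """Cumulative sums omega(t), mu(t) for t = 1..K and the global mean.

    Accumulation runs in extended precision so the endpoint identities
    omega(K) = 1 and mu(K) = mu_E hold to the construction tolerance.
    """
    probs = q.q.astype(np.longdouble)
    levels = np.arange(1, q.n_levels + 1, dtype=np.longdouble)
    omega = np.cumsum(probs)
    mu = np.cumsum(levels * probs)
    # renormalize away the accumulated rounding at the endpoint
    omega = omega / omega[-1]
    return CumulativeMoments(
        omega=omega.astype(np.float64),
        mu=mu.astype(np.float64),
        mu_e=float(mu[-1]),
    )


def _check_admissible(q: NormalizedHistogram, t: int) -> None:
    k = q.n_levels
    if not 1 <= t < k:
        raise DegenerateSplitError(f"threshold t={t} outside 1..{k - 1}")
    if q.q[:t].sum() == 0.0 or q.q[t:].sum() == 0.0:
        raise DegenerateSplitError(f"threshold t={t} leaves an empty class")


def class_statistics(
    q: NormalizedHistogram, m: CumulativeMoments, t: int
) -> ClassStatistics:
    """Class probabilities, means and variances for the split at level t.

    The low class B0 holds levels ``1..t`` with probability
    ``omega0 = omega(t)`` and mean ``mu0 = mu(t)/omega(t)``; the high class
    B1 holds ``t+1..K``.  The mixture identities
    ``omega0 + omega1 = 1`` and ``omega0 mu0 + omega1 mu1 = mu_E`` hold by
    construction.
    """
    _check_admissible(q, t)
    omega0 = float(m.omega[t - 1])
    omega1 = 1.0 - omega0
    mu0 = float(m.mu[t - 1]) / omega0
    mu1 = (m.mu_e - float(m.mu[t - 1])) / omega1
    levels = np.arange(1, q.n_levels + 1, dtype=np.float64)
    var0 = float(np.sum((levels[:t] - mu0) ** 2 * q.q[:t]) / omega0)
    var1 = float(np.sum((levels[t:] - mu1) ** 2 * q.q[t:]) / omega1)
    return ClassStatistics(
        t=t, omega0=omega0, omega1=omega1, mu0=mu0, mu1=mu1, var0=var0, var1=var1
    )


def variance_decomposition(
    q: NormalizedHistogram, m: CumulativeMoments, t: int
) -> VarianceDecomposition:
    """Within-, between- and total variance at threshold t plus the criteria.

    Raises :class:`ConstantImageError` when the total variance is zero, in
    which case no separability criterion is defined.
    """
    cs = class_statistics(q, m, t)
    sigma_v2 = cs.omega0 * cs.var0 + cs.omega1 * cs.var1
    sigma_c2 = cs.omega0 * (cs.mu0 - m.mu_e) ** 2 + cs.omega1 * (cs.mu1 - m.mu_e) ** 2
    levels = np.arange(1, q.n_levels + 1, dtype=np.float64)
    sigma_e2 = float(np.sum((levels - m.mu_e) ** 2 * q.q))
    if sigma_e2 == 0.0:
        raise ConstantImageError(int(np.argmax(q.q)) + 1)
    if sigma_v2 > 0.0:
        lambda_ = sigma_c2 / sigma_v2
        kappa = sigma_e2 / sigma_v2
    else:
        lambda_ = np.inf
        kappa = np.inf
    return VarianceDecomposition(
        t=t,
        sigma_v2=float(sigma_v2),
        sigma_c2=float(sigma_c2),
        sigma_e2=sigma_e2,
        lambda_=float(lambda_),
        kappa=float(kappa),
        eta=float(sigma_c2 / sigma_e2),
    )


def between_class_variance_fast(m: CumulativeMoments, t: int) -> float:
    """sigma_C^2(t) from the cumulative sums alone.

    Evaluates ``(mu_E omega(t) - mu(t))^2 / (omega(t)(1 - omega(t)))``,
    algebraically identical to the two-term mixture form but requiring only
    the cumulative moments.
    """
    omega_t = float(m.omega[t - 1])
    denom = omega_t * (1.0 - omega_t)
    if denom <= 0.0:
        raise DegenerateSplitError(f"threshold t={t} leaves an empty class")
    num = m.mu_e * omega_t - float(m.mu[t - 1])
    return num * num / denom


def select_threshold(h: GrayHistogram) -> ThresholdResult:
    """Select the threshold maximizing the between-class variance.

    Evaluates sigma_C^2(t) over every admissible split (both classes
    non-empty), takes the argmax, and averages exact ties (relative
    tolerance 1e-12) into a real-valued ``t_star``.

    Raises :class:`ConstantImageError` if fewer than two levels are
    occupied.
    """
    q = normalize_histogram(h)
    m = cumulative_moments(q)
    occupied = np.flatnonzero(h.counts > 0)
    if occupied.size < 2:
        raise ConstantImageError(int(occupied[0]) + 1)

    # admissible t: at least one occupied level on each side
    lo = int(occupied[0]) + 1  # first t with mass below the cut
    hi = int(occupied[-1])     # last t with mass above the cut
    ts = np.arange(lo, hi + 1)

    omega_t = m.omega[ts - 1]
    mu_t = m.mu[ts - 1]
    curve = (m.mu_e * omega_t - mu_t) ** 2 / (omega_t * (1.0 - omega_t))

    peak = float(curve.max())
    tied = ts[np.isclose(curve, peak, rtol=_TIE_RTOL, atol=0.0)]
    t_star = float(tied.mean())

    t_nearest = int(ts[np.argmin(np.abs(ts - t_star))])
    vd = variance_decomposition(q, m, t_nearest)
    return ThresholdResult(
        t_star=t_star,
        admissible_t=ts,
        curve=curve,
        tied_levels=tied,
        eta_at_star=vd.eta,
        sigma_e2=vd.sigma_e2,
    )
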