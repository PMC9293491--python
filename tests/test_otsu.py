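"""Histogram-threshold mathematics: exact examples, identities, oracle parity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from icga_otsu.otsu import (
    ConstantImageError,
    CumulativeMoments,
    DegenerateHistogramError,
    DegenerateSplitError,
    GrayHistogram,
    between_class_variance_fast,
    class_statistics,
    cumulative_moments,
    normalize_histogram,
    select_threshold,
    variance_decomposition,
)

from helpers import naive_class_stats, naive_threshold, random_histogram


def prep(counts):
    q = normalize_histogram(GrayHistogram(np.asarray(counts)))
    return q, cumulative_moments(q)


# strategy: counts with at least two occupied levels
histograms = st.lists(st.integers(0, 50), min_size=2, max_size=32).filter(
    lambda c: sum(1 for x in c if x > 0) >= 2
)


@pytest.mark.parametrize(
    "counts, expected_q",
    [
        ([2, 2], [0.5, 0.5]),
        ([10, 0, 0, 0], [1.0, 0.0, 0.0, 0.0]),
        ([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4]),
    ],
)
def test_normalization_divides_by_total(counts, expected_q):
    q = normalize_histogram(GrayHistogram(np.asarray(counts)))
    np.testing.assert_allclose(q.q, expected_q, atol=1e-15)
    assert abs(q.q.sum() - 1.0) < 1e-12


def test_empty_histogram_is_degenerate():
    with pytest.raises(DegenerateHistogramError):
        normalize_histogram(GrayHistogram(np.array([0, 0, 0])))


@pytest.mark.parametrize(
    "counts, omega, mu, mu_e",
    [
        ([1, 1], [0.5, 1.0], [0.5, 1.5], 1.5),
        ([1, 0, 0, 0], [1, 1, 1, 1], [1, 1, 1, 1], 1.0),
        ([1, 2, 3, 4], None, None, 3.0),  # mu_E = 0.1 + 0.4 + 0.9 + 1.6
    ],
)
def test_cumulative_moments_examples(counts, omega, mu, mu_e):
    _, m = prep(counts)
    if omega is not None:
        np.testing.assert_allclose(m.omega, omega, atol=1e-12)
        np.testing.assert_allclose(m.mu, mu, atol=1e-12)
    assert m.mu_e == pytest.approx(mu_e, abs=1e-12)


def test_class_statistics_point_masses():
    q, m = prep([1, 1])
    cs = class_statistics(q, m, 1)
    assert cs.omega0 == pytest.approx(0.5)
    assert (cs.mu0, cs.mu1) == (pytest.approx(1.0), pytest.approx(2.0))
    assert cs.var0 == cs.var1 == 0.0


@pytest.mark.parametrize(
    "counts, t, omega0, mu0, mu1",
    [
        ([1, 1, 1, 1], 2, 0.5, 1.5, 3.5),
        ([1, 2, 3, 4], 2, 0.3, 5.0 / 3.0, None),
    ],
)
def test_class_statistics_hand_values(counts, t, omega0, mu0, mu1):
    q, m = prep(counts)
    cs = class_statistics(q, m, t)
    assert cs.omega0 == pytest.approx(omega0, abs=1e-12)
    assert cs.mu0 == pytest.approx(mu0, abs=1e-12)
    if mu1 is not None:
        assert cs.mu1 == pytest.approx(mu1, abs=1e-12)


def test_inadmissible_split_raises():
    q, m = prep([0, 5, 5])
    with pytest.raises(DegenerateSplitError):
        class_statistics(q, m, 1)  # low class empty
    with pytest.raises(DegenerateSplitError):
        class_statistics(q, m, 3)  # t out of range
    with pytest.raises(DegenerateSplitError):
        between_class_variance_fast(m, 1)


def test_variance_decomposition_two_point_masses():
    # two point masses at levels 1 and 2, mu_E = 1.5: between-class
    # variance 0.25, zero within-class variance, eta = 1
    q, m = prep([1, 1])
    vd = variance_decomposition(q, m, 1)
    assert vd.sigma_c2 == pytest.approx(0.25, abs=1e-12)
    assert vd.sigma_v2 == 0.0
    assert vd.sigma_e2 == pytest.approx(0.25, abs=1e-12)
    assert vd.eta == pytest.approx(1.0, abs=1e-12)
    assert np.isinf(vd.lambda_) and np.isinf(vd.kappa)
    assert between_class_variance_fast(m, 1) == pytest.approx(0.25, abs=1e-12)


def test_constant_image_has_no_criteria():
    with pytest.raises(ConstantImageError) as exc:
        select_threshold(GrayHistogram(np.array([0, 0, 7, 0])))
    assert exc.value.level == 3


def test_eta_matches_independent_two_pass_summation():
    q, m = prep([1, 1, 1, 1])
    vd = variance_decomposition(q, m, 2)
    ref = naive_class_stats(q.q, 2)
    assert vd.eta == pytest.approx(ref["sigma_c2"] / ref["sigma_e2"], abs=1e-12)


@pytest.mark.parametrize(
    "counts, t_star",
    [
        ([5, 0, 0, 5], 2.0),          # plateau over t in {1,2,3}, averaged
        ([50, 0, 0, 0, 0, 0, 0, 50], 4.0),  # symmetric bimodal, ties 1..7
    ],
)
def test_tie_averaging(counts, t_star):
    oracle_t, _ = naive_threshold(counts)
    assert oracle_t == t_star  # the frozen value agrees with brute force
    res = select_threshold(GrayHistogram(np.asarray(counts)))
    assert res.t_star == t_star
    np.testing.assert_allclose(res.curve, res.curve[0], rtol=1e-12)


@given(histograms)
def test_identities_and_oracle_parity(counts):
    """Conservation, mixture identity, fast-form parity, oracle argmax."""
    counts = np.asarray(counts)
    q, m = prep(counts)
    for t in range(1, len(counts)):
        if q.q[:t].sum() == 0.0 or q.q[t:].sum() == 0.0:
            continue
        cs = class_statistics(q, m, t)
        assert cs.omega0 + cs.omega1 == pytest.approx(1.0, abs=1e-12)
        assert cs.omega0 * cs.mu0 + cs.omega1 * cs.mu1 == pytest.approx(
            m.mu_e, abs=1e-9
        )
        vd = variance_decomposition(q, m, t)
        assert vd.sigma_v2 + vd.sigma_c2 == pytest.approx(
            vd.sigma_e2, rel=1e-9, abs=1e-12
        )
        assert between_class_variance_fast(m, t) == pytest.approx(
            vd.sigma_c2, rel=1e-9, abs=1e-12
        )
    res = select_threshold(GrayHistogram(counts))
    oracle_t, _ = naive_threshold(counts)
    assert res.t_star == pytest.approx(oracle_t, abs=1e-9)


@given(histograms, st.integers(2, 7))
def test_scale_invariance(counts, factor):
    """Multiplying all counts by a constant leaves the threshold unchanged."""
    base = select_threshold(GrayHistogram(np.asarray(counts)))
    scaled = select_threshold(GrayHistogram(np.asarray(counts) * factor))
    assert scaled.t_star == pytest.approx(base.t_star, abs=1e-9)


def test_criterion_equivalence(rng):
    """argmax of lambda, eta and sigma_C^2 coincide when sigma_V^2 > 0."""
    for _ in range(200):
        counts = random_histogram(rng, k_max=16)
        q, m = prep(counts)
        rows = []
        for t in range(1, len(counts)):
            if q.q[:t].sum() == 0.0 or q.q[t:].sum() == 0.0:
                continue
            vd = variance_decomposition(q, m, t)
            rows.append(vd)
        if any(v.sigma_v2 == 0.0 for v in rows):
            continue
        def argmax_set(key):
            vals = np.array([key(v) for v in rows])
            return {rows[i].t for i in np.flatnonzero(
                np.isclose(vals, vals.max(), rtol=1e-9, atol=0))}
        assert argmax_set(lambda v: v.sigma_c2) == argmax_set(lambda v: v.eta) \
            == argmax_set(lambda v: v.lambda_)


def test_moment_invariants_enforced():
    with pytest.raises(ValueError):
        CumulativeMoments(omega=np.array([0.5, 0.9]), mu=np.array([0.5, 1.4]), mu_e=1.4)
    with pytest.raises(ValueError):
        GrayHistogram(np.array([1, -1]))
    with pytest.raises(ValueError):
        GrayHistogram(np.array([3]))
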