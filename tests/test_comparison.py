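"""KS test, escort families, Hellinger distance and entropy scans."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from escorthist import (
    EscortParameters,
    ProbabilityHistogram,
    ProfileShape,
    beta_scan,
    classify_profile,
    entropy_difference,
    escort,
    hellinger,
    ks_compare,
    shannon_entropy,
)

from conftest import make_hist, random_histogram


def brute_force_ks(p: ProbabilityHistogram, q: ProbabilityHistogram) -> float:
    """Independent oracle: scan all 256 bins for the largest CDF gap."""
    best = 0.0
    for g in range(256):
        fp = sum(p.probs[h] for h in range(g + 1))
        fq = sum(q.probs[h] for h in range(g + 1))
        best = max(best, abs(fp - fq))
    return best


class TestKSCompare:
    def test_identical_histograms(self):
        h = make_hist({0: 0.5, 10: 0.5})
        res = ks_compare(h, h, 7, 7)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_opposite_point_masses(self):
        res = ks_compare(make_hist({0: 1.0}), make_hist({255: 1.0}), 10, 10)
        assert res.statistic == pytest.approx(1.0)

    def test_quarter_gap(self):
        p = make_hist({0: 0.5, 1: 0.5})
        q = make_hist({0: 0.25, 1: 0.75})
        res = ks_compare(p, q, 100, 100)
        assert res.statistic == pytest.approx(0.25)
        assert res.statistic == pytest.approx(brute_force_ks(p, q))

    def test_statistic_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            p = random_histogram(rng, k=int(rng.integers(1, 60)))
            q = random_histogram(rng, k=int(rng.integers(1, 60)))
            res = ks_compare(p, q, 5, 5)
            assert res.statistic == pytest.approx(brute_force_ks(p, q), abs=1e-12)

    def test_nonpositive_sizes_rejected(self):
        h = make_hist({0: 1.0})
        with pytest.raises(ValueError):
            ks_compare(h, h, 0, 5)

    def test_larger_n_eff_smaller_p(self):
        p = make_hist({0: 0.5, 1: 0.5})
        q = make_hist({0: 0.3, 1: 0.7})
        assert (
            ks_compare(p, q, 10000, 10000).p_value
            < ks_compare(p, q, 10, 10).p_value
        )


class TestEscort:
    def test_beta_one_identity(self, rng):
        h = random_histogram(rng, k=30)
        assert np.allclose(escort(h, 1.0).probs, h.probs, atol=1e-12)

    def test_beta_zero_uniform_on_support(self, rng):
        h = random_histogram(rng, k=17)
        e = escort(h, 0.0)
        assert np.allclose(e.probs[e.support], 1 / 17, atol=1e-12)
        assert np.array_equal(e.support, h.support)

    def test_hand_arithmetic_beta_two(self):
        e = escort(make_hist({0: 0.8, 1: 0.2}), 2.0)
        assert e.probs[0] == pytest.approx(16 / 17)
        assert e.probs[1] == pytest.approx(1 / 17)

    def test_overflow_reported(self):
        h = make_hist({0: 0.5, 1: 0.5})
        with pytest.raises(OverflowError, match="beta"):
            escort(h, 1e308 * 10)  # inf * ln p is not representable

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-3, 3, allow_nan=False),
        st.floats(-3, 3, allow_nan=False),
    )
    def test_composition_property(self, seed, a, b):
        """escort(escort(h, a), b) == escort(h, a*b) on a fixed support."""
        h = random_histogram(np.random.default_rng(seed), k=25)
        lhs = escort(escort(h, a), b)
        rhs = escort(h, a * b)
        assert np.allclose(lhs.probs, rhs.probs, atol=1e-9)


class TestHellinger:
    def test_identity(self, rng):
        h = random_histogram(rng, k=12)
        assert hellinger(h, h) == 0.0

    def test_disjoint_supports_maximal(self):
        assert hellinger(make_hist({0: 1.0}), make_hist({255: 1.0})) == pytest.approx(1.0)

    def test_closed_form(self):
        h = hellinger(make_hist({0: 1.0}), make_hist({0: 0.5, 1: 0.5}))
        assert h == pytest.approx(np.sqrt(1 - np.sqrt(2) / 2), abs=1e-12)
        assert h == pytest.approx(0.54120, abs=5e-6)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(30):
            p, q, r = (random_histogram(rng, k=9) for _ in range(3))
            assert hellinger(p, q) == pytest.approx(hellinger(q, p), abs=1e-12)
            assert hellinger(p, p) == 0.0
            assert hellinger(p, r) <= hellinger(p, q) + hellinger(q, r) + 1e-9

    def test_squared_diff_variant(self):
        p = make_hist({0: 1.0})
        q = make_hist({0: 0.5, 1: 0.5})
        assert hellinger(p, q, form="squared_diff") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hellinger(p, q, form="nonsense")


class TestEntropy:
    def test_point_mass_zero(self):
        assert shannon_entropy(make_hist({42: 1.0})) == 0.0

    def test_uniform_log_k(self):
        h = make_hist({g: 0.125 for g in range(0, 80, 10)})
        assert shannon_entropy(h) == pytest.approx(np.log(8), abs=1e-12)

    def test_hand_arithmetic(self):
        s = shannon_entropy(make_hist({0: 0.5, 1: 0.25, 2: 0.25}))
        assert s == pytest.approx(1.5 * np.log(2), abs=1e-12)

    def test_escort_entropy_bounds_max_at_zero(self, rng):
        h = random_histogram(rng, k=21)
        s0 = shannon_entropy(escort(h, 0.0))
        assert s0 == pytest.approx(np.log(21), abs=1e-9)
        for beta in (-3.0, -1.0, 0.5, 1.0, 2.0, 4.0):
            s = shannon_entropy(escort(h, beta))
            assert 0.0 <= s <= s0 + 1e-12


class TestEntropyDifference:
    def test_identical_inputs_zero(self, rng):
        h = random_histogram(rng, k=15)
        for beta in (-2.0, 0.0, 1.0, 3.0):
            assert entropy_difference(h, h, beta) == 0.0

    def test_equal_support_sizes_beta_zero(self, rng):
        p = random_histogram(rng, k=10)
        q = random_histogram(rng, k=10)
        assert entropy_difference(p, q, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_vs_point_mass(self):
        cells = make_hist({0: 0.25, 1: 0.25, 2: 0.25, 3: 0.25})
        control = make_hist({5: 1.0})
        assert entropy_difference(cells, control, 1.0) == pytest.approx(np.log(4))


class TestBetaScan:
    def test_grid_requires_zero_and_one(self):
        with pytest.raises(ValueError):
            EscortParameters(beta_grid=np.array([-1.0, 0.5, 2.0]))
        with pytest.raises(ValueError):
            EscortParameters(beta_grid=np.array([0.0, 0.0, 1.0]))

    def test_default_grid(self):
        grid = EscortParameters.default().beta_grid
        assert 0.0 in grid and 1.0 in grid
        assert np.all(np.diff(grid) > 0)
        assert grid[0] == -5.0 and grid[-1] == 5.0

    def test_anchor_facts(self, rng):
        """H vanishes at beta=0 for equal supports; H at beta=1 is the plain distance."""
        bins = rng.choice(256, size=20, replace=False)
        w1, w2 = rng.random(20) + 0.1, rng.random(20) + 0.1
        p = make_hist(dict(zip(bins.tolist(), (w1 / w1.sum()).tolist())))
        q = make_hist(dict(zip(bins.tolist(), (w2 / w2.sum()).tolist())))
        scan = beta_scan(p, q)
        i0 = np.flatnonzero(scan.beta == 0.0)[0]
        i1 = np.flatnonzero(scan.beta == 1.0)[0]
        assert scan.hellinger[i0] == pytest.approx(0.0, abs=1e-9)
        assert scan.hellinger[i1] == hellinger(p, q)  # bit-for-bit
        assert np.all((scan.hellinger >= 0) & (scan.hellinger <= 1))

    def test_identical_inputs_flat_zero(self, rng):
        h = random_histogram(rng, k=14)
        scan = beta_scan(h, h)
        assert np.all(scan.hellinger == 0.0)
        assert np.all(scan.delta_entropy == 0.0)

    def test_labels_propagated_and_tsv(self, tmp_path, rng):
        import pandas as pd

        p, q = random_histogram(rng, k=6), random_histogram(rng, k=6)
        scan = beta_scan(p, q, labels={"staining": "M", "channel": "red"})
        assert scan.labels == {"staining": "M", "channel": "red"}
        scan.to_tsv(tmp_path / "scan.tsv")
        df = pd.read_csv(tmp_path / "scan.tsv", sep="\t")
        assert np.allclose(df["hellinger"].to_numpy(), scan.hellinger)


class TestClassifyProfile:
    def test_monotonic_growth(self):
        c = classify_profile([0, 1, 2, 3], [0.0, 0.1, 0.2, 0.3])
        assert c.shape is ProfileShape.MONOTONIC_GROWTH

    def test_flat(self):
        c = classify_profile([0, 1, 2], [0.5, 0.5, 0.5])
        assert c.shape is ProfileShape.FLAT

    def test_non_monotonic_with_argmax(self):
        c = classify_profile([-1.0, 0.5, 1.0], [0.0, 0.3, 0.1])
        assert c.shape is ProfileShape.NON_MONOTONIC
        assert c.argmax_beta == 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            classify_profile([0, 1], [0.1, 0.2])
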