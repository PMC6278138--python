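import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ordhom import (
    CumulativeDistribution,
    OrdinalDistribution,
    ValidationError,
    block,
    di_uniform,
    divergence_index,
    uniform,
)
from conftest import compositions, proportion_vectors


def bimodal(n: int) -> OrdinalDistribution:
    p = np.zeros(n)
    p[0] = p[-1] = 0.5
    return OrdinalDistribution(p)


class TestAxioms:
    @pytest.mark.parametrize("cat", [1, 4, 10])
    def test_normalisation_zero_iff_singleton(self, cat):
        assert divergence_index(block(1, 10, start=cat)) == pytest.approx(0.0, abs=1e-12)

    @given(proportion_vectors())
    def test_positive_off_singleton(self, p):
        d = OrdinalDistribution(p)
        if np.max(d.proportions) < 1.0:
            assert divergence_index(d) > 0.0

    @pytest.mark.parametrize("s", [2, 4, 7])
    def test_exact_shift_invariance_blocks(self, s):
        vals = {divergence_index(block(s, 10, start=k)) for k in range(1, 10 - s + 2)}
        assert len({round(v, 15) for v in vals}) == 1

    @given(proportion_vectors(min_n=6, max_n=12), st.integers(1, 3))
    def test_exact_shift_invariance_general_patterns(self, p, shift):
        """Any pattern occupying the low categories keeps its DI when the
        whole pattern slides along the axis."""
        n = len(p)
        pattern = np.zeros(n)
        pattern[: n - shift] = p[: n - shift]
        if pattern.sum() <= 1e-9:
            return
        pattern /= pattern.sum()
        moved = np.roll(pattern, shift)
        assert divergence_index(OrdinalDistribution(pattern)) == pytest.approx(
            divergence_index(OrdinalDistribution(moved)), abs=1e-13
        )

    @given(proportion_vectors())
    def test_reflection_symmetry(self, p):
        d = OrdinalDistribution(p)
        assert divergence_index(d) == pytest.approx(
            divergence_index(d.reverse()), abs=1e-13
        )

    def test_median_preserving_spread_strictly_increases(self, rng):
        """Moving mass from (m-k, m+k) one step toward the extremes raises DI."""
        checked = 0
        for _ in range(500):
            n = int(rng.integers(5, 13))
            p = rng.dirichlet(np.ones(n))
            F = np.cumsum(p)
            m = int(np.searchsorted(F, 0.5)) + 1
            k = int(rng.integers(0, n))
            if m - k - 2 < 0 or m + k > n - 1:
                continue
            eps = 0.4 * min(p[m - k - 1], p[m + k - 1])
            if eps < 1e-9:
                continue
            q = p.copy()
            q[m - k - 1] -= eps
            q[m - k - 2] += eps
            q[m + k - 1] -= eps
            q[m + k] += eps
            assert divergence_index(OrdinalDistribution(q)) > divergence_index(
                OrdinalDistribution(p)
            )
            checked += 1
        assert checked > 50

    def test_maximised_by_half_at_each_end(self):
        """Over all compositions of 8 units into 10 bins the extremal
        half-at-each-end distribution uniquely maximises DI."""
        target = bimodal(10).proportions
        best_val, best_p = -1.0, None
        for p in compositions(8, 10):
            v = divergence_index(OrdinalDistribution(p))
            if v > best_val:
                best_val, best_p = v, p
        np.testing.assert_allclose(best_p, target)
        assert best_val == pytest.approx(divergence_index(bimodal(10)), abs=1e-12)

    @given(proportion_vectors())
    def test_bimodal_is_global_max(self, p):
        d = OrdinalDistribution(p)
        assert divergence_index(d) <= divergence_index(bimodal(d.n)) + 1e-12

    def test_translates_have_equal_di(self):
        """Same shape at different locations: equal spread, equal DI."""
        shape = np.array([0.2, 0.5, 0.3])
        for n in (6, 9):
            base = np.zeros(n)
            base[:3] = shape
            for off in range(1, n - 2):
                assert divergence_index(OrdinalDistribution(np.roll(base, off))) == (
                    pytest.approx(divergence_index(OrdinalDistribution(base)), abs=1e-13)
                )


class TestDiUniform:
    def test_definitional_identity(self):
        assert di_uniform(10) == pytest.approx(divergence_index(uniform(10)), abs=1e-15)

    @pytest.mark.parametrize("n", [3, 10])
    def test_between_singleton_and_bimodal(self, n):
        assert 0.0 < di_uniform(n) < divergence_index(bimodal(n))

    def test_reversal_of_uniform(self):
        assert divergence_index(uniform(10).reverse()) == pytest.approx(
            di_uniform(10), abs=1e-15
        )

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            di_uniform(2)


class TestCumulativeDistribution:
    def test_median_gaps(self):
        c = CumulativeDistribution(np.array([0.25, 0.5, 0.75, 1.0]))
        np.testing.assert_allclose(c.median_gaps(), [0.25, 0.5, 0.25])

    def test_rejects_decreasing(self):
        with pytest.raises(ValidationError):
            CumulativeDistribution(np.array([0.5, 0.4, 1.0]))

    def test_rejects_bad_terminal(self):
        with pytest.raises(ValidationError):
            CumulativeDistribution(np.array([0.2, 0.5, 0.9]))
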