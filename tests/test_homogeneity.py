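import numpy as np
import pytest
from hypothesis import given

from ordhom import (
    AreaRecord,
    OrdinalDistribution,
    ValidationError,
    assess,
    block,
    class_thresholds,
    classify,
    classify_dataset,
    homogeneity_index,
    uniform,
)
from conftest import proportion_vectors

# decile-scale guideline values (test-only regression constants)
HI4_10, HI5_10, HI6_10 = 68.53, 57.62, 46.62


class TestHomogeneityIndex:
    def test_uniform_zero(self):
        assert homogeneity_index(uniform(10)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n", [3, 6, 10, 15])
    def test_singleton_hundred(self, n):
        assert homogeneity_index(block(1, n)) == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize(
        "s, expected", [(4, HI4_10), (5, HI5_10), (6, HI6_10)]
    )
    def test_decile_block_guideline_values(self, s, expected):
        assert homogeneity_index(block(s, 10)) == pytest.approx(expected, abs=0.01)

    def test_strictly_decreasing_in_block_size(self):
        his = [homogeneity_index(block(s, 10)) for s in range(1, 11)]
        assert all(a > b for a, b in zip(his, his[1:]))

    @pytest.mark.parametrize("s", [2, 4, 7])
    def test_block_shift_invariance(self, s):
        vals = {
            round(homogeneity_index(block(s, 10, start=k)), 12)
            for k in range(1, 10 - s + 2)
        }
        assert len(vals) == 1

    @given(proportion_vectors())
    def test_bounds_and_reflection(self, p):
        d = OrdinalDistribution(p)
        hi = homogeneity_index(d)
        assert 0.0 <= hi <= 100.0
        assert hi == pytest.approx(homogeneity_index(d.reverse()), abs=1e-9)


class TestClassThresholds:
    def test_decile_values(self):
        th = class_thresholds(10)
        assert th.hi4 == pytest.approx(HI4_10, abs=0.01)
        assert th.hi5 == pytest.approx(HI5_10, abs=0.01)
        assert th.hi6 == pytest.approx(HI6_10, abs=0.01)

    @pytest.mark.parametrize("n", [6, 8, 10, 12, 20])
    def test_ordering_any_n(self, n):
        th = class_thresholds(n)
        assert 100.0 > th.hi4 > th.hi5 > th.hi6 >= 0.0

    def test_computed_from_blocks_not_hardcoded(self):
        th = class_thresholds(12)
        assert th.hi4 == pytest.approx(homogeneity_index(block(4, 12)), abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            class_thresholds(5)


class TestClassify:
    def test_boundary_block_is_class_a(self):
        # the A/B boundary is inclusive from above
        assert classify(block(4, 10)) == "A"

    def test_blocks_land_in_their_classes(self):
        assert classify(block(1, 10)) == "A"
        assert classify(block(5, 10)) == "B"
        assert classify(block(6, 10)) == "C"
        assert classify(uniform(10)) == "D"

    def test_partition_of_range(self):
        """Every HI value maps to exactly one class; boundaries explicit."""
        th = class_thresholds(10)
        from ordhom.homogeneity import _classify_value

        grid = np.concatenate(
            [
                np.linspace(0, 100, 2001),
                [th.hi4, th.hi5, th.hi6, 0.0, 100.0],
                np.nextafter([th.hi4, th.hi5, th.hi6], -np.inf),
            ]
        )
        for hi in grid:
            labels = [
                k
                for k, (lo, hi_b) in {
                    "A": (th.hi4, 100.0),
                    "B": (th.hi5, th.hi4),
                    "C": (th.hi6, th.hi5),
                    "D": (0.0, th.hi6),
                }.items()
                if (lo <= hi <= hi_b if k == "A" else lo <= hi < hi_b)
            ]
            assert len(labels) == 1
            assert _classify_value(float(hi), th) == labels[0]

    @given(proportion_vectors(min_n=6, max_n=12))
    def test_reflection_invariance(self, p):
        d = OrdinalDistribution(p)
        assert classify(d) == classify(d.reverse())

    def test_assess_consistency(self):
        r = assess(block(4, 10))
        assert r.klass == "A"
        assert r.s == pytest.approx(4.0, abs=1e-9)
        assert r.hi == pytest.approx(HI4_10, abs=0.01)


class TestClassifyDataset:
    def test_three_synthetic_areas(self):
        areas = [
            AreaRecord("U", uniform(10)),
            AreaRecord("B4", block(4, 10)),
            AreaRecord("S", block(1, 10)),
        ]
        res = classify_dataset(areas)
        counts = res.class_summary["count"]
        assert counts["A"] == 2 and counts["D"] == 1
        assert counts["B"] == 0 and counts["C"] == 0
        assert res.class_summary["percent"].sum() == pytest.approx(100.0, abs=0.01)
        assert res.table.loc["B4", "klass"] == "A"

    def test_duplicate_ids_rejected(self):
        areas = [AreaRecord("X", uniform(10)), AreaRecord("X", block(1, 10))]
        with pytest.raises(ValidationError):
            classify_dataset(areas)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            classify_dataset([])

    def test_percentages_rounded_two_decimals(self):
        areas = [AreaRecord(f"a{i}", uniform(10)) for i in range(3)]
        res = classify_dataset(areas)
        assert res.class_summary.loc["D", "percent"] == 100.0
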