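import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fosnet.connectivity import (
    CorrelationMatrix,
    collection_values,
    compare_group_r,
    correlation_matrix,
    offdiagonal_values,
)
from fosnet.counts import CountTable
from fosnet.errors import DegenerateVarianceError, FosnetError
from fosnet.scheme import RegionScheme
from fosnet.synthetic import generate_cohort, paperlike_config


def table_from_columns(scheme, group_columns):
    """Build a CountTable from {group: {region: [values...]}}."""
    rows, index = [], []
    for group, cols in group_columns.items():
        n = len(next(iter(cols.values())))
        for i in range(n):
            rows.append({"group": group, **{r: cols[r][i] for r in scheme.regions}})
            index.append(f"{group}{i}")
    frame = pd.DataFrame(rows, index=pd.Index(index, name="animal_id"))
    return CountTable(scheme=scheme, frame=frame)


@pytest.fixture
def two_region_scheme():
    return RegionScheme(("X", "Y"))


def _pair_table(scheme2, x, y, group="G"):
    return table_from_columns(scheme2, {group: {"X": x, "Y": y}})


class TestCorrelationMatrix:
    def test_hand_computed_r(self, two_region_scheme):
        # X=[1,2,3,4], Y=[2,1,4,3]: cov=1, sd_x=sd_y=sqrt(5/3) -> r=0.6
        t = _pair_table(two_region_scheme, [1, 2, 3, 4], [2, 1, 4, 3])
        m = correlation_matrix(t, "G")
        assert m.value("X", "Y") == pytest.approx(0.6, abs=1e-12)

    def test_antithetic(self, two_region_scheme):
        t = _pair_table(two_region_scheme, [1, 2, 5], [9, 8, 5])
        assert correlation_matrix(t, "G").value("X", "Y") == pytest.approx(-1.0)

    def test_positive_affine(self, two_region_scheme):
        x = [1.0, 4.0, 2.0, 9.0]
        t = _pair_table(two_region_scheme, x, [3 * v + 2 for v in x])
        assert correlation_matrix(t, "G").value("X", "Y") == pytest.approx(1.0)

    def test_diagonal_zeroed(self):
        t = generate_cohort(paperlike_config(8, seed=0))
        m = correlation_matrix(t, "2S")
        assert np.all(np.diag(m.r) == 0.0)
        assert np.allclose(m.r, m.r.T)

    def test_too_few_animals(self, two_region_scheme):
        t = _pair_table(two_region_scheme, [1, 2], [3, 4])
        with pytest.raises(FosnetError, match="at least 3"):
            correlation_matrix(t, "G")

    def test_zero_variance_region_named(self, two_region_scheme):
        t = _pair_table(two_region_scheme, [5, 5, 5], [1, 2, 3])
        with pytest.raises(DegenerateVarianceError, match="X"):
            correlation_matrix(t, "G")

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.1, 100.0),
        shift=st.floats(0.0, 50.0),  # counts must stay non-negative
    )
    def test_affine_rescale_invariance(self, scheme, scale, shift):
        t = generate_cohort(paperlike_config(8, seed=9))
        m1 = correlation_matrix(t, "2S")
        frame = t.frame.copy()
        frame["BLA"] = frame["BLA"] * scale + shift
        m2 = correlation_matrix(
            CountTable(scheme=scheme, frame=frame), "2S"
        )
        assert np.allclose(m1.r, m2.r, atol=1e-9)


class TestOffdiagonalValues:
    def test_66_values_for_12_regions(self):
        t = generate_cohort(paperlike_config(8, seed=0))
        assert len(offdiagonal_values(correlation_matrix(t, "NS"))) == 66

    def test_three_region_enumeration(self):
        regions = ("A", "B", "C")
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = 0.1
        r[0, 2] = r[2, 0] = 0.2
        r[1, 2] = r[2, 1] = 0.3
        m = CorrelationMatrix("g", regions, r, 5)
        assert list(offdiagonal_values(m)) == pytest.approx([0.1, 0.2, 0.3])

    def test_asymmetric_matrix_rejected(self):
        r = np.zeros((3, 3))
        r[1, 0] = 0.5  # lower triangle only
        with pytest.raises(FosnetError, match="symmetric"):
            CorrelationMatrix("g", ("A", "B", "C"), r, 5)

    @pytest.mark.parametrize("p", [2, 3, 5, 8, 12])
    def test_length_formula(self, p):
        regions = tuple(f"R{i}" for i in range(p))
        m = CorrelationMatrix("g", regions, np.zeros((p, p)), 4)
        assert len(offdiagonal_values(m)) == p * (p - 1) // 2


class TestCollectionValues:
    @pytest.fixture
    def matrix(self, scheme):
        t = generate_cohort(paperlike_config(8, seed=4))
        return correlation_matrix(t, "2S")

    def test_amyg_incident_count(self, matrix, scheme):
        # 1 within pair + 2 members x 10 outside regions = 21
        assert len(collection_values(matrix, scheme, "Amyg")) == 21

    def test_within_rule(self, matrix, scheme):
        vals = collection_values(matrix, scheme, "Amyg", rule="within")
        assert len(vals) == 1
        assert vals[0] == pytest.approx(matrix.value("BLA", "CeA"))

    def test_all_regions_collection_equals_offdiagonal(self, matrix, scheme):
        full = RegionScheme(scheme.regions, {"all12": scheme.regions})
        vals = collection_values(matrix, full, "all12")
        assert np.array_equal(np.sort(vals), np.sort(offdiagonal_values(matrix)))
        assert len(vals) == 66

    def test_singleton_collection(self, matrix, scheme):
        rest = tuple(r for r in scheme.regions if r != "RSC")
        single = RegionScheme(scheme.regions, {"one": ("RSC",), "rest": rest})
        assert len(collection_values(matrix, single, "one")) == 11

    def test_unknown_collection(self, matrix, scheme):
        with pytest.raises(KeyError):
            collection_values(matrix, scheme, "nope")


class TestCompareGroupR:
    def _matrices(self, seed=0):
        t = generate_cohort(paperlike_config(8, seed=seed))
        return [correlation_matrix(t, g) for g in t.groups]

    def test_identical_matrices_h_zero(self):
        m = self._matrices()[0]
        res = compare_group_r([m, m, m])
        assert res.omnibus.statistic == pytest.approx(0.0)
        assert res.pairwise == {}

    def test_fixture_separation(self, scheme):
        res = compare_group_r(self._matrices(seed=1), scheme)
        assert res.omnibus.p_value < 0.05
        assert res.medians["2S"] > res.medians["NS"]
        assert res.pairwise[("NS", "2S")].p_value < 0.05

    def test_complete_separation_u_zero(self):
        regions = ("A", "B", "C")

        def const_matrix(v, group):
            r = np.full((3, 3), v)
            np.fill_diagonal(r, 0.0)
            return CorrelationMatrix(group, regions, r, 5)

        low = const_matrix(0.1, "lo")
        m_lo = CorrelationMatrix(
            "lo", regions, np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]), 5
        )
        m_hi = CorrelationMatrix(
            "hi", regions, np.array([[0, 0.7, 0.8], [0.7, 0, 0.9], [0.8, 0.9, 0]]), 5
        )
        res = compare_group_r([m_lo, m_hi], alpha=1.1)
        assert res.pairwise[("lo", "hi")].statistic == 0.0

    def test_requires_two_matrices(self):
        with pytest.raises(FosnetError):
            compare_group_r(self._matrices()[:1])
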