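import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernakit.errors import ParameterError, UnknownIdError
from cernakit.trends import (
    TrendProfile,
    assign_genes,
    classify_profiles,
    enumerate_candidate_profiles,
    profile_significance,
    select_model_profiles,
)

from conftest import make_matrix


class TestEnumerateCandidates:
    def test_t4_c1_count(self):
        assert len(enumerate_candidate_profiles(4, 1)) == 26

    def test_t2_c1_exhaustive(self):
        assert enumerate_candidate_profiles(2, 1) == [(0, -1), (0, 1)]

    def test_t4_c2_count(self):
        assert len(enumerate_candidate_profiles(4, 2)) == 124

    def test_t_too_small(self):
        with pytest.raises(ParameterError):
            enumerate_candidate_profiles(1, 1)

    @settings(max_examples=20, deadline=None)
    @given(T=st.integers(2, 5), c=st.integers(1, 3))
    def test_count_formula(self, T, c):
        assert len(enumerate_candidate_profiles(T, c)) == (2 * c + 1) ** (T - 1) - 1

    def test_all_start_at_zero_and_bounded(self):
        for values in enumerate_candidate_profiles(4, 2):
            assert values[0] == 0
            assert all(abs(b - a) <= 2 for a, b in zip(values, values[1:]))


class TestSelectModelProfiles:
    def test_default_extremes(self):
        profiles = select_model_profiles(enumerate_candidate_profiles(4, 1), 20)
        assert profiles[0].values == (0, -1, -2, -3)
        assert profiles[19].values == (0, 1, 2, 3)
        assert [p.profile_id for p in profiles] == list(range(20))

    def test_identity_selection(self):
        cands = enumerate_candidate_profiles(4, 1)
        profiles = select_model_profiles(cands, len(cands))
        assert sorted(p.values for p in profiles) == sorted(cands)

    def test_m2_maximally_anticorrelated(self):
        profiles = select_model_profiles(enumerate_candidate_profiles(4, 1), 2)
        a = np.asarray(profiles[0].values, dtype=float)
        b = np.asarray(profiles[1].values, dtype=float)
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_m_too_large(self):
        with pytest.raises(ParameterError):
            select_model_profiles(enumerate_candidate_profiles(2, 1), 3)


@pytest.fixture
def model_profiles():
    return select_model_profiles(enumerate_candidate_profiles(4, 1), 20)


class TestAssignGenes:
    def test_monotone_increasing_distance_zero(self, design, model_profiles):
        expr = make_matrix({"g": [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]})
        result = assign_genes(expr, design, model_profiles)
        pid, dist = result.assignments["g"]
        assert pid == 19
        assert dist == pytest.approx(0.0, abs=1e-12)

    def test_constant_gene_unassigned(self, design, model_profiles):
        expr = make_matrix({"g": [5.0] * 12})
        result = assign_genes(expr, design, model_profiles)
        assert result.assignments == {}
        assert result.unassigned == ["g"]

    def test_offset_invariance(self, design, model_profiles):
        base = [0, 0, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        shifted = [v + 7 for v in base]
        expr = make_matrix({"a": base, "b": shifted})
        result = assign_genes(expr, design, model_profiles)
        assert result.assignments["a"][0] == result.assignments["b"][0]
        # the matching profile (0,1,0,0) is a candidate, so distance is 0
        assert result.assignments["a"][1] == pytest.approx(
            result.assignments["b"][1], abs=1e-12
        )

    def test_profile_length_mismatch(self, design):
        with pytest.raises(ParameterError):
            assign_genes(
                make_matrix({"g": [1.0] * 11 + [2.0]}),
                design,
                [TrendProfile(0, (0, 1))],
            )


class TestProfileSignificance:
    def test_conservation_single_gene(self, design, model_profiles):
        expr = make_matrix({"g": [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4]})
        assignment = assign_genes(expr, design, model_profiles)
        assignment = profile_significance(assignment, expr, design, model_profiles)
        assert sum(assignment.expected.values()) == pytest.approx(1.0, abs=1e-9)

    def test_enriched_profile_significant(self, design, model_profiles):
        rows = {
            f"g{i}": [1, 1, 1, 2, 2, 2, 4, 4, 4, 8, 8, 8] for i in range(20)
        }
        expr = make_matrix(rows)
        assignment = assign_genes(expr, design, model_profiles)
        assignment = profile_significance(assignment, expr, design, model_profiles)
        assert assignment.observed[19] == 20
        assert assignment.significant[19]

    def test_pure_noise_calibrated(self, design, model_profiles, rng):
        """Few profiles reach significance on structure-free genes."""
        n_sig = []
        for _ in range(3):
            rows = {f"g{i}": rng.uniform(1, 10, 12).tolist() for i in range(40)}
            expr = make_matrix(rows)
            assignment = assign_genes(expr, design, model_profiles)
            assignment = profile_significance(
                assignment, expr, design, model_profiles
            )
            n_sig.append(sum(assignment.significant.values()))
        assert np.mean(n_sig) <= 3

    def test_conservation_many_genes(self, design, model_profiles, rng):
        rows = {f"g{i}": rng.uniform(1, 10, 12).tolist() for i in range(25)}
        expr = make_matrix(rows)
        assignment = assign_genes(expr, design, model_profiles)
        assignment = profile_significance(assignment, expr, design, model_profiles)
        G = len(assignment.assignments)
        assert sum(assignment.observed.values()) == G
        assert sum(assignment.expected.values()) == pytest.approx(G, abs=1e-9)


class TestClassifyProfiles:
    def test_categories(self, model_profiles):
        labels = classify_profiles(model_profiles)
        assert labels[19] == "increasing"
        assert labels[0] == "decreasing"

    def test_net_zero_complex(self):
        profiles = [TrendProfile(0, (0, 1, 0, 0))]
        assert classify_profiles(profiles) == {0: "complex"}

    def test_unknown_id(self, model_profiles):
        with pytest.raises(UnknownIdError):
            classify_profiles(model_profiles, [99])

    def test_planted_monotone_extremes(self, design, model_profiles):
        expr = make_matrix(
            {
                "up": [1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 4, 4],
                "down": [4, 4, 4, 3, 3, 3, 2, 2, 2, 1, 1, 1],
            }
        )
        result = assign_genes(expr, design, model_profiles)
        assert result.assignments["up"][0] == 19
        assert result.assignments["down"][0] == 0
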