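import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernakit.errors import (
    DegenerateInputError,
    ParameterError,
    UnknownIdError,
)
from cernakit.graph import Triplet
from cernakit.io_core import LocalizationTable, TargetTable
from cernakit.network import (
    CeRNAPair,
    build_cerna_network,
    candidate_cerna_pairs,
    filter_mirna_cerna_pairs,
    hypergeom_sf,
    pearson_r,
    spearman_rho,
)

from conftest import make_matrix
from oracles import (
    hypergeom_tail_enumeration,
    hypergeom_tail_formula,
    naive_pearson,
    naive_spearman,
)


class TestSpearman:
    def test_strict_monotone_decreasing(self):
        assert spearman_rho([1, 2, 3, 4], [8, 6, 4, 2]) == -1.0

    def test_hand_value(self):
        assert spearman_rho([1, 2, 3], [2, 1, 3]) == pytest.approx(0.5, abs=1e-12)

    def test_tied_ranks_exact_negative(self):
        assert spearman_rho([1, 2, 2, 3], [3, 2, 2, 1]) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ParameterError):
            spearman_rho([1, 2], [1, 2, 3])


class TestPearson:
    def test_affine(self):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        assert pearson_r(x, 2 * x + 3) == 1.0
        assert pearson_r(x, -x) == -1.0

    def test_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(200):
            x = rng.uniform(size=12)
            y = rng.uniform(size=12)
            assert pearson_r(x, y) == pytest.approx(
                naive_pearson(x.tolist(), y.tolist()), abs=1e-10
            )
            assert spearman_rho(x, y) == pytest.approx(
                naive_spearman(x.tolist(), y.tolist()), abs=1e-10
            )


class TestHypergeomSF:
    def test_k_zero_is_one(self):
        assert hypergeom_sf(0, 3, 4, 10) == 1.0

    def test_forced_overlap(self):
        assert hypergeom_sf(5, 5, 5, 5) == 1.0

    def test_hand_enumeration_value(self):
        assert hypergeom_sf(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_inconsistent_counts(self):
        with pytest.raises(ParameterError):
            hypergeom_sf(3, 2, 5, 10)
        with pytest.raises(ParameterError):
            hypergeom_sf(1, 11, 5, 10)

    def test_monotone_in_k(self):
        values = [hypergeom_sf(k, 6, 7, 20) for k in range(0, 7)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_matches_formula_oracle_medium_n(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(1, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_sf(k, K, n, N) == pytest.approx(
                hypergeom_tail_formula(k, K, n, N), abs=1e-12
            )


def two_triplet_matrices():
    """Two planted triplets with perfect structure plus one decoy each."""
    up = [1, 1, 1, 4, 4, 4, 16, 16, 16, 64, 64, 64]
    down = up[::-1]
    flat_ish = [5, 6, 5, 6, 5, 6, 5, 6, 5, 6, 5, 6]
    mirna = make_matrix({"M1": up, "M2": [2 * v for v in up], "M3": flat_ish}, "miRNA")
    lnc = make_matrix({"L1": down, "L2": [3 * v for v in down], "L3": flat_ish}, "lncRNA")
    mrna = make_matrix({"G1": down, "G2": [5 * v for v in down], "G3": flat_ish}, "mRNA")
    return mirna, lnc, mrna


def target_table(pairs, target_class):
    rows = [
        {"mirna_id": m, "target_id": t, "target_class": target_class,
         "site_class": "6mer", "source": "seedmatch"}
        for m, t in pairs
    ]
    return TargetTable(pd.DataFrame(rows, columns=list(TargetTable.COLUMNS)))


class TestFilterMirnaCernaPairs:
    def test_planted_retained_decoy_dropped(self):
        mirna, lnc, _ = two_triplet_matrices()
        table = target_table([("M1", "L1"), ("M3", "L3"), ("M1", "L3")], "lncRNA")
        pairs = filter_mirna_cerna_pairs(table, mirna, lnc)
        assert [(p.mirna_id, p.partner_id) for p in pairs] == [("M1", "L1")]
        assert pairs[0].rho == -1.0

    def test_boundary_strict(self):
        mirna, lnc, _ = two_triplet_matrices()
        table = target_table([("M1", "L1")], "lncRNA")
        assert filter_mirna_cerna_pairs(table, mirna, lnc, threshold_neg=-1.0) == []

    def test_missing_id_raises(self):
        mirna, lnc, _ = two_triplet_matrices()
        table = target_table([("M9", "L1")], "lncRNA")
        with pytest.raises(UnknownIdError, match="M9"):
            filter_mirna_cerna_pairs(table, mirna, lnc)


class TestCandidatePairs:
    def _pairs(self, lnc_map, mrna_map):
        from cernakit.network import MirnaCeRNAPair

        lnc_pairs = [
            MirnaCeRNAPair(m, l, "lncRNA", -0.9)
            for l, ms in lnc_map.items() for m in ms
        ]
        mrna_pairs = [
            MirnaCeRNAPair(m, g, "mRNA", -0.9)
            for g, ms in mrna_map.items() for m in ms
        ]
        return candidate_cerna_pairs(lnc_pairs, mrna_pairs)

    def test_shared_set_and_counts(self):
        cands = self._pairs({"L": {"m1", "m2"}}, {"G": {"m2", "m3"}})
        (c,) = cands
        assert c.shared_mirnas == frozenset({"m2"})
        assert (c.k, c.K, c.n, c.N) == (1, 2, 2, 3)

    def test_disjoint_no_candidate(self):
        assert self._pairs({"L": {"m1"}}, {"G": {"m2"}}) == []

    def test_identical_partner_sets(self):
        (c,) = self._pairs({"L": {"m1", "m2", "m3"}}, {"G": {"m1", "m2", "m3"}})
        assert c.k == 3


class TestBuildCernaNetwork:
    def setup_method(self):
        self.mirna, self.lnc, self.mrna = two_triplet_matrices()
        self.loc = LocalizationTable({"L1": "Cytoplasm", "L2": "Cytoplasm"})

    def _candidates(self):
        from cernakit.network import MirnaCeRNAPair

        lnc_pairs = [
            MirnaCeRNAPair("M1", "L1", "lncRNA", -1.0),
            MirnaCeRNAPair("M2", "L2", "lncRNA", -1.0),
        ]
        # give the universe enough miRNAs that k=1 overlaps can be significant
        lnc_pairs += [
            MirnaCeRNAPair(f"MX{i}", "L2", "lncRNA", -0.9) for i in range(40)
        ]
        mrna_pairs = [
            MirnaCeRNAPair("M1", "G1", "mRNA", -1.0),
            MirnaCeRNAPair("M2", "G2", "mRNA", -1.0),
        ]
        return candidate_cerna_pairs(lnc_pairs, mrna_pairs)

    def test_planted_retained(self):
        result = build_cerna_network(
            self._candidates(), self.lnc, self.mrna, self.loc
        )
        assert Triplet("L1", "M1", "G1") in result.triplets

    def test_nucleus_excluded(self):
        loc = LocalizationTable({"L1": "Nucleus", "L2": "Cytoplasm"})
        result = build_cerna_network(self._candidates(), self.lnc, self.mrna, loc)
        assert all(t.lncrna != "L1" for t in result.triplets)

    def test_unlocalized_excluded_by_default_kept_with_flag(self):
        loc = LocalizationTable({"L2": "Cytoplasm"})
        dropped = build_cerna_network(self._candidates(), self.lnc, self.mrna, loc)
        assert all(t.lncrna != "L1" for t in dropped.triplets)
        kept = build_cerna_network(
            self._candidates(), self.lnc, self.mrna, loc, keep_unlocalized=True
        )
        assert any(t.lncrna == "L1" for t in kept.triplets)

    def test_forced_overlap_excluded(self):
        """k=1 with K=n=N=1 has p_sponge = 1 and never survives."""
        pair = CeRNAPair("L1", "G1", frozenset({"M1"}), K=1, n=1, N=1)
        result = build_cerna_network([pair], self.lnc, self.mrna, self.loc)
        assert result.retained_pairs == []
        assert result.funnel["sponge_gated"] == 0

    def test_two_shared_mirnas_two_triplets(self):
        lnc = make_matrix({"L1": [1, 1, 1, 4, 4, 4, 16, 16, 16, 64, 64, 64][::-1]},
                          "lncRNA")
        mrna = make_matrix({"G1": [2, 2, 2, 8, 8, 8, 32, 32, 32, 128, 128, 128][::-1]},
                           "mRNA")
        pair = CeRNAPair("L1", "G1", frozenset({"M1", "M2"}), K=2, n=2, N=40)
        result = build_cerna_network([pair], lnc, mrna, self.loc)
        assert len(result.triplets) == 2

    def test_funnel_monotone(self):
        result = build_cerna_network(self._candidates(), self.lnc, self.mrna, self.loc)
        f = result.funnel
        assert (
            f["candidate_pairs"] >= f["coexpression_gated"]
            >= f["sponge_gated"] >= f["localization_gated"]
        )


class TestHypergeomEnumerationProperty:
    @settings(max_examples=60, deadline=None)
    @given(
        N=st.integers(1, 9),
        data=st.data(),
    )
    def test_small_n_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert hypergeom_sf(k, K, n, N) == pytest.approx(
            hypergeom_tail_enumeration(k, K, n, N), abs=1e-12
        )
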