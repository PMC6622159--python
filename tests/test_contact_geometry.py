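import itertools

import numpy as np
import pytest
from scipy.stats import pearsonr, rankdata

from coevocontacts.contact_geometry import (
    DistanceMatrix,
    ReferenceMethod,
    contacts_fixed,
    contacts_matched,
    distance_correlation,
    distance_matrix,
    eligible_pairs,
    overlap_fraction,
    pair_distance,
    reference_point,
)

from conftest import make_chain, make_residue, random_structure

RM = ReferenceMethod


def dm_from_array(d, method=RM.CA):
    return DistanceMatrix(method=method, d=np.asarray(d, dtype=float))


class TestReferencePoints:
    def test_glycine_uses_ca_under_all_point_methods(self):
        r = make_residue(1, "G", {"N": (0, 1, 0), "CA": (1, 2, 3), "C": (1, 0, 0)})
        for m in (RM.CA, RM.CB, RM.SC_CENTER):
            assert np.allclose(reference_point(r, m), [1, 2, 3])

    def test_alanine_sc_center_is_cb(self):
        r = make_residue(1, "A", {"CA": (0, 0, 0), "CB": (1.0, 0.5, -0.5)})
        assert np.allclose(reference_point(r, RM.SC_CENTER), [1.0, 0.5, -0.5])

    def test_sc_center_is_unweighted_mean(self):
        r = make_residue(1, "S", {"CA": (5, 5, 5), "CB": (0, 0, 0), "OG": (2, 0, 0)})
        assert np.allclose(reference_point(r, RM.SC_CENTER), [1, 0, 0])

    def test_min_methods_have_no_point(self):
        r = make_residue(1, "A", {"CA": (0, 0, 0), "CB": (1, 0, 0)})
        with pytest.raises(ValueError):
            reference_point(r, RM.MIN_ALL)


class TestPairDistance:
    def test_single_atom_residues_agree_across_methods(self):
        a = make_residue(1, "G", {"CA": (0, 0, 0)})
        b = make_residue(2, "G", {"CA": (3, 4, 0)})
        for m in RM:
            assert pair_distance(a, b, m) == pytest.approx(5.0)

    def test_min_all_le_min_sc(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            s = random_structure(rng, L=2)
            a, b = s.residues
            assert pair_distance(a, b, RM.MIN_ALL) <= pair_distance(a, b, RM.MIN_SC) + 1e-12

    def test_min_distance_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = random_structure(rng, L=2)
            a, b = s.residues
            brute = min(
                np.linalg.norm(x.coords - y.coords)
                for x in a.atoms
                for y in b.atoms
            )
            assert pair_distance(a, b, RM.MIN_ALL) == pytest.approx(brute)


class TestDistanceMatrix:
    def test_three_residue_symmetric_zero_diagonal(self):
        s = make_chain([
            ("G", {"CA": (0, 0, 0)}),
            ("G", {"CA": (3, 0, 0)}),
            ("G", {"CA": (0, 4, 0)}),
        ])
        dm = distance_matrix(s, RM.CA)
        assert dm.d.shape == (3, 3)
        assert dm.d[0, 1] == pytest.approx(3) and dm.d[0, 2] == pytest.approx(4)
        assert dm.d[1, 2] == pytest.approx(5)

    @pytest.mark.parametrize("method", list(RM))
    def test_matches_naive_double_loop(self, method):
        rng = np.random.default_rng(2)
        s = random_structure(rng, L=7)
        dm = distance_matrix(s, method)
        for i in range(s.L):
            for j in range(i + 1, s.L):
                expect = pair_distance(s.residues[i], s.residues[j], method)
                assert dm.d[i, j] == pytest.approx(expect, abs=1e-9)

    def test_all_glycine_point_methods_coincide(self):
        rng = np.random.default_rng(3)
        s = make_chain([
            ("G", {"CA": rng.uniform(-5, 5, 3)}) for _ in range(5)
        ])
        ca = distance_matrix(s, RM.CA).d
        for m in (RM.CB, RM.SC_CENTER):
            assert np.allclose(distance_matrix(s, m).d, ca)

    def test_point_methods_obey_triangle_inequality(self):
        rng = np.random.default_rng(4)
        s = random_structure(rng, L=6)
        for m in (RM.CA, RM.CB, RM.SC_CENTER):
            d = distance_matrix(s, m).d
            for i, j, k in itertools.permutations(range(6), 3):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestContactsFixed:
    def test_cutoff_below_all_distances_gives_empty_map(self):
        d = np.full((30, 30), 50.0)
        np.fill_diagonal(d, 0)
        cm = contacts_fixed(dm_from_array(d), cutoff=8.0, min_sep=12)
        assert cm.pairs == frozenset()

    def test_boundary_pair_at_exact_cutoff_included(self):
        d = np.full((30, 30), 50.0)
        np.fill_diagonal(d, 0)
        d[0, 20] = d[20, 0] = 8.0
        cm = contacts_fixed(dm_from_array(d), cutoff=8.0, min_sep=12)
        assert cm.pairs == frozenset({(1, 21)})

    def test_min_sep_is_inclusive_at_twelve(self):
        # pair (1, 13) has separation exactly 12 and must be eligible
        d = np.full((30, 30), 50.0)
        np.fill_diagonal(d, 0)
        d[0, 12] = d[12, 0] = 5.0
        d[0, 11] = d[11, 0] = 5.0  # separation 11: never eligible
        cm = contacts_fixed(dm_from_array(d), cutoff=8.0, min_sep=12)
        assert cm.pairs == frozenset({(1, 13)})

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(6)
        s = random_structure(rng, L=30, spread=12)
        dm = distance_matrix(s, RM.CA)
        prev = frozenset()
        for cutoff in (4.0, 8.0, 12.0, 20.0):
            cur = contacts_fixed(dm, cutoff, 12).pairs
            assert prev <= cur
            prev = cur


class TestContactsMatched:
    def _random_dm(self, seed, L=30):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 15, (L, 3))
        d = np.linalg.norm(x[:, None] - x[None], axis=-1)
        return dm_from_array(d)

    def test_exact_count_for_every_n(self):
        dm = self._random_dm(0)
        n_elig = len(eligible_pairs(30, 12))
        for n in range(1, n_elig + 1):
            assert len(contacts_matched(dm, n, 12).contact_map.pairs) == n

    def test_exact_count_under_heavy_ties(self):
        d = np.full((30, 30), 7.0)  # every eligible distance identical
        np.fill_diagonal(d, 0)
        dm = dm_from_array(d)
        for n in (1, 5, 100):
            res = contacts_matched(dm, n, 12)
            assert len(res.contact_map.pairs) == n
            assert res.effective_cutoff == pytest.approx(7.0)

    def test_tie_break_is_lexicographic(self):
        d = np.full((30, 30), 7.0)
        np.fill_diagonal(d, 0)
        res = contacts_matched(dm_from_array(d), 2, 12)
        assert sorted(res.contact_map.pairs) == [(1, 13), (1, 14)]

    def test_n_equal_all_eligible_returns_everything(self):
        dm = self._random_dm(1)
        n_elig = len(eligible_pairs(30, 12))
        res = contacts_matched(dm, n_elig, 12)
        assert len(res.contact_map.pairs) == n_elig
        iu = np.triu_indices(30, k=12)
        assert res.effective_cutoff == pytest.approx(dm.d[iu].max())

    def test_n_one_is_brute_force_argmin(self):
        dm = self._random_dm(2)
        res = contacts_matched(dm, 1, 12)
        best = min(eligible_pairs(30, 12), key=lambda p: (dm.d[p[0] - 1, p[1] - 1], p))
        assert res.contact_map.pairs == frozenset({best})

    def test_consistent_with_fixed_cutoff_when_no_ties(self):
        dm = self._random_dm(3)
        cm = contacts_fixed(dm, 9.0, 12)
        res = contacts_matched(dm, len(cm.pairs), 12)
        assert res.contact_map.pairs == cm.pairs

    def test_n_exceeding_eligible_raises(self):
        dm = self._random_dm(4)
        with pytest.raises(ValueError):
            contacts_matched(dm, len(eligible_pairs(30, 12)) + 1, 12)


class TestOverlapAndCorrelation:
    def test_identical_maps_overlap_one(self):
        dm = TestContactsMatched()._random_dm(5)
        cm = contacts_matched(dm, 10, 12).contact_map
        assert overlap_fraction(cm, cm) == 1.0

    def test_disjoint_maps_overlap_zero(self):
        from coevocontacts.contact_geometry import ContactMap
        a = ContactMap(RM.CA, 40, 12, 8.0, frozenset({(1, 13), (2, 14)}))
        b = ContactMap(RM.CB, 40, 12, 8.0, frozenset({(3, 15), (4, 16)}))
        assert overlap_fraction(a, b) == 0.0

    def test_count_mismatch_raises(self):
        from coevocontacts.contact_geometry import ContactMap
        a = ContactMap(RM.CA, 40, 12, 8.0, frozenset({(1, 13)}))
        b = ContactMap(RM.CB, 40, 12, 8.0, frozenset({(3, 15), (4, 16)}))
        with pytest.raises(ValueError, match="count-matched"):
            overlap_fraction(a, b)

    def test_spearman_self_is_one(self):
        dm = TestContactsMatched()._random_dm(6)
        assert distance_correlation(dm, dm) == pytest.approx(1.0)

    def test_spearman_against_reversed_order_is_minus_one(self):
        dm = TestContactsMatched()._random_dm(7)
        flipped = np.where(np.eye(30, dtype=bool), 0.0, dm.d.max() + 1 - dm.d)
        neg = DistanceMatrix(method=RM.CB, d=flipped)
        assert distance_correlation(dm, neg) == pytest.approx(-1.0)

    def test_spearman_matches_rank_then_pearson(self):
        a = TestContactsMatched()._random_dm(8)
        b = TestContactsMatched()._random_dm(9)
        iu = np.triu_indices(30, k=12)
        expect = pearsonr(rankdata(a.d[iu]), rankdata(b.d[iu])).statistic
        assert distance_correlation(a, b) == pytest.approx(expect)

    def test_too_few_pairs_raises(self):
        d = np.zeros((13, 13))
        dm = dm_from_array(d)
        with pytest.raises(ValueError, match="fewer than 3"):
            distance_correlation(dm, dm)
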