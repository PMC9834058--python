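import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omegac import (
    QuantileMap,
    UNIVERSAL_CODE,
    build_rate_matrix,
    build_tensors,
    c_over_d,
    combination_record,
    correct_dsc,
    enumerate_pairs,
    expected_substitution_tensors,
    observed_combinatorial,
    omega_c,
    pair_table,
    rates,
    rescale_branch_lengths,
)
from omegac.ancestral import AncestralPosteriors
from omegac.metrics import CATEGORIES, combinatorial_per_site, pairwise_totals
from conftest import delta_posteriors, oracle_combinatorial, sparse_distribution

C = UNIVERSAL_CODE.codon_index


def posteriors_on(tree, rows_by_node, L):
    """Point/default posteriors: unspecified nodes keep state AAA."""
    probs = np.zeros((tree.n_nodes, L, 61))
    probs[:, :, C["AAA"]] = 1.0
    for (node, site), codon in rows_by_node.items():
        probs[node, site] = 0.0
        probs[node, site, C[codon]] = 1.0
    missing = np.zeros((tree.n_nodes, L), dtype=bool)
    return AncestralPosteriors(probs, missing, UNIVERSAL_CODE)


class TestObservedCategories:
    def test_identical_determined_substitutions(self, tree4):
        # branches 2 (tip t1) and 5 (tip t3) both substitute AAA -> AAC
        post = posteriors_on(tree4, {(2, 0): "AAC", (5, 0): "AAC"}, L=2)
        tens = build_tensors(post, tree4)
        for cat in ("any2any", "any2spe", "spe2spe"):
            assert observed_combinatorial(tens, [2, 5], cat, "N") == pytest.approx(1.0)
        assert observed_combinatorial(tens, [2, 5], "any2dif", "N") == pytest.approx(0.0)

    def test_different_ancestors_same_derived_state(self, tree4):
        # branch 2: AAA -> AAC; branch 5: GGA -> AAC (parent node 4 set to GGA)
        post = posteriors_on(
            tree4, {(2, 0): "AAC", (4, 0): "GGA", (5, 0): "AAC"}, L=2
        )
        tens = build_tensors(post, tree4)
        assert observed_combinatorial(tens, [2, 5], "any2spe", "N") == pytest.approx(1.0)
        assert observed_combinatorial(tens, [2, 5], "spe2spe", "N") == pytest.approx(0.0)
        assert observed_combinatorial(tens, [2, 5], "dif2spe", "N") == pytest.approx(1.0)

    def test_synonymous_convergence_is_in_the_s_view(self, tree4):
        post = posteriors_on(tree4, {(2, 0): "AAG", (5, 0): "AAG"}, L=1)
        tens = build_tensors(post, tree4)
        assert observed_combinatorial(tens, [2, 5], "any2spe", "S") == pytest.approx(1.0)
        assert observed_combinatorial(tens, [2, 5], "any2spe", "N") == pytest.approx(0.0)

    def test_too_few_branches_rejected(self, tree4):
        post = posteriors_on(tree4, {}, L=1)
        tens = build_tensors(post, tree4)
        with pytest.raises(ValueError, match="at least two"):
            observed_combinatorial(tens, [2], "any2any", "N")
        with pytest.raises(KeyError):
            observed_combinatorial(tens, [2, 99], "any2any", "N")


class TestExhaustiveOracle:
    @pytest.mark.parametrize("k", [2, 3])
    def test_all_categories_match_weighted_enumeration(self, tree4, rng, k):
        """Random sparse posteriors on every node: the array formulas must
        equal the exhaustive codon-level enumeration to 1e-10."""
        L = 3
        probs = np.stack(
            [[sparse_distribution(rng, n_support=4) for _ in range(L)]
             for _ in range(tree4.n_nodes)]
        )
        post = AncestralPosteriors(
            probs, np.zeros((tree4.n_nodes, L), dtype=bool), UNIVERSAL_CODE
        )
        tens = build_tensors(post, tree4)
        branches = [2, 5] if k == 2 else [2, 3, 5]
        parents = [tree4.parent[b] for b in branches]
        for cat in CATEGORIES:
            for view in "NS":
                got = combinatorial_per_site(tens, branches, cat, view)
                for site in range(L):
                    want = oracle_combinatorial(
                        [probs[p, site] for p in parents],
                        [probs[b, site] for b in branches],
                        cat, view,
                    )
                    assert got[site] == pytest.approx(want, abs=1e-10)


class TestCategoryAlgebra:
    def test_observed_and_expected_identities_hold(self, tree4, rng):
        """any2dif = any2any - any2spe and dif2spe = any2spe - spe2spe,
        for random tensors, both views, pairwise and per record."""
        probs = rng.dirichlet(np.ones(61), size=(tree4.n_nodes, 3))
        post = AncestralPosteriors(
            probs, np.zeros((tree4.n_nodes, 3), dtype=bool), UNIVERSAL_CODE
        )
        tens = build_tensors(post, tree4)
        for view in "NS":
            m_aa = pairwise_totals(tens, "any2any", view)
            m_as = pairwise_totals(tens, "any2spe", view)
            m_ss = pairwise_totals(tens, "spe2spe", view)
            assert np.allclose(
                pairwise_totals(tens, "any2dif", view), m_aa - m_as, atol=1e-12
            )
            assert np.allclose(
                pairwise_totals(tens, "dif2spe", view), m_as - m_ss, atol=1e-12
            )
            # ordering O_any2any >= O_any2spe >= O_spe2spe >= 0
            assert (m_aa - m_as >= -1e-12).all()
            assert (m_as - m_ss >= -1e-12).all()
            assert (m_ss >= -1e-12).all()

    def test_record_and_vectorised_table_agree(self, tree4, rng):
        states = rng.integers(0, 61, size=(tree4.n_nodes, 6))
        post = delta_posteriors(states)
        tens = build_tensors(post, tree4)
        model = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.2)
        resc = rescale_branch_lengths(tens)
        exp = expected_substitution_tensors(post, tree4, model, resc)
        pairs = enumerate_pairs(tree4, exclude_sisters=True)
        table = pair_table(tens, exp, pairs, correct=False)
        for row in table.itertuples(index=False):
            rec = combination_record(tens, exp, [row.branch1, row.branch2])
            for cat in CATEGORIES:
                for col in (f"OCN_{cat}", f"OCS_{cat}", f"ECN_{cat}", f"ECS_{cat}"):
                    assert getattr(row, col) == pytest.approx(rec[col], abs=1e-10)
            assert row.effective_sites == rec["effective_sites"]


class TestExpectedTensors:
    def test_zero_rescaled_lengths_give_zero_expectation(self, tree4):
        from omegac.tensors import RescaledBranchLengths

        post = posteriors_on(tree4, {}, L=2)
        B = tree4.n_branches
        resc = RescaledBranchLengths(
            np.zeros(B), np.zeros(B), np.zeros(B), np.full(B, 2)
        )
        model = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.2)
        exp = expected_substitution_tensors(post, tree4, model, resc)
        assert exp.AN.sum() == pytest.approx(0.0, abs=1e-12)
        assert exp.AS.sum() == pytest.approx(0.0, abs=1e-12)

    def test_small_t_expectation_follows_first_order_rates(self, tree4):
        """Ancestral point mass on AAA with a short branch: expected mass
        into amino acid a is proportional to the instantaneous rates
        q(AAA -> j in a), normalised so the branch total equals t^N (the
        conservation property of the view-time inversion)."""
        from omegac.tensors import RescaledBranchLengths

        model = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.2)
        post = posteriors_on(tree4, {}, L=1)
        B = tree4.n_branches
        t = 1e-4
        resc = RescaledBranchLengths(
            np.full(B, 2 * t), np.full(B, t), np.full(B, t), np.full(B, 1)
        )
        exp = expected_substitution_tensors(post, tree4, model, resc)
        aaa = C["AAA"]
        aa = UNIVERSAL_CODE.aa_of_codon
        rates_row = np.zeros(20)
        for j in range(61):
            if aa[j] != aa[aaa]:
                rates_row[aa[j]] += model.Q[aaa, j]
        expected_row = rates_row * t / rates_row.sum()
        got = exp.AN[0, 0, aa[aaa], :]
        assert np.allclose(got, expected_row, rtol=1e-2, atol=1e-8)
        assert exp.AN[0, 0].sum() == pytest.approx(t, rel=1e-2)

    def test_totals_reproduce_rescaled_lengths_at_small_t(self, tree4, rng):
        """Conservation: expected tensors integrate to ~ t^N L and t^S L."""
        from omegac.tensors import RescaledBranchLengths

        model = build_rate_matrix("MG", rng.dirichlet(np.ones(61)) + 1e-3, omega=0.2)
        L = 5
        probs = rng.dirichlet(np.ones(61), size=(tree4.n_nodes, L))
        post = AncestralPosteriors(
            probs, np.zeros((tree4.n_nodes, L), dtype=bool), UNIVERSAL_CODE
        )
        B = tree4.n_branches
        resc = RescaledBranchLengths(
            np.full(B, 0.02), np.full(B, 0.01), np.full(B, 0.01), np.full(B, L)
        )
        exp = expected_substitution_tensors(post, tree4, model, resc)
        for b in range(B):
            assert exp.AN[b].sum() == pytest.approx(0.01 * L, rel=0.05)
            assert exp.AS[b].sum() == pytest.approx(0.01 * L, rel=0.05)


class TestRatesAndRatios:
    @pytest.mark.parametrize("o,e,want", [(4, 2, 2.0), (0, 2, 0.0), (3, 3, 1.0)])
    def test_rate_arithmetic(self, o, e, want):
        dn, ds = rates(o, e, o, e)
        assert dn == pytest.approx(want) and ds == pytest.approx(want)

    def test_degenerate_rates(self):
        dn, _ = rates(0.0, 0.0, 0, 1)
        assert np.isnan(dn)
        dn, _ = rates(1.0, 0.0, 0, 1)
        assert np.isinf(dn)

    def test_omega_c_cases(self):
        assert omega_c(3.0, 1.5) == pytest.approx(2.0)
        assert omega_c(2.0, 2.0) == pytest.approx(1.0)
        assert np.isinf(omega_c(1.0, 0.0))
        assert np.isnan(omega_c(0.0, 0.0))

    def test_c_over_d_cases(self):
        assert c_over_d(1.0, 2.0) == pytest.approx(0.5)
        assert np.isnan(c_over_d(1.0, 0.0))


class TestDscCorrection:
    def test_ds_at_least_dn_is_unchanged(self):
        qmap = QuantileMap.from_rates(np.arange(10.0), np.arange(10.0))
        assert correct_dsc(2.0, 2.0, qmap) == pytest.approx(2.0)
        assert correct_dsc(2.0, 5.0, qmap) == pytest.approx(5.0)

    def test_hand_quantile_mapping(self):
        qmap = QuantileMap.from_rates(
            np.array([10.0, 20.0, 30.0, 40.0]), np.array([1.0, 2.0, 3.0, 4.0])
        )
        assert correct_dsc(30.0, 2.0, qmap) == pytest.approx(20.0)

    def test_median_maps_to_median(self):
        ds_dist = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        dn_dist = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        qmap = QuantileMap.from_rates(dn_dist, ds_dist)
        assert correct_dsc(100.0, 1.5, qmap) == pytest.approx(6.0)

    def test_missing_map_returns_uncorrected(self):
        assert correct_dsc(5.0, 1.0, None) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_correction_preserves_rank_order(self, seed):
        rng = np.random.default_rng(seed)
        dn = rng.gamma(1.0, 2.0, size=30)
        ds = rng.gamma(1.0, 1.0, size=30)
        qmap = QuantileMap.from_rates(dn, ds)
        corrected = correct_dsc(np.full_like(ds, np.inf), ds, qmap)
        order = np.argsort(ds)
        assert (np.diff(corrected[order]) >= -1e-12).all()


class TestPairTable:
    def test_corrected_table_columns_and_cd(self, tree4, rng):
        states = rng.integers(0, 61, size=(tree4.n_nodes, 8))
        post = delta_posteriors(states)
        tens = build_tensors(post, tree4)
        model = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.2)
        exp = expected_substitution_tensors(
            post, tree4, model, rescale_branch_lengths(tens)
        )
        pairs = enumerate_pairs(tree4, exclude_sisters=True)
        table = pair_table(tens, exp, pairs)
        assert len(table) == len(pairs)
        for cat in CATEGORIES:
            assert f"omegaC_{cat}" in table
            assert f"dSC_{cat}_uncorrected" in table
        finite = np.isfinite(table["CD"])
        expect_cd = table["OCN_any2spe"] / table["OCN_any2dif"]
        assert np.allclose(table["CD"][finite], expect_cd[finite], atol=1e-12)
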