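import numpy as np
import pytest

from omegac import (
    UNIVERSAL_CODE,
    balanced_tree,
    build_rate_matrix,
    discrete_gamma_rates,
    estimate_frequencies,
    estimate_omega,
    estimate_site_rates,
    read_codon_alignment,
    read_exchangeabilities,
    transition_matrix,
)
from omegac.codon_model import SiteRates
from omegac.phylo_io import CodonAlignment
from omegac.simulate import SimulationScenario, simulate_neutral


def random_pi(rng):
    pi = rng.random(61) + 0.05
    return pi / pi.sum()


def random_empirical(rng):
    s = rng.random((61, 61))
    s = s + s.T
    np.fill_diagonal(s, 0.0)
    return build_rate_matrix("empirical", random_pi(rng), s=s)


class TestBuildRateMatrix:
    def test_mg_uniform_frequencies_neutral_omega_is_symmetric(self):
        pi = np.full(61, 1 / 61)
        m = build_rate_matrix("MG", pi, omega=1.0)
        single = UNIVERSAL_CODE.single_nt_mask()
        off = m.Q[single]
        assert np.allclose(off, off[0])
        assert np.allclose(m.Q[~single & ~np.eye(61, dtype=bool)], 0.0)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-10)

    @pytest.mark.parametrize("family,kwargs", [
        ("MG", dict(omega=0.2)),
        ("GY", dict(omega=0.5, kappa=2.0)),
        ("empirical", dict()),
    ])
    def test_mean_rate_normalisation(self, family, kwargs, rng):
        if family == "empirical":
            m = random_empirical(rng)
        else:
            m = build_rate_matrix(family, random_pi(rng), **kwargs)
        Qoff = m.Q.copy()
        np.fill_diagonal(Qoff, 0.0)
        assert np.isclose(m.pi @ Qoff.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-10)

    def test_gy_kappa_scales_synonymous_transitions(self, rng):
        pi = random_pi(rng)
        m1 = build_rate_matrix("GY", pi, omega=0.3, kappa=1.0)
        m2 = build_rate_matrix("GY", pi, omega=0.3, kappa=2.0)
        code = UNIVERSAL_CODE
        i, j = code.codon_index["AAA"], code.codon_index["AAG"]  # syn transition
        i2, j2 = code.codon_index["AAA"], code.codon_index["AAC"]  # transversion
        ratio_ts = (m2.Q[i, j] / m1.Q[i, j])
        ratio_tv = (m2.Q[i2, j2] / m1.Q[i2, j2])
        # kappa doubles transitions relative to transversions (up to the
        # global renormalisation, which cancels in the double ratio)
        assert np.isclose(ratio_ts / ratio_tv, 2.0, rtol=1e-10)

    def test_detailed_balance(self, rng):
        m = random_empirical(rng)
        flux = m.pi[:, None] * m.Q
        assert np.allclose(flux, flux.T, atol=1e-10)

    def test_exchangeability_scaling_invariance(self, rng):
        s = rng.random((61, 61))
        s = s + s.T
        np.fill_diagonal(s, 0.0)
        pi = random_pi(rng)
        m1 = build_rate_matrix("empirical", pi, s=s)
        m2 = build_rate_matrix("empirical", pi, s=17.5 * s)
        assert np.allclose(m1.Q, m2.Q, atol=1e-10)

    def test_invalid_inputs_are_rejected(self, rng):
        pi = random_pi(rng)
        with pytest.raises(ValueError, match="negative"):
            build_rate_matrix("MG", -pi, omega=0.2)
        s = rng.random((61, 61))
        with pytest.raises(ValueError, match="symmetric"):
            build_rate_matrix("empirical", pi, s=s)
        with pytest.raises(ValueError, match="requires omega"):
            build_rate_matrix("MG", pi)


class TestTransitionMatrix:
    def test_zero_time_gives_identity(self, rng):
        m = build_rate_matrix("MG", random_pi(rng), omega=0.2)
        assert np.allclose(transition_matrix(m, 0.0), np.eye(61), atol=1e-12)

    def test_short_time_matches_first_order_series(self, rng):
        m = build_rate_matrix("MG", random_pi(rng), omega=0.2)
        P = transition_matrix(m, 0.01)
        assert np.abs(P - (np.eye(61) + 0.01 * m.Q)).max() < 1e-3

    def test_long_time_converges_to_equilibrium(self, rng):
        m = build_rate_matrix("MG", random_pi(rng), omega=0.2)
        P = transition_matrix(m, 1000.0)
        assert np.abs(P - m.pi[None, :]).max() < 1e-6

    def test_rows_are_distributions(self, rng):
        m = random_empirical(rng)
        P = transition_matrix(m, 0.7, r=1.3)
        assert (P >= 0).all()
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self, rng):
        m = build_rate_matrix("GY", random_pi(rng), omega=0.4, kappa=2.0)
        P12 = transition_matrix(m, 0.9, r=0.8)
        P1 = transition_matrix(m, 0.4, r=0.8)
        P2 = transition_matrix(m, 0.5, r=0.8)
        assert np.abs(P12 - P1 @ P2).max() < 1e-8

    def test_nonfinite_time_is_rejected(self, rng):
        m = build_rate_matrix("MG", random_pi(rng), omega=0.2)
        with pytest.raises(ValueError):
            transition_matrix(m, np.nan)


class TestEstimateFrequencies:
    @pytest.mark.parametrize("fasta,pseudo,expect", [
        # only AAA codons, no smoothing -> all mass on AAA
        (">A\nAAAAAA\n", 0.0, {"AAA": 1.0}),
        # equal counts of two codons
        (">A\nAAAAAC\n", 0.0, {"AAA": 0.5, "AAC": 0.5}),
        # counts {AAA: 3, AAC: 1} with pseudo-count 1 per codon
        (">A\nAAAAAAAAAAAC\n", 1.0, {"AAA": 4 / 65, "AAC": 2 / 65}),
    ])
    def test_closed_form_counts(self, fasta, pseudo, expect):
        aln = read_codon_alignment(fasta)
        pi = estimate_frequencies(aln, pseudocount=pseudo)
        assert np.isclose(pi.sum(), 1.0)
        for codon, p in expect.items():
            assert np.isclose(pi[UNIVERSAL_CODE.codon_index[codon]], p)

    def test_all_missing_is_rejected(self):
        aln = read_codon_alignment(">A\n---\n")
        with pytest.raises(ValueError, match="no non-missing"):
            estimate_frequencies(aln)


class TestSiteRates:
    def test_discrete_gamma_mean_is_one(self):
        for alpha in (0.2, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 4)
            assert np.isclose(r.mean(), 1.0, atol=1e-6)
            assert (np.diff(r) > 0).all()
        assert np.allclose(discrete_gamma_rates(500.0, 4), 1.0, atol=0.1)

    def test_single_category_gives_unit_rates(self, tree4):
        aln = read_codon_alignment(">t1\nATG\n>t2\nATG\n>t3\nATG\n>t4\nATG\n")
        m = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.2)
        sr = estimate_site_rates(tree4, aln, m, n_categories=1)
        assert (sr.rates == 1.0).all()

    def test_identical_columns_get_identical_rates(self, tree4):
        aln = read_codon_alignment(
            ">t1\nATGATG\n>t2\nAAAAAA\n>t3\nATGATG\n>t4\nCCACCA\n"
        )
        m = build_rate_matrix("MG", np.full(61, 1 / 61), omega=0.5)
        sr = estimate_site_rates(tree4, aln, m, n_categories=4)
        assert np.isclose(sr.rates[0], sr.rates[1], atol=1e-8)

    def test_recovers_rate_heterogeneity_from_simulation(self):
        # two-category truth {0.5, 2.0}: posterior-mean rates should rank
        # fast sites above slow sites (Spearman rho > 0.5 at L = 500)
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        scen = SimulationScenario(scenario="Neutral", n_tips=16,
                                  branch_length=0.4, n_codons=500)
        tree = scen.resolved_tree()
        model = scen.base_model()
        true_r = np.where(rng.random(500) < 0.5, 0.5, 2.0)
        from omegac.simulate import _evolve, _to_alignment

        half = int((true_r == 0.5).sum())
        states_slow = _evolve(
            type(tree)(tree.parent, tree.children, tree.lengths * 0.5,
                       tree.labels), model, half, rng)
        states_fast = _evolve(
            type(tree)(tree.parent, tree.children, tree.lengths * 2.0,
                       tree.labels), model, 500 - half, rng)
        states = np.empty((tree.n_nodes, 500), dtype=np.int64)
        states[:, true_r == 0.5] = states_slow
        states[:, true_r == 2.0] = states_fast
        aln = _to_alignment(tree, states, scen.code)
        sr = estimate_site_rates(tree, aln, model, n_categories=4)
        rho = spearmanr(sr.rates, true_r).statistic
        assert rho > 0.5
        assert sr.alpha is not None and sr.alpha > 0


class TestEstimateOmega:
    def test_recovers_simulated_omega(self):
        scen = SimulationScenario(scenario="Neutral", n_tips=16,
                                  branch_length=0.3, n_codons=300)
        aln, _, tree = simulate_neutral(scen, 11)
        pi = estimate_frequencies(aln)
        w = estimate_omega(tree, aln, pi, family="MG")
        assert 0.1 < w < 0.4  # truth 0.2


class TestReadExchangeabilities:
    def test_round_trip_through_text(self, rng):
        code = UNIVERSAL_CODE
        s = rng.random((61, 61))
        s = s + s.T
        np.fill_diagonal(s, 0.0)
        perm = rng.permutation(61)
        header = " ".join(code.codons[i] for i in perm)
        sp = s[np.ix_(perm, perm)]
        body = "\n".join(
            " ".join(f"{sp[i, j]:.12g}" for j in range(i)) for i in range(1, 61)
        )
        parsed = read_exchangeabilities(header + "\n" + body)
        assert np.allclose(parsed, s, atol=1e-9)
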