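import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import founderage as fa
from founderage.coalescent import (
    encode_for_dating,
    genealogy_loglikelihood,
    run_age_mcmc,
    sample_intraallelic_genealogy,
    star_loglikelihood,
)
from founderage.datamodel import encode_carriers
from founderage.demography import DemographyConfig
from founderage.trees import Genealogy, star_genealogy


def _one_marker_enc(alleles, p_anc=0.4, theta=0.01):
    freqs = [{"1": p_anc, "2": 1 - p_anc}]
    return encode_carriers([(a,) for a in alleles], freqs, np.array([theta]))


class TestStarLikelihood:
    def test_zero_age_identical_carriers(self):
        enc = _one_marker_enc(["1"] * 10)
        assert star_loglikelihood(0.0, enc, ("1",)) == pytest.approx(0.0, abs=1e-12)

    def test_large_age_asymptote_is_population_probability(self):
        enc = _one_marker_enc(["1", "2", "1"])
        ll = star_loglikelihood(1e7, enc, ("1",))
        expected = math.log(0.4) * 2 + math.log(0.6)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_decreasing_in_age_for_ancestral_data(self):
        enc = _one_marker_enc(["1"] * 5)
        lls = [star_loglikelihood(t, enc, ("1",)) for t in np.linspace(0, 200, 40)]
        assert all(b < a for a, b in zip(lls, lls[1:]))

    def test_matches_monte_carlo_recombination(self):
        """Per-chromosome match probability vs direct simulation of Poisson
        recombination over t generations on 1e6 lineages."""
        t, theta, p_anc = 30.0, 0.01, 0.4
        rng = np.random.default_rng(42)
        n_lineages = 1_000_000
        recombined = rng.poisson(theta * t, size=n_lineages) > 0
        allele_after = rng.random(n_lineages) < p_anc
        match = ~recombined | (recombined & allele_after)
        p_hat = match.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / n_lineages)
        enc = _one_marker_enc(["1"], p_anc=p_anc, theta=theta)
        p_model = math.exp(star_loglikelihood(t, enc, ("1",)))
        assert abs(p_model - p_hat) < 3 * se

    def test_missing_alleles_contribute_zero(self):
        enc = _one_marker_enc(["1", fa.MISSING])
        full = star_loglikelihood(25.0, _one_marker_enc(["1"]), ("1",))
        assert star_loglikelihood(25.0, enc, ("1",)) == pytest.approx(full, abs=1e-12)


class TestGenealogyLikelihood:
    def test_star_tree_reduces_to_star_model(self, small_sim):
        cfg, res = small_sim
        enc = encode_for_dating(res.haplotype_set, cfg.gmap)
        anc = res.truth["ancestral"]
        n = enc.X.shape[0]
        t = 47.0
        tree = star_genealogy(n, t)
        ll_tree = genealogy_loglikelihood(t, tree, enc, anc)
        ll_star = star_loglikelihood(t, enc, anc)
        assert ll_tree == pytest.approx(ll_star, abs=1e-10)

    def test_four_leaf_tree_matches_forward_simulation(self):
        """Fixed 4-leaf tree, one marker: configuration probability vs a
        forward simulation of the jump process along every branch."""
        theta, p_anc = 0.05, 0.3
        t = 35.0
        parent = np.array([4, 4, 5, 5, 6, 6, -1])
        time = np.array([0.0, 0.0, 0.0, 0.0, 10.0, 20.0, 30.0])
        tree = Genealogy(4, parent, time, t)
        rng = np.random.default_rng(1)
        R = 400_000
        p = np.array([p_anc, 1 - p_anc])

        def transmit(start, L):
            # jump-to-stationarity: keep with exp(-theta L), else draw from p
            keep = rng.random(R) < math.exp(-theta * L)
            fresh = (rng.random(R) < p[1]).astype(int)  # 0='1', 1='2'
            return np.where(keep, start, fresh)

        root = transmit(np.zeros(R, dtype=int), t - 30.0)
        n5 = transmit(root, 10.0)
        n4 = transmit(root, 20.0)
        leaves = [
            transmit(n4, 10.0),
            transmit(n4, 10.0),
            transmit(n5, 20.0),
            transmit(n5, 20.0),
        ]
        config = np.array([0, 0, 1, 0])  # observed alleles 1,1,2,1
        hits = np.ones(R, dtype=bool)
        for leaf, c in zip(leaves, config):
            hits &= leaf == c
        p_hat = hits.mean()
        se = math.sqrt(p_hat * (1 - p_hat) / R)
        enc = _one_marker_enc(["1", "1", "2", "1"], p_anc=p_anc, theta=theta)
        p_model = math.exp(genealogy_loglikelihood(t, tree, enc, ("1",)))
        assert abs(p_model - p_hat) < 3 * se

    def test_leaf_count_mismatch_rejected(self):
        enc = _one_marker_enc(["1", "1"])
        tree = star_genealogy(3, 10.0)
        with pytest.raises(fa.ValidationError, match="leaves"):
            genealogy_loglikelihood(10.0, tree, enc, ("1",))


class TestGenealogySampler:
    def test_two_lineages_single_time(self):
        dem = DemographyConfig()
        tree = sample_intraallelic_genealogy(2, 40.0, dem, seed=0)
        assert tree.n_leaves == 2
        root_age = tree.time[tree.root]
        assert 0 < root_age <= 40.0

    def test_age_too_small_raises(self):
        dem = DemographyConfig(growth_rate=2.0)
        with pytest.raises(fa.ValidationError, match="larger t"):
            sample_intraallelic_genealogy(40, 1.0, dem, seed=0, max_retries=5)

    def test_coalescence_time_cdf_matches_numeric_integration(self):
        """Pooled coalescence-age CDF for n=5, d=0.095, t=50 against the
        master equation of the inhomogeneous pure-death (coalescing)
        process, conditioned on full coalescence by t."""
        n, d, t = 5, 0.095, 50.0
        dem = DemographyConfig(growth_rate=d)
        rng = np.random.default_rng(3)
        ages = []
        for _ in range(2500):
            tree = sample_intraallelic_genealogy(n, t, dem, rng)
            ages.extend(tree.time[n:])
        ages = np.sort(ages)

        def rates(s, k):
            return k * (k - 1) / 2.0 * math.exp(-d * (t - s))

        def forward(s, P):  # states k = n..1 -> indices 0..n-1
            dP = np.zeros(n)
            for i, k in enumerate(range(n, 0, -1)):
                lam = rates(s, k)
                if k > 1:
                    dP[i] -= lam * P[i]
                if k < n:
                    dP[i] += rates(s, k + 1) * P[i - 1]
            return dP

        sgrid = np.linspace(0, t, 201)
        P0 = np.zeros(n)
        P0[0] = 1.0
        sol = solve_ivp(forward, (0, t), P0, t_eval=sgrid, rtol=1e-8, atol=1e-10)

        # absorption probability by t from state k at time s: run the same
        # master equation forward from (s, state k) and read P(k=1 at t)
        hs = np.zeros((n, len(sgrid)))
        coarse = sgrid[::10]
        for i, k in enumerate(range(n, 0, -1)):
            if k == 1:
                hs[i] = 1.0
                continue
            vals = []
            for s in coarse:
                if s >= t:
                    vals.append(0.0)
                    continue
                P0k = np.zeros(n)
                P0k[n - k] = 1.0
                solk = solve_ivp(forward, (s, t), P0k, rtol=1e-8, atol=1e-10)
                vals.append(float(solk.y[-1, -1]))
            hs[i] = np.interp(sgrid, coarse, vals)
        joint = sol.y * hs
        z = joint.sum(axis=0)
        cond = joint / z
        k_vals = np.array(range(n, 0, -1), dtype=float)
        e_k = (cond.T * k_vals).sum(axis=1)
        cdf_expected = (n - e_k) / (n - 1)

        emp = np.searchsorted(ages, sgrid, side="right") / len(ages)
        ks = np.max(np.abs(emp - cdf_expected))
        assert ks < 0.02


class TestRunAgeMcmc:
    def test_flat_likelihood_recovers_uniform_prior(self):
        """With no markers the star-model posterior must reproduce the
        uniform age prior (KS < 0.02 at 1e5 draws)."""
        enc = encode_carriers(
            [(), ()], [], np.array([])
        )
        dem = DemographyConfig(max_age=500)
        est = run_age_mcmc(
            enc, None, dem, n_iter=120_000, burn_in=20_000, seed=9, model="star",
            n_chains=1,
        )
        draws = est.samples
        assert len(draws) >= 100_000
        u = (draws - 1.0) / (500.0 - 1.0)
        grid = np.linspace(0, 1, 401)
        emp = np.searchsorted(np.sort(u), grid, side="right") / len(u)
        assert np.max(np.abs(emp - grid)) < 0.02

    def test_years_reporting_identity(self, small_sim):
        cfg, res = small_sim
        dem = DemographyConfig(generation_years=20.0)
        est = run_age_mcmc(
            res.haplotype_set, cfg.gmap, dem, n_iter=3000, seed=1, model="star",
            n_chains=2,
        )
        assert est.years["mode"] == est.mode * 20.0
        assert est.years["ci95_low"] == est.ci95[0] * 20.0
        assert est.years["ci95_high"] == est.ci95[1] * 20.0

    def test_doubling_iterations_stable_mode(self, small_sim):
        """Doubling the chain length moves the star-model posterior mode by
        at most one generation on the study-size fixture."""
        cfg, res = small_sim
        dem = DemographyConfig()
        est1 = run_age_mcmc(
            res.haplotype_set, cfg.gmap, dem, n_iter=400_000, seed=2, model="star",
            n_chains=2,
        )
        est2 = run_age_mcmc(
            res.haplotype_set, cfg.gmap, dem, n_iter=800_000, seed=2, model="star",
            n_chains=2,
        )
        assert abs(est1.mode - est2.mode) <= 1.0

    def test_genealogy_model_recovers_truth_on_fixture(self, small_sim):
        """The full intra-allelic coalescent posterior covers the fixture's
        true age and reports sane diagnostics."""
        cfg, res = small_sim
        dem = DemographyConfig(
            sampled_proportion=res.truth["sampled_proportion_true"]
        )
        est = run_age_mcmc(
            res.haplotype_set, cfg.gmap, dem, n_iter=12_000, burn_in=3_000,
            seed=4, model="genealogy", n_chains=2,
        )
        assert est.ci95[0] <= 43 <= est.ci95[1]
        assert est.rhat < 1.2
        assert 10 <= est.mode <= 90

    def test_unknown_model_rejected(self, small_sim):
        cfg, res = small_sim
        with pytest.raises(fa.ValidationError, match="model"):
            run_age_mcmc(
                res.haplotype_set, cfg.gmap, DemographyConfig(), n_iter=10, model="blah"
            )
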