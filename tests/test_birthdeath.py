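import math

import numpy as np
import pytest
from numba import njit

import founderage as fa
from founderage.birthdeath import (
    AllelicClassSummary,
    BirthDeathParams,
    _extract_genealogy,
    _log_copy_number_pmf,
    bd_copy_number_pmf,
    bdmc_likelihood,
    effective_class_exit_rate,
    expected_copies_given_survival,
    modal_carrier_haplotype,
    profile_likelihood,
    sample_reconstructed_coalescence_ages,
    simulate_bd_genealogy,
    summarize_allelic_classes,
    survival_probability,
)
from founderage.datamodel import ValidationError


@njit(cache=True)
def _forward_counts(t, lam, mu, n_reps, seed):
    """Independent Gillespie oracle for the linear birth-death copy number."""
    np.random.seed(seed)
    out = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        n = 1
        now = 0.0
        while n > 0:
            rate = (lam + mu) * n
            now += -np.log(np.random.random()) / rate
            if now >= t:
                break
            if np.random.random() < lam / (lam + mu):
                n += 1
            else:
                n -= 1
        out[r] = n
    return out


class TestCopyNumberPmf:
    def test_age_zero_is_point_mass_at_one(self):
        pmf = bd_copy_number_pmf(0.0, BirthDeathParams(1.095, 1.0), 10)
        assert pmf[0] == 1.0
        assert pmf[1:].sum() == 0.0

    @pytest.mark.parametrize("t", [5.0, 20.0, 50.0])
    def test_conditional_mean_identity(self, t):
        """E[N | survival] from the pmf equals exp(d t) / P(survive)."""
        params = BirthDeathParams(1.095, 1.0)
        n_max = 2_000_000
        pmf = bd_copy_number_pmf(t, params, n_max)
        mean = float(np.arange(1, n_max + 1) @ pmf)
        # account for the documented geometric tail beyond n_max
        assert pmf.sum() == pytest.approx(1.0, abs=1e-6)
        assert mean == pytest.approx(expected_copies_given_survival(t, params), rel=1e-4)

    @pytest.mark.parametrize(
        "t,d",
        [(5.0, 0.05), (5.0, 0.095), (5.0, 0.2),
         (15.0, 0.05), (15.0, 0.095), (15.0, 0.2),
         (30.0, 0.05), (30.0, 0.095), (30.0, 0.2)],
    )
    def test_matches_forward_simulation(self, t, d):
        """Total-variation distance to an independent Gillespie simulation
        below 0.01 at 1e6 replicates, across a grid of (t, d).

        The distance is computed on geometrically growing copy-number
        bins: on the raw support (hundreds of values, ~10% survival) the
        empirical TV has a Monte-Carlo noise floor above the threshold
        even for the exactly correct law, so the raw-support comparison
        would test the replicate count rather than the pmf.
        """
        params = BirthDeathParams(1.0 + d, 1.0)
        n_reps = 1_000_000
        counts = _forward_counts(t, 1.0 + d, 1.0, n_reps, seed=int(t * 1000 + d * 100))
        surv = counts[counts > 0]
        n_max = int(surv.max())
        pmf = bd_copy_number_pmf(t, params, n_max)
        edges = [1]
        while edges[-1] <= n_max:
            edges.append(max(edges[-1] + 1, int(edges[-1] * 1.5)))
        edges = np.array(edges)
        emp_binned = np.histogram(surv, bins=np.append(edges, np.inf))[0] / len(surv)
        idx = np.searchsorted(edges, np.arange(1, n_max + 1), side="right") - 1
        pmf_binned = np.bincount(idx, weights=pmf, minlength=len(edges))
        pmf_binned[-1] += 1.0 - pmf.sum()  # documented tail beyond n_max
        tv = 0.5 * np.abs(emp_binned - pmf_binned).sum()
        assert tv < 0.01

    def test_survival_probability_matches_simulation(self):
        params = BirthDeathParams(1.095, 1.0)
        counts = _forward_counts(30.0, 1.095, 1.0, 200_000, seed=5)
        p_hat = (counts > 0).mean()
        se = math.sqrt(p_hat * (1 - p_hat) / len(counts))
        assert abs(survival_probability(30.0, params) - p_hat) < 3 * se

    def test_critical_case_handled(self):
        pmf = bd_copy_number_pmf(10.0, BirthDeathParams(1.0, 1.0), 100)
        assert np.all(pmf > 0)
        assert pmf.sum() < 1.0


class TestForwardGenealogy:
    def test_single_sample_is_single_branch(self):
        tree = simulate_bd_genealogy(1, 12.0, BirthDeathParams(1.095, 1.0), seed=0)
        assert tree.n_leaves == 1
        assert tree.branch_length(0) == 12.0

    @pytest.mark.parametrize("n", [2, 5, 10])
    def test_leaf_count_contract(self, n):
        tree = simulate_bd_genealogy(n, 25.0, BirthDeathParams(1.095, 1.0), seed=n)
        assert tree.n_leaves == n
        assert tree.time[tree.root] < 25.0

    @pytest.mark.parametrize("lam,mu", [(1.095, 1.0), (1.0, 1.0)])
    def test_root_split_age_matches_reconstructed_process(self, lam, mu):
        """Forward-simulated genealogies with complete sampling of exactly n
        survivors follow the analytic reconstructed-process law: the n-1
        coalescence ages are iid with CDF q(s)/q(t), so the root age has
        CDF (q(s)/q(t))^(n-1).  Checked for supercritical and critical
        rates."""
        from founderage._kernels import bd_forward

        n, t = 3, 6.0
        rng = np.random.default_rng(0)
        roots = []
        attempts = 0
        while len(roots) < 3000 and attempts < 400_000:
            attempts += 1
            status, _c, parent_rec, tb, alive, n_alive = bd_forward(
                t, lam, mu, int(rng.integers(2**31 - 1)), 5000
            )
            if status != 0 or n_alive != n:
                continue
            tree = _extract_genealogy(parent_rec, tb, [int(a) for a in alive[:n]], t)
            roots.append(tree.time[tree.root])
        assert len(roots) == 3000
        roots = np.sort(roots)

        params = BirthDeathParams(lam, mu)
        d = lam - mu
        A, B = 1.0 * lam, mu  # rho = 1 (complete sampling)

        def q(s):
            if abs(d) < 1e-12:
                return s / (1.0 + A * s)
            E = math.exp(-d * s)
            return (1.0 - E) / (A - B * E)

        grid = np.linspace(0, t, 200)
        cdf = np.array([(q(s) / q(t)) ** (n - 1) for s in grid])
        emp = np.searchsorted(roots, grid, side="right") / len(roots)
        assert np.max(np.abs(emp - cdf)) < 0.02

    def test_reconstructed_sampler_matches_its_cdf(self):
        params = BirthDeathParams(1.095, 1.0)
        rng = np.random.default_rng(1)
        ages = np.concatenate(
            [sample_reconstructed_coalescence_ages(6, 40.0, params, 0.1, rng)
             for _ in range(3000)]
        )
        d = 0.095
        A, B = 0.1 * 1.095, 1.0 - 1.095 * 0.9

        def q(s):
            E = math.exp(-d * s)
            return (1.0 - E) / (A - B * E)

        grid = np.linspace(0.01, 39.99, 150)
        cdf = np.array([q(s) / q(40.0) for s in grid])
        srt = np.sort(ages)
        emp = np.searchsorted(srt, grid, side="right") / len(srt)
        assert np.max(np.abs(emp - cdf)) < 0.02


class TestClassSummary:
    def test_intact_count_against_known_ancestral(self, small_sim):
        cfg, res = small_sim
        anc = res.truth["ancestral"]
        s = summarize_allelic_classes(res.haplotype_set, 0.05, ancestral=anc)
        direct = sum(
            1 for h in res.haplotype_set.carriers if h.alleles == tuple(anc)
        )
        assert s.intact_count == direct
        assert sum(s.class_counts) == s.n_sampled == 51

    def test_class_partition_counts(self):
        haps = [
            fa.Haplotype(("1", "A"), True, sample_id=f"s{i}")
            for i in range(3)
        ] + [fa.Haplotype(("2", "A"), True, sample_id="s3")]
        s = summarize_allelic_classes(haps, 0.5, statistic="classes")
        assert s.class_counts == (3, 1)
        assert s.ancestral_class_size == 3

    def test_modal_haplotype(self):
        haps = [
            fa.Haplotype(("1", "A"), True, sample_id="a"),
            fa.Haplotype(("1", "G"), True, sample_id="b"),
            fa.Haplotype(("1", "A"), True, sample_id="c"),
        ]
        assert modal_carrier_haplotype(haps) == ("1", "A")

    def test_effective_exit_rate_below_raw_rate(self, study):
        from founderage.simulate import study_control_frequencies

        panel, gmap = study
        freqs = study_control_frequencies(panel)
        anc = [sorted(t, key=t.get)[-1] for t in freqs]
        raw = fa.class_exit_rate_from_map(panel, gmap)
        eff = effective_class_exit_rate(panel, gmap, freqs, anc)
        assert 0 < eff < raw


class TestLikelihoodProfile:
    def test_separability_all_one_class_tight_map(self):
        """With a vanishing exit rate and every carrier in one class, the
        likelihood varies only through the copy-number term."""
        params = BirthDeathParams(1.095, 1.0)
        summary = AllelicClassSummary(20, 0.1, (20,), intact_count=20)
        grid = [10.0, 30.0, 60.0, 120.0]
        curve = profile_likelihood(
            summary, params, grid, n_reps=500, seed=0, class_exit_rate=0.0
        )
        copy = np.array(
            [_log_copy_number_pmf(t, params, summary.implied_copy_number) for t in grid]
        )
        assert np.allclose(curve.loglik, copy, atol=1e-9)

    def test_single_point_grid(self):
        params = BirthDeathParams(1.095, 1.0)
        summary = AllelicClassSummary(10, 0.2, (10,), intact_count=10)
        curve = profile_likelihood(summary, params, [40.0], n_reps=200, seed=0,
                                   class_exit_rate=0.01)
        assert curve.ml_age == 40.0
        assert curve.ci95 == (40.0, 40.0)

    def test_monotone_flanks_for_all_one_class(self):
        """With every chromosome intact, the exact-ancestral likelihood is
        unimodal: non-increasing away from the maximum beyond MC noise."""
        params = BirthDeathParams(1.095, 1.0)
        summary = AllelicClassSummary(30, 0.05, (30,), intact_count=30)
        grid = list(range(5, 200, 5))
        curve = profile_likelihood(summary, params, grid, n_reps=3000, seed=1,
                                   class_exit_rate=0.02)
        i_ml = int(np.argmax(curve.loglik))
        tol = 3 * np.maximum(curve.mc_se, 1e-3)
        left = curve.loglik[: i_ml + 1]
        assert np.all(np.diff(left) >= -(tol[: i_ml] + tol[1 : i_ml + 1]))
        right = curve.loglik[i_ml:]
        assert np.all(np.diff(right) <= (tol[i_ml:-1] + tol[i_ml + 1 :]))

    def test_grid_refinement_stability(self, small_sim):
        cfg, res = small_sim
        hs = res.haplotype_set
        params = BirthDeathParams.from_growth(0.095)
        summary = summarize_allelic_classes(hs, res.truth["sampled_proportion_true"])
        kwargs = dict(
            n_reps=2000, seed=3, panel=cfg.panel, gmap=cfg.gmap,
            freqs=hs.population_allele_freqs, method="pipeline",
        )
        coarse = profile_likelihood(summary, params, list(range(4, 200, 8)), **kwargs)
        fine = profile_likelihood(summary, params, list(range(4, 200, 4)), **kwargs)
        assert abs(coarse.ml_age - fine.ml_age) <= 12.0

    def test_pipeline_method_needs_panel(self):
        params = BirthDeathParams(1.095, 1.0)
        summary = AllelicClassSummary(10, 0.2, (10,), intact_count=10)
        with pytest.raises(ValidationError, match="pipeline"):
            profile_likelihood(summary, params, [10.0], method="pipeline")

    def test_bdmc_likelihood_single_age(self):
        params = BirthDeathParams(1.095, 1.0)
        summary = AllelicClassSummary(15, 0.1, (15,), intact_count=15)
        ll, se = bdmc_likelihood(30.0, summary, params, class_exit_rate=0.01,
                                 n_reps=500, seed=2)
        assert np.isfinite(ll)
        assert se >= 0
        with pytest.raises(ValidationError, match="n_reps"):
            bdmc_likelihood(30.0, summary, params, n_reps=10)
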