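import math

import numpy as np
import pytest
from scipy.stats import spearmanr

import founderage as fa
from founderage.phasing import find_shared_core, phase_pedigree
from founderage.simulate import (
    panel_summary_stats,
    simulate_founder_panel,
    study_simulation_config,
    two_locus_dprime,
)


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = study_simulation_config(true_age=43, seed=9, with_families=True)
        a = simulate_founder_panel(cfg)
        b = simulate_founder_panel(cfg)
        assert a.truth == b.truth
        assert [(r.sample_id, r.genotypes) for r in a.records] == [
            (r.sample_id, r.genotypes) for r in b.records
        ]

    def test_different_seed_differs(self):
        a = simulate_founder_panel(study_simulation_config(seed=1, with_families=False))
        b = simulate_founder_panel(study_simulation_config(seed=2, with_families=False))
        assert a.truth["ancestral"] != b.truth["ancestral"] or (
            a.records[0].genotypes != b.records[0].genotypes
        )


class TestYoungFounder:
    def test_core_intact_immediately_after_founding(self):
        """At age 1 the core markers cannot have recombined (theta ~ 7.6e-5)."""
        from dataclasses import replace

        cfg = study_simulation_config(true_age=1, seed=3, with_families=False)
        cfg = replace(cfg, n_carriers=2)
        res = simulate_founder_panel(cfg)
        anc = res.truth["ancestral"]
        core_idx = [cfg.panel.index(n) for n in
                    ("rs3219828", "rs2266782", "rs2266780", "rs2234708")]
        for h in res.haplotype_set.carriers:
            for i in core_idx:
                assert h.alleles[i] == anc[i]


class TestOldFounder:
    def test_ld_fully_decayed_at_old_age(self):
        """At an age where the outermost markers have seen ~6-7 expected
        crossovers per lineage, carrier allele frequencies there match the
        control frequencies within 3 binomial SEs.  (Growth is slowed so
        the surviving class stays forward-simulable; a surviving
        birth-death class scales like (lambda/d) exp(d t), which rules
        out literal 1e4-generation forward runs.)"""
        from dataclasses import replace

        cfg = study_simulation_config(
            true_age=250, seed=4, with_families=False,
            demography=fa.DemographyConfig(growth_rate=0.02),
        )
        cfg = replace(cfg, n_carriers=30)
        res = simulate_founder_panel(cfg)
        anc = res.truth["ancestral"]
        freqs = dict(zip(cfg.panel.names, cfg.control_allele_freqs))
        n = len(res.haplotype_set.carriers)
        for name in ("D1S1165", "rs3223566"):
            i = cfg.panel.index(name)
            p = freqs[name].get(anc[i], 0.0)
            hits = sum(1 for h in res.haplotype_set.carriers if h.alleles[i] == anc[i])
            se = math.sqrt(p * (1 - p) / n)
            assert abs(hits / n - p) < 3 * se + 1e-9


class TestEndToEndProperties:
    def test_core_recovered_in_most_seeds(self):
        """find_shared_core recovers a nonempty core containing the variant
        in at least 95 of 100 seeds on study-shaped panels."""
        hits = 0
        for seed in range(100):
            cfg = study_simulation_config(true_age=43, seed=seed, with_families=False)
            res = simulate_founder_panel(cfg)
            core = find_shared_core(res.haplotype_set, cfg.panel)
            if core.size > 0:
                hits += 1
        assert hits >= 95

    def test_retention_decays_with_distance(self):
        """Ancestral-allele retention decreases with marker distance
        (average Spearman correlation over 100 seeds is negative)."""
        rhos = []
        for seed in range(100):
            cfg = study_simulation_config(true_age=43, seed=5000 + seed,
                                          with_families=False)
            res = simulate_founder_panel(cfg)
            stats = panel_summary_stats(res)
            ok = stats["retention"].notna()
            rho = spearmanr(
                stats.loc[ok, "distance_to_variant_bp"], stats.loc[ok, "retention"]
            ).statistic
            if not math.isnan(rho):
                rhos.append(rho)
        assert np.mean(rhos) < -0.3

    def test_mean_copy_number_tracks_exponential_growth(self):
        """Unconditional forward birth-death mean copy number is exp(d t)."""
        from founderage._kernels import bd_forward

        t, d = 10.0, 0.095
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(20_000):
            _s, _c, _p, _tb, _al, n_alive = bd_forward(
                t, 1.0 + d, 1.0, int(rng.integers(2**31 - 1)), 4000
            )
            counts.append(n_alive)
        counts = np.array(counts)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert abs(counts.mean() - math.exp(d * t)) < 3 * se


class TestDprime:
    def test_complete_ld_toy_table(self):
        assert two_locus_dprime(10, 0, 0, 10) == pytest.approx(1.0)

    def test_equilibrium_is_zero(self):
        assert two_locus_dprime(25, 25, 25, 25) == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        assert math.isnan(two_locus_dprime(10, 0, 10, 0))

    def test_summary_reports_monomorphic_marker_as_nan(self, small_sim):
        cfg, res = small_sim
        stats = panel_summary_stats(res)
        row = stats[stats.marker == "rs6133"].iloc[0]
        assert math.isnan(row["dprime"])
        assert row["retention"] == 1.0  # monomorphic C always matches


class TestFamilies:
    def test_carriers_are_heterozygous(self, family_sim):
        _, res = family_sim
        for rec in res.records:
            if rec.status == fa.CARRIER:
                assert rec.variant_genotype == "het"

    def test_pedigree_data_is_mendelian_consistent(self, family_sim):
        """Pedigree phasing runs without Mendelian errors and identifies
        the variant chromosome of every affected child."""
        cfg, res = family_sim
        fam_records = [r for r in res.records if r.family_id]
        result = phase_pedigree(fam_records, res.pedigree, cfg.panel)
        children = [
            m.sample_id
            for m in res.pedigree.members.values()
            if m.father or m.mother
        ]
        affected_children = [
            s for s in children
            if any(r.sample_id == s and r.status == fa.CARRIER for r in fam_records)
        ]
        assert affected_children
        for sid in affected_children:
            assert result.variant_resolved[sid]

    def test_family_counts_match_study_shape(self, family_sim):
        cfg, res = family_sim
        carriers = [r for r in res.records if r.status == fa.CARRIER]
        in_families = [r for r in carriers if r.family_id]
        assert len(carriers) == 51
        assert len(in_families) == 35
        assert len({r.family_id for r in in_families}) == 3
        controls = [r for r in res.records
                    if r.status == fa.CONTROL and not r.family_id]
        assert len(controls) == 32

    def test_conditioned_copy_band_respected(self):
        cfg = study_simulation_config(
            true_age=43, seed=6, with_families=True, condition_on_implied_copies=True
        )
        res = simulate_founder_panel(cfg)
        lo, hi = cfg.condition_copies
        assert lo <= res.truth["population_copies"] <= hi
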