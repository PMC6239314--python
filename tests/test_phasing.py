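import itertools

import numpy as np
import pytest

import founderage as fa
from founderage.datamodel import MISSING, GenotypeRecord, ValidationError
from founderage.phasing import (
    MendelianError,
    Pedigree,
    PedigreeMember,
    _compatible_pairs,
    assign_most_probable_phase,
    em_haplotype_inference,
    find_shared_core,
    phase_pedigree,
)


def _panel(n_markers=2, alleles_per=3):
    markers = tuple(
        fa.Marker(f"m{i}", fa.STR, "1", 1_000_000 * (i + 1)) for i in range(n_markers)
    )
    variant = fa.Marker("var", fa.SNP, "1", markers[0].position_bp + 1)
    return fa.MarkerPanel(markers=markers, focal_variant=variant)


def _rec(panel, sid, genos, vg="absent", status="control", fam="F1"):
    return GenotypeRecord(
        sample_id=sid,
        status=status,
        genotypes={m.name: g for m, g in zip(panel.markers, genos)},
        variant_genotype=vg,
        family_id=fam,
    )


def _trio_ped():
    return Pedigree(
        members={
            "dad": PedigreeMember("dad", "F1"),
            "mum": PedigreeMember("mum", "F1"),
            "kid": PedigreeMember("kid", "F1", father="dad", mother="mum"),
        }
    )


class TestPedigreePhasing:
    def test_homozygote_is_phased_regardless_of_parents(self):
        panel = _panel(1)
        ped = _trio_ped()
        recs = [
            _rec(panel, "dad", [("1", "2")]),
            _rec(panel, "mum", [("2", "3")]),
            _rec(panel, "kid", [("2", "2")]),
        ]
        res = phase_pedigree(recs, ped, panel)
        kid = [h for h in res.haplotype_set.haplotypes if h.sample_id == "kid"]
        assert all(h.alleles == ("2",) for h in kid)

    def test_forced_transmission(self):
        # father 1/1, mother 2/3, child 1/2 -> paternal 1, maternal 2
        panel = _panel(1)
        ped = _trio_ped()
        recs = [
            _rec(panel, "dad", [("1", "1")]),
            _rec(panel, "mum", [("2", "3")]),
            _rec(panel, "kid", [("1", "2")]),
        ]
        res = phase_pedigree(recs, ped, panel)
        kid = [h for h in res.haplotype_set.haplotypes if h.sample_id == "kid"]
        assert {h.alleles for h in kid} == {("1",), ("2",)}
        assert res.unphased_sites["kid"] == []

    def test_ambiguous_site_left_unphased(self):
        panel = _panel(1)
        ped = _trio_ped()
        recs = [
            _rec(panel, "dad", [("1", "2")]),
            _rec(panel, "mum", [("1", "2")]),
            _rec(panel, "kid", [("1", "2")]),
        ]
        res = phase_pedigree(recs, ped, panel)
        kid = [h for h in res.haplotype_set.haplotypes if h.sample_id == "kid"]
        assert all(h.alleles == (MISSING,) for h in kid)
        assert res.unphased_sites["kid"] == ["m0"]

    def test_mendelian_inconsistency_names_trio_and_marker(self):
        panel = _panel(1)
        ped = _trio_ped()
        recs = [
            _rec(panel, "dad", [("1", "1")]),
            _rec(panel, "mum", [("1", "1")]),
            _rec(panel, "kid", [("2", "3")]),
        ]
        with pytest.raises(MendelianError, match="kid") as exc:
            phase_pedigree(recs, ped, panel)
        assert "m0" in str(exc.value)

    def test_unknown_sample_rejected(self):
        panel = _panel(1)
        ped = _trio_ped()
        recs = [_rec(panel, "stranger", [("1", "1")])]
        with pytest.raises(ValidationError, match="stranger"):
            phase_pedigree(recs, ped, panel)

    def test_variant_chromosome_identified_with_noncarrier_parent(self):
        panel = _panel(1)
        ped = _trio_ped()
        recs = [
            _rec(panel, "dad", [("1", "2")], vg="het", status="carrier"),
            _rec(panel, "mum", [("3", "3")]),
            _rec(panel, "kid", [("2", "3")], vg="het", status="carrier"),
        ]
        res = phase_pedigree(recs, ped, panel)
        kid = {h.alleles: h.carries_variant for h in res.haplotype_set.haplotypes
               if h.sample_id == "kid"}
        # the paternal chromosome (allele 2, from the carrier father) carries it
        assert kid[("2",)] is True
        assert kid[("3",)] is False
        assert res.variant_resolved["kid"]

    def test_matches_exhaustive_enumeration_on_random_pedigrees(self):
        """Forced phases equal the consensus of all Mendelian-consistent
        full phase assignments found by brute force."""
        rng = np.random.default_rng(7)
        panel = _panel(4)
        for trial in range(12):
            # 3-generation pedigree: 2 grandparents, 2 parents, children
            members = {
                "gpa": PedigreeMember("gpa", "F1"),
                "gma": PedigreeMember("gma", "F1"),
                "dad": PedigreeMember("dad", "F1", father="gpa", mother="gma"),
                "mum": PedigreeMember("mum", "F1"),
            }
            n_kids = int(rng.integers(1, 4))
            for i in range(n_kids):
                members[f"k{i}"] = PedigreeMember(f"k{i}", "F1", father="dad", mother="mum")
            ped = Pedigree(members=members)
            # draw Mendelian-consistent genotypes by gene dropping
            haps = {}
            for founder in ("gpa", "gma", "mum"):
                haps[founder] = [
                    [str(rng.integers(1, 4)) for _ in range(4)] for _ in range(2)
                ]
            haps["dad"] = [
                [haps["gpa"][rng.integers(2)][l] for l in range(4)],
                [haps["gma"][rng.integers(2)][l] for l in range(4)],
            ]
            for i in range(n_kids):
                haps[f"k{i}"] = [
                    [haps["dad"][rng.integers(2)][l] for l in range(4)],
                    [haps["mum"][rng.integers(2)][l] for l in range(4)],
                ]
            recs = [
                _rec(
                    panel,
                    sid,
                    [tuple(sorted((haps[sid][0][l], haps[sid][1][l]))) for l in range(4)],
                )
                for sid in members
            ]
            result = phase_pedigree(recs, ped, panel)
            by_sample = {}
            for h in result.haplotype_set.haplotypes:
                by_sample.setdefault(h.sample_id, []).append(h.alleles)

            # oracle: per locus, enumerate all orientation assignments
            genos = {r.sample_id: [r.genotypes[m.name] for m in panel.markers]
                     for r in recs}
            ids = list(members)
            for l in range(4):
                consistent = []
                for combo in itertools.product([0, 1], repeat=len(ids)):
                    phased = {}
                    for sid, o in zip(ids, combo):
                        a, b = genos[sid][l]
                        phased[sid] = (a, b) if o == 0 else (b, a)
                    ok = True
                    for sid in ids:
                        mem = members[sid]
                        pat, mat = phased[sid]
                        if mem.father and pat not in genos[mem.father][l]:
                            ok = False
                            break
                        if mem.mother and mat not in genos[mem.mother][l]:
                            ok = False
                            break
                    if ok:
                        consistent.append(phased)
                assert consistent, "gene-dropped data must be consistent"
                for sid in ids:
                    vals = {c[sid] for c in consistent}
                    got = (by_sample[sid][0][l], by_sample[sid][1][l])
                    if len(vals) == 1:
                        assert got == next(iter(vals)), (trial, sid, l)
                    else:
                        a, b = genos[sid][l]
                        if a != b:  # ambiguous het must stay unphased
                            assert got == (MISSING, MISSING), (trial, sid, l)


class TestEM:
    def test_all_homozygous_equals_direct_counting(self):
        panel = _panel(2)
        recs = [
            _rec(panel, "a", [("1", "1"), ("2", "2")], fam=None),
            _rec(panel, "b", [("1", "1"), ("2", "2")], fam=None),
            _rec(panel, "c", [("3", "3"), ("1", "1")], fam=None),
        ]
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0)
        freqs = {h: f for h, f in zip(model.haplotypes, model.frequencies)}
        assert freqs[("1", "2")] == pytest.approx(2 / 3, abs=1e-9)
        assert freqs[("3", "1")] == pytest.approx(1 / 3, abs=1e-9)

    def test_single_diallelic_marker_equals_allele_counting(self):
        panel = _panel(1)
        recs = [
            _rec(panel, "a", [("1", "2")], fam=None),
            _rec(panel, "b", [("1", "1")], fam=None),
            _rec(panel, "c", [("2", "2")], fam=None),
            _rec(panel, "d", [("1", "2")], fam=None),
        ]
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0)
        freqs = {h: f for h, f in zip(model.haplotypes, model.frequencies)}
        assert freqs[("1",)] == pytest.approx(4 / 8, abs=1e-8)
        assert freqs[("2",)] == pytest.approx(4 / 8, abs=1e-8)

    def test_em_reaches_grid_search_optimum(self):
        """Two diallelic loci, 20 genotypes: the EM optimum log-likelihood
        matches a dense grid search over the haplotype-frequency simplex."""
        panel = _panel(2)
        rng = np.random.default_rng(3)
        true_f = np.array([0.4, 0.3, 0.2, 0.1])  # haplotypes 11, 12, 21, 22
        hap_pool = [("1", "1"), ("1", "2"), ("2", "1"), ("2", "2")]
        recs = []
        for i in range(20):
            h1 = hap_pool[rng.choice(4, p=true_f)]
            h2 = hap_pool[rng.choice(4, p=true_f)]
            recs.append(
                _rec(
                    panel,
                    f"s{i}",
                    [tuple(sorted((h1[l], h2[l]))) for l in range(2)],
                    fam=None,
                )
            )
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0,
                                       n_restarts=4, tol=1e-12, max_iter=5000)

        # independent oracle: dense grid over the 3-simplex, fully vectorised
        genos = [[r.genotypes[m.name] for m in panel.markers] for r in recs]
        masks = np.zeros((len(genos), 4, 4))
        for gi, g in enumerate(genos):
            for i, h1 in enumerate(hap_pool):
                for j, h2 in enumerate(hap_pool):
                    if all(tuple(sorted((h1[l], h2[l]))) == g[l] for l in range(2)):
                        masks[gi, i, j] = 1.0
        step = 0.02
        vals = np.arange(0, 1 + 1e-9, step)
        pts = [
            (f1, f2, f3, 1 - f1 - f2 - f3)
            for f1 in vals
            for f2 in vals
            if f1 + f2 <= 1 + 1e-9
            for f3 in vals
            if f1 + f2 + f3 <= 1 + 1e-9
        ]
        F = np.maximum(np.array(pts), 1e-12)
        outer = np.einsum("gi,gj->gij", F, F).reshape(len(F), 16)
        probs = outer @ masks.reshape(len(genos), 16).T  # (grid, genotypes)
        best = np.max(np.sum(np.log(probs), axis=1))
        assert model.loglik >= best - 1e-6

    def test_all_missing_individual_excluded_with_warning(self):
        panel = _panel(1)
        recs = [
            _rec(panel, "a", [(MISSING, MISSING)], fam=None),
            _rec(panel, "b", [("1", "2")], fam=None),
        ]
        with pytest.warns(UserWarning, match="all genotypes missing"):
            model = em_haplotype_inference(recs, panel, include_variant=False, seed=0)
        assert model.converged


class TestAssignPhase:
    def test_homozygote_has_posterior_one(self):
        panel = _panel(2)
        recs = [_rec(panel, "a", [("1", "1"), ("2", "2")], fam=None)]
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0)
        h1, h2, post = assign_most_probable_phase(model, recs[0])
        assert post == pytest.approx(1.0)
        assert h1.alleles == h2.alleles == ("1", "2")

    def test_complete_ld_resolves_double_het(self):
        panel = _panel(2)
        recs = [
            _rec(panel, "a", [("1", "1"), ("1", "1")], fam=None),
            _rec(panel, "b", [("2", "2"), ("2", "2")], fam=None),
            _rec(panel, "c", [("1", "2"), ("1", "2")], fam=None),
        ]
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0,
                                       tol=1e-14, max_iter=10_000)
        h1, h2, post = assign_most_probable_phase(model, recs[2])
        assert {h1.alleles, h2.alleles} == {("1", "1"), ("2", "2")}
        assert post > 0.99

    def test_posterior_equals_enumeration(self):
        """The reported posterior equals the weight of the chosen
        configuration among all consistent ones, enumerated directly."""
        panel = _panel(3)
        rng = np.random.default_rng(5)
        recs = []
        for i in range(12):
            genos = [tuple(sorted(rng.choice(["1", "2"], size=2))) for _ in range(3)]
            recs.append(_rec(panel, f"s{i}", genos, fam=None))
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=1)
        for rec in recs[:5]:
            h1, h2, post = assign_most_probable_phase(model, rec)
            g = [rec.genotypes[m.name] for m in panel.markers]
            pairs = _compatible_pairs(g, [("1", "2")] * 3)
            weights = []
            for a, b in pairs:
                mult = 1.0 if a == b else 2.0
                weights.append(mult * model.frequency_of(a) * model.frequency_of(b))
            assert post == pytest.approx(max(weights) / sum(weights), rel=1e-9)

    def test_inconsistent_record_rejected(self):
        panel = _panel(1)
        recs = [_rec(panel, "a", [("1", "1")], fam=None)]
        model = em_haplotype_inference(recs, panel, include_variant=False, seed=0)
        odd = _rec(panel, "z", [("7", "7")], fam=None)
        with pytest.raises(ValidationError, match="inconsistent"):
            assign_most_probable_phase(model, odd)


class TestSharedCore:
    def _haps(self, rows, carries=True):
        return [
            fa.Haplotype(alleles=tuple(r), carries_variant=carries, sample_id=f"s{i}")
            for i, r in enumerate(rows)
        ]

    def test_identical_carriers_give_whole_panel(self, study):
        panel, _ = study
        row = ["1"] * len(panel)
        core = find_shared_core(self._haps([row] * 5), panel)
        assert core.size == len(panel)
        assert all(f == 1.0 for f in core.match_fractions)

    def test_constructed_central_core(self):
        markers = tuple(
            fa.Marker(f"m{i}", fa.STR, "1", 1_000_000 * (i + 1)) for i in range(8)
        )
        variant = fa.Marker("var", fa.SNP, "1", 4_500_000)
        panel = fa.MarkerPanel(markers=markers, focal_variant=variant, window_bp=10_000_000)
        rng = np.random.default_rng(0)
        rows = []
        for i in range(30):
            row = [str(rng.integers(1, 30)) for _ in range(8)]  # effectively unique
            row[2:6] = ["5", "5", "5", "5"]  # conserved core around the variant
            rows.append(row)
        core = find_shared_core(self._haps(rows), panel)
        assert core.marker_names == ["m2", "m3", "m4", "m5"]
        assert core.alleles == ["5"] * 4

    def test_study_fixture_recovers_four_marker_core(self, small_sim):
        cfg, res = small_sim
        core = find_shared_core(res.haplotype_set, cfg.panel)
        assert set(core.marker_names) == {
            "rs3219828",
            "rs2266782",
            "rs2266780",
            "rs2234708",
        }

    def test_invariant_under_carrier_permutation(self, small_sim):
        cfg, res = small_sim
        carriers = res.haplotype_set.carriers
        core1 = find_shared_core(carriers, cfg.panel)
        core2 = find_shared_core(carriers[::-1], cfg.panel)
        assert core1.marker_names == core2.marker_names
        assert core1.alleles == core2.alleles

    def test_no_core_warns_and_returns_empty(self):
        markers = (
            fa.Marker("a", fa.STR, "1", 1_000_000),
            fa.Marker("b", fa.STR, "1", 2_000_000),
        )
        panel = fa.MarkerPanel(
            markers=markers, focal_variant=fa.Marker("v", fa.SNP, "1", 1_500_000)
        )
        rows = [[str(2 * i + 1), str(2 * i + 2)] for i in range(10)]
        with pytest.warns(UserWarning, match="empty core"):
            core = find_shared_core(self._haps(rows), panel)
        assert core.size == 0
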