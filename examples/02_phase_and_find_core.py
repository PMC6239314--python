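"""Phase raw genotypes and locate the conserved founder core.

Families are phased by Mendelian pedigree analysis, unrelated samples by
variant-anchored two-locus EM; the shared core is the contiguous marker
window around the variant carried intact by every carrier chromosome.
"""

import founderage as fa

cfg = fa.study_simulation_config(true_age=43, seed=7, with_families=True)
sim = fa.simulate_founder_panel(cfg)

hapset = fa.phase_panel(sim.records, cfg.panel, sim.pedigree, seed=7)
print(f"phased chromosomes: {len(hapset.haplotypes)}")
print(f"variant-bearing chromosomes identified: {len(hapset.carriers)}")

core = fa.find_shared_core(hapset, cfg.panel)
print()
print("conserved core around the variant:")
print(core.to_frame().to_string(index=False))
print()
print(
    "All carrier chromosomes share one allele at each core marker — the\n"
    "signature of descent from a single founder chromosome.  Markers\n"
    "monomorphic in the population (rs6133) carry no such evidence and are\n"
    "omitted; more distant markers have already recombined on some carriers."
)
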