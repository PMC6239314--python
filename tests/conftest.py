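import pytest

import founderage as fa


@pytest.fixture(scope="session")
def study():
    """Study-shaped panel and map (12 markers in 5 Mb around the variant)."""
    panel, gmap = fa.study_panel()
    return panel, gmap


@pytest.fixture(scope="session")
def toy_panel():
    """Two STRs and one SNP bracketing the variant."""
    markers = (
        fa.Marker("m1", fa.STR, "1", 1_000_000),
        fa.Marker("m2", fa.SNP, "1", 1_500_000),
        fa.Marker("m3", fa.STR, "1", 2_000_000),
    )
    variant = fa.Marker("var", fa.SNP, "1", 1_600_000)
    return fa.MarkerPanel(markers=markers, focal_variant=variant, window_bp=5_000_000)


@pytest.fixture(scope="session")
def toy_map():
    return fa.GeneticMap.uniform(900_000, 2_100_000, rate_cM_per_Mb=1.0)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated founder panel reused by read-only tests."""
    cfg = fa.study_simulation_config(true_age=43, seed=11, with_families=False)
    return cfg, fa.simulate_founder_panel(cfg)


@pytest.fixture(scope="session")
def family_sim():
    """Study-shaped simulation including the three families."""
    cfg = fa.study_simulation_config(true_age=43, seed=5, with_families=True)
    return cfg, fa.simulate_founder_panel(cfg)
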