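import pytest

from famshare.simulate import (
    SimulationConfig,
    default_gene_models,
    default_pathogenic_plan,
    default_pedigrees,
    gene_drop,
    plant_pathogenic_variants,
    simulate_frequency_panel,
    simulate_variant_sites,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        chrom_lengths_bp={"chr1": 60_000_000, "chr2": 60_000_000, "chr3": 40_000_000},
        n_variants=1200,
        pathogenic_plan=default_pathogenic_plan(),
    )


@pytest.fixture(scope="session")
def pedigree():
    return default_pedigrees()


@pytest.fixture(scope="session")
def small_world(small_config, pedigree):
    """One simulated two-family dataset shared across tests: sites, panel,
    raw gene-drop genotypes + truth, and the planted version."""
    genes = default_gene_models(small_config)
    sites = simulate_variant_sites(small_config, genes)
    panel = simulate_frequency_panel(small_config, sites)
    gm, truth = gene_drop(pedigree, panel, small_config, sites)
    gm_planted, plant_truth = plant_pathogenic_variants(
        sites, gm, pedigree, genes, small_config.pathogenic_plan, small_config, panel=panel
    )
    truth.true_deleterious = plant_truth.true_deleterious
    truth.planted = plant_truth.planted
    return {
        "config": small_config,
        "pedigree": pedigree,
        "genes": genes,
        "sites": sites,
        "panel": panel,
        "gm_raw": gm,
        "gm": gm_planted,
        "truth": truth,
    }
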