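"""Gene-drop simulator: determinism, Mendelian transmission, true-IBD
structure, planting and predictor noise."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from famshare.models import Region
from famshare.simulate import (
    MendelianError,
    PlantSpec,
    SimulationConfig,
    default_gene_models,
    default_pedigrees,
    gene_drop,
    ibd1_fraction,
    plant_pathogenic_variants,
    simulate_frequency_panel,
    simulate_predictions,
    simulate_variant_sites,
    write_fixture_bundle,
)


def test_fixture_bundle_is_byte_deterministic(tmp_path):
    cfg = SimulationConfig(
        seed=11, n_variants=300,
        chrom_lengths_bp={"chr1": 30_000_000, "chr2": 30_000_000, "chr3": 20_000_000},
        pathogenic_plan=[PlantSpec("COL12A1", 1)],
    )
    p1 = write_fixture_bundle(tmp_path / "a", cfg)
    p2 = write_fixture_bundle(tmp_path / "b", cfg)
    for name in p1:
        assert filecmp.cmp(p1[name], p2[name], shallow=False), f"{name} differs"


def test_panel_requires_populations_and_is_seed_deterministic():
    with pytest.raises(ValueError):
        SimulationConfig(populations=(), rare_population="X")
    cfg = SimulationConfig(seed=3, n_variants=100)
    sites = simulate_variant_sites(cfg)
    p1 = simulate_frequency_panel(cfg, sites)
    p2 = simulate_frequency_panel(cfg, sites)
    for k in p1.keys():
        assert p1.row(k) == p2.row(k)


def test_panel_rare_fraction_one_forces_rarity():
    cfg = SimulationConfig(seed=5, n_variants=200, rare_fraction=1.0)
    sites = simulate_variant_sites(cfg)
    panel = simulate_frequency_panel(cfg, sites)
    for v in sites:
        af = panel.get(v.key, cfg.rare_population)
        assert min(af, 1 - af) <= 0.05


def test_panel_rare_fraction_matches_binomial_oracle():
    # binomial sampling oracle: observed rare share within 3 SE of target
    cfg = SimulationConfig(seed=13, n_variants=10_000, rare_fraction=0.3)
    sites = simulate_variant_sites(cfg)
    panel = simulate_frequency_panel(cfg, sites)
    n_rare = sum(
        1 for v in sites if min(panel.get(v.key, cfg.rare_population),
                                1 - panel.get(v.key, cfg.rare_population)) <= 0.05
    )
    se = np.sqrt(0.3 * 0.7 / len(sites))
    # common variants can also land below 0.05 MAF, so the observed share
    # may exceed the planted fraction slightly; the Balding-Nichols draw
    # leaves ~4% of common draws under the threshold
    observed = n_rare / len(sites)
    assert observed >= 0.3 - 3 * se
    assert observed <= 0.3 + 0.08 + 3 * se


def test_mz_twins_identical_and_fully_ibd(small_world):
    gm, truth, cfg = small_world["gm_raw"], small_world["truth"], small_world["config"]
    assert np.array_equal(gm.column("A_twin1"), gm.column("A_twin2"))
    assert np.array_equal(gm.column("B_twin3"), gm.column("B_twin4"))
    # true IBD between MZ twins covers every chromosome end to end
    for pair in (("A_twin1", "A_twin2"), ("B_twin3", "B_twin4")):
        segs = truth.pair_segments(*pair)
        by_chrom = {c: [] for c in cfg.chrom_lengths_bp}
        for s in segs:
            by_chrom[s.chrom].append(s)
        for chrom, length in cfg.chrom_lengths_bp.items():
            assert len(by_chrom[chrom]) == 1
            (s,) = by_chrom[chrom]
            assert s.start_bp == 1 and s.end_bp == length


def test_mendelian_consistency_every_site(small_world):
    gm, pedigree = small_world["gm_raw"], small_world["pedigree"]
    for ind in pedigree:
        if ind.is_founder:
            continue
        child = gm.column(ind.id)
        for pid in (ind.father_id, ind.mother_id):
            parent = gm.column(pid)
            # child cannot be hom-ref where parent is hom-alt and vice versa
            assert not ((child == 0) & (parent == 2)).any()
            assert not ((child == 2) & (parent == 0)).any()


def test_every_allele_traces_to_founder_haplotype(small_world):
    # conservation: haplotype alleles equal the founder haplotype allele on
    # the ancestry track at every site (spot-check one non-founder)
    gm, truth, cfg = small_world["gm_raw"], small_world["truth"], small_world["config"]
    sites = small_world["sites"]
    pedigree = small_world["pedigree"]
    founders = {i.id for i in pedigree if i.is_founder}
    founder_hap = {}
    for fid in founders:
        for c in cfg.chrom_lengths_bp:
            for h in (0, 1):
                track = truth.founder_origin[fid][c][h]
                founder_hap[track[0][2]] = (fid, h)
    child = "A_brother"
    j = gm.sample_index(child)
    for c in list(cfg.chrom_lengths_bp)[:1]:
        rows = [i for i, v in enumerate(sites) if v.chrom == c]
        for h in (0, 1):
            track = truth.founder_origin[child][c][h]
            for i in rows[:200]:
                pos = sites[i].pos
                fid_hap = next(f for s, e, f in track if s <= pos <= e)
                fid, fh = founder_hap[fid_hap]
                jf = gm.sample_index(fid)
                assert gm.haplotypes[h][i, j] == gm.haplotypes[fh][i, jf]


def test_true_ibd_implies_allele_sharing(small_world):
    # inside any true IBD segment the pair shares >= 1 allele IBS
    gm, truth = small_world["gm_raw"], small_world["truth"]
    sites = small_world["sites"]
    for s in truth.true_ibd[:40]:
        g1, g2 = gm.column(s.id1), gm.column(s.id2)
        for i, v in enumerate(sites):
            if v.chrom == s.chrom and s.start_bp <= v.pos <= s.end_bp:
                assert not (g1[i] == 0 and g2[i] == 2)
                assert not (g1[i] == 2 and g2[i] == 0)


def test_sib_pair_ibd1_fraction_near_expectation():
    # quick version of the analytic sib-pair check: E[IBD>=1] = 0.75
    cfg = SimulationConfig(
        seed=21, n_variants=0,
        chrom_lengths_bp={f"c{i}": 500_000_000 for i in range(7)},  # 35 Morgans
    )
    ped = default_pedigrees()[:5]  # Family A only
    fracs = []
    for rep in range(30):
        rep_cfg = SimulationConfig(
            seed=1000 + rep, n_variants=0, chrom_lengths_bp=cfg.chrom_lengths_bp
        )
        _, truth = gene_drop(ped, _empty_panel(rep_cfg), rep_cfg, variants=[])
        fracs.append(ibd1_fraction(truth, "A_twin1", "A_brother", rep_cfg))
    mean = np.mean(fracs)
    se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
    assert abs(mean - 0.75) <= 3 * se + 1e-9


def _empty_panel(cfg):
    from famshare.models import PopulationFrequency

    return PopulationFrequency(populations=list(cfg.populations))


def test_half_specified_parent_rejected():
    from famshare.models import Individual, PedigreeError, Sex

    ped = [
        Individual("f", "F", None, None, Sex.male),
        Individual("m", "F", None, None, Sex.female),
        Individual("c", "F", "f", None, Sex.male),
    ]
    cfg = SimulationConfig(seed=1, n_variants=10)
    with pytest.raises(PedigreeError):
        gene_drop(ped, _empty_panel(cfg), cfg, variants=[])


# ---------------------------------------------------------------------------
# Planting


def test_planting_sets_affected_homozygous(small_world):
    gm, truth, pedigree = small_world["gm"], small_world["truth"], small_world["pedigree"]
    assert len(truth.true_deleterious) == 7  # 3+ shared (1+1+2) + 3 private
    row = {k: i for i, k in enumerate(gm.variant_keys)}
    for gene, info in truth.planted.items():
        for key in info["variants"]:
            r = row[key]
            for ind in pedigree:
                if ind.affected and ind.family_id in info["families"]:
                    assert gm.genotypes[r, gm.sample_index(ind.id)] == 2, (gene, ind.id)


def test_empty_plan_leaves_genotypes_unchanged(small_world):
    sites, pedigree, genes, cfg = (
        small_world["sites"], small_world["pedigree"],
        small_world["genes"], small_world["config"],
    )
    gm = small_world["gm_raw"]
    gm2, truth = plant_pathogenic_variants(sites, gm, pedigree, genes, [], cfg)
    assert truth.true_deleterious == set()
    assert np.array_equal(gm.genotypes, gm2.genotypes)


def test_impossible_carrier_pattern_raises(small_world):
    sites, pedigree, genes, cfg = (
        small_world["sites"], small_world["pedigree"],
        small_world["genes"], small_world["config"],
    )
    gm = small_world["gm_raw"]
    # forcing a founder of affected homozygotes to 0/0 is Mendelian-impossible
    with pytest.raises(MendelianError):
        plant_pathogenic_variants(
            sites, gm, pedigree, genes,
            [PlantSpec("COL12A1", 1, "all_affected_homozygous", ["FamilyA"])],
            cfg,
            forced_genotypes={"COL12A1": {"A_mother": 0}},
        )


# ---------------------------------------------------------------------------
# Predictor simulation


def test_perfect_predictors_are_noise_free(small_world):
    cfg = SimulationConfig(
        seed=2, n_variants=0, predictor_sensitivity=1.0, predictor_specificity=1.0
    )
    truth = small_world["truth"]
    sites = small_world["sites"]
    profiles = simulate_predictions(sites, truth, cfg)
    for v in sites:
        votes = profiles[v.key].qualifying_votes()
        assert votes == (21 if v.key in truth.true_deleterious else 0)


@pytest.mark.parametrize(
    "sens,spec,true_variant", [(0.9, 1.0, True), (1.0, 0.95, False)]
)
def test_vote_rates_match_binomial_tail(sens, spec, true_variant):
    """Retention of simulated profiles matches the exact Bin(21, p) tail."""
    n = 5000
    cfg = SimulationConfig(
        seed=17, n_variants=0, predictor_sensitivity=sens, predictor_specificity=spec
    )
    cfg2 = SimulationConfig(seed=17, n_variants=n, rare_fraction=0.0)
    sites = simulate_variant_sites(cfg2, genes=[])
    from famshare.simulate import GroundTruth

    truth = GroundTruth(
        true_deleterious={v.key for v in sites} if true_variant else set()
    )
    profiles = simulate_predictions(sites, truth, cfg)
    retained = sum(p.qualifying_votes() >= 17 for p in profiles.values())
    p_site = sens if true_variant else (1 - spec)
    expected = stats.binom.sf(16, 21, p_site)
    se = np.sqrt(expected * (1 - expected) / len(sites)) + 1e-12
    assert abs(retained / len(sites) - expected) <= 3 * se + 1e-9
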