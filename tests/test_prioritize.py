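"""Casting-vote consensus, rarity/consequence/carrier filters, per-family
reports and the cross-family gene intersection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famshare import reference_data as ref
from famshare.models import PredictionProfile, Variant
from famshare.prioritize import (
    CandidateGeneReport,
    ConfigError,
    casting_vote,
    family_carrier_filter,
    filter_consequence,
    filter_rare,
    intersect_families,
    prioritize_family,
)


# ---------------------------------------------------------------------------
# Casting vote


def _profile(statuses):
    return PredictionProfile("chr1:1:A:C", list(statuses))


def test_unanimous_damaging_retained():
    assert casting_vote(_profile(["D"] * 21)) is True


def test_sixteen_votes_fall_short_of_threshold():
    assert casting_vote(_profile(["D"] * 16 + ["T"] * 5)) is False


def test_threshold_is_inclusive_and_automatic_counts():
    assert casting_vote(_profile(["D"] * 16 + ["A"] + ["T"] * 4)) is True
    # U never qualifies even though it is not a benign call
    assert casting_vote(_profile(["D"] * 16 + ["U"] * 5)) is False


def test_min_votes_above_tool_count_is_config_error():
    with pytest.raises(ConfigError):
        casting_vote(_profile(["D"] * 21), min_votes=22)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.lists(st.sampled_from("DATU"), min_size=21, max_size=21))
def test_casting_vote_equals_brute_force_count(statuses):
    oracle = len([s for s in statuses if s == "D" or s == "A"]) >= 17
    assert casting_vote(_profile(statuses)) == oracle


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(st.sampled_from("DATU"), min_size=21, max_size=21),
    st.integers(min_value=0, max_value=20),
)
def test_vote_monotonicity(statuses, i):
    """Upgrading one status to qualifying never flips retained -> dropped;
    raising min_votes never grows the retained set."""
    before = casting_vote(_profile(statuses))
    upgraded = list(statuses)
    upgraded[i] = "D"
    assert casting_vote(_profile(upgraded)) >= before
    for lo, hi in [(5, 10), (10, 17), (17, 21)]:
        assert casting_vote(_profile(statuses), lo) >= casting_vote(_profile(statuses), hi)


# ---------------------------------------------------------------------------
# Rarity filter (worked example: the COL12A1 shared variant is rare in the
# African panel, AF 0.0026, yet common in the European panel, AF 0.73)


@pytest.fixture(scope="module")
def exac():
    return ref.exac_panel()


@pytest.fixture(scope="module")
def shared_variants():
    return {v.rsid: v for v in ref.shared_variant_objects()}


def test_rs970547_rare_in_afr_only(exac, shared_variants):
    v = shared_variants["rs970547"]
    assert filter_rare(v, exac, max_af=0.01, scope=["AFR"], scope_mode="all") is True
    assert filter_rare(v, exac, max_af=0.01, scope=["AFR", "EUR"], scope_mode="all") is False
    assert filter_rare(v, exac, max_af=0.01, scope=["AFR", "EUR"], scope_mode="any") is True


def test_max_af_one_accepts_everything(exac, shared_variants):
    for v in shared_variants.values():
        assert filter_rare(v, exac, max_af=1.0)


def test_absent_variant_counts_as_rare(exac):
    novel = Variant("chr9", 1, "A", "G", region="exonic", consequence="nonsynonymous")
    assert filter_rare(novel, exac, max_af=0.0001)


def test_unknown_scope_population_is_config_error(exac, shared_variants):
    with pytest.raises(ConfigError):
        filter_rare(shared_variants["rs970547"], exac, scope=["MARS"])


# ---------------------------------------------------------------------------
# Consequence filter


@pytest.mark.parametrize(
    "region,consequence,expected",
    [
        ("exonic", "nonsynonymous", True),
        ("exonic", "stopgain", True),
        ("exonic", "stoploss", True),
        ("exonic", "synonymous", False),
        ("intronic", None, False),
        ("intergenic", None, False),
    ],
)
def test_consequence_filter(region, consequence, expected):
    v = Variant("chr1", 10, "A", "C", region=region, consequence=consequence)
    assert filter_consequence(v) is expected


# ---------------------------------------------------------------------------
# Carrier filter


def test_carrier_filter_homozygous_mode(small_world):
    gm, pedigree, truth = small_world["gm"], small_world["pedigree"], small_world["truth"]
    sites = small_world["sites"]
    planted_a = {
        k for g, info in truth.planted.items() if "FamilyA" in info["families"]
        for k in info["variants"]
    }
    kept = family_carrier_filter(sites, gm, pedigree, "FamilyA", "all_affected_homozygous")
    assert planted_a <= kept
    # carry mode is a superset of homozygous mode
    carry = family_carrier_filter(sites, gm, pedigree, "FamilyA", "all_affected_carry")
    assert kept <= carry


def test_carrier_filter_drops_het_affected(small_world):
    gm, pedigree = small_world["gm"], small_world["pedigree"]
    sites = small_world["sites"]
    gm2 = gm.subset_samples(gm.samples)
    gm2.haplotypes = None
    key = next(iter(small_world["truth"].true_deleterious))
    r = gm2.variant_keys.index(key)
    gm2.genotypes[r, gm2.sample_index("A_twin1")] = 1
    kept = family_carrier_filter(sites, gm2, pedigree, "FamilyA", "all_affected_homozygous")
    assert key not in kept


def test_carrier_filter_requires_affected(small_world):
    gm, sites = small_world["gm"], small_world["sites"]
    from famshare.models import Individual, Sex

    lone = [Individual("x", "FamX", None, None, Sex.male, affected=False)]
    with pytest.raises(ConfigError):
        family_carrier_filter(sites, gm, lone, "FamX")


# ---------------------------------------------------------------------------
# Full per-family prioritization on the planted fixture


@pytest.fixture(scope="module")
def perfect_profiles(small_world):
    from famshare.simulate import SimulationConfig, simulate_predictions

    cfg = SimulationConfig(seed=3, n_variants=0, predictor_sensitivity=1.0,
                           predictor_specificity=1.0)
    return simulate_predictions(small_world["sites"], small_world["truth"], cfg)


def _report(small_world, profiles, family):
    return prioritize_family(
        family,
        small_world["sites"],
        small_world["gm"],
        small_world["pedigree"],
        profiles,
        small_world["panel"],
        max_af=0.05,
        scope=[small_world["config"].rare_population],
        scope_mode="all",
        carrier_mode="all_affected_homozygous",
    )


def test_prioritize_family_recovers_planted_genes(small_world, perfect_profiles):
    truth = small_world["truth"]
    rep_a = _report(small_world, perfect_profiles, "FamilyA")
    rep_b = _report(small_world, perfect_profiles, "FamilyB")
    planted_a = {g for g, i in truth.planted.items() if "FamilyA" in i["families"]}
    planted_b = {g for g, i in truth.planted.items() if "FamilyB" in i["families"]}
    assert set(rep_a.genes) == planted_a
    assert set(rep_b.genes) == planted_b
    shared, union = intersect_families([rep_a, rep_b])
    assert shared == planted_a & planted_b == {"COL12A1", "CATSPER2", "KCNJ12"}
    assert set(union) == planted_a | planted_b


def test_lowering_vote_threshold_only_grows_report(small_world, perfect_profiles):
    sizes = []
    for min_votes in (21, 17, 10, 1, 0):
        rep = prioritize_family(
            "FamilyA", small_world["sites"], small_world["gm"], small_world["pedigree"],
            perfect_profiles, small_world["panel"],
            max_af=0.05, scope=[small_world["config"].rare_population],
            scope_mode="all", min_votes=min_votes,
            carrier_mode="all_affected_homozygous",
        )
        sizes.append({v.key for v in rep.retained})
    for smaller, bigger in zip(sizes, sizes[1:]):
        assert smaller <= bigger


def test_filter_predicates_commute(small_world, perfect_profiles):
    """rarity, consequence and vote are per-variant predicates: any
    application order retains the same variant set."""
    sites = small_world["sites"][:300]
    panel = small_world["panel"]
    cfg = small_world["config"]
    preds = {
        "rare": lambda v: filter_rare(v, panel, 0.05, [cfg.rare_population], "all"),
        "csq": filter_consequence,
        "vote": lambda v: v.key in perfect_profiles and casting_vote(perfect_profiles[v.key]),
    }
    results = set()
    for order in itertools.permutations(preds.values()):
        kept = [v for v in sites if all(p(v) for p in order)]
        results.add(frozenset(v.key for v in kept))
    assert len(results) == 1


def test_no_survivors_is_valid_empty_report(small_world, perfect_profiles):
    rep = prioritize_family(
        "FamilyA", small_world["sites"], small_world["gm"], small_world["pedigree"],
        perfect_profiles, small_world["panel"],
        max_af=0.0, scope=[small_world["config"].rare_population], scope_mode="all",
        carrier_mode="all_affected_homozygous",
    )
    assert rep.genes == [] and rep.retained == []


# ---------------------------------------------------------------------------
# Cross-family intersection worked example


def _gene_list_report(family, genes):
    return CandidateGeneReport(
        family_id=family,
        retained=[],
        gene_support={g: [f"{g}:support"] for g in genes},
        genes=list(genes),
    )


def test_published_family_lists_intersect_to_three_genes():
    rep_a = _gene_list_report("FamilyA", ref.FAMILY_A_CANDIDATE_GENES)
    rep_b = _gene_list_report("FamilyB", ref.FAMILY_B_CANDIDATE_GENES)
    assert len(ref.FAMILY_A_CANDIDATE_GENES) == 29
    assert len(ref.FAMILY_B_CANDIDATE_GENES) == 18
    shared, union = intersect_families([rep_a, rep_b])
    assert shared == {"COL12A1", "CATSPER2", "KCNJ12"}
    shared_swapped, _ = intersect_families([rep_b, rep_a])
    assert shared_swapped == shared
    assert len(union) == 29 + 18 - 3


def test_identical_and_disjoint_reports():
    rep1 = _gene_list_report("F1", ["A", "B", "C"])
    rep2 = _gene_list_report("F2", ["A", "B", "C"])
    assert intersect_families([rep1, rep2])[0] == {"A", "B", "C"}
    rep3 = _gene_list_report("F3", ["X"])
    assert intersect_families([rep1, rep3])[0] == set()
    with pytest.raises(ConfigError):
        intersect_families([rep1])
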