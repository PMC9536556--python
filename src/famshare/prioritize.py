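"""Variant filtering, the 21-tool casting-vote consensus, and per-family
candidate gene lists with cross-family intersection.

The consensus rule retains a variant only if at least ``min_votes`` of the
configured predictor panel (default 17 of 21) call it damaging (status D)
or disease-causing-automatic (status A); unknown statuses (U) never qualify
and the denominator stays at the configured tool count. The surviving
variants are further required to be rare in the frequency panel, exonic
protein-altering, and carried by every affected family member under the
configured carrier mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import (
    Consequence,
    GenotypeMatrix,
    Individual,
    PopulationFrequency,
    PredictionProfile,
    Region,
    Variant,
)

logger = logging.getLogger("famshare")

QUALIFYING = frozenset({"D", "A"})
DEFAULT_CONSEQUENCES = frozenset(
    {Consequence.nonsynonymous, Consequence.stopgain, Consequence.stoploss}
)


class ConfigError(ValueError):
    pass


def casting_vote(
    profile: PredictionProfile,
    min_votes: int = 17,
    qualifying: frozenset = QUALIFYING,
) -> bool:
    """True iff >= ``min_votes`` statuses are qualifying (D or A)."""
    if min_votes > len(profile.statuses):
        raise ConfigError(
            f"min_votes {min_votes} exceeds tool count {len(profile.statuses)}"
        )
    return profile.qualifying_votes(qualifying) >= min_votes


def filter_rare(
    variant: Variant,
    panel: PopulationFrequency,
    max_af: float = 0.01,
    scope: Optional[Iterable[str]] = None,
    scope_mode: str = "any",
) -> bool:
    """True iff the alt-allele frequency is <= ``max_af`` in at least one
    (``scope_mode='any'``) or all (``'all'``) scope populations.

    A variant absent from the panel counts as frequency 0 (rare): novel
    family variants are exactly the interesting case. The occurrence is
    logged so absent-variant counts are auditable.
    """
    if scope_mode not in ("any", "all"):
        raise ConfigError(f"scope_mode must be 'any' or 'all', got {scope_mode!r}")
    pops = list(scope) if scope is not None else list(panel.populations)
    unknown = [p for p in pops if p not in panel.populations]
    if unknown:
        raise ConfigError(f"scope populations not in panel: {unknown}")
    if variant.key not in panel:
        logger.debug("variant %s absent from frequency panel; treated as rare", variant.key)
        return True
    tests = []
    for p in pops:
        af = panel.get(variant.key, p)
        tests.append((af if af is not None else 0.0) <= max_af)
    return any(tests) if scope_mode == "any" else all(tests)


def filter_consequence(
    variant: Variant, allowed: frozenset = DEFAULT_CONSEQUENCES
) -> bool:
    """True iff the variant is exonic with a protein-altering consequence."""
    return variant.region is Region.exonic and variant.consequence in allowed


def family_carrier_filter(
    variants: list[Variant],
    gm: GenotypeMatrix,
    pedigree: list[Individual],
    family_id: str,
    mode: str = "all_affected_carry",
) -> set[str]:
    """Keys of variants carried by every affected, genotyped family member.

    ``all_affected_carry`` requires genotype >= 1; ``all_affected_homozygous``
    requires genotype 2. Missing genotypes fail the test (strict).
    """
    if mode not in ("all_affected_carry", "all_affected_homozygous"):
        raise ConfigError(f"unknown carrier mode {mode!r}")
    affected = [
        i.id for i in pedigree
        if i.family_id == family_id and i.affected and i.id in gm.samples
    ]
    if not affected:
        raise ConfigError(f"family {family_id!r} has no genotyped affected members")
    need = 2 if mode == "all_affected_homozygous" else 1
    row_index = {k: r for r, k in enumerate(gm.variant_keys)}
    cols = [gm.sample_index(s) for s in affected]
    kept: set[str] = set()
    for v in variants:
        r = row_index.get(v.key)
        if r is None:
            continue
        gts = gm.genotypes[r, cols]
        if ((gts >= need) & (gts >= 0)).all():
            kept.add(v.key)
    return kept


@dataclass
class CandidateGeneReport:
    family_id: str
    retained: list[Variant]
    gene_support: dict[str, list[str]]  # gene -> supporting variant keys
    genes: list[str]  # ordered by (chrom, first supporting position)

    def __post_init__(self) -> None:
        for g in self.genes:
            if not self.gene_support.get(g):
                raise ValueError(f"gene {g} listed without a supporting variant")


def prioritize_family(
    family_id: str,
    variants: list[Variant],
    gm: GenotypeMatrix,
    pedigree: list[Individual],
    profiles: dict[str, PredictionProfile],
    panel: PopulationFrequency,
    max_af: float = 0.01,
    min_votes: int = 17,
    scope: Optional[Iterable[str]] = None,
    scope_mode: str = "any",
    carrier_mode: str = "all_affected_carry",
    allowed_consequences: frozenset = DEFAULT_CONSEQUENCES,
) -> CandidateGeneReport:
    """Run the full per-family prioritization: rarity -> consequence ->
    casting vote -> family carrier pattern; report retained variants and
    their genes ordered by genomic position of first support."""
    surviving = [
        v for v in variants
        if filter_rare(v, panel, max_af, scope, scope_mode)
        and filter_consequence(v, allowed_consequences)
        and v.key in profiles
        and casting_vote(profiles[v.key], min_votes)
    ]
    kept_keys = family_carrier_filter(surviving, gm, pedigree, family_id, carrier_mode)
    retained = [v for v in surviving if v.key in kept_keys]
    gene_support: dict[str, list[str]] = {}
    first_pos: dict[str, tuple[str, int]] = {}
    for v in sorted(retained, key=lambda v: (v.chrom, v.pos)):
        for g in v.genes:
            gene_support.setdefault(g, []).append(v.key)
            first_pos.setdefault(g, (v.chrom, v.pos))
    genes = sorted(gene_support, key=lambda g: first_pos[g])
    return CandidateGeneReport(
        family_id=family_id, retained=retained, gene_support=gene_support, genes=genes
    )


def intersect_families(
    reports: list[CandidateGeneReport],
) -> tuple[set[str], dict[str, dict[str, list[str]]]]:
    """Genes present in every family report.

    Returns the shared gene set and, for every gene in the union, the
    per-family supporting variant keys (empty list where a family lacks the
    gene), so callers can build membership-flag tables. Symmetric in report
    order.
    """
    if len(reports) < 2:
        raise ConfigError("cross-family intersection needs >= 2 family reports")
    shared = set(reports[0].genes)
    for rep in reports[1:]:
        shared &= set(rep.genes)
    union: dict[str, dict[str, list[str]]] = {}
    for rep in reports:
        for g in set().union(*(r.genes for r in reports)):
            union.setdefault(g, {})[rep.family_id] = list(rep.gene_support.get(g, []))
    return shared, union
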