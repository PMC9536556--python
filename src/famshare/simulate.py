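"""Pedigree gene-drop simulator with recombination-driven IBD structure.

Emulates the study design the pipeline analyses: two nuclear families, each
with a monozygotic twin pair, genotyped at SNP sites drawn against a
multi-population allele-frequency panel; "true deleterious" variants are
planted with a prescribed carrier pattern, and a configurable 21-tool
predictor panel emits noisy deleteriousness statuses. Ground truth (planted
variants, founder-haplotype ancestry tracks and the exact pairwise IBD
segments they imply) is exported alongside the fixtures so every downstream
stage can be verified.

Model: founder haplotypes are sampled per-site from the founder population's
allele frequency; each meiosis places crossovers as a Poisson process with a
uniform genetic map (``cm_per_mb``, no interference); monozygotic twins
receive copies of the same meiosis products. True IBD between two samples is
the union of maximal intervals on which any of their four haplotype pairings
carries the same founder haplotype id.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as fio
from .models import (
    Consequence,
    GeneModel,
    GenotypeMatrix,
    IBDSegment,
    Individual,
    PedigreeError,
    PopulationFrequency,
    PredictionProfile,
    Region,
    Sex,
    Variant,
    validate_pedigree,
)

#: 1000-Genomes-style panel labels used for the default 20-population panel.
DEFAULT_POPULATIONS: tuple[str, ...] = (
    "ACB", "ASW", "ESN", "GWD", "LWK", "MSL", "YRI",
    "CEU", "FIN", "GBR", "IBS", "TSI",
    "CDX", "CHB", "CHS", "JPT", "KHV",
    "BEB", "GIH", "ITU",
)


class MendelianError(ValueError):
    """A requested carrier pattern is impossible under Mendelian transmission."""


@dataclass
class PlantSpec:
    """One planted-gene instruction: n true deleterious variants in a gene,
    carried per ``pattern`` by the affected members of ``families``
    (None = every family in the pedigree)."""

    gene: str
    n_variants: int = 1
    pattern: str = "all_affected_homozygous"  # or all_affected_carry
    families: Optional[list[str]] = None


@dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths_bp: dict[str, int] = field(
        default_factory=lambda: {"chr1": 100_000_000, "chr2": 100_000_000, "chr3": 60_000_000}
    )
    cm_per_mb: float = 1.0
    n_variants: int = 4000
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    #: fraction of variants forced rare (MAF <= 0.05) in ``rare_population``
    rare_fraction: float = 0.3
    rare_population: str = "ACB"
    #: Balding–Nichols-style between-population spread of common variants
    fst: float = 0.05
    #: guaranteed exonic sites laid inside every fixture gene
    min_sites_per_gene: int = 5
    founder_population: str = "GBR"
    pathogenic_plan: list[PlantSpec] = field(default_factory=list)
    predictor_sensitivity: float = 0.95
    predictor_specificity: float = 0.99
    genotype_error_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, p in (
            ("rare_fraction", self.rare_fraction),
            ("predictor_sensitivity", self.predictor_sensitivity),
            ("predictor_specificity", self.predictor_specificity),
            ("genotype_error_rate", self.genotype_error_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if len(self.populations) < 1:
            raise ValueError("need at least one population")
        if self.rare_population not in self.populations:
            raise ValueError(f"rare_population {self.rare_population!r} not in panel")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream so stages do not perturb each other's draws."""
        # stable across processes (built-in str hash is salted)
        digest = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng(np.random.SeedSequence((self.seed, digest)))


# ---------------------------------------------------------------------------
# Study-shaped fixtures


def default_pedigrees() -> list[Individual]:
    """Two-family structure mirroring the study: Family A = father, mother,
    MZ twins, brother (father, twins and brother affected); Family B =
    father (deceased, not genotyped), mother, MZ twins, sister (twins
    affected)."""
    a, b = "FamilyA", "FamilyB"
    inds = [
        Individual("A_father", a, None, None, Sex.male, affected=True),
        Individual("A_mother", a, None, None, Sex.female, affected=False),
        Individual("A_twin1", a, "A_father", "A_mother", Sex.male, affected=True, mz_group="A_MZ"),
        Individual("A_twin2", a, "A_father", "A_mother", Sex.male, affected=True, mz_group="A_MZ"),
        Individual("A_brother", a, "A_father", "A_mother", Sex.male, affected=True),
        Individual("B_father", b, None, None, Sex.male, affected=False, genotyped=False),
        Individual("B_mother", b, None, None, Sex.female, affected=False),
        Individual("B_twin3", b, "B_father", "B_mother", Sex.male, affected=True, mz_group="B_MZ"),
        Individual("B_twin4", b, "B_father", "B_mother", Sex.male, affected=True, mz_group="B_MZ"),
        Individual("B_sister", b, "B_father", "B_mother", Sex.female, affected=False),
    ]
    validate_pedigree(inds)
    return inds


def default_gene_models(config: SimulationConfig) -> list[GeneModel]:
    """Fixture gene spans (synthetic coordinates, field-realistic symbols)."""
    lengths = config.chrom_lengths_bp
    chroms = list(lengths)
    spans = [
        ("COL12A1", 0, 20_000_000, 120_000),
        ("CATSPER2", 0, 45_000_000, 25_000),
        ("KCNJ12", 0, 70_000_000, 40_000),
        ("COL11A1", 1, 10_000_000, 230_000),
        ("TNC", 1, 35_000_000, 100_000),
        ("COL5A1", 1, 60_000_000, 200_000),
        ("LINC01250", 1, 3_005_000, 53_000),
        ("MMP3", 2, 8_000_000, 8_000),
        ("IL6", 2, 20_000_000, 5_000),
        ("VEGFA", 2, 40_000_000, 16_000),
    ]
    genes = []
    for symbol, ci, start, width in spans:
        chrom = chroms[ci % len(chroms)]
        start = min(start, lengths[chrom] - width - 1)
        genes.append(GeneModel(symbol=symbol, chrom=chrom, start_bp=start + 1, end_bp=start + width))
    return genes


def simulate_variant_sites(
    config: SimulationConfig, genes: Optional[list[GeneModel]] = None
) -> list[Variant]:
    """Place SNP sites uniformly along each chromosome (proportional to
    length), guaranteeing >= 1 exonic site inside every fixture gene."""
    rng = config.rng("sites")
    lengths = config.chrom_lengths_bp
    total = sum(lengths.values())
    bases = ["A", "C", "G", "T"]
    sites: dict[tuple[str, int], Variant] = {}

    def _mk(chrom: str, pos: int, region: Region, cons: Optional[Consequence], gene_syms: list[str]) -> None:
        ref, alt = rng.choice(4, size=2, replace=False)
        sites[(chrom, pos)] = Variant(
            chrom=chrom, pos=pos, ref=bases[ref], alt=bases[alt],
            genes=gene_syms, region=region, consequence=cons,
        )

    gene_list = genes if genes is not None else default_gene_models(config)
    # gene intervals first: each gene gets guaranteed exonic sites
    for g in gene_list:
        placed = 0
        while placed < max(1, config.min_sites_per_gene):
            pos = int(rng.integers(g.start_bp, g.end_bp + 1))
            if (g.chrom, pos) in sites:
                continue
            _mk(g.chrom, pos, Region.exonic, Consequence.nonsynonymous, [g.symbol])
            placed += 1

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)

    consequences = [Consequence.nonsynonymous, Consequence.synonymous, Consequence.stopgain, Consequence.stoploss]
    cons_probs = [0.55, 0.40, 0.03, 0.02]
    while len(sites) < config.n_variants:
        u = rng.random() * total
        acc = 0
        for chrom, L in lengths.items():
            acc += L
            if u < acc:
                break
        pos = int(rng.integers(1, L + 1))
        if (chrom, pos) in sites:
            continue
        hit = [g.symbol for g in by_chrom.get(chrom, []) if g.start_bp <= pos <= g.end_bp]
        if hit:
            if rng.random() < 0.6:
                _mk(chrom, pos, Region.exonic, consequences[rng.choice(4, p=cons_probs)], hit)
            else:
                _mk(chrom, pos, Region.intronic, None, hit)
        else:
            _mk(chrom, pos, Region.intergenic, None, [])
    out = sorted(sites.values(), key=lambda v: (v.chrom, v.pos))
    return out


# ---------------------------------------------------------------------------
# Frequency panel


def simulate_frequency_panel(
    config: SimulationConfig, variants: Optional[list[Variant]] = None
) -> PopulationFrequency:
    """Draw per-population alternate-allele frequencies for every site.

    A ``rare_fraction`` share of variants is forced rare (MAF <= 0.05) in
    ``rare_population``; those variants may still be common elsewhere
    (mirroring variants rare in one ancestry and common in another). Common
    variants follow a Balding–Nichols-style draw around a shared ancestral
    frequency, spreading MAFs across the whole (0, 0.5] range.
    """
    if len(config.populations) == 0:
        raise ValueError("zero populations")
    rng = config.rng("panel")
    if variants is None:
        variants = simulate_variant_sites(config)
    panel = PopulationFrequency(populations=list(config.populations))
    f = config.fst
    a_scale = (1 - f) / f if f > 0 else None
    for v in variants:
        if rng.random() < config.rare_fraction:
            rare_af = float(rng.uniform(0.0005, 0.05))
            for pop in config.populations:
                if pop == config.rare_population:
                    panel.set(v.key, pop, rare_af)
                elif rng.random() < 0.15:  # occasionally common elsewhere
                    panel.set(v.key, pop, float(rng.uniform(0.05, 0.95)))
                else:
                    panel.set(v.key, pop, float(np.clip(rng.normal(rare_af, 0.01), 0.0, 1.0)))
        else:
            p0 = float(rng.uniform(0.05, 0.95))
            for pop in config.populations:
                if a_scale is None:
                    af = p0
                else:
                    af = float(rng.beta(p0 * a_scale, (1 - p0) * a_scale))
                panel.set(v.key, pop, min(max(af, 0.0), 1.0))
    return panel


# ---------------------------------------------------------------------------
# Gene drop

Track = list[tuple[int, int, int]]  # (start_bp, end_bp, founder_hap_id), 1-based inclusive


@dataclass
class GroundTruth:
    true_deleterious: set[str] = field(default_factory=set)
    #: gene -> (variant keys, families planted)
    planted: dict[str, dict] = field(default_factory=dict)
    true_ibd: list[IBDSegment] = field(default_factory=list)
    #: sample -> chrom -> (track for haplotype 0, track for haplotype 1)
    founder_origin: dict[str, dict[str, tuple[Track, Track]]] = field(default_factory=dict)

    def pair_segments(self, id1: str, id2: str) -> list[IBDSegment]:
        pair = frozenset((id1, id2))
        return [s for s in self.true_ibd if s.pair == pair]

    def to_json(self) -> dict:
        return {
            "true_deleterious": sorted(self.true_deleterious),
            "planted": self.planted,
            "true_ibd": [
                {"id1": s.id1, "id2": s.id2, "chrom": s.chrom, "start_bp": s.start_bp,
                 "end_bp": s.end_bp, "lod": s.lod, "length_cm": s.length_cm}
                for s in self.true_ibd
            ],
        }


def _slice_track(track: Track, lo: int, hi: int) -> Track:
    out = []
    for s, e, fid in track:
        if e < lo or s > hi:
            continue
        out.append((max(s, lo), min(e, hi), fid))
    return out


def _meiosis(
    tracks: tuple[Track, Track],
    hap_alleles: tuple[np.ndarray, np.ndarray],
    positions: np.ndarray,
    chrom_len: int,
    cm_per_mb: float,
    rng: np.random.Generator,
) -> tuple[Track, np.ndarray]:
    """One meiosis on one chromosome: Poisson crossovers, uniform map."""
    morgans = chrom_len / 1e6 * cm_per_mb / 100.0
    n_cross = rng.poisson(morgans)
    cuts = sorted(int(x) for x in rng.integers(1, chrom_len, size=n_cross))
    src = int(rng.integers(2))  # starting parental haplotype
    out_track: Track = []
    out_allele = np.empty(len(positions), dtype=np.int8)
    lo = 1
    bounds = cuts + [chrom_len]
    for cut in bounds:
        hi = cut
        if hi >= lo:
            out_track.extend(_slice_track(tracks[src], lo, hi))
            m = (positions >= lo) & (positions <= hi)
            out_allele[m] = hap_alleles[src][m]
        lo = hi + 1
        src = 1 - src
    # merge adjacent pieces with the same founder id
    merged: Track = []
    for s, e, fid in out_track:
        if merged and merged[-1][2] == fid and merged[-1][1] + 1 == s:
            merged[-1] = (merged[-1][0], e, fid)
        else:
            merged.append((s, e, fid))
    return merged, out_allele


def _topological(pedigree: list[Individual]) -> list[Individual]:
    done: set[str] = set()
    ordered: list[Individual] = []
    pending = list(pedigree)
    while pending:
        progress = False
        for ind in list(pending):
            parents_ok = all(
                p is None or p in done for p in (ind.father_id, ind.mother_id)
            )
            if parents_ok:
                ordered.append(ind)
                done.add(ind.id)
                pending.remove(ind)
                progress = True
        if not progress:
            raise PedigreeError("pedigree contains a parent cycle or unresolved reference")
    return ordered


def gene_drop(
    pedigree: list[Individual],
    panel: PopulationFrequency,
    config: SimulationConfig,
    variants: Optional[list[Variant]] = None,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Drop founder haplotypes through the pedigree with recombination.

    Founder haplotypes are per-site Bernoulli draws at the founder
    population's allele frequency; non-founders receive one meiosis product
    from each parent; monozygotic co-twins receive copies of the SAME
    meiosis products. Returns phased genotypes for all pedigree members and
    the ground truth (ancestry tracks and exact pairwise IBD segments).
    """
    validate_pedigree(pedigree)
    if variants is None:
        variants = simulate_variant_sites(config)
    rng = config.rng("genedrop")
    chroms = list(config.chrom_lengths_bp)
    pos_by_chrom = {
        c: np.array([v.pos for v in variants if v.chrom == c], dtype=np.int64) for c in chroms
    }
    key_order = [v.key for v in variants]
    row_index = {v.key: i for i, v in enumerate(variants)}
    idx_by_chrom = {
        c: np.array([row_index[v.key] for v in variants if v.chrom == c], dtype=np.int64)
        for c in chroms
    }

    ordered = _topological(pedigree)
    # per sample: chrom -> (tracks, tracks) and chrom -> (alleles, alleles)
    tracks: dict[str, dict[str, tuple[Track, Track]]] = {}
    alleles: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    founder_hap_counter = 0
    mz_products: dict[str, dict[str, tuple]] = {}  # mz_group -> chrom -> products

    for ind in ordered:
        tracks[ind.id] = {}
        alleles[ind.id] = {}
        if ind.is_founder:
            hap_ids = (founder_hap_counter, founder_hap_counter + 1)
            founder_hap_counter += 2
            for c in chroms:
                L = config.chrom_lengths_bp[c]
                afs = np.array(
                    [panel.get(k, config.founder_population) or 0.0
                     for k in (variants[j].key for j in idx_by_chrom[c])],
                    dtype=float,
                )
                h0 = (rng.random(len(afs)) < afs).astype(np.int8)
                h1 = (rng.random(len(afs)) < afs).astype(np.int8)
                tracks[ind.id][c] = ([(1, L, hap_ids[0])], [(1, L, hap_ids[1])])
                alleles[ind.id][c] = (h0, h1)
        else:
            if ind.mz_group and ind.mz_group in mz_products:
                for c in chroms:
                    pt, pa = mz_products[ind.mz_group][c]
                    tracks[ind.id][c] = pt
                    alleles[ind.id][c] = pa
                continue
            for c in chroms:
                L = config.chrom_lengths_bp[c]
                pos = pos_by_chrom[c]
                tr_f, al_f = _meiosis(
                    tracks[ind.father_id][c], alleles[ind.father_id][c], pos, L, config.cm_per_mb, rng
                )
                tr_m, al_m = _meiosis(
                    tracks[ind.mother_id][c], alleles[ind.mother_id][c], pos, L, config.cm_per_mb, rng
                )
                tracks[ind.id][c] = (tr_f, tr_m)
                alleles[ind.id][c] = (al_f, al_m)
            if ind.mz_group:
                mz_products[ind.mz_group] = {
                    c: ((tracks[ind.id][c]), (alleles[ind.id][c])) for c in chroms
                }

    n_var, n_samp = len(variants), len(pedigree)
    h1 = np.zeros((n_var, n_samp), dtype=np.int8)
    h2 = np.zeros((n_var, n_samp), dtype=np.int8)
    sample_ids = [ind.id for ind in pedigree]
    for j, sid in enumerate(sample_ids):
        for c in chroms:
            rows = idx_by_chrom[c]
            h1[rows, j] = alleles[sid][c][0]
            h2[rows, j] = alleles[sid][c][1]
    geno = h1 + h2
    if config.genotype_error_rate > 0:
        flip = rng.random(geno.shape) < config.genotype_error_rate
        geno = np.where(flip, rng.integers(0, 3, size=geno.shape, dtype=np.int8), geno)
        haps = None
    else:
        haps = (h1, h2)
    gm = GenotypeMatrix(
        samples=sample_ids, variant_keys=key_order, genotypes=geno.astype(np.int8), haplotypes=haps
    )

    truth = GroundTruth(founder_origin=tracks)
    truth.true_ibd = _true_ibd_segments(pedigree, tracks, config)
    return gm, truth


def _shared_intervals(t1: Track, t2: Track) -> list[tuple[int, int]]:
    """Intervals where two ancestry tracks carry the same founder hap id."""
    out = []
    i = j = 0
    while i < len(t1) and j < len(t2):
        s1, e1, f1 = t1[i]
        s2, e2, f2 = t2[j]
        lo, hi = max(s1, s2), min(e1, e2)
        if lo <= hi and f1 == f2:
            out.append((lo, hi))
        if e1 <= e2:
            i += 1
        else:
            j += 1
    return out


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    merged = [iv[0]]
    for s, e in iv[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _true_ibd_segments(
    pedigree: list[Individual],
    tracks: dict[str, dict[str, tuple[Track, Track]]],
    config: SimulationConfig,
) -> list[IBDSegment]:
    segs: list[IBDSegment] = []
    ids = [ind.id for ind in pedigree]
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i1, i2 = ids[a], ids[b]
            for c in config.chrom_lengths_bp:
                shared: list[tuple[int, int]] = []
                for ha in tracks[i1][c]:
                    for hb in tracks[i2][c]:
                        shared.extend(_shared_intervals(ha, hb))
                for s, e in _merge_intervals(shared):
                    if e <= s:
                        continue
                    segs.append(
                        IBDSegment(
                            id1=i1, id2=i2, chrom=c, start_bp=s, end_bp=e,
                            lod=99.0,
                            length_cm=(e - s + 1) / 1e6 * config.cm_per_mb,
                        )
                    )
    return segs


def ibd1_fraction(truth: GroundTruth, id1: str, id2: str, config: SimulationConfig) -> float:
    """Fraction of the simulated genome where the pair shares >= 1 founder
    haplotype (IBD state >= 1)."""
    total = sum(config.chrom_lengths_bp.values())
    covered = sum(s.length_bp for s in truth.pair_segments(id1, id2))
    return covered / total


# ---------------------------------------------------------------------------
# Planting pathogenic variants


def _desired_genotypes(
    pedigree: list[Individual], pattern: str, families: Optional[list[str]]
) -> dict[str, int]:
    """Target genotype per sample for a planted site, with Mendelian checks."""
    fams = set(families) if families else {i.family_id for i in pedigree}
    target_gt = 2 if pattern == "all_affected_homozygous" else 1
    if pattern not in ("all_affected_homozygous", "all_affected_carry"):
        raise ValueError(f"unknown carrier pattern {pattern!r}")
    desired = {
        i.id: (target_gt if (i.affected and i.family_id in fams) else 0) for i in pedigree
    }
    by_id = {i.id: i for i in pedigree}
    # propagate Mendelian requirements to a fixpoint
    changed = True
    while changed:
        changed = False
        for ind in pedigree:
            if ind.is_founder:
                continue
            g = desired[ind.id]
            for pid in (ind.father_id, ind.mother_id):
                if g == 2 and desired[pid] < 1:
                    desired[pid] = 1
                    changed = True
                if desired[pid] == 2 and g < 1:
                    desired[ind.id] = 1
                    changed = True
            if g == 1 and desired[ind.father_id] == 0 and desired[ind.mother_id] == 0:
                desired[ind.father_id] = 1
                changed = True
    # MZ coherence
    groups: dict[str, set[int]] = {}
    for ind in pedigree:
        if ind.mz_group:
            groups.setdefault(ind.mz_group, set()).add(desired[ind.id])
    for label, gts in groups.items():
        if len(gts) > 1:
            raise MendelianError(f"mz_group {label!r} members would need different genotypes")
    return desired


def plant_pathogenic_variants(
    variants: list[Variant],
    gm: GenotypeMatrix,
    pedigree: list[Individual],
    genes: list[GeneModel],
    plan: list[PlantSpec],
    config: SimulationConfig,
    panel: Optional[PopulationFrequency] = None,
    forced_genotypes: Optional[dict[str, dict[str, int]]] = None,
) -> tuple[GenotypeMatrix, GroundTruth]:
    """Write planted deleterious variants into the genotype matrix.

    For each plan entry, exonic sites inside the target gene are chosen and
    every affected member of the target families is set per the carrier
    pattern (default homozygous alternate); unaffected members are set to
    the minimal genotype consistent with Mendelian transmission. Impossible
    patterns (including explicit ``forced_genotypes`` conflicts, keyed
    gene -> sample -> genotype) raise :class:`MendelianError` — never a
    silent adjustment. If a panel is given, planted sites are re-assigned a
    rare frequency in the panel's rare population.
    """
    rng = config.rng("plant")
    gene_by_symbol: dict[str, list[GeneModel]] = {}
    for g in genes:
        gene_by_symbol.setdefault(g.symbol, []).append(g)
    row_index = {v.key: i for i, v in enumerate(variants)}
    geno = gm.genotypes.copy()
    haps = None
    if gm.haplotypes is not None:
        haps = (gm.haplotypes[0].copy(), gm.haplotypes[1].copy())
    truth = GroundTruth()
    col = {s: j for j, s in enumerate(gm.samples)}

    for spec in plan:
        if spec.gene not in gene_by_symbol:
            raise ValueError(f"planted gene {spec.gene!r} not in the fixture gene model")
        desired = _desired_genotypes(pedigree, spec.pattern, spec.families)
        if forced_genotypes and spec.gene in forced_genotypes:
            for sid, g in forced_genotypes[spec.gene].items():
                if desired.get(sid, 0) > g:
                    raise MendelianError(
                        f"gene {spec.gene}: sample {sid} forced to genotype {g} but "
                        f"pattern requires {desired[sid]}"
                    )
                desired[sid] = g
            _check_mendelian(pedigree, desired)
        spans = gene_by_symbol[spec.gene]
        candidates = [
            v for v in variants
            if v.region is Region.exonic
            and any(g.chrom == v.chrom and g.start_bp <= v.pos <= g.end_bp for g in spans)
        ]
        if len(candidates) < spec.n_variants:
            raise ValueError(
                f"gene {spec.gene}: {len(candidates)} exonic sites available, "
                f"{spec.n_variants} requested"
            )
        chosen = [candidates[int(i)] for i in rng.choice(len(candidates), size=spec.n_variants, replace=False)]
        keys = []
        for v in chosen:
            v.consequence = Consequence.nonsynonymous
            r = row_index[v.key]
            for sid, g in desired.items():
                if sid in col:
                    j = col[sid]
                    geno[r, j] = g
                    if haps is not None:
                        haps[0][r, j] = 1 if g >= 1 else 0
                        haps[1][r, j] = 1 if g == 2 else 0
            truth.true_deleterious.add(v.key)
            keys.append(v.key)
            if panel is not None:
                panel.set(v.key, config.rare_population, float(rng.uniform(0.001, 0.01)))
        truth.planted[spec.gene] = {
            "variants": keys,
            "families": spec.families or sorted({i.family_id for i in pedigree}),
        }
    new_gm = GenotypeMatrix(
        samples=gm.samples, variant_keys=gm.variant_keys, genotypes=geno, haplotypes=haps
    )
    return new_gm, truth


def _check_mendelian(pedigree: list[Individual], desired: dict[str, int]) -> None:
    for ind in pedigree:
        if ind.is_founder:
            continue
        g = desired[ind.id]
        pf, pm = desired[ind.father_id], desired[ind.mother_id]
        if g == 2 and (pf < 1 or pm < 1):
            raise MendelianError(
                f"{ind.id} requires genotype 2 but parents have {pf}/{pm}"
            )
        if g >= 1 and pf == 0 and pm == 0:
            raise MendelianError(f"{ind.id} requires an alt allele but both parents are 0")
        if (pf == 2 or pm == 2) and g == 0:
            raise MendelianError(f"{ind.id} forced to 0 under a homozygous-alt parent")


# ---------------------------------------------------------------------------
# Predictor panel simulation


def simulate_predictions(
    variants: list[Variant],
    truth: GroundTruth,
    config: SimulationConfig,
    tool_config: Optional[fio.ToolConfig] = None,
    automatic_tools: frozenset = frozenset({"MutationTaster"}),
) -> dict[str, PredictionProfile]:
    """Emit noisy per-tool statuses: each tool calls a true deleterious
    variant qualifying (D, or A for ``automatic_tools``) with probability
    ``predictor_sensitivity``; any other variant is miscalled D with
    probability 1 - ``predictor_specificity``; otherwise T."""
    cfg = tool_config or fio.ToolConfig()
    rng = config.rng("predict")
    sens, spec = config.predictor_sensitivity, config.predictor_specificity
    profiles: dict[str, PredictionProfile] = {}
    for v in variants:
        is_true = v.key in truth.true_deleterious
        statuses = []
        for tool in cfg.tools:
            if is_true:
                hit = rng.random() < sens
                statuses.append(("A" if tool in automatic_tools else "D") if hit else "T")
            else:
                statuses.append("D" if rng.random() < (1 - spec) else "T")
        profiles[v.key] = PredictionProfile(key=v.key, statuses=statuses)
    return profiles


# ---------------------------------------------------------------------------
# Fixture bundle


def write_fixture_bundle(
    outdir: str | Path,
    config: SimulationConfig,
    pedigree: Optional[list[Individual]] = None,
    genes: Optional[list[GeneModel]] = None,
) -> dict[str, Path]:
    """Run the full generator and write VCF, PED, prediction TSV, frequency
    TSV, gene BED and a ground-truth JSON. Byte-identical under a fixed
    config (fixed seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree = pedigree or default_pedigrees()
    genes = genes if genes is not None else default_gene_models(config)
    variants = simulate_variant_sites(config, genes)
    panel = simulate_frequency_panel(config, variants)
    gm, truth = gene_drop(pedigree, panel, config, variants)
    gm2, plant_truth = plant_pathogenic_variants(
        variants, gm, pedigree, genes, config.pathogenic_plan, config, panel=panel
    )
    truth.true_deleterious = plant_truth.true_deleterious
    truth.planted = plant_truth.planted
    profiles = simulate_predictions(variants, truth, config)

    genotyped = [i.id for i in pedigree if i.genotyped]
    paths = {
        "vcf": outdir / "families.vcf",
        "ped": outdir / "families.ped",
        "predictions": outdir / "predictions.tsv",
        "frequencies": outdir / "frequencies.tsv",
        "genes": outdir / "genes.bed",
        "truth": outdir / "truth.json",
    }
    fio.write_vcf(paths["vcf"], variants, gm2.subset_samples(genotyped))
    fio.write_pedigree(paths["ped"], pedigree)
    fio.write_prediction_table(paths["predictions"], profiles)
    fio.write_frequency_table(paths["frequencies"], panel)
    fio.write_gene_bed(paths["genes"], genes)
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
    return paths


def default_pathogenic_plan() -> list[PlantSpec]:
    """Scaled-down analogue of the study's candidate structure: three genes
    planted in both families (the cross-family truth), plus family-private
    genes, all homozygous in every affected carrier."""
    return [
        PlantSpec("COL12A1", 1, "all_affected_homozygous", None),
        PlantSpec("CATSPER2", 1, "all_affected_homozygous", None),
        PlantSpec("KCNJ12", 2, "all_affected_homozygous", None),
        PlantSpec("COL11A1", 1, "all_affected_homozygous", ["FamilyA"]),
        PlantSpec("TNC", 1, "all_affected_homozygous", ["FamilyA"]),
        PlantSpec("COL5A1", 1, "all_affected_homozygous", ["FamilyB"]),
    ]
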