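"""Identity-by-descent segment filtering, gene annotation, within-family
sharing tables and cross-family common regions, plus a simple
genotype-based segment detector for end-to-end synthetic runs.

The detector is deliberately modest: it scans each sample pair for maximal
marker runs free of opposite homozygotes (IBS0) and scores each run with a
LOD contrasting IBD1 sharing against non-sharing under Hardy–Weinberg
panel frequencies. It assumes error-free unphased genotypes and is NOT a
replacement for a haplotype-HMM detector on real data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from intervaltree import IntervalTree

from .models import (
    GeneModel,
    GenotypeMatrix,
    IBDSegment,
    Individual,
    PopulationFrequency,
    Variant,
)

logger = logging.getLogger("famshare")


def filter_segments(
    segments: list[IBDSegment], min_lod: float = 3.0, min_cm: float = 0.0
) -> list[IBDSegment]:
    """Keep segments with LOD >= min_lod and genetic length >= min_cm.

    Both bounds are closed; a missing genetic length passes the length test.
    """
    return [
        s for s in segments
        if s.lod >= min_lod and (s.length_cm is None or s.length_cm >= min_cm)
    ]


class GeneIndex:
    """Per-chromosome interval index over gene models (1-based inclusive)."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = list(genes)
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            # IntervalTree is half-open; +1 on the end makes it inclusive
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start_bp, g.end_bp + 1, g)

    def overlapping(self, chrom: str, start_bp: int, end_bp: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start_bp, end_bp + 1)]
        return sorted(hits, key=lambda g: (g.start_bp, g.end_bp, g.symbol))


def annotate_segment_genes(
    segment: IBDSegment,
    genes: list[GeneModel] | GeneIndex,
    rule: str = "any_overlap",
    dedup: bool = False,
) -> list[str]:
    """Symbols of gene models overlapping the segment, ordered by start.

    ``any_overlap`` requires >= 1 bp intersection of the closed intervals;
    ``full_containment`` requires the gene span inside the segment.
    Duplicate symbols (two models sharing a symbol) are kept as listed
    unless ``dedup``.
    """
    if rule not in ("any_overlap", "full_containment"):
        raise ValueError(f"unknown overlap rule {rule!r}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    hits = index.overlapping(segment.chrom, segment.start_bp, segment.end_bp)
    if rule == "full_containment":
        hits = [g for g in hits if g.start_bp >= segment.start_bp and g.end_bp <= segment.end_bp]
    symbols = [g.symbol for g in hits]
    if dedup:
        seen: set[str] = set()
        symbols = [s for s in symbols if not (s in seen or seen.add(s))]
    return symbols


@dataclass
class SharedSegmentRecord:
    family_id: str
    id1: str
    id2: str
    affected1: bool
    affected2: bool
    segment: IBDSegment
    genes: list[str]

    @property
    def both_affected(self) -> bool:
        return self.affected1 and self.affected2


def pairwise_sharing_table(
    segments: list[IBDSegment],
    pedigree: list[Individual],
    genes: list[GeneModel] | GeneIndex,
    rule: str = "any_overlap",
    dedup: bool = False,
) -> list[SharedSegmentRecord]:
    """One record per segment with family, affected flags and gene overlap,
    ordered deterministically by (family, chrom, start)."""
    by_id = {i.id: i for i in pedigree}
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    records = []
    for s in segments:
        for sid in (s.id1, s.id2):
            if sid not in by_id:
                raise KeyError(f"IBD segment sample id {sid!r} not in pedigree")
        i1, i2 = by_id[s.id1], by_id[s.id2]
        fam = i1.family_id if i1.family_id == i2.family_id else f"{i1.family_id}+{i2.family_id}"
        records.append(
            SharedSegmentRecord(
                family_id=fam,
                id1=s.id1, id2=s.id2,
                affected1=i1.affected, affected2=i2.affected,
                segment=s,
                genes=annotate_segment_genes(s, index, rule=rule, dedup=dedup),
            )
        )
    records.sort(key=lambda r: (r.family_id, r.segment.chrom, r.segment.start_bp, r.segment.end_bp))
    return records


@dataclass
class CrossFamilyRegion:
    chrom: str
    start_bp: int
    end_bp: int
    family1: str
    family2: str
    record1: SharedSegmentRecord
    record2: SharedSegmentRecord
    common_genes: list[str]


def cross_family_common(
    records: list[SharedSegmentRecord],
    affected_only: bool = True,
) -> tuple[list[CrossFamilyRegion], set[str]]:
    """Chromosome-interval intersections between segment records of
    different families, with the gene symbols present in both records.

    With ``affected_only`` (the default) only pairs where all four samples
    are affected contribute. The gene-level summary is the union of genes
    appearing in >= 1 cross-family intersection.
    """
    regions: list[CrossFamilyRegion] = []
    common_genes: set[str] = set()
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            r1, r2 = records[i], records[j]
            if r1.family_id == r2.family_id:
                continue
            if affected_only and not (r1.both_affected and r2.both_affected):
                continue
            overlap = r1.segment.intersect(r2.segment)
            if overlap is None:
                continue
            genes = sorted(set(r1.genes) & set(r2.genes))
            regions.append(
                CrossFamilyRegion(
                    chrom=r1.segment.chrom,
                    start_bp=overlap[0], end_bp=overlap[1],
                    family1=r1.family_id, family2=r2.family_id,
                    record1=r1, record2=r2,
                    common_genes=genes,
                )
            )
            common_genes.update(genes)
    regions.sort(key=lambda r: (r.chrom, r.start_bp, r.end_bp, r.family1, r.family2))
    return regions, common_genes


# ---------------------------------------------------------------------------
# Simple genotype-based detector


def _site_lods(g1: np.ndarray, g2: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-site log10 LR of IBD1 sharing vs independence under HWE."""
    q = 1.0 - p
    marg = np.stack([q * q, 2 * p * q, p * p])  # P(g) for g = 0,1,2
    # joint under IBD1: shared allele alt w.p. p / ref w.p. q,
    # each genotype contributes its free allele
    cond_alt = np.stack([np.zeros_like(p), q, p])  # P(g | shared alt)
    cond_ref = np.stack([q, p, np.zeros_like(p)])  # P(g | shared ref)
    idx = np.arange(len(p))
    joint = p * cond_alt[g1, idx] * cond_alt[g2, idx] + q * cond_ref[g1, idx] * cond_ref[g2, idx]
    denom = marg[g1, idx] * marg[g2, idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.log10(joint / denom)
    return lod


def _best_subsegments(
    scores: np.ndarray, min_lod: float, min_markers: int
) -> list[tuple[int, int, float]]:
    """Recursively extract disjoint maximum-sum score windows (Kadane)."""
    out: list[tuple[int, int, float]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < min_markers:
            continue
        best = cur = 0.0
        best_i = best_j = cur_i = lo
        for k in range(lo, hi):
            if cur <= 0:
                cur = 0.0
                cur_i = k
            cur += scores[k]
            if cur > best:
                best, best_i, best_j = cur, cur_i, k + 1
        if best < min_lod or best_j - best_i < min_markers:
            continue
        out.append((best_i, best_j, best))
        stack.append((lo, best_i))
        stack.append((best_j, hi))
    return sorted(out)


def detect_ibd_segments(
    gm: GenotypeMatrix,
    variants: list[Variant],
    panel: PopulationFrequency,
    population: str,
    min_markers: int = 25,
    min_lod: float = 3.0,
    max_ibs0: int = 0,
    cm_per_mb: float = 1.0,
    pairs: Optional[list[tuple[str, str]]] = None,
) -> list[IBDSegment]:
    """Detect pairwise IBD segments from unphased genotypes.

    For every sample pair and chromosome the marker sequence is split at
    opposite-homozygote (IBS0) sites — with ``max_ibs0 > 0``, IBS0 sites
    instead incur a fixed penalty and detected segments containing more
    than ``max_ibs0`` of them are discarded — and maximal positive-LOD
    windows with >= ``min_markers`` markers and LOD >= ``min_lod`` are
    emitted. Monomorphic or panel-absent sites are ignored.
    """
    if population not in panel.populations:
        raise KeyError(f"population {population!r} not in panel")
    chroms: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        chroms.setdefault(v.chrom, []).append(i)
    freqs = np.array(
        [panel.get(v.key, population) if panel.get(v.key, population) is not None else np.nan
         for v in variants]
    )
    samples = gm.samples
    if pairs is None:
        pairs = [
            (samples[a], samples[b])
            for a in range(len(samples)) for b in range(a + 1, len(samples))
        ]
    ibs0_penalty = -3.0
    segments: list[IBDSegment] = []
    for chrom, rows in chroms.items():
        rows = sorted(rows, key=lambda i: variants[i].pos)
        pos = np.array([variants[i].pos for i in rows], dtype=np.int64)
        p = freqs[rows]
        usable = np.isfinite(p) & (p > 0.001) & (p < 0.999)
        rows_u = np.array(rows)[usable]
        pos_u = pos[usable]
        p_u = np.clip(p[usable], 0.005, 0.995)
        if len(rows_u) == 0:
            continue
        for id1, id2 in pairs:
            g1 = gm.column(id1)[rows_u]
            g2 = gm.column(id2)[rows_u]
            ok = (g1 >= 0) & (g2 >= 0)
            if not ok.any():
                logger.warning("pair (%s, %s): all genotypes missing on %s; skipped", id1, id2, chrom)
                continue
            gi1, gi2, pp, ppos = g1[ok], g2[ok], p_u[ok], pos_u[ok]
            ibs0 = ((gi1 == 0) & (gi2 == 2)) | ((gi1 == 2) & (gi2 == 0))
            scores = _site_lods(gi1.astype(int), gi2.astype(int), pp)
            scores[ibs0] = ibs0_penalty
            if max_ibs0 == 0:
                # split runs at IBS0 sites
                run_bounds = []
                start = 0
                for k in np.flatnonzero(ibs0):
                    if k > start:
                        run_bounds.append((start, k))
                    start = k + 1
                if start < len(scores):
                    run_bounds.append((start, len(scores)))
            else:
                run_bounds = [(0, len(scores))]
            for lo, hi in run_bounds:
                for i0, j0, lod in _best_subsegments(scores[lo:hi], min_lod, min_markers):
                    a, b = lo + i0, lo + j0
                    if max_ibs0 and int(ibs0[a:b].sum()) > max_ibs0:
                        continue
                    start_bp, end_bp = int(ppos[a]), int(ppos[b - 1])
                    if end_bp <= start_bp:
                        continue
                    segments.append(
                        IBDSegment(
                            id1=id1, id2=id2, chrom=chrom,
                            start_bp=start_bp, end_bp=end_bp,
                            lod=float(lod),
                            length_cm=(end_bp - start_bp + 1) / 1e6 * cm_per_mb,
                        )
                    )
    segments.sort(key=lambda s: (s.chrom, s.start_bp, s.id1, s.id2))
    return segments
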