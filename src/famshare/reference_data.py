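"""Published summary records from the two-family ACL rupture study that
this package reproduces at desk scale.

These are the study's printed outputs — the six shared candidate variants
with their ExAC African/European frequencies, the per-family shared-IBD
segment table with its gene lists, and the per-family candidate gene list
sizes — used as worked-example inputs to the intersection, annotation and
counting operations. Genomic positions for the shared variants and the
per-gene spans inside the 19q13.42 segment are NOT published; where an
operation needs them, synthetic placeholder coordinates are constructed
(clearly marked below) so only the published quantities are asserted.
"""

from __future__ import annotations

from .models import GeneModel, IBDSegment, PopulationFrequency, Variant
from .ibd import SharedSegmentRecord

#: Shared candidate variants (both families, homozygous in every affected
#: member): rsid, gene, cytoband, ref>alt, protein change, ExAC AFR / EUR
#: alternate-allele frequencies. Positions are synthetic placeholders.
SHARED_VARIANTS = [
    # (rsid, gene, band, chrom, synthetic_pos, ref, alt, protein_change, af_afr, af_eur)
    ("rs970547", "COL12A1", "6q14.1", "chr6", 75_000_001, "C", "T", "Gly3058Ser", 0.0026, 0.73),
    ("rs144399798", "CATSPER2", "15q15.3", "chr15", 43_000_001, "C", "T", "Arg511His", 0.0083, 0.0003),
    ("rs76265595", "KCNJ12", "17p11.2", "chr17", 21_000_001, "G", "A", "Glu139Lys", 0.0, 0.71),
    ("rs75029097", "KCNJ12", "17p11.2", "chr17", 21_000_101, "G", "A", "Gly145Ser", 0.0, 0.32),
    ("rs77270326", "KCNJ12", "17p11.2", "chr17", 21_000_201, "G", "A", "Arg261His", 0.001, 0.11),
    ("rs76684759", "KCNJ12", "17p11.2", "chr17", 21_000_301, "T", "G", "Ile262Ser", 0.002, 0.017),
]


def shared_variant_objects() -> list[Variant]:
    return [
        Variant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, rsid=rsid,
            genes=[gene], region="exonic", consequence="nonsynonymous",
            protein_change=pchange,
        )
        for rsid, gene, _band, chrom, pos, ref, alt, pchange, _afr, _eur in SHARED_VARIANTS
    ]


def exac_panel() -> PopulationFrequency:
    """ExAC AFR/EUR frequencies of the six shared variants."""
    panel = PopulationFrequency(populations=["AFR", "EUR"])
    for rsid, gene, _band, chrom, pos, ref, alt, _pc, afr, eur in SHARED_VARIANTS:
        key = f"{chrom}:{pos}:{ref}:{alt}"
        panel.set(key, "AFR", afr)
        panel.set(key, "EUR", eur)
    return panel


#: Per-family candidate gene list sizes as published: 29 genes for Family A
#: (including COL11A1 and the three shared genes), 18 for Family B. The
#: full supplementary lists are not published; FILLER symbols are synthetic
#: placeholders that pad each list to its published size while keeping the
#: published intersection {COL12A1, CATSPER2, KCNJ12}.
FAMILY_A_CANDIDATE_GENES = (
    ["COL12A1", "CATSPER2", "KCNJ12", "COL11A1"]
    + [f"FA_FILLER{i:02d}" for i in range(1, 26)]
)
FAMILY_B_CANDIDATE_GENES = (
    ["COL12A1", "CATSPER2", "KCNJ12"]
    + [f"FB_FILLER{i:02d}" for i in range(1, 16)]
)

#: The published shared-segment table: (family, id1, affected1, id2,
#: affected2, cytoband, chrom, start, end, genes-as-listed, LOD, cM).
#: Band labels are carried verbatim; the chr2 locus is labelled both
#: "2p25.3" and "2q25.3" in the source — coordinates are trusted instead.
SEGMENT_TABLE = [
    ("FamilyA", "Twin1+Twin2", True, "Brother", True, "2p25.3", "chr2", 3005297, 3057952,
     ["LINC01250"], 5.34, 3.944),
    ("FamilyA", "Twin1", True, "Twin2", True, "2q25.3", "chr2", 3005007, 3058005,
     ["LINC01250"], 6.37, 3.945),
    ("FamilyA", "Twin1", True, "Twin2", True, "15q11.2", "chr15", 22292484, 22584320,
     ["GOLGA6L22", "GOLGA8EP", "HERC2P2", "HERC2P7", "RN7SL545P", "SPATA31E3P"], 5.94, 3.59),
    ("FamilyA", "Twin1", True, "Twin2", True, "21q21.1", "chr21", 16448783, 16633125,
     ["MIR125B2", "MIR99A", "MIRLET7C", "MIR99AHG"], 10.67, 2.077),
    ("FamilyA", "Father", True, "Brother", True, "14q32.33", "chr14", 105952630, 106208389,
     ["ADAM6", "IGHV1-2", "IGHVIII-2-1", "IGHV1-3", "IGHV4-4", "IGHV7-4-1", "IGHV2-5",
      "IGHVIII-5-1", "IGHVIII-5-2", "IGHV3-6", "IGHV3-7", "IGHV3-64D", "IGHV5-10-1",
      "IGHV3-11", "IGHVIII-11-1", "IGHV1-12", "IGHV3-13", "IGHVIII-13-1", "IGHV1-14",
      "IGHV3-15", "IGHVII-15-1", "IGHV3-16", "IGHVIII-16-1", "IGHV1-17", "IGHV1-18",
      "IGHV3-19", "SLC20A1P2"], 56.56, 1.516),
    ("FamilyA", "Mother", False, "Brother", True, "19q13.42", "chr19", 54184163, 54537844,
     ["CDC42EP5", "KIR3DX1", "LAIR1", "LAIR2", "LENG8", "LENG8-AS1", "LENG9", "LILRA4",
      "LILRA5", "LILRA6", "LILRB2", "LILRB3", "LILRB5", "MBOAT7", "MIR4752",
      "RNU6-1307P", "RPS9", "TSEN34", "TTYH1", "VN1R104P"], 7.76, 1.778),
    ("FamilyB", "Twin3", True, "Twin4", True, "2q25.3", "chr2", 3009692, 3047881,
     ["LINC01250"], 3.31, 2.748),
    ("FamilyB", "Twin3", True, "Twin4", True, "15q11.2", "chr15", 22370898, 22524432,
     ["GOLGA6L22", "GOLGA8EP", "HERC2P2", "HERC2P7", "RN7SL545P", "SPATA31E3P"], 4.3, 1.918),
    ("FamilyB", "Twin3", True, "Twin4", True, "19q13.42", "chr19", 54529431, 55093392,
     ["EPS8L1", "FCAR", "GP6", "GP6-AS1", "KIR2DL1", "KIR2DL3", "KIR2DL4", "KIR2DP1",
      "KIR2DS4", "KIR3DL1", "KIR3DL2", "KIR3DL3", "KIR3DP1", "KIR3DX1", "LILRA1",
      "LILRA2"], 7.4, 1.775),
    ("FamilyB", "Twin3", True, "Twin4", True, "19q13.42", "chr19", 54539272, 55088813,
     ["LILRB1", "LILRB1-AS1", "LILRB4", "LILRP1", "LILRP1", "LILRP2", "MIR8061", "NCR1",
      "NLRP2", "NLRP7", "PPP1R12C", "RDH13", "RNU6-222P", "VN1R105P"], 7.35, 1.751),
    ("FamilyB", "Twin3", True, "Sister", False, "13q34", "chr13", 111663671, 111916421,
     ["LINC00354"], 4.31, 1.551),
]

#: Fixture gene span for the long non-coding RNA shared across families,
#: taken from the published twins+brother segment bounds.
LINC01250_GENE = GeneModel(symbol="LINC01250", chrom="chr2", start_bp=3005297, end_bp=3057952)


def segment_objects() -> list[IBDSegment]:
    return [
        IBDSegment(id1=id1, id2=id2, chrom=chrom, start_bp=start, end_bp=end,
                   lod=lod, length_cm=cm)
        for (_fam, id1, _a1, id2, _a2, _band, chrom, start, end, _genes, lod, cm)
        in SEGMENT_TABLE
    ]


def segment_records() -> list[SharedSegmentRecord]:
    """The published table as SharedSegmentRecord objects, carrying the
    printed gene lists verbatim (duplicates as listed)."""
    return [
        SharedSegmentRecord(
            family_id=fam, id1=id1, id2=id2, affected1=a1, affected2=a2,
            segment=IBDSegment(id1=id1, id2=id2, chrom=chrom, start_bp=start,
                               end_bp=end, lod=lod, length_cm=cm),
            genes=list(genes),
        )
        for (fam, id1, a1, id2, a2, _band, chrom, start, end, genes, lod, cm)
        in SEGMENT_TABLE
    ]


def mother_brother_gene_models() -> list[GeneModel]:
    """Synthetic spans for the 20 published symbols of the 19q13.42
    mother–brother segment, evenly laid inside the published bounds so the
    segment→gene annotation reproduces the published gene count."""
    _, _, _, _, _, _, chrom, start, end, genes, _, _ = SEGMENT_TABLE[5]
    step = (end - start) // len(genes)
    models = []
    for i, sym in enumerate(genes):
        s = start + i * step + 1
        models.append(GeneModel(symbol=sym, chrom=chrom, start_bp=s, end_bp=s + step // 2))
    return models


def write_segment_tsv(path, dialect: str = "simple_tsv") -> None:
    """Write the published segment table in an IBD-file dialect (fixture
    for the reader; gene lists are not part of the format)."""
    from . import io as fio

    fio.write_ibd_file(path, segment_objects(), dialect=dialect)
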