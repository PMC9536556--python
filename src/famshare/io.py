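"""Readers and writers for the external formats the pipeline touches.

Conventions
-----------
* Internal coordinates are 1-based inclusive. BED (0-based half-open) is
  converted at this boundary: ``start_bp = bed_start + 1``.
* VCF is read with cyvcf2; multi-allelic records are decomposed into one
  biallelic row per ALT allele, genotypes recoded as alt-allele counts.
* Pedigrees are PED-like text (FID IID PAT MAT SEX PHENO) with an optional
  7th column carrying a monozygotic-twin group label.
* Per-variant predictor statuses come from an ANNOVAR-multianno-style TSV,
  mapped through a configurable :class:`ToolConfig` to {D, A, T, U}.
* IBD segments are read either in the Refined-IBD output dialect
  (id1 hap1 id2 hap2 chrom start end LOD) or a simple fixture dialect
  (id1 id2 chrom start end lod cm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .models import (
    MISSING,
    Consequence,
    GeneModel,
    GenotypeMatrix,
    IBDSegment,
    Individual,
    PopulationFrequency,
    PredictionProfile,
    Region,
    Sex,
    Variant,
    validate_pedigree,
)

logger = logging.getLogger("famshare")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> tuple[list[Variant], GenotypeMatrix]:
    """Read a VCF into biallelic variants and an alt-allele-count matrix.

    Multi-allelic records are decomposed: one output row per (record, ALT)
    pair, the genotype counting only that ALT. Missing calls stay missing.
    Optional INFO keys GENE (comma-separated symbols), REGION and CSQ are
    mapped onto the variant annotation; the ID column becomes ``rsid``.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # malformed header
        raise ParseError(f"{path}: cannot parse VCF header: {exc}") from exc

    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    hap_rows: list[tuple[np.ndarray, np.ndarray]] = []
    all_phased = True
    record_no = 0
    try:
        for rec in vcf:
            record_no += 1
            gts = rec.genotypes  # [[a0, a1, phased], ...]
            for alt_index, alt in enumerate(rec.ALT, start=1):
                region = rec.INFO.get("REGION") or "other"
                csq = rec.INFO.get("CSQ")
                genes_raw = rec.INFO.get("GENE")
                variants.append(
                    Variant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        rsid=rec.ID,
                        genes=genes_raw.split(",") if genes_raw else [],
                        region=Region(region),
                        consequence=Consequence(csq) if csq else None,
                    )
                )
                row = np.empty(len(samples), dtype=np.int8)
                h1 = np.zeros(len(samples), dtype=np.int8)
                h2 = np.zeros(len(samples), dtype=np.int8)
                for j, g in enumerate(gts):
                    alleles = g[:-1]
                    if any(a < 0 for a in alleles):
                        row[j] = MISSING
                    else:
                        row[j] = sum(1 for a in alleles if a == alt_index)
                        h1[j] = 1 if alleles[0] == alt_index else 0
                        h2[j] = 1 if len(alleles) > 1 and alleles[1] == alt_index else 0
                    if not g[-1]:
                        all_phased = False
                rows.append(row)
                hap_rows.append((h1, h2))
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF record #{record_no + 1}: {exc}") from exc
    finally:
        vcf.close()

    genotypes = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    haplotypes = None
    if all_phased and rows and not (genotypes == MISSING).any():
        haplotypes = (
            np.vstack([h[0] for h in hap_rows]),
            np.vstack([h[1] for h in hap_rows]),
        )
    gm = GenotypeMatrix(
        samples=samples,
        variant_keys=[v.key for v in variants],
        genotypes=genotypes,
        haplotypes=haplotypes,
    )
    return variants, gm


def write_vcf(path: str | Path, variants: list[Variant], gm: GenotypeMatrix) -> None:
    """Write biallelic variants and genotypes as a minimal VCF v4.2."""
    phased = gm.haplotypes is not None
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=famshare\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=.,Type=String,Description="Gene symbols">\n')
        fh.write('##INFO=<ID=REGION,Number=1,Type=String,Description="Genomic region class">\n')
        fh.write('##INFO=<ID=CSQ,Number=1,Type=String,Description="Exonic consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        sep = "|" if phased else "/"
        for i, v in enumerate(variants):
            info_parts = []
            if v.genes:
                info_parts.append("GENE=" + ",".join(v.genes))
            info_parts.append(f"REGION={v.region.value}")
            if v.consequence is not None:
                info_parts.append(f"CSQ={v.consequence.value}")
            gt_fields = []
            for j in range(gm.n_samples):
                g = gm.genotypes[i, j]
                if g == MISSING:
                    gt_fields.append(f".{sep}.")
                elif phased:
                    gt_fields.append(f"{gm.haplotypes[0][i, j]}{sep}{gm.haplotypes[1][i, j]}")
                else:
                    gt_fields.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.rsid or ".",
                        v.ref,
                        v.alt,
                        ".",
                        "PASS",
                        ";".join(info_parts),
                        "GT",
                    ]
                    + gt_fields
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pedigree

_SEX_CODES = {"1": Sex.male, "2": Sex.female, "0": Sex.unknown, "-9": Sex.unknown}


def read_pedigree(path: str | Path) -> list[Individual]:
    """Read a PED-like file; optional 7th column is the mz_group label.

    Phenotype code 2 means affected. Parent id "0" marks a founder.
    Validates parent links and monozygotic-group coherence.
    """
    individuals: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path} line {lineno}: expected >= 6 tab-separated columns")
            fid, iid, pat, mat, sex, pheno = fields[:6]
            mz = fields[6].strip() if len(fields) > 6 and fields[6].strip() else None
            individuals.append(
                Individual(
                    id=iid,
                    family_id=fid,
                    father_id=None if pat == "0" else pat,
                    mother_id=None if mat == "0" else mat,
                    sex=_SEX_CODES.get(sex, Sex.unknown),
                    affected=pheno.strip() == "2",
                    mz_group=mz,
                )
            )
    validate_pedigree(individuals)
    return individuals


def write_pedigree(path: str | Path, individuals: list[Individual]) -> None:
    sex_out = {Sex.male: "1", Sex.female: "2", Sex.unknown: "0"}
    with open(path, "w") as fh:
        for ind in individuals:
            fields = [
                ind.family_id,
                ind.id,
                ind.father_id or "0",
                ind.mother_id or "0",
                sex_out[ind.sex],
                "2" if ind.affected else "1",
            ]
            if ind.mz_group:
                fields.append(ind.mz_group)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Predictor status table

#: The default 21-tool ensemble (ANNOVAR-library style deleteriousness
#: predictors). Tools marked numeric report scores rather than categorical
#: calls and are thresholded by the configured cutoff.
DEFAULT_TOOLS: tuple[str, ...] = (
    "SIFT",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "fathmm-MKL",
    "RadialSVM",
    "LR",
    "PROVEAN",
    "MetaSVM",
    "MetaLR",
    "CADD",
    "GERP++",
    "DANN",
    "M-CAP",
    "Eigen",
    "GenoCanyon",
    "Polyphen2_HVAR",
    "Polyphen2_HDIV",
    "PhyloP",
    "SiPhy",
)

NUMERIC_TOOLS: frozenset = frozenset({"CADD", "GERP++", "DANN", "Eigen", "GenoCanyon", "PhyloP", "SiPhy"})

#: Raw categorical call -> internal status. "deleterious" and
#: "probably damaging" and "disease_causing" map to D;
#: "disease_causing_automatic" maps to A.
DEFAULT_STATUS_MAP: dict[str, str] = {
    "D": "D",
    "A": "A",
    "T": "T",
    "U": "U",
    "deleterious": "D",
    "probably damaging": "D",
    "possibly damaging": "D",
    "disease_causing": "D",
    "disease_causing_automatic": "A",
    "damaging": "D",
    "tolerated": "T",
    "benign": "T",
    "neutral": "T",
    "N": "T",
    "P": "D",
    "B": "T",
    ".": "U",
    "": "U",
    "NA": "U",
}


@dataclass
class ToolConfig:
    """Ordered predictor panel plus the raw-value -> status mapping.

    Numeric scores (CADD-class tools) carry no categorical call; values are
    thresholded at ``numeric_threshold`` (score >= threshold -> D, else T).
    """

    tools: tuple[str, ...] = DEFAULT_TOOLS
    status_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STATUS_MAP))
    numeric_tools: frozenset = NUMERIC_TOOLS
    numeric_threshold: float = 20.0

    @property
    def n_tools(self) -> int:
        return len(self.tools)

    def map_value(self, tool: str, raw: str) -> str:
        raw = raw.strip()
        if raw in self.status_map:
            return self.status_map[raw]
        if tool in self.numeric_tools:
            try:
                score = float(raw)
            except ValueError:
                raise ParseError(f"unmapped value {raw!r} in predictor column {tool!r}")
            if math.isnan(score):
                return "U"
            return "D" if score >= self.numeric_threshold else "T"
        raise ParseError(f"unmapped value {raw!r} in predictor column {tool!r}")


def read_prediction_table(
    path: str | Path, tool_config: Optional[ToolConfig] = None
) -> dict[str, PredictionProfile]:
    """Read an ANNOVAR-multianno-style TSV into per-variant status profiles.

    Requires Chr/Start/Ref/Alt key columns; each configured predictor column
    is mapped through the tool config. Predictors whose column is absent from
    the file yield status U. Unmapped raw values raise, never drop silently.
    """
    cfg = tool_config or ToolConfig()
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Chr", "Start", "Ref", "Alt"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing key column {col!r}")
    present = [t for t in cfg.tools if t in df.columns]
    absent = [t for t in cfg.tools if t not in df.columns]
    if absent:
        logger.warning("prediction table %s: %d predictor columns absent (-> U): %s",
                       path, len(absent), ",".join(absent))
    profiles: dict[str, PredictionProfile] = {}
    for _, row in df.iterrows():
        key = f"{row['Chr']}:{row['Start']}:{row['Ref']}:{row['Alt']}"
        statuses = [
            cfg.map_value(t, row[t]) if t in present else "U" for t in cfg.tools
        ]
        profiles[key] = PredictionProfile(key=key, statuses=statuses)
    return profiles


def write_prediction_table(
    path: str | Path,
    profiles: dict[str, PredictionProfile],
    tool_config: Optional[ToolConfig] = None,
) -> None:
    cfg = tool_config or ToolConfig()
    records = []
    for key, prof in profiles.items():
        chrom, pos, ref, alt = key.split(":")
        rec = {"Chr": chrom, "Start": pos, "Ref": ref, "Alt": alt}
        rec.update(dict(zip(cfg.tools, prof.statuses)))
        records.append(rec)
    pd.DataFrame.from_records(records, columns=["Chr", "Start", "Ref", "Alt", *cfg.tools]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# IBD segments


class IBDReadResult(list):
    """List of IBDSegment with a count of rejected malformed rows."""

    def __init__(self, segments=(), n_rejected: int = 0):
        super().__init__(segments)
        self.n_rejected = n_rejected


def read_ibd_file(path: str | Path, dialect: str = "refined_ibd") -> IBDReadResult:
    """Read pairwise IBD segments.

    ``refined_ibd``: id1 hap1 id2 hap2 chrom start end LOD (haplotype
    indices discarded). ``simple_tsv``: id1 id2 chrom start end lod cm.
    Rows with start >= end are rejected with a warning and counted.
    """
    if dialect not in ("refined_ibd", "simple_tsv"):
        raise ValueError(f"unknown IBD dialect {dialect!r}")
    segments: list[IBDSegment] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "refined_ibd":
                    id1, _hap1, id2, _hap2, chrom, start, end, lod = f[:8]
                    cm = float(f[8]) if len(f) > 8 and f[8] not in (".", "") else None
                else:
                    id1, id2, chrom, start, end, lod = f[:6]
                    cm = float(f[6]) if len(f) > 6 and f[6] not in (".", "") else None
                seg = IBDSegment(
                    id1=id1, id2=id2, chrom=chrom,
                    start_bp=int(start), end_bp=int(end),
                    lod=float(lod), length_cm=cm,
                )
            except (ValueError, IndexError) as exc:
                n_rejected += 1
                logger.warning("%s line %d: rejected IBD row (%s)", path, lineno, exc)
                continue
            segments.append(seg)
    return IBDReadResult(segments, n_rejected)


def write_ibd_file(path: str | Path, segments: list[IBDSegment], dialect: str = "simple_tsv") -> None:
    with open(path, "w") as fh:
        for s in segments:
            cm = f"{s.length_cm}" if s.length_cm is not None else "."
            if dialect == "simple_tsv":
                fh.write(f"{s.id1}\t{s.id2}\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{s.lod}\t{cm}\n")
            else:
                fh.write(f"{s.id1}\t1\t{s.id2}\t1\t{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{s.lod}\t{cm}\n")


# ---------------------------------------------------------------------------
# Gene models (BED)


def read_gene_bed(path: str | Path) -> list[GeneModel]:
    """Read BED3+name gene spans, converting to 1-based inclusive."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path} line {lineno}: BED3+name requires 4 columns")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else None
            if start < 0 or end < 0:
                raise ParseError(f"{path} line {lineno}: negative coordinate")
            if end <= start:
                raise ParseError(f"{path} line {lineno}: zero- or negative-length interval")
            genes.append(GeneModel(symbol=name, chrom=chrom, start_bp=start + 1, end_bp=end, strand=strand))
    return genes


def write_gene_bed(path: str | Path, genes: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fields = [g.chrom, str(g.start_bp - 1), str(g.end_bp), g.symbol]
            if g.strand:
                fields += ["0", g.strand]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Population frequency table


def read_frequency_table(path: str | Path) -> PopulationFrequency:
    """Read a TSV with a variant_key column and one column per population."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_key": str})
    if "variant_key" not in df.columns:
        raise ParseError(f"{path}: missing 'variant_key' column")
    pops = [c for c in df.columns if c != "variant_key"]
    panel = PopulationFrequency(populations=pops)
    for _, row in df.iterrows():
        for p in pops:
            af = row[p]
            if pd.notna(af):
                panel.set(row["variant_key"], p, float(af))
    return panel


def write_frequency_table(path: str | Path, panel: PopulationFrequency) -> None:
    records = []
    for key in panel.keys():
        rec = {"variant_key": key}
        rec.update(panel.row(key))
        records.append(rec)
    pd.DataFrame.from_records(records, columns=["variant_key", *panel.populations]).to_csv(
        path, sep="\t", index=False
    )
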