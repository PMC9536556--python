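"""Cross-population descriptive statistics: per-gene pathogenic SNP
fractions, minor-allele-frequency spectra in six fixed bins, and gene-level
aggregated SNP frequencies.

The six MAF bins are [0, 0.05], (0.05, 0.1], (0.1, 0.2], (0.2, 0.3],
(0.3, 0.4], (0.4, 0.5]; the first bin is closed at 0.05. A gene's
"SNP frequency" is by default the SUM of the MAFs of the SNPs assigned to
it (including a configurable up/downstream flank), which is why reported
values can exceed 1; mean aggregation is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .models import GeneModel, PopulationFrequency

MAF_BIN_EDGES = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
MAF_BIN_LABELS = ("0-0.05", ">0.05-0.1", ">0.1-0.2", ">0.2-0.3", ">0.3-0.4", ">0.4-0.5")


def compute_maf(af: float) -> float:
    """Minor-allele frequency: min(af, 1 - af), in [0, 0.5]."""
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    return min(af, 1.0 - af)


@dataclass
class MAFSpectrum:
    population: str
    proportions: tuple[float, ...]  # one per bin, sums to 1 when defined
    n_snps: int

    @property
    def defined(self) -> bool:
        return self.n_snps > 0


def bin_maf(mafs: list[float], population: str = "") -> MAFSpectrum:
    """Assign MAFs to the six bins and return per-bin proportions.

    The first bin is closed ([0, 0.05]); later bins are half-open (a, b].
    An empty input yields an all-zero, undefined spectrum.
    """
    arr = np.asarray(mafs, dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 0.5):
        raise ValueError("MAF values must lie in [0, 0.5]")
    if arr.size == 0:
        return MAFSpectrum(population=population, proportions=(0.0,) * 6, n_snps=0)
    counts = np.zeros(6, dtype=int)
    for m in arr:
        for b in range(6):
            if (b == 0 and m <= MAF_BIN_EDGES[1]) or (
                b > 0 and MAF_BIN_EDGES[b] < m <= MAF_BIN_EDGES[b + 1]
            ):
                counts[b] += 1
                break
    return MAFSpectrum(
        population=population,
        proportions=tuple(counts / counts.sum()),
        n_snps=int(arr.size),
    )


def pathogenic_fraction(pathogenic_flags: list[bool]) -> Optional[float]:
    """Count of pathogenic SNPs over total SNPs assigned to the gene;
    undefined (None), not 0, for an empty SNP set."""
    if len(pathogenic_flags) == 0:
        return None
    return sum(bool(f) for f in pathogenic_flags) / len(pathogenic_flags)


def assign_snps_to_gene(
    gene: GeneModel, snp_positions: dict[str, tuple[str, int]], flank_bp: int = 2000
) -> list[str]:
    """Variant keys falling within the gene span extended by ``flank_bp``
    up- and downstream. ``snp_positions`` maps key -> (chrom, pos)."""
    lo, hi = gene.start_bp - flank_bp, gene.end_bp + flank_bp
    return [
        k for k, (chrom, pos) in snp_positions.items()
        if chrom == gene.chrom and lo <= pos <= hi
    ]


def gene_snp_frequency(mafs: list[float], aggregation: str = "sum") -> Optional[float]:
    """Aggregate per-SNP MAFs at the gene level (default: sum, unbounded
    above); undefined for a gene with no assigned SNPs."""
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if len(mafs) == 0:
        return None
    return float(np.sum(mafs)) if aggregation == "sum" else float(np.mean(mafs))


@dataclass
class GeneBurdenStats:
    gene: str
    population: str
    pathogenic_fraction: Optional[float]
    gene_snp_frequency: Optional[float]
    n_snps: int


def population_comparison_table(
    genes: list[GeneModel],
    panel: PopulationFrequency,
    pathogenic: set[str],
    flank_bp: int = 2000,
    aggregation: str = "sum",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-gene/per-population burden table plus per-population
    MAF spectra.

    ``pathogenic`` is the set of variant keys flagged pathogenic (an input
    emulating reported-pathogenicity annotation, not recomputed here).
    Returns (burden, spectra) DataFrames with deterministic ordering;
    undefined statistics appear as NaN.
    """
    snp_positions: dict[str, tuple[str, int]] = {}
    for key in panel.keys():
        chrom, pos, _ref, _alt = key.split(":")
        snp_positions[key] = (chrom, int(pos))

    burden_rows = []
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start_bp, g.symbol)):
        keys = assign_snps_to_gene(gene, snp_positions, flank_bp)
        for pop in panel.populations:
            present = [k for k in keys if panel.get(k, pop) is not None]
            mafs = [compute_maf(panel.get(k, pop)) for k in present]
            flags = [k in pathogenic for k in present]
            burden_rows.append(
                {
                    "gene": gene.symbol,
                    "population": pop,
                    "pathogenic_fraction": pathogenic_fraction(flags),
                    "gene_snp_frequency": gene_snp_frequency(mafs, aggregation),
                    "n_snps": len(present),
                }
            )
    burden = pd.DataFrame(burden_rows)

    spectra_rows = []
    for pop in panel.populations:
        mafs = [
            compute_maf(panel.get(k, pop))
            for k in panel.keys()
            if panel.get(k, pop) is not None
        ]
        spec = bin_maf(mafs, population=pop)
        row = {"population": pop, "n_snps": spec.n_snps}
        row.update(dict(zip(MAF_BIN_LABELS, spec.proportions)))
        spectra_rows.append(row)
    spectra = pd.DataFrame(spectra_rows)
    return burden, spectra
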