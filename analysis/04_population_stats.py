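#!/usr/bin/env python
"""Cross-population burden statistics with the two families as extra groups.

Computes per-gene pathogenic fractions and summed-MAF gene SNP frequencies
for the 20-population panel plus FamilyA/FamilyB allele frequencies derived
from the simulated genotypes, together with the six-bin MAF spectrum of
every group. Writes results/gene_burden.tsv and results/maf_spectra.tsv and
prints the genes where the families rank above every panel population —
the qualitative pattern the family-versus-panel comparison looks for.
"""

import json
from pathlib import Path

import numpy as np

from famshare import io as fio
from famshare.models import PopulationFrequency
from famshare.popstats import population_comparison_table

ROOT = Path(__file__).resolve().parent.parent
FX = ROOT / "results" / "synthetic"
OUT = ROOT / "results"


def family_frequencies(gm, pedigree):
    """Alternate-allele frequency per family from genotyped members."""
    out = {}
    for fam in sorted({i.family_id for i in pedigree}):
        ids = [i.id for i in pedigree if i.family_id == fam and i.id in gm.samples]
        cols = [gm.sample_index(s) for s in ids]
        g = gm.genotypes[:, cols].astype(float)
        g[g < 0] = np.nan
        with np.errstate(invalid="ignore"):
            out[fam] = np.nanmean(g, axis=1) / 2.0
    return out


def main() -> None:
    variants, gm = fio.read_vcf(FX / "families.vcf")
    pedigree = fio.read_pedigree(FX / "families.ped")
    panel = fio.read_frequency_table(FX / "frequencies.tsv")
    genes = fio.read_gene_bed(FX / "genes.bed")
    pathogenic = set(json.loads((FX / "truth.json").read_text())["true_deleterious"])

    fam_af = family_frequencies(gm, pedigree)
    extended = PopulationFrequency(populations=list(panel.populations) + list(fam_af))
    for key in panel.keys():
        for pop, af in panel.row(key).items():
            extended.set(key, pop, af)
    # a family "has" a SNP only if it actually segregates there; this is what
    # makes the family pathogenic fraction comparable to the panel's
    for fam, afs in fam_af.items():
        for key, af in zip(gm.variant_keys, afs):
            if np.isfinite(af) and af > 0:
                extended.set(key, fam, float(af))

    burden, spectra = population_comparison_table(genes, extended, pathogenic, flank_bp=2000)
    burden.to_csv(OUT / "gene_burden.tsv", sep="\t", index=False)
    spectra.to_csv(OUT / "maf_spectra.tsv", sep="\t", index=False)

    fam_top = []
    for gene, sub in burden.dropna(subset=["pathogenic_fraction"]).groupby("gene"):
        fams = sub[sub.population.isin(fam_af)]
        others = sub[~sub.population.isin(fam_af)]
        if len(fams) and fams.pathogenic_fraction.min() > others.pathogenic_fraction.max():
            fam_top.append(gene)
    print(f"{len(burden)} burden rows ({burden.gene.nunique()} genes x "
          f"{burden.population.nunique()} groups)")
    print(f"genes where both families exceed every panel population in "
          f"pathogenic fraction: {', '.join(sorted(fam_top)) or '-'}")
    print("MAF spectra (first bin = rare [0,0.05]):")
    print(spectra.to_string(index=False, max_rows=25))


if __name__ == "__main__":
    main()
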