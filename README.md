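# famshare

Family-based variant prioritization and identity-by-descent (IBD) sharing
analysis for small pedigrees, built around the design of a two-family
whole-genome study of non-contact anterior cruciate ligament (ACL) rupture:
two unrelated nuclear families, each with a monozygotic twin pair, analysed
for (i) rare, protein-altering variants that a multi-tool deleteriousness
consensus and a family carrier pattern both support, (ii) shared IBD
segments within and between families and the genes they contain, and
(iii) cross-population per-gene pathogenic burden and minor-allele-frequency
(MAF) spectra. It is intended for genetic epidemiologists and statistical
geneticists who need this family of analyses to be reproducible and testable
without access to the original (undeposited) sequence data.

At its core are three operations:

* **Casting vote.** A variant with predictor statuses s₁…s₂₁ ∈ {D, A, T, U}
  is retained iff #{i : sᵢ ∈ {D, A}} ≥ 17, combined with rarity
  (AF ≤ 0.01 in a scoped population panel), consequence (nonsynonymous /
  stopgain / stoploss) and carrier filters (e.g. homozygous in every
  affected family member); per-family candidate gene lists are then
  intersected across families.
* **IBD sharing.** Pairwise segments (Refined-IBD-style input, or a
  built-in genotype-based detector scoring LOD = Σ log₁₀ P(g₁,g₂|IBD1) /
  P(g₁)P(g₂) over IBS0-free marker runs) are filtered at LOD ≥ 3,
  annotated with overlapping genes, and intersected across families.
* **Gene-drop simulation.** Founder haplotypes drawn from a 20-population
  frequency panel are dropped through the pedigrees with Poisson
  recombination; monozygotic twins copy the same meiosis products; planted
  deleterious variants and exact ancestry-derived IBD segments provide
  ground truth for every stage.

## Worked example

The analysis is organised as numbered drivers over the `famshare` library
(`src/famshare/`), writing tables under `results/`:

```
python analysis/01_simulate_families.py    # synthetic two-family bundle
python analysis/02_prioritize_variants.py  # casting vote + intersection
python analysis/03_ibd_sharing.py          # detector + sharing tables
python analysis/04_population_stats.py     # burden + MAF spectra
python analysis/05_worked_examples.py      # published-record examples
```

Step 02 prints, for the default seed:

```
FamilyA: 6 retained variants in 5 genes: COL12A1, CATSPER2, KCNJ12, COL11A1, TNC
FamilyB: 5 retained variants in 4 genes: COL12A1, CATSPER2, KCNJ12, COL5A1
shared genes across families: ['CATSPER2', 'COL12A1', 'KCNJ12']
planted cross-family truth:   ['CATSPER2', 'COL12A1', 'KCNJ12']
MATCH
```

i.e. the per-family candidate lists recover exactly the planted genes and
their intersection equals the three genes planted in both families. Step 03
reports MZ-twin detected IBD covering 99.9% of the genome and lists the
cross-family gene intersections; step 05 re-runs the operations on the
published summary records and reproduces the printed quantities — the
29- and 18-gene candidate lists intersect to 3 genes, all 11 published
segments pass LOD ≥ 3, the two families' twin segments on chr2 intersect at
3,009,692–3,047,881 containing LINC01250, the 15q11.2 intersection carries
6 genes, and the mother–brother 19q13.42 segment overlaps 20 genes.

The same stages are scriptable through a CLI
(`famshare simulate|prioritize|ibd|popstats|run`) driven by a YAML config;
`famshare run --seed 2026 --out rundir` executes the whole pipeline and
writes `summary.json`.

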