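# Methods

`famshare` implements a family-based rare-variant sharing analysis for
whole-genome data from small pedigrees — here, two unrelated nuclear
families, each containing a monozygotic (MZ) twin pair with non-contact
anterior cruciate ligament (ACL) rupture, plus affected/unaffected
relatives. Because the families' sequence data are not publicly deposited,
every stage is paired with a pedigree gene-drop simulator that emulates the
study design and exports ground truth, so the pipeline is verifiable end to
end without any external download.

## Variant prioritization: the casting-vote consensus

Each biallelic variant carries an ordered vector of categorical calls from
a panel of deleteriousness predictors (default 21: SIFT, LRT,
MutationTaster, MutationAssessor, FATHMM, fathmm-MKL, RadialSVM, LR,
PROVEAN, MetaSVM, MetaLR, CADD, GERP++, DANN, M-CAP, Eigen, GenoCanyon,
PolyPhen-2 HVAR/HDIV, PhyloP, SiPhy). Raw calls are normalised to four
statuses: D (damaging/deleterious, including "probably damaging" and
"disease_causing"), A (disease_causing_automatic), T (tolerated/benign),
U (unknown/not scored). The casting vote retains a variant iff

&nbsp;&nbsp;&nbsp;&nbsp;#{tools with status ∈ {D, A}} ≥ `min_votes`,&nbsp;&nbsp;default 17 of 21.

U never qualifies and the denominator stays at the configured tool count,
so missing predictions can only hurt a variant. Tools that emit numeric
scores rather than categorical calls (the CADD/GERP++/PhyloP class) carry
no published voting rule; they are thresholded by a configurable cutoff
(default: score ≥ 20 → D, else T), which is an explicit assumption of this
implementation, logged per run.

The full per-family filter is rarity → exonic protein-altering consequence
(nonsynonymous, stopgain, stoploss) → casting vote → carrier pattern. The
three predicates are per-variant and commute; they are applied once each
(the source protocol mentions rarity filtering both before and after the
vote without distinct thresholds, which is equivalent to a single
idempotent application). Defaults that the source leaves open:

* `max_af` = 0.01, scope = any panel population. The published shared
  variants include one with European AF 0.73 but African AF 0.0026, so an
  all-population rarity rule cannot reproduce the published list; "rare in
  at least one scoped population" is the weakest rule consistent with it.
  Scope and mode (`any`/`all`) are configurable.
* Variants absent from the frequency panel count as rare (novel family
  variants are exactly the interesting case); occurrences are logged.
* Carrier mode: `all_affected_carry` (genotype ≥ 1 in every affected,
  genotyped family member) or `all_affected_homozygous` (genotype 2, the
  pattern of the published shared variants). Missing genotypes fail the
  test. The pipeline default is the homozygous mode.

Per-family candidate genes are the genes of retained variants, ordered by
the position of first support; the cross-family result is their set
intersection (symmetric in family order), with a union table carrying
per-family membership flags.

## IBD sharing

Pairwise shared segments are consumed in Refined-IBD output format (or a
simple TSV dialect for fixtures), filtered at LOD ≥ 3.0 — chosen below the
smallest published segment LOD of 3.31 so every published row survives —
and annotated with overlapping gene models via an interval tree. Overlap is
≥ 1 bp intersection of 1-based closed intervals (`full_containment`
optional); gene lists keep duplicate symbols as listed (the published table
prints one symbol twice), with an optional dedup. Cross-family common
regions are interval intersections of segment pairs from different
families, reporting the gene symbols present in both segments' lists;
by default only pairs in which all four samples are affected contribute.
Band labels like "2p25.3"/"2q25.3" are carried as opaque strings —
coordinates, which are unambiguous, drive all computation.

Published counts that do not reconcile internally (e.g. prose totals of
17/8/29 genes versus 11/6/27 listed entries for the same segments) are
handled by always counting entries as listed.

### The built-in segment detector

For synthetic end-to-end runs the package includes a deliberately simple
genotype-based detector (it is not a haplotype-HMM and is documented as
unsuitable for real, error-prone data). For each sample pair and
chromosome, markers are scanned for maximal runs free of opposite
homozygotes (IBS0 sites, which are impossible under IBD ≥ 1 without
genotype error); within each run, maximal positive-sum windows of the
per-site score

&nbsp;&nbsp;&nbsp;&nbsp;LOD(site) = log₁₀ [ P(g₁, g₂ | IBD1) / P(g₁) P(g₂) ]

are extracted recursively (Kadane's algorithm), where both terms use
Hardy–Weinberg genotype probabilities at the panel allele frequency, and
P(g₁, g₂ | IBD1) conditions on the shared allele being alternate (prob. p)
or reference (1 − p) with one free allele per sample. Windows need
≥ `min_markers` (default 25) and LOD ≥ 3. With `max_ibs0` > 0, IBS0 sites
score a fixed −3 penalty instead of splitting, and any window containing
more than `max_ibs0` of them is discarded. Sites with panel frequency
outside (0.001, 0.999) or missing are ignored; frequencies are clipped to
[0.005, 0.995] for scoring. Genetic lengths come from the uniform map.

## Gene-drop simulator

Founder haplotypes are per-site Bernoulli draws at the founder population's
panel frequency. Each meiosis places crossovers as a Poisson process with a
uniform genetic map (default 1 cM/Mb; no interference — adequate for
segment-length behaviour at pedigree scale). MZ co-twins receive copies of
the same meiosis products, so their genomes are byte-identical and their
true IBD trivially covers every chromosome. Every transmitted allele traces
to a founder haplotype via ancestry tracks, from which exact pairwise IBD
segments are computed as merged maximal intervals where any of the four
haplotype pairings shares a founder haplotype id. For full siblings this
yields the textbook genome fraction E[IBD ≥ 1] = 3/4, which the tests
recover over 200 replicates of a 35-Morgan map.

The default pedigrees mirror the study: Family A = father, mother, MZ
twins, brother (father, twins, brother affected); Family B = father
(deceased, simulated but not genotyped), mother, MZ twins, sister (twins
affected) — six affected genotyped individuals in total.

The frequency panel covers 20 populations (1000-Genomes-style labels); a
configurable fraction of variants (default 0.3) is forced rare
(MAF ≤ 0.05) in a designated population while remaining occasionally
common elsewhere, and the rest follow a Balding–Nichols-style draw
(F_ST = 0.05) around a shared ancestral frequency, populating all six MAF
bins. This is a parametric stand-in, not a coalescent model: it has no
mutation/selection/demography, no linkage disequilibrium between sites
beyond pedigree transmission, and no genotype error by default (a
symmetric flip rate exists for stress tests). Passing tests therefore
validate the pipeline's logic and its statistical behaviour under clean
Mendelian transmission, not robustness to real sequencing artefacts.

Planted "true deleterious" variants are written into chosen exonic sites of
target genes: affected members of the target families get the pattern
genotype (default homozygous alternate), unaffected members the minimal
Mendelian-consistent genotype, with a feasibility check that raises on
impossible patterns (never a silent adjustment). Planting rewrites
genotypes directly rather than re-threading founder haplotypes; allele
sharing inside true IBD segments is preserved because every carrier holds
the alternate allele. Planted sites are re-assigned a rare panel frequency
in the designated rare population, mirroring the published
rare-in-one-ancestry pattern. The default plan is a scaled-down analogue of
the published candidate structure: COL12A1, CATSPER2 and KCNJ12 (two
variants) planted in both families, plus family-private genes, so the
cross-family truth is exactly three genes.

Simulated predictors emit qualifying statuses with per-tool sensitivity
(default 0.95) for true variants — MutationTaster emits A, the others D —
and false D calls at 1 − specificity (default 0.99) otherwise, making
retention of true variants an exact binomial tail P(Bin(21, s) ≥ 17) that
the tests verify against `scipy.stats.binom`.

## Population statistics

MAF is min(p, 1 − p) of the alternate-allele frequency. Spectra use six
fixed bins [0, 0.05], (0.05, 0.1], (0.1, 0.2], (0.2, 0.3], (0.3, 0.4],
(0.4, 0.5]; the boundary 0.05 belongs to the first bin, following the
bin-notation convention "0–0.05, >0.05–0.1". A gene's pathogenic fraction
is (# reported-pathogenic SNPs)/(# SNPs assigned to the gene), undefined —
not zero — for genes with no SNPs; pathogenic flags are an input (emulating
reported-pathogenicity annotation), never recomputed. Gene-level SNP
frequency assigns SNPs within the gene span ± 2 kb flank (the conventional
up/downstream window; no size is published) and aggregates per-SNP MAFs by
SUM by default: published per-gene values exceed 1, which is impossible for
a mean of MAFs ≤ 0.5, so sum is the only aggregation consistent with them;
mean is selectable and the choice is recorded in output metadata.

## Orchestration and determinism

All randomness flows from one integer seed through named substreams
(CRC32-keyed `SeedSequence`), so enabling or disabling one stage never
shifts another's draws, and a fixed configuration reproduces every fixture
byte-identically. The run directory archives the configuration verbatim;
output TSVs are sorted (family, chromosome, position) for diff-stability;
a failing stage leaves a FAILED marker naming the stage and keeps partial
outputs.

## Problem sizes

The shipped analyses use 4,000 variant sites on three chromosomes
(100 + 100 + 60 Mb) for the default two-family run, 10,000 markers on
2 × 120 Mb for detector evaluation, 200 ancestry-only replicates of a
35-Morgan, 7-chromosome map for the sib-pair IBD expectation, and
5,000-variant batches for binomial-recovery checks — sizes at which each
analysis completes in seconds while leaving Monte-Carlo standard errors
small relative to the tested tolerances.

## Known limitations

* The detector ignores phase and linkage disequilibrium; on real data it
  would fragment at genotype errors (IBS0 splitting) and over-call in
  LD-dense regions. It exists to close the loop on synthetic runs.
* The simulator's sites are in linkage equilibrium among founders; only
  co-inheritance within the pedigree creates correlation.
* No penetrance model links planted variants to affection status; the
  carrier-pattern plan is a deliberate abstraction, not an inference
  target.
* Candidate-list worked examples pad unpublished portions of the
  per-family gene lists with clearly-marked synthetic filler symbols; only
  published quantities (list sizes, the three-gene intersection) are
  asserted.
* Genome-build liftover, structural variants and BAM/CRAM handling are out
  of scope; printed intervals are treated as 1-based inclusive hg38-style
  coordinates.
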