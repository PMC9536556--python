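#!/usr/bin/env python
"""Generate the synthetic two-family dataset used by the downstream steps.

Writes the full fixture bundle (VCF, PED, predictor statuses, 20-population
frequency panel, gene BED, ground truth) under results/synthetic/ with the
default study-shaped configuration: two nuclear families each containing a
monozygotic twin pair, six affected genotyped individuals, and seven planted
deleterious variants across six genes (three genes planted in both families).
"""

from pathlib import Path

from famshare.simulate import SimulationConfig, default_pathogenic_plan, write_fixture_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 2026


def main() -> None:
    cfg = SimulationConfig(seed=SEED, pathogenic_plan=default_pathogenic_plan())
    paths = write_fixture_bundle(OUT, cfg)
    print(f"seed {SEED}: simulated {cfg.n_variants} sites on "
          f"{len(cfg.chrom_lengths_bp)} chromosomes for 10 pedigree members")
    for name, p in paths.items():
        print(f"  {name}: {p}")
    print("planted genes (cross-family truth = genes planted in both families):")
    for spec in cfg.pathogenic_plan:
        fams = ",".join(spec.families) if spec.families else "both"
        print(f"  {spec.gene}: {spec.n_variants} variant(s), {spec.pattern}, families={fams}")


if __name__ == "__main__":
    main()
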