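"""One-config orchestration: simulate -> prioritize -> ibd -> popstats.

Each stage reads the previous stage's files from the run directory (or
externally supplied paths), writes deterministic, diff-stable TSVs, and the
run ends with a combined ``summary.json``. The configuration is archived
verbatim into the run directory; re-running an archived config reproduces
every deterministic output byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as fio
from . import ibd as fibd
from . import popstats as fpop
from . import prioritize as fpri
from .simulate import (
    PlantSpec,
    SimulationConfig,
    default_pathogenic_plan,
    write_fixture_bundle,
)

logger = logging.getLogger("famshare")


@dataclass
class RunConfig:
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {"simulate": True, "prioritize": True, "ibd": True, "popstats": True}
    )
    # inputs (filled by the simulate stage when enabled)
    vcf: Optional[str] = None
    ped: Optional[str] = None
    predictions: Optional[str] = None
    frequencies: Optional[str] = None
    genes: Optional[str] = None
    ibd_segments: Optional[str] = None
    ibd_dialect: str = "refined_ibd"
    # simulation
    simulate: dict = field(default_factory=dict)
    # prioritization thresholds
    max_af: float = 0.01
    min_votes: int = 17
    scope: Optional[list] = None
    scope_mode: str = "any"
    carrier_mode: str = "all_affected_homozygous"
    # IBD
    min_lod: float = 3.0
    min_cm: float = 0.0
    affected_only: bool = True
    detector: dict = field(default_factory=lambda: {"min_markers": 25, "max_ibs0": 0})
    # population stats
    flank_bp: int = 2000
    aggregation: str = "sum"

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        plan = params.pop("pathogenic_plan", None)
        if plan is None:
            plan_specs = default_pathogenic_plan()
        else:
            plan_specs = [PlantSpec(**p) for p in plan]
        return SimulationConfig(seed=self.seed, pathogenic_plan=plan_specs, **params)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise fpri.ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the enabled stages into ``outdir`` and write summary.json.

    On stage failure a FAILED marker naming the stage is left in the run
    directory, partial outputs are retained, and StageError is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "init"
    try:
        if config.stages.get("simulate"):
            stage = "simulate"
            sim_cfg = config.simulation_config()
            paths = write_fixture_bundle(outdir / "fixtures", sim_cfg)
            config.vcf = str(paths["vcf"])
            config.ped = str(paths["ped"])
            config.predictions = str(paths["predictions"])
            config.frequencies = str(paths["frequencies"])
            config.genes = str(paths["genes"])
            summary["stages"]["simulate"] = {
                "n_variants": sim_cfg.n_variants,
                "fixtures": {k: str(Path(v).relative_to(outdir)) for k, v in paths.items()},
            }

        needs_inputs = config.stages.get("prioritize") or config.stages.get("ibd") or config.stages.get("popstats")
        if needs_inputs:
            stage = "load"
            variants, gm = fio.read_vcf(config.vcf)
            pedigree = fio.read_pedigree(config.ped)
            panel = fio.read_frequency_table(config.frequencies)
            genes = fio.read_gene_bed(config.genes)

        if config.stages.get("prioritize"):
            stage = "prioritize"
            profiles = fio.read_prediction_table(config.predictions)
            families = sorted({i.family_id for i in pedigree})
            reports = []
            rows = []
            for fam in families:
                rep = fpri.prioritize_family(
                    fam, variants, gm, pedigree, profiles, panel,
                    max_af=config.max_af, min_votes=config.min_votes,
                    scope=config.scope, scope_mode=config.scope_mode,
                    carrier_mode=config.carrier_mode,
                )
                reports.append(rep)
                for v in rep.retained:
                    prof = profiles[v.key]
                    for g in v.genes:
                        rows.append(
                            {
                                "family": fam, "gene": g, "chrom": v.chrom, "pos": v.pos,
                                "ref": v.ref, "alt": v.alt, "rsid": v.rsid or ".",
                                "qualifying_votes": prof.qualifying_votes(),
                                "statuses": "".join(prof.statuses),
                            }
                        )
            import pandas as pd

            pd.DataFrame(
                rows,
                columns=["family", "gene", "chrom", "pos", "ref", "alt", "rsid",
                         "qualifying_votes", "statuses"],
            ).sort_values(["family", "chrom", "pos"]).to_csv(
                outdir / "candidates.tsv", sep="\t", index=False
            )
            shared, union = fpri.intersect_families(reports)
            with open(outdir / "shared_genes.tsv", "w") as fh:
                fh.write("gene\t" + "\t".join(families) + "\tshared\n")
                for g in sorted(union):
                    flags = ["1" if union[g].get(f) else "0" for f in families]
                    fh.write(f"{g}\t" + "\t".join(flags) + f"\t{int(g in shared)}\n")
            summary["stages"]["prioritize"] = {
                "per_family_gene_counts": {r.family_id: len(r.genes) for r in reports},
                "shared_genes": sorted(shared),
            }

        if config.stages.get("ibd"):
            stage = "ibd"
            sim_cfg = config.simulation_config() if config.stages.get("simulate") else None
            if config.ibd_segments:
                segments = list(fio.read_ibd_file(config.ibd_segments, config.ibd_dialect))
            else:
                pop = sim_cfg.founder_population if sim_cfg else panel.populations[0]
                cm_per_mb = sim_cfg.cm_per_mb if sim_cfg else 1.0
                fams: dict[str, list[str]] = {}
                for ind in pedigree:
                    if ind.id in gm.samples:
                        fams.setdefault(ind.family_id, []).append(ind.id)
                pairs = [
                    (ids[a], ids[b])
                    for ids in fams.values()
                    for a in range(len(ids)) for b in range(a + 1, len(ids))
                ]
                segments = fibd.detect_ibd_segments(
                    gm, variants, panel, pop,
                    min_lod=config.min_lod, cm_per_mb=cm_per_mb, pairs=pairs,
                    **config.detector,
                )
            kept = fibd.filter_segments(segments, min_lod=config.min_lod, min_cm=config.min_cm)
            records = fibd.pairwise_sharing_table(kept, pedigree, genes)
            with open(outdir / "ibd_sharing.tsv", "w") as fh:
                fh.write("family\tsample1\tsample2\taffected1\taffected2\tchrom\tstart\tend\tgenes\tlod\tcm\n")
                for r in records:
                    s = r.segment
                    fh.write(
                        f"{r.family_id}\t{r.id1}\t{r.id2}\t{int(r.affected1)}\t{int(r.affected2)}\t"
                        f"{s.chrom}\t{s.start_bp}\t{s.end_bp}\t{','.join(r.genes)}\t"
                        f"{s.lod:.3f}\t{s.length_cm if s.length_cm is not None else '.'}\n"
                    )
            regions, cross_genes = fibd.cross_family_common(records, affected_only=config.affected_only)
            with open(outdir / "ibd_cross_family.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\tfamily1\tfamily2\tcommon_genes\n")
                for r in regions:
                    fh.write(
                        f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.family1}\t{r.family2}\t"
                        f"{','.join(r.common_genes)}\n"
                    )
            summary["stages"]["ibd"] = {
                "n_segments": len(kept),
                "n_cross_family_regions": len(regions),
                "cross_family_genes": sorted(cross_genes),
            }

        if config.stages.get("popstats"):
            stage = "popstats"
            pathogenic: set[str] = set()
            if config.stages.get("simulate"):
                with open(Path(config.vcf).parent / "truth.json") as fh:
                    pathogenic = set(json.load(fh)["true_deleterious"])
            burden, spectra = fpop.population_comparison_table(
                genes, panel, pathogenic,
                flank_bp=config.flank_bp, aggregation=config.aggregation,
            )
            burden.to_csv(outdir / "gene_burden.tsv", sep="\t", index=False)
            spectra.to_csv(outdir / "maf_spectra.tsv", sep="\t", index=False)
            defined = burden.dropna(subset=["gene_snp_frequency"])
            top = (
                defined.groupby("gene")["gene_snp_frequency"].mean()
                .sort_values(ascending=False).head(5)
            )
            summary["stages"]["popstats"] = {
                "aggregation": config.aggregation,
                "top_genes_by_snp_frequency": {g: round(v, 4) for g, v in top.items()},
            }
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise StageError(stage, exc) from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return outdir
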