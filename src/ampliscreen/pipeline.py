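"""End-to-end pipeline: simulate/ingest -> genotype -> filter -> annotate ->
predict -> cohort statistics, with a deterministic report bundle.

The pipeline is configuration-driven.  Two input routes exist and compose:

* a simulation block (synthetic cohort generated in-run), or a FASTQ
  directory plus a genotyping-site table, feeding the k-mer genotyper;
* optionally a multi-sample VCF plus gene FASTA/GFF, feeding the filter
  cascade, the effect annotator and the phenotype caller.

Every stage logs its input/output counts; all randomness flows from the
single config seed, and re-running an identical config writes byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import effect_annotator, hiplex_sim, pgeno, popstats, resistance, variant_filter
from .fixtures import location_from_sample
from .gene_model import load_gene_model

logger = logging.getLogger("ampliscreen.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "ampliscreen_out"
    seed: int = 0

    # route 1a: synthetic cohort
    simulate: dict[str, Any] | None = None
    # route 1b: real reads
    fastq_dir: str | None = None
    site_table: str | None = None

    # route 2: variant analysis
    vcf: str | None = None
    gene_fasta: str | None = None
    exon_gff: str | None = None
    susceptible_list: str | None = None
    known_alleles: list[str] = field(default_factory=list)

    # thresholds / report options
    pgeno: dict[str, Any] = field(default_factory=dict)
    filter: dict[str, Any] = field(default_factory=dict)
    frequency_mode: str = "standard"
    rounding_mode: str = "round"
    table_compat: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None and (self.fastq_dir is None or self.site_table is None):
            raise PipelineError(
                "config", "either a simulate block or fastq_dir + site_table is required"
            )
        for label in ("fastq_dir", "site_table", "vcf", "gene_fasta", "exon_gff",
                      "susceptible_list"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise PipelineError("config", f"{label} path does not exist: {value}")
        if self.vcf is not None and (self.gene_fasta is None or self.exon_gff is None):
            raise PipelineError(
                "config", "vcf analysis requires gene_fasta and exon_gff"
            )


def _genotyping_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim_args = dict(cfg.simulate)
        sim_args.setdefault("seed", cfg.seed)
        sim = hiplex_sim.make_cohort_fixture(**sim_args)
        paths = hiplex_sim.write_cohort(sim, outdir / "simulated")
        logger.info(
            "simulate: %d samples, %d tiles", len(sim.specs), len(sim.design.tiles)
        )
        site_def = hiplex_sim.default_sites(sim.model)["gc_ins"]
        anchor = site_def.pos
        seq = sim.model.sequence
        site = pgeno.InsertionSite(
            site_id="gc_ins",
            left_flank=seq[anchor - 10 : anchor],
            inserted=site_def.alt[len(site_def.ref):],
            right_flank=seq[anchor : anchor + 10],
        )
        samples = {s.sample_id: sim.reads[s.sample_id] for s in sim.specs}
        truth = sim.truth
        return samples, site, truth
    sites = pgeno.read_site_table(cfg.site_table)
    if not sites:
        raise PipelineError("pgeno", "site table is empty")
    fastq_dir = Path(cfg.fastq_dir)
    samples = {
        p.stem: p for p in sorted(fastq_dir.glob("*.fastq"))
    }
    if not samples:
        raise PipelineError("pgeno", f"no .fastq files under {fastq_dir}")
    return samples, sites[0], None


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the configured stages and write the report bundle.

    Returns the summary dictionary that is also written as
    ``summary.json`` in the output directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"seed": config.seed, "stages": []}

    # --- genotyping ---------------------------------------------------
    samples, site, truth = _genotyping_inputs(config, outdir)
    calls, call_summary = pgeno.genotype_cohort(samples, site, **config.pgeno)
    calls.insert(1, "location", calls["sample_id"].map(location_from_sample))
    pgeno.write_calls(calls, outdir / "calls.tsv")
    summary["stages"].append({"stage": "pgeno", "n_samples": len(calls)})
    summary["genotype_counts"] = call_summary

    n_total = len(calls)
    n_het = call_summary["n_Sr"]
    n_hom = call_summary["n_rr"]
    freq = popstats.allele_frequency(n_het, n_hom, n_total, mode=config.frequency_mode)
    summary["allele_frequency"] = {
        "site_id": site.site_id,
        "mode": config.frequency_mode,
        "value": popstats.format_frequency(freq, 4, config.rounding_mode),
        "raw": freq,
    }

    cohort = calls[["sample_id", "location", "call"]].copy()
    cohort["method"] = "kmer"
    per_location = popstats.carrier_summary(cohort, "kmer")
    summary["carriers_by_location"] = {
        loc: {
            "n": int(row["n"]),
            "pct_carriers": int(row["pct_carriers"]),
            "pct_hom": int(row["pct_hom"]),
            "pct_het": int(row["pct_het"]),
        }
        for loc, row in per_location.iterrows()
    }

    if truth is not None:
        site_truth = truth[truth["site_id"] == site.site_id]
        merged = calls.merge(site_truth, on="sample_id", how="inner")
        agree = (merged["call"] == merged["genotype"]).mean()
        summary["truth_agreement"] = float(agree)

    # --- variant analysis ---------------------------------------------
    if config.vcf is not None:
        model = load_gene_model(config.gene_fasta, config.exon_gff, partial=True)
        records, sample_names = variant_filter.read_vcf(config.vcf)
        cfg = variant_filter.FilterConfig(**config.filter)
        kept, report = variant_filter.filter_variants(records, len(sample_names), cfg)
        if cfg.biallelic_only:
            kept, tallies = variant_filter.select_biallelic(kept)
        else:
            tallies = {}
        report.write(outdir / "attrition.tsv")
        variant_filter.write_vcf(kept, sample_names, outdir / "filtered.vcf")
        summary["stages"].append(
            {"stage": "filter", "n_input": report.n_input, "n_out": len(kept)}
        )
        summary["variant_tallies"] = tallies

        annotations = []
        for rec in kept:
            try:
                annotations.append(effect_annotator.annotate_variant(model, rec))
            except ValueError as exc:
                logger.warning("annotate: skipping record at %d: %s", rec.pos, exc)
        if config.susceptible_list:
            known = effect_annotator.read_susceptible_changes(config.susceptible_list)
            annotations = effect_annotator.filter_novel(annotations, known)
        effect_annotator.write_annotations(
            annotations, outdir / "annotations.tsv", compat=config.table_compat
        )
        summary["stages"].append({"stage": "annotate", "n_annotations": len(annotations)})

        classes = resistance.classify_alleles(annotations)
        genotype_rows = []
        for name in sample_names:
            genotypes = {}
            for rec, ann in zip(kept, annotations):
                call = rec.samples.get(name)
                if call is None or not call.is_called:
                    continue
                n_alt = sum(a == 1 for a in call.gt)
                genotypes[effect_annotator.aa_key(ann.aa_change)] = (
                    "rr" if n_alt == 2 else "Sr" if n_alt == 1 else "SS"
                )
            if genotypes:
                pred = resistance.predict_phenotype(name, genotypes, classes)
                genotype_rows.append(
                    {
                        "sample_id": name,
                        "verdict": pred.verdict.value,
                        "alleles": ";".join(a for a, _g in pred.supporting_alleles),
                    }
                )
        pd.DataFrame(
            genotype_rows, columns=["sample_id", "verdict", "alleles"]
        ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        summary["stages"].append({"stage": "predict", "n_samples": len(genotype_rows)})

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
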