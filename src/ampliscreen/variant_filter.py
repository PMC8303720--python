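"""Post-calling filter cascade for a multi-sample amplicon VCF.

The cascade mirrors a standard targeted-resequencing cleanup: a sample-level
QC step retains only samples with an alignment mapping rate of at least 80%,
then variant records survive only if (1) site quality exceeds 40, (2) enough
samples support the call — total depth >= 8 with every called allele backed
by >= 2 reads, in at least 25% of samples — and (3) the cohort alternate
allele frequency is at least 5%.  A final selection keeps bi-allelic records
only (multi-allelic records are dropped, not decomposed).

The filter consumes VCF 4.2 with per-sample GT and AD produced by any
caller; calling itself (GATK/bcftools territory) is out of scope.
Comparator boundaries follow the printed rules exactly: QUAL strictly > 40,
all depth/AD/AF thresholds inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

__all__ = [
    "FilterConfig",
    "SampleCall",
    "VariantRecord",
    "FilterReport",
    "qc_samples",
    "filter_variants",
    "select_biallelic",
    "read_vcf",
    "write_vcf",
]


@dataclass(frozen=True)
class FilterConfig:
    qual_min: float = 40.0
    depth_min: int = 8
    allele_depth_min: int = 2
    alt_af_min: float = 0.05
    call_fraction_min: float = 0.25
    biallelic_only: bool = True
    mapping_rate_min: float = 0.80

    def __post_init__(self) -> None:
        if min(self.qual_min, self.depth_min, self.allele_depth_min) < 0:
            raise ValueError("thresholds must be non-negative")
        for frac in (self.alt_af_min, self.call_fraction_min, self.mapping_rate_min):
            if not 0 <= frac <= 1:
                raise ValueError("fractional thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class SampleCall:
    """Genotype (allele indices, None = missing) and per-allele depths."""

    gt: tuple[int | None, ...] | None
    ad: tuple[int, ...] | None

    @property
    def is_called(self) -> bool:
        return self.gt is not None and all(a is not None for a in self.gt)


@dataclass
class VariantRecord:
    """One VCF row: site fields plus per-sample calls, order-preserving."""

    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    samples: dict[str, SampleCall] = field(default_factory=dict)
    chrom: str = "gene"
    record_id: str = "."

    @property
    def is_indel(self) -> bool:
        return any(len(a) != len(self.ref) for a in self.alts)

    @property
    def is_snp(self) -> bool:
        return not self.is_indel


def qc_samples(
    mapping_rates: Mapping[str, float], min_rate: float = 0.80
) -> list[str]:
    """Retain samples whose mapping rate is ``min_rate`` or higher.

    Input order is preserved; the boundary is inclusive ("80% or higher").
    """
    for sample, rate in mapping_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"mapping rate for {sample} outside [0, 1]")
    return [s for s, rate in mapping_rates.items() if rate >= min_rate]


@dataclass
class FilterReport:
    """Per-stage attrition: input = survivors + sum of removals."""

    n_input: int = 0
    removed_malformed: int = 0
    removed_qual: int = 0
    removed_support: int = 0
    removed_af: int = 0
    n_survivors: int = 0
    flagged: list[tuple[int, str]] = field(default_factory=list)

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("input", self.n_input),
            ("removed_malformed", self.removed_malformed),
            ("removed_qual", self.removed_qual),
            ("removed_support", self.removed_support),
            ("removed_af", self.removed_af),
            ("survivors", self.n_survivors),
        ]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for stage, count in self.to_rows():
                fh.write(f"{stage}\t{count}\n")


def _sample_supports(call: SampleCall, cfg: FilterConfig) -> bool:
    if not call.is_called or call.ad is None:
        return False
    if sum(call.ad) < cfg.depth_min:
        return False
    for allele in set(call.gt):
        if allele >= len(call.ad) or call.ad[allele] < cfg.allele_depth_min:
            return False
    return True


def _alt_frequency(record: VariantRecord) -> float:
    """Max alternate allele frequency over called genotypes at the site."""
    counts = [0] * (len(record.alts) + 1)
    total = 0
    for call in record.samples.values():
        if call.is_called:
            for allele in call.gt:
                if allele < len(counts):
                    counts[allele] += 1
                total += 1
    if total == 0 or len(counts) < 2:
        return 0.0
    return max(counts[1:]) / total


def filter_variants(
    records: Sequence[VariantRecord],
    n_samples: int,
    cfg: FilterConfig | None = None,
) -> tuple[list[VariantRecord], FilterReport]:
    """Apply the quality / genotype-support / allele-frequency cascade.

    A record survives iff QUAL > ``qual_min``, at least
    ``ceil(call_fraction_min * n_samples)`` samples individually support it
    (depth and per-allele depth rules) and its alternate allele frequency
    across called samples is >= ``alt_af_min``.  Records missing allele-depth
    fields in every sample are flagged and excluded with a reason.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cfg = cfg or FilterConfig()
    min_support = math.ceil(cfg.call_fraction_min * n_samples)

    report = FilterReport(n_input=len(records))
    survivors: list[VariantRecord] = []
    for rec in records:
        if rec.samples and all(c.ad is None for c in rec.samples.values()):
            report.removed_malformed += 1
            report.flagged.append((rec.pos, "missing allele depths"))
            continue
        if rec.qual is None or not rec.qual > cfg.qual_min:
            report.removed_qual += 1
            continue
        n_support = sum(_sample_supports(c, cfg) for c in rec.samples.values())
        if n_support < min_support:
            report.removed_support += 1
            continue
        if _alt_frequency(rec) < cfg.alt_af_min:
            report.removed_af += 1
            continue
        survivors.append(rec)
    report.n_survivors = len(survivors)
    return survivors, report


def select_biallelic(
    records: Sequence[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep records with exactly one alternate allele; tally SNPs vs indels."""
    kept = [r for r in records if len(r.alts) == 1]
    tallies = {
        "n_biallelic": len(kept),
        "n_snp": sum(r.is_snp for r in kept),
        "n_indel": sum(r.is_indel for r in kept),
        "n_multiallelic_dropped": len(records) - len(kept),
    }
    return kept, tallies


# ---------------------------------------------------------------------------
# VCF I/O (pysam; uncompressed VCF 4.2 with GT and AD)
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a multi-sample VCF into :class:`VariantRecord` objects."""
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        for rec in vcf:
            samples: dict[str, SampleCall] = {}
            for name in sample_names:
                fmt = rec.samples[name]
                gt = fmt.get("GT")
                if gt is not None and all(a is None for a in gt):
                    gt = None
                ad = fmt.get("AD")
                samples[name] = SampleCall(
                    gt=tuple(gt) if gt is not None else None,
                    ad=tuple(int(x) for x in ad)
                    if ad is not None and not all(x is None for x in ad)
                    else None,
                )
            records.append(
                VariantRecord(
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=rec.qual,
                    samples=samples,
                    chrom=rec.chrom,
                    record_id=rec.id or ".",
                )
            )
    return records, sample_names


def write_vcf(
    records: Sequence[VariantRecord],
    sample_names: Sequence[str],
    path: str | Path,
    contig: str | None = None,
) -> None:
    """Write records to an uncompressed VCF 4.2 with GT and AD fields."""
    contigs = {contig} if contig else {r.chrom for r in records} or {"gene"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(contigs):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for rec in records:
            qual = "." if rec.qual is None else f"{rec.qual:g}"
            cols = [
                rec.chrom,
                str(rec.pos),
                rec.record_id,
                rec.ref,
                ",".join(rec.alts) or ".",
                qual,
                "PASS",
                ".",
                "GT:AD",
            ]
            for name in sample_names:
                call = rec.samples.get(name, SampleCall(gt=None, ad=None))
                if call.gt is None:
                    gt = "./."
                else:
                    gt = "/".join("." if a is None else str(a) for a in call.gt)
                ad = "." if call.ad is None else ",".join(map(str, call.ad))
                cols.append(f"{gt}:{ad}")
            fh.write("\t".join(cols) + "\n")
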