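"""Synthetic Hi-Plex style amplicon data for a diploid insect gene.

This module emulates the data a highly multiplexed tiled-amplicon assay
produces after read merging: for each sample, one FASTQ of full-length
amplicon copies drawn from the sample's two haplotypes with equal prior,
scaled by a per-tile amplification efficiency, with i.i.d. substitution
sequencing errors.  Amplicons tile the gene in 180-200 bp windows overlapping
by 50 bp, so any short genotyping motif is always fully contained in at least
one tile.

The cohort generator draws diploid genotypes at configurable variant sites
under Hardy-Weinberg proportions and emits a truth table for parameter
recovery tests downstream.  Defaults mirror the field study this toolkit
models: 41 moths split across three Puerto Rico trapping locations, a 2-bp GC
insertion allele segregating at frequency 0.33 and a frameshift deletion at
0.32, mean per-tile depth 200 and substitution error 1e-3.

Deliberately *not* modelled: paired-end structure (reads represent already
merged amplicons), in-read sample barcodes (one FASTQ per sample stands in
for demultiplexing), indel sequencing errors, primer thermodynamics and
quality-score error profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_model import GeneModel, build_gene_model

__all__ = [
    "AmpliconDesign",
    "VariantSite",
    "SampleSpec",
    "CohortSim",
    "design_tiles",
    "apply_edits",
    "simulate_sample_reads",
    "make_cohort_fixture",
    "default_gene_model",
    "default_sites",
    "write_fastq",
    "write_cohort",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Study-scale defaults: sample naming prefixes and per-location counts.
DEFAULT_LOCATIONS: tuple[tuple[str, str], ...] = (
    ("PRL", "Lajas"),
    ("PRS", "Salinas"),
    ("PRSI", "Santa Isabel"),
)
DEFAULT_LOCATION_WEIGHTS = (15, 12, 14)


@dataclass(frozen=True)
class AmpliconDesign:
    """Tiled amplicon layout over a gene region (1-based inclusive tiles)."""

    tiles: tuple[tuple[int, int], ...]
    amp_len_range: tuple[int, int]
    overlap: int


@dataclass(frozen=True)
class VariantSite:
    """A VCF-style anchored edit: ``ref`` at ``pos`` is replaced by ``alt``."""

    site_id: str
    pos: int
    ref: str
    alt: str

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)


@dataclass
class SampleSpec:
    """Diploid truth for one synthetic sample.

    ``haplotypes`` holds two edit lists (possibly empty) applied to the gene
    sequence; ``efficiencies`` one positive multiplier per design tile.
    """

    sample_id: str
    location: str
    haplotypes: tuple[tuple[VariantSite, ...], tuple[VariantSite, ...]]
    efficiencies: tuple[float, ...]
    seed: int

    def genotype(self, site_id: str) -> str:
        n = sum(
            any(v.site_id == site_id for v in hap) for hap in self.haplotypes
        )
        return {0: "SS", 1: "Sr", 2: "rr"}[n]


def design_tiles(
    region_length: int, amp_len: int = 180, overlap: int = 50
) -> AmpliconDesign:
    """Tile ``1..region_length`` with fixed-length overlapping amplicons.

    Tiles advance by ``amp_len - overlap``; the final tile is right-aligned
    to the region end so coverage is complete.  A region shorter than one
    amplicon yields a single full-region tile.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    if overlap >= amp_len:
        raise ValueError(f"overlap {overlap} must be smaller than amp_len {amp_len}")

    if region_length <= amp_len:
        tiles = [(1, region_length)]
    else:
        step = amp_len - overlap
        tiles = []
        start = 1
        while start + amp_len - 1 <= region_length:
            tiles.append((start, start + amp_len - 1))
            start += step
        if tiles[-1][1] < region_length:
            tail = (region_length - amp_len + 1, region_length)
            if tail != tiles[-1]:
                tiles.append(tail)
    lengths = [e - s + 1 for s, e in tiles]
    return AmpliconDesign(
        tiles=tuple(tiles),
        amp_len_range=(min(lengths), max(lengths)),
        overlap=overlap,
    )


def apply_edits(
    sequence: str, edits: Sequence[VariantSite]
) -> tuple[str, list[int | None]]:
    """Apply anchored edits to a sequence.

    Returns the haplotype sequence and ``posmap`` where ``posmap[p]`` is the
    0-based haplotype index of reference position ``p`` (1-based), or ``None``
    for deleted bases.  Edits must be non-overlapping and match the reference.
    """
    ordered = sorted(edits, key=lambda e: e.pos)
    out: list[str] = []
    posmap: list[int | None] = [None] * (len(sequence) + 1)
    cursor = 1
    for e in ordered:
        if e.pos < cursor:
            raise ValueError(f"overlapping edits at position {e.pos}")
        if e.pos + len(e.ref) - 1 > len(sequence):
            raise ValueError(f"edit at {e.pos} runs past the sequence end")
        if sequence[e.pos - 1 : e.pos - 1 + len(e.ref)] != e.ref:
            raise ValueError(
                f"edit ref {e.ref!r} does not match sequence at position {e.pos}"
            )
        for p in range(cursor, e.pos):
            posmap[p] = len(out)
            out.append(sequence[p - 1])
        posmap[e.pos] = len(out)
        out.extend(e.alt)
        cursor = e.pos + len(e.ref)
    for p in range(cursor, len(sequence) + 1):
        posmap[p] = len(out)
        out.append(sequence[p - 1])
    return "".join(out), posmap


def _tile_read(hap: str, posmap: list[int | None], start: int, end: int) -> str:
    """Extract the haplotype bases corresponding to reference tile [start, end].

    Insertions anchored inside the tile lengthen the read; deleted reference
    bases shorten it.
    """
    i = start
    while i <= end and posmap[i] is None:
        i += 1
    if i > end:
        return ""
    lo = posmap[i]
    nxt = end + 1
    while nxt < len(posmap) and posmap[nxt] is None:
        nxt += 1
    hi = posmap[nxt] if nxt < len(posmap) else len(hap)
    return hap[lo:hi]


def _add_errors(read: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0 or not read:
        return read
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < error_rate
    n = int(mask.sum())
    if n:
        # replace with one of the three other bases, uniformly
        originals = arr[mask]
        subs = _BASES[rng.integers(0, 4, size=n)]
        clash = subs == originals
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == originals
        arr[mask] = subs
    return arr.tobytes().decode()


def simulate_sample_reads(
    model: GeneModel,
    spec: SampleSpec,
    design: AmpliconDesign,
    mean_depth: float = 200.0,
    error_rate: float = 0.001,
    seed: int | None = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Simulate merged amplicon reads for one diploid sample.

    Per tile the read count is Poisson(mean_depth x efficiency); each read is
    drawn from one of the two haplotypes with equal probability and receives
    i.i.d. substitution errors at ``error_rate``.  Returns ``(reads, truth)``
    where reads are ``(read_id, sequence)`` pairs and truth maps each edited
    site to the sample's SS/Sr/rr genotype.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    if not (0 <= error_rate < 0.1):
        raise ValueError("error_rate must be in [0, 0.1)")
    if len(spec.efficiencies) != len(design.tiles):
        raise ValueError("one efficiency multiplier required per tile")
    if any(m <= 0 for m in spec.efficiencies):
        raise ValueError("efficiency multipliers must be positive")

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    haps = [apply_edits(model.sequence, hap) for hap in spec.haplotypes]

    reads: list[tuple[str, str]] = []
    for t, ((start, end), eff) in enumerate(zip(design.tiles, spec.efficiencies)):
        n_reads = int(rng.poisson(mean_depth * eff))
        hap_choice = rng.integers(0, 2, size=n_reads)
        for k in range(n_reads):
            hap_seq, posmap = haps[hap_choice[k]]
            read = _tile_read(hap_seq, posmap, start, end)
            read = _add_errors(read, error_rate, rng)
            reads.append((f"{spec.sample_id}|tile{t}|{k}", read))

    sites = {v.site_id for hap in spec.haplotypes for v in hap}
    truth = {site_id: spec.genotype(site_id) for site_id in sorted(sites)}
    return reads, truth


# ---------------------------------------------------------------------------
# Default synthetic gene and sites
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = sorted(
    set(map("".join, itertools.product("ACGT", repeat=3))) - {"TAA", "TAG", "TGA"}
)

# Wild-type genotyping context embedded codon-aligned into the synthetic CDS.
# 21 bp = 7 codons-worth, none of them stops; the insertion allele adds "GC"
# between the left and right 10-mers.
_SITE_CONTEXT = "CCAAGCACATCCCACTTGTAC"
_SITE_LEFT = "CCAAGCACAT"
_SITE_RIGHT = "CCCACTTGTA"
_SITE_INSERT = "GC"
_GENE_BUILD_SEED = 618  # fixed so the default gene is a stable reference


def default_gene_model(
    n_codons: int = 400, n_exons: int = 4, intron_len: int = 150
) -> GeneModel:
    """A deterministic synthetic receptor-like gene for simulations.

    The CDS (``n_codons`` codons incl. start and stop, no internal stops)
    embeds a fixed 21-bp genotyping context at its midpoint; exon/intron
    structure is regular.  The same arguments always return the same model.
    """
    rng = np.random.default_rng(_GENE_BUILD_SEED)
    body = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 2)
    ]
    cds = "ATG" + "".join(body) + "TAA"
    paste_at = 3 * (n_codons // 2)  # codon-aligned
    cds = cds[:paste_at] + _SITE_CONTEXT + cds[paste_at + len(_SITE_CONTEXT) :]

    # split the CDS across exons with intronic spacers
    exon_cds_len = len(cds) // n_exons
    bounds = [exon_cds_len * i for i in range(n_exons)] + [len(cds)]
    intron_alpha = np.array(list("ACGT"))
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    gpos = 0
    for i in range(n_exons):
        chunk = cds[bounds[i] : bounds[i + 1]]
        exons.append((gpos + 1, gpos + len(chunk)))
        pieces.append(chunk)
        gpos += len(chunk)
        if i < n_exons - 1:
            intron = "GT" + "".join(
                intron_alpha[rng.integers(0, 4, size=intron_len - 4)]
            ) + "AG"
            pieces.append(intron)
            gpos += intron_len
    return build_gene_model("synthgene", "".join(pieces), exons)


def default_sites(model: GeneModel | None = None) -> dict[str, VariantSite]:
    """The two canonical simulated alleles: a 2-bp GC insertion and a 1-bp
    frameshift deletion, both exonic in the default gene."""
    model = model or default_gene_model()
    idx = model.sequence.find(_SITE_LEFT + _SITE_RIGHT)
    if idx < 0:
        raise ValueError("genotyping context not present in gene sequence")
    anchor = idx + len(_SITE_LEFT)  # 1-based position of the last left-flank base
    ins = VariantSite(
        site_id="gc_ins",
        pos=anchor,
        ref=model.sequence[anchor - 1],
        alt=model.sequence[anchor - 1] + _SITE_INSERT,
    )
    # frameshift deletion two tiles away from the insertion site
    del_pos = max(10, anchor - 300)
    fs = VariantSite(
        site_id="fs_del",
        pos=del_pos,
        ref=model.sequence[del_pos - 1 : del_pos + 1],
        alt=model.sequence[del_pos - 1],
    )
    return {"gc_ins": ins, "fs_del": fs}


@dataclass
class CohortSim:
    """A simulated cohort: design, per-sample specs/reads and the truth table."""

    model: GeneModel
    design: AmpliconDesign
    specs: list[SampleSpec]
    reads: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame
    site_freqs: dict[str, float]


def _assign_locations(n_samples: int) -> list[tuple[str, str]]:
    weights = np.array(DEFAULT_LOCATION_WEIGHTS, dtype=float)
    counts = np.floor(weights / weights.sum() * n_samples).astype(int)
    # largest-remainder top-up
    rem = (weights / weights.sum() * n_samples) - counts
    for i in np.argsort(-rem)[: n_samples - counts.sum()]:
        counts[i] += 1
    out = []
    for (prefix, name), c in zip(DEFAULT_LOCATIONS, counts):
        out.extend([(prefix, name)] * int(c))
    return out[:n_samples]


def make_cohort_fixture(
    n_samples: int = 41,
    site_freqs: Mapping[str, float] | None = None,
    sites: Mapping[str, VariantSite] | None = None,
    model: GeneModel | None = None,
    mean_depth: float = 200.0,
    error_rate: float = 0.001,
    efficiency_sigma: float = 0.5,
    amp_len: int = 180,
    overlap: int = 50,
    seed: int = 0,
) -> CohortSim:
    """Simulate a field-cohort fixture end to end.

    Genotypes per site are drawn under Hardy-Weinberg proportions at the
    requested allele frequencies; per-tile efficiencies are lognormal
    (``sigma=efficiency_sigma``, normalised to mean 1) and shared across
    samples, reflecting reproducible primer efficiencies.  All randomness
    derives from ``seed``; per-sample seeds are recorded in the truth table.
    """
    model = model or default_gene_model()
    if sites is None:
        sites = default_sites(model)
    if site_freqs is None:
        site_freqs = {"gc_ins": 0.33, "fs_del": 0.32}
    unknown = set(site_freqs) - set(sites)
    if unknown:
        raise KeyError(f"frequencies given for unknown sites: {sorted(unknown)}")
    for sid, f in site_freqs.items():
        if not 0 <= f <= 1:
            raise ValueError(f"frequency for {sid} outside [0, 1]")

    design = design_tiles(model.length, amp_len=amp_len, overlap=overlap)
    rng = np.random.default_rng(seed)
    eff = np.exp(rng.normal(0.0, efficiency_sigma, size=len(design.tiles)))
    eff /= eff.mean()

    locations = _assign_locations(n_samples)
    loc_counter: dict[str, int] = {}

    specs: list[SampleSpec] = []
    reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[dict] = []
    for (prefix, loc_name) in locations:
        loc_counter[prefix] = loc_counter.get(prefix, 0) + 1
        sample_id = f"{prefix}_{loc_counter[prefix]}"
        hap_edits: tuple[list[VariantSite], list[VariantSite]] = ([], [])
        for sid in sorted(site_freqs):
            q = site_freqs[sid]
            u = rng.random()
            if u < (1 - q) ** 2:
                carried = 0
            elif u < (1 - q) ** 2 + 2 * q * (1 - q):
                carried = 1
            else:
                carried = 2
            if carried == 2:
                hap_edits[0].append(sites[sid])
                hap_edits[1].append(sites[sid])
            elif carried == 1:
                hap_edits[int(rng.integers(0, 2))].append(sites[sid])
        sample_seed = int(rng.integers(0, 2**31 - 1))
        spec = SampleSpec(
            sample_id=sample_id,
            location=loc_name,
            haplotypes=(tuple(hap_edits[0]), tuple(hap_edits[1])),
            efficiencies=tuple(float(x) for x in eff),
            seed=sample_seed,
        )
        specs.append(spec)
        sample_reads, _ = simulate_sample_reads(
            model, spec, design, mean_depth=mean_depth, error_rate=error_rate
        )
        reads[sample_id] = sample_reads
        for sid in sorted(site_freqs):
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "location": loc_name,
                    "site_id": sid,
                    "genotype": spec.genotype(sid),
                    "seed": sample_seed,
                }
            )

    truth = pd.DataFrame(truth_rows)
    return CohortSim(
        model=model,
        design=design,
        specs=specs,
        reads=reads,
        truth=truth,
        site_freqs=dict(site_freqs),
    )


# ---------------------------------------------------------------------------
# Writers (plain text: FASTQ Phred+33 with constant quality, TSV tables)
# ---------------------------------------------------------------------------


def write_fastq(
    reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_cohort(sim: CohortSim, outdir: str | Path) -> dict[str, Path]:
    """Write a cohort to disk: per-sample FASTQ, truth TSV and design TSV.

    The design TSV uses 1-based inclusive tile coordinates.
    """
    outdir = Path(outdir)
    fastq_dir = outdir / "fastq"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, reads in sim.reads.items():
        write_fastq(reads, fastq_dir / f"{sample_id}.fastq")
    truth_path = outdir / "truth.tsv"
    sim.truth.to_csv(truth_path, sep="\t", index=False)
    design_path = outdir / "design.tsv"
    with open(design_path, "w") as fh:
        fh.write("tile\tstart\tend\n")
        for i, (s, e) in enumerate(sim.design.tiles):
            fh.write(f"{i}\t{s}\t{e}\n")
    return {"fastq_dir": fastq_dir, "truth": truth_path, "design": design_path}
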