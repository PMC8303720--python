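"""k-mer flank-matching genotyper for a known insertion allele.

The method genotypes a known insertion (e.g. the 2-bp GC insertion that
truncates an ABC-transporter Cry1F receptor) directly from merged amplicon
reads, without alignment: a read is scanned for the two 10-mer sequences
flanking the insertion point.  Each flank tolerates up to two mismatches; the
inserted bases themselves must match exactly.  A read where the flanks occur
contiguously around the inserted bases supports the mutant allele (MUT); a
read where the flanks abut with nothing between supports wild type (WT); any
other read is uninformative.  Both orientations are scanned by default since
merged reads have arbitrary strand.

Calls follow fixed evidence thresholds: at least 40 informative reads for any
call, strictly more than 15% mutant-supporting reads for a carrier call, and
(symmetrically, a configurable choice) at least 85% for a homozygous-mutant
call.  "Coverage" here means informative reads (WT + MUT), the reads in which
both flanks were located.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "InsertionSite",
    "GenotypeCall",
    "ReadClass",
    "reverse_complement",
    "scan_read",
    "genotype_site",
    "genotype_cohort",
    "read_site_table",
    "write_site_table",
    "write_calls",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReadClass(enum.Enum):
    MUT = "MUT"
    WT = "WT"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass(frozen=True)
class InsertionSite:
    """A known insertion defined by its two flanking 10-mers.

    ``left_flank`` and ``right_flank`` are the reference sequences
    immediately 5' and 3' of the insertion point; ``inserted`` is the mutant
    insertion.  ``max_mismatch_per_flank`` is the Hamming budget granted to
    each flank (the inserted bases get none).
    """

    site_id: str
    left_flank: str
    inserted: str
    right_flank: str
    max_mismatch_per_flank: int = 2

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ValueError("flanks must be non-empty")
        if not self.inserted:
            raise ValueError("inserted sequence must be non-empty")
        if not (
            0
            <= self.max_mismatch_per_flank
            <= min(len(self.left_flank), len(self.right_flank))
        ):
            raise ValueError("mismatch budget outside [0, flank length]")


@dataclass(frozen=True)
class GenotypeCall:
    """Per-sample call at one insertion site with its read evidence."""

    sample_id: str
    site_id: str
    call: str  # SS | Sr | rr | NoCall
    n_wt: int
    n_mut: int

    @property
    def coverage(self) -> int:
        return self.n_wt + self.n_mut

    @property
    def proportion(self) -> float | None:
        """Mutant-supporting fraction of informative reads (None at 0 coverage)."""
        if self.coverage == 0:
            return None
        return self.n_mut / self.coverage


def _match_positions(arr: np.ndarray, pattern: np.ndarray, max_mm: int) -> np.ndarray:
    """Boolean mask over start offsets where ``pattern`` fits with <= max_mm
    mismatches (Hamming; any differing symbol, N included, is a mismatch)."""
    n, m = arr.size, pattern.size
    out = np.zeros(n, dtype=bool)
    if n >= m:
        windows = sliding_window_view(arr, m)
        out[: n - m + 1] = (windows != pattern).sum(axis=1) <= max_mm
    return out


def _scan_oriented(arr: np.ndarray, site: InsertionSite) -> ReadClass:
    left = np.frombuffer(site.left_flank.upper().encode(), dtype=np.uint8)
    right = np.frombuffer(site.right_flank.upper().encode(), dtype=np.uint8)
    ins = np.frombuffer(site.inserted.upper().encode(), dtype=np.uint8)
    mm = site.max_mismatch_per_flank

    left_hits = np.nonzero(_match_positions(arr, left, mm))[0]
    if left_hits.size == 0:
        return ReadClass.UNINFORMATIVE
    right_ok = _match_positions(arr, right, mm)
    ins_ok = _match_positions(arr, ins, 0)

    ll, li = left.size, ins.size
    mut_j = left_hits + ll
    mut = (
        (mut_j + li < arr.size)
        & ins_ok[np.minimum(mut_j, arr.size - 1)]
        & right_ok[np.minimum(mut_j + li, arr.size - 1)]
    )
    if mut.any():
        return ReadClass.MUT
    wt_j = np.minimum(left_hits + ll, arr.size - 1)
    if (((left_hits + ll) < arr.size) & right_ok[wt_j]).any():
        return ReadClass.WT
    return ReadClass.UNINFORMATIVE


def scan_read(read: str, site: InsertionSite, scan_revcomp: bool = True) -> ReadClass:
    """Classify one read as MUT, WT or UNINFORMATIVE for ``site``.

    Within an orientation a mutant match takes precedence over a wild-type
    match; the forward orientation is scanned first and the first informative
    orientation wins.
    """
    if not read:
        raise ValueError("empty read")
    seq = read.upper()
    orientations = (seq, reverse_complement(seq)) if scan_revcomp else (seq,)
    for oriented in orientations:
        arr = np.frombuffer(oriented.encode(), dtype=np.uint8)
        result = _scan_oriented(arr, site)
        if result is not ReadClass.UNINFORMATIVE:
            return result
    return ReadClass.UNINFORMATIVE


def genotype_site(
    reads: Iterable[str],
    site: InsertionSite,
    sample_id: str = "sample",
    min_coverage: int = 40,
    carrier_min_proportion: float = 0.15,
    hom_min_proportion: float = 0.85,
    scan_revcomp: bool = True,
) -> GenotypeCall:
    """Call SS/Sr/rr/NoCall from a read collection.

    Thresholds follow the published rule set: fewer than ``min_coverage``
    informative reads yields NoCall; a mutant proportion strictly above
    ``carrier_min_proportion`` is required for any mutant call ("more than
    15%"), and a proportion of at least ``hom_min_proportion`` upgrades the
    call to homozygous mutant.
    """
    if not 0 < carrier_min_proportion < hom_min_proportion <= 1:
        raise ValueError("thresholds must satisfy 0 < carrier_min < hom_min <= 1")
    n_wt = n_mut = 0
    for read in reads:
        if not read:
            continue
        result = scan_read(read, site, scan_revcomp=scan_revcomp)
        if result is ReadClass.MUT:
            n_mut += 1
        elif result is ReadClass.WT:
            n_wt += 1
    coverage = n_wt + n_mut
    if coverage < min_coverage:
        call = "NoCall"
    else:
        proportion = n_mut / coverage
        if proportion <= carrier_min_proportion:
            call = "SS"
        elif proportion >= hom_min_proportion:
            call = "rr"
        else:
            call = "Sr"
    return GenotypeCall(
        sample_id=sample_id, site_id=site.site_id, call=call, n_wt=n_wt, n_mut=n_mut
    )


def _reads_from_source(source) -> list[str]:
    if isinstance(source, (str, Path)):
        return [str(rec.seq) for rec in SeqIO.parse(str(source), "fastq")]
    return [seq for _id, seq in source] if source and isinstance(source[0], tuple) else list(source)


def genotype_cohort(
    samples: Mapping[str, object],
    site: InsertionSite,
    min_coverage: int = 40,
    carrier_min_proportion: float = 0.15,
    hom_min_proportion: float = 0.85,
    scan_revcomp: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Genotype every sample of a cohort at one insertion site.

    ``samples`` maps sample_id to a FASTQ path, a list of sequences or a list
    of ``(read_id, sequence)`` pairs.  Returns a cohort table (one row per
    sample: call, read counts, proportion, error flag) and summary counts.
    Samples whose FASTQ cannot be read are flagged and excluded from the
    summary rather than aborting the cohort.
    """
    if not samples:
        raise ValueError("cohort must contain at least one sample")
    rows = []
    for sample_id in samples:
        error = ""
        try:
            reads = _reads_from_source(samples[sample_id])
            call = genotype_site(
                reads,
                site,
                sample_id=sample_id,
                min_coverage=min_coverage,
                carrier_min_proportion=carrier_min_proportion,
                hom_min_proportion=hom_min_proportion,
                scan_revcomp=scan_revcomp,
            )
        except (OSError, ValueError) as exc:
            error = str(exc) or exc.__class__.__name__
            call = GenotypeCall(
                sample_id=sample_id, site_id=site.site_id, call="Error", n_wt=0, n_mut=0
            )
        rows.append(
            {
                "sample_id": sample_id,
                "site_id": site.site_id,
                "call": call.call,
                "n_wt": call.n_wt,
                "n_mut": call.n_mut,
                "coverage": call.coverage,
                "proportion": call.proportion if call.proportion is not None else float("nan"),
                "error": error,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""]
    summary = {
        f"n_{label}": int((ok["call"] == label).sum())
        for label in ("SS", "Sr", "rr", "NoCall")
    }
    summary["n_error"] = int((table["error"] != "").sum())
    return table, summary


# ---------------------------------------------------------------------------
# Site-table and call-table I/O (TSV)
# ---------------------------------------------------------------------------


def read_site_table(path: str | Path) -> list[InsertionSite]:
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            InsertionSite(
                site_id=row.site_id,
                left_flank=row.left_flank,
                inserted=row.inserted,
                right_flank=row.right_flank,
                max_mismatch_per_flank=int(getattr(row, "max_mm", 2)),
            )
        )
    return sites


def write_site_table(sites: Sequence[InsertionSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site_id\tleft_flank\tinserted\tright_flank\tmax_mm\n")
        for s in sites:
            fh.write(
                f"{s.site_id}\t{s.left_flank}\t{s.inserted}\t{s.right_flank}\t"
                f"{s.max_mismatch_per_flank}\n"
            )


def write_calls(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False, float_format="%.6g")
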