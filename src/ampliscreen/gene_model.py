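"""Single-gene coding models for targeted amplicon panels.

A :class:`GeneModel` couples a gene-local reference sequence (plus strand,
1-based inclusive coordinates) with an ordered list of exon intervals.  The
coding sequence (CDS) is the concatenation of the exon substrings; every gene
position maps to exactly one of *exonic* (with a unique CDS index), *intronic*
(with a distance to the nearest splice site) or *outside*.

The typical use here is an insect toxin-receptor gene — e.g. an ABC
transporter whose truncation confers resistance to a Bt Cry protein — whose
exon coordinates are supplied externally (GFF3 subset) rather than recomputed
by spliced alignment.  Models flagged ``partial`` may contain runs of ``N``
standing in for unsequenced regions (such as an inter-scaffold gap) and are
exempt from the complete-ORF checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "CodingCoordinate",
    "GeneStructureError",
    "GeneModelError",
    "TranslationWarning",
    "build_gene_model",
    "map_to_cds",
    "translate",
    "read_gene_fasta",
    "write_gene_fasta",
    "read_exon_intervals",
    "write_exon_gff",
    "load_gene_model",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = {
    **_STANDARD_TABLE.forward_table,
    **{codon: "*" for codon in _STANDARD_TABLE.stop_codons},
}
_DNA = frozenset("ACGTN")


class GeneStructureError(ValueError):
    """Exon intervals violate the structural invariants of a gene model."""


class GeneModelError(ValueError):
    """The assembled CDS is not a valid complete open reading frame."""


class TranslationWarning(UserWarning):
    """Non-fatal oddity during translation (e.g. a trailing partial codon)."""


def translate(cds: str) -> str:
    """Translate a coding DNA string with the standard genetic code.

    Codons containing ``N`` translate to ``X``; stop codons render ``*``.
    A trailing incomplete codon is ignored with a :class:`TranslationWarning`.

    Parameters
    ----------
    cds
        DNA text over ``{A,C,G,T,N}`` (case-insensitive), length >= 3.
    """
    if len(cds) < 3:
        raise ValueError(f"CDS shorter than one codon: {cds!r}")
    seq = cds.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA symbols in CDS: {sorted(bad)}")
    if len(seq) % 3:
        warnings.warn(
            "CDS length is not a multiple of 3; trailing bases ignored",
            TranslationWarning,
            stacklevel=2,
        )
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(aas)


@dataclass(frozen=True)
class CodingCoordinate:
    """Location of one gene position relative to the coding model.

    ``kind`` is ``"exonic"``, ``"intronic"`` or ``"outside"``.  Exonic
    positions carry a 1-based ``cds_index``, the ``codon_number`` =
    ceil(cds_index / 3) and a 1-based ``offset_in_codon``.  Intronic positions
    carry the count of intronic bases to the nearest splice site and which
    side (``"donor"`` = downstream of an exon end, ``"acceptor"`` = upstream
    of an exon start) that is.
    """

    kind: str
    cds_index: int | None = None
    codon_number: int | None = None
    offset_in_codon: int | None = None
    distance_to_splice_site: int | None = None
    splice_side: str | None = None


@dataclass
class GeneModel:
    """A gene-local reference sequence with an ordered exon structure."""

    gene_id: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    partial: bool = False

    @cached_property
    def cds(self) -> str:
        return "".join(self.sequence[s - 1 : e] for s, e in self.exons)

    @cached_property
    def protein(self) -> str:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", TranslationWarning)
            return translate(self.cds)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def codon(self, codon_number: int) -> str:
        """Reference codon ``codon_number`` (1-based) from the CDS."""
        start = 3 * (codon_number - 1)
        if codon_number < 1 or start >= len(self.cds):
            raise IndexError(f"codon {codon_number} outside CDS")
        return self.cds[start : start + 3]

    def map_to_cds(self, pos: int) -> CodingCoordinate:
        return map_to_cds(self, pos)


def build_gene_model(
    gene_id: str,
    sequence: str,
    exons: Iterable[Sequence[int]],
    partial: bool = False,
) -> GeneModel:
    """Validate and assemble a :class:`GeneModel`.

    Raises :class:`GeneStructureError` for malformed exon intervals and, for
    non-partial models, :class:`GeneModelError` when the CDS is not a complete
    ORF (length multiple of 3, starts ``ATG``, only the terminal stop).
    """
    if not sequence:
        raise GeneModelError("empty gene sequence")
    seq = sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise GeneModelError(f"non-DNA symbols in gene sequence: {sorted(bad)}")

    intervals = tuple((int(s), int(e)) for s, e in exons)
    if not intervals:
        raise GeneStructureError("gene model requires at least one exon")
    prev_end = 0
    for s, e in intervals:
        if s > e:
            raise GeneStructureError(f"inverted exon interval ({s}, {e})")
        if s < 1 or e > len(seq):
            raise GeneStructureError(f"exon ({s}, {e}) outside 1..{len(seq)}")
        if s <= prev_end:
            raise GeneStructureError(
                f"exon ({s}, {e}) overlaps or is unsorted after position {prev_end}"
            )
        prev_end = e

    model = GeneModel(gene_id=gene_id, sequence=seq, exons=intervals, partial=partial)

    if not partial:
        cds = model.cds
        if len(cds) % 3:
            raise GeneModelError(
                f"CDS length {len(cds)} is not a multiple of 3 for non-partial model"
            )
        if not cds.startswith("ATG"):
            raise GeneModelError("CDS of non-partial model must begin with ATG")
        protein = model.protein
        if "*" in protein[:-1]:
            raise GeneModelError("internal stop codon in non-partial model")
        if not protein.endswith("*"):
            raise GeneModelError("non-partial model lacks a terminal stop codon")
    return model


def map_to_cds(model: GeneModel, pos: int) -> CodingCoordinate:
    """Map a 1-based gene position onto the coding model.

    Positions beyond the sequence, before the first exon or after the last
    exon are ``outside``; positions between two exons are ``intronic``.
    """
    if pos < 1:
        raise ValueError(f"position {pos} below 1")
    first_start = model.exons[0][0]
    last_end = model.exons[-1][1]
    if pos > model.length or pos < first_start or pos > last_end:
        return CodingCoordinate(kind="outside")

    cum = 0
    for s, e in model.exons:
        if s <= pos <= e:
            cds_index = cum + (pos - s + 1)
            return CodingCoordinate(
                kind="exonic",
                cds_index=cds_index,
                codon_number=(cds_index + 2) // 3,
                offset_in_codon=(cds_index - 1) % 3 + 1,
            )
        cum += e - s + 1

    # intronic: locate the flanking exons
    donor_dist = acceptor_dist = None
    for (s1, e1), (s2, _e2) in zip(model.exons, model.exons[1:]):
        if e1 < pos < s2:
            donor_dist = pos - e1
            acceptor_dist = s2 - pos
            break
    assert donor_dist is not None and acceptor_dist is not None
    if donor_dist <= acceptor_dist:
        return CodingCoordinate(
            kind="intronic", distance_to_splice_site=donor_dist, splice_side="donor"
        )
    return CodingCoordinate(
        kind="intronic", distance_to_splice_site=acceptor_dist, splice_side="acceptor"
    )


# ---------------------------------------------------------------------------
# I/O: FASTA for the gene sequence, GFF3 subset for exon intervals
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def read_gene_fasta(path: str | Path) -> tuple[str, str]:
    """Return ``(record_id, sequence)`` for the first FASTA record."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_gene_fasta(model: GeneModel, path: str | Path) -> None:
    record = SeqRecord(Seq(model.sequence), id=model.gene_id, description="")
    SeqIO.write([record], str(path), "fasta")


def read_exon_intervals(
    path: str | Path, gene_id: str | None = None
) -> list[tuple[int, int]]:
    """Read ``exon`` features (1-based inclusive) from a GFF3-like file.

    When ``gene_id`` is given, the seqid column must match it; rows for other
    sequences raise, mirroring the single-gene scope of the panel.
    """
    df = pd.read_csv(
        str(path), sep="\t", comment="#", header=None, names=_GFF_COLUMNS, dtype=str
    )
    exons = df[df["type"] == "exon"]
    if gene_id is not None:
        foreign = set(exons["seqid"]) - {gene_id}
        if foreign:
            raise GeneStructureError(
                f"exon features for unexpected seqid(s) {sorted(foreign)}; "
                f"expected {gene_id!r}"
            )
    intervals = sorted(
        (int(row.start), int(row.end)) for row in exons.itertuples(index=False)
    )
    return intervals


def write_exon_gff(model: GeneModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, e) in enumerate(model.exons, start=1):
            fh.write(
                f"{model.gene_id}\tampliscreen\texon\t{s}\t{e}\t.\t+\t.\t"
                f"ID=exon{i};Parent={model.gene_id}\n"
            )


def load_gene_model(
    fasta_path: str | Path, gff_path: str | Path, partial: bool = False
) -> GeneModel:
    gene_id, sequence = read_gene_fasta(fasta_path)
    exons = read_exon_intervals(gff_path, gene_id=gene_id)
    return build_gene_model(gene_id, sequence, exons, partial=partial)
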