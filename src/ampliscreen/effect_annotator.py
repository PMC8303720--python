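"""Codon-level functional annotation of variants against a gene model.

Variants are classified as synonymous (SYN), missense (MISS), nonsense
(NON), frameshift (SHIFT), in-frame indel (INFRAME), intronic (INTRONIC,
with a splice-region flag near exon junctions) or non-coding (NONCODING).
Nonsense and frameshift changes are flagged *truncating*: for a toxin
receptor gene they predict a shortened, non-functional protein and hence a
candidate resistance allele.

Amino-acid change notation follows the compact published convention:
substitutions are ``refAA`` + codon number + ``altAA`` (a stop rendered
``" *"``); insertions append the translation of the altered codons — one per
started codon of inserted sequence — with ``" *"`` when the insertion shifts
the reading frame (a premature stop is expected downstream but its position
is not encoded); in-frame deletions list the deleted residues with no
alternate.  Codon display keeps context lowercase and the changed or
inserted bases uppercase (e.g. ``gat/gCGat`` for a 2-bp insertion).

Because the published mutation table labels in-frame deletions as SHIFT, a
*table-compat* reporting mode maps {SHIFT, INFRAME} onto SHIFT so published
tallies reproduce while the annotator itself stays strict.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from .gene_model import GeneModel, translate

__all__ = [
    "EffectClass",
    "EffectAnnotation",
    "SpliceWindow",
    "ReferenceMismatchError",
    "classify_codon_change",
    "format_aa_change",
    "annotate_variant",
    "filter_novel",
    "table_compat_class",
    "aa_key",
    "read_susceptible_changes",
    "write_annotations",
]


class EffectClass(enum.Enum):
    SYN = "SYN"
    MISS = "MISS"
    NON = "NON"
    SHIFT = "SHIFT"
    INFRAME = "INFRAME"
    SPLICE_REGION = "SPLICE_REGION"
    INTRONIC = "INTRONIC"
    NONCODING = "NONCODING"


TRUNCATING_CLASSES = frozenset({EffectClass.NON, EffectClass.SHIFT})


class ReferenceMismatchError(ValueError):
    """Variant REF allele does not match the gene sequence at its position."""


@dataclass(frozen=True)
class SpliceWindow:
    """Bases around an internal exon junction flagged as splice region.

    ``intronic`` bases of intron adjacent to the junction (the first two of
    which are the canonical donor/acceptor dinucleotide) and ``exonic`` bases
    of exon adjacent to the junction.
    """

    exonic: int = 3
    intronic: int = 8


@dataclass(frozen=True)
class EffectAnnotation:
    pos: int
    ref: str
    alt: str
    effect_class: EffectClass
    aa_change: str
    codon_display: str
    truncating: bool
    splice_region: bool = False
    novel: bool = True

    @property
    def compat_class(self) -> str:
        return table_compat_class(self.effect_class)


def table_compat_class(effect_class: EffectClass) -> str:
    """Published-table vocabulary: in-frame indels are reported as SHIFT."""
    if effect_class is EffectClass.INFRAME:
        return EffectClass.SHIFT.value
    return effect_class.value


def aa_key(aa_change: str) -> str:
    """Canonical allele key: the Aa-change string minus any stop marker."""
    return aa_change.replace(" *", "").replace("*", "").strip()


def _inserted_run(ref_codons: str, alt_codons: str) -> tuple[str, str]:
    """Return (prefix, inserted) from a codon-display style alt string.

    The inserted bases are the maximal uppercase run; if the display carries
    no case information the insertion is inferred by stripping the common
    prefix/suffix shared with the reference.
    """
    m = re.search(r"[A-Z]+", alt_codons)
    if m and len(alt_codons) - (m.end() - m.start()) <= len(ref_codons):
        return alt_codons[: m.start()], m.group(0)
    ref_u, alt_u = ref_codons.upper(), alt_codons.upper()
    i = 0
    while i < len(ref_u) and i < len(alt_u) and ref_u[i] == alt_u[i]:
        i += 1
    j = 0
    while (
        j < len(ref_u) - i
        and j < len(alt_u) - i
        and ref_u[len(ref_u) - 1 - j] == alt_u[len(alt_u) - 1 - j]
    ):
        j += 1
    return alt_codons[:i], alt_codons[i : len(alt_codons) - j]


def classify_codon_change(ref_codons: str, alt_codons: str) -> EffectClass:
    """Classify a codon-context change (display-style strings accepted)."""
    ref, alt = ref_codons.strip(), alt_codons.strip()
    if not ref:
        raise ValueError("reference codons must be non-empty")
    if not alt:
        return EffectClass.SHIFT if len(ref) % 3 else EffectClass.INFRAME
    if len(ref) == len(alt):
        ref_aa = translate(ref)
        alt_aa = translate(alt)
        if ref_aa == alt_aa:
            return EffectClass.SYN
        if "*" in alt_aa and "*" not in ref_aa:
            return EffectClass.NON
        return EffectClass.MISS
    if len(alt) > len(ref):
        _prefix, inserted = _inserted_run(ref, alt)
        return EffectClass.SHIFT if len(inserted) % 3 else EffectClass.INFRAME
    diff = len(ref) - len(alt)
    return EffectClass.SHIFT if diff % 3 else EffectClass.INFRAME


def format_aa_change(ref_codons: str, alt_codons: str, codon_number: int) -> str:
    """Render the amino-acid change notation for a codon-context change."""
    ref, alt = ref_codons.strip(), alt_codons.strip()
    ref_aa = translate(ref) if len(ref) >= 3 else ""

    if not alt:  # deletion
        star = " *" if len(ref) % 3 else ""
        return f"{ref_aa}{codon_number}{star}"

    if len(alt) == len(ref):  # substitution
        alt_aa = translate(alt)
        if alt_aa.endswith("*"):
            return f"{ref_aa.rstrip('*')}{codon_number} *"
        return f"{ref_aa}{codon_number}{alt_aa}"

    if len(alt) > len(ref):  # insertion
        prefix, inserted = _inserted_run(ref, alt)
        full = prefix + inserted + ref[len(prefix):]
        n_codons = -(-len(inserted) // 3)  # ceil: one AA per started codon
        shown = translate(full[: 3 * n_codons]) if 3 * n_codons >= 3 else ""
        star = " *" if len(inserted) % 3 else ""
        return f"{ref_aa}{codon_number}{shown}{star}"

    # partial deletion / delins
    diff = len(ref) - len(alt)
    alt_aa = translate(alt) if len(alt) >= 3 else ""
    star = " *" if diff % 3 else ""
    return f"{ref_aa}{codon_number}{alt_aa}{star}"


def _variant_fields(variant) -> tuple[int, str, str]:
    pos = int(variant.pos)
    ref = variant.ref.upper()
    alt = getattr(variant, "alt", None)
    if alt is None:
        alts = variant.alts
        if len(alts) != 1:
            raise ValueError("annotate_variant expects a bi-allelic variant")
        alt = alts[0]
    return pos, ref, alt.upper()


def _splice_flag(
    model: GeneModel, positions: Iterable[int], window: SpliceWindow
) -> bool:
    junctions = []
    for (s1, e1), (s2, _e2) in zip(model.exons, model.exons[1:]):
        junctions.append(("donor", e1))  # intron is e1+1 ..
        junctions.append(("acceptor", s2))  # intron is .. s2-1
    for pos in positions:
        for side, edge in junctions:
            if side == "donor":
                if edge - window.exonic + 1 <= pos <= edge + window.intronic:
                    return True
            else:
                if edge - window.intronic <= pos <= edge + window.exonic - 1:
                    return True
    return False


def _case_display(codons: str, changed: set[int]) -> str:
    """Lowercase context with positions (0-based within codons) uppercased."""
    return "".join(
        c.upper() if i in changed else c.lower() for i, c in enumerate(codons)
    )


def annotate_variant(
    model: GeneModel,
    variant,
    splice_window: SpliceWindow = SpliceWindow(),
) -> EffectAnnotation:
    """Annotate one bi-allelic variant against the gene model.

    ``variant`` needs ``pos``, ``ref`` and ``alt`` (or a single-entry
    ``alts``) attributes; coordinates are gene-local 1-based.  Codons
    containing ``N`` (unsequenced reference) are left unclassified as
    NONCODING rather than guessed.
    """
    pos, ref, alt = _variant_fields(variant)
    if model.sequence[pos - 1 : pos - 1 + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"REF {ref!r} does not match gene sequence at position {pos}"
        )

    if len(ref) == len(alt):
        return _annotate_substitution(model, pos, ref, alt, splice_window)
    if len(alt) > len(ref) and len(ref) == 1 and alt[0] == ref:
        return _annotate_insertion(model, pos, alt[1:], ref, alt, splice_window)
    if len(ref) > len(alt) and len(alt) == 1 and ref[0] == alt:
        return _annotate_deletion(model, pos, ref, alt, splice_window)
    raise ValueError(
        f"unsupported complex variant at {pos}: {ref}>{alt} "
        "(only substitutions and simple anchored indels are annotated)"
    )


def _intronic_annotation(model, pos, ref, alt, positions, window) -> EffectAnnotation:
    return EffectAnnotation(
        pos=pos,
        ref=ref,
        alt=alt,
        effect_class=EffectClass.INTRONIC,
        aa_change="",
        codon_display="",
        truncating=False,
        splice_region=_splice_flag(model, positions, window),
    )


def _annotate_substitution(model, pos, ref, alt, window) -> EffectAnnotation:
    coords = [model.map_to_cds(p) for p in range(pos, pos + len(ref))]
    kinds = {c.kind for c in coords}
    if kinds == {"outside"}:
        return EffectAnnotation(pos, ref, alt, EffectClass.NONCODING, "", "", False)
    if "exonic" not in kinds:
        return _intronic_annotation(
            model, pos, ref, alt, range(pos, pos + len(ref)), window
        )
    if kinds != {"exonic"}:
        # change straddles a splice junction
        return EffectAnnotation(
            pos, ref, alt, EffectClass.SPLICE_REGION, "", "", False, splice_region=True
        )
    c1, c2 = coords[0], coords[-1]
    n1, n2 = c1.codon_number, c2.codon_number
    ref_codons = "".join(model.codon(n) for n in range(n1, n2 + 1))
    offset0 = c1.offset_in_codon - 1
    alt_codons = ref_codons[:offset0] + alt + ref_codons[offset0 + len(alt):]
    changed = {offset0 + i for i in range(len(ref)) if ref[i] != alt_codons[offset0 + i]}
    ref_disp = _case_display(ref_codons, changed)
    alt_disp = _case_display(alt_codons, changed)
    effect = classify_codon_change(ref_disp, alt_disp)
    aa = "" if "N" in ref_codons or "N" in alt_codons else format_aa_change(
        ref_disp, alt_disp, n1
    )
    if "N" in ref_codons or "N" in alt_codons:
        effect = EffectClass.NONCODING
    return EffectAnnotation(
        pos=pos,
        ref=ref,
        alt=alt,
        effect_class=effect,
        aa_change=aa if effect is not EffectClass.SYN else aa,
        codon_display=f"{ref_disp}/{alt_disp}",
        truncating=effect in TRUNCATING_CLASSES,
        splice_region=_splice_flag(model, range(pos, pos + len(ref)), window),
    )


def _annotate_insertion(model, pos, inserted, ref, alt, window) -> EffectAnnotation:
    coord = model.map_to_cds(pos)
    if coord.kind == "outside":
        return EffectAnnotation(pos, ref, alt, EffectClass.NONCODING, "", "", False)
    if coord.kind == "intronic":
        return _intronic_annotation(model, pos, ref, alt, [pos], window)
    offset = coord.offset_in_codon
    if offset == 3:
        codon_number = coord.codon_number + 1
        try:
            context = model.codon(codon_number)
        except IndexError:  # insertion after the final codon
            context = ""
        ref_disp = context.lower()
        alt_disp = inserted.upper() + context.lower()
    else:
        codon_number = coord.codon_number
        context = model.codon(codon_number)
        ref_disp = context.lower()
        alt_disp = (
            context[:offset].lower() + inserted.upper() + context[offset:].lower()
        )
    if "N" in context.upper() + inserted.upper():
        return EffectAnnotation(
            pos, ref, alt, EffectClass.NONCODING, "", f"{ref_disp}/{alt_disp}", False
        )
    effect = classify_codon_change(ref_disp, alt_disp)
    aa = format_aa_change(ref_disp, alt_disp, codon_number)
    return EffectAnnotation(
        pos=pos,
        ref=ref,
        alt=alt,
        effect_class=effect,
        aa_change=aa,
        codon_display=f"{ref_disp}/{alt_disp}",
        truncating=effect in TRUNCATING_CLASSES,
        splice_region=_splice_flag(model, [pos, pos + 1], window),
    )


def _annotate_deletion(model, pos, ref, alt, window) -> EffectAnnotation:
    deleted_positions = list(range(pos + 1, pos + len(ref)))
    coords = [model.map_to_cds(p) for p in deleted_positions]
    kinds = {c.kind for c in coords}
    if kinds == {"outside"}:
        return EffectAnnotation(pos, ref, alt, EffectClass.NONCODING, "", "", False)
    if "exonic" not in kinds:
        return _intronic_annotation(model, pos, ref, alt, deleted_positions, window)
    if kinds != {"exonic"}:
        return EffectAnnotation(
            pos, ref, alt, EffectClass.SPLICE_REGION, "", "", False, splice_region=True
        )
    cds_indices = [c.cds_index for c in coords]
    n1 = coords[0].codon_number
    n2 = coords[-1].codon_number
    ref_codons = "".join(model.codon(n) for n in range(n1, n2 + 1))
    base = 3 * (n1 - 1)
    deleted_rel = {i - base - 1 for i in cds_indices}
    alt_codons = "".join(
        c for i, c in enumerate(ref_codons) if i not in deleted_rel
    )
    ref_disp = ref_codons.lower()
    alt_disp = alt_codons.lower()
    if "N" in ref_codons:
        return EffectAnnotation(
            pos, ref, alt, EffectClass.NONCODING, "", f"{ref_disp}/{alt_disp}", False
        )
    effect = classify_codon_change(ref_disp, alt_disp)
    aa = format_aa_change(ref_disp, alt_disp, n1)
    return EffectAnnotation(
        pos=pos,
        ref=ref,
        alt=alt,
        effect_class=effect,
        aa_change=aa,
        codon_display=f"{ref_disp}/{alt_disp}",
        truncating=effect in TRUNCATING_CLASSES,
        splice_region=_splice_flag(model, deleted_positions, window),
    )


def filter_novel(
    annotations: Sequence[EffectAnnotation], susceptible_changes: Iterable[str]
) -> list[EffectAnnotation]:
    """Flag annotations already seen in susceptible-reference cDNAs.

    Nothing is deleted: ``novel`` is set False for changes whose allele key
    appears in ``susceptible_changes`` and downstream summaries select on it.
    """
    known = {aa_key(c) for c in susceptible_changes}
    return [
        replace(ann, novel=aa_key(ann.aa_change) not in known)
        for ann in annotations
    ]


def read_susceptible_changes(path: str | Path) -> set[str]:
    """One allele key per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(aa_key(line))
    return out


def write_annotations(
    annotations: Sequence[EffectAnnotation], path: str | Path, compat: bool = True
) -> None:
    with open(path, "w") as fh:
        fh.write("position\tclass\tmutation\taa_change\ttruncating\tsplice_region\tnovel\n")
        for ann in annotations:
            cls = ann.compat_class if compat else ann.effect_class.value
            fh.write(
                f"{ann.pos}\t{cls}\t{ann.codon_display}\t{ann.aa_change}\t"
                f"{int(ann.truncating)}\t{int(ann.splice_region)}\t{int(ann.novel)}\n"
            )
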