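"""Resistance phenotype prediction from receptor-truncating alleles.

The biological rule: a Cry1F-resistant phenotype is expected when an
individual retains no intact copy of the receptor gene.  Nonsense and
frameshift alleles truncate the protein, so a sample homozygous for any
truncating allele is predicted resistant; a sample heterozygous for two
*different* truncating alleles may be resistant by complementation (the two
defects could sit in trans, leaving no intact allele) but short reads cannot
phase them, so such samples are reported as candidates only.  Missense
alleles are surfaced as candidates for functional testing but never drive a
resistance verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .effect_annotator import (
    EffectAnnotation,
    EffectClass,
    aa_key,
    table_compat_class,
)

__all__ = [
    "AlleleCategory",
    "PhenotypeVerdict",
    "PhenotypePrediction",
    "classify_alleles",
    "predict_phenotype",
    "summarize_candidates",
]


class AlleleCategory(enum.Enum):
    TRUNCATING = "TRUNCATING"
    MISSENSE_CANDIDATE = "MISSENSE_CANDIDATE"
    NON_CANDIDATE = "NON_CANDIDATE"


class PhenotypeVerdict(enum.Enum):
    PREDICTED_RESISTANT_HOM = "PREDICTED_RESISTANT_HOM"
    CANDIDATE_RESISTANT_COMPLEMENTATION = "CANDIDATE_RESISTANT_COMPLEMENTATION"
    CARRIER = "CARRIER"
    NO_TRUNCATING_ALLELE = "NO_TRUNCATING_ALLELE"


@dataclass(frozen=True)
class PhenotypePrediction:
    sample_id: str
    verdict: PhenotypeVerdict
    supporting_alleles: tuple[tuple[str, str], ...]  # (allele, genotype)


def _category_of(annotation) -> AlleleCategory:
    cls = annotation.effect_class if isinstance(annotation, EffectAnnotation) else annotation
    if isinstance(cls, str):
        cls = EffectClass(cls)
    if cls in (EffectClass.NON, EffectClass.SHIFT):
        return AlleleCategory.TRUNCATING
    if cls is EffectClass.MISS:
        return AlleleCategory.MISSENSE_CANDIDATE
    return AlleleCategory.NON_CANDIDATE


def classify_alleles(
    annotations: Iterable[EffectAnnotation],
) -> dict[str, AlleleCategory]:
    """Map allele keys (Aa-change minus stop marker) to candidacy classes."""
    return {aa_key(a.aa_change): _category_of(a) for a in annotations}


def predict_phenotype(
    sample_id: str,
    genotypes: Mapping[str, str],
    classes: Mapping[str, AlleleCategory],
) -> PhenotypePrediction:
    """Predict a sample's Cry1F phenotype from per-allele genotypes.

    Verdicts are evaluated in priority order: homozygous truncating, then
    trans-heterozygous candidate (>= 2 distinct heterozygous truncating
    alleles, none homozygous), then carrier, then none.  ``genotypes`` maps
    allele key to SS/Sr/rr (NoCall tolerated, ignored).
    """
    if not genotypes:
        raise ValueError("genotype map must be non-empty")
    unknown = set(genotypes) - set(classes)
    if unknown:
        raise KeyError(f"genotypes for unclassified allele(s): {sorted(unknown)}")

    hom = []
    het = []
    for allele, call in genotypes.items():
        if classes[allele] is not AlleleCategory.TRUNCATING:
            continue
        if call == "rr":
            hom.append(allele)
        elif call == "Sr":
            het.append(allele)

    if hom:
        support = tuple((a, "rr") for a in sorted(hom))
        verdict = PhenotypeVerdict.PREDICTED_RESISTANT_HOM
    elif len(het) >= 2:
        support = tuple((a, "Sr") for a in sorted(het))
        verdict = PhenotypeVerdict.CANDIDATE_RESISTANT_COMPLEMENTATION
    elif het:
        support = ((het[0], "Sr"),)
        verdict = PhenotypeVerdict.CARRIER
    else:
        support = ()
        verdict = PhenotypeVerdict.NO_TRUNCATING_ALLELE
    return PhenotypePrediction(
        sample_id=sample_id, verdict=verdict, supporting_alleles=support
    )


def _normalize_annotations(annotations) -> pd.DataFrame:
    """Accept a list of EffectAnnotation or a table with class/aa_change."""
    if isinstance(annotations, pd.DataFrame):
        df = annotations.copy()
        if "class" not in df.columns and "effect_class" in df.columns:
            df = df.rename(columns={"effect_class": "class"})
        if "novel" not in df.columns:
            df["novel"] = True
        return df[["class", "aa_change", "novel"]]
    rows = [
        {"class": a.compat_class, "aa_change": a.aa_change, "novel": a.novel}
        for a in annotations
    ]
    return pd.DataFrame(rows, columns=["class", "aa_change", "novel"])


def summarize_candidates(
    annotations,
    genotype_table: pd.DataFrame | None = None,
    known_alleles: Iterable[str] = (),
) -> dict[str, int]:
    """Tally candidate resistance alleles, table-compat class vocabulary.

    ``annotations`` is a list of :class:`EffectAnnotation` or a DataFrame
    with ``class`` and ``aa_change`` columns (classes already in the
    published MISS/NON/SHIFT vocabulary).  ``known_alleles`` (allele keys)
    are excluded from the frameshift count, matching how a previously
    characterised allele is reported apart from the novel candidates.
    ``genotype_table`` (samples x allele-key columns, values SS/Sr/rr) adds
    carrier tallies over truncating alleles.
    """
    df = _normalize_annotations(annotations)
    known = {aa_key(k) for k in known_alleles}
    keys = df["aa_change"].map(aa_key)

    n_missense = int((df["class"] == "MISS").sum())
    n_nonsense = int((df["class"] == "NON").sum())
    shift_mask = df["class"] == "SHIFT"
    n_frameshift_excl_known = int((shift_mask & ~keys.isin(known)).sum())

    tallies = {
        "n_missense": n_missense,
        "n_nonsense": n_nonsense,
        "n_nonsynonymous": n_missense + n_nonsense,
        "n_frameshift_excl_known": n_frameshift_excl_known,
        "n_carriers_any_truncating": 0,
        "n_hom_truncating": 0,
    }

    if genotype_table is not None and len(genotype_table):
        truncating_keys = set(keys[shift_mask | (df["class"] == "NON")])
        cols = [c for c in genotype_table.columns if aa_key(c) in truncating_keys]
        if cols:
            sub = genotype_table[cols]
            any_carrier = sub.isin(["Sr", "rr"]).any(axis=1)
            any_hom = (sub == "rr").any(axis=1)
            tallies["n_carriers_any_truncating"] = int(any_carrier.sum())
            tallies["n_hom_truncating"] = int(any_hom.sum())
    return tallies
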