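"""Cohort statistics for a resistance-allele screen.

Covers the descriptive statistics such a screen reports: allele frequency
from genotype counts (in two estimator variants, see below), per-location
carrier summaries, concordance between two genotyping methods, a genotype
PCA, and a per-site case/control association scan.

Allele-frequency modes
----------------------
Given ObsAA/ObsAa/Obsaa genotype counts for a bi-allelic locus, the standard
estimator of the "a" allele frequency is ``(2*Obsaa + ObsAa) / (2*N)``.  The
screen this toolkit reproduces typeset the formula with the factor of two on
the heterozygote count, ``(2*ObsAa + Obsaa) / (2*N)``, and some of its
printed frequencies reproduce only under that typeset form while others
reproduce only under the standard estimator.  Both are therefore first-class
(``mode="standard"`` is the default; ``mode="printed"`` is the typeset
variant), and frequencies are returned at full precision — display rounding
or truncation is the formatter's job (:func:`format_frequency`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "allele_frequency",
    "format_frequency",
    "display_percent",
    "ConcordanceResult",
    "concordance",
    "concordance_from_table",
    "carrier_summary",
    "genotype_pca",
    "association_scan",
    "DegenerateInputError",
    "CALL_CODES",
]

CALL_CODES = {"SS": 0, "Sr": 1, "rr": 2}


class DegenerateInputError(ValueError):
    """Input carries no usable variation (e.g. a zero-variance matrix)."""


def allele_frequency(
    n_het: int, n_hom: int, n_total: int, mode: str = "standard"
) -> float:
    """Frequency of the minor ("r") allele from genotype counts.

    ``n_het`` heterozygous and ``n_hom`` homozygous-mutant individuals out of
    ``n_total`` genotyped.  ``mode="standard"`` computes
    ``(2*n_hom + n_het) / (2*n_total)``; ``mode="printed"`` computes the
    typeset variant ``(2*n_het + n_hom) / (2*n_total)``.  The two coincide
    when ``n_het == n_hom``.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if n_het < 0 or n_hom < 0 or n_het + n_hom > n_total:
        raise ValueError("genotype counts inconsistent with the total")
    if mode == "standard":
        return (2 * n_hom + n_het) / (2 * n_total)
    if mode == "printed":
        return (2 * n_het + n_hom) / (2 * n_total)
    raise ValueError(f"unknown mode {mode!r} (expected 'standard' or 'printed')")


def format_frequency(value: float, decimals: int = 4, mode: str = "round") -> float:
    """Display-round a frequency; ``mode`` is ``"round"`` or ``"truncate"``.

    Both conventions occur in print; operations return full precision and
    reports pin the convention explicitly.
    """
    if mode == "round":
        return round(value, decimals)
    if mode == "truncate":
        scale = 10**decimals
        return math.floor(value * scale) / scale
    raise ValueError(f"unknown rounding mode {mode!r}")


def display_percent(fraction: float) -> int:
    """Whole-number percent, round-half-away-from-zero."""
    return int(math.floor(fraction * 100 + 0.5))


@dataclass(frozen=True)
class ConcordanceResult:
    n_concordant: int
    n_total: int
    discrepancies: tuple[tuple[str, str, str], ...]  # (sample, call_a, call_b)

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_total if self.n_total else float("nan")


def concordance(
    calls_a: Sequence[str],
    calls_b: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> ConcordanceResult:
    """Agreement between two aligned call lists (symmetric in its arguments)."""
    if len(calls_a) != len(calls_b):
        raise ValueError("call lists must be aligned (equal length)")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(calls_a))]
    elif len(sample_ids) != len(calls_a):
        raise ValueError("sample_ids misaligned with call lists")
    disc = tuple(
        (s, a, b)
        for s, a, b in zip(sample_ids, calls_a, calls_b)
        if a != b
    )
    return ConcordanceResult(
        n_concordant=len(calls_a) - len(disc),
        n_total=len(calls_a),
        discrepancies=disc,
    )


def concordance_from_table(
    table: pd.DataFrame, method_a: str, method_b: str
) -> ConcordanceResult:
    """Concordance between two method columns of a cohort table.

    ``table`` is long format (sample_id, method, call); rows are aligned on
    sample_id and every sample must appear under both methods.
    """
    wide = table.pivot(index="sample_id", columns="method", values="call")
    for m in (method_a, method_b):
        if m not in wide.columns or wide[m].isna().any():
            raise ValueError(f"method {m!r} missing calls for some samples")
    return concordance(
        list(wide[method_a]), list(wide[method_b]), sample_ids=list(wide.index)
    )


def carrier_summary(table: pd.DataFrame, method: str) -> pd.DataFrame:
    """Per-location carrier/homozygote/heterozygote summary for one method.

    Returns one row per location with raw fractions (``frac_*``) and
    whole-percent display values (``pct_*``).  Carriers are Sr + rr;
    denominators are all of that location's samples under ``method``.
    """
    if table.empty:
        raise ValueError("cohort table is empty")
    sub = table[table["method"] == method]
    if sub.empty:
        raise KeyError(f"no calls for method {method!r}")
    rows = []
    for location, grp in sub.groupby("location", sort=True):
        n = len(grp)
        n_hom = int((grp["call"] == "rr").sum())
        n_het = int((grp["call"] == "Sr").sum())
        frac_hom, frac_het = n_hom / n, n_het / n
        frac_carriers = frac_hom + frac_het
        rows.append(
            {
                "location": location,
                "n": n,
                "n_hom": n_hom,
                "n_het": n_het,
                "frac_carriers": frac_carriers,
                "frac_hom": frac_hom,
                "frac_het": frac_het,
                "pct_carriers": display_percent(frac_carriers),
                "pct_hom": display_percent(frac_hom),
                "pct_het": display_percent(frac_het),
            }
        )
    return pd.DataFrame(rows).set_index("location")


def genotype_pca(
    genotypes: np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of a samples x sites genotype matrix coded 0/1/2, NaN = missing.

    Missing entries are mean-imputed per site, columns are mean-centred and a
    singular value decomposition supplies the projections.  Component signs
    are fixed by making each component's largest-magnitude loading positive,
    so results are deterministic.  Returns ``(projections, explained)`` where
    ``explained`` are non-increasing explained-variance fractions.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need a 2-D matrix with >= 2 samples and >= 1 site")
    col_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    filled = np.where(np.isnan(X), col_means[None, :], X)
    centred = filled - filled.mean(axis=0)
    total_var = (centred**2).sum()
    if total_var == 0:
        raise DegenerateInputError("genotype matrix has zero variance")
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    # deterministic sign convention
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    k = n_components or min(10, len(S))
    projections = U[:, :k] * S[:k]
    explained = (S[:k] ** 2) / total_var
    return projections, explained


def association_scan(
    genotypes: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-site allele-count association with a binary label.

    For each site a 2x2 table of (reference, alternate) allele counts by
    label class is tested with Fisher's exact test (two-sided) — an exact
    choice suited to small cohorts.  Missing genotypes are dropped per site.
    Output is sorted by position with p-values and their -log10 transform.
    """
    X = np.asarray(genotypes, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("genotypes and labels misaligned")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if positions is None:
        positions = list(range(1, X.shape[1] + 1))

    rows = []
    for j in range(X.shape[1]):
        col = X[:, j]
        called = ~np.isnan(col)
        table = np.zeros((2, 2), dtype=int)
        for k, cls in enumerate(classes):
            mask = called & (y == cls)
            alt = int(col[mask].sum())
            total = 2 * int(mask.sum())
            table[k] = (total - alt, alt)
        if table.sum() == 0:
            p = 1.0
        else:
            _odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "position": positions[j],
                "p_value": float(p),
                "neg_log10_p": float(-np.log10(p)) if p > 0 else float("inf"),
            }
        )
    return pd.DataFrame(rows).sort_values("position", ignore_index=True)
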