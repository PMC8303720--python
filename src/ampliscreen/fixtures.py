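"""Packaged cohort fixtures and naming conventions.

Two small tables ship with the package, transcribed from the published
screen of 41 field-collected moths:

``table1``
    Per-sample genotype calls for the known GC-insertion allele under two
    methods (TaqMan probe assay vs k-mer flank genotyping), with the trapping
    location recovered from the sample-name prefix.
``table2``
    The 24 nonsynonymous/frameshift mutation rows (position, class in the
    MISS/NON/SHIFT vocabulary, codon display, amino-acid change, carrier
    count).
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = [
    "load_fixture",
    "location_from_sample",
    "cohort_table_from_table1",
    "LOCATION_PREFIXES",
]

LOCATION_PREFIXES = {
    "PRL": "Lajas",
    "PRS": "Salinas",
    "PRSI": "Santa Isabel",
}


def location_from_sample(sample_id: str) -> str:
    """Trapping location from the sample-name prefix; unknowns map to 'other'."""
    prefix = sample_id.split("_", 1)[0]
    return LOCATION_PREFIXES.get(prefix, "other")


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture by name ('table1' or 'table2')."""
    if name not in ("table1", "table2"):
        raise KeyError(f"unknown fixture {name!r}")
    path = files("ampliscreen.data").joinpath(f"{name}.tsv")
    with path.open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    if name == "table1":
        df["location"] = df["sample_id"].map(location_from_sample)
    return df


def cohort_table_from_table1(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format cohort table (sample_id, location, method, call)."""
    if df is None:
        df = load_fixture("table1")
    long = df.melt(
        id_vars=["sample_id", "location"],
        value_vars=["taqman", "kmer"],
        var_name="method",
        value_name="call",
    )
    return long[["sample_id", "location", "method", "call"]]
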