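"""Packaged reference fixtures: the transcribed case-variant tables and the
published burden-count table, used by tests and the ``reproduce-table4``
subcommand."""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

__all__ = ["load_case_variant_table", "load_burden_count_table", "parse_percent_af"]


def _read(name: str) -> pd.DataFrame:
    text = resources.files("varburden.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), sep="\t", dtype={"POSITION": "Int64"})


def parse_percent_af(value: str) -> float:
    """Parse a printed AF cell: 'novel' -> 0.0, '0.0013%' -> 1.3e-5."""
    v = str(value).strip()
    if v.lower() == "novel":
        return 0.0
    if v.endswith("%"):
        return float(v[:-1]) / 100.0
    return float(v)


def load_case_variant_table() -> pd.DataFrame:
    """Per-case variant rows (hematologic, solid and CNS cohorts) with the
    printed AF strings parsed into a fractional ``AF_FRACTION`` column and
    the ddG column coerced to float (NaN when structurally unavailable)."""
    df = _read("rpa_case_variants.tsv")
    df["AF_FRACTION"] = df["AF"].map(parse_percent_af)
    df["DDG_VALUE"] = pd.to_numeric(df["DDG"], errors="coerce")
    return df


def load_burden_count_table() -> pd.DataFrame:
    """Published per-cell collapsed allele counts and statistics.

    ``stats_reliable`` is 0 for rows whose OR/FDR cells are column-shifted in
    the published table; only their one-sided p-values are comparable.
    """
    return _read("table4_counts.tsv")
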