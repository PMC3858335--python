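"""Curated Caucasian star-allele frequency catalog.

Loads a wide TSV (one row per star allele, one frequency column per
ethnicity), applies the >=1% pharmacogenetic-polymorphism filter, and
produces per-CYP summaries and lookups. The packaged fixture
``table1_caucasian.tsv`` holds 34 alleles; known text/table discrepancies
in its source are listed in ``data/ERRATA.md``.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Activity",
    "AlleleRecord",
    "CatalogSummary",
    "load_catalog",
    "export_catalog",
    "filter_polymorphic",
    "summarize",
    "lookup",
    "coverage_stats",
    "default_catalog_path",
]

_FIXED_COLUMNS = ["cyp", "allele", "aa_changes", "activity", "test_drug", "source_ids"]

_PERCENT_RE = re.compile(r"(\d+(?:\.\d+)?)")


class Activity(str, Enum):
    INCREASE = "INCREASE"
    DECREASE = "DECREASE"
    NO_ENZYME = "NO_ENZYME"
    NONFUNCTIONAL = "NONFUNCTIONAL"
    HIGHER_INDUCIBILITY = "HIGHER_INDUCIBILITY"
    INCREASE_TRANSCRIPTION = "INCREASE_TRANSCRIPTION"
    DECREASE_EXPRESSION = "DECREASE_EXPRESSION"


_ACTIVITY_ALIASES = {
    "increase": Activity.INCREASE,
    "increased": Activity.INCREASE,
    "decrease": Activity.DECREASE,
    "decreased": Activity.DECREASE,
    "no enzyme": Activity.NO_ENZYME,
    "nonfunctional": Activity.NONFUNCTIONAL,
    "higher inducibility": Activity.HIGHER_INDUCIBILITY,
    "increase (transcription)": Activity.INCREASE_TRANSCRIPTION,
    "increased (transcription)": Activity.INCREASE_TRANSCRIPTION,
    "decrease (expression)": Activity.DECREASE_EXPRESSION,
    "decreased (expression)": Activity.DECREASE_EXPRESSION,
}


@dataclass
class AlleleRecord:
    """One star allele with per-ethnicity frequencies on the 0-100 scale."""

    cyp: str
    allele: str
    aa_changes: list[str]
    frequencies: dict[str, float]
    activity: Activity
    test_drug: str | None = None
    source_ids: list[str] = field(default_factory=list)
    raw_frequencies: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for eth, f in self.frequencies.items():
            if not (0.0 <= f <= 100.0):
                raise ValueError(f"{self.cyp}{self.allele}: frequency[{eth}]={f} outside [0, 100]")


@dataclass
class CatalogSummary:
    n_alleles: int
    per_cyp_counts: dict[str, int]
    max_frequency: tuple[str, str, float]
    ranked_alleles: list[AlleleRecord]


def default_catalog_path() -> str:
    return str(resources.files("cypscope.data").joinpath("table1_caucasian.tsv"))


def _parse_frequency_cell(cell: str) -> float:
    """First percentage in the cell; genotype-style breakdowns keep their
    leading carrier percentage as the scalar value."""
    m = _PERCENT_RE.search(cell)
    if m is None:
        raise ValueError(f"unparseable frequency cell: {cell!r}")
    return float(m.group(1))


def load_catalog(path: str | Path | None = None) -> list[AlleleRecord]:
    """Read a catalog TSV; columns after the fixed six are ethnicity frequencies.

    Frequency cells may be plain numbers or genotype breakdowns; the raw cell
    text is preserved verbatim in :attr:`AlleleRecord.raw_frequencies`.
    """
    path = default_catalog_path() if path is None else path
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"catalog {path} missing columns: {missing}")
    ethnicities = [c for c in df.columns if c not in _FIXED_COLUMNS]
    records: list[AlleleRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        key = (row["cyp"], row["allele"])
        if key in seen:
            raise ValueError(f"duplicate (cyp, allele) {key} at row {i + 2}")
        seen.add(key)
        activity_text = row["activity"].strip().lower()
        if activity_text not in _ACTIVITY_ALIASES:
            raise ValueError(f"row {i + 2}: unknown activity {row['activity']!r}")
        frequencies: dict[str, float] = {}
        raw: dict[str, str] = {}
        for eth in ethnicities:
            cell = row[eth].strip()
            if not cell:
                continue
            try:
                frequencies[eth] = _parse_frequency_cell(cell)
            except ValueError as exc:
                raise ValueError(f"row {i + 2} ({row['cyp']}{row['allele']}): {exc}") from exc
            raw[eth] = cell
        records.append(
            AlleleRecord(
                cyp=row["cyp"],
                allele=row["allele"],
                aa_changes=[a for a in row["aa_changes"].split(";") if a],
                frequencies=frequencies,
                activity=_ACTIVITY_ALIASES[activity_text],
                test_drug=row["test_drug"] or None,
                source_ids=[s for s in row["source_ids"].split(";") if s],
                raw_frequencies=raw,
            )
        )
    return records


def export_catalog(records: Sequence[AlleleRecord], path: str | Path) -> None:
    """Inverse of :func:`load_catalog`; raw frequency cells are written back."""
    ethnicities: list[str] = []
    for r in records:
        for eth in r.raw_frequencies:
            if eth not in ethnicities:
                ethnicities.append(eth)
    activity_text = {v: k for k, v in reversed(_ACTIVITY_ALIASES.items())}
    rows = []
    for r in records:
        row = {
            "cyp": r.cyp,
            "allele": r.allele,
            "aa_changes": ";".join(r.aa_changes),
            "activity": activity_text[r.activity],
            "test_drug": r.test_drug or "",
            "source_ids": ";".join(r.source_ids),
        }
        for eth in ethnicities:
            row[eth] = r.raw_frequencies.get(eth, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_FIXED_COLUMNS + ethnicities).to_csv(path, sep="\t", index=False)


def filter_polymorphic(
    records: Sequence[AlleleRecord],
    threshold_percent: float = 1.0,
    ethnicity: str = "Caucasian",
) -> list[AlleleRecord]:
    """Keep alleles at or above the threshold frequency in one ethnicity.

    Records lacking a frequency for that ethnicity are dropped with a
    warning; an ethnicity absent from every record is an error.
    """
    if not (0.0 < threshold_percent < 100.0) and threshold_percent != 100.0:
        raise ValueError(f"threshold must be in (0, 100], got {threshold_percent}")
    known = sorted({eth for r in records for eth in r.frequencies})
    if records and ethnicity not in known:
        raise ValueError(f"unknown ethnicity {ethnicity!r}; known: {known}")
    kept: list[AlleleRecord] = []
    for r in records:
        if ethnicity not in r.frequencies:
            logger.warning("%s%s has no %s frequency; dropped", r.cyp, r.allele, ethnicity)
            continue
        if r.frequencies[ethnicity] >= threshold_percent:
            kept.append(r)
    return kept


def summarize(records: Sequence[AlleleRecord], ethnicity: str = "Caucasian") -> CatalogSummary:
    """Counts and a descending-frequency ranking; ties break by (cyp, allele)."""
    if not records:
        raise ValueError("cannot summarize an empty catalog")
    per_cyp: dict[str, int] = {}
    for r in records:
        per_cyp[r.cyp] = per_cyp.get(r.cyp, 0) + 1
    ranked = sorted(
        records,
        key=lambda r: (-r.frequencies.get(ethnicity, float("-inf")), r.cyp, r.allele),
    )
    top = ranked[0]
    return CatalogSummary(
        n_alleles=len(records),
        per_cyp_counts=per_cyp,
        max_frequency=(top.cyp, top.allele, top.frequencies[ethnicity]),
        ranked_alleles=ranked,
    )


def lookup(records: Sequence[AlleleRecord], cyp: str, allele: str) -> AlleleRecord:
    """Exact catalog lookup; the star prefix on the allele name is optional."""
    name = allele if allele.startswith("*") else "*" + allele
    for r in records:
        if r.cyp == cyp and r.allele == name:
            return r
    same_cyp = [r.allele for r in records if r.cyp == cyp]
    suggestions = difflib.get_close_matches(name, same_cyp, n=3, cutoff=0.0)
    hint = f"; nearest for CYP{cyp}: {', '.join(suggestions)}" if suggestions else ""
    raise KeyError(f"no catalog entry for CYP{cyp}{name}{hint}")


def coverage_stats(counts: dict[str, int]) -> pd.DataFrame:
    """Percent share and cumulative percent over a descending count ranking.

    Returns a DataFrame indexed by key with columns ``count``, ``percent``,
    ``cumulative_percent``; ties in the ranking break lexicographically.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    keys = sorted(counts, key=lambda k: (-counts[k], k))
    df = pd.DataFrame(
        {"count": [counts[k] for k in keys]},
        index=pd.Index(keys, name="key"),
    )
    df["percent"] = 100.0 * df["count"] / total
    df["cumulative_percent"] = df["percent"].cumsum()
    return df
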