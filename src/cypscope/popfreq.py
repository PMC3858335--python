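"""Population allele frequencies from diploid genotypes.

Reads VCF genotype data for CYP loci, computes AC/AN-style global allele
frequencies, applies the non-synonymous >=1% filter, calls star-allele
presence at cohort level against defining-variant tables, and partitions
variants into known vs novel relative to a nomenclature catalog.

Consequence classes and damaging calls are consumed as annotations (a
configurable INFO key); no effect prediction is performed here.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "Consequence",
    "DamagingCall",
    "PresenceStatus",
    "VariantRecord",
    "FrequencyResult",
    "StarAlleleDefinition",
    "read_variants",
    "allele_frequencies",
    "filter_nonsyn_common",
    "summarize_by_gene",
    "call_star_alleles",
    "flag_novel",
    "load_table_results",
    "load_definitions",
    "write_results",
    "default_table_path",
]


class Consequence(str, Enum):
    NON_SYNONYMOUS = "NON_SYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    SPLICE = "SPLICE"
    FRAMESHIFT = "FRAMESHIFT"
    OTHER = "OTHER"


_CONSEQUENCE_ALIASES = {
    "non_synonymous": Consequence.NON_SYNONYMOUS,
    "nonsynonymous": Consequence.NON_SYNONYMOUS,
    "missense": Consequence.NON_SYNONYMOUS,
    "missense_variant": Consequence.NON_SYNONYMOUS,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "splice": Consequence.SPLICE,
    "splice_variant": Consequence.SPLICE,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "other": Consequence.OTHER,
}


class DamagingCall(str, Enum):
    BENIGN = "BENIGN"
    POSSIBLY_DAMAGING = "POSSIBLY_DAMAGING"
    PROBABLY_DAMAGING = "PROBABLY_DAMAGING"


class PresenceStatus(str, Enum):
    PRESENT = "PRESENT"
    PARTIAL = "PARTIAL"
    ABSENT = "ABSENT"


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    rsid: str | None = None
    gene: str = ""
    consequence: Consequence = Consequence.OTHER
    aa_change: str | None = None
    cdna_change: str | None = None
    damaging_call: DamagingCall | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FrequencyResult:
    """A variant with its cohort allele frequency (AC/AN semantics).

    ``ac``/``an`` are None for results loaded from pre-computed frequency
    tables rather than genotypes.
    """

    variant: VariantRecord
    ac: int | None
    an: int | None
    frequency_percent: float

    def __post_init__(self) -> None:
        if (self.ac is None) != (self.an is None):
            raise ValueError("ac and an must both be set or both be None")
        if self.ac is not None:
            if not (0 <= self.ac <= self.an):
                raise ValueError(f"need 0 <= ac <= an, got ac={self.ac}, an={self.an}")
            if self.an % 2 != 0:
                raise ValueError(f"an must be even for diploid calls, got {self.an}")
        if not (0.0 <= self.frequency_percent <= 100.0):
            raise ValueError(f"frequency_percent {self.frequency_percent} outside [0, 100]")


@dataclass(frozen=True)
class StarAlleleDefinition:
    cyp: str
    allele: str
    defining_variants: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        if not self.defining_variants:
            raise ValueError(f"{self.cyp}{self.allele}: defining_variants must be non-empty")


def default_table_path() -> str:
    """Packaged pre-computed frequency table (72 non-synonymous SNPs, 24 CYPs)."""
    return str(resources.files("cypscope.data").joinpath("table2_1000g.tsv"))


def _parse_annotation(raw: str | None, n_alts: int) -> list[dict[str, str]]:
    """Annotation INFO format: comma list per alt of gene|consequence|aa|cdna|damaging
    (trailing fields optional)."""
    if raw is None:
        return [{} for _ in range(n_alts)]
    chunks = str(raw).split(",")
    if len(chunks) != n_alts:
        chunks = chunks[:n_alts] + [""] * (n_alts - len(chunks))
    parsed = []
    for chunk in chunks:
        fields = chunk.split("|")
        d: dict[str, str] = {}
        for name, value in zip(("gene", "consequence", "aa", "cdna", "damaging"), fields):
            if value:
                d[name] = value
        parsed.append(d)
    return parsed


def read_variants(
    vcf_path: str | Path,
    annotation_key: str = "CSQ_CLASS",
) -> tuple[list[VariantRecord], np.ndarray]:
    """Read a VCF with GT calls into variant records and an alt-count matrix.

    Multi-allelic sites are split into one record per alternate allele. The
    returned matrix has shape (n_records, n_samples) holding the per-sample
    count of that alternate allele (0/1/2), with -1 for missing genotypes.
    Records are sorted by (chrom, pos, alt). Phasing is ignored.
    """
    vcf = VCF(str(vcf_path), gts012=False)
    if "GT" not in {f for f in _format_ids(vcf)}:
        raise ValueError(f"{vcf_path} has no GT FORMAT field")
    rows: list[tuple[VariantRecord, np.ndarray]] = []
    for v in vcf:
        annos = _parse_annotation(v.INFO.get(annotation_key), len(v.ALT))
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        for alt_index, alt in enumerate(v.ALT, start=1):
            counts = np.full(len(gts), -1, dtype=np.int8)
            for s, gt in enumerate(gts):
                alleles = [a for a in gt[:-1]]
                if any(a is None or a < 0 for a in alleles):
                    continue  # half-calls treated as missing
                counts[s] = sum(1 for a in alleles if a == alt_index)
            anno = annos[alt_index - 1]
            cons_text = anno.get("consequence", "").lower()
            if cons_text in _CONSEQUENCE_ALIASES:
                consequence = _CONSEQUENCE_ALIASES[cons_text]
            else:
                if cons_text:
                    logger.warning(
                        "unknown consequence %r at %s:%s; mapped to OTHER",
                        cons_text, v.CHROM, v.POS,
                    )
                consequence = Consequence.OTHER
            damaging = anno.get("damaging")
            rows.append(
                (
                    VariantRecord(
                        chrom=v.CHROM,
                        pos=v.POS,
                        ref=v.REF,
                        alt=alt,
                        rsid=v.ID if v.ID not in (None, ".") else None,
                        gene=anno.get("gene", ""),
                        consequence=consequence,
                        aa_change=anno.get("aa"),
                        cdna_change=anno.get("cdna"),
                        damaging_call=DamagingCall(damaging) if damaging else None,
                    ),
                    counts,
                )
            )
    rows.sort(key=lambda r: (r[0].chrom, r[0].pos, r[0].alt))
    variants = [r[0] for r in rows]
    matrix = (
        np.vstack([r[1] for r in rows]) if rows else np.empty((0, 0), dtype=np.int8)
    )
    return variants, matrix


def _format_ids(vcf: VCF) -> list[str]:
    ids = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.append(line.split("ID=")[1].split(",")[0])
    return ids


def allele_frequencies(
    variants: Sequence[VariantRecord],
    genotypes: np.ndarray,
) -> list[FrequencyResult]:
    """AC/AN frequency per variant; missing genotypes are excluded from AN.

    Variants with no called genotypes (AN = 0) are dropped with a warning.
    """
    if len(variants) != genotypes.shape[0]:
        raise ValueError("genotype matrix does not conform with variants")
    results: list[FrequencyResult] = []
    for variant, row in zip(variants, genotypes):
        called = row >= 0
        an = int(2 * called.sum())
        if an == 0:
            logger.warning("no called genotypes at %s:%s; excluded", variant.chrom, variant.pos)
            continue
        ac = int(row[called].sum())
        results.append(
            FrequencyResult(variant=variant, ac=ac, an=an, frequency_percent=100.0 * ac / an)
        )
    return results


def filter_nonsyn_common(
    results: Sequence[FrequencyResult],
    threshold_percent: float = 1.0,
) -> list[FrequencyResult]:
    """Keep non-synonymous variants at or above the frequency threshold."""
    if not (0.0 < threshold_percent < 100.0):
        raise ValueError(f"threshold must be in (0, 100), got {threshold_percent}")
    return [
        r
        for r in results
        if r.variant.consequence is Consequence.NON_SYNONYMOUS
        and r.frequency_percent >= threshold_percent
    ]


def summarize_by_gene(
    results: Sequence[FrequencyResult],
) -> dict[str, tuple[int, FrequencyResult]]:
    """Per-gene variant count and most frequent variant (rsid breaks ties)."""
    if not results:
        raise ValueError("cannot summarize empty results")
    by_gene: dict[str, list[FrequencyResult]] = {}
    for r in results:
        by_gene.setdefault(r.variant.gene, []).append(r)
    summary: dict[str, tuple[int, FrequencyResult]] = {}
    for gene in sorted(by_gene):
        rs = by_gene[gene]
        top = min(rs, key=lambda r: (-r.frequency_percent, r.variant.rsid or ""))
        summary[gene] = (len(rs), top)
    return summary


def call_star_alleles(
    results: Sequence[FrequencyResult],
    definitions: Sequence[StarAlleleDefinition],
    threshold_percent: float = 1.0,
) -> dict[tuple[str, str], tuple[PresenceStatus, str]]:
    """Cohort-level presence of star alleles from their defining variants.

    PRESENT if every defining variant survives :func:`filter_nonsyn_common`
    at the threshold, PARTIAL if only some do, ABSENT otherwise. This is a
    population-level report, not per-sample diplotyping.
    """
    passing = {r.variant.key for r in filter_nonsyn_common(results, threshold_percent)}
    genes_seen = {r.variant.gene for r in results}
    report: dict[tuple[str, str], tuple[PresenceStatus, str]] = {}
    for d in definitions:
        if d.cyp not in genes_seen:
            report[(d.cyp, d.allele)] = (
                PresenceStatus.ABSENT,
                f"gene {d.cyp} absent from results",
            )
            continue
        n_hit = sum(1 for key in d.defining_variants if key in passing)
        if n_hit == len(d.defining_variants):
            status = PresenceStatus.PRESENT
        elif n_hit > 0:
            status = PresenceStatus.PARTIAL
        else:
            status = PresenceStatus.ABSENT
        report[(d.cyp, d.allele)] = (status, f"{n_hit}/{len(d.defining_variants)} defining variants")
    return report


def flag_novel(
    results: Sequence[FrequencyResult],
    catalog: Sequence[StarAlleleDefinition],
) -> tuple[list[FrequencyResult], list[FrequencyResult]]:
    """Partition results into (known, novel) by defining-variant membership."""
    defined = {key for d in catalog for key in d.defining_variants}
    known = [r for r in results if r.variant.key in defined]
    novel = [r for r in results if r.variant.key not in defined]
    return known, novel


# ---------------------------------------------------------------------------
# tabular I/O


def load_table_results(path: str | Path | None = None) -> list[FrequencyResult]:
    """Load a pre-computed frequency table (cyp, rsid, cdna, aa, frequency).

    All rows are treated as non-synonymous coding SNPs (the table is defined
    that way); positions are synthesized from row order since the table does
    not carry genomic coordinates.
    """
    path = default_table_path() if path is None else path
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["cyp", "rsid", "cdna_change", "aa_change", "global_frequency_percent"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"table {path} missing columns: {missing}")
    results = []
    for i, row in df.iterrows():
        variant = VariantRecord(
            chrom="NA",
            pos=i + 1,
            ref="N",
            alt="V",
            rsid=row["rsid"] or None,
            gene=row["cyp"],
            consequence=Consequence.NON_SYNONYMOUS,
            aa_change=row["aa_change"] or None,
            cdna_change=row["cdna_change"] or None,
        )
        results.append(
            FrequencyResult(
                variant=variant,
                ac=None,
                an=None,
                frequency_percent=float(row["global_frequency_percent"]),
            )
        )
    return results


def load_definitions(path: str | Path) -> list[StarAlleleDefinition]:
    """Star-allele definition TSV: cyp, allele, variants (semicolon list of pos:ref:alt)."""
    defs: list[StarAlleleDefinition] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"cyp", "allele", "variants"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"definitions {path} must have columns {sorted(required)}")
        for row in reader:
            keys = []
            for chunk in row["variants"].split(";"):
                chunk = chunk.strip()
                if not chunk:
                    continue
                pos, ref, alt = chunk.split(":")
                keys.append((int(pos), ref, alt))
            defs.append(StarAlleleDefinition(row["cyp"], row["allele"], tuple(keys)))
    return defs


def write_results(
    results: Sequence[FrequencyResult],
    path: str | Path,
    novel_keys: set[tuple[int, str, str]] | None = None,
) -> None:
    """Write results as TSV mirroring the summary-table columns plus AC/AN."""
    rows = []
    for r in results:
        v = r.variant
        rows.append(
            {
                "cyp": v.gene,
                "rsid": v.rsid or "",
                "cdna_change": v.cdna_change or "",
                "aa_change": v.aa_change or "",
                "global_frequency_percent": round(r.frequency_percent, 4),
                "ac": "" if r.ac is None else r.ac,
                "an": "" if r.an is None else r.an,
                "novel": "" if novel_keys is None else str(v.key in novel_keys).lower(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
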