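"""Seed-deterministic generators for every pipeline stage.

Each generator returns its artificial input together with a
:class:`SyntheticTruth` ledger of planted facts, so precision/recall and
parameter-recovery checks can be scored without re-reading generator
internals. Modeling choices: abstracts are filler-word token sequences with
entities planted at exact token distances (so distance rules are testable
to the token); genotypes are Hardy-Weinberg independent Bernoulli allele
draws; expression backgrounds are log-normal intensities with planted
multiplicative tissue effects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from .textmine_relations import Document

__all__ = [
    "TruthKind",
    "SyntheticTruth",
    "gen_abstracts",
    "gen_vcf",
    "gen_expression",
]


class TruthKind(str, Enum):
    RELATIONS = "RELATIONS"
    GENOTYPES = "GENOTYPES"
    EXPRESSION = "EXPRESSION"


@dataclass
class SyntheticTruth:
    kind: TruthKind
    entries: list[dict]
    seed: int

    def to_tsv(self, path: str | Path) -> None:
        columns: list[str] = []
        for e in self.entries:
            for k in e:
                if k not in columns:
                    columns.append(k)
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t", lineterminator="\n")
            writer.writeheader()
            writer.writerows(self.entries)


# filler vocabulary: disjoint from the default lexicon, never matches the
# CYP/frequency pattern rules, so planted token distances stay exact
_FILLER = (
    "cohort genotype assay enzyme clinical metabolism variant sample tissue "
    "protein pathway subject dosage plasma hepatic profile analysis marker "
    "kinetic substrate response outcome therapy measurement"
).split()

_CYP_POOL = ["2D6", "2C19", "2C9", "1A2", "3A4", "3A5", "2B6", "2A6"]
_ETHNICITY_POOL = [
    ("Caucasians", "caucasian"),
    ("Asians", "asian"),
    ("Africans", "african"),
    ("Japanese", "japanese"),
    ("Chinese", "chinese"),
]
_EFFECT_POOL = ["increased", "decreased", "reduced", "elevated"]


def _pick_distance(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, tuple):
        lo, hi = spec
        return int(rng.integers(lo, hi + 1))
    return int(spec)


def _filler_sentence(rng: np.random.Generator, n_words: int = 6) -> str:
    words = rng.choice(_FILLER, size=n_words, replace=True)
    return " ".join(words) + " ."


def _triple_sentence(
    rng: np.random.Generator,
    cyp: str,
    eth_surface: str,
    freq_value: float,
    d_ce: int,
    d_fc: int,
    effect: str | None,
) -> str:
    """Tokens: [lead] FREQ [d_fc-1 fillers] CYP [d_ce-1 fillers] ETH [tail] '.'"""
    if d_ce < 1 or d_fc < 1:
        raise ValueError("planted distances must be >= 1 (distinct tokens)")
    if d_ce + d_fc > 60:
        raise ValueError(f"distance spec d_ce={d_ce}, d_fc={d_fc} exceeds sentence budget")
    lead = list(rng.choice(_FILLER, size=int(rng.integers(0, 3)), replace=True))
    tail = list(rng.choice(_FILLER, size=int(rng.integers(1, 3)), replace=True))
    if effect is not None:
        tail.insert(0, effect)
    tokens = (
        lead
        + [f"{freq_value}%"]
        + list(rng.choice(_FILLER, size=d_fc - 1, replace=True))
        + [f"CYP{cyp}"]
        + list(rng.choice(_FILLER, size=d_ce - 1, replace=True))
        + [eth_surface]
        + tail
        + ["."]
    )
    return " ".join(tokens)


def gen_abstracts(
    n_docs: int,
    n_planted: int,
    d_ce: int | tuple[int, int] = (1, 7),
    d_fc: int | tuple[int, int] = (1, 6),
    decoy_rate: float = 1.0,
    seed: int = 0,
    include_effect: bool = True,
    decoy_margin: int = 6,
) -> tuple[list[Document], SyntheticTruth]:
    """Corpus with in-window planted triples and out-of-window decoys.

    Every planted document contains exactly one (CYP, ethnicity, frequency)
    triple at the requested token distances; a ``decoy_rate`` fraction of
    the remaining documents contain a triple whose distances exceed the
    scoring thresholds by more than 5 tokens, the rest are pure filler.
    """
    if n_planted > n_docs:
        raise ValueError("n_planted must be <= n_docs")
    if not (0.0 <= decoy_rate <= 1.0):
        raise ValueError("decoy_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    docs: list[Document] = []
    entries: list[dict] = []
    for i in range(n_docs):
        doc_id = f"{10_000_000 + i}"
        planted = i < n_planted
        sentences = [_filler_sentence(rng)]
        if planted:
            ce = _pick_distance(d_ce, rng)
            fc = _pick_distance(d_fc, rng)
            cyp = _CYP_POOL[int(rng.integers(len(_CYP_POOL)))]
            eth_surface, eth_canonical = _ETHNICITY_POOL[int(rng.integers(len(_ETHNICITY_POOL)))]
            freq_value = round(float(rng.uniform(1.0, 99.0)), 1)
            effect = _EFFECT_POOL[int(rng.integers(len(_EFFECT_POOL)))] if include_effect else None
            sentences.append(_triple_sentence(rng, cyp, eth_surface, freq_value, ce, fc, effect))
            entries.append(
                {
                    "doc_id": doc_id,
                    "cyp": cyp,
                    "ethnicity": eth_canonical,
                    "frequency": freq_value,
                    "d_ce": ce,
                    "d_fc": fc,
                }
            )
        elif rng.random() < decoy_rate:
            # decoy triples sit well past both thresholds
            ce = 7 + decoy_margin + int(rng.integers(0, 4))
            fc = 6 + decoy_margin + int(rng.integers(0, 4))
            cyp = _CYP_POOL[int(rng.integers(len(_CYP_POOL)))]
            eth_surface, _ = _ETHNICITY_POOL[int(rng.integers(len(_ETHNICITY_POOL)))]
            freq_value = round(float(rng.uniform(1.0, 99.0)), 1)
            sentences.append(_triple_sentence(rng, cyp, eth_surface, freq_value, ce, fc, None))
        sentences.append(_filler_sentence(rng))
        docs.append(Document(doc_id, title="", abstract=" ".join(sentences)))
    return docs, SyntheticTruth(TruthKind.RELATIONS, entries, seed)


def write_corpus(docs: Sequence[Document], path: str | Path) -> None:
    """TSV corpus writer matching :func:`cypscope.textmine_relations.read_corpus`."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "title", "abstract"])
        for d in docs:
            writer.writerow([d.doc_id, d.title, d.abstract])


def gen_vcf(
    n_samples: int,
    variant_spec: Sequence[tuple[str, str, float]],
    seed: int = 0,
    chrom: str = "19",
    annotation_key: str = "CSQ_CLASS",
) -> tuple[str, SyntheticTruth]:
    """Plain-text VCF with Hardy-Weinberg genotypes at known frequencies.

    ``variant_spec`` rows are (gene, consequence, true_freq in [0, 1]); each
    sample's genotype is two independent Bernoulli(true_freq) alleles.
    Returns the VCF text and a ledger of true frequencies.
    """
    for gene, consequence, f in variant_spec:
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"true_freq for {gene} must be in [0, 1], got {f}")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    lines = [
        "##fileformat=VCFv4.2",
        f'##INFO=<ID={annotation_key},Number=.,Type=String,'
        'Description="gene|consequence|aa_change per alternate allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        f"##contig=<ID={chrom}>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    entries: list[dict] = []
    for i, (gene, consequence, f) in enumerate(variant_spec):
        pos = 1000 * (i + 1)
        rsid = f"rs{900000 + i}"
        alleles = rng.binomial(1, f, size=(n_samples, 2))
        gts = "\t".join(f"{a}/{b}" for a, b in alleles)
        aa = f"X{i + 1}Y"
        info = f"{annotation_key}={gene}|{consequence}|{aa}"
        lines.append(f"{chrom}\t{pos}\t{rsid}\tA\tG\t.\tPASS\t{info}\tGT\t{gts}")
        entries.append(
            {
                "gene": gene,
                "rsid": rsid,
                "pos": pos,
                "consequence": consequence,
                "true_freq": f,
                "planted_ac": int(alleles.sum()),
            }
        )
    return "\n".join(lines) + "\n", SyntheticTruth(TruthKind.GENOTYPES, entries, seed)


def gen_expression(
    n_genes: int = 40,
    tissues: int | Sequence[str] = 65,
    planted: Sequence[tuple[str, str, float]] = (),
    noise_sd: float = 0.15,
    n_probes: int = 84,
    seed: int = 0,
    baseline_intensity: float = 100.0,
):
    """Probe x tissue intensity matrix with planted fold effects.

    Background intensities are log-normal around ``baseline_intensity`` with
    log-scale sd ``noise_sd``; each gene owns 1-3 probes (``n_probes`` total);
    planted (gene, tissue, fold) triples multiply every probe of that gene in
    that tissue by the fold. Returns (ExpressionMatrix, ProbeGeneMap, truth).
    """
    from .expression_map import ExpressionMatrix, ProbeGeneMap

    if not n_genes <= n_probes <= 3 * n_genes:
        raise ValueError(f"need n_genes <= n_probes <= 3*n_genes, got {n_probes} for {n_genes}")
    if isinstance(tissues, int):
        tissue_ids = ["liver"] + [f"T{i:02d}" for i in range(2, tissues + 1)]
    else:
        tissue_ids = list(tissues)
    genes = [f"G{i + 1:02d}" for i in range(n_genes)]
    for gene, tissue, fold in planted:
        if gene not in genes:
            raise ValueError(f"planted gene {gene!r} outside the matrix")
        if tissue not in tissue_ids:
            raise ValueError(f"planted tissue {tissue!r} outside the matrix")
        if fold <= 0:
            raise ValueError(f"planted fold must be > 0, got {fold}")

    rng = np.random.default_rng(seed)
    # distribute the extra probes (beyond one each) over genes, max 3 per gene
    probes_per_gene = np.ones(n_genes, dtype=int)
    extra = n_probes - n_genes
    while extra > 0:
        gi = int(rng.integers(n_genes))
        if probes_per_gene[gi] < 3:
            probes_per_gene[gi] += 1
            extra -= 1

    probe_ids: list[str] = []
    probe_gene: dict[str, str] = {}
    for gi, gene in enumerate(genes):
        for k in range(probes_per_gene[gi]):
            pid = f"P{len(probe_ids) + 1:03d}_at"
            probe_ids.append(pid)
            probe_gene[pid] = gene

    log_mu = np.log(baseline_intensity)
    intensities = np.exp(rng.normal(log_mu, noise_sd, size=(len(probe_ids), len(tissue_ids))))
    gene_index = {g: i for i, g in enumerate(genes)}
    tissue_index = {t: i for i, t in enumerate(tissue_ids)}
    for gene, tissue, fold in planted:
        rows = [i for i, p in enumerate(probe_ids) if probe_gene[p] == gene]
        intensities[rows, tissue_index[tissue]] *= fold

    matrix = ExpressionMatrix(probe_ids, tissue_ids, intensities)
    truth = SyntheticTruth(
        TruthKind.EXPRESSION,
        [{"gene": g, "tissue": t, "fold": f} for g, t, f in planted],
        seed,
    )
    return matrix, ProbeGeneMap(probe_gene), truth
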