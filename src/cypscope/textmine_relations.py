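"""Dictionary-based entity recognition and distance-rule relation scoring.

The pipeline turns plain-text abstracts into scored
(CYP, ethnicity, frequency[, effect]) relation candidates:

1. :func:`tokenize` — sentence segmentation plus a tokenizer that keeps
   star alleles (``CYP2D6*4``), rsIDs and percentages as single tokens;
2. :func:`detect_mentions` — longest-match dictionary lookup against a
   :class:`Lexicon`, plus pattern rules for CYP names and percentages;
3. :func:`extract_relations` — sentence-windowed triple enumeration,
   negation detection and distance-based scoring;
4. :func:`deduplicate` / :func:`export_records` — post-processing and a
   TSV export of validated hits.

Scoring: a candidate whose CYP↔ethnicity token distance is at most 7 and
whose frequency↔CYP distance is at most 6 scores exactly 100; each
excess token in either dimension subtracts ``decay_weight`` points (default
10), negated candidates are multiplied by ``negation_factor`` (default 0.5)
and the result is clamped to [0, 100].
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "Lexicon",
    "EntityMention",
    "RelationCandidate",
    "ScoringParams",
    "ValidationRecord",
    "ValidationState",
    "build_query",
    "tokenize",
    "detect_mentions",
    "score_relation",
    "extract_relations",
    "deduplicate",
    "export_records",
    "read_records",
    "read_corpus",
    "default_lexicon",
]

# Canonical CYP ids look like "2C19", "3A5", "11B1": family digits, a
# subfamily letter, optional member digits.
CYP_ID_RE = re.compile(r"^\d+[A-Za-z]\d*$")

# Token-level patterns. A "CYP..." token may carry a star-allele suffix.
_CYP_TOKEN_RE = re.compile(r"^CYP(\d+[A-Za-z]\d*)(?:\*[\w/]+)?$", re.IGNORECASE)
_FAMILY_TOKEN_RE = re.compile(r"^(\d+[A-Za-z]\d*)(?:\*[\w/]+)?$")
_PERCENT_TOKEN_RE = re.compile(r"^(\d+(?:\.\d+)?)%$")
_NUMBER_TOKEN_RE = re.compile(r"^\d+(?:\.\d+)?$")

_TOKEN_RE = re.compile(
    r"\d+(?:\.\d+)?%"        # percentages: 81.3%
    r"|rs\d+"                # dbSNP ids
    r"|[A-Za-z][\w-]*\*[\w/]+"  # star alleles: CYP2D6*4
    r"|\d+[A-Za-z]\w*(?:\*[\w/]+)?"  # digit-led codes: 2D6, 2C19, 3A5*3C
    r"|\d+(?:\.\d+)?"        # bare numbers
    r"|[A-Za-z][\w'-]*"      # words
    r"|\S"                   # any leftover symbol
)

_SENTENCE_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")


class EntityClass(str, Enum):
    CYP = "CYP"
    ETHNICITY = "ETHNICITY"
    FREQUENCY = "FREQUENCY"
    EFFECT = "EFFECT"
    NEGATION = "NEGATION"


@dataclass(frozen=True)
class Document:
    """One abstract with a PubMed-style identifier."""

    doc_id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass(frozen=True)
class LexiconEntry:
    entity_class: EntityClass
    surface_form: str
    canonical_id: str


class Lexicon:
    """Surface-form dictionary mapping phrases to canonical entity ids."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = []
        seen: set[tuple[EntityClass, str]] = set()
        for e in entries:
            if not e.surface_form:
                raise ValueError("lexicon surface forms must be non-empty")
            key = (e.entity_class, e.surface_form.lower())
            if key in seen:
                raise ValueError(f"duplicate lexicon entry: {key}")
            if e.entity_class is EntityClass.CYP and not CYP_ID_RE.match(e.canonical_id):
                raise ValueError(
                    f"CYP canonical id {e.canonical_id!r} does not match the "
                    "family-letter-subfamily pattern"
                )
            seen.add(key)
            self.entries.append(e)
        # phrase index keyed by lower-cased token tuples, longest first
        self._index: dict[tuple[str, ...], LexiconEntry] = {}
        for e in self.entries:
            toks = tuple(t.lower() for t in _TOKEN_RE.findall(e.surface_form))
            self._index[toks] = e
        self.max_phrase_len = max((len(k) for k in self._index), default=0)

    def match(self, tokens_lower: Sequence[str], start: int) -> tuple[LexiconEntry, int] | None:
        """Longest dictionary match beginning at ``start``; returns (entry, n_tokens)."""
        limit = min(self.max_phrase_len, len(tokens_lower) - start)
        for n in range(limit, 0, -1):
            entry = self._index.get(tuple(tokens_lower[start : start + n]))
            if entry is not None:
                return entry, n
        return None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"entity_class", "surface_form", "canonical_id"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"lexicon {path} must have columns {sorted(required)}")
            for row in reader:
                entries.append(
                    LexiconEntry(
                        EntityClass(row["entity_class"]),
                        row["surface_form"],
                        row["canonical_id"],
                    )
                )
        return cls(entries)


def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package (ethnicity/effect/negation terms)."""
    path = resources.files("cypscope.data").joinpath("lexicon_default.tsv")
    return Lexicon.from_tsv(str(path))


@dataclass(frozen=True)
class Token:
    text: str
    index: int          # 0-based position in the whole document
    sentence_index: int


@dataclass(frozen=True)
class EntityMention:
    entity_class: EntityClass
    canonical_id: str
    token_start: int
    sentence_index: int
    surface: str
    value: float | None = None  # percent, FREQUENCY mentions only

    def __post_init__(self) -> None:
        if self.token_start < 0:
            raise ValueError("token_start must be >= 0")
        if self.entity_class is EntityClass.FREQUENCY:
            if self.value is None or not (0.0 <= self.value <= 100.0):
                raise ValueError("FREQUENCY mentions require value in [0, 100]")
        elif self.value is not None:
            raise ValueError("only FREQUENCY mentions carry a value")


@dataclass
class ScoringParams:
    """Knobs of the distance-decay scoring rule."""

    max_d_ce: int = 7
    max_d_fc: int = 6
    decay_weight: float = 10.0
    negation_factor: float = 0.5
    min_score: float = 0.0
    cross_sentence: bool = False
    cross_sentence_cap: float = 90.0


@dataclass
class RelationCandidate:
    doc_id: str
    cyp: EntityMention | None
    ethnicity: EntityMention | None
    frequency: EntityMention | None
    effect: EntityMention | None
    d_ce: int
    d_fc: int
    negated: bool = False
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.d_ce < 0 or self.d_fc < 0:
            raise ValueError("token distances must be non-negative")
        if self.cyp is not None and self.ethnicity is not None:
            if self.d_ce != abs(self.cyp.token_start - self.ethnicity.token_start):
                raise ValueError("d_ce inconsistent with mention positions")
        if self.cyp is not None and self.frequency is not None:
            if self.d_fc != abs(self.frequency.token_start - self.cyp.token_start):
                raise ValueError("d_fc inconsistent with mention positions")

    @classmethod
    def from_mentions(
        cls,
        doc_id: str,
        cyp: EntityMention,
        ethnicity: EntityMention,
        frequency: EntityMention,
        effect: EntityMention | None = None,
        negated: bool = False,
    ) -> "RelationCandidate":
        return cls(
            doc_id=doc_id,
            cyp=cyp,
            ethnicity=ethnicity,
            frequency=frequency,
            effect=effect,
            d_ce=abs(cyp.token_start - ethnicity.token_start),
            d_fc=abs(frequency.token_start - cyp.token_start),
            negated=negated,
        )

    @property
    def key(self) -> tuple:
        """Deduplication key: (doc, CYP, ethnicity, frequency value)."""
        return (
            self.doc_id,
            self.cyp.canonical_id if self.cyp else None,
            self.ethnicity.canonical_id if self.ethnicity else None,
            self.frequency.value if self.frequency else None,
        )


class ValidationState(str, Enum):
    UNREVIEWED = "UNREVIEWED"
    TRUE = "TRUE"
    FALSE = "FALSE"
    NOT_SURE = "NOT_SURE"


_ALLOWED_TRANSITIONS = {
    ValidationState.UNREVIEWED: {ValidationState.TRUE, ValidationState.FALSE, ValidationState.NOT_SURE},
    ValidationState.NOT_SURE: {ValidationState.TRUE, ValidationState.FALSE},
    ValidationState.TRUE: set(),
    ValidationState.FALSE: set(),
}


@dataclass
class ValidationRecord:
    """A relation candidate together with its manual-review state."""

    candidate: RelationCandidate
    state: ValidationState = ValidationState.UNREVIEWED
    reviewer: str = ""
    comment: str = ""

    def resolve(self, new_state: ValidationState, reviewer: str = "", comment: str = "") -> None:
        if new_state not in _ALLOWED_TRANSITIONS[self.state]:
            raise ValueError(f"illegal state transition {self.state.value} -> {new_state.value}")
        self.state = new_state
        if reviewer:
            self.reviewer = reviewer
        if comment:
            self.comment = comment

    def export_tuple(self) -> tuple:
        c = self.candidate
        return (
            c.doc_id,
            c.cyp.canonical_id if c.cyp else "",
            c.ethnicity.canonical_id if c.ethnicity else "",
            c.frequency.value if c.frequency else None,
            c.effect.canonical_id if c.effect else "",
            c.score,
            self.state.value,
            self.reviewer,
            self.comment,
        )


# ---------------------------------------------------------------------------
# query construction


def build_query(
    cyp_canonical: str,
    population_terms: Sequence[str],
    effect_terms: Sequence[str],
) -> str:
    """Render the four-clause conjunctive abstract/title query for one CYP.

    ``build_query("2C19", ["population"], ["effect"])`` yields::

        (Abstract: CYP2C19* OR Title: CYP2C19*) AND (Abstract: population OR
        Title: population) AND (Abstract: effect OR Title: effect) AND
        (Abstract: frequenc* OR Title: frequenc*)
    """
    if not CYP_ID_RE.match(cyp_canonical):
        raise ValueError(f"malformed CYP id: {cyp_canonical!r}")
    if not population_terms:
        raise ValueError("empty synonym list: population_terms")
    if not effect_terms:
        raise ValueError("empty synonym list: effect_terms")

    def clause(terms: Sequence[str]) -> str:
        parts = []
        for t in terms:
            parts.append(f"Abstract: {t} OR Title: {t}")
        return "(" + " OR ".join(parts) + ")"

    cyp_term = f"CYP{cyp_canonical}*"
    return " AND ".join(
        [
            f"(Abstract: {cyp_term} OR Title: {cyp_term})",
            clause(population_terms),
            clause(effect_terms),
            "(Abstract: frequenc* OR Title: frequenc*)",
        ]
    )


# ---------------------------------------------------------------------------
# tokenization


def tokenize(document: Document | str) -> list[Token]:
    """Split text into sentence-indexed tokens.

    Star alleles, rsIDs and percentages survive as single tokens; sentence
    indices are non-decreasing. Title (if any) counts as sentence 0 context:
    it is segmented like any other text, prepended before the abstract.
    """
    if isinstance(document, Document):
        text = (document.title + "\n" + document.abstract).strip()
    else:
        text = document
    if not text:
        return []
    tokens: list[Token] = []
    sentence_index = 0
    idx = 0
    for chunk in text.split("\n"):
        chunk = chunk.strip()
        if not chunk:
            continue
        for sentence in _SENTENCE_SPLIT_RE.split(chunk):
            if not sentence:
                continue
            for m in _TOKEN_RE.finditer(sentence):
                tokens.append(Token(m.group(0), idx, sentence_index))
                idx += 1
            sentence_index += 1
    return tokens


# ---------------------------------------------------------------------------
# mention detection


def _cyp_canonical_from_token(text: str) -> str | None:
    m = _CYP_TOKEN_RE.match(text)
    if m:
        return m.group(1).upper()
    return None


def detect_mentions(tokens: Sequence[Token], lexicon: Lexicon) -> list[EntityMention]:
    """Dictionary + pattern entity detection over a token stream.

    Dictionary matching is case-insensitive and longest-match-wins. On top
    of the dictionary, two pattern rules fire: CYP names (``CYP2C19``,
    ``CYP 2C19``, star-allele forms) and frequencies (``16.0%`` or
    ``16 percent``); frequency values outside [0, 100] are discarded with a
    warning.
    """
    mentions: list[EntityMention] = []
    lower = [t.text.lower() for t in tokens]
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        matched = lexicon.match(lower, i)
        if matched is not None:
            entry, n = matched
            surface = " ".join(t.text for t in tokens[i : i + n])
            mentions.append(
                EntityMention(entry.entity_class, entry.canonical_id, tok.index, tok.sentence_index, surface)
            )
            i += n
            continue
        # pattern: CYP names, fused ("CYP2C19*2") or spaced ("CYP 2C19")
        canonical = _cyp_canonical_from_token(tok.text)
        if canonical is not None:
            mentions.append(
                EntityMention(EntityClass.CYP, canonical, tok.index, tok.sentence_index, tok.text)
            )
            i += 1
            continue
        if tok.text.upper() == "CYP" and i + 1 < len(tokens):
            nxt = tokens[i + 1]
            fam = _FAMILY_TOKEN_RE.match(nxt.text)
            if fam and nxt.sentence_index == tok.sentence_index:
                mentions.append(
                    EntityMention(
                        EntityClass.CYP,
                        fam.group(1).upper(),
                        tok.index,
                        tok.sentence_index,
                        f"{tok.text} {nxt.text}",
                    )
                )
                i += 2
                continue
        # pattern: frequencies
        pm = _PERCENT_TOKEN_RE.match(tok.text)
        value: float | None = None
        if pm:
            value = float(pm.group(1))
        elif (
            _NUMBER_TOKEN_RE.match(tok.text)
            and i + 1 < len(tokens)
            and lower[i + 1] in ("%", "percent")
        ):
            value = float(tok.text)
        if value is not None:
            if 0.0 <= value <= 100.0:
                mentions.append(
                    EntityMention(
                        EntityClass.FREQUENCY, f"{value}", tok.index, tok.sentence_index, tok.text, value
                    )
                )
            else:
                logger.warning("discarding out-of-range frequency mention %r", tok.text)
            i += 1
            continue
        i += 1
    mentions.sort(key=lambda m: m.token_start)
    return mentions


# ---------------------------------------------------------------------------
# scoring


def score_relation(candidate: RelationCandidate, params: ScoringParams | None = None) -> float:
    """Distance-decay score in [0, 100].

    Within-threshold non-negated candidates score exactly 100; each excess
    token beyond either threshold costs ``decay_weight`` points; negation
    multiplies by ``negation_factor``; the result is clamped to [0, 100].
    """
    params = params or ScoringParams()
    if candidate.d_ce < 0 or candidate.d_fc < 0:
        raise ValueError("token distances must be non-negative")
    if candidate.d_ce <= params.max_d_ce and candidate.d_fc <= params.max_d_fc and not candidate.negated:
        return 100.0
    excess = max(0, candidate.d_ce - params.max_d_ce) + max(0, candidate.d_fc - params.max_d_fc)
    score = max(0.0, 100.0 - params.decay_weight * excess)
    if candidate.negated:
        score *= params.negation_factor
    return min(100.0, max(0.0, score))


def _negation_between(
    negations: Sequence[EntityMention],
    cyp: EntityMention,
    ethnicity: EntityMention,
    frequency: EntityMention,
) -> bool:
    # negation counts if it sits strictly between the closest pair of the triple
    pairs = sorted(
        [(abs(cyp.token_start - ethnicity.token_start), cyp, ethnicity),
         (abs(frequency.token_start - cyp.token_start), frequency, cyp)],
        key=lambda p: p[0],
    )
    _, a, b = pairs[0]
    lo, hi = sorted((a.token_start, b.token_start))
    return any(lo < n.token_start < hi for n in negations)


def extract_relations(
    document: Document,
    lexicon: Lexicon,
    params: ScoringParams | None = None,
) -> list[RelationCandidate]:
    """Enumerate and score (CYP, ethnicity, frequency) triples in one document.

    Triples must share a sentence (or adjacent sentences when
    ``params.cross_sentence`` — such candidates are capped at
    ``cross_sentence_cap``). The nearest in-window EFFECT mention is
    attached; a NEGATION term between the closest pair of the triple marks
    the candidate negated. Candidates scoring below ``params.min_score``
    are dropped; the rest are sorted by descending score, ties by CYP then
    ethnicity position.
    """
    params = params or ScoringParams()
    tokens = tokenize(document)
    mentions = detect_mentions(tokens, lexicon)
    by_class: dict[EntityClass, list[EntityMention]] = {c: [] for c in EntityClass}
    for m in mentions:
        by_class[m.entity_class].append(m)

    out: list[RelationCandidate] = []
    for cyp in by_class[EntityClass.CYP]:
        for eth in by_class[EntityClass.ETHNICITY]:
            for freq in by_class[EntityClass.FREQUENCY]:
                sents = {cyp.sentence_index, eth.sentence_index, freq.sentence_index}
                span = max(sents) - min(sents)
                if span == 0:
                    cross = False
                elif params.cross_sentence and span == 1:
                    cross = True
                else:
                    continue
                window_sents = set(range(min(sents), max(sents) + 1))
                negated = _negation_between(
                    [n for n in by_class[EntityClass.NEGATION] if n.sentence_index in window_sents],
                    cyp, eth, freq,
                )
                effects = [e for e in by_class[EntityClass.EFFECT] if e.sentence_index in window_sents]
                effect = min(effects, key=lambda e: abs(e.token_start - cyp.token_start)) if effects else None
                cand = RelationCandidate.from_mentions(
                    document.doc_id, cyp, eth, freq, effect=effect, negated=negated
                )
                cand.score = score_relation(cand, params)
                if cross:
                    cand.score = min(cand.score, params.cross_sentence_cap)
                if cand.score >= params.min_score:
                    out.append(cand)
    out.sort(
        key=lambda c: (
            -c.score,
            c.cyp.token_start if c.cyp else 0,
            c.ethnicity.token_start if c.ethnicity else 0,
        )
    )
    return out


def deduplicate(candidates: Sequence[RelationCandidate]) -> list[RelationCandidate]:
    """Keep the highest-scoring candidate per (doc, CYP, ethnicity, value) key."""
    best: dict[tuple, RelationCandidate] = {}
    order: list[tuple] = []
    for c in candidates:
        k = c.key
        if k not in best:
            best[k] = c
            order.append(k)
        elif c.score > best[k].score:
            best[k] = c
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# I/O

_EXPORT_COLUMNS = [
    "doc_id", "cyp", "ethnicity", "frequency", "effect",
    "score", "state", "reviewer", "comment",
]


def export_records(
    validated: Sequence[ValidationRecord],
    path: str | Path,
    allow_unresolved: bool = True,
) -> None:
    """Write validation records as TSV; strict mode rejects unresolved states."""
    if not allow_unresolved:
        bad = [r for r in validated if r.state in (ValidationState.UNREVIEWED, ValidationState.NOT_SURE)]
        if bad:
            keys = ", ".join(str(r.candidate.key) for r in bad)
            raise ValueError(f"unresolved records: {keys}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EXPORT_COLUMNS)
        for r in validated:
            row = list(r.export_tuple())
            row[3] = "" if row[3] is None else repr(row[3])
            writer.writerow(row)


def read_records(path: str | Path) -> list[ValidationRecord]:
    """Read a TSV written by :func:`export_records`.

    Mentions are reconstructed canonically (positions are not serialized),
    so round-trip equality holds on :meth:`ValidationRecord.export_tuple`.
    """
    records: list[ValidationRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != _EXPORT_COLUMNS:
            raise ValueError(f"unexpected columns in {path}: {reader.fieldnames}")
        for row in reader:
            freq_val = float(row["frequency"]) if row["frequency"] else None

            def mention(cls: EntityClass, cid: str, value: float | None = None) -> EntityMention | None:
                if not cid and value is None:
                    return None
                return EntityMention(cls, cid or (f"{value}" if value is not None else ""), 0, 0,
                                     cid, value)

            cyp = mention(EntityClass.CYP, row["cyp"])
            eth = mention(EntityClass.ETHNICITY, row["ethnicity"])
            freq = mention(EntityClass.FREQUENCY, "", freq_val) if freq_val is not None else None
            eff = mention(EntityClass.EFFECT, row["effect"])
            cand = RelationCandidate(
                doc_id=row["doc_id"], cyp=cyp, ethnicity=eth, frequency=freq, effect=eff,
                d_ce=0, d_fc=0, negated=False, score=float(row["score"]),
            )
            records.append(
                ValidationRecord(cand, ValidationState(row["state"]), row["reviewer"], row["comment"])
            )
    return records


def read_corpus(path: str | Path) -> list[Document]:
    """Load a corpus: TSV (doc_id, title, abstract) or a directory of .txt files."""
    p = Path(path)
    docs: list[Document] = []
    if p.is_dir():
        for txt in sorted(p.glob("*.txt")):
            docs.append(Document(txt.stem, "", txt.read_text(encoding="utf-8")))
    else:
        with open(p, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            required = {"doc_id", "title", "abstract"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(f"corpus {path} must have columns {sorted(required)}")
            for row in reader:
                docs.append(Document(row["doc_id"], row["title"], row["abstract"]))
    ids = [d.doc_id for d in docs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate doc_ids in corpus")
    return docs
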