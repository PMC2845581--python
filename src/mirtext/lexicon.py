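"""Synonym dictionaries for genes/proteins, taxa and tissues, plus the
five-type relation-keyword lexicon.

Entity dictionaries are merged from tab-separated snapshot tables
(entity_id, entity_type, species, synonym), expanded with orthographic
variants and acronym/long-form pairs (e.g. IL = Interleukin), and
curated against stoplists of general-English words and technical
abbreviations that would otherwise cause spurious matches.

The relation lexicon maps five association types — physical_target,
co_expression, repression, induction, cleavage — to keywords; the
bundled default carries explicit inflected forms (``represses``,
``repressed`` ...) rather than a stemmer so every hit is auditable.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Iterator, Sequence

from ._text import norm_key

logger = logging.getLogger(__name__)

__all__ = [
    "Synonym",
    "LexiconEntry",
    "Lexicon",
    "RelationLexicon",
    "ExpansionRules",
    "RELATION_TYPES",
    "build_lexicon",
    "expand_synonyms",
    "expand_all",
    "curate",
    "load_relation_keywords",
    "default_relation_lexicon",
    "read_synonym_tsv",
    "load_stoplist",
    "default_stoplists",
    "bundled_taxa",
    "bundled_tissues",
    "default_expansion_rules",
]

RELATION_TYPES = (
    "physical_target",
    "co_expression",
    "repression",
    "induction",
    "cleavage",
)

ENTITY_TYPES = ("gene", "protein", "taxon", "tissue")


@dataclass
class Synonym:
    text: str
    ambiguous: bool = False
    curated_out: bool = False
    generated: bool = False

    @property
    def retained(self) -> bool:
        return not self.curated_out


@dataclass
class LexiconEntry:
    entity_id: str
    entity_type: str
    species: str = "any"
    synonyms: dict[str, Synonym] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.entity_type, self.species, self.entity_id)

    def retained_synonyms(self) -> list[Synonym]:
        return [s for s in self.synonyms.values() if s.retained]

    def add(self, text: str, generated: bool = False) -> None:
        if text not in self.synonyms:
            self.synonyms[text] = Synonym(text, generated=generated)


class Lexicon:
    """Merged synonym dictionary keyed by (entity_type, species, id)."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, str], LexiconEntry] = {}
        self.skipped_records = 0
        self.curated_out_count = 0

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    def entries(self, entity_type: str | None = None) -> list[LexiconEntry]:
        out = list(self._entries.values())
        if entity_type is not None:
            out = [e for e in out if e.entity_type == entity_type]
        return out

    def get(self, entity_type: str, species: str,
            entity_id: str) -> LexiconEntry | None:
        return self._entries.get((entity_type, species, entity_id))

    def find_entity(self, entity_type: str,
                    entity_id: str) -> LexiconEntry | None:
        """Lookup by id alone (species unknown)."""
        for entry in self._entries.values():
            if entry.entity_type == entity_type and entry.entity_id == entity_id:
                return entry
        return None

    def entry_for(self, entity_id: str, entity_type: str,
                  species: str) -> LexiconEntry:
        key = (entity_type, species, entity_id)
        if key not in self._entries:
            self._entries[key] = LexiconEntry(entity_id, entity_type, species)
        return self._entries[key]

    def refresh_ambiguity(self) -> None:
        """Recompute the ambiguity flag: a synonym is ambiguous iff its
        tolerant-matching key is retained by >= 2 entities of the same
        entity_type."""
        owners: dict[tuple[str, str], set[tuple[str, str, str]]] = {}
        for entry in self._entries.values():
            for syn in entry.retained_synonyms():
                owners.setdefault(
                    (entry.entity_type, norm_key(syn.text)), set()
                ).add(entry.key)
        for entry in self._entries.values():
            for syn in entry.synonyms.values():
                key = (entry.entity_type, norm_key(syn.text))
                syn.ambiguous = syn.retained and len(owners.get(key, ())) >= 2


def read_synonym_tsv(stream: IO[str]) -> Iterator[Sequence[str]]:
    """Yield (entity_id, entity_type, species, synonym) rows."""
    for row in csv.reader(stream, delimiter="\t"):
        if row:
            yield row


def build_lexicon(source_tables: Iterable[Iterable[Sequence[str]]]) -> Lexicon:
    """Merge synonym source tables into one dictionary.

    Duplicate (entity, synonym) pairs collapse; synonyms retained by more
    than one entity of a type are flagged ambiguous.  Malformed records
    are skipped with a logged count.
    """
    lex = Lexicon()
    for table in source_tables:
        for row in table:
            if len(row) < 4 or not all(str(x).strip() for x in row[:4]):
                lex.skipped_records += 1
                continue
            entity_id, entity_type, species, synonym = (
                str(row[0]).strip(), str(row[1]).strip(),
                str(row[2]).strip(), str(row[3]).strip())
            if entity_type not in ENTITY_TYPES:
                lex.skipped_records += 1
                continue
            lex.entry_for(entity_id, entity_type, species).add(synonym)
    if lex.skipped_records:
        logger.warning("build_lexicon: skipped %d malformed records",
                       lex.skipped_records)
    lex.refresh_ambiguity()
    return lex


# ---------------------------------------------------------------------------
# synonym expansion

_ROMAN = ["i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x"]
_ROMAN_TO_ARABIC = {r: str(n) for n, r in enumerate(_ROMAN, start=1)}
_ARABIC_TO_ROMAN = {v: k for k, v in _ROMAN_TO_ARABIC.items()}


@dataclass(frozen=True)
class ExpansionRules:
    """Orthographic transforms plus an acronym <-> long-form pair table."""

    acronym_pairs: tuple[tuple[str, str], ...] = ()
    separators: bool = True        # hyphen <-> space <-> fused
    slash_split: bool = True       # "A/B" -> "A", "B" (parts of length >= 3)
    roman_arabic: bool = True      # trailing "II" <-> "2"
    fold_case: bool = False        # add a lowercased variant


def default_expansion_rules() -> ExpansionRules:
    with resources.files("mirtext.data").joinpath(
            "acronym_pairs.tsv").open(encoding="utf-8") as fh:
        pairs = tuple((r[0], r[1]) for r in csv.reader(fh, delimiter="\t") if r)
    return ExpansionRules(acronym_pairs=pairs)


def _variants_of(text: str, rules: ExpansionRules) -> set[str]:
    out: set[str] = set()
    if rules.separators:
        if "-" in text:
            out.add(text.replace("-", " "))
            out.add(text.replace("-", ""))
        if " " in text:
            out.add(text.replace(" ", "-"))
            out.add(text.replace(" ", ""))
        # fuse only a single trailing letter<->digit boundary separator,
        # e.g. "IL-6" -> "IL6"; broader fusions come from the rules above
    if rules.slash_split and "/" in text:
        for part in text.split("/"):
            part = part.strip()
            if len(part) >= 3:
                out.add(part)
    if rules.roman_arabic:
        m = re.match(r"^(.*[ \-])([ivx]+|\d+)$", text, re.IGNORECASE)
        if m:
            head, tail = m.group(1), m.group(2)
            low = tail.lower()
            if low in _ROMAN_TO_ARABIC:
                out.add(head + _ROMAN_TO_ARABIC[low])
            elif tail in _ARABIC_TO_ROMAN and int(tail) <= 4:
                # higher numerals are rarely written as Roman in practice
                out.add(head + _ARABIC_TO_ROMAN[tail].upper())
    for short, long in rules.acronym_pairs:
        m = re.match(rf"^{re.escape(short)}([^A-Za-z].*|\d.*)?$", text)
        if m:
            out.add(long + (m.group(1) or ""))
        m = re.match(rf"^{re.escape(long)}([^A-Za-z].*|\d.*)?$", text,
                     re.IGNORECASE)
        if m:
            out.add(short + (m.group(1) or ""))
    if rules.fold_case:
        out.add(text.lower())
    out.discard(text)
    out.discard("")
    return out


def expand_synonyms(entry: LexiconEntry,
                    rules: ExpansionRules | None = None) -> LexiconEntry:
    """Add generated spelling variants / acronym long forms to ``entry``.

    Computes the closure of the transforms, so a second application adds
    nothing (idempotent).  Originals are untouched; generated variants
    carry the ``generated`` flag.
    """
    if rules is None:
        rules = default_expansion_rules()
    frontier = [s.text for s in entry.synonyms.values()]
    seen = set(entry.synonyms)
    while frontier:
        nxt: list[str] = []
        for text in frontier:
            for variant in _variants_of(text, rules):
                if variant not in seen:
                    seen.add(variant)
                    entry.add(variant, generated=True)
                    nxt.append(variant)
        frontier = nxt
    return entry


def expand_all(lexicon: Lexicon, rules: ExpansionRules | None = None,
               entity_types: Sequence[str] = ("gene", "protein")) -> Lexicon:
    if rules is None:
        rules = default_expansion_rules()
    for entry in lexicon:
        if entry.entity_type in entity_types:
            expand_synonyms(entry, rules)
    lexicon.refresh_ambiguity()
    return lexicon


# ---------------------------------------------------------------------------
# curation

def load_stoplist(stream: IO[str]) -> frozenset[str]:
    return frozenset(line.strip() for line in stream if line.strip())


def default_stoplists() -> tuple[frozenset[str], frozenset[str]]:
    lists = []
    for name in ("stoplist_english.txt", "stoplist_abbrev.txt"):
        with resources.files("mirtext.data").joinpath(name).open(
                encoding="utf-8") as fh:
            lists.append(load_stoplist(fh))
    return tuple(lists)


def curate(lexicon: Lexicon,
           stoplists: Iterable[frozenset[str]] | None = None) -> Lexicon:
    """Flag stoplisted synonyms as curated-out (case-sensitive terms).

    Entities left with zero retained synonyms are kept but become inert
    for matching.  Removal counts are logged and recorded on the lexicon.
    """
    if stoplists is None:
        stoplists = default_stoplists()
    stop: set[str] = set()
    for s in stoplists:
        stop.update(s)
    removed = 0
    for entry in lexicon:
        for syn in entry.synonyms.values():
            if syn.text in stop and not syn.curated_out:
                syn.curated_out = True
                removed += 1
    lexicon.curated_out_count += removed
    if removed:
        logger.info("curate: removed %d stoplisted synonyms", removed)
    lexicon.refresh_ambiguity()
    return lexicon


# ---------------------------------------------------------------------------
# relation-keyword lexicon

class RelationKeywordError(ValueError):
    pass


class RelationLexicon:
    """Keywords for the five miRNA-gene association types.

    Matching is case-insensitive and whole-word (multi-word keywords
    allowed).
    """

    def __init__(self, mapping: dict[str, set[str]]):
        unknown = set(mapping) - set(RELATION_TYPES)
        if unknown:
            raise RelationKeywordError(
                f"unknown relation types: {sorted(unknown)}")
        self._mapping = {t: frozenset(mapping.get(t, ())) for t in RELATION_TYPES}
        self._by_keyword: dict[str, set[str]] = {}
        for rtype, kws in self._mapping.items():
            for kw in kws:
                self._by_keyword.setdefault(kw.lower(), set()).add(rtype)
        pattern = "|".join(
            re.escape(k) for k in sorted(self._by_keyword, key=len,
                                         reverse=True))
        self._regex = re.compile(rf"\b(?:{pattern})\b", re.IGNORECASE) \
            if pattern else None

    @property
    def types(self) -> tuple[str, ...]:
        return RELATION_TYPES

    def keywords(self, relation_type: str) -> frozenset[str]:
        return self._mapping[relation_type]

    def total_keywords(self) -> int:
        return sum(len(v) for v in self._mapping.values())

    def matches(self, text: str) -> list[tuple[tuple[int, int], str, frozenset[str]]]:
        """All keyword hits: ((start, end), keyword, types)."""
        if self._regex is None:
            return []
        out = []
        for m in self._regex.finditer(text):
            kw = m.group(0).lower()
            out.append(((m.start(), m.end()), m.group(0),
                        frozenset(self._by_keyword[kw])))
        return out

    def types_in(self, text: str) -> frozenset[str]:
        types: set[str] = set()
        for _, _, t in self.matches(text):
            types |= t
        return frozenset(types)


def load_relation_keywords(stream: IO[str]) -> RelationLexicon:
    """Read "type<TAB>keyword" lines into a :class:`RelationLexicon`."""
    mapping: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise RelationKeywordError(
                f"line {lineno}: expected 'type<TAB>keyword', got {line!r}")
        rtype, keyword = parts[0].strip(), parts[1].strip()
        if rtype not in RELATION_TYPES:
            raise RelationKeywordError(
                f"line {lineno}: unknown relation type {rtype!r}")
        if not keyword:
            raise RelationKeywordError(f"line {lineno}: empty keyword")
        mapping.setdefault(rtype, set()).add(keyword)
    return RelationLexicon(mapping)


def default_relation_lexicon() -> RelationLexicon:
    with resources.files("mirtext.data").joinpath(
            "relation_keywords.txt").open(encoding="utf-8") as fh:
        return load_relation_keywords(fh)


def _bundled_lexicon(filename: str) -> Lexicon:
    with resources.files("mirtext.data").joinpath(filename).open(
            encoding="utf-8") as fh:
        return build_lexicon([read_synonym_tsv(fh)])


def bundled_taxa() -> Lexicon:
    """Small default taxonomy dictionary (species codes + common names)."""
    return _bundled_lexicon("taxa.tsv")


def bundled_tissues() -> Lexicon:
    """Small default tissue / cell-line dictionary for disambiguation."""
    return _bundled_lexicon("tissues.tsv")
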