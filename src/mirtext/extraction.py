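"""miRNA-gene pair extraction, relation typing and the six result filters.

A *co-occurrence pair* is a miRNA and a gene mentioned in the same
scope: every distinct pair in a document yields an abstract-level
association, and each sentence containing both yields an additional
sentence-level association (sentence-level pairs are therefore always a
subset of abstract-level pairs).  A *tri-occurrence* of a miRNA, a
relation keyword and a gene in one sentence assigns the keyword's
association type(s); no word-distance or syntactic constraint is
imposed beyond sharing the sentence, and negation is not interpreted.

Six independent, AND-combined filters mirror the result filters of the
mining pipeline: strictness, single-sentence, relation-type, taxonomy
(organism tri-occurrence), unambiguous gene synonym, and cross-database
confirmation against user-supplied reference tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

from .corpus import Document
from .lexicon import RELATION_TYPES, RelationLexicon
from .ner import Match, Matcher, resolve_context, scan, suppress_mirna_overlaps
from .nomenclature import (MirnaIdentifier, MirnaParse, MirnaSynonymTable,
                           find_mirna_mentions, normalize_mirna,
                           parse_mirna_name)

__all__ = [
    "MirnaMention",
    "Evidence",
    "Association",
    "FilterConfig",
    "mirna_mentions_for",
    "extract_pairs",
    "type_relations",
    "confirm_taxonomy",
    "apply_filters",
    "annotate_crossrefs",
    "read_crossrefs",
    "process_document",
    "aggregate",
    "write_associations_tsv",
    "read_associations_tsv",
    "write_aggregate_tsv",
    "read_aggregate_tsv",
    "to_dot",
]

EVIDENCE_SENTENCE = "sentence"
EVIDENCE_ABSTRACT = "abstract"


@dataclass(frozen=True)
class MirnaMention:
    """A grammar hit in a document, with its normalised identity."""

    span: tuple[int, int]
    raw: str
    parse: MirnaParse
    identifier: MirnaIdentifier


@dataclass(frozen=True, order=True)
class Evidence:
    pmid: str
    sentence_index: int | None
    mirna_span: tuple[int, int]
    gene_span: tuple[int, int]
    strict: bool


@dataclass
class Association:
    """One miRNA-gene pair at sentence or abstract evidence level."""

    mirna: MirnaIdentifier
    gene: str
    pmid: str
    evidence_level: str
    sentence_index: int | None = None
    relation_types: set[str] = field(default_factory=set)
    taxonomy_confirmed: bool = False
    gene_ambiguous: bool = False
    strict_evidence: bool = False
    crossref_sources: set[str] = field(default_factory=set)
    evidence: list[Evidence] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.pmid, self.mirna.canonical_name, self.gene,
                self.evidence_level,
                -1 if self.sentence_index is None else self.sentence_index)


def mirna_mentions_for(doc: Document,
                       species_context: Iterable[str] = (),
                       known_names: MirnaSynonymTable | None = None,
                       ) -> list[MirnaMention]:
    """Grammar mentions of a document, parsed and normalised."""
    out = []
    for span, raw in find_mirna_mentions(doc.text):
        parse = parse_mirna_name(raw)
        ident = normalize_mirna(parse, species_context, known_names)
        out.append(MirnaMention(span, raw, parse, ident))
    return out


def extract_pairs(doc: Document,
                  mirna_mentions: Sequence[MirnaMention],
                  gene_matches: Sequence[Match]) -> list[Association]:
    """Co-occurrence pairs of one document at both evidence levels.

    Suppressed matches never contribute.  An ambiguous gene hit yields
    one association per candidate entity, each flagged
    ``gene_ambiguous`` so the gene-synonym filter can drop it later.
    """
    genes = [m for m in gene_matches
             if not m.suppressed and m.entity_type in ("gene", "protein")]
    assocs: dict[tuple, Association] = {}

    def record(mirna: MirnaMention, gene_match: Match, entity_id: str,
               level: str, sentence_index: int | None) -> None:
        a = Association(mirna=mirna.identifier, gene=entity_id, pmid=doc.pmid,
                        evidence_level=level, sentence_index=sentence_index)
        a = assocs.setdefault(a.key(), a)
        ev = Evidence(doc.pmid, sentence_index, mirna.span, gene_match.span,
                      strict=gene_match.strict)
        if ev not in a.evidence:
            a.evidence.append(ev)
        a.gene_ambiguous = a.gene_ambiguous or gene_match.ambiguous
        a.strict_evidence = a.strict_evidence or ev.strict

    for mm in mirna_mentions:
        for gm in genes:
            for entity_id in gm.entity_ids:
                record(mm, gm, entity_id, EVIDENCE_ABSTRACT, None)

    for i, (s, e) in enumerate(doc.sentences):
        in_sent_m = [m for m in mirna_mentions
                     if s <= m.span[0] and m.span[1] <= e]
        in_sent_g = [g for g in genes if s <= g.span[0] and g.span[1] <= e]
        for mm in in_sent_m:
            for gm in in_sent_g:
                for entity_id in gm.entity_ids:
                    record(mm, gm, entity_id, EVIDENCE_SENTENCE, i)

    return sorted(assocs.values(), key=lambda a: a.key())


def type_relations(assoc: Association, doc: Document,
                   relation_lexicon: RelationLexicon) -> Association:
    """Assign association types from keywords sharing the sentence.

    Multiple keywords contribute the union of their types; a sentence
    without any keyword leaves the pair untyped but reported.
    """
    if assoc.evidence_level != EVIDENCE_SENTENCE:
        raise ValueError("relation typing applies to sentence-level evidence")
    text = doc.sentence_text(assoc.sentence_index)
    assoc.relation_types |= relation_lexicon.types_in(text)
    return assoc


def confirm_taxonomy(assoc: Association, doc: Document,
                     taxon_matches: Sequence[Match]) -> Association:
    """Organism tri-occurrence: the association's species must itself be
    mentioned somewhere in the same document (abstract scope)."""
    doc_species = {c.species for m in taxon_matches for c in m.candidates
                   if not m.suppressed}
    assoc.taxonomy_confirmed = (assoc.mirna.species != "unspecified"
                                and assoc.mirna.species in doc_species)
    return assoc


def read_crossrefs(stream: IO[str]) -> dict[tuple[str, str], set[str]]:
    """Cross-reference TSV: mirna_canonical<TAB>gene_id<TAB>source_label."""
    out: dict[tuple[str, str], set[str]] = {}
    for row in csv.reader(stream, delimiter="\t"):
        if not row:
            continue
        if len(row) != 3:
            raise ValueError(f"crossref rows need 3 columns, got {row!r}")
        out.setdefault((row[0].casefold(), row[1]), set()).add(row[2])
    return out


def annotate_crossrefs(associations: Iterable[Association],
                       crossrefs: dict[tuple[str, str], set[str]],
                       ) -> list[Association]:
    out = []
    for a in associations:
        a.crossref_sources |= crossrefs.get(
            (a.mirna.canonical_name.casefold(), a.gene), set())
        out.append(a)
    return out


@dataclass(frozen=True)
class FilterConfig:
    """Switches for the six result filters (all off = identity)."""

    strictness: bool = False
    single_sentence: bool = False
    relation_type: str | None = None
    taxonomy: bool = False
    unambiguous_gene: bool = False
    database: bool = False

    def __post_init__(self) -> None:
        if (self.relation_type is not None
                and self.relation_type not in RELATION_TYPES):
            raise ValueError(
                f"unknown relation type: {self.relation_type!r}")


def apply_filters(associations: Iterable[Association],
                  config: FilterConfig,
                  crossrefs: dict[tuple[str, str], set[str]] | None = None,
                  ) -> list[Association]:
    """AND-combine the active filter predicates; contractive for every
    configuration and independent of application order."""
    assocs = list(associations)
    if config.database:
        if not crossrefs:
            raise ValueError(
                "database filter requires loaded cross-reference tables")
        assocs = annotate_crossrefs(assocs, crossrefs)
    out = []
    for a in assocs:
        if config.strictness and not a.strict_evidence:
            continue
        if config.single_sentence and a.evidence_level != EVIDENCE_SENTENCE:
            continue
        if (config.relation_type is not None
                and config.relation_type not in a.relation_types):
            continue
        if config.taxonomy and not a.taxonomy_confirmed:
            continue
        if config.unambiguous_gene and a.gene_ambiguous:
            continue
        if config.database and not a.crossref_sources:
            continue
        out.append(a)
    return out


def process_document(doc: Document,
                     gene_matcher: Matcher,
                     relation_lexicon: RelationLexicon,
                     tissue_matcher: Matcher | None = None,
                     taxon_matcher: Matcher | None = None,
                     known_names: MirnaSynonymTable | None = None,
                     ) -> list[Association]:
    """Full per-document pipeline: NER, context resolution, pairing,
    relation typing, taxonomy confirmation.

    Abstract-level pairs inherit the union of the relation types of
    their sentence-level evidence, if any.
    """
    mirna_spans = [span for span, _ in find_mirna_mentions(doc.text)]
    taxon_matches = scan(taxon_matcher, doc) if taxon_matcher else []
    taxon_matches = suppress_mirna_overlaps(taxon_matches, mirna_spans)
    species_context = {c.species for m in taxon_matches
                       for c in m.candidates if not m.suppressed}
    mentions = mirna_mentions_for(doc, species_context, known_names)
    matches = scan(gene_matcher, doc)
    matches = suppress_mirna_overlaps(matches, mirna_spans)
    matches = resolve_context(matches, doc, tissue_matcher,
                              taxon_matches=taxon_matches)
    assocs = extract_pairs(doc, mentions, matches)
    by_pair_types: dict[tuple[str, str], set[str]] = {}
    for a in assocs:
        if a.evidence_level == EVIDENCE_SENTENCE:
            type_relations(a, doc, relation_lexicon)
            key = (a.mirna.canonical_name, a.gene)
            by_pair_types.setdefault(key, set()).update(a.relation_types)
    for a in assocs:
        if a.evidence_level == EVIDENCE_ABSTRACT:
            a.relation_types |= by_pair_types.get(
                (a.mirna.canonical_name, a.gene), set())
        confirm_taxonomy(a, doc, taxon_matches)
    return assocs


# ---------------------------------------------------------------------------
# serialization

_ASSOC_HEADER = [
    "pmid", "mirna", "mirna_level", "mirna_species", "gene",
    "evidence_level", "sentence_index", "mirna_start", "mirna_end",
    "gene_start", "gene_end", "relation_types", "taxonomy_confirmed",
    "gene_ambiguous", "strict", "crossref_sources",
]


def write_associations_tsv(associations: Iterable[Association],
                           stream: IO[str]) -> None:
    """One row per evidence record; lossless for re-import."""
    stream.write("\t".join(_ASSOC_HEADER) + "\n")
    for a in sorted(associations, key=lambda a: a.key()):
        for ev in sorted(a.evidence, key=lambda e: (e.mirna_span, e.gene_span)):
            stream.write("\t".join([
                a.pmid, a.mirna.canonical_name, a.mirna.level,
                a.mirna.species, a.gene, a.evidence_level,
                "" if a.sentence_index is None else str(a.sentence_index),
                str(ev.mirna_span[0]), str(ev.mirna_span[1]),
                str(ev.gene_span[0]), str(ev.gene_span[1]),
                ",".join(sorted(a.relation_types)),
                str(int(a.taxonomy_confirmed)), str(int(a.gene_ambiguous)),
                str(int(ev.strict)),
                ",".join(sorted(a.crossref_sources)),
            ]) + "\n")


def read_associations_tsv(stream: IO[str]) -> list[Association]:
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header != _ASSOC_HEADER:
        raise ValueError("not an association TSV (unexpected header)")
    assocs: dict[tuple, Association] = {}
    for row in reader:
        rec = dict(zip(_ASSOC_HEADER, row))
        ident = MirnaIdentifier(rec["mirna"], rec["mirna_level"],
                                rec["mirna_species"])
        a = Association(
            mirna=ident, gene=rec["gene"], pmid=rec["pmid"],
            evidence_level=rec["evidence_level"],
            sentence_index=(None if rec["sentence_index"] == ""
                            else int(rec["sentence_index"])))
        a = assocs.setdefault(a.key(), a)
        a.relation_types |= set(filter(None, rec["relation_types"].split(",")))
        a.taxonomy_confirmed = rec["taxonomy_confirmed"] == "1"
        a.gene_ambiguous = rec["gene_ambiguous"] == "1"
        a.crossref_sources |= set(
            filter(None, rec["crossref_sources"].split(",")))
        ev = Evidence(rec["pmid"], a.sentence_index,
                      (int(rec["mirna_start"]), int(rec["mirna_end"])),
                      (int(rec["gene_start"]), int(rec["gene_end"])),
                      strict=rec["strict"] == "1")
        if ev not in a.evidence:
            a.evidence.append(ev)
        a.strict_evidence = a.strict_evidence or ev.strict
    return sorted(assocs.values(), key=lambda a: a.key())


@dataclass(frozen=True)
class AggregateRow:
    mirna: str
    gene: str
    n_pmids: int
    n_sentence_evidence: int
    pmids: tuple[str, ...]
    relation_types: tuple[str, ...]
    taxonomy_confirmed: bool
    gene_ambiguous: bool
    strict_evidence: bool
    crossref_sources: tuple[str, ...]


def aggregate(associations: Iterable[Association]) -> list[AggregateRow]:
    """Collapse associations to one row per (mirna, gene) pair.

    Evidence is counted once per (mirna, gene, pmid, sentence).
    """
    groups: dict[tuple[str, str], list[Association]] = {}
    for a in associations:
        groups.setdefault((a.mirna.canonical_name, a.gene), []).append(a)
    rows = []
    for (mirna, gene), group in sorted(groups.items()):
        pmids = tuple(sorted({a.pmid for a in group}))
        sent_ev = {(a.pmid, a.sentence_index) for a in group
                   if a.evidence_level == EVIDENCE_SENTENCE}
        types: set[str] = set()
        xrefs: set[str] = set()
        for a in group:
            types |= a.relation_types
            xrefs |= a.crossref_sources
        rows.append(AggregateRow(
            mirna=mirna, gene=gene, n_pmids=len(pmids),
            n_sentence_evidence=len(sent_ev), pmids=pmids,
            relation_types=tuple(sorted(types)),
            taxonomy_confirmed=any(a.taxonomy_confirmed for a in group),
            gene_ambiguous=any(a.gene_ambiguous for a in group),
            strict_evidence=any(a.strict_evidence for a in group),
            crossref_sources=tuple(sorted(xrefs))))
    return rows


_AGG_HEADER = ["mirna", "gene", "n_pmids", "n_sentence_evidence", "pmids",
               "relation_types", "taxonomy_confirmed", "gene_ambiguous",
               "strict_evidence", "crossref_sources"]


def write_aggregate_tsv(rows: Iterable[AggregateRow], stream: IO[str]) -> None:
    stream.write("\t".join(_AGG_HEADER) + "\n")
    for r in rows:
        stream.write("\t".join([
            r.mirna, r.gene, str(r.n_pmids), str(r.n_sentence_evidence),
            ",".join(r.pmids), ",".join(r.relation_types),
            str(int(r.taxonomy_confirmed)), str(int(r.gene_ambiguous)),
            str(int(r.strict_evidence)), ",".join(r.crossref_sources),
        ]) + "\n")


def read_aggregate_tsv(stream: IO[str]) -> list[AggregateRow]:
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header != _AGG_HEADER:
        raise ValueError("not an aggregate TSV (unexpected header)")
    rows = []
    for row in reader:
        rec = dict(zip(_AGG_HEADER, row))
        rows.append(AggregateRow(
            mirna=rec["mirna"], gene=rec["gene"],
            n_pmids=int(rec["n_pmids"]),
            n_sentence_evidence=int(rec["n_sentence_evidence"]),
            pmids=tuple(filter(None, rec["pmids"].split(","))),
            relation_types=tuple(
                filter(None, rec["relation_types"].split(","))),
            taxonomy_confirmed=rec["taxonomy_confirmed"] == "1",
            gene_ambiguous=rec["gene_ambiguous"] == "1",
            strict_evidence=rec["strict_evidence"] == "1",
            crossref_sources=tuple(
                filter(None, rec["crossref_sources"].split(",")))))
    return rows


def to_dot(rows: Iterable[AggregateRow]) -> str:
    """Bipartite miRNA/gene interaction graph in DOT syntax.

    Edges carry the relation types and the distinct-sentence evidence
    count; node and edge order is sorted, so output is deterministic.
    """
    rows = sorted(rows, key=lambda r: (r.mirna, r.gene))
    mirnas = sorted({r.mirna for r in rows})
    genes = sorted({r.gene for r in rows})
    lines = ["graph mirna_gene {"]
    for m in mirnas:
        lines.append(f'  "mirna:{m}" [label="{m}", shape=ellipse];')
    for g in genes:
        lines.append(f'  "gene:{g}" [label="{g}", shape=box];')
    for r in rows:
        label = ",".join(r.relation_types) or "co-occurrence"
        lines.append(
            f'  "mirna:{r.mirna}" -- "gene:{r.gene}" '
            f'[label="{label} ({r.n_sentence_evidence})"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
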