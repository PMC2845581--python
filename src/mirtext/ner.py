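"""Multi-pattern dictionary matching over abstracts.

Synonyms from the curated lexicon are compiled into an Aho-Corasick
automaton over a normalized token stream, so one pass over a document
finds every dictionary occurrence.  Matching is *tolerant* — case and
hyphen/space/fused separator variation are ignored — and every hit is
additionally annotated ``strict`` when the text equals a dictionary
synonym byte for byte (the strictness filter later keeps only those).

Overlapping hits of one entity type are resolved longest-match-first,
ties by leftmost start, then by lexicographically smallest entity id.
Context resolution implements exactly two documented mechanisms: a
gene/protein hit overlapping a tissue/cell-line hit is suppressed, and
hits ambiguous across species are narrowed to the species actually
mentioned in the document (taxonomy hits).  miRNA mentions come from
the nomenclature grammar, never from this automaton; gene hits that
overlap a miRNA mention (e.g. host-gene symbols) are suppressed.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from ._text import SEP, norm_key, tokenize
from .corpus import Document
from .lexicon import Lexicon

__all__ = [
    "AhoCorasick",
    "Candidate",
    "Match",
    "Matcher",
    "compile_matcher",
    "scan",
    "resolve_context",
    "suppress_mirna_overlaps",
    "write_matches_tsv",
]


class AhoCorasick:
    """Classic Aho-Corasick automaton: single pass, all occurrences.

    Construction is linear in total pattern length; matching is linear
    in text length plus the number of reported occurrences.
    """

    def __init__(self) -> None:
        self._goto: list[dict[str, int]] = [{}]
        self._fail: list[int] = [0]
        self._out: list[list[str]] = [[]]
        self._built = False

    def add(self, pattern: str) -> None:
        if self._built:
            raise RuntimeError("automaton already built")
        if not pattern:
            raise ValueError("empty pattern")
        node = 0
        for ch in pattern:
            nxt = self._goto[node].get(ch)
            if nxt is None:
                nxt = len(self._goto)
                self._goto.append({})
                self._fail.append(0)
                self._out.append([])
                self._goto[node][ch] = nxt
            node = nxt
        self._out[node].append(pattern)

    def build(self) -> None:
        queue: deque[int] = deque()
        for child in self._goto[0].values():
            self._fail[child] = 0
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self._goto[node].items():
                queue.append(child)
                state = self._fail[node]
                while state and ch not in self._goto[state]:
                    state = self._fail[state]
                self._fail[child] = self._goto[state].get(ch, 0) \
                    if self._goto[state].get(ch, 0) != child else 0
                self._out[child] = self._out[child] + self._out[self._fail[child]]
        self._built = True

    def iter_matches(self, text: str) -> Iterator[tuple[int, str]]:
        """Yield (end_index_inclusive, pattern) for every occurrence."""
        if not self._built:
            raise RuntimeError("call build() first")
        state = 0
        for i, ch in enumerate(text):
            while state and ch not in self._goto[state]:
                state = self._fail[state]
            state = self._goto[state].get(ch, 0)
            for pattern in self._out[state]:
                yield i, pattern


@dataclass(frozen=True)
class Candidate:
    entity_id: str
    species: str
    synonym: str


@dataclass
class Match:
    """One dictionary hit in ``Document.text`` (0-based, half-open)."""

    span: tuple[int, int]
    matched_text: str
    entity_type: str
    candidates: tuple[Candidate, ...]
    strict: bool
    ambiguous: bool
    suppressed: bool = False
    reason: str | None = None

    @property
    def entity_ids(self) -> tuple[str, ...]:
        return tuple(sorted({c.entity_id for c in self.candidates}))

    def overlaps(self, span: tuple[int, int]) -> bool:
        return self.span[0] < span[1] and span[0] < self.span[1]


@dataclass
class Matcher:
    """Compiled dictionary: automaton plus per-pattern candidate lists."""

    automaton: AhoCorasick
    candidates: dict[str, list[tuple[str, Candidate]]]  # key -> (etype, cand)

    @property
    def n_patterns(self) -> int:
        return len(self.candidates)


def compile_matcher(lexicon: Lexicon | None,
                    entity_types: Sequence[str] | None = None) -> Matcher:
    """Build the multi-pattern automaton from the retained synonyms.

    An empty lexicon yields a valid matcher that never matches.
    """
    ac = AhoCorasick()
    table: dict[str, list[tuple[str, Candidate]]] = {}
    if lexicon is not None:
        for entry in lexicon:
            if entity_types and entry.entity_type not in entity_types:
                continue
            for syn in entry.retained_synonyms():
                key = norm_key(syn.text)
                if not key:
                    continue
                if key not in table:
                    table[key] = []
                    ac.add(key)
                table[key].append(
                    (entry.entity_type,
                     Candidate(entry.entity_id, entry.species, syn.text)))
    ac.build()
    return Matcher(automaton=ac, candidates=table)


_TOLERANT_GAPS = ("", "-", " ")


def _raw_hits(matcher: Matcher, doc: Document) -> list[
        tuple[tuple[int, int], str, list[tuple[str, Candidate]]]]:
    tokens = tokenize(doc.text)
    if not tokens:
        return []
    text_norm = SEP.join(tok for _, _, tok in tokens)
    # token index for each normalized position
    tok_at: list[int] = []
    for i, (_, _, tok) in enumerate(tokens):
        if i:
            tok_at.append(-1)  # separator slot
        tok_at.extend([i] * len(tok))
    hits = []
    for end, pattern in matcher.automaton.iter_matches(text_norm):
        start = end - len(pattern) + 1
        if start > 0 and text_norm[start - 1] != SEP:
            continue
        if end < len(text_norm) - 1 and text_norm[end + 1] != SEP:
            continue
        ti, tj = tok_at[start], tok_at[end]
        span = (tokens[ti][0], tokens[tj][1])
        matched_text = doc.text[span[0]:span[1]]
        # tolerant variation covers hyphen/space/fused separators only,
        # unless the surface text equals the synonym exactly
        gaps_ok = all(doc.text[tokens[k][1]:tokens[k + 1][0]] in _TOLERANT_GAPS
                      for k in range(ti, tj))
        pairs = []
        for etype, cand in matcher.candidates[pattern]:
            exact = matched_text == cand.synonym
            if not exact:
                if not gaps_ok:
                    continue
                if len(cand.synonym) <= 2:
                    continue  # short synonyms match in strict mode only
            pairs.append((etype, cand))
        if pairs:
            hits.append((span, matched_text, pairs))
    return hits


def scan(matcher: Matcher, doc: Document) -> list[Match]:
    """All dictionary occurrences in ``doc`` at word boundaries.

    Deterministic: repeated scans of the same document are identical.
    """
    merged: dict[tuple[tuple[int, int], str], dict] = {}
    for span, matched_text, pairs in _raw_hits(matcher, doc):
        for etype, cand in pairs:
            slot = merged.setdefault((span, etype), {
                "matched_text": matched_text, "cands": {}, "strict": False})
            slot["cands"][(cand.entity_id, cand.species)] = cand
            if matched_text == cand.synonym:
                slot["strict"] = True

    candidates_list: list[Match] = []
    for (span, etype), slot in merged.items():
        cands = tuple(sorted(slot["cands"].values(),
                             key=lambda c: (c.entity_id, c.species)))
        candidates_list.append(Match(
            span=span, matched_text=slot["matched_text"], entity_type=etype,
            candidates=cands, strict=slot["strict"],
            ambiguous=len({c.entity_id for c in cands}) > 1))

    # longest match first, ties leftmost, then smallest entity id;
    # retained matches of one entity type never overlap
    candidates_list.sort(key=lambda m: (-(m.span[1] - m.span[0]), m.span[0],
                                        m.entity_ids[0], m.entity_type))
    kept: list[Match] = []
    by_type: dict[str, list[Match]] = {}
    for m in candidates_list:
        if any(m.overlaps(k.span) for k in by_type.get(m.entity_type, ())):
            continue
        by_type.setdefault(m.entity_type, []).append(m)
        kept.append(m)
    kept.sort(key=lambda m: (m.span, m.entity_type))
    return kept


def resolve_context(matches: Sequence[Match], doc: Document,
                    tissue_matcher: Matcher | None = None,
                    taxon_matcher: Matcher | None = None,
                    taxon_matches: Sequence[Match] | None = None,
                    ) -> list[Match]:
    """Contextual disambiguation of gene/protein matches.

    Never adds matches: gene/protein hits overlapping a tissue or
    cell-line hit are suppressed (reason ``tissue-overlap``), and hits
    whose candidates span several species are narrowed to the species
    mentioned in the document.  Remaining multi-candidate hits keep
    ``ambiguous=True``.
    """
    tissue_matches: list[Match] = []
    if tissue_matcher is not None:
        tissue_matches = scan(tissue_matcher, doc)
    if taxon_matches is None:
        taxon_matches = scan(taxon_matcher, doc) if taxon_matcher else []
    doc_species = {c.species for m in taxon_matches for c in m.candidates
                   if not m.suppressed}

    out: list[Match] = []
    for m in matches:
        if m.entity_type not in ("gene", "protein") or m.suppressed:
            out.append(m)
            continue
        if any(m.overlaps(t.span) for t in tissue_matches):
            out.append(replace(m, suppressed=True, reason="tissue-overlap"))
            continue
        cand_species = {c.species for c in m.candidates}
        if len(cand_species) > 1 and doc_species:
            narrowed = tuple(c for c in m.candidates
                             if c.species in doc_species or c.species == "any")
            if narrowed and len(narrowed) < len(m.candidates):
                m = replace(m, candidates=narrowed,
                            ambiguous=len({c.entity_id for c in narrowed}) > 1)
        out.append(m)
    return out


def suppress_mirna_overlaps(matches: Sequence[Match],
                            mirna_spans: Iterable[tuple[int, int]],
                            ) -> list[Match]:
    """The grammar channel wins: a dictionary hit overlapping a miRNA
    mention is suppressed — a gene hit on a miRNA host-gene symbol as
    well as a taxon hit on the species prefix inside a miRNA name."""
    spans = list(mirna_spans)
    out: list[Match] = []
    for m in matches:
        if (not m.suppressed and any(m.overlaps(s) for s in spans)):
            m = replace(m, suppressed=True, reason="mirna-overlap")
        out.append(m)
    return out


def write_matches_tsv(pmid: str, matches: Iterable[Match],
                      stream: IO[str], header: bool = False) -> None:
    if header:
        stream.write("pmid\tstart\tend\tmatched_text\tentity_type\t"
                     "entity_ids\tstrict\tambiguous\tsuppressed\treason\n")
    for m in matches:
        stream.write("\t".join([
            pmid, str(m.span[0]), str(m.span[1]), m.matched_text,
            m.entity_type, ",".join(m.entity_ids),
            str(int(m.strict)), str(int(m.ambiguous)),
            str(int(m.suppressed)), m.reason or "",
        ]) + "\n")
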