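"""Abstract records and offset-faithful sentence segmentation.

A :class:`Document` carries one unified text (title + ``"\\n"`` +
abstract) over which every downstream span — miRNA mentions, dictionary
matches, sentence intervals — is expressed as 0-based half-open
character offsets.  The title counts as the first sentence, since both
titles and abstracts are mined.

Readers accept PubMed/MEDLINE article XML (streaming) and a simple
``pmid<TAB>title<TAB>abstract`` TSV.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Iterator

from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "read_abstracts",
    "load_corpus",
    "split_sentences",
    "write_corpus_tsv",
]


def _load_abbreviations() -> frozenset[str]:
    with resources.files("mirtext.data").joinpath(
            "sentence_abbreviations.txt").open(encoding="utf-8") as fh:
        return frozenset(line.strip() for line in fh if line.strip())


_ABBREVIATIONS = _load_abbreviations()

# sentence-final punctuation followed by whitespace and an upper-case
# letter or digit; decimal points never qualify (no whitespace follows)
_BOUNDARY_RE = re.compile(r"([.!?]+)(\s+)(?=[A-Z0-9])")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Rule-based sentence intervals over ``text``.

    Splits at ``.!?`` + whitespace + uppercase/digit, unless the word
    before the period is a known abbreviation ("et al.", "Fig.",
    "i.e." ...) or a single initial.  Deterministic; returns half-open
    char intervals excluding inter-sentence whitespace.
    """
    if not text.strip():
        return []
    cuts: list[tuple[int, int]] = []  # (sentence_end, next_start)
    for m in _BOUNDARY_RE.finditer(text):
        before = text[:m.start()]
        word = re.search(r"(\S+)$", before)
        token = word.group(1) if word else ""
        token = token.rstrip(".").lstrip("([\"'")
        if token in _ABBREVIATIONS or re.fullmatch(r"[A-Z]", token):
            continue
        # multi-word abbreviations such as "et al"
        tail2 = " ".join(before.split()[-2:]).rstrip(".")
        if tail2 in _ABBREVIATIONS:
            continue
        cuts.append((m.end(1), m.end(2)))
    spans: list[tuple[int, int]] = []
    start = 0
    for end, nxt in cuts:
        spans.append((start, end))
        start = nxt
    # trailing sentence (strip outer whitespace only)
    rest = text[start:]
    if rest.strip():
        lead = len(rest) - len(rest.lstrip())
        spans.append((start + lead, start + len(rest.rstrip())))
    # strip leading whitespace of the first sentence
    if spans:
        s0, e0 = spans[0]
        chunk = text[s0:e0]
        lead = len(chunk) - len(chunk.lstrip())
        spans[0] = (s0 + lead, e0)
    return spans


@dataclass
class Document:
    """One abstract record with pre-computed sentence intervals."""

    pmid: str
    title: str
    abstract: str = ""
    text: str = field(init=False)
    sentences: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("Document requires a non-empty pmid")
        self.text = (self.title + "\n" + self.abstract if self.abstract
                     else self.title)
        # the title is sentence 0
        spans: list[tuple[int, int]] = [(0, len(self.title))] \
            if self.title.strip() else []
        offset = len(self.title) + 1
        for s, e in split_sentences(self.abstract):
            spans.append((s + offset, e + offset))
        self.sentences = spans

    def sentence_index(self, span: tuple[int, int]) -> int | None:
        """Index of the sentence fully containing ``span``, else None."""
        for i, (s, e) in enumerate(self.sentences):
            if s <= span[0] and span[1] <= e:
                return i
        return None

    def sentence_text(self, index: int) -> str:
        s, e = self.sentences[index]
        return self.text[s:e]


def _xml_documents(stream: IO[bytes] | IO[str]) -> Iterator[Document]:
    index = 0
    try:
        for _, elem in etree.iterparse(stream, tag="PubmedArticle"):
            index += 1
            pmid = elem.findtext(".//PMID") or ""
            title = elem.findtext(".//ArticleTitle") or ""
            parts = [t.text or "" for t in elem.iter("AbstractText")]
            abstract = " ".join(p for p in parts if p)
            yield Document(pmid=pmid.strip(), title=title.strip(),
                           abstract=abstract.strip())
            elem.clear()
    except etree.XMLSyntaxError as exc:
        raise ValueError(
            f"malformed MEDLINE XML near record {index + 1}: {exc}") from exc


def _tsv_documents(stream: IO[str]) -> Iterator[Document]:
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(
                f"corpus TSV line {lineno}: expected pmid<TAB>title[<TAB>abstract]")
        pmid, title = parts[0], parts[1]
        abstract = parts[2] if len(parts) > 2 else ""
        yield Document(pmid=pmid.strip(), title=title, abstract=abstract)


def read_abstracts(stream, format: str = "tsv") -> Iterator[Document]:
    """Stream :class:`Document` objects from a corpus file.

    ``format`` is ``"tsv"`` (pmid<TAB>title<TAB>abstract) or
    ``"medline-xml"`` (PubMed article XML).  Records without an abstract
    yield title-only documents.  Duplicate pmids are logged; last wins
    when materialised through :func:`load_corpus`.
    """
    if format == "tsv":
        docs = _tsv_documents(stream)
    elif format == "medline-xml":
        docs = _xml_documents(stream)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    seen: set[str] = set()
    for doc in docs:
        if doc.pmid in seen:
            logger.warning("duplicate pmid %s: last record wins", doc.pmid)
        seen.add(doc.pmid)
        yield doc


def load_corpus(stream, format: str = "tsv") -> dict[str, Document]:
    """Materialise a corpus as {pmid: Document}, last duplicate winning."""
    out: dict[str, Document] = {}
    for doc in read_abstracts(stream, format=format):
        out[doc.pmid] = doc
    return out


def write_corpus_tsv(documents: Iterable[Document], stream: IO[str]) -> None:
    for doc in documents:
        if "\t" in doc.title or "\t" in doc.abstract:
            raise ValueError("corpus TSV cannot carry embedded tabs")
        stream.write(f"{doc.pmid}\t{doc.title}\t{doc.abstract}\n")
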