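"""Dictionary matcher: automaton correctness, tie rules, context resolution."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirtext._text import norm_key, tokenize
from mirtext.corpus import Document
from mirtext.lexicon import build_lexicon
from mirtext.ner import (AhoCorasick, compile_matcher, resolve_context, scan,
                         suppress_mirna_overlaps)


def _lexicon(*rows):
    return build_lexicon([[list(r) for r in rows]])


def _doc(text):
    return Document(pmid="1", title=text)


# -- independent brute-force oracle ------------------------------------------

def _naive_scan(rows, text):
    """Per-synonym substring search over normalized tokens with the scan
    tie rules: longest first, leftmost, smallest entity id; no overlaps
    within an entity type."""
    tokens = tokenize(text)
    candidates = {}
    for entity_id, etype, species, synonym in rows:
        syn_tokens = norm_key(synonym).split("\x00")
        if syn_tokens == [""]:
            continue
        n = len(syn_tokens)
        for i in range(len(tokens) - n + 1):
            if [t for _, _, t in tokens[i:i + n]] == syn_tokens:
                span = (tokens[i][0], tokens[i + n - 1][1])
                surface = text[span[0]:span[1]]
                exact = surface == synonym
                if not exact:
                    gaps = [text[tokens[k][1]:tokens[k + 1][0]]
                            for k in range(i, i + n - 1)]
                    if any(g not in ("", "-", " ") for g in gaps):
                        continue
                    if len(synonym) <= 2:
                        continue
                candidates.setdefault((span, etype), set()).add(
                    (entity_id, exact))
    flat = []
    for (span, etype), cands in candidates.items():
        ids = sorted({c[0] for c in cands})
        flat.append((span, etype, tuple(ids), any(e for _, e in cands)))
    flat.sort(key=lambda c: (-(c[0][1] - c[0][0]), c[0][0], c[2][0], c[1]))
    kept, by_type = [], {}
    for span, etype, ids, strict in flat:
        if any(span[0] < e and s < span[1]
               for s, e in by_type.get(etype, ())):
            continue
        by_type.setdefault(etype, []).append(span)
        kept.append((span, etype, ids, strict))
    kept.sort(key=lambda c: (c[0], c[1]))
    return kept


def _as_tuples(matches):
    return [(m.span, m.entity_type, m.entity_ids, m.strict) for m in matches]


def test_single_pattern_scan():
    matcher = compile_matcher(_lexicon(("7157", "gene", "hsa", "p53")))
    matches = scan(matcher, _doc("The p53 pathway was active."))
    assert len(matches) == 1
    assert matches[0].matched_text == "p53"
    assert matches[0].strict and not matches[0].ambiguous


def test_empty_lexicon_never_matches():
    matcher = compile_matcher(_lexicon())
    assert scan(matcher, _doc("p53 and anything else")) == []


def test_longest_match_wins():
    matcher = compile_matcher(_lexicon(
        ("3569", "gene", "hsa", "Interleukin-6"),
        ("9999", "gene", "hsa", "Interleukin"),
    ))
    matches = scan(matcher, _doc("Interleukin-6 induces growth."))
    assert [m.matched_text for m in matches] == ["Interleukin-6"]
    assert matches[0].entity_ids == ("3569",)


def test_case_variation_matches_tolerantly():
    matcher = compile_matcher(_lexicon(("3569", "gene", "hsa",
                                        "Interleukin-6")))
    strict = scan(matcher, _doc("Interleukin-6 rose."))[0]
    tolerant = scan(matcher, _doc("interleukin-6 rose."))[0]
    fused = scan(matcher, _doc("Interleukin6 rose."))[0]
    spaced = scan(matcher, _doc("Interleukin 6 rose."))[0]
    assert strict.strict
    assert not tolerant.strict and not fused.strict and not spaced.strict


def test_short_synonyms_match_only_strictly():
    matcher = compile_matcher(_lexicon(("x", "gene", "hsa", "WT")))
    assert scan(matcher, _doc("the WT allele"))
    assert scan(matcher, _doc("the wt allele")) == []


def test_word_boundaries_respected():
    matcher = compile_matcher(_lexicon(("x", "gene", "hsa", "p53")))
    assert scan(matcher, _doc("tp53 is different")) == []
    assert scan(matcher, _doc("(p53) in parentheses"))


def test_scan_matches_bruteforce_oracle_randomized():
    rng = random.Random(17)
    alphabet = ["ab", "abc", "bc", "b", "cab", "ABC", "a-b", "x1"]
    for trial in range(200):
        rows = []
        for i in range(rng.randrange(1, 8)):
            syn = rng.choice(alphabet)
            rows.append((f"e{rng.randrange(5)}", "gene", "any", syn))
        words = [rng.choice(alphabet + ["filler", "zz"])
                 for _ in range(rng.randrange(1, 30))]
        text = " ".join(words)
        doc = _doc(text)
        matcher = compile_matcher(build_lexicon([rows]))
        assert _as_tuples(scan(matcher, doc)) == _naive_scan(rows, text), \
            (trial, rows, text)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_scan_oracle_property(data):
    """Automaton scan is equivalent to naive search with identical
    tie-breaking for arbitrary small lexica and texts."""
    word = st.text(alphabet="abAB1-", min_size=1, max_size=6)
    rows = data.draw(st.lists(
        st.tuples(st.sampled_from(["e1", "e2", "e3"]), st.just("gene"),
                  st.just("any"), word),
        min_size=0, max_size=10))
    rows = [r for r in rows if norm_key(r[3])]
    text = " ".join(data.draw(st.lists(word, min_size=0, max_size=20)))
    doc = Document(pmid="1", title=text) if text.strip() else None
    if doc is None:
        return
    matcher = compile_matcher(build_lexicon([rows]))
    assert _as_tuples(scan(matcher, doc)) == _naive_scan(rows, text)


def test_repeated_scans_identical():
    rows = [("a", "gene", "any", "KRAS"), ("b", "gene", "any", "TP53")]
    matcher = compile_matcher(build_lexicon([rows]))
    doc = _doc("KRAS and TP53 and KRAS again.")
    assert _as_tuples(scan(matcher, doc)) == _as_tuples(scan(matcher, doc))


# -- context resolution ------------------------------------------------------

def test_tissue_overlap_suppresses_gene_match():
    gene_m = compile_matcher(_lexicon(("g1", "gene", "hsa", "HeLa")))
    tissue_m = compile_matcher(_lexicon(("cl1", "tissue", "any", "HeLa")))
    doc = _doc("Shown in HeLa cells.")
    resolved = resolve_context(scan(gene_m, doc), doc, tissue_m)
    assert len(resolved) == 1
    assert resolved[0].suppressed and resolved[0].reason == "tissue-overlap"


def test_species_narrowing_via_taxon_mentions():
    gene_m = compile_matcher(_lexicon(
        ("h1", "gene", "hsa", "Abc1"), ("m1", "gene", "mmu", "Abc1")))
    taxon_m = compile_matcher(_lexicon(("t", "taxon", "mmu", "mice")))
    doc = _doc("Abc1 was studied in mice.")
    resolved = resolve_context(scan(gene_m, doc), doc, None, taxon_m)
    gene = [m for m in resolved if m.entity_type == "gene"][0]
    assert gene.entity_ids == ("m1",)
    assert not gene.ambiguous


def test_same_species_ambiguity_is_kept():
    gene_m = compile_matcher(_lexicon(
        ("h1", "gene", "hsa", "DUP"), ("h2", "gene", "hsa", "DUP")))
    doc = _doc("DUP is mentioned without context.")
    resolved = resolve_context(scan(gene_m, doc), doc)
    assert resolved[0].ambiguous
    assert resolved[0].entity_ids == ("h1", "h2")


def test_resolution_is_contractive():
    gene_m = compile_matcher(_lexicon(
        ("h1", "gene", "hsa", "Abc1"), ("m1", "gene", "mmu", "Abc1"),
        ("g2", "gene", "hsa", "HeLa")))
    tissue_m = compile_matcher(_lexicon(("cl", "tissue", "any", "HeLa")))
    taxon_m = compile_matcher(_lexicon(("t", "taxon", "hsa", "human")))
    doc = _doc("Abc1 and HeLa in human cells.")
    before = scan(gene_m, doc)
    after = resolve_context(before, doc, tissue_m, taxon_m)
    assert len(after) == len(before)
    for b, a in zip(before, after):
        assert a.span == b.span
        assert set(a.entity_ids) <= set(b.entity_ids)


def test_mirna_mention_beats_overlapping_gene_symbol():
    gene_m = compile_matcher(_lexicon(("host", "gene", "hsa", "MIR17HG")))
    doc = _doc("The MIR17HG locus was profiled.")
    matches = scan(gene_m, doc)
    span = matches[0].span
    out = suppress_mirna_overlaps(matches, [span])
    assert out[0].suppressed and out[0].reason == "mirna-overlap"


def test_strict_matches_are_subset_of_tolerant():
    rows = [("a", "gene", "any", "Interleukin-6"),
            ("b", "gene", "any", "KRAS")]
    matcher = compile_matcher(build_lexicon([rows]))
    doc = _doc("interleukin 6 with KRAS and kras.")
    matches = scan(matcher, doc)
    strict_spans = {m.span for m in matches if m.strict}
    all_spans = {m.span for m in matches}
    assert strict_spans <= all_spans


def test_aho_corasick_reports_all_occurrences():
    ac = AhoCorasick()
    for p in ("he", "she", "his", "hers"):
        ac.add(p)
    ac.build()
    hits = sorted((i - len(p) + 1, p) for i, p in ac.iter_matches("ushers"))
    assert hits == [(1, "she"), (2, "he"), (2, "hers")]
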