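"""Pair extraction, relation typing, taxonomy confirmation, filters, export."""

import io
import itertools

import pytest

from mirtext.corpus import Document
from mirtext.extraction import (EVIDENCE_ABSTRACT, EVIDENCE_SENTENCE,
                                FilterConfig, aggregate, apply_filters,
                                extract_pairs, mirna_mentions_for,
                                process_document, read_aggregate_tsv,
                                read_associations_tsv, read_crossrefs, to_dot,
                                type_relations, write_aggregate_tsv,
                                write_associations_tsv)
from mirtext.lexicon import build_lexicon, default_relation_lexicon
from mirtext.ner import compile_matcher, scan
from tests.conftest import run_pipeline


def _gene_matcher(*rows):
    return compile_matcher(build_lexicon([[list(r) for r in rows]]))


def _assocs_for(doc, matcher):
    mentions = mirna_mentions_for(doc)
    return extract_pairs(doc, mentions, scan(matcher, doc))


def test_cross_sentence_pair_is_abstract_level_only():
    doc = Document("1", "A study.",
                   "miR-21 was measured. PTEN was also measured.")
    assocs = _assocs_for(doc, _gene_matcher(("5728", "gene", "hsa", "PTEN")))
    levels = {a.evidence_level for a in assocs}
    assert levels == {EVIDENCE_ABSTRACT}


def test_same_sentence_pair_has_both_levels():
    doc = Document("1", "A study.", "Notably, miR-21 represses PTEN here.")
    assocs = _assocs_for(doc, _gene_matcher(("5728", "gene", "hsa", "PTEN")))
    levels = sorted(a.evidence_level for a in assocs)
    assert levels == [EVIDENCE_ABSTRACT, EVIDENCE_SENTENCE]
    sent = [a for a in assocs if a.evidence_level == EVIDENCE_SENTENCE][0]
    assert sent.sentence_index == 1
    assert sent.evidence[0].pmid == "1"


def test_sentence_pairs_subset_of_abstract_pairs(clean_bundle,
                                                 relation_lexicon,
                                                 tissue_matcher, taxa_matcher):
    by_doc = run_pipeline(clean_bundle, relation_lexicon, tissue_matcher,
                          taxa_matcher)
    for assocs in by_doc.values():
        sent = {(a.mirna.canonical_name, a.gene) for a in assocs
                if a.evidence_level == EVIDENCE_SENTENCE}
        abst = {(a.mirna.canonical_name, a.gene) for a in assocs
                if a.evidence_level == EVIDENCE_ABSTRACT}
        assert sent <= abst


def test_relation_typing_union_and_empty(relation_lexicon):
    doc = Document("1", "A study.",
                   "Here miR-21 targets and cleaves PTEN. "
                   "Also miR-21 accompanies PTEN.")
    assocs = _assocs_for(doc, _gene_matcher(("5728", "gene", "hsa", "PTEN")))
    sent = [a for a in assocs if a.evidence_level == EVIDENCE_SENTENCE]
    typed = {a.sentence_index: type_relations(a, doc, relation_lexicon)
             .relation_types for a in sent}
    assert typed[1] == {"physical_target", "cleavage"}
    assert typed[2] == set()


def test_typing_rejects_abstract_level(relation_lexicon):
    doc = Document("1", "miR-21 here.", "PTEN there.")
    assocs = _assocs_for(doc, _gene_matcher(("5728", "gene", "hsa", "PTEN")))
    with pytest.raises(ValueError):
        type_relations(assocs[0], doc, relation_lexicon)


def test_taxonomy_confirmation(taxa_matcher, relation_lexicon):
    matcher = _gene_matcher(("5728", "gene", "hsa", "PTEN"))

    def confirmed(abstract):
        doc = Document("1", "A study.", abstract)
        assocs = process_document(doc, matcher, relation_lexicon,
                                  taxon_matcher=taxa_matcher)
        return {a.taxonomy_confirmed for a in assocs}

    assert confirmed("In humans, hsa-miR-21 represses PTEN.") == {True}
    assert confirmed("Generally, hsa-miR-21 represses PTEN.") == {False}
    assert confirmed("In mice, hsa-miR-21 represses PTEN.") == {False}


def test_no_association_references_suppressed_mentions(relation_lexicon,
                                                       tissue_matcher):
    # "HeLa" is a gene alias here, but overlaps the cell-line dictionary
    matcher = _gene_matcher(("g1", "gene", "hsa", "HeLa"))
    doc = Document("1", "A study.", "Notably, miR-21 represses HeLa cells.")
    assocs = process_document(doc, matcher, relation_lexicon,
                              tissue_matcher=tissue_matcher)
    assert assocs == []


def test_ambiguous_gene_yields_flagged_association_per_candidate():
    matcher = _gene_matcher(("g1", "gene", "hsa", "DUP"),
                            ("g2", "gene", "hsa", "DUP"))
    doc = Document("1", "A study.", "Notably, miR-21 represses DUP.")
    assocs = _assocs_for(doc, matcher)
    genes = {a.gene for a in assocs}
    assert genes == {"g1", "g2"}
    assert all(a.gene_ambiguous for a in assocs)


# -- filters -----------------------------------------------------------------

def _pipeline_assocs(bundle, relation_lexicon, tissue_matcher, taxa_matcher):
    by_doc = run_pipeline(bundle, relation_lexicon, tissue_matcher,
                          taxa_matcher)
    return [a for assocs in by_doc.values() for a in assocs]


def _crossrefs_from(assocs):
    pairs = sorted({(a.mirna.canonical_name, a.gene) for a in assocs})
    return {(m.casefold(), g): {"refdb"} for m, g in pairs[::3]}


def test_all_filters_off_is_identity(small_bundle, relation_lexicon,
                                     tissue_matcher, taxa_matcher):
    assocs = _pipeline_assocs(small_bundle, relation_lexicon, tissue_matcher,
                              taxa_matcher)
    assert apply_filters(assocs, FilterConfig()) == assocs


def test_single_sentence_filter_drops_abstract_only_pair():
    doc = Document("1", "A study.",
                   "miR-21 was measured. PTEN was also measured.")
    assocs = _assocs_for(doc, _gene_matcher(("5728", "gene", "hsa", "PTEN")))
    assert assocs
    assert apply_filters(assocs, FilterConfig(single_sentence=True)) == []


def test_unknown_relation_type_rejected():
    with pytest.raises(ValueError):
        FilterConfig(relation_type="binding")


def test_database_filter_requires_crossrefs():
    with pytest.raises(ValueError):
        apply_filters([], FilterConfig(database=True), crossrefs=None)


def test_filters_contractive_and_order_independent(small_bundle,
                                                   relation_lexicon,
                                                   tissue_matcher,
                                                   taxa_matcher):
    """All 64 filter configurations shrink the association set, and
    sequential application commutes with the combined application."""
    assocs = _pipeline_assocs(small_bundle, relation_lexicon, tissue_matcher,
                              taxa_matcher)
    crossrefs = _crossrefs_from(assocs)
    names = ["strictness", "single_sentence", "relation_type", "taxonomy",
             "unambiguous_gene", "database"]
    for bits in itertools.product([False, True], repeat=6):
        kwargs = {n: b for n, b in zip(names, bits)}
        kwargs["relation_type"] = "repression" if kwargs["relation_type"] \
            else None
        combined = apply_filters(assocs, FilterConfig(**kwargs), crossrefs)
        assert len(combined) <= len(assocs)
        combined_keys = {id(a) for a in combined}

        active = [(n, v) for n, v in kwargs.items()
                  if v not in (False, None)]
        for order in (active, list(reversed(active))):
            seq = assocs
            for name, value in order:
                seq = apply_filters(seq, FilterConfig(**{name: value}),
                                    crossrefs)
            assert {id(a) for a in seq} == combined_keys, kwargs


def test_switching_filters_on_is_monotone(small_bundle, relation_lexicon,
                                          tissue_matcher, taxa_matcher):
    assocs = _pipeline_assocs(small_bundle, relation_lexicon, tissue_matcher,
                              taxa_matcher)
    crossrefs = _crossrefs_from(assocs)
    sizes = [len(assocs)]
    config = {}
    for name, value in [("single_sentence", True), ("strictness", True),
                        ("taxonomy", True), ("unambiguous_gene", True),
                        ("relation_type", "repression"), ("database", True)]:
        config[name] = value
        sizes.append(len(apply_filters(assocs, FilterConfig(**config),
                                       crossrefs)))
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


# -- aggregation and export --------------------------------------------------

def test_association_tsv_roundtrip(small_bundle, relation_lexicon,
                                   tissue_matcher, taxa_matcher):
    assocs = _pipeline_assocs(small_bundle, relation_lexicon, tissue_matcher,
                              taxa_matcher)
    buf = io.StringIO()
    write_associations_tsv(assocs, buf)
    buf.seek(0)
    back = read_associations_tsv(buf)
    assert len(back) == len(assocs)
    for a, b in zip(sorted(assocs, key=lambda x: x.key()), back):
        assert a.key() == b.key()
        assert a.mirna == b.mirna
        assert a.relation_types == b.relation_types
        assert sorted(a.evidence) == sorted(b.evidence)
        assert (a.taxonomy_confirmed, a.gene_ambiguous, a.strict_evidence) \
            == (b.taxonomy_confirmed, b.gene_ambiguous, b.strict_evidence)


def test_aggregate_counts_evidence_once_per_sentence():
    doc = Document("1", "A study.",
                   "First, miR-21 represses PTEN. Second, miR-21 binds PTEN.")
    matcher = _gene_matcher(("5728", "gene", "hsa", "PTEN"))
    assocs = process_document(doc, matcher, default_relation_lexicon())
    rows = aggregate(assocs)
    assert len(rows) == 1
    assert rows[0].n_sentence_evidence == 2
    assert rows[0].relation_types == ("physical_target", "repression")


def test_aggregate_tsv_and_dot_roundtrip(small_bundle, relation_lexicon,
                                         tissue_matcher, taxa_matcher):
    assocs = _pipeline_assocs(small_bundle, relation_lexicon, tissue_matcher,
                              taxa_matcher)
    rows = aggregate(assocs)
    buf = io.StringIO()
    write_aggregate_tsv(rows, buf)
    buf.seek(0)
    assert read_aggregate_tsv(buf) == rows

    dot = to_dot(rows)
    assert dot == to_dot(rows)  # deterministic
    assert dot.startswith("graph mirna_gene {")
    assert dot.count(" -- ") == len(rows)


def test_empty_association_set_exports_cleanly():
    buf = io.StringIO()
    write_aggregate_tsv(aggregate([]), buf)
    assert buf.getvalue().count("\n") == 1  # header only
    assert to_dot([]) == "graph mirna_gene {\n}\n"


def test_crossref_reader_rejects_bad_rows():
    assert read_crossrefs(io.StringIO("mir-21\t5728\ttarbase\n")) \
        == {("mir-21", "5728"): {"tarbase"}}
    with pytest.raises(ValueError):
        read_crossrefs(io.StringIO("only\ttwo\n"))
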