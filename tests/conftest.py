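import pytest

from mirtext.evaluation import AssociationItem
from mirtext.extraction import process_document
from mirtext.lexicon import (bundled_taxa, bundled_tissues,
                             default_relation_lexicon)
from mirtext.ner import compile_matcher
from mirtext.synthetic import FixtureConfig, generate_corpus


@pytest.fixture(scope="session")
def relation_lexicon():
    return default_relation_lexicon()


@pytest.fixture(scope="session")
def taxa_matcher():
    return compile_matcher(bundled_taxa(), ("taxon",))


@pytest.fixture(scope="session")
def tissue_matcher():
    return compile_matcher(bundled_tissues(), ("tissue",))


@pytest.fixture(scope="session")
def clean_bundle():
    """100 clean documents: no decoys, planted structure fully known."""
    return generate_corpus(FixtureConfig(n_documents=100, seed=7,
                                         decoy_rate=0.0))


@pytest.fixture(scope="session")
def small_bundle():
    """50 documents with decoys and ambiguity, for filter contracts."""
    return generate_corpus(FixtureConfig(n_documents=50, seed=11))


def run_pipeline(bundle, relation_lexicon, tissue_matcher, taxa_matcher):
    """All associations of a fixture corpus, by document."""
    gene_m = compile_matcher(bundle.gene_lexicon, ("gene", "protein"))
    out = {}
    for doc in bundle.documents:
        out[doc.pmid] = process_document(doc, gene_m, relation_lexicon,
                                         tissue_matcher, taxa_matcher)
    return out


def predicted_items(assocs_by_doc, level="sentence"):
    """Merge pipeline associations into per-pair AssociationItems with
    the union of their relation types (the gold granularity)."""
    merged = {}
    for assocs in assocs_by_doc.values():
        for a in assocs:
            if a.evidence_level != level:
                continue
            merged.setdefault((a.pmid, a.mirna.canonical_name, a.gene),
                              set()).update(a.relation_types)
    return [AssociationItem(p, m, g, frozenset(t))
            for (p, m, g), t in sorted(merged.items())]
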