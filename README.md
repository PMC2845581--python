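# mirtext

Literature mining of **miRNA–gene associations** from publication titles
and abstracts: dictionary- and grammar-based named entity recognition,
sentence- and abstract-level co-occurrence pair extraction, relation-type
classification, result filters, and evaluation against gold annotations.

## Who it is for

Researchers building or auditing collections of miRNA–target
relationships from the literature. Manually curated target databases are
small and skewed toward a few large-scale experiments; text mining of
abstracts recovers many additional candidate pairs together with the
sentence-level evidence behind each one. `mirtext` implements that
pipeline as a library plus a composable command-line tool, with a
synthetic-corpus generator so every stage is testable offline with a
known ground truth.

## What it computes

1. **miRNA mentions** are found with an explicit grammar built from the
   community naming conventions (`hsa-mir-100` stem-loop vs `hsa-miR-100`
   mature, arm suffixes `-5p/-3p/-s/-as/*`, paralog letters and locus
   numbers, plant `MIR472`, viral `ebv-mir-BARTT8`, legacy `lin-4`/`let-7`)
   including free-text spelling variants (`miR101b`, `miRNA-101b`,
   `microRNA-101b`, `microRNA101b`). Mentions are parsed into structured
   form and normalised to stem-loop / mature / gene-family identifiers.
2. **Gene and protein names** are matched against curated synonym
   dictionaries with an Aho–Corasick automaton (one pass, all
   occurrences), tolerating case and hyphen/space/fused variation, with
   tissue/cell-line overlap suppression and species narrowing from
   taxonomy mentions.
3. **Pairs**: a miRNA and a gene co-occurring in an abstract yield an
   abstract-level association; co-occurrence within a single sentence
   additionally yields a sentence-level association (always a subset).
   A *tri-occurrence* with a relation keyword in the same sentence
   classifies the pair into one or more of five association types —
   physical target, co-expression, repression, induction, cleavage.
4. **Six filters** (AND-combined, each contractive): strictness
   (byte-exact dictionary match), single-sentence, relation-type,
   taxonomy confirmation, unambiguous gene synonym, and cross-database
   confirmation against user-supplied reference tables.
5. **Evaluation**: recall `TP/(TP+FN)`, precision `TP/(TP+FP)` and their
   harmonic mean (F-measure) for occurrences, associations and typed
   associations.

## Worked example

```python
from mirtext import (Document, build_lexicon, compile_matcher,
                     default_relation_lexicon, process_document)
from mirtext.extraction import aggregate
from mirtext.lexicon import bundled_taxa, bundled_tissues

doc = Document(
    pmid="17110380",
    title="miR-21-mediated tumor growth.",
    abstract=("MicroRNA-21 (miR-21) is overexpressed in glioblastoma. "
              "We found that hsa-miR-21 suppresses PTEN in human cells."),
)
lex = build_lexicon([[("5728", "gene", "hsa", "PTEN")]])
assocs = process_document(
    doc,
    gene_matcher=compile_matcher(lex, ("gene", "protein")),
    relation_lexicon=default_relation_lexicon(),
    tissue_matcher=compile_matcher(bundled_tissues(), ("tissue",)),
    taxon_matcher=compile_matcher(bundled_taxa(), ("taxon",)),
)
for a in assocs:
    print(a.pmid, a.mirna.canonical_name, a.gene, a.evidence_level,
          sorted(a.relation_types), a.taxonomy_confirmed)
for row in aggregate(assocs):
    print(row.mirna, row.gene, row.n_sentence_evidence, row.relation_types)
```

prints

```
17110380 hsa-mir-21 5728 abstract ['repression'] True
17110380 hsa-mir-21 5728 sentence ['repression'] True
hsa-mir-21 5728 1 ('repression',)
```

All three mention spellings (`miR-21-mediated` in the title,
`MicroRNA-21`, `miR-21`, `hsa-miR-21`) normalise to the family identifier
`hsa-mir-21` — species resolved from the "human" taxonomy mention — and
the pair with gene 5728 (PTEN) is reported at both evidence levels, typed
`repression` by the keyword "suppresses", with taxonomy confirmation.
The aggregate row counts one distinct supporting sentence.

## Command line

```bash
mirtext fixtures --out fx --n-docs 100 --seed 7      # synthetic corpus
mirtext extract  --corpus fx/corpus.tsv --lexicon fx/gene_lexicon.tsv --out run
mirtext filter   --associations run/associations.tsv --single-sentence \
                 --strictness --out run/filtered.tsv
mirtext evaluate --predicted run/associations.tsv \
                 --gold fx/gold_sentence.tsv --mode association
mirtext export   --associations run/filtered.tsv --format dot --out graph.dot
```

Every stage reads and writes flat TSV, echoes its effective
configuration as JSON, and is deterministic (sorted serialization
everywhere). Corpora are read either as `pmid<TAB>title<TAB>abstract`
TSV or as PubMed/MEDLINE article XML.

## Layout

| module | role |
| --- | --- |
| `mirtext.nomenclature` | miRNA name grammar, parsing, normalization |
| `mirtext.lexicon` | synonym dictionaries, expansion, curation, relation keywords |
| `mirtext.corpus` | abstract records, sentence segmentation |
| `mirtext.ner` | Aho–Corasick dictionary matcher, context resolution |
| `mirtext.extraction` | pairs, typing, taxonomy, filters, aggregation, DOT export |
| `mirtext.evaluation` | TP/FP/FN counting, recall/precision/F-measure |
| `mirtext.synthetic` | planted-corpus generator and perturbations |
| `mirtext.cli` | the `mirtext` command |

See `docs/methods.md` for the underlying modelling choices and known
limitations.
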