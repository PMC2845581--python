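"""Synthetic corpora with known planted structure.

Every other module is testable offline against fixtures from this
generator: abstracts with planted miRNA names drawn from the
nomenclature grammar (all schemes, arms and suffix forms), planted gene
synonyms from a generated vocabulary with controlled ambiguity, planted
relation keywords and taxonomy mentions, near-miss decoy strings, plus
the matching gold annotations.  The planting log records everything
that was planted and is the ground-truth oracle for extraction and
evaluation tests.

Sentence templates are deliberately plain subject-verb-object English:
realism is not a goal, oracle-exactness is.  Sampling uses only integer
draws from one seeded pseudo-random stream, so identical (config, seed)
reproduce byte-identical corpora on any platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Document, write_corpus_tsv
from .evaluation import AssociationItem, OccurrenceItem, write_gold_tsv
from .lexicon import (Lexicon, RelationLexicon, build_lexicon,
                      default_relation_lexicon)
from .nomenclature import (MirnaParse, find_mirna_mentions, format_mirna,
                           normalize_mirna, parse_mirna_name)

__all__ = [
    "FixtureConfig",
    "NoiseSpec",
    "FixtureBundle",
    "generate_corpus",
    "perturb_corpus",
]

_SPECIES = ("hsa", "mmu", "rno")
_TAXON_WORDS = {
    "hsa": ("human", "humans"),
    "mmu": ("mouse", "mice", "murine"),
    "rno": ("rat", "rats"),
}
_FILLERS = (
    "The experimental protocol followed previously described procedures.",
    "Samples were processed according to the approved workflow.",
    "Additional cohort details are provided in the appendix.",
    "Statistical thresholds were fixed before data collection.",
)
_DECOYS = (
    "The admiral's smirk impressed visitors of the MIR building.",
    "A microcosm of the letdown was apparent near the Mirage annex.",
)
_CONSONANTS = "BCDFGHJKLNPQRSTVWXZ"


def _bern(rng: random.Random, rate: float) -> bool:
    return rng.randrange(1_000_000) < int(round(rate * 1_000_000))


@dataclass(frozen=True)
class FixtureConfig:
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (2, 4)
    planted_pair_rate: float = 0.7
    keyword_rate: float = 0.65
    ambiguous_synonym_rate: float = 0.1
    decoy_rate: float = 0.1
    taxon_mention_rate: float = 0.5
    n_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_pair_rate", "keyword_rate",
                     "ambiguous_synonym_rate", "decoy_rate",
                     "taxon_mention_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_documents < 0 or self.n_genes < 1:
            raise ValueError("invalid corpus dimensions")


@dataclass(frozen=True)
class NoiseSpec:
    """Controlled corpus perturbations with computable consequences."""

    case_mangle_rate: float = 0.0   # gene mention loses dictionary case
    split_name_rate: float = 0.0    # miRNA name broken, mention lost
    remove_keywords: bool = False   # typed associations become untyped
    seed: int = 0


@dataclass
class _PairPlan:
    mirna_surface: str
    mirna_key: str                  # canonical identifier for pairing
    gene_entities: tuple[str, ...]  # >1 when an ambiguous synonym is used
    gene_surface: str
    keyword: str | None
    keyword_types: frozenset[str]
    taxon_surface: str | None
    # perturbation state
    gene_mangled: bool = False
    mirna_split: bool = False
    keyword_removed: bool = False


@dataclass
class _SentencePlan:
    kind: str                       # pair | filler | decoy
    pair: _PairPlan | None = None
    filler_index: int = 0


@dataclass
class _DocPlan:
    pmid: str
    species: str
    title: str
    sentences: list[_SentencePlan] = field(default_factory=list)


def _render_pair(plan: _PairPlan) -> tuple[str, dict[str, tuple[int, int]]]:
    spans: dict[str, tuple[int, int]] = {}
    gene_surface = (plan.gene_surface.lower() if plan.gene_mangled
                    else plan.gene_surface)
    mirna_surface = plan.mirna_surface
    if plan.mirna_split:
        # break the head-identifier join so neither half matches the
        # grammar: "hsa-miR-1224-5p" -> "hsa-miR- and 1224-5p"
        cut = next(i for i, c in enumerate(mirna_surface) if c.isdigit())
        mirna_surface = mirna_surface[:cut] + " and " + mirna_surface[cut:]
    keyword = None if plan.keyword_removed else plan.keyword
    if keyword:
        parts = ["We found that ", mirna_surface, " ", keyword, " ",
                 gene_surface]
    else:
        parts = ["We observed ", mirna_surface, " together with ",
                 gene_surface]
    text = ""
    for part in parts:
        if part is mirna_surface:
            spans["mirna"] = (len(text), len(text) + len(part))
        elif part is gene_surface:
            spans["gene"] = (len(text), len(text) + len(part))
        text += part
    taxon = plan.taxon_surface
    if taxon:
        lead = " in "
        spans["taxon"] = (len(text) + len(lead),
                          len(text) + len(lead) + len(taxon))
        text += lead + taxon + " samples"
    else:
        text += " in cultured samples"
    return text + ".", spans


def _render_sentence(plan: _SentencePlan) -> tuple[str, dict]:
    if plan.kind == "pair":
        return _render_pair(plan.pair)
    if plan.kind == "decoy":
        return _DECOYS[plan.filler_index % len(_DECOYS)], {}
    return _FILLERS[plan.filler_index % len(_FILLERS)], {}


@dataclass
class FixtureBundle:
    """A rendered synthetic corpus plus its planted ground truth."""

    config: FixtureConfig
    documents: list[Document]
    gene_lexicon_rows: list[tuple[str, str, str, str]]
    gold_occurrences: list[OccurrenceItem]
    gold_sentence_associations: list[AssociationItem]
    gold_abstract_associations: list[AssociationItem]
    planting_log: list[dict]
    perturbation_log: list[dict] = field(default_factory=list)
    _plans: list[_DocPlan] = field(default_factory=list, repr=False)

    @property
    def gene_lexicon(self) -> Lexicon:
        return build_lexicon([self.gene_lexicon_rows])

    @property
    def relation_lexicon(self) -> RelationLexicon:
        return default_relation_lexicon()

    def expected_sentence_associations(
            self, strict_only: bool = False,
            typed_only: bool = False) -> set[AssociationItem]:
        """Associations the pipeline should detect, given any recorded
        perturbations (computed from the plans alone)."""
        out: set[AssociationItem] = set()
        for doc_plan in self._plans:
            for sp in doc_plan.sentences:
                p = sp.pair
                if sp.kind != "pair" or p is None:
                    continue
                if p.mirna_split:
                    continue
                if strict_only and p.gene_mangled:
                    continue
                types = (frozenset() if p.keyword_removed or not p.keyword
                         else p.keyword_types)
                if typed_only and not types:
                    continue
                for gene in p.gene_entities:
                    out.add(AssociationItem(doc_plan.pmid, p.mirna_key,
                                            gene, types))
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "corpus.tsv", "w", encoding="utf-8") as fh:
            write_corpus_tsv(self.documents, fh)
        with open(outdir / "gene_lexicon.tsv", "w", encoding="utf-8") as fh:
            for row in self.gene_lexicon_rows:
                fh.write("\t".join(row) + "\n")
        with open(outdir / "gold_sentence.tsv", "w", encoding="utf-8") as fh:
            write_gold_tsv(self.gold_occurrences,
                           self.gold_sentence_associations, fh)
        with open(outdir / "gold_abstract.tsv", "w", encoding="utf-8") as fh:
            write_gold_tsv([], self.gold_abstract_associations, fh)
        log_fields = ["pmid", "sentence_index", "kind", "detail"]
        with open(outdir / "planting_log.tsv", "w", encoding="utf-8") as fh:
            fh.write("\t".join(log_fields) + "\n")
            for row in self.planting_log:
                fh.write("\t".join(str(row.get(k, "")) for k in log_fields)
                         + "\n")


def _gene_vocabulary(rng: random.Random, config: FixtureConfig,
                     relation_lexicon: RelationLexicon):
    """Entity vocabulary with controlled synonym ambiguity.

    Symbols are consonant trigrams plus a digit, so they can collide
    neither with English filler words nor with the miRNA grammar.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    while len(symbols) < config.n_genes:
        sym = "".join(rng.choice(_CONSONANTS) for _ in range(3)) \
            + str(rng.randrange(1, 10))
        if sym in seen:
            continue
        seen.add(sym)
        symbols.append(sym)
    rows: list[tuple[str, str, str, str]] = []
    surfaces: list[tuple[str, tuple[str, ...]]] = []  # (surface, owners)
    ids = [f"g{1000 + i}" for i in range(config.n_genes)]
    for gid, sym in zip(ids, symbols):
        rows.append((gid, "gene", "any", sym))
        rows.append((gid, "gene", "any", f"{sym} modulator"))
        surfaces.append((sym, (gid,)))
    k = 0
    for i in range(0, config.n_genes - 1, 2):
        if _bern(rng, config.ambiguous_synonym_rate):
            shared = f"SHRD{k}{rng.randrange(1, 10)}"
            k += 1
            rows.append((ids[i], "gene", "any", shared))
            rows.append((ids[i + 1], "gene", "any", shared))
            surfaces.append((shared, (ids[i], ids[i + 1])))
    for surface, _ in surfaces:
        assert not relation_lexicon.types_in(surface)
    return rows, surfaces


def _sample_mirna(rng: random.Random, species: str) -> MirnaParse:
    roll = rng.randrange(100)
    prefix = species if _bern(rng, 0.7) else None
    if roll < 80:  # standard scheme
        base = rng.randrange(1, 500)
        letter = rng.choice("abc") if _bern(rng, 0.3) else None
        locus = None
        arm = "none"
        if _bern(rng, 0.15):
            locus = rng.randrange(1, 4)
            form = "precursor"
        else:
            if _bern(rng, 0.3):
                arm = rng.choice(["5p", "3p", "s", "as", "star"])
            if arm in ("5p", "3p", "star"):
                form = rng.choice(["mature", "unspecified"])
            else:
                form = rng.choice(["precursor", "mature", "unspecified"])
        parse = MirnaParse(raw_text="", scheme="standard", base_id=base,
                           species_prefix=prefix, letter_suffix=letter,
                           locus_suffix=locus, arm=arm, form=form)
    elif roll < 90:  # legacy lin-4 / let-7 family
        base = rng.choice(["lin-4", "let-7"])
        letter = rng.choice("abc") if _bern(rng, 0.3) else None
        parse = MirnaParse(raw_text="", scheme="legacy-special", base_id=base,
                           species_prefix=prefix if _bern(rng, 0.5) else None,
                           letter_suffix=letter)
    elif roll < 95:  # plant scheme
        parse = MirnaParse(raw_text="", scheme="plant",
                           base_id=str(rng.randrange(100, 999)),
                           letter_suffix=(rng.choice("abc")
                                          if _bern(rng, 0.3) else None),
                           form="unspecified")
    else:  # viral scheme
        parse = MirnaParse(raw_text="", scheme="viral",
                           base_id=f"BART{rng.randrange(1, 20)}",
                           species_prefix="ebv",
                           form=rng.choice(["precursor", "mature"]))
    surface = format_mirna(parse)
    return parse_mirna_name(surface)


def generate_corpus(config: FixtureConfig) -> FixtureBundle:
    """Generate documents, lexicon rows, gold annotations and the
    planting log for one seeded configuration."""
    rng = random.Random(config.seed)
    relation_lexicon = default_relation_lexicon()
    gene_rows, gene_surfaces = _gene_vocabulary(rng, config, relation_lexicon)
    keywords_by_type = {t: sorted(relation_lexicon.keywords(t))
                        for t in relation_lexicon.types}

    plans: list[_DocPlan] = []
    for i in range(config.n_documents):
        pmid = str(90_000_001 + i)
        species = _SPECIES[rng.randrange(len(_SPECIES))]
        doc_plan = _DocPlan(pmid=pmid, species=species,
                            title=f"Regulatory observations for record {pmid}.")
        lo, hi = config.sentences_per_doc
        for _ in range(rng.randrange(lo, hi + 1)):
            if _bern(rng, config.planted_pair_rate):
                mirna = _sample_mirna(rng, species)
                surface, owners = gene_surfaces[
                    rng.randrange(len(gene_surfaces))]
                keyword = None
                ktypes: frozenset[str] = frozenset()
                if _bern(rng, config.keyword_rate):
                    rtype = relation_lexicon.types[
                        rng.randrange(len(relation_lexicon.types))]
                    kws = keywords_by_type[rtype]
                    keyword = kws[rng.randrange(len(kws))]
                    ktypes = frozenset(relation_lexicon.types_in(keyword))
                taxon = None
                if _bern(rng, config.taxon_mention_rate):
                    words = _TAXON_WORDS[species]
                    taxon = words[rng.randrange(len(words))]
                doc_plan.sentences.append(_SentencePlan(
                    kind="pair",
                    pair=_PairPlan(
                        mirna_surface=mirna.raw_text,
                        mirna_key="",  # filled once doc context is known
                        gene_entities=owners, gene_surface=surface,
                        keyword=keyword, keyword_types=ktypes,
                        taxon_surface=taxon)))
                # stash the parse for later normalization
                doc_plan.sentences[-1].pair._parse = mirna  # type: ignore
            elif _bern(rng, config.decoy_rate):
                doc_plan.sentences.append(_SentencePlan(
                    kind="decoy", filler_index=rng.randrange(len(_DECOYS))))
            else:
                doc_plan.sentences.append(_SentencePlan(
                    kind="filler", filler_index=rng.randrange(len(_FILLERS))))
        plans.append(doc_plan)

    # normalise miRNA identities with the same document-level species
    # context the pipeline will see
    for doc_plan in plans:
        context = {doc_plan.species} if any(
            sp.kind == "pair" and sp.pair.taxon_surface
            for sp in doc_plan.sentences) else set()
        for sp in doc_plan.sentences:
            if sp.kind == "pair":
                ident = normalize_mirna(sp.pair._parse, context)  # type: ignore
                sp.pair.mirna_key = ident.canonical_name

    return _render_bundle(config, plans, gene_rows, relation_lexicon)


def _render_bundle(config: FixtureConfig, plans: list[_DocPlan],
                   gene_rows, relation_lexicon) -> FixtureBundle:
    documents: list[Document] = []
    occurrences: list[OccurrenceItem] = []
    sent_assocs: dict[tuple, AssociationItem] = {}
    abs_assocs: dict[tuple, AssociationItem] = {}
    log: list[dict] = []

    for doc_plan in plans:
        pieces: list[str] = []
        local_spans: list[dict] = []
        for sp in doc_plan.sentences:
            text, spans = _render_sentence(sp)
            pieces.append(text)
            local_spans.append(spans)
        abstract = " ".join(pieces)
        doc = Document(pmid=doc_plan.pmid, title=doc_plan.title,
                       abstract=abstract)
        documents.append(doc)

        offset = len(doc_plan.title) + 1
        pair_keys_in_doc: list[_PairPlan] = []
        for sp, spans in zip(doc_plan.sentences, local_spans):
            if sp.kind == "pair":
                pair_keys_in_doc.append(sp.pair)
            for name, (s, e) in spans.items():
                abs_span = (s + offset, e + offset)
                if name == "mirna" and not sp.pair.mirna_split:
                    log.append({"pmid": doc_plan.pmid,
                                "sentence_index": doc.sentence_index(abs_span),
                                "kind": "mirna",
                                "detail": sp.pair.mirna_key})
                elif name == "gene":
                    for gid in sp.pair.gene_entities:
                        occurrences.append(OccurrenceItem(
                            doc_plan.pmid, abs_span, "gene", gid))
                    log.append({"pmid": doc_plan.pmid,
                                "sentence_index": doc.sentence_index(abs_span),
                                "kind": "gene",
                                "detail": ",".join(sp.pair.gene_entities)})
            if sp.kind == "pair" and not sp.pair.mirna_split:
                s, e = spans["mirna"]
                occurrences.append(OccurrenceItem(
                    doc_plan.pmid, (s + offset, e + offset), "mirna",
                    sp.pair.mirna_key))
            offset += len(_render_sentence(sp)[0]) + 1  # joining space

        # sentence-level gold: planted pairs (original, unperturbed truth)
        for idx, sp in enumerate(doc_plan.sentences):
            if sp.kind != "pair":
                continue
            p = sp.pair
            for gid in p.gene_entities:
                key = (doc_plan.pmid, p.mirna_key, gid)
                types = p.keyword_types if p.keyword else frozenset()
                prev = sent_assocs.get(key)
                merged = types | (prev.relation_types if prev else frozenset())
                sent_assocs[key] = AssociationItem(
                    doc_plan.pmid, p.mirna_key, gid, frozenset(merged))
                log.append({"pmid": doc_plan.pmid, "sentence_index": idx + 1,
                            "kind": "pair",
                            "detail": f"{p.mirna_key}|{gid}|"
                                      f"{','.join(sorted(types))}"})

        # abstract-level gold: cross product of distinct mentions per doc
        mirnas = sorted({p.mirna_key for p in pair_keys_in_doc})
        genes = sorted({g for p in pair_keys_in_doc for g in p.gene_entities})
        for mk in mirnas:
            for g in genes:
                key = (doc_plan.pmid, mk, g)
                types = (sent_assocs[key].relation_types
                         if key in sent_assocs else frozenset())
                abs_assocs[key] = AssociationItem(doc_plan.pmid, mk, g, types)

    return FixtureBundle(
        config=config,
        documents=documents,
        gene_lexicon_rows=list(gene_rows),
        gold_occurrences=sorted(occurrences,
                                key=lambda o: (o.pmid, o.span, o.entity_id)),
        gold_sentence_associations=sorted(
            sent_assocs.values(),
            key=lambda a: (a.pmid, a.mirna, a.gene)),
        gold_abstract_associations=sorted(
            abs_assocs.values(),
            key=lambda a: (a.pmid, a.mirna, a.gene)),
        planting_log=log,
        _plans=plans,
    )


def perturb_corpus(bundle: FixtureBundle, noise: NoiseSpec) -> FixtureBundle:
    """Re-render a bundle with controlled errors.

    Perturbations are recorded in ``perturbation_log`` and reflected in
    :meth:`FixtureBundle.expected_sentence_associations`, so the exact
    metric degradation is computable.  Gold annotations keep the
    original (unperturbed) truth.  An empty noise spec is the identity.
    """
    rng = random.Random(noise.seed)
    import copy
    plans = copy.deepcopy(bundle._plans)
    perturbations: list[dict] = []
    for doc_plan in plans:
        for idx, sp in enumerate(doc_plan.sentences):
            if sp.kind != "pair":
                continue
            p = sp.pair
            if _bern(rng, noise.case_mangle_rate) \
                    and p.gene_surface != p.gene_surface.lower():
                p.gene_mangled = True
                perturbations.append({
                    "pmid": doc_plan.pmid, "sentence_index": idx + 1,
                    "kind": "case-mangle", "detail": p.gene_surface})
            # viral names keep their virus-acronym prefix out of the
            # split pool: the residue ("ebv ...") would still be a
            # taxonomy mention and change the document species context
            if _bern(rng, noise.split_name_rate) \
                    and not p.mirna_surface.lower().startswith("ebv"):
                p.mirna_split = True
                perturbations.append({
                    "pmid": doc_plan.pmid, "sentence_index": idx + 1,
                    "kind": "split-name", "detail": p.mirna_surface})
            if noise.remove_keywords and p.keyword:
                p.keyword_removed = True
                perturbations.append({
                    "pmid": doc_plan.pmid, "sentence_index": idx + 1,
                    "kind": "keyword-removed", "detail": p.keyword})

    rendered = _render_bundle(bundle.config, plans, bundle.gene_lexicon_rows,
                              bundle.relation_lexicon)
    # gold stays the unperturbed truth; detection expectations come from
    # the perturbed plans
    rendered.gold_occurrences = bundle.gold_occurrences
    rendered.gold_sentence_associations = bundle.gold_sentence_associations
    rendered.gold_abstract_associations = bundle.gold_abstract_associations
    rendered.perturbation_log = perturbations
    return rendered
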