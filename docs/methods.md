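# Methods

## The extraction model

`mirtext` treats miRNA–gene association mining as four deterministic
stages over the unified text of each abstract record (title + `"\n"` +
abstract; the title counts as sentence 0, all coordinates are 0-based
half-open character offsets into that one string).

1. **miRNA recognition** is grammar-based, not dictionary-based: the
   community nomenclature is regular enough that a single explicit
   grammar covers it, and many names in recent abstracts predate any
   database release. The grammar is: optional species prefix (3–4
   lowercase letters + hyphen), head in {`mir`, `miR`, `MIR`, `miRNA`,
   `microRNA`, `lin`, `let`} with an optional single hyphen/space before
   the identifier, identifier = digits (standard/plant) or letters+digits
   (viral locus tokens), optional paralog letter, optional `-locus`
   digits, optional arm (`-5p`/`-3p`/`-s`/`-as`/`*`). Matches must not be
   flanked by letters or digits; adjacent hyphens do not block a match,
   so `anti-miR-21` and `pre-miR-21` yield the mention `miR-21` (a small
   stop set {`anti`, `pre`, `pri`} keeps those hyphenated English
   prefixes from being read as species codes). Scanning is leftmost with
   the longest match at each position winning.
2. **Gene/protein/taxon/tissue recognition** is dictionary-based via a
   hand-implemented Aho–Corasick automaton over a normalized token
   stream (lowercased alphanumeric runs split at letter/digit
   boundaries). Tolerant matching therefore ignores exactly case and
   hyphen/space/fused separator variation, nothing else; every hit is
   additionally labelled `strict` when the surface text equals a
   dictionary synonym byte for byte. Overlapping hits of one entity type
   resolve longest-first, then leftmost, then smallest entity id.
3. **Pairing**: each distinct (miRNA, gene) in a document yields an
   abstract-level association; each sentence containing both adds a
   sentence-level association. Relation typing is tri-occurrence at
   sentence scope: any relation keyword sharing the sentence contributes
   its type(s), with no word-distance or syntactic constraint and no
   negation handling (see limitations). Abstract-level pairs inherit the
   union of the types of their sentence-level evidence, since typing is
   defined at sentence scope only.
4. **Filtering and scoring**: six independent predicates, AND-combined,
   each a pure subset operation — so any application order gives the
   same result, which the tests assert over all 64 configurations.

## Identity and normalization choices

A parsed name normalises to the most specific level its suffixes
warrant: an explicit arm makes it a mature identifier, a locus suffix a
stem-loop identifier. Otherwise a user-supplied synonym table decides
(head casing selects between stem-loop and mature entries when both
exist), and names absent from any table fall back to a gene-family
identifier (species + base + paralog letter) — an incomplete name such
as `miR-1224` does not commit to a molecular form, and capitalisation is
treated as advisory throughout because authors do not use it
consistently. Species comes from the name's own prefix first, else from
a document-level taxonomy context when it names exactly one species,
else stays unspecified. This makes `miR-195` in a human-context abstract
and `hsa-miR-195` aggregate to one pair, which is the behaviour the pair
counts rely on.

Context resolution implements exactly two mechanisms: gene/protein hits
overlapping a tissue/cell-line hit are suppressed, and hits ambiguous
across species are narrowed to the species mentioned in the document.
On any span overlap between the grammar channel and the dictionary
channel the miRNA mention wins (this also suppresses taxonomy hits on
the species prefix inside a name like `ebv-mir-BART11`). Synonyms of
one or two characters match in strict mode only.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| relation keywords | bundled file, 5 types, 86 keywords | explicit inflected forms (`represses`, `repressed`, ...) rather than a stemmer, so every hit is auditable; replaceable via `type<TAB>keyword` files |
| stoplists | two bundled lists (general English, technical abbreviations) | case-sensitive curation of dictionary synonyms; editable data files, contents deliberately conservative |
| expansion rules | separators, slash split, Roman↔Arabic (Arabic→Roman only ≤ 4), acronym pairs (`IL` = `Interleukin`, ...) | computed to closure, hence idempotent |
| short-synonym guard | ≤ 2 characters | such synonyms match only byte-exactly |
| sentence splitter | `.!?` + whitespace + uppercase/digit, abbreviation list | rule-based for determinism; decimal points and `et al.`/`Fig.`-style abbreviations never split |

## The synthetic-data generator

The generator emulates the inputs the pipeline consumes: abstracts with
planted miRNA names sampled from the grammar itself (all schemes, arms
and suffix forms; one shared definition guarantees grammar closure),
gene mentions from a generated vocabulary of consonant-trigram symbols
(collision-free with English and with the grammar) with controlled
synonym ambiguity, relation keywords, taxonomy words, and near-miss
decoys ("smirk", "the MIR building"). Defaults: 50 documents of 2–4
sentences, pair rate 0.7 per sentence, keyword rate 0.65 (matching the
reported share of classified pairs), ambiguous-synonym rate 0.1, decoy
rate 0.1, taxonomy-mention rate 0.5. Sampling uses integer draws from
one seeded stream, so identical (config, seed) reproduce byte-identical
corpora anywhere.

Templates are plain subject–verb–object English with a fixed opener per
kind; realism is not a goal, oracle-exactness is. The planting log (and
the derived gold TSVs) is the ground truth: on a clean corpus the
pipeline's sentence-level pairs and types equal it exactly, which is
what the recovery tests and the acceptance script assert. The
perturbation operator re-renders the same plans with controlled errors —
case-mangled gene mentions (strict evidence lost), broken miRNA names
(mention lost; viral names whose prefix is itself a taxonomy acronym are
exempt because their residue would remain a taxonomy mention), removed
keywords (types lost) — and records each one, so the exact metric
degradation is computable in advance and compared to 2 decimals.

What passing these tests does *not* show: performance on real abstracts,
whose language is far noisier (anaphora, coordination, novel synonyms,
negation). The generator makes correctness of the machinery testable,
not the linguistic coverage of the dictionaries.

## Numerical and procedural conventions

- Rates are reported at 2 decimal places, rounded half up; undefined
  denominators yield flagged undefined values, never a silent zero.
- Occurrence scoring credits each gold item at most once, pairing
  greedily left to right; span overlap plus entity agreement counts as a
  hit (byte-exact spans available via a flag), since manual annotation
  protocols are rarely character-exact. Typed comparison requires the
  relation-type sets to intersect; two untyped pairs agree vacuously.
- Evaluation refuses predictions whose pmids lie outside the gold
  corpus, treating that as an experiment-design error rather than as
  false positives.
- All serializations sort their keys; repeated runs are byte-identical.

## Known limitations

- Negated statements ("does not target") are typed like affirmative
  ones; a documented precision limitation of sentence-scope
  tri-occurrence.
- Anaphoric mentions (a bare "101b" after an earlier full name) are out
  of scope by design.
- The tolerant matcher does not attempt abbreviation-definition
  detection, coreference, or learned disambiguation; context resolution
  is limited to the two documented mechanisms above.
- Cross-database confirmation consumes user-supplied reference tables;
  no third-party database content is bundled.
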