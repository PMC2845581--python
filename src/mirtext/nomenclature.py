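"""miRNA name grammar: mention finding, structured parsing, normalization.

miRNA names follow a small set of community conventions rather than a
dictionary: a stem-loop (precursor) locus is written with a lowercase
``mir`` head and an optional 3-4 letter species code (``hsa-mir-100``),
the excised mature sequence with a capitalised ``miR`` head
(``hsa-miR-100``), arm variants carry ``-5p``/``-3p`` (legacy ``-s``/
``-as``, or a trailing ``*`` for the minor product), paralogous loci get
letter suffixes (``hsa-mir-10a``/``-10b``) and identical-product loci
numeric ones (``hsa-mir-101-1``/``-101-2``).  Plant names use an
uppercase ``MIR`` head (``MIR472``), viral names a locus token instead
of a number (``ebv-mir-BARTT8``), and ``lin-4``/``let-7`` predate the
scheme entirely.  Free text additionally uses spelling variants such as
``miR101b``, ``miRNA-101b``, ``microRNA-101b`` and ``microRNA101b``.

This module recognises all of the above with one explicit regular
grammar, parses hits into :class:`MirnaParse`, and normalises parses to
stem-loop / mature / gene-family identifiers (:class:`MirnaIdentifier`).
Capitalisation is treated as advisory: unusual casings are flagged, not
rejected, because authors do not use it consistently.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "MirnaParse",
    "MirnaIdentifier",
    "MirnaParseError",
    "MirnaSynonymTable",
    "find_mirna_mentions",
    "parse_mirna_name",
    "format_mirna",
    "normalize_mirna",
]

SCHEME_STANDARD = "standard"
SCHEME_PLANT = "plant"
SCHEME_VIRAL = "viral"
SCHEME_LEGACY = "legacy-special"

FORM_PRECURSOR = "precursor"
FORM_MATURE = "mature"
FORM_UNSPECIFIED = "unspecified"

ARM_NONE = "none"
ARMS = ("5p", "3p", "s", "as", "star", ARM_NONE)

LEVEL_STEM_LOOP = "stem-loop"
LEVEL_MATURE = "mature"
LEVEL_FAMILY = "family"

#: Hyphenated English prefixes that would otherwise be mistaken for a
#: 3-4 letter species code ("anti-miR-21", "pre-miR-21", "pri-miR-21").
NON_SPECIES_PREFIXES = ("anti", "pre", "pri")

_CORE = r"""
    (?:(?!(?:anti|pre|pri)-)(?P<prefix>[a-z]{3,4})-)?
    (?:
        (?P<legacy>(?:lin|let)-(?P<lnum>\d+))(?P<lletter>[a-z])?
      |
        (?P<head>microrna|mirna|mir)[ \-]?
        (?:
            (?P<vident>[a-z]+\d+)
          |
            (?P<num>\d+)
        )
        (?P<letter>[a-z])?
        (?:-(?P<locus>\d+))?
        (?:-(?P<arm>5p|3p|as|s))?
        (?P<star>\*)?
    )
"""

# A mention must not sit inside a longer alphanumeric token; adjacent
# hyphens are permitted so that e.g. "anti-miR-21" still yields "miR-21".
_MENTION_RE = re.compile(
    r"(?<![A-Za-z0-9])" + _CORE + r"(?![A-Za-z0-9])",
    re.IGNORECASE | re.VERBOSE,
)
_FULL_RE = re.compile(_CORE + r"\Z", re.IGNORECASE | re.VERBOSE)


class MirnaParseError(ValueError):
    """Raised when a string does not conform to the miRNA name grammar."""

    def __init__(self, raw: str, offending: str):
        self.raw = raw
        self.offending = offending
        super().__init__(
            f"not a miRNA name: {raw!r} (offending token: {offending!r})"
        )


@dataclass(frozen=True)
class MirnaParse:
    """Structured decomposition of a single miRNA name as written."""

    raw_text: str
    scheme: str
    base_id: int | str
    species_prefix: str | None = None
    letter_suffix: str | None = None
    locus_suffix: int | None = None
    arm: str = ARM_NONE
    form: str = FORM_UNSPECIFIED
    #: advisory convention violations (never grounds for rejection)
    convention_flags: tuple[str, ...] = ()

    def canonical_fields(self) -> tuple:
        """Identity of the parse irrespective of surface spelling."""
        return (
            self.scheme,
            self.base_id,
            self.species_prefix,
            self.letter_suffix,
            self.locus_suffix,
            self.arm,
            self.form,
        )


@dataclass(frozen=True)
class MirnaIdentifier:
    """A normalised miRNA identity at stem-loop, mature or family level."""

    canonical_name: str
    level: str
    species: str = "unspecified"


def find_mirna_mentions(text: str) -> list[tuple[tuple[int, int], str]]:
    """Locate every miRNA name mention in ``text``.

    Returns ``[((start, end), raw), ...]`` with 0-based half-open char
    offsets.  Matches are maximal, non-overlapping, resolved left to
    right with the longest hit at each position winning, and never occur
    inside a longer alphanumeric token.
    """
    out: list[tuple[tuple[int, int], str]] = []
    for m in _MENTION_RE.finditer(text):
        out.append(((m.start(), m.end()), m.group(0)))
    return out


def _classify_head(head: str) -> tuple[str | None, tuple[str, ...]]:
    """Map the matched head token to (form, flags)."""
    if head == "mir":
        return FORM_PRECURSOR, ()
    if head == "miR":
        return FORM_MATURE, ()
    if head in ("miRNA", "microRNA", "MIR"):
        return FORM_UNSPECIFIED, ()
    # casing the conventions do not anticipate: advisory only
    return FORM_UNSPECIFIED, ("unusual-casing",)


def _parse_match(m: re.Match) -> MirnaParse:
    raw = m.group(0)
    flags: list[str] = []
    prefix = m.group("prefix")
    prefix = prefix.lower() if prefix else None

    if m.group("legacy"):
        base = m.group("legacy").lower()
        return MirnaParse(
            raw_text=raw,
            scheme=SCHEME_LEGACY,
            base_id=base,
            species_prefix=prefix,
            letter_suffix=(m.group("lletter") or None),
            form=FORM_UNSPECIFIED,
        )

    head = m.group("head")
    form, head_flags = _classify_head(head)
    flags.extend(head_flags)

    arm = m.group("arm")
    star = m.group("star")
    if arm and star:
        flags.append("arm-and-star")
    arm_value = arm.lower() if arm else ("star" if star else ARM_NONE)

    letter = m.group("letter")
    locus = m.group("locus")

    if m.group("vident"):
        scheme = SCHEME_VIRAL
        base_id: int | str = m.group("vident")
    elif head == "MIR":
        scheme = SCHEME_PLANT
        base_id = m.group("num")
    else:
        scheme = SCHEME_STANDARD
        base_id = int(m.group("num"))

    if locus is not None and scheme != SCHEME_STANDARD:
        flags.append("locus-outside-standard-scheme")
    if form == FORM_PRECURSOR and arm_value in ("5p", "3p", "star"):
        flags.append("precursor-with-mature-arm")

    return MirnaParse(
        raw_text=raw,
        scheme=scheme,
        base_id=base_id,
        species_prefix=prefix,
        letter_suffix=(letter.lower() if letter else None),
        locus_suffix=(int(locus) if locus is not None else None),
        arm=arm_value,
        form=form,
        convention_flags=tuple(flags),
    )


def parse_mirna_name(raw: str) -> MirnaParse:
    """Parse a full miRNA name into its structured form.

    Raises :class:`MirnaParseError` (naming the offending token) when
    ``raw`` does not conform to the grammar end to end.
    """
    m = _FULL_RE.match(raw)
    if m is None:
        # identify where the grammar stops accepting the string
        probe = _MENTION_RE.search(raw)
        offending = raw[probe.end():] if probe else raw
        raise MirnaParseError(raw, offending.strip() or raw)
    return _parse_match(m)


def format_mirna(parse: MirnaParse) -> str:
    """Render a parse in canonical style.

    Lowercase species prefix; ``mir``/``miR`` head per form (``miRNA``
    when the form is unspecified, so the rendering re-parses to the same
    form); hyphen-separated numeric/arm suffixes with the paralog letter
    fused to the base.  Round trip: ``parse_mirna_name(format_mirna(p))``
    has the same :meth:`MirnaParse.canonical_fields` as ``p``.
    """
    prefix = f"{parse.species_prefix}-" if parse.species_prefix else ""
    letter = parse.letter_suffix or ""
    if parse.scheme == SCHEME_LEGACY:
        return f"{prefix}{parse.base_id}{letter}"
    if parse.scheme == SCHEME_PLANT:
        return f"{prefix}MIR{parse.base_id}{letter}"
    head = {
        FORM_PRECURSOR: "mir",
        FORM_MATURE: "miR",
        FORM_UNSPECIFIED: "miRNA",
    }[parse.form]
    name = f"{prefix}{head}-{parse.base_id}{letter}"
    if parse.locus_suffix is not None:
        name += f"-{parse.locus_suffix}"
    if parse.arm == "star":
        name += "*"
    elif parse.arm != ARM_NONE:
        name += f"-{parse.arm}"
    return name


def family_base(parse: MirnaParse, species: str = "unspecified") -> str:
    """Gene-family identifier: species + base + paralog letter.

    Drops form, locus and arm, so all spelling variants of one family
    collapse ("miR101b", "miRNA-101b", "microRNA-101b", "microRNA101b"
    all yield ``mir-101b``; with species hsa, ``hsa-mir-101b``).
    """
    prefix = "" if species == "unspecified" else f"{species}-"
    letter = parse.letter_suffix or ""
    if parse.scheme == SCHEME_LEGACY:
        return f"{prefix}{parse.base_id}{letter}"
    if parse.scheme == SCHEME_PLANT:
        return f"{prefix}MIR{parse.base_id}{letter}"
    return f"{prefix}mir-{parse.base_id}{letter}"


class MirnaSynonymTable:
    """Known miRNA names: TSV of (identifier, level, species, synonym)."""

    def __init__(self) -> None:
        self._by_synonym: dict[str, list[tuple[str, str, str]]] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str]]
    ) -> "MirnaSynonymTable":
        table = cls()
        for identifier, level, species, synonym in records:
            if level not in (LEVEL_STEM_LOOP, LEVEL_MATURE, LEVEL_FAMILY):
                raise ValueError(f"unknown miRNA identifier level: {level!r}")
            table._by_synonym.setdefault(synonym.casefold(), []).append(
                (identifier, level, species)
            )
        return table

    @classmethod
    def from_tsv(cls, stream) -> "MirnaSynonymTable":
        reader = csv.reader(stream, delimiter="\t")
        return cls.from_records(
            (row[0], row[1], row[2], row[3]) for row in reader if row
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_synonym.values())

    def lookup(self, name: str) -> list[tuple[str, str, str]]:
        return list(self._by_synonym.get(name.casefold(), ()))


_EMPTY_TABLE = MirnaSynonymTable()


def resolve_species(
    parse: MirnaParse, species_context: Iterable[str] = ()
) -> str:
    """Species from the name's own prefix, else from a single
    unambiguous document-level taxon context, else ``"unspecified"``."""
    if parse.species_prefix:
        return parse.species_prefix
    context = set(species_context)
    if len(context) == 1:
        return next(iter(context))
    return "unspecified"


def normalize_mirna(
    parse: MirnaParse,
    species_context: Iterable[str] = (),
    known_names: MirnaSynonymTable | None = None,
) -> MirnaIdentifier:
    """Normalise a parse to a database-style identifier.

    A name carrying an explicit arm is a mature identifier and one
    carrying a locus suffix a stem-loop identifier regardless of any
    synonym table.  Otherwise the table decides the level (head casing
    selects between a stem-loop and a mature entry when both exist,
    since e.g. a bare ``miR-1224`` "could mean precursor or mature").
    Names absent from the table fall back to a grammar-canonical
    gene-family identifier — an incomplete name does not commit to a
    molecular form.
    """
    known = known_names if known_names is not None else _EMPTY_TABLE
    species = resolve_species(parse, species_context)

    if parse.arm != ARM_NONE:
        mature = replace(parse, form=FORM_MATURE, species_prefix=None,
                         locus_suffix=None)
        prefix = "" if species == "unspecified" else f"{species}-"
        return MirnaIdentifier(prefix + format_mirna(mature),
                               LEVEL_MATURE, species)
    if parse.locus_suffix is not None:
        stem = replace(parse, form=FORM_PRECURSOR, species_prefix=None)
        prefix = "" if species == "unspecified" else f"{species}-"
        return MirnaIdentifier(prefix + format_mirna(stem),
                               LEVEL_STEM_LOOP, species)

    hits = known.lookup(parse.raw_text) or known.lookup(format_mirna(parse))
    if hits:
        hits = [h for h in hits if h[2] == species or species == "unspecified"
                or h[2] == "unspecified"] or hits
        preferred = {
            FORM_PRECURSOR: LEVEL_STEM_LOOP,
            FORM_MATURE: LEVEL_MATURE,
        }.get(parse.form)
        for identifier, level, sp in hits:
            if preferred is None or level == preferred:
                return MirnaIdentifier(identifier, level,
                                       sp if sp != "any" else species)
        identifier, level, sp = hits[0]
        return MirnaIdentifier(identifier, level,
                               sp if sp != "any" else species)

    return MirnaIdentifier(family_base(parse, species), LEVEL_FAMILY, species)
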