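"""Scoring of predicted occurrences and associations against gold
annotations.

Recall is TP over all true items, precision TP over all predictions,
and the F-measure their harmonic mean.  Undefined denominators are
reported as flagged undefined values, never silently as zero.  Reported
rates are rounded to two decimals, half up.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Sequence

__all__ = [
    "Metrics",
    "OccurrenceItem",
    "AssociationItem",
    "compare",
    "metrics",
    "f_from_rates",
    "round2",
    "read_gold_tsv",
    "write_gold_tsv",
]

MODE_OCCURRENCE = "occurrence"
MODE_ASSOCIATION = "association"
MODE_TYPED = "typed-association"


def round2(x: float) -> float:
    """Round to 2 decimal places, half up (presentation rounding)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"),
                                           rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def recall(self) -> float | None:
        denom = self.tp + self.fn
        return None if denom == 0 else self.tp / denom

    @property
    def precision(self) -> float | None:
        denom = self.tp + self.fp
        return None if denom == 0 else self.tp / denom

    @property
    def f_measure(self) -> float | None:
        r, p = self.recall, self.precision
        if r is None or p is None:
            return None
        return f_from_rates(r, p)

    @property
    def undefined(self) -> bool:
        return self.recall is None or self.precision is None

    def rounded(self) -> tuple[float | None, float | None, float | None]:
        return tuple(None if v is None else round2(v)
                     for v in (self.recall, self.precision, self.f_measure))


def f_from_rates(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; 0 iff either rate is 0."""
    if recall < 0 or precision < 0:
        raise ValueError("rates must be non-negative")
    if recall + precision == 0:
        return 0.0
    return 2 * recall * precision / (recall + precision)


def metrics(tp: int, fp: int, fn: int) -> Metrics:
    return Metrics(tp=tp, fp=fp, fn=fn)


@dataclass(frozen=True)
class OccurrenceItem:
    pmid: str
    span: tuple[int, int]
    entity_type: str
    entity_id: str


@dataclass(frozen=True)
class AssociationItem:
    pmid: str
    mirna: str
    gene: str
    relation_types: frozenset[str] = frozenset()


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _check_pmids(predicted: Sequence, gold: Sequence) -> None:
    pred_pmids = {p.pmid for p in predicted}
    gold_pmids = {g.pmid for g in gold}
    extra = pred_pmids - gold_pmids
    if gold and extra:
        raise ValueError(
            f"predicted items reference pmids outside the gold corpus: "
            f"{sorted(extra)[:5]}")


def compare(predicted: Sequence, gold: Sequence, mode: str,
            exact_span: bool = False) -> tuple[int, int, int]:
    """Count (tp, fp, fn); every gold item is credited at most once.

    ``occurrence`` mode pairs predictions and gold greedily left to
    right on (pmid, overlapping span — or identical span with
    ``exact_span`` — and agreeing entity id).  ``association`` mode
    matches on (pmid, mirna, gene); ``typed-association`` additionally
    requires the relation-type sets to intersect (two untyped pairs
    agree vacuously).
    """
    _check_pmids(predicted, gold)
    if mode == MODE_OCCURRENCE:
        pred = sorted(predicted, key=lambda x: (x.pmid, x.span))
        remaining = sorted(gold, key=lambda x: (x.pmid, x.span))
        tp = 0
        for p in pred:
            for g in remaining:
                same_span = (p.span == g.span if exact_span
                             else _spans_overlap(p.span, g.span))
                if (p.pmid == g.pmid and same_span
                        and p.entity_type == g.entity_type
                        and p.entity_id == g.entity_id):
                    tp += 1
                    remaining.remove(g)
                    break
        return tp, len(pred) - tp, len(remaining)
    if mode == MODE_ASSOCIATION:
        pred_keys = {(p.pmid, p.mirna, p.gene) for p in predicted}
        gold_keys = {(g.pmid, g.mirna, g.gene) for g in gold}
        tp = len(pred_keys & gold_keys)
        return tp, len(pred_keys - gold_keys), len(gold_keys - pred_keys)
    if mode == MODE_TYPED:
        remaining = list(gold)
        pred = sorted(predicted,
                      key=lambda x: (x.pmid, x.mirna, x.gene,
                                     tuple(sorted(x.relation_types))))
        # deduplicate predictions on the full typed key
        seen: set[tuple] = set()
        deduped = []
        for p in pred:
            key = (p.pmid, p.mirna, p.gene,
                   frozenset(p.relation_types))
            if key not in seen:
                seen.add(key)
                deduped.append(p)
        tp = 0
        for p in deduped:
            for g in remaining:
                types_agree = (set(p.relation_types) & set(g.relation_types)
                               or (not p.relation_types
                                   and not g.relation_types))
                if ((p.pmid, p.mirna, p.gene) == (g.pmid, g.mirna, g.gene)
                        and types_agree):
                    tp += 1
                    remaining.remove(g)
                    break
        return tp, len(deduped) - tp, len(remaining)
    raise ValueError(f"unknown comparison mode: {mode!r}")


# ---------------------------------------------------------------------------
# gold annotation TSV
# columns: pmid, mode, start, end, entity_type, entity_id, mirna, gene,
#          relation_types

def write_gold_tsv(occurrences: Iterable[OccurrenceItem],
                   associations: Iterable[AssociationItem],
                   stream: IO[str]) -> None:
    for o in sorted(occurrences, key=lambda x: (x.pmid, x.span)):
        stream.write("\t".join([
            o.pmid, MODE_OCCURRENCE, str(o.span[0]), str(o.span[1]),
            o.entity_type, o.entity_id, "", "", ""]) + "\n")
    for a in sorted(associations,
                    key=lambda x: (x.pmid, x.mirna, x.gene,
                                   tuple(sorted(x.relation_types)))):
        stream.write("\t".join([
            a.pmid, MODE_ASSOCIATION, "", "", "", "", a.mirna, a.gene,
            ",".join(sorted(a.relation_types))]) + "\n")


def read_gold_tsv(stream: IO[str]) -> tuple[list[OccurrenceItem],
                                            list[AssociationItem]]:
    occurrences: list[OccurrenceItem] = []
    associations: list[AssociationItem] = []
    for row in csv.reader(stream, delimiter="\t"):
        if not row:
            continue
        pmid, mode = row[0], row[1]
        if mode == MODE_OCCURRENCE:
            occurrences.append(OccurrenceItem(
                pmid, (int(row[2]), int(row[3])), row[4], row[5]))
        elif mode == MODE_ASSOCIATION:
            types = frozenset(filter(None, row[8].split(","))) \
                if len(row) > 8 else frozenset()
            associations.append(AssociationItem(pmid, row[6], row[7], types))
        else:
            raise ValueError(f"unknown gold annotation mode: {mode!r}")
    return occurrences, associations
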