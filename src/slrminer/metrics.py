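"""Evaluation: precision, recall and F1 under strict and relaxed matching.

``precision = correct / predicted``, ``recall = correct / actual`` and the F1
score is the harmonic mean of the two.  A *strict* entity match requires the
identical character span and entity type; a *relaxed* match requires the same
type and any span overlap (at least one shared character) — the convention
used when human reviewers disagree only on boundaries, e.g. extracting
"1.3 mg/m^2" where another reviewer extracted the whole dosage sentence.

Predicted and gold mentions are paired one-to-one: exact-boundary matches
are seeded first (document order), then the pairing is grown to a
maximum-cardinality bipartite matching by augmenting paths, preferring
larger overlaps.  Because augmentation never unmatches a vertex and the
relaxed edge set contains the strict one, relaxed F1 >= strict F1 holds for
every input, and the reported counts are provably maximal — no prediction
is left unmatched when a valid one-to-one assignment exists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .corpus import Document, EntityMention
from .schema import ExtractionSchema, SYMMETRIC_LABELS

Mode = str  # "strict" | "relaxed"


@dataclass(frozen=True)
class MatchCounts:
    correct: int = 0
    predicted: int = 0
    actual: int = 0

    def __post_init__(self) -> None:
        if self.correct > min(self.predicted, self.actual):
            raise ValueError("correct exceeds predicted or actual positives")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.correct + other.correct,
                           self.predicted + other.predicted,
                           self.actual + other.actual)

    @property
    def precision(self) -> float:
        return self.correct / self.predicted if self.predicted else 0.0

    @property
    def recall(self) -> float:
        return self.correct / self.actual if self.actual else 0.0

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "correct": self.correct, "predicted": self.predicted, "actual": self.actual,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "precision_defined": self.predicted > 0, "recall_defined": self.actual > 0,
        }


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, v in (("precision", precision), ("recall", recall)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _overlap(a: EntityMention, b: EntityMention) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def match_entities(
    predicted: Sequence[EntityMention],
    gold: Sequence[EntityMention],
    mode: Mode = "relaxed",
) -> tuple[MatchCounts, list[tuple[int, int]]]:
    """One-to-one pairing of predictions and gold mentions within a document.

    Returns the match counts and the pairing as (predicted index, gold index)
    pairs.  Exact-boundary same-type pairs are matched first in both modes;
    relaxed mode then pairs remaining same-type mentions greedily by
    descending overlap length, tie-break earliest predicted start.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    # admissible edges per prediction, best overlap first (ties: earliest gold)
    adj: list[list[int]] = []
    for p in predicted:
        edges = []
        for gi, g in enumerate(gold):
            if g.entity_type != p.entity_type:
                continue
            if mode == "strict":
                if (p.start, p.end) == (g.start, g.end):
                    edges.append((0, g.start, gi))
            else:
                ov = _overlap(p, g)
                if ov > 0:
                    edges.append((-ov, g.start, gi))
        adj.append([gi for _, _, gi in sorted(edges)])

    # exact-boundary pairs first, in document order
    match_p: dict[int, int] = {}
    match_g: dict[int, int] = {}
    for pi in sorted(range(len(predicted)),
                     key=lambda i: (predicted[i].start, predicted[i].end)):
        p = predicted[pi]
        for gi in adj[pi]:
            g = gold[gi]
            if gi not in match_g and (p.start, p.end) == (g.start, g.end):
                match_p[pi] = gi
                match_g[gi] = pi
                break

    # grow to a maximum-cardinality matching with augmenting paths; matched
    # vertices never become unmatched, so exact pairs stay paired (possibly
    # re-partnered) and adding overlap edges can only increase the count —
    # hence relaxed correct >= strict correct
    def augment(pi: int, seen: set[int]) -> bool:
        for gi in adj[pi]:
            if gi in seen:
                continue
            seen.add(gi)
            if gi not in match_g or augment(match_g[gi], seen):
                match_p[pi] = gi
                match_g[gi] = pi
                return True
        return False

    for pi in sorted(range(len(predicted)),
                     key=lambda i: (predicted[i].start, predicted[i].end)):
        if pi not in match_p:
            augment(pi, set())

    pairs = sorted(match_p.items())
    counts = MatchCounts(len(pairs), len(predicted), len(gold))
    return counts, pairs


@dataclass
class EvalReport:
    strict: MatchCounts
    relaxed: MatchCounts
    per_type_strict: dict[str, MatchCounts]
    per_type_relaxed: dict[str, MatchCounts]

    def as_dict(self) -> dict:
        return {
            "strict": {"overall": self.strict.as_dict(),
                       "per_type": {t: c.as_dict() for t, c in sorted(self.per_type_strict.items())}},
            "relaxed": {"overall": self.relaxed.as_dict(),
                        "per_type": {t: c.as_dict() for t, c in sorted(self.per_type_relaxed.items())}},
        }


def evaluate(
    doc_pairs: Sequence[tuple[Sequence[EntityMention], Sequence[EntityMention]]],
    schema: ExtractionSchema | None = None,
) -> EvalReport:
    """Overall and per-type P/R/F1 in both modes over (predicted, gold) documents.

    Matching never crosses documents.  Types reported are those present in
    the schema (if given) or observed in the data.
    """
    types: set[str] = set(schema.entity_names) if schema is not None else set()
    for pred, gold in doc_pairs:
        types.update(m.entity_type for m in pred)
        types.update(m.entity_type for m in gold)

    totals = {"strict": MatchCounts(), "relaxed": MatchCounts()}
    per_type = {"strict": {t: MatchCounts() for t in types},
                "relaxed": {t: MatchCounts() for t in types}}
    for pred, gold in doc_pairs:
        for mode in ("strict", "relaxed"):
            counts, pairs = match_entities(pred, gold, mode)
            totals[mode] = totals[mode] + counts
            matched_by_type: dict[str, int] = {}
            for pi, gi in pairs:
                matched_by_type[gold[gi].entity_type] = matched_by_type.get(gold[gi].entity_type, 0) + 1
            for t in types:
                per_type[mode][t] = per_type[mode][t] + MatchCounts(
                    matched_by_type.get(t, 0),
                    sum(1 for m in pred if m.entity_type == t),
                    sum(1 for m in gold if m.entity_type == t),
                )
    return EvalReport(totals["strict"], totals["relaxed"],
                      per_type["strict"], per_type["relaxed"])


# ---------------------------------------------------------------------------
# Relations

ResolvedRelation = tuple[str, EntityMention, EntityMention]  # (label, arg1, arg2)


def resolve_relations(doc: Document) -> list[ResolvedRelation]:
    by_id = {m.mention_id: m for m in doc.mentions}
    return [(r.label, by_id[r.arg1], by_id[r.arg2]) for r in doc.relations]


def _args_match(p: EntityMention, g: EntityMention, arg_mode: Mode) -> bool:
    if p.entity_type != g.entity_type:
        return False
    if arg_mode == "strict":
        return (p.start, p.end) == (g.start, g.end)
    return _overlap(p, g) > 0


def _relation_matches(p: ResolvedRelation, g: ResolvedRelation, arg_mode: Mode) -> bool:
    if p[0] != g[0]:
        return False
    direct = _args_match(p[1], g[1], arg_mode) and _args_match(p[2], g[2], arg_mode)
    if direct:
        return True
    if p[0] in SYMMETRIC_LABELS:
        return _args_match(p[1], g[2], arg_mode) and _args_match(p[2], g[1], arg_mode)
    return False


def match_relations(
    predicted: Sequence[ResolvedRelation],
    gold: Sequence[ResolvedRelation],
    arg_mode: Mode = "relaxed",
) -> tuple[MatchCounts, list[tuple[int, int]]]:
    """One-to-one relation pairing: label must agree, each argument must match
    the corresponding gold argument under ``arg_mode`` (symmetric labels match
    in either order).  Exact-argument pairs are taken first, mirroring the
    entity pairing policy."""
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int]] = []
    order = sorted(range(len(predicted)),
                   key=lambda i: (predicted[i][1].start, predicted[i][2].start, predicted[i][0]))
    for strict_pass in (True, False):
        mode = "strict" if strict_pass else arg_mode
        for pi in order:
            if pi in used_p:
                continue
            for gi in range(len(gold)):
                if gi in used_g:
                    continue
                if _relation_matches(predicted[pi], gold[gi], mode):
                    pairs.append((pi, gi))
                    used_p.add(pi)
                    used_g.add(gi)
                    break
        if arg_mode == "strict":
            break
    return MatchCounts(len(pairs), len(predicted), len(gold)), sorted(pairs)


def pair_type_key(rel: ResolvedRelation) -> tuple[str, str, str]:
    label, a, b = rel
    t1, t2 = a.entity_type, b.entity_type
    if label in SYMMETRIC_LABELS and t2 < t1:
        t1, t2 = t2, t1
    return (label, t1, t2)


@dataclass
class RelationEvalReport:
    overall: MatchCounts
    per_pair: dict[tuple[str, str, str], MatchCounts]
    arg_mode: Mode

    def as_dict(self) -> dict:
        return {
            "arg_mode": self.arg_mode,
            "overall": self.overall.as_dict(),
            "per_pair": {"|".join(k): c.as_dict() for k, c in sorted(self.per_pair.items())},
        }


def evaluate_relations(
    doc_pairs: Sequence[tuple[Sequence[ResolvedRelation], Sequence[ResolvedRelation]]],
    arg_mode: Mode = "relaxed",
) -> RelationEvalReport:
    """Overall and per-entity-type-pair relation P/R/F1."""
    keys: set[tuple[str, str, str]] = set()
    for pred, gold in doc_pairs:
        keys.update(pair_type_key(r) for r in pred)
        keys.update(pair_type_key(r) for r in gold)
    total = MatchCounts()
    per_pair = {k: MatchCounts() for k in keys}
    for pred, gold in doc_pairs:
        counts, pairs = match_relations(pred, gold, arg_mode)
        total = total + counts
        matched: dict[tuple[str, str, str], int] = {}
        for pi, gi in pairs:
            k = pair_type_key(gold[gi])
            matched[k] = matched.get(k, 0) + 1
        for k in keys:
            per_pair[k] = per_pair[k] + MatchCounts(
                matched.get(k, 0),
                sum(1 for r in pred if pair_type_key(r) == k),
                sum(1 for r in gold if pair_type_key(r) == k),
            )
    return RelationEvalReport(total, per_pair, arg_mode)


# ---------------------------------------------------------------------------
# Confusion matrix

UNLABELLED = "unlabelled"


@dataclass
class ConfusionMatrix:
    """Rows: actual entity types; columns: predicted types plus "unlabelled".

    Each gold mention contributes one row event — the type of the prediction
    it pairs with under relaxed (overlap) matching, or "unlabelled" when no
    prediction overlaps it.  Same-type pairs are made first, so off-diagonal
    cells reflect genuine mislabelling rather than pairing artefacts.
    Raw counts are conserved (each row sums to that type's actual positives);
    percentage rows are row-normalised and rounded to one decimal, so they
    may not sum to exactly 100.
    """

    types: tuple[str, ...]
    counts: dict[str, dict[str, int]]

    def percentages(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for t in self.types:
            row = self.counts[t]
            total = sum(row.values())
            out[t] = {c: (round(100.0 * v / total, 1) if total else 0.0)
                      for c, v in row.items()}
        return out

    def as_dict(self) -> dict:
        return {"types": list(self.types),
                "counts": self.counts,
                "percentages": self.percentages()}


def confusion(
    doc_pairs: Sequence[tuple[Sequence[EntityMention], Sequence[EntityMention]]],
    schema: ExtractionSchema,
) -> ConfusionMatrix:
    types = schema.entity_names
    cols = list(types) + [UNLABELLED]
    counts = {t: {c: 0 for c in cols} for t in types}
    for pred, gold in doc_pairs:
        # same-type relaxed pairing first
        _, same_pairs = match_entities(pred, gold, "relaxed")
        used_p = {pi for pi, _ in same_pairs}
        used_g = {gi for _, gi in same_pairs}
        for pi, gi in same_pairs:
            counts[gold[gi].entity_type][pred[pi].entity_type] += 1
        # remaining gold: pair cross-type by descending overlap
        cands = []
        for gi, g in enumerate(gold):
            if gi in used_g:
                continue
            for pi, p in enumerate(pred):
                if pi in used_p:
                    continue
                ov = _overlap(p, g)
                if ov > 0:
                    cands.append((-ov, p.start, g.start, pi, gi))
        for _, _, _, pi, gi in sorted(cands):
            if pi not in used_p and gi not in used_g:
                used_p.add(pi)
                used_g.add(gi)
                counts[gold[gi].entity_type][pred[pi].entity_type] += 1
        for gi, g in enumerate(gold):
            if gi not in used_g:
                counts[g.entity_type][UNLABELLED] += 1
    return ConfusionMatrix(types, counts)
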