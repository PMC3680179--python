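"""Classification instances and sparse features for the four pipeline stages.

The extraction pipeline classifies, in order: candidate trigger/entity words
(span stage), trigger-argument pairs (relation stage), combinations of
detected relations (structure stage) and whole events (hedge stage).
Candidate construction is identical in training and prediction; gold labels
are attached only when gold annotation is available.

Candidates at every stage are restricted to type inventories observed in the
pooled training data: a per-type lexicon of trigger/entity base forms for the
span stage, attested (trigger type, argument type) pairs for the relation
stage and attested structure signatures for the structure stage.  This
restriction bounds enumeration and is applied identically under every
training strategy; it is distinct from the per-corpus negative-instance
filtering implemented in :mod:`eventweave.filters`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus import Corpus, Signature
from .standoff import NONE_LABEL, Document, TextBound, base_form

logger = logging.getLogger(__name__)

Span = tuple[int, int]


# ---------------------------------------------------------------------------
# trigger/entity lexicon
# ---------------------------------------------------------------------------

@dataclass
class TriggerLexicon:
    """Per semantic type, the base forms observed as annotated positives."""

    by_type: dict[str, set[str]] = field(default_factory=dict)

    def add(self, type_: str, base: str) -> None:
        self.by_type.setdefault(type_, set()).add(base)

    def match(self, base: str) -> set[str]:
        return {t for t, forms in self.by_type.items() if base in forms}

    def all_bases(self) -> set[str]:
        out: set[str] = set()
        for forms in self.by_type.values():
            out |= forms
        return out

    def to_text(self) -> str:
        lines = [f"{t}\t{b}" for t in sorted(self.by_type)
                 for b in sorted(self.by_type[t])]
        return "\n".join(lines) + ("\n" if lines else "")

    @classmethod
    def from_text(cls, content: str) -> "TriggerLexicon":
        lex = cls()
        for line in content.splitlines():
            if line.strip():
                t, b = line.split("\t")
                lex.add(t, b)
        return lex


def build_trigger_lexicon(
        corpora: Sequence[Corpus],
        external_entries: Optional[dict[str, set[str]]] = None,
        include_given_entities: bool = False,
        splits: Iterable[str] = ("train",)) -> TriggerLexicon:
    """Union of annotated trigger/detected-entity base forms over corpora.

    Given (.a1) named entities are inputs to extraction, not prediction
    targets, so they are excluded by default."""
    lex = TriggerLexicon()
    for corpus in corpora:
        for doc in corpus.docs(splits):
            for tb in doc.triggers:
                lex.add(tb.type, base_form(tb.text.split()[-1]))
            if include_given_entities:
                for tb in doc.entities:
                    lex.add(tb.type, base_form(tb.text.split()[-1]))
    for t, forms in (external_entries or {}).items():
        for b in forms:
            lex.add(t, b)
    return lex


# ---------------------------------------------------------------------------
# instances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpanInstance:
    doc_id: str
    corpus: str
    token_index: int
    surface: str
    base: str
    gold: str = NONE_LABEL

    @property
    def key(self) -> tuple:
        return ("span", self.doc_id, self.token_index)


@dataclass(frozen=True)
class RelationInstance:
    doc_id: str
    corpus: str
    trigger_span: Span
    trigger_type: str
    arg_span: Span
    arg_type: Optional[str]
    arg_base: str
    arg_is_given_entity: bool
    gold: str = NONE_LABEL
    #: the role assigned to this relation (gold role in training, predicted
    #: role at prediction time); NONE until a role is assigned.
    role: str = NONE_LABEL

    @property
    def key(self) -> tuple:
        return ("rel", self.doc_id, self.trigger_span, self.trigger_type,
                self.arg_span, self.arg_type)


@dataclass(frozen=True)
class StructureInstance:
    doc_id: str
    corpus: str
    trigger_span: Span
    trigger_type: str
    #: sorted tuple of (role, argument type, argument span)
    members: tuple[tuple[str, str, Span], ...]
    #: relations detected on this trigger but not part of the structure
    n_competing: int = 0
    gold: str = NONE_LABEL

    @property
    def signature(self) -> Signature:
        return (self.trigger_type,
                tuple(sorted((r, t) for r, t, _s in self.members)))

    @property
    def key(self) -> tuple:
        return ("struct", self.doc_id, self.trigger_span, self.trigger_type,
                self.members)


@dataclass(frozen=True)
class HedgeInstance:
    doc_id: str
    corpus: str
    event_id: str
    trigger_span: Span
    trigger_type: str
    members: tuple[tuple[str, str, Span], ...]
    gold: str = NONE_LABEL

    @property
    def key(self) -> tuple:
        return ("hedge", self.doc_id, self.event_id)


Instance = SpanInstance | RelationInstance | StructureInstance | HedgeInstance


# ---------------------------------------------------------------------------
# candidate generation
# ---------------------------------------------------------------------------

def _gold_span_labels(doc: Document) -> dict[int, str]:
    """Map head token index -> type of the .a2 text-bound anchored there."""
    labels: dict[int, str] = {}
    for tb in sorted(doc.triggers, key=lambda t: (t.type, t.start)):
        head = doc.head_token_index(tb)
        if head is not None and head not in labels:
            labels[head] = tb.type
    return labels


def generate_span_candidates(doc: Document, lexicon: TriggerLexicon,
                             corpus_name: str,
                             with_gold: bool = False) -> list[SpanInstance]:
    """One candidate per lexicon-matched token outside given entities."""
    if doc.tokens is None:
        raise ValueError(f"{doc.doc_id}: document is not tokenized")
    given_heads = set()
    for tb in doc.entities:
        h = doc.head_token_index(tb)
        if h is not None:
            given_heads.add(h)
    gold = _gold_span_labels(doc) if with_gold else {}
    out = []
    for i, tok in enumerate(doc.tokens):
        if i in given_heads:
            continue
        if not lexicon.match(tok.base):
            continue
        out.append(SpanInstance(doc.doc_id, corpus_name, i, tok.surface,
                                tok.base, gold.get(i, NONE_LABEL)))
    return out


def _gold_relation_labels(doc: Document) -> dict[tuple, str]:
    """(trigger span, trigger type, arg span) -> role, from gold events."""
    idx = doc.ann_index()
    labels: dict[tuple, str] = {}
    for ev in sorted(doc.events, key=lambda e: e.id):
        trig = idx[ev.trigger]
        assert isinstance(trig, TextBound)
        for role, ref in ev.args:
            tgt = idx[ref]
            if isinstance(tgt, TextBound):
                span = tgt.span
            else:
                inner_trig = idx[tgt.trigger]
                span = inner_trig.span
            key = (trig.span, trig.type, span)
            labels.setdefault(key, role)
    return labels


def generate_relation_candidates(
        doc: Document,
        detected: Sequence[TextBound],
        corpus_name: str,
        attested_pairs: Optional[set[tuple[str, str]]] = None,
        head_types: Optional[set[str]] = None,
        with_gold: bool = False) -> list[RelationInstance]:
    """Same-sentence (trigger, candidate argument) pairs.

    ``detected`` holds the stage-one output (gold .a2 spans in training).
    Candidate arguments are given entities plus other detected spans; pairs
    may be restricted to globally attested (trigger type, argument type)
    combinations and to triggers of event-bearing ``head_types``.
    """
    doc.ensure_tokens()
    gold = _gold_relation_labels(doc) if with_gold else {}
    given = [(tb, True) for tb in doc.entities]
    others = [(tb, False) for tb in detected]
    out = []
    for trig in sorted(detected, key=lambda t: (t.start, t.end, t.type)):
        if head_types is not None and trig.type not in head_types:
            continue
        t_head = doc.head_token_index(trig)
        if t_head is None:
            continue
        t_sent = doc.token_sentence(t_head)
        for arg, is_given in sorted(given + others,
                                    key=lambda p: (p[0].start, p[0].end,
                                                   p[0].type)):
            if arg.span == trig.span and arg.type == trig.type:
                continue
            a_head = doc.head_token_index(arg)
            if a_head is None or doc.token_sentence(a_head) != t_sent:
                continue
            if (attested_pairs is not None
                    and (trig.type, arg.type) not in attested_pairs):
                continue
            role = gold.get((trig.span, trig.type, arg.span), NONE_LABEL)
            out.append(RelationInstance(
                doc.doc_id, corpus_name, trig.span, trig.type, arg.span,
                arg.type, base_form(arg.text.split()[-1]), is_given,
                gold=role, role=role if with_gold else NONE_LABEL))
    return out


def _gold_structures(doc: Document) -> dict[tuple, str]:
    """(trigger span, trigger type, member tuple) -> event type."""
    idx = doc.ann_index()
    out: dict[tuple, str] = {}
    for ev in doc.events:
        trig = idx[ev.trigger]
        assert isinstance(trig, TextBound)
        members = []
        for role, ref in ev.args:
            tgt = idx[ref]
            if isinstance(tgt, TextBound):
                span, atype = tgt.span, tgt.type
            else:
                inner = idx[tgt.trigger]
                span, atype = inner.span, tgt.type
            members.append((role, atype, span))
        out[(trig.span, trig.type, tuple(sorted(members)))] = ev.type
    return out


def enumerate_structures(
        trigger: TextBound,
        relations: Sequence[RelationInstance],
        signatures: set[Signature],
        doc: Document,
        corpus_name: str,
        cap: int = 1000,
        with_gold: bool = False) -> list[StructureInstance]:
    """All relation subsets of one trigger matching an attested signature.

    Arity is bounded by the largest attested signature for the trigger's
    type; enumeration beyond ``cap`` candidates is truncated (smallest
    structures first, then lexicographic) with a warning.
    """
    rels = sorted([r for r in relations if r.trigger_span == trigger.span
                   and r.trigger_type == trigger.type
                   and r.role != NONE_LABEL],
                  key=lambda r: (r.arg_span, r.arg_type or "", r.role))
    max_arity = max((len(pairs) for t, pairs in signatures
                     if t == trigger.type), default=0)
    gold = _gold_structures(doc) if with_gold else {}
    out = []
    truncated = False
    for size in range(0, min(max_arity, len(rels)) + 1):
        for combo in itertools.combinations(range(len(rels)), size):
            members = tuple(sorted(
                (rels[i].role, rels[i].arg_type or rels[i].arg_base,
                 rels[i].arg_span)
                for i in combo))
            inst = StructureInstance(
                doc.doc_id, corpus_name, trigger.span, trigger.type, members,
                n_competing=len(rels) - size,
                gold=gold.get((trigger.span, trigger.type, members),
                              NONE_LABEL))
            if inst.signature not in signatures:
                continue
            out.append(inst)
            if len(out) >= cap:
                truncated = True
                break
        if truncated:
            break
    if truncated:
        logger.warning("structure enumeration for %s trigger at %s "
                       "truncated at %d candidates", trigger.type,
                       trigger.span, cap)
    return out
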