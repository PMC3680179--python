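"""Corpora, annotation scopes, normalization and transferable-event counts.

A corpus is a named collection of standoff documents with train/devel/test
split labels.  Its *annotation scope* is the set of semantic types (entities,
events, roles), type combinations and event-structure signatures that its
annotation guidelines actually produced — computed here by enumeration over
the annotated (positive) instances.  Scopes drive both the negative-instance
filters and scope-restricted evaluation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .standoff import Document, EventAnn, TextBound

logger = logging.getLogger(__name__)

SPLITS = ("train", "devel", "test")

#: A structure signature: (event type, sorted tuple of (role, argument type)).
Signature = tuple[str, tuple[tuple[str, str], ...]]


@dataclass
class Corpus:
    name: str
    documents: dict[str, Document] = field(default_factory=dict)
    splits: dict[str, str] = field(default_factory=dict)
    #: optional per-document sub-domain labels (e.g. abstract vs full text),
    #: consulted only by domain-adaptation training.
    subdomains: dict[str, str] = field(default_factory=dict)

    def add(self, doc: Document, split: str = "train",
            subdomain: Optional[str] = None) -> None:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        self.documents[doc.doc_id] = doc
        self.splits[doc.doc_id] = split
        if subdomain is not None:
            self.subdomains[doc.doc_id] = subdomain

    def docs(self, splits: Iterable[str] = ("train",)) -> list[Document]:
        wanted = set(splits)
        bad = wanted - set(SPLITS)
        if bad:
            raise ValueError(f"unknown splits {sorted(bad)}")
        return [self.documents[d] for d in sorted(self.documents)
                if self.splits[d] in wanted]

    def domain_of(self, doc_id: str) -> str:
        sub = self.subdomains.get(doc_id)
        return f"{self.name}:{sub}" if sub else self.name


def _arg_type(doc: Document, ref: str, idx: dict) -> str:
    tgt = idx[ref]
    if isinstance(tgt, TextBound):
        return tgt.type
    assert isinstance(tgt, EventAnn)
    return tgt.type


def event_signature(doc: Document, ev: EventAnn,
                    idx: Optional[dict] = None) -> Signature:
    if idx is None:
        idx = doc.ann_index()
    pairs = tuple(sorted((role, _arg_type(doc, ref, idx))
                         for role, ref in ev.args))
    return (ev.type, pairs)


@dataclass
class CorpusScope:
    """Semantic types and combinations observed as positives in one corpus."""

    entity_types: set[str] = field(default_factory=set)
    #: types of .a2 text-bound annotations (triggers and detected entities) —
    #: the label space of the trigger/entity detector.
    span_types: set[str] = field(default_factory=set)
    event_types: set[str] = field(default_factory=set)
    role_types: set[str] = field(default_factory=set)
    #: (event type, role, argument type) triples observed on annotated events.
    relation_combos: set[tuple[str, str, str]] = field(default_factory=set)
    structure_signatures: Counter = field(default_factory=Counter)

    @property
    def arg_pairs(self) -> set[tuple[str, str]]:
        """(event type, argument type) pairs, roles projected out."""
        return {(t, a) for t, _r, a in self.relation_combos}

    def union(self, other: "CorpusScope") -> "CorpusScope":
        out = CorpusScope(
            entity_types=self.entity_types | other.entity_types,
            span_types=self.span_types | other.span_types,
            event_types=self.event_types | other.event_types,
            role_types=self.role_types | other.role_types,
            relation_combos=self.relation_combos | other.relation_combos,
        )
        out.structure_signatures = (self.structure_signatures
                                    + other.structure_signatures)
        return out


def compute_scope(corpus: Corpus,
                  splits: Iterable[str] = ("train",)) -> CorpusScope:
    """Enumerate the annotation scope of ``corpus`` over selected splits."""
    splits = tuple(splits)
    if not splits:
        raise ValueError("empty split selection")
    docs = corpus.docs(splits)
    if not docs:
        raise ValueError(
            f"corpus {corpus.name!r} has no documents in splits {splits}")
    scope = CorpusScope()
    for doc in docs:
        idx = doc.ann_index()
        for tb in doc.entities:
            scope.entity_types.add(tb.type)
        for tb in doc.triggers:
            scope.span_types.add(tb.type)
        for ev in doc.events:
            scope.event_types.add(ev.type)
            for role, ref in ev.args:
                scope.role_types.add(role)
                scope.relation_combos.add(
                    (ev.type, role, _arg_type(doc, ref, idx)))
            scope.structure_signatures[event_signature(doc, ev, idx)] += 1
    return scope


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationRules:
    """Label unification applied before multi-corpus training.

    ``ptm_collapse`` is carried here but deliberately *not* applied to stored
    corpora: collapsing post-translational-modification event types to one
    placeholder concerns only the label spaces of the argument/structure
    classifiers (the trigger detector keeps distinct types and assigns the
    final label), so it is consumed by the training configuration instead.
    """

    event_type_map: dict[str, str] = field(default_factory=dict)
    entity_type_map: dict[str, str] = field(default_factory=dict)
    role_map: dict[str, str] = field(default_factory=dict)
    roles_to_drop: set[str] = field(default_factory=set)
    drop_singleton_structures: bool = False
    ptm_collapse: Optional[dict[str, str]] = None

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationRules":
        return cls(
            event_type_map=dict(d.get("event_type_map", {})),
            entity_type_map=dict(d.get("entity_type_map", {})),
            role_map=dict(d.get("role_map", {})),
            roles_to_drop=set(d.get("roles_to_drop", [])),
            drop_singleton_structures=bool(
                d.get("drop_singleton_structures", False)),
            ptm_collapse=(dict(d["ptm_collapse"])
                          if d.get("ptm_collapse") else None),
        )


def _rewrite_doc(doc: Document, rules: NormalizationRules) -> Document:
    emap, nmap, rmap = (rules.event_type_map, rules.entity_type_map,
                        rules.role_map)
    entities = [replace(tb, type=nmap.get(tb.type, tb.type))
                for tb in doc.entities]
    triggers = [replace(tb, type=emap.get(tb.type, tb.type))
                for tb in doc.triggers]
    events = []
    for ev in doc.events:
        args = tuple((rmap.get(r, r), ref) for r, ref in ev.args
                     if rmap.get(r, r) not in rules.roles_to_drop
                     and r not in rules.roles_to_drop)
        events.append(replace(ev, type=emap.get(ev.type, ev.type), args=args))
    out = Document(doc_id=doc.doc_id, text=doc.text, entities=entities,
                   triggers=triggers, events=events,
                   modifications=list(doc.modifications),
                   extras=list(doc.extras), tokens=doc.tokens, deps=doc.deps)
    out.validate()
    return out


def _drop_events(doc: Document, doomed: set[str]) -> Document:
    """Remove events by id, cascading through event arguments."""
    changed = True
    dead = set(doomed)
    while changed:
        changed = False
        for ev in doc.events:
            if ev.id in dead:
                continue
            if any(ref in dead for _r, ref in ev.args):
                dead.add(ev.id)
                changed = True
    events = [ev for ev in doc.events if ev.id not in dead]
    mods = [m for m in doc.modifications if m.target not in dead]
    return replace(doc, events=events, modifications=mods)


def normalize_corpus(corpus: Corpus,
                     rules: NormalizationRules) -> Corpus:
    """Apply unification rules; idempotent under re-application."""
    out = Corpus(name=corpus.name, subdomains=dict(corpus.subdomains))
    for doc_id in sorted(corpus.documents):
        out.documents[doc_id] = _rewrite_doc(corpus.documents[doc_id], rules)
        out.splits[doc_id] = corpus.splits[doc_id]
    n_dropped = 0
    if rules.drop_singleton_structures:
        # signatures counted over the training split only
        counts: Counter = Counter()
        for doc in out.docs(("train",)):
            idx = doc.ann_index()
            for ev in doc.events:
                counts[event_signature(doc, ev, idx)] += 1
        for doc_id, doc in list(out.documents.items()):
            if out.splits[doc_id] != "train":
                continue
            idx = doc.ann_index()
            doomed = {ev.id for ev in doc.events
                      if counts[event_signature(doc, ev, idx)] == 1}
            if doomed:
                new_doc = _drop_events(doc, doomed)
                n_dropped += len(doc.events) - len(new_doc.events)
                new_doc.validate()
                out.documents[doc_id] = new_doc
    if n_dropped:
        logger.info("normalize_corpus(%s): removed %d singleton-structure "
                    "events", corpus.name, n_dropped)
    return out


# ---------------------------------------------------------------------------
# transferable events
# ---------------------------------------------------------------------------

def _event_transferable(doc: Document, ev: EventAnn, scope: CorpusScope,
                        idx: dict, recursive: bool) -> bool:
    if ev.type not in scope.event_types:
        return False
    if not recursive:
        return True
    for _role, ref in ev.args:
        tgt = idx[ref]
        if isinstance(tgt, EventAnn):
            if not _event_transferable(doc, tgt, scope, idx, recursive):
                return False
        else:
            known = (scope.entity_types | scope.span_types
                     | scope.event_types)
            if tgt.type not in known:
                return False
    return True


def count_transferable(source: Corpus, target_scope: CorpusScope,
                       splits: Iterable[str] = ("train", "devel"),
                       recursive: bool = True) -> int:
    """Number of source events expressible under the target scope.

    An event transfers when its type is in the target scope and — in the
    default recursive mode — every participant's type (entities, and event
    arguments checked recursively) is also in scope.  ``recursive=False``
    checks the event type only.
    """
    n = 0
    for doc in source.docs(splits):
        idx = doc.ann_index()
        for ev in doc.events:
            if _event_transferable(doc, ev, target_scope, idx, recursive):
                n += 1
    return n


def transfer_matrix(corpora: list[Corpus],
                    splits: Iterable[str] = ("train", "devel"),
                    recursive: bool = True) -> pd.DataFrame:
    """Pairwise transferable-event counts plus SUM and RATIO rows.

    Cell (r, c) counts events of corpus ``r`` transferable to corpus ``c``'s
    scope; SUM totals the events transferable *into* each column corpus from
    the others, and RATIO divides that by the column corpus's own event
    count."""
    names = [c.name for c in corpora]
    scopes = {c.name: compute_scope(c, splits) for c in corpora}
    own = {c.name: sum(len(d.events) for d in c.docs(splits))
           for c in corpora}
    mat = pd.DataFrame(index=names + ["SUM", "RATIO"], columns=names,
                       dtype=float)
    for src in corpora:
        for tgt in corpora:
            if src.name == tgt.name:
                mat.loc[src.name, tgt.name] = float("nan")
            else:
                mat.loc[src.name, tgt.name] = count_transferable(
                    src, scopes[tgt.name], splits, recursive)
    for name in names:
        incoming = mat.loc[names, name].dropna().sum()
        mat.loc["SUM", name] = incoming
        mat.loc["RATIO", name] = (incoming / own[name] if own[name]
                                  else float("nan"))
    return mat
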