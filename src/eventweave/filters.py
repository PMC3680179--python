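"""Negative-instance filtering for training on partially overlapping corpora.

Under the closed-world assumption, every unannotated candidate in a corpus
becomes a negative training example.  When corpora with different annotation
scopes are pooled, that assumption manufactures *spurious negatives*:
candidates that are unannotated only because their type was out of scope for
their source corpus.  The remedy implemented here builds, from positive
annotations only,

* per-type filters ``F_j`` (surface base forms for the span stage,
  (role, argument-type) combinations and structure signatures for the
  relation/structure stages, keyed by the owning event type), and
* per-corpus filters ``F_i`` as the union of ``F_j`` over the types
  annotated in corpus ``C_i``,

then admits a candidate from corpus ``C_i`` as a negative only if it matches
``F_i``.  Per-type training sets pool all positives ``P_j`` across corpora;
the negatives for type ``T_j`` are the filtered negatives ``N_i`` of the
corpora that annotate ``T_j`` plus the positives of every other type, and a
dedicated NONE classifier is trained on all filtered negatives versus all
positives.  The hedge stage is never filtered (every event carries hedge
annotation in every corpus).  Prediction applies no filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .corpus import Corpus, CorpusScope, Signature
from .instances import (Instance, RelationInstance, SpanInstance,
                        StructureInstance, TriggerLexicon)
from .standoff import NONE_LABEL

logger = logging.getLogger(__name__)

STAGES = ("span", "relation", "structure", "hedge")


@dataclass
class OverlapFilters:
    """Per-type filters F_j and per-corpus filters F_i for all stages."""

    #: span stage F_j: admissible base forms per span type
    span_by_type: dict[str, set[str]] = field(default_factory=dict)
    #: relation stage F_j, keyed by owning event/trigger type: argument
    #: types (or surface base forms for untyped arguments) seen as positives
    args_by_type: dict[str, set[str]] = field(default_factory=dict)
    #: structure stage F_j: attested signatures per event type
    sigs_by_type: dict[str, set[Signature]] = field(default_factory=dict)
    #: per-corpus F_i
    span_by_corpus: dict[str, set[str]] = field(default_factory=dict)
    pairs_by_corpus: dict[str, set[tuple[str, str]]] = field(
        default_factory=dict)
    sigs_by_corpus: dict[str, set[Signature]] = field(default_factory=dict)
    #: per-corpus annotated label sets, used to pick which corpora
    #: contribute negatives to each type's classifier
    span_types_by_corpus: dict[str, set[str]] = field(default_factory=dict)
    roles_by_corpus: dict[str, set[str]] = field(default_factory=dict)
    event_types_by_corpus: dict[str, set[str]] = field(default_factory=dict)

    @property
    def global_pairs(self) -> set[tuple[str, str]]:
        return {(t, a) for t, args in self.args_by_type.items()
                for a in args}

    @property
    def global_sigs(self) -> set[Signature]:
        return {s for sigs in self.sigs_by_type.values() for s in sigs}

    def to_text(self) -> str:
        """Plain-text sidecar serialization, one entry per line."""
        lines = []
        for t in sorted(self.span_by_type):
            for b in sorted(self.span_by_type[t]):
                lines.append(f"span\t{t}\t{b}")
        for t in sorted(self.args_by_type):
            for a in sorted(self.args_by_type[t]):
                lines.append(f"arg\t{t}\t{a}")
        for t in sorted(self.sigs_by_type):
            for sig in sorted(self.sigs_by_type[t]):
                pairs = ",".join(f"{r}:{a}" for r, a in sig[1])
                lines.append(f"sig\t{t}\t{pairs}")
        for c in sorted(self.span_by_corpus):
            for b in sorted(self.span_by_corpus[c]):
                lines.append(f"corpus-span\t{c}\t{b}")
        return "\n".join(lines) + ("\n" if lines else "")


def build_filters(corpora: Sequence[Corpus],
                  scopes: Mapping[str, CorpusScope],
                  lexicon: Optional[TriggerLexicon] = None,
                  splits: tuple[str, ...] = ("train",)) -> OverlapFilters:
    """Construct F_j / F_i from positive annotations only."""
    from .instances import build_trigger_lexicon

    if lexicon is None:
        lexicon = build_trigger_lexicon(corpora, splits=splits)
    f = OverlapFilters()
    f.span_by_type = {t: set(b) for t, b in lexicon.by_type.items()}
    for name, scope in scopes.items():
        for etype, _role, atype in scope.relation_combos:
            f.args_by_type.setdefault(etype, set()).add(atype)
        for sig in scope.structure_signatures:
            f.sigs_by_type.setdefault(sig[0], set()).add(sig)
    for corpus in corpora:
        scope = scopes[corpus.name]
        if not scope.span_types and not scope.event_types:
            logger.warning("corpus %s has an empty annotation scope; "
                           "its F_i is empty", corpus.name)
        f.span_by_corpus[corpus.name] = set().union(
            *(f.span_by_type.get(t, set()) for t in scope.span_types),
            set())
        f.pairs_by_corpus[corpus.name] = {
            (t, a) for t in scope.event_types
            for a in f.args_by_type.get(t, set())}
        f.sigs_by_corpus[corpus.name] = set().union(
            *(f.sigs_by_type.get(t, set()) for t in scope.event_types),
            set())
        f.span_types_by_corpus[corpus.name] = set(scope.span_types)
        f.roles_by_corpus[corpus.name] = set(scope.role_types)
        f.event_types_by_corpus[corpus.name] = set(scope.event_types)
    return f


def admissible_negative_span(candidate: SpanInstance,
                             filters: OverlapFilters) -> bool:
    """A span candidate is a valid negative for its source corpus iff its
    base form occurs as a positive of a type in the corpus's scope."""
    return candidate.base in filters.span_by_corpus.get(candidate.corpus,
                                                        set())


def admissible_negative_relation(
        candidate: RelationInstance | StructureInstance,
        filters: OverlapFilters) -> bool:
    """Type-combination admissibility for relation/structure negatives.

    Relations: the (trigger type, argument type) pair must be attested as a
    positive of an in-scope type; untyped arguments fall back to their
    surface base form.  Structures: the full signature must be attested for
    an in-scope type."""
    if isinstance(candidate, StructureInstance):
        return (candidate.signature
                in filters.sigs_by_corpus.get(candidate.corpus, set()))
    atype = candidate.arg_type if candidate.arg_type is not None \
        else candidate.arg_base
    return ((candidate.trigger_type, atype)
            in filters.pairs_by_corpus.get(candidate.corpus, set()))


# ---------------------------------------------------------------------------
# training-set assembly
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Per-type positive/negative instance pools with provenance.

    ``positives[j]`` is P_j; ``negatives[j]`` is N_j (filtered negatives of
    the T_j-annotated corpora plus other types' positives); ``none_pos`` /
    ``none_neg`` are the NONE classifier's P_neg / N_neg; ``raw_negatives``
    and ``filtered_negatives`` keep the per-corpus N_i' and N_i."""

    stage: str
    positives: dict[str, list[Instance]] = field(default_factory=dict)
    negatives: dict[str, list[Instance]] = field(default_factory=dict)
    none_pos: list[Instance] = field(default_factory=list)
    none_neg: list[Instance] = field(default_factory=list)
    raw_negatives: dict[str, list[Instance]] = field(default_factory=dict)
    filtered_negatives: dict[str, list[Instance]] = field(
        default_factory=dict)
    excluded_types: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[str]:
        return sorted(self.positives)


def _annotated_labels(filters: OverlapFilters, corpus: str,
                      stage: str) -> set[str]:
    if stage == "span":
        return filters.span_types_by_corpus.get(corpus, set())
    if stage == "relation":
        return filters.roles_by_corpus.get(corpus, set())
    if stage == "structure":
        return filters.event_types_by_corpus.get(corpus, set())
    raise ValueError(stage)


def assemble_training_sets(
        instances_by_corpus: Mapping[str, Sequence[Instance]],
        filters: OverlapFilters,
        stage: str,
        filtered: bool = True) -> TrainingSet:
    """Assemble per-type training sets from gold-labelled candidates.

    ``filtered=True`` applies the per-corpus spurious-negative filter and
    restricts each type's corpus-negatives to the corpora annotating it (the
    Multiple strategy); ``filtered=False`` is the closed-world merge.  The
    hedge stage is never filtered."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    ts = TrainingSet(stage=stage)
    for corpus in sorted(instances_by_corpus):
        raw = [i for i in instances_by_corpus[corpus]
               if i.gold == NONE_LABEL]
        ts.raw_negatives[corpus] = raw
        if not filtered or stage == "hedge":
            kept = list(raw)
        elif stage == "span":
            kept = [i for i in raw if admissible_negative_span(i, filters)]
        else:
            kept = [i for i in raw
                    if admissible_negative_relation(i, filters)]
        ts.filtered_negatives[corpus] = kept
        for inst in instances_by_corpus[corpus]:
            if inst.gold != NONE_LABEL:
                ts.positives.setdefault(inst.gold, []).append(inst)
    for label in list(ts.positives):
        if not ts.positives[label]:
            ts.excluded_types.append(label)
            del ts.positives[label]
    for label in ts.labels:
        negs: list[Instance] = []
        for corpus in sorted(instances_by_corpus):
            if (filtered and stage not in ("hedge",)
                    and label not in _annotated_labels(filters, corpus,
                                                       stage)):
                continue
            negs.extend(ts.filtered_negatives[corpus])
        for other in ts.labels:
            if other != label:
                negs.extend(ts.positives[other])
        ts.negatives[label] = negs
    for corpus in sorted(instances_by_corpus):
        ts.none_pos.extend(ts.filtered_negatives[corpus])
    for label in ts.labels:
        ts.none_neg.extend(ts.positives[label])
    return ts
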