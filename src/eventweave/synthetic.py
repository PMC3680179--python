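"""Synthetic multi-corpus generator with controllable annotation scopes.

Generates document sets that emulate the structure of real event-annotated
corpora whose scopes only partially overlap: every corpus's *text* is drawn
from one shared template language covering the union of the scenario's event
types, but each corpus *annotates* only its in-scope types.  Out-of-scope
mentions are therefore planted unannotated by construction, which is exactly
the situation in which a naive corpus merge manufactures spurious negative
training instances.

Text is templated English-like clauses (subject - trigger - object), with
optional nested regulation events, negation/speculation cues, site (Entity)
arguments and trigger words deliberately ambiguous between two event types.
The token/dependency layer is a deterministic head-chain per clause.  Equal
seeds yield byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .corpus import Corpus
from .standoff import (Document, EventAnn, ModificationAnn, TextBound,
                       Token, base_form)

PROTEINS = ("TP53", "MDM2", "STAT3", "AKT1", "IL2", "TNF", "EGFR",
            "BRCA1", "MYC", "JAK2", "FOXP3", "NFKB1")
SITES = ("Lys4", "Ser15", "Thr308", "Lys27", "Tyr701")

TRIGGERS = {
    "Phosphorylation": ("phosphorylation",),
    "Methylation": ("methylation",),
    "Binding": ("binding", "interaction"),
    "Gene_expression": ("expression", "overexpression"),
    "Positive_regulation": ("activation", "upregulation"),
    "Negative_regulation": ("inhibition", "suppression"),
}
#: word usable as a trigger of two different types, disambiguated only by a
#: context marker token
AMBIGUOUS_TRIGGER = "modification"
AMBIGUOUS_MARKERS = {
    "Phosphorylation": "kinase-mediated",
    "Methylation": "histone-linked",
}
SIMPLE_TYPES = ("Phosphorylation", "Methylation", "Binding",
                "Gene_expression")
REGULATION_TYPES = ("Positive_regulation", "Negative_regulation")


@dataclass(frozen=True)
class CorpusSpec:
    name: str
    event_types: tuple[str, ...]


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    corpora: tuple[CorpusSpec, ...]
    docs_per_corpus: int = 30
    sentences_per_doc: int = 4
    negation_prob: float = 0.0
    speculation_prob: float = 0.0
    nesting_prob: float = 0.0
    site_prob: float = 0.0
    decoy_prob: float = 0.15
    ambiguous_prob: float = 0.0
    train_frac: float = 0.7
    devel_frac: float = 0.1
    seed: int = 0

    @property
    def union_types(self) -> tuple[str, ...]:
        return tuple(sorted({t for c in self.corpora
                             for t in c.event_types}))

    @property
    def shared_types(self) -> tuple[str, ...]:
        counts: dict[str, int] = {}
        for c in self.corpora:
            for t in set(c.event_types):
                counts[t] = counts.get(t, 0) + 1
        return tuple(sorted(t for t, n in counts.items() if n >= 2))

    def validate(self) -> None:
        if not self.corpora:
            raise ValueError("scenario config: corpora list is empty")
        names = [c.name for c in self.corpora]
        if len(set(names)) != len(names):
            raise ValueError(f"scenario config: duplicate corpus names "
                             f"{names}")
        for c in self.corpora:
            unknown = set(c.event_types) - set(TRIGGERS)
            if unknown:
                raise ValueError(
                    f"scenario config: corpus {c.name}: unknown event "
                    f"types {sorted(unknown)}")
        for fld in ("negation_prob", "speculation_prob", "nesting_prob",
                    "site_prob", "decoy_prob", "ambiguous_prob",
                    "train_frac", "devel_frac"):
            v = getattr(self, fld)
            if not 0.0 <= v <= 1.0:
                raise ValueError(
                    f"scenario config: field {fld} = {v} outside [0, 1]")
        if self.docs_per_corpus < 1:
            raise ValueError("scenario config: docs_per_corpus < 1")
        if len(self.corpora) > 1 and not self.shared_types:
            raise ValueError("scenario config: multi-corpus scenarios need "
                             "at least one shared event type")


# ---------------------------------------------------------------------------
# sentence plans
# ---------------------------------------------------------------------------

@dataclass
class PlannedEvent:
    etype: str
    trigger_idx: int  # token index within the sentence
    #: args: (role, ("ent"|"site", token idx) or ("ev", planned event idx))
    args: list[tuple[str, tuple]] = field(default_factory=list)
    hedge: Optional[str] = None


@dataclass
class SentencePlan:
    tokens: list[str]
    entity_idxs: list[int] = field(default_factory=list)  # Protein tokens
    site_idxs: list[int] = field(default_factory=list)    # Entity tokens
    events: list[PlannedEvent] = field(default_factory=list)


def _plan_simple(rng: random.Random, etype: str,
                 cfg: ScenarioConfig) -> SentencePlan:
    hedge = None
    r = rng.random()
    if r < cfg.negation_prob:
        hedge = "Negation"
    elif r < cfg.negation_prob + cfg.speculation_prob:
        hedge = "Speculation"
    p1 = rng.choice(PROTEINS)
    p2 = rng.choice([p for p in PROTEINS if p != p1])
    ambiguous = (etype in AMBIGUOUS_MARKERS
                 and rng.random() < cfg.ambiguous_prob)
    if ambiguous:
        trig_word = AMBIGUOUS_TRIGGER
        marker = AMBIGUOUS_MARKERS[etype]
    else:
        trig_word = rng.choice(TRIGGERS[etype])
        marker = None
    with_site = (etype in ("Phosphorylation", "Methylation")
                 and rng.random() < cfg.site_prob)
    use_cause = (etype in ("Phosphorylation", "Methylation")
                 and not with_site and not ambiguous
                 and hedge is None and rng.random() < 0.4)

    plan = SentencePlan(tokens=[])
    toks = plan.tokens
    ev = PlannedEvent(etype, 0, hedge=hedge)
    if use_cause:
        toks.extend([p1, "undergoes", trig_word, "by", p2, "."])
        plan.entity_idxs = [0, 4]
        ev.trigger_idx = 2
        ev.args = [("Theme", ("ent", 0)), ("Cause", ("ent", 4))]
    elif etype == "Binding" and rng.random() < 0.6:
        det = "No" if hedge == "Negation" else "The"
        toks.extend([det, trig_word, "of", p1, "and", p2])
        if hedge == "Speculation":
            toks.extend(["was", "possibly", "detected", "."])
        else:
            toks.extend(["was", "detected", "."])
        plan.entity_idxs = [3, 5]
        ev.trigger_idx = 1
        ev.args = [("Theme", ("ent", 3)), ("Theme", ("ent", 5))]
    else:
        det = "No" if hedge == "Negation" else "The"
        toks.append(det)
        if marker:
            toks.append(marker)
        ti = len(toks)
        toks.extend([trig_word, "of", p1])
        pi = len(toks) - 1
        ev.trigger_idx = ti
        ev.args = [("Theme", ("ent", pi))]
        plan.entity_idxs = [pi]
        if with_site:
            toks.extend(["at", rng.choice(SITES)])
            si = len(toks) - 1
            plan.site_idxs = [si]
            ev.args.append(("Site", ("site", si)))
        if hedge == "Speculation":
            toks.extend(["was", "possibly", "observed", "."])
        else:
            toks.extend(["was", "observed", "."])
    plan.events = [ev]
    return plan


def _plan_regulation(rng: random.Random, etype: str,
                     cfg: ScenarioConfig) -> SentencePlan:
    p1 = rng.choice(PROTEINS)
    p3 = rng.choice([p for p in PROTEINS if p != p1])
    rtrig = rng.choice(TRIGGERS[etype])
    nested_pool = [t for t in SIMPLE_TYPES
                   if t in set(cfg.union_types)]
    plan = SentencePlan(tokens=[])
    toks = plan.tokens
    if nested_pool and rng.random() < cfg.nesting_prob:
        itype = rng.choice(nested_pool)
        itrig = rng.choice(TRIGGERS[itype])
        toks.extend([p3, "causes", "the", rtrig, "of", "the", itrig,
                     "of", p1, "."])
        plan.entity_idxs = [0, 8]
        inner = PlannedEvent(itype, 6, args=[("Theme", ("ent", 8))])
        outer = PlannedEvent(etype, 3, args=[("Theme", ("ev", 0)),
                                             ("Cause", ("ent", 0))])
        plan.events = [inner, outer]
    else:
        toks.extend([p3, "mediates", "the", rtrig, "of", p1, "."])
        plan.entity_idxs = [0, 5]
        plan.events = [PlannedEvent(etype, 3,
                                    args=[("Theme", ("ent", 5)),
                                          ("Cause", ("ent", 0))])]
    return plan


def _plan_decoy(rng: random.Random) -> SentencePlan:
    p1 = rng.choice(PROTEINS)
    if rng.random() < 0.5:
        toks = ["The", "role", "of", p1, "remains", "unclear", "."]
        idx = 3
    else:
        toks = [p1, "levels", "were", "measured", "in", "cells", "."]
        idx = 0
    return SentencePlan(tokens=toks, entity_idxs=[idx])


def _plan_sentence(rng: random.Random, cfg: ScenarioConfig) -> SentencePlan:
    if rng.random() < cfg.decoy_prob:
        return _plan_decoy(rng)
    etype = rng.choice(list(cfg.union_types))
    if etype in REGULATION_TYPES:
        return _plan_regulation(rng, etype, cfg)
    return _plan_simple(rng, etype, cfg)


# ---------------------------------------------------------------------------
# document assembly
# ---------------------------------------------------------------------------

def _assemble_document(doc_id: str, plans: list[SentencePlan],
                       scope: set[str]) -> Document:
    lines = [" ".join(p.tokens) for p in plans]
    text = "\n".join(lines) + "\n"
    tokens: list[Token] = []
    token_span: list[list[tuple[int, int]]] = []
    deps: list[tuple[int, int, str]] = []
    pos = 0
    for sent_i, plan in enumerate(plans):
        spans = []
        sent_start_tok = len(tokens)
        for k, w in enumerate(plan.tokens):
            spans.append((pos, pos + len(w)))
            tokens.append(Token(pos, pos + len(w), w, base_form(w), sent_i))
            pos += len(w) + 1
        token_span.append(spans)
        # deterministic head chain: token k attaches to token k+1
        for k in range(len(plan.tokens) - 1):
            deps.append((sent_start_tok + k + 1, sent_start_tok + k, "dep"))
    doc = Document(doc_id=doc_id, text=text, tokens=tokens, deps=deps)

    tid = 0
    for sent_i, plan in enumerate(plans):
        spans = token_span[sent_i]
        for k in plan.entity_idxs:
            tid += 1
            s, e = spans[k]
            doc.entities.append(TextBound(f"T{tid}", "Protein", s, e,
                                          plan.tokens[k]))
    eid = 0
    mid = 0
    for sent_i, plan in enumerate(plans):
        spans = token_span[sent_i]
        annotatable: dict[int, bool] = {}
        for i, ev in enumerate(plan.events):
            ok = ev.etype in scope
            for _role, tgt in ev.args:
                if tgt[0] == "ev" and not annotatable.get(tgt[1], False):
                    ok = False
            annotatable[i] = ok
        ev_ids: dict[int, str] = {}
        ent_ids = {tb.span: tb.id for tb in doc.entities}
        for i, ev in enumerate(plan.events):
            if not annotatable[i]:
                continue
            s, e = spans[ev.trigger_idx]
            tid += 1
            trig_id = f"T{tid}"
            doc.triggers.append(TextBound(trig_id, ev.etype, s, e,
                                          plan.tokens[ev.trigger_idx]))
            args = []
            for role, tgt in ev.args:
                if tgt[0] == "ent":
                    args.append((role, ent_ids[spans[tgt[1]]]))
                elif tgt[0] == "site":
                    ss, se = spans[tgt[1]]
                    tid += 1
                    doc.triggers.append(TextBound(f"T{tid}", "Entity", ss,
                                                  se, plan.tokens[tgt[1]]))
                    args.append((role, f"T{tid}"))
                else:
                    args.append((role, ev_ids[tgt[1]]))
            eid += 1
            ev_ids[i] = f"E{eid}"
            doc.events.append(EventAnn(f"E{eid}", ev.etype, trig_id,
                                       tuple(args)))
            if ev.hedge is not None:
                mid += 1
                doc.modifications.append(
                    ModificationAnn(f"M{mid}", ev.hedge, ev_ids[i]))
    doc.validate()
    return doc


def generate(config: ScenarioConfig) -> list[Corpus]:
    """Generate all corpora of a scenario; same seed, same bytes."""
    config.validate()
    corpora = []
    n_train = round(config.docs_per_corpus * config.train_frac)
    n_devel = round(config.docs_per_corpus * config.devel_frac)
    for spec in config.corpora:
        rng = random.Random(f"{config.seed}:{config.name}:{spec.name}")
        corpus = Corpus(name=spec.name)
        scope = set(spec.event_types)
        for d in range(config.docs_per_corpus):
            plans = [_plan_sentence(rng, config)
                     for _ in range(config.sentences_per_doc)]
            doc = _assemble_document(f"{spec.name}-{d:04d}", plans, scope)
            if d < n_train:
                split = "train"
            elif d < n_train + n_devel:
                split = "devel"
            else:
                split = "test"
            corpus.add(doc, split)
        corpora.append(corpus)
    return corpora


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def standard_scenarios() -> dict[str, ScenarioConfig]:
    """Named scenario configurations used throughout the test-suite."""
    return {
        "identical-scopes": ScenarioConfig(
            name="identical-scopes",
            corpora=(CorpusSpec("X1", ("Phosphorylation", "Binding",
                                       "Gene_expression")),
                     CorpusSpec("X2", ("Phosphorylation", "Binding",
                                       "Gene_expression"))),
            docs_per_corpus=30, site_prob=0.3),
        "disjoint-plus-shared": ScenarioConfig(
            name="disjoint-plus-shared",
            corpora=(CorpusSpec("A", ("Phosphorylation", "Binding")),
                     CorpusSpec("B", ("Phosphorylation", "Methylation"))),
            docs_per_corpus=150, sentences_per_doc=4,
            ambiguous_prob=0.25, site_prob=0.2),
        "nested-regulation": ScenarioConfig(
            name="nested-regulation",
            corpora=(CorpusSpec("A", ("Positive_regulation",
                                      "Negative_regulation",
                                      "Phosphorylation", "Gene_expression",
                                      "Binding")),
                     CorpusSpec("B", ("Positive_regulation",
                                      "Negative_regulation",
                                      "Phosphorylation", "Gene_expression",
                                      "Methylation"))),
            docs_per_corpus=60, nesting_prob=0.6),
        "hedge-mix": ScenarioConfig(
            name="hedge-mix",
            corpora=(CorpusSpec("A", ("Phosphorylation", "Gene_expression",
                                      "Binding")),
                     CorpusSpec("B", ("Phosphorylation", "Gene_expression",
                                      "Methylation"))),
            docs_per_corpus=60, negation_prob=0.2, speculation_prob=0.2),
    }


def random_scenario(seed: int) -> ScenarioConfig:
    """A small random scenario with guaranteed partial overlap."""
    rng = random.Random(f"scenario:{seed}")
    n_corpora = rng.choice([2, 2, 3])
    types = list(TRIGGERS)
    shared = rng.choice(types)
    specs = []
    for i in range(n_corpora):
        k = rng.randint(1, 3)
        own = rng.sample([t for t in types if t != shared], k)
        specs.append(CorpusSpec(f"C{i + 1}",
                                tuple(sorted(set(own) | {shared}))))
    return ScenarioConfig(
        name=f"random-{seed}",
        corpora=tuple(specs),
        docs_per_corpus=rng.randint(8, 14),
        sentences_per_doc=3,
        negation_prob=rng.choice([0.0, 0.15]),
        speculation_prob=rng.choice([0.0, 0.15]),
        nesting_prob=rng.choice([0.0, 0.4]),
        site_prob=rng.choice([0.0, 0.3]),
        ambiguous_prob=rng.choice([0.0, 0.3]),
        seed=seed)
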