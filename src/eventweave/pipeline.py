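"""End-to-end extraction pipeline and shared-task-style scoring.

Extraction runs four stages in fixed order — trigger/entity detection,
argument (relation) detection, multiple-argument (structure) detection and
hedge detection — with each stage consuming the previous stage's
predictions.  Scoring follows the shared-task conventions: an event matches
a gold event when the types agree, the trigger spans match (strictly, or
approximately within the gold span extended by one token on each side) and
the argument sets match role-wise, recursively through event arguments;
with the FULL criteria the negation/speculation flags must also agree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .corpus import CorpusScope
from .instances import (HedgeInstance, RelationInstance,
                        enumerate_structures, generate_relation_candidates,
                        generate_span_candidates)
from .standoff import (NONE_LABEL, Document, EventAnn, ModificationAnn,
                       TextBound)
from .strategies import ModelSet, collapse_type, resolve_label

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract(doc: Document, models: ModelSet, corpus_name: str = "",
            domain: Optional[str] = None) -> Document:
    """Run the four-stage pipeline on one document.

    Returns a new document carrying the given entities plus predicted
    triggers, events and modifications.  ``domain`` is required for
    easyadapt models (their application is corpus-dependent)."""
    if models.strategy == "easyadapt" and domain is None:
        raise ValueError("an easyadapt model requires a domain to be "
                         "applied; pass domain=<corpus or subdomain>")
    doc.ensure_tokens()
    out = Document(doc_id=doc.doc_id, text=doc.text,
                   entities=list(doc.entities), tokens=doc.tokens,
                   deps=doc.deps)
    threshold = models.config.threshold
    docs = {doc.doc_id: doc}

    # stage 1: trigger/entity detection
    span_model = models.stage_models.get("span")
    triggers: list[TextBound] = []
    if span_model is not None:
        cands = generate_span_candidates(doc, models.lexicon, corpus_name)
        if cands:
            scored = models.score_stage("span", cands, docs, domain)
            n = 0
            for cand, (scores, none_score) in zip(cands, scored):
                label = resolve_label(scores, none_score, threshold)
                if label == NONE_LABEL:
                    continue
                n += 1
                tok = doc.tokens[cand.token_index]
                triggers.append(TextBound(f"T{1000 + n}", label, tok.start,
                                          tok.end, tok.surface))
    out.triggers = triggers

    # stage 2: argument detection on predicted triggers
    detected_rels: list[RelationInstance] = []
    rel_model = models.stage_models.get("relation")
    if rel_model is not None and triggers:
        cands = generate_relation_candidates(
            doc, triggers, corpus_name,
            attested_pairs=models.filters.global_pairs,
            head_types=models.head_types)
        if cands:
            scored = models.score_stage("relation", cands, docs, domain)
            for cand, (scores, none_score) in zip(cands, scored):
                role = resolve_label(scores, none_score, threshold)
                if role != NONE_LABEL:
                    detected_rels.append(replace(cand, role=role))

    # stage 3: multiple-argument detection -> events
    accepted: dict[tuple, list] = {}
    struct_model = models.stage_models.get("structure")
    if struct_model is not None:
        for trig in sorted(triggers, key=lambda t: (t.start, t.end, t.type)):
            if trig.type not in models.head_types:
                continue
            structs = enumerate_structures(
                trig, detected_rels, models.filters.global_sigs, doc,
                corpus_name, cap=models.config.structure_cap)
            if not structs:
                continue
            scored = models.score_stage("structure", structs, docs, domain)
            keep = []
            for inst, (scores, none_score) in zip(structs, scored):
                label = resolve_label(scores, none_score, threshold)
                if label != NONE_LABEL and \
                        label == collapse_type(trig.type, models.config):
                    keep.append(inst)
            # drop structures strictly contained in another accepted
            # structure of the same trigger
            keep = [s for s in keep
                    if not any(set(s.members) < set(t.members)
                               for t in keep)]
            if keep:
                accepted[(trig.span, trig.type)] = keep
    events = _build_events(out, accepted)
    out.events = events

    # stage 4: hedge detection
    mods: list[ModificationAnn] = []
    hedge_model = models.stage_models.get("hedge")
    if hedge_model is not None and events:
        idx = {tb.id: tb for tb in out.triggers}
        insts = []
        for ev in events:
            trig = idx[ev.trigger]
            members = []
            ev_idx = out.ann_index()
            for role, ref in ev.args:
                tgt = ev_idx[ref]
                if isinstance(tgt, TextBound):
                    members.append((role, tgt.type, tgt.span))
                else:
                    inner = ev_idx[tgt.trigger]
                    members.append((role, tgt.type, inner.span))
            insts.append(HedgeInstance(doc.doc_id, corpus_name, ev.id,
                                       trig.span, trig.type,
                                       tuple(sorted(members))))
        scored = models.score_stage("hedge", insts, docs, domain)
        m = 0
        for ev, (scores, none_score) in zip(events, scored):
            kind = resolve_label(scores, none_score, threshold)
            if kind != NONE_LABEL:
                m += 1
                mods.append(ModificationAnn(f"M{m}", kind, ev.id))
    out.modifications = mods
    out.validate()
    return out


def _build_events(doc: Document, accepted: Mapping[tuple, list]
                  ) -> list[EventAnn]:
    """Assemble events bottom-up so event arguments reference built events.

    A structure member whose argument span is a predicted trigger refers to
    the (first) event anchored at that trigger; structures whose inner
    trigger never yields an event are dropped (no dangling references)."""
    entity_by_span: dict[tuple, TextBound] = {}
    for tb in doc.entities:
        entity_by_span.setdefault(tb.span, tb)
    eventful_spans = {key[0] for key in accepted}
    events: list[EventAnn] = []
    event_at: dict[tuple, str] = {}  # trigger span -> first built event id
    pending = dict(accepted)
    eid = 0
    progress = True
    while pending and progress:
        progress = False
        pending_spans = {k[0] for k in pending}
        for key in sorted(pending):
            trig_span, trig_type = key
            deps = {span for s in pending[key]
                    for _r, _a, span in s.members}
            if (deps & pending_spans) - {trig_span}:
                continue  # an argument trigger's events are not built yet
            trig_id = None
            for tb in doc.triggers:
                if tb.span == trig_span and tb.type == trig_type:
                    trig_id = tb.id
            for s in sorted(pending[key], key=lambda s: s.members):
                args = []
                ok = True
                for role, _atype, span in s.members:
                    if span == trig_span:
                        ok = False  # self-reference
                        break
                    if span in event_at:
                        args.append((role, event_at[span]))
                    elif span in entity_by_span:
                        args.append((role, entity_by_span[span].id))
                    elif span not in eventful_spans:
                        # detected text-bound (e.g. an Entity span) with no
                        # event of its own: reference it directly
                        inner = next((tb.id for tb in doc.triggers
                                      if tb.span == span), None)
                        if inner is None:
                            ok = False
                            break
                        args.append((role, inner))
                    else:
                        ok = False  # inner trigger yielded no event
                        break
                if not ok:
                    continue
                eid += 1
                ev = EventAnn(f"E{eid}", trig_type, trig_id, tuple(args))
                events.append(ev)
                event_at.setdefault(trig_span, ev.id)
            del pending[key]
            progress = True
    if pending:
        logger.info("dropped %d triggers' event structures with cyclic "
                    "argument references", len(pending))
    return events


# ---------------------------------------------------------------------------
# scope restriction
# ---------------------------------------------------------------------------

def scope_restrict(doc: Document, target_scope: CorpusScope) -> Document:
    """Remove predicted events whose type (or any recursive event argument's
    type) is outside the target scope; removal cascades."""
    evs = doc.event_by_id()
    doomed = {eid for eid, ev in evs.items()
              if ev.type not in target_scope.event_types}
    changed = True
    while changed:
        changed = False
        for eid, ev in evs.items():
            if eid in doomed:
                continue
            if any(ref in doomed for _r, ref in ev.args):
                doomed.add(eid)
                changed = True
    events = [ev for ev in doc.events if ev.id not in doomed]
    mods = [m for m in doc.modifications if m.target not in doomed]
    return replace(doc, events=events, modifications=mods)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class TypeCounts:
    gold: int = 0
    predicted: int = 0
    matched: int = 0

    @property
    def recall(self) -> float:
        return self.matched / self.gold if self.gold else 0.0

    @property
    def precision(self) -> float:
        return self.matched / self.predicted if self.predicted else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


@dataclass
class ScoreReport:
    overall: TypeCounts = field(default_factory=TypeCounts)
    per_type: dict[str, TypeCounts] = field(default_factory=dict)

    def to_tsv(self) -> str:
        lines = ["type\trecall\tprecision\tf1\tgold\tmatched\tpredicted"]
        for t in sorted(self.per_type):
            c = self.per_type[t]
            lines.append(f"{t}\t{c.recall:.4f}\t{c.precision:.4f}\t"
                         f"{c.f1:.4f}\t{c.gold}\t{c.matched}\t{c.predicted}")
        c = self.overall
        lines.append(f"TOTAL\t{c.recall:.4f}\t{c.precision:.4f}\t"
                     f"{c.f1:.4f}\t{c.gold}\t{c.matched}\t{c.predicted}")
        return "\n".join(lines) + "\n"


def _span_match(gold_tb: TextBound, pred_tb: TextBound, gold_doc: Document,
                approximate: bool, slack: int = 1) -> bool:
    if gold_tb.span == pred_tb.span:
        return True
    if not approximate:
        return False
    toks = gold_doc.ensure_tokens()
    overlapping = [i for i, t in enumerate(toks)
                   if t.start < gold_tb.end and t.end > gold_tb.start]
    if not overlapping:
        return False
    lo = max(0, overlapping[0] - slack)
    hi = min(len(toks) - 1, overlapping[-1] + slack)
    ext_start, ext_end = toks[lo].start, toks[hi].end
    return ext_start <= pred_tb.start and pred_tb.end <= ext_end


def _event_matches(g: EventAnn, p: EventAnn, gdoc: Document, pdoc: Document,
                   gidx: dict, pidx: dict, approximate: bool,
                   memo: dict) -> bool:
    key = (g.id, p.id)
    if key in memo:
        return memo[key]
    memo[key] = False  # guard against reference cycles
    ok = _event_matches_inner(g, p, gdoc, pdoc, gidx, pidx, approximate,
                              memo)
    memo[key] = ok
    return ok


def _event_matches_inner(g, p, gdoc, pdoc, gidx, pidx, approximate, memo):
    if g.type != p.type:
        return False
    gt, pt = gidx[g.trigger], pidx[p.trigger]
    if not _span_match(gt, pt, gdoc, approximate):
        return False
    if len(g.args) != len(p.args):
        return False
    groles = sorted(r for r, _ in g.args)
    proles = sorted(r for r, _ in p.args)
    if groles != proles:
        return False

    def arg_matches(gref: str, pref: str) -> bool:
        gtgt, ptgt = gidx[gref], pidx[pref]
        if isinstance(gtgt, TextBound) and isinstance(ptgt, TextBound):
            return (gtgt.type == ptgt.type
                    and _span_match(gtgt, ptgt, gdoc, approximate))
        if isinstance(gtgt, EventAnn) and isinstance(ptgt, EventAnn):
            return _event_matches(gtgt, ptgt, gdoc, pdoc, gidx, pidx,
                                  approximate, memo)
        return False

    # role-wise one-to-one assignment; arities are tiny, so permutation
    # search is exhaustive and exact
    by_role_g: dict[str, list[str]] = {}
    by_role_p: dict[str, list[str]] = {}
    for r, ref in g.args:
        by_role_g.setdefault(r, []).append(ref)
    for r, ref in p.args:
        by_role_p.setdefault(r, []).append(ref)
    for role, grefs in by_role_g.items():
        prefs = by_role_p[role]
        if len(grefs) != len(prefs):
            return False
        matched = False
        for perm in itertools.permutations(prefs):
            if all(arg_matches(a, b) for a, b in zip(grefs, perm)):
                matched = True
                break
        if not matched:
            return False
    return True


def _mod_kinds(doc: Document, eid: str) -> frozenset:
    return frozenset(m.kind for m in doc.modifications if m.target == eid)


def score(gold: Sequence[Document], predicted: Sequence[Document],
          criteria: str = "approximate", full: bool = False) -> ScoreReport:
    """Event-level recall/precision/F1, overall and per event type.

    Matching is greedy and one-to-one in document (id) order.  With
    ``full=True`` the negation/speculation flags of matched events must
    also agree."""
    if criteria not in ("strict", "approximate"):
        raise ValueError(f"unknown criteria {criteria!r}")
    approximate = criteria == "approximate"
    gmap = {d.doc_id: d for d in gold}
    pmap = {d.doc_id: d for d in predicted}
    if set(gmap) != set(pmap):
        raise ValueError(
            "gold and predicted document sets differ: "
            f"{sorted(set(gmap) ^ set(pmap))[:5]}")
    report = ScoreReport()

    def bump(tc_type: str, attr: str) -> None:
        tc = report.per_type.setdefault(tc_type, TypeCounts())
        setattr(tc, attr, getattr(tc, attr) + 1)
        setattr(report.overall, attr, getattr(report.overall, attr) + 1)

    for doc_id in sorted(gmap):
        gdoc, pdoc = gmap[doc_id], pmap[doc_id]
        gidx, pidx = gdoc.ann_index(), pdoc.ann_index()
        gevents = sorted(gdoc.events, key=lambda e: e.id)
        pevents = sorted(pdoc.events, key=lambda e: e.id)
        for ev in gevents:
            bump(ev.type, "gold")
        for ev in pevents:
            bump(ev.type, "predicted")
        memo: dict = {}
        used: set[str] = set()
        for g in gevents:
            for p in pevents:
                if p.id in used:
                    continue
                if not _event_matches(g, p, gdoc, pdoc, gidx, pidx,
                                      approximate, memo):
                    continue
                if full and _mod_kinds(gdoc, g.id) != _mod_kinds(pdoc,
                                                                 p.id):
                    continue
                used.add(p.id)
                bump(g.type, "matched")
                break
    return report
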