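"""Independent brute-force oracles used by the test-suite.

Everything here is written as literal nested loops over document
annotations, independently of the package's candidate-generation and
filter machinery, so it can serve as ground truth for equivalence tests.
"""

from __future__ import annotations

from collections import Counter

from eventweave.corpus import Corpus
from eventweave.standoff import Document, EventAnn, base_form


def oracle_scope(corpus: Corpus, splits=("train",)):
    """Scope sets by direct enumeration."""
    entity_types, span_types, event_types, role_types = (set(), set(),
                                                         set(), set())
    combos = set()
    signatures: Counter = Counter()
    for doc in corpus.docs(splits):
        idx = doc.ann_index()

        def typ(ref):
            return idx[ref].type

        for tb in doc.entities:
            entity_types.add(tb.type)
        for tb in doc.triggers:
            span_types.add(tb.type)
        for ev in doc.events:
            event_types.add(ev.type)
            for role, ref in ev.args:
                role_types.add(role)
                combos.add((ev.type, role, typ(ref)))
            sig = (ev.type,
                   tuple(sorted((r, typ(ref)) for r, ref in ev.args)))
            signatures[sig] += 1
    return (entity_types, span_types, event_types, role_types, combos,
            signatures)


def oracle_transferable(source: Corpus, target: Corpus,
                        splits=("train", "devel")) -> int:
    """Recursive transferability by direct recursion over event graphs."""
    (ent_t, span_t, ev_t, _roles, _combos, _sigs) = oracle_scope(
        target, splits)
    known = ent_t | span_t | ev_t
    n = 0
    for doc in source.docs(splits):
        idx = doc.ann_index()

        def ok(ev: EventAnn) -> bool:
            if ev.type not in ev_t:
                return False
            for _role, ref in ev.args:
                tgt = idx[ref]
                if isinstance(tgt, EventAnn):
                    if not ok(tgt):
                        return False
                elif tgt.type not in known:
                    return False
            return True

        n += sum(ok(ev) for ev in doc.events)
    return n


def _head_token(doc: Document, start: int, end: int):
    head = None
    for i, t in enumerate(doc.ensure_tokens()):
        if t.start < end and t.end > start:
            head = i
    return head


def oracle_span_sets(corpora: list[Corpus], filtered: bool):
    """Literal construction of the span-stage training sets.

    Steps: pool positives P_j; build surface filters F_j from them; build
    per-corpus F_i over in-scope types; enumerate token candidates; keep a
    NONE candidate of corpus i only if its base form is in F_i (when
    ``filtered``); per-type negatives come from the corpora annotating the
    type plus other types' positives.  Returns per-type positive/negative
    key multisets plus the NONE classifier's sets."""
    # step 1-2: P_j and F_j
    F: dict[str, set[str]] = {}
    scope_span_types: dict[str, set[str]] = {}
    for c in corpora:
        scope_span_types[c.name] = set()
        for doc in c.docs(("train",)):
            for tb in doc.triggers:
                F.setdefault(tb.type, set()).add(
                    base_form(tb.text.split()[-1]))
                scope_span_types[c.name].add(tb.type)
    all_bases = set().union(*F.values()) if F else set()
    # step 3: F_i
    Fi = {c.name: set().union(*(F.get(t, set())
                                for t in scope_span_types[c.name]), set())
          for c in corpora}
    # candidates and steps 4-6
    pos: dict[str, list] = {}
    Ni: dict[str, list] = {c.name: [] for c in corpora}
    for c in corpora:
        for doc in c.docs(("train",)):
            gold: dict[int, str] = {}
            for tb in sorted(doc.triggers, key=lambda t: (t.type, t.start)):
                h = _head_token(doc, tb.start, tb.end)
                if h is not None and h not in gold:
                    gold[h] = tb.type
            given = {_head_token(doc, tb.start, tb.end)
                     for tb in doc.entities}
            for i, tok in enumerate(doc.ensure_tokens()):
                if i in given or tok.base not in all_bases:
                    continue
                key = ("span", doc.doc_id, i)
                if i in gold:
                    pos.setdefault(gold[i], []).append(key)
                elif not filtered or tok.base in Fi[c.name]:
                    Ni[c.name].append(key)
    neg: dict[str, list] = {}
    for j in pos:
        negs = []
        for c in corpora:
            if filtered and j not in scope_span_types[c.name]:
                continue
            negs.extend(Ni[c.name])
        for m in pos:
            if m != j:
                negs.extend(pos[m])
        neg[j] = negs
    none_pos = [k for c in corpora for k in Ni[c.name]]
    none_neg = [k for j in pos for k in pos[j]]
    return pos, neg, none_pos, none_neg


def oracle_relation_sets(corpora: list[Corpus], filtered: bool):
    """Literal construction of the relation-stage training sets."""
    # global attested pairs and per-corpus scopes, from annotations only
    attested: set[tuple[str, str]] = set()
    per_type_args: dict[str, set[str]] = {}
    scope_events: dict[str, set[str]] = {}
    scope_roles: dict[str, set[str]] = {}
    for c in corpora:
        scope_events[c.name] = set()
        scope_roles[c.name] = set()
        for doc in c.docs(("train",)):
            idx = doc.ann_index()
            for ev in doc.events:
                scope_events[c.name].add(ev.type)
                for role, ref in ev.args:
                    scope_roles[c.name].add(role)
                    tgt = idx[ref]
                    atype = tgt.type
                    attested.add((ev.type, atype))
                    per_type_args.setdefault(ev.type, set()).add(atype)
    head_types = set().union(*scope_events.values(), set())
    Fi = {c.name: {(t, a) for t in scope_events[c.name]
                   for a in per_type_args.get(t, set())}
          for c in corpora}
    pos: dict[str, list] = {}
    Ni: dict[str, list] = {c.name: [] for c in corpora}
    for c in corpora:
        for doc in c.docs(("train",)):
            idx = doc.ann_index()
            gold_roles: dict[tuple, str] = {}
            for ev in sorted(doc.events, key=lambda e: e.id):
                trig = idx[ev.trigger]
                for role, ref in ev.args:
                    tgt = idx[ref]
                    span = (tgt.start, tgt.end) if hasattr(tgt, "start") \
                        else (idx[tgt.trigger].start, idx[tgt.trigger].end)
                    gold_roles.setdefault(
                        ((trig.start, trig.end), trig.type, span), role)
            anns = ([(tb, tb.type) for tb in doc.entities]
                    + [(tb, tb.type) for tb in doc.triggers])
            toks = doc.ensure_tokens()
            for trig in doc.triggers:
                if trig.type not in head_types:
                    continue
                th = _head_token(doc, trig.start, trig.end)
                for arg, atype in anns:
                    if (arg.start, arg.end) == (trig.start, trig.end) \
                            and atype == trig.type:
                        continue
                    ah = _head_token(doc, arg.start, arg.end)
                    if th is None or ah is None or \
                            toks[th].sent != toks[ah].sent:
                        continue
                    if (trig.type, atype) not in attested:
                        continue
                    key = ("rel", doc.doc_id, (trig.start, trig.end),
                           trig.type, (arg.start, arg.end), atype)
                    role = gold_roles.get(((trig.start, trig.end),
                                           trig.type,
                                           (arg.start, arg.end)))
                    if role is not None:
                        pos.setdefault(role, []).append(key)
                    elif not filtered or (trig.type, atype) in Fi[c.name]:
                        Ni[c.name].append(key)
    neg: dict[str, list] = {}
    for j in pos:
        negs = []
        for c in corpora:
            if filtered and j not in scope_roles[c.name]:
                continue
            negs.extend(Ni[c.name])
        for m in pos:
            if m != j:
                negs.extend(pos[m])
        neg[j] = negs
    none_pos = [k for c in corpora for k in Ni[c.name]]
    none_neg = [k for j in pos for k in pos[j]]
    return pos, neg, none_pos, none_neg
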