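"""Reading, validating and writing BioNLP-ST standoff annotation.

A document is distributed as a ``.txt`` / ``.a1`` / ``.a2`` triple sharing a
basename.  The ``.a1`` file carries the given named entities (text-bound ``T``
records), the ``.a2`` file carries event triggers and detected entities
(``T``), events (``E``) and event modifications (``M``).  Offsets are 0-based
character offsets into the ``.txt`` content, end-exclusive.

An optional token/dependency layer can be attached from a CoNLL-style
tabular file (columns: index, surface, base form, head index, relation).
When no parse layer is supplied a deterministic fallback tokenizer is used so
that downstream feature extraction stays reproducible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional


class StandoffError(ValueError):
    """Base class for standoff I/O failures."""


class StandoffParseError(StandoffError):
    """A line could not be parsed as a standoff record."""


class StandoffValidationError(StandoffError):
    """Parsed annotation violates a document-level invariant."""


class AlignmentError(StandoffError):
    """A parse layer does not align with the document text."""


NONE_LABEL = "NONE"
MODIFICATION_KINDS = ("Negation", "Speculation")

# Characters peeled off token edges by the fallback tokenizer.
_EDGE_PUNCT = ".,;:!?()[]{}'\"`"


def base_form(surface: str) -> str:
    """Deterministic base form: lowercase plus fixed suffix stripping.

    Strips ``-ing``, ``-ed``, ``-es`` and plural ``-s`` by fixed rules.  This
    is intentionally crude; it only has to be deterministic and consistent so
    that inflected trigger mentions of the same word share a base form.
    """
    w = surface.lower()
    if w.endswith("ing") and len(w) >= 6:
        return w[:-3]
    if w.endswith("ed") and len(w) >= 5:
        return w[:-2]
    if w.endswith("es") and len(w) >= 5:
        return w[:-2]
    if w.endswith("s") and not w.endswith("ss") and len(w) >= 4:
        return w[:-1]
    return w


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    surface: str
    base: str
    sent: int


@dataclass(frozen=True)
class TextBound:
    """A typed text span (entity, trigger or detected entity)."""

    id: str
    type: str
    start: int
    end: int
    text: str

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class EventAnn:
    """An n-ary event: a typed trigger plus (role, argument) pairs.

    Arguments are references by annotation id (``T...`` for text-bound
    arguments, ``E...`` for event arguments)."""

    id: str
    type: str
    trigger: str
    args: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class ModificationAnn:
    id: str
    kind: str
    target: str


@dataclass
class Document:
    doc_id: str
    text: str
    entities: list[TextBound] = field(default_factory=list)
    triggers: list[TextBound] = field(default_factory=list)
    events: list[EventAnn] = field(default_factory=list)
    modifications: list[ModificationAnn] = field(default_factory=list)
    #: Equiv ("*") records and non-Negation/Speculation M records, preserved
    #: verbatim but ignored by all downstream computation.
    extras: list[str] = field(default_factory=list)
    tokens: Optional[list[Token]] = None
    deps: Optional[list[tuple[int, int, str]]] = None

    # -- lookup helpers -------------------------------------------------
    def ann_index(self) -> dict[str, object]:
        idx: dict[str, object] = {}
        for tb in self.entities + self.triggers:
            idx[tb.id] = tb
        for ev in self.events:
            idx[ev.id] = ev
        for m in self.modifications:
            idx[m.id] = m
        return idx

    def event_by_id(self) -> dict[str, EventAnn]:
        return {ev.id: ev for ev in self.events}

    def sentence_spans(self) -> list[tuple[int, int]]:
        """Sentences are lines of the text (one sentence per line)."""
        spans = []
        pos = 0
        for line in self.text.split("\n"):
            spans.append((pos, pos + len(line)))
            pos += len(line) + 1
        return spans

    def ensure_tokens(self) -> list[Token]:
        if self.tokens is None:
            self.tokens = tokenize(self.text)
        return self.tokens

    def token_sentence(self, token_index: int) -> int:
        assert self.tokens is not None
        return self.tokens[token_index].sent

    def head_token_index(self, tb: TextBound) -> Optional[int]:
        """Index of the last token overlapping the span (head convention)."""
        toks = self.ensure_tokens()
        head = None
        for i, t in enumerate(toks):
            if t.start < tb.end and t.end > tb.start:
                head = i
        return head

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        ids: set[str] = set()
        for tb in self.entities + self.triggers:
            if tb.id in ids:
                raise StandoffValidationError(
                    f"{self.doc_id}: duplicate annotation id {tb.id}")
            ids.add(tb.id)
            if not (0 <= tb.start < tb.end <= len(self.text)):
                raise StandoffValidationError(
                    f"{self.doc_id}: span {tb.span} of {tb.id} outside text")
            if self.text[tb.start:tb.end] != tb.text:
                raise StandoffValidationError(
                    f"{self.doc_id}: text of {tb.id} ({tb.text!r}) does not "
                    f"match .txt content "
                    f"({self.text[tb.start:tb.end]!r})")
        idx = self.ann_index()
        trigger_ids = {tb.id for tb in self.triggers}
        for ev in self.events:
            if ev.id in ids:
                raise StandoffValidationError(
                    f"{self.doc_id}: duplicate annotation id {ev.id}")
            ids.add(ev.id)
            if ev.trigger not in trigger_ids:
                raise StandoffValidationError(
                    f"{self.doc_id}: event {ev.id} trigger {ev.trigger} "
                    "unresolved")
            trig = idx[ev.trigger]
            assert isinstance(trig, TextBound)
            if trig.type != ev.type:
                raise StandoffValidationError(
                    f"{self.doc_id}: event {ev.id} type {ev.type} differs "
                    f"from trigger type {trig.type}")
            for role, ref in ev.args:
                if ref not in idx:
                    raise StandoffValidationError(
                        f"{self.doc_id}: event {ev.id} argument {role}:{ref} "
                        "unresolved")
        self._check_acyclic()
        seen_mod: set[tuple[str, str]] = set()
        evs = self.event_by_id()
        for m in self.modifications:
            if m.kind not in MODIFICATION_KINDS:
                raise StandoffValidationError(
                    f"{self.doc_id}: unknown modification kind {m.kind}")
            if m.target not in evs:
                raise StandoffValidationError(
                    f"{self.doc_id}: modification {m.id} target {m.target} "
                    "unresolved")
            key = (m.kind, m.target)
            if key in seen_mod:
                raise StandoffValidationError(
                    f"{self.doc_id}: duplicate {m.kind} on {m.target}")
            seen_mod.add(key)

    def _check_acyclic(self) -> None:
        evs = self.event_by_id()
        state: dict[str, int] = {}  # 1 = on stack, 2 = done

        def visit(eid: str, stack: list[str]) -> None:
            if state.get(eid) == 2:
                return
            if state.get(eid) == 1:
                raise StandoffValidationError(
                    f"{self.doc_id}: reference cycle among events: "
                    f"{' -> '.join(stack + [eid])}")
            state[eid] = 1
            for _, ref in evs[eid].args:
                if ref in evs:
                    visit(ref, stack + [eid])
            state[eid] = 2

        for eid in evs:
            visit(eid, [])


def tokenize(text: str) -> list[Token]:
    """Fallback tokenizer: whitespace split, edge punctuation peeled off."""
    tokens: list[Token] = []
    sent_spans = []
    pos = 0
    for line in text.split("\n"):
        sent_spans.append((pos, pos + len(line)))
        pos += len(line) + 1

    def sent_of(start: int) -> int:
        for i, (s, e) in enumerate(sent_spans):
            if s <= start <= e:
                return i
        return len(sent_spans) - 1

    for m in re.finditer(r"\S+", text):
        start, end = m.start(), m.end()
        while start < end and text[start] in _EDGE_PUNCT:
            tokens.append(Token(start, start + 1, text[start],
                                text[start], sent_of(start)))
            start += 1
        trailing = []
        while end > start and text[end - 1] in _EDGE_PUNCT:
            trailing.append(Token(end - 1, end, text[end - 1],
                                  text[end - 1], sent_of(end - 1)))
            end -= 1
        if end > start:
            surf = text[start:end]
            tokens.append(Token(start, end, surf, base_form(surf),
                                sent_of(start)))
        tokens.extend(reversed(trailing))
    return tokens


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _parse_textbound(line: str, lineno: int, text: str) -> TextBound:
    parts = line.split("\t")
    if len(parts) != 3:
        raise StandoffParseError(
            f"line {lineno}: expected 3 tab-separated fields in T record: "
            f"{line!r}")
    tid, mid, surf = parts
    fields = mid.split(" ")
    if len(fields) != 3:
        if ";" in mid:
            raise StandoffParseError(
                f"line {lineno}: discontinuous spans are not supported: "
                f"{line!r}")
        raise StandoffParseError(
            f"line {lineno}: malformed T record type/span field: {line!r}")
    ttype, s, e = fields
    try:
        start, end = int(s), int(e)
    except ValueError as exc:
        raise StandoffParseError(
            f"line {lineno}: non-integer offsets in {line!r}") from exc
    if not (0 <= start < end <= len(text)):
        raise StandoffValidationError(
            f"line {lineno}: span ({start},{end}) of {tid} outside text "
            f"(length {len(text)})")
    if text[start:end] != surf:
        raise StandoffValidationError(
            f"line {lineno}: {tid} text {surf!r} does not match .txt "
            f"substring {text[start:end]!r}")
    return TextBound(tid, ttype, start, end, surf)


def _parse_event(line: str, lineno: int) -> EventAnn:
    parts = line.split("\t")
    if len(parts) != 2:
        raise StandoffParseError(
            f"line {lineno}: expected 2 tab-separated fields in E record: "
            f"{line!r}")
    eid, body = parts
    items = body.split(" ")
    head = items[0].split(":")
    if len(head) != 2:
        raise StandoffParseError(
            f"line {lineno}: malformed event head {items[0]!r}")
    etype, trig = head
    args = []
    for item in items[1:]:
        if not item:
            continue
        pair = item.split(":")
        if len(pair) != 2:
            raise StandoffParseError(
                f"line {lineno}: malformed argument {item!r}")
        args.append((pair[0], pair[1]))
    return EventAnn(eid, etype, trig, tuple(args))


def read_document(doc_id: str, txt_content: str, a1_content: str,
                  a2_content: str) -> Document:
    """Parse a standoff triple into a validated :class:`Document`."""
    if not txt_content:
        raise StandoffValidationError(f"{doc_id}: empty text")
    doc = Document(doc_id=doc_id, text=txt_content)
    for lineno, line in enumerate(a1_content.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            doc.entities.append(_parse_textbound(line, lineno, txt_content))
        elif line.startswith("*"):
            doc.extras.append(line)
        else:
            raise StandoffParseError(
                f"line {lineno}: unexpected record in .a1: {line!r}")
    for lineno, line in enumerate(a2_content.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            doc.triggers.append(_parse_textbound(line, lineno, txt_content))
        elif line.startswith("E"):
            doc.events.append(_parse_event(line, lineno))
        elif line.startswith("M"):
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[1].split(" ")) != 2:
                raise StandoffParseError(
                    f"line {lineno}: malformed M record: {line!r}")
            kind, target = parts[1].split(" ")
            if kind in MODIFICATION_KINDS:
                doc.modifications.append(
                    ModificationAnn(parts[0], kind, target))
            else:
                doc.extras.append(line)
        elif line.startswith("*"):
            doc.extras.append(line)
        else:
            raise StandoffParseError(
                f"line {lineno}: unexpected record in .a2: {line!r}")
    doc.validate()
    return doc


def _id_sort_key(ann_id: str) -> tuple[str, int]:
    m = re.match(r"([A-Za-z]+)(\d+)$", ann_id)
    if m:
        return (m.group(1), int(m.group(2)))
    return (ann_id, 0)


def write_document(doc: Document) -> tuple[str, str]:
    """Serialize back to ``(a1_content, a2_content)``; order is id-sorted."""
    doc.validate()

    def tb_line(tb: TextBound) -> str:
        return f"{tb.id}\t{tb.type} {tb.start} {tb.end}\t{tb.text}"

    a1_lines = [tb_line(tb) for tb in
                sorted(doc.entities, key=lambda t: _id_sort_key(t.id))]
    a2_lines = [tb_line(tb) for tb in
                sorted(doc.triggers, key=lambda t: _id_sort_key(t.id))]
    for ev in sorted(doc.events, key=lambda e: _id_sort_key(e.id)):
        body = f"{ev.type}:{ev.trigger}"
        for role, ref in ev.args:
            body += f" {role}:{ref}"
        a2_lines.append(f"{ev.id}\t{body}")
    for m in sorted(doc.modifications, key=lambda m: _id_sort_key(m.id)):
        a2_lines.append(f"{m.id}\t{m.kind} {m.target}")
    a2_lines.extend(doc.extras)
    a1 = "\n".join(a1_lines) + ("\n" if a1_lines else "")
    a2 = "\n".join(a2_lines) + ("\n" if a2_lines else "")
    return a1, a2


def read_parse_layer(doc: Document, conll_content: str) -> Document:
    """Attach tokens and dependencies from a CoNLL-style table.

    Sentences are blank-line separated blocks.  Head indices are 1-based
    within the sentence, 0 marking the root (no dependency record emitted
    for the root).  Surfaces must align with ``doc.text`` after whitespace
    normalization."""
    tokens: list[Token] = []
    deps: list[tuple[int, int, str]] = []
    pos = 0
    sent = 0
    sent_start_tok = 0
    rows: list[tuple[int, str, str, int, str]] = []

    def flush_sentence() -> None:
        nonlocal sent, sent_start_tok
        for idx, surface, base, head, rel in rows:
            if head < 0 or head > len(rows):
                raise AlignmentError(
                    f"{doc.doc_id}: head index {head} out of range in "
                    f"sentence {sent} (length {len(rows)})")
            if head > 0:
                deps.append((sent_start_tok + head - 1,
                             sent_start_tok + idx - 1, rel))
        sent += 1
        sent_start_tok = len(tokens)
        rows.clear()

    for raw in conll_content.splitlines():
        line = raw.strip()
        if not line:
            if rows:
                flush_sentence()
            continue
        cols = re.split(r"\t|\s{2,}| ", raw.strip())
        if len(cols) < 5:
            raise StandoffParseError(
                f"{doc.doc_id}: malformed parse line {raw!r}")
        idx, surface, base, head, rel = (int(cols[0]), cols[1], cols[2],
                                         int(cols[3]), cols[4])
        while pos < len(doc.text) and doc.text[pos].isspace():
            pos += 1
        if doc.text[pos:pos + len(surface)] != surface:
            raise AlignmentError(
                f"{doc.doc_id}: parse token {surface!r} (sentence {sent}, "
                f"index {idx}) does not align with text at offset {pos}: "
                f"{doc.text[pos:pos + len(surface)]!r}")
        tokens.append(Token(pos, pos + len(surface), surface, base, sent))
        pos += len(surface)
        rows.append((idx, surface, base, head, rel))
    if rows:
        flush_sentence()
    doc.tokens = tokens
    doc.deps = deps
    return doc


def write_parse_layer(doc: Document) -> str:
    """Serialize the token/dependency layer back to the CoNLL-style table."""
    assert doc.tokens is not None
    head_of: dict[int, tuple[int, str]] = {}
    for head, dep, rel in doc.deps or []:
        head_of[dep] = (head, rel)
    lines = []
    prev_sent = 0
    sent_start = 0
    for i, tok in enumerate(doc.tokens):
        if tok.sent != prev_sent:
            lines.append("")
            prev_sent = tok.sent
            sent_start = i
        if i in head_of:
            head, rel = head_of[i]
            head_local = head - sent_start + 1
        else:
            head_local, rel = 0, "root"
        lines.append(f"{i - sent_start + 1}\t{tok.surface}\t{tok.base}\t"
                     f"{head_local}\t{rel}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# structural equivalence (id-independent)
# ---------------------------------------------------------------------------

def canonical_events(doc: Document) -> list[tuple]:
    """Canonical id-free forms of all events, for structural comparison."""
    idx = doc.ann_index()
    evs = doc.event_by_id()

    def canon(eid: str) -> tuple:
        ev = evs[eid]
        trig = idx[ev.trigger]
        assert isinstance(trig, TextBound)
        args = []
        for role, ref in ev.args:
            tgt = idx[ref]
            if isinstance(tgt, TextBound):
                args.append((role, ("T", tgt.type, tgt.start, tgt.end)))
            else:
                args.append((role, ("E",) + canon(ref)))
        return (ev.type, trig.start, trig.end, tuple(sorted(args)))

    return sorted(canon(eid) for eid in evs)


def annotation_equivalent(a: Document, b: Document) -> bool:
    """Structural (id-independent) equality of two documents' annotation."""
    def tb_set(tbs: Iterable[TextBound]) -> set[tuple]:
        return {(tb.type, tb.start, tb.end, tb.text) for tb in tbs}

    if a.text != b.text:
        return False
    if tb_set(a.entities) != tb_set(b.entities):
        return False
    if tb_set(a.triggers) != tb_set(b.triggers):
        return False
    if canonical_events(a) != canonical_events(b):
        return False

    def mod_set(doc: Document) -> list[tuple]:
        evs = doc.event_by_id()
        idx = doc.ann_index()

        def canon(eid):
            ev = evs[eid]
            trig = idx[ev.trigger]
            return (ev.type, trig.start, trig.end)

        return sorted((m.kind,) + canon(m.target) for m in doc.modifications)

    return mod_set(a) == mod_set(b)
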