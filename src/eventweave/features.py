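"""Sparse feature extraction for pipeline instances.

Features are deterministic functions of the instance and its document:
character n-grams of candidate surfaces, base-form context n-grams,
endpoint/participant types, bag-of-words between relation endpoints and
shortest dependency paths when a parse layer is attached.  Every feature is
a namespaced string mapped to a positive count.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .instances import (HedgeInstance, Instance, RelationInstance,
                        SpanInstance, StructureInstance)
from .standoff import Document

DEFAULT_HEDGE_CUES = (
    "not", "no", "cannot", "fail", "failed", "unable", "may", "might",
    "could", "possible", "possibly", "suggest", "suggests", "appear",
    "appears", "likely", "unlikely", "whether", "putative",
)


@dataclass(frozen=True)
class FeatureConfig:
    char_ngram_min: int = 2
    char_ngram_max: int = 4
    context_window: int = 3
    context_ngram_max: int = 3
    hedge_cues: tuple[str, ...] = DEFAULT_HEDGE_CUES


def char_ngrams(s: str, lo: int, hi: int) -> list[str]:
    s = s.lower()
    out = []
    for n in range(lo, hi + 1):
        out.extend(s[i:i + n] for i in range(len(s) - n + 1))
    return out


def _add(fv: dict[str, float], name: str, value: float = 1.0) -> None:
    fv[name] = fv.get(name, 0.0) + value


def _context_ngrams(fv: dict, doc: Document, i: int,
                    cfg: FeatureConfig, prefix: str = "ctx") -> None:
    toks = doc.tokens or []
    sent = toks[i].sent
    lo = max(0, i - cfg.context_window)
    hi = min(len(toks), i + cfg.context_window + 1)
    window = [(j, toks[j].base) for j in range(lo, hi)
              if toks[j].sent == sent]
    for n in range(1, cfg.context_ngram_max + 1):
        for k in range(len(window) - n + 1):
            idxs = [window[k + m][0] for m in range(n)]
            if i in idxs and n == 1:
                continue
            gram = " ".join(window[k + m][1] for m in range(n))
            side = "L" if idxs[-1] < i else ("R" if idxs[0] > i else "C")
            _add(fv, f"{prefix}{n}:{side}:{gram}")


def shortest_dep_path(doc: Document, src: int, dst: int) -> Optional[str]:
    """Shortest path in the (undirected) dependency graph, as a string of
    direction-marked relation labels; exhaustive BFS."""
    if doc.deps is None or src == dst:
        return "" if src == dst else None
    adj: dict[int, list[tuple[int, str]]] = {}
    for head, dep, rel in doc.deps:
        adj.setdefault(head, []).append((dep, f">{rel}"))
        adj.setdefault(dep, []).append((head, f"<{rel}"))
    seen = {src: ""}
    q = deque([src])
    while q:
        node = q.popleft()
        for nxt, step in sorted(adj.get(node, [])):
            if nxt not in seen:
                seen[nxt] = seen[node] + step
                if nxt == dst:
                    return seen[nxt]
                q.append(nxt)
    return None


def _nearest_entity(doc: Document, i: int):
    best = None
    for tb in doc.entities:
        h = doc.head_token_index(tb)
        if h is None or h == i:
            continue
        d = abs(h - i)
        if best is None or (d, h) < (best[0], best[1]):
            best = (d, h, tb)
    return best


def _dist_bucket(d: int) -> str:
    if d <= 1:
        return str(d)
    if d <= 2:
        return "2"
    if d <= 4:
        return "3-4"
    if d <= 7:
        return "5-7"
    return "8+"


def featurize_span(inst: SpanInstance, doc: Document,
                   cfg: FeatureConfig) -> dict[str, float]:
    fv: dict[str, float] = {}
    i = inst.token_index
    _add(fv, f"base:{inst.base}")
    for g in char_ngrams(inst.surface, cfg.char_ngram_min, cfg.char_ngram_max):
        _add(fv, f"cn:{g}")
    _context_ngrams(fv, doc, i, cfg)
    near = _nearest_entity(doc, i)
    if near is not None:
        _, h, tb = near
        _add(fv, f"nearent:{tb.type}")
        path = shortest_dep_path(doc, i, h)
        if path is not None:
            _add(fv, f"entpath:{path}:{tb.type}")
    return fv


def featurize_relation(inst: RelationInstance, doc: Document,
                       cfg: FeatureConfig) -> dict[str, float]:
    fv: dict[str, float] = {}
    toks = doc.ensure_tokens()
    _add(fv, f"ttype:{inst.trigger_type}")
    _add(fv, f"atype:{inst.arg_type or inst.arg_base}")
    _add(fv, f"pair:{inst.trigger_type}:{inst.arg_type or inst.arg_base}")
    t_surf = doc.text[inst.trigger_span[0]:inst.trigger_span[1]]
    a_surf = doc.text[inst.arg_span[0]:inst.arg_span[1]]
    for g in char_ngrams(t_surf, cfg.char_ngram_min, cfg.char_ngram_max):
        _add(fv, f"tcn:{g}")
    for g in char_ngrams(a_surf, cfg.char_ngram_min, cfg.char_ngram_max):
        _add(fv, f"acn:{g}")
    t_head = _span_head(doc, inst.trigger_span)
    a_head = _span_head(doc, inst.arg_span)
    if t_head is not None and a_head is not None:
        lo, hi = sorted((t_head, a_head))
        for j in range(lo + 1, hi):
            _add(fv, f"btw:{toks[j].base}")
        _add(fv, f"dist:{_dist_bucket(hi - lo)}")
        _add(fv, f"dir:{'TA' if t_head < a_head else 'AT'}")
        path = shortest_dep_path(doc, t_head, a_head)
        if path is not None:
            _add(fv, f"path:{path}")
    return fv


def _span_head(doc: Document, span: tuple[int, int]) -> Optional[int]:
    toks = doc.ensure_tokens()
    head = None
    for i, t in enumerate(toks):
        if t.start < span[1] and t.end > span[0]:
            head = i
    return head


def featurize_structure(inst: StructureInstance, doc: Document,
                        cfg: FeatureConfig) -> dict[str, float]:
    fv: dict[str, float] = {}
    _add(fv, f"ttype:{inst.trigger_type}")
    _add(fv, f"nmem:{len(inst.members)}")
    roles = sorted(r for r, _t, _s in inst.members)
    for role, atype, _span in inst.members:
        _add(fv, f"mem:{role}:{atype}")
    for i in range(len(roles)):
        for j in range(i + 1, len(roles)):
            _add(fv, f"rolepair:{roles[i]}:{roles[j]}")
    _add(fv, f"compete:{_dist_bucket(inst.n_competing)}")
    t_head = _span_head(doc, inst.trigger_span)
    if t_head is not None:
        toks = doc.ensure_tokens()
        _add(fv, f"tbase:{toks[t_head].base}")
    return fv


def featurize_hedge(inst: HedgeInstance, doc: Document,
                    cfg: FeatureConfig) -> dict[str, float]:
    fv: dict[str, float] = {}
    toks = doc.ensure_tokens()
    _add(fv, f"ttype:{inst.trigger_type}")
    t_head = _span_head(doc, inst.trigger_span)
    if t_head is not None:
        _add(fv, f"tbase:{toks[t_head].base}")
        _context_ngrams(fv, doc, t_head, cfg, prefix="hctx")
        sent = toks[t_head].sent
        for t in toks:
            if t.sent == sent and t.base in cfg.hedge_cues:
                _add(fv, f"cue:{t.base}")
    for role, atype, _span in inst.members:
        _add(fv, f"mem:{role}:{atype}")
    return fv


def featurize(inst: Instance, doc: Document,
              cfg: Optional[FeatureConfig] = None) -> dict[str, float]:
    """Dispatch on instance kind; deterministic sparse vector."""
    cfg = cfg or FeatureConfig()
    if isinstance(inst, SpanInstance):
        return featurize_span(inst, doc, cfg)
    if isinstance(inst, RelationInstance):
        return featurize_relation(inst, doc, cfg)
    if isinstance(inst, StructureInstance):
        return featurize_structure(inst, doc, cfg)
    if isinstance(inst, HedgeInstance):
        return featurize_hedge(inst, doc, cfg)
    raise TypeError(f"unsupported instance type {type(inst)!r}")
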