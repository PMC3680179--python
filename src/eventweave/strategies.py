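"""Training strategies for multi-corpus event extraction.

Five strategies are supported:

``single``
    one corpus, closed-world negatives — the conventional setup.
``merge``
    pool all corpora and train closed-world, accepting the spurious
    negatives that partial scope overlap creates.
``stacking``
    a single-corpus model whose instances carry, as extra indicator
    features, the predictions of models trained on each other corpus.
``easyadapt``
    feature-augmentation domain adaptation: every feature is duplicated
    into a shared copy and a domain-specific copy, one domain per corpus
    (optionally per corpus sub-domain), and one model is trained on the
    pooled augmented instances.  Applying the model requires a domain.
``multiple``
    one corpus-independent model trained on pooled positives and
    spurious-negative-filtered negatives (see :mod:`eventweave.filters`),
    with a separate one-vs-rest binary scorer per type because the negative
    set varies by type.  Prediction applies no filtering.

All stages use linear large-margin one-vs-rest scorers with real-valued
decision scores; label resolution is deterministic with lexicographic
tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .corpus import Corpus, CorpusScope, compute_scope
from .features import FeatureConfig, featurize
from .filters import (STAGES, OverlapFilters, TrainingSet,
                      assemble_training_sets, build_filters)
from .instances import (HedgeInstance, Instance, TriggerLexicon,
                        build_trigger_lexicon, enumerate_structures,
                        generate_relation_candidates,
                        generate_span_candidates)
from .standoff import NONE_LABEL, Document

logger = logging.getLogger(__name__)

STRATEGIES = ("single", "merge", "stacking", "easyadapt", "multiple")

FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for the stage classifiers.

    ``C`` is the inverse regularization strength of the linear scorers;
    ``threshold`` the decision threshold used by label resolution;
    ``class_weight`` may be ``"balanced"`` for inverse-frequency weighting
    (off by default); ``ptm_collapse`` optionally maps post-translational
    modification event types to one placeholder label in the relation and
    structure classifiers (the span stage keeps distinct types and assigns
    the final label)."""

    C: float = 1.0
    threshold: float = 0.0
    class_weight: Optional[str] = None
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ptm_collapse: Optional[dict[str, str]] = None
    structure_cap: int = 1000


def easyadapt_augment(fv: Mapping[str, float], domain: str,
                      domains: Sequence[str]) -> dict[str, float]:
    """Duplicate every feature into a shared and a domain-specific copy."""
    if domain not in domains:
        raise ValueError(f"undeclared domain {domain!r}; known: "
                         f"{sorted(domains)}")
    out: dict[str, float] = {}
    for k, v in fv.items():
        out[f"*/{k}"] = v
        out[f"{domain}/{k}"] = v
    return out


def resolve_label(scores: Mapping[str, float], none_score: float,
                  threshold: float = 0.0) -> str:
    """Highest-scoring type if it clears the threshold and beats NONE;
    deterministic lexicographic tie-break."""
    if not scores:
        raise ValueError("no scores to resolve")
    best_label, best = sorted(scores.items(),
                              key=lambda kv: (-kv[1], kv[0]))[0]
    if best > threshold and best > none_score:
        return best_label
    return NONE_LABEL


# ---------------------------------------------------------------------------
# stage scorers
# ---------------------------------------------------------------------------

@dataclass
class StageModel:
    stage: str
    vectorizer: DictVectorizer
    classifiers: dict[str, object]  # label -> fitted LinearSVC
    none_clf: Optional[object]
    labels: list[str]

    def score(self, fvs: Sequence[Mapping[str, float]]
              ) -> list[tuple[dict[str, float], float]]:
        if not fvs:
            return []
        X = self.vectorizer.transform(fvs)
        per_label = {}
        for label in self.labels:
            clf = self.classifiers[label]
            per_label[label] = clf.decision_function(X)
        if self.none_clf is not None:
            none_scores = self.none_clf.decision_function(X)
        else:
            none_scores = np.full(X.shape[0], -np.inf)
        out = []
        for i in range(X.shape[0]):
            out.append(({lab: float(per_label[lab][i])
                         for lab in self.labels}, float(none_scores[i])))
        return out


@dataclass
class ModelSet:
    """Trained per-type scorers for all stages plus supporting tables."""

    strategy: str
    stage_models: dict[str, StageModel]
    lexicon: TriggerLexicon
    filters: OverlapFilters
    head_types: set[str]
    config: TrainConfig
    target: Optional[str] = None
    domains: Optional[tuple[str, ...]] = None
    aux: Optional[dict[str, "ModelSet"]] = None
    format_version: int = FORMAT_VERSION

    @property
    def corpus_independent(self) -> bool:
        return self.strategy in ("merge", "multiple")

    def score_stage(self, stage: str, instances: Sequence[Instance],
                    docs: Mapping[str, Document],
                    domain: Optional[str] = None
                    ) -> list[tuple[dict[str, float], float]]:
        model = self.stage_models.get(stage)
        if model is None:
            raise ValueError(f"model set has no stage {stage!r}")
        fvs = [featurize(inst, docs[inst.doc_id], self.config.features)
               for inst in instances]
        fvs = self._transform_features(stage, fvs, instances, docs, domain)
        return model.score(fvs)

    def _transform_features(self, stage, fvs, instances, docs, domain):
        if self.strategy == "easyadapt":
            if domain is None:
                raise ValueError(
                    "an easyadapt model is corpus-dependent: a domain is "
                    "required to apply it")
            fvs = [easyadapt_augment(fv, domain, self.domains or ())
                   for fv in fvs]
        elif self.strategy == "stacking" and self.aux:
            fvs = [dict(fv) for fv in fvs]
            for aux_name in sorted(self.aux):
                aux = self.aux[aux_name]
                if stage not in aux.stage_models:
                    continue
                preds = aux.score_stage(stage, instances, docs)
                for fv, (scores, none_score) in zip(fvs, preds):
                    lab = resolve_label(scores, none_score,
                                        aux.config.threshold)
                    fv[f"stack:{aux_name}:{lab}"] = 1.0
        return fvs


# ---------------------------------------------------------------------------
# gold instance collection
# ---------------------------------------------------------------------------

def collapse_type(t: str, config: TrainConfig) -> str:
    if config.ptm_collapse:
        return config.ptm_collapse.get(t, t)
    return t


def collect_gold_instances(
        corpus: Corpus, lexicon: TriggerLexicon, filters: OverlapFilters,
        head_types: set[str], config: TrainConfig,
        splits: tuple[str, ...] = ("train",),
        ) -> dict[str, list[Instance]]:
    """Gold-labelled candidates for all four stages from one corpus.

    Later stages are chained on gold annotation (gold triggers feed the
    relation stage, gold relations the structure stage), the standard
    training regime for pipeline extractors."""
    pairs = filters.global_pairs
    sigs = filters.global_sigs
    out: dict[str, list[Instance]] = {s: [] for s in STAGES}
    for doc in corpus.docs(splits):
        doc.ensure_tokens()
        out["span"].extend(generate_span_candidates(
            doc, lexicon, corpus.name, with_gold=True))
        rels = generate_relation_candidates(
            doc, doc.triggers, corpus.name, attested_pairs=pairs,
            head_types=head_types, with_gold=True)
        out["relation"].extend(rels)
        for trig in sorted(doc.triggers,
                           key=lambda t: (t.start, t.end, t.type)):
            if trig.type not in head_types:
                continue
            trig_rels = [r for r in rels
                         if r.trigger_span == trig.span
                         and r.trigger_type == trig.type]
            structs = enumerate_structures(
                trig, trig_rels, sigs, doc, corpus.name,
                cap=config.structure_cap, with_gold=True)
            if config.ptm_collapse:
                # label-space collapse: the structure classifier pools
                # post-translational modification types into one label;
                # the span stage keeps distinct types and assigns the
                # final label.
                from dataclasses import replace as _rep
                structs = [_rep(s, gold=collapse_type(s.gold, config))
                           if s.gold != NONE_LABEL else s
                           for s in structs]
            out["structure"].extend(structs)
        idx = doc.ann_index()
        mods: dict[str, str] = {}
        for m in sorted(doc.modifications, key=lambda m: m.kind):
            mods.setdefault(m.target, m.kind)
        for ev in sorted(doc.events, key=lambda e: e.id):
            trig = idx[ev.trigger]
            members = []
            for role, ref in ev.args:
                tgt = idx[ref]
                if hasattr(tgt, "span"):
                    members.append((role, tgt.type, tgt.span))
                else:
                    inner = idx[tgt.trigger]
                    members.append((role, tgt.type, inner.span))
            out["hedge"].append(HedgeInstance(
                doc.doc_id, corpus.name, ev.id, trig.span, trig.type,
                tuple(sorted(members)), mods.get(ev.id, NONE_LABEL)))
    return out


def _collapse_structure_gold(inst: Instance, config: TrainConfig) -> str:
    if inst.gold == NONE_LABEL:
        return inst.gold
    return collapse_type(inst.gold, config)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _fit_binary(X_pos, X_neg, config: TrainConfig, seed: int):
    if X_pos.shape[0] == 0 or X_neg.shape[0] == 0:
        return None
    X = sparse.vstack([X_pos, X_neg]).tocsr()
    y = np.concatenate([np.ones(X_pos.shape[0]),
                        -np.ones(X_neg.shape[0])])
    rng = np.random.RandomState(seed % (2 ** 31))
    order = rng.permutation(X.shape[0])
    clf = LinearSVC(C=config.C, class_weight=config.class_weight,
                    random_state=seed % (2 ** 31), max_iter=5000)
    clf.fit(X[order], y[order])
    return clf


def _train_stage(stage: str, ts: TrainingSet,
                 fv_of: Mapping[tuple, Mapping[str, float]],
                 config: TrainConfig, seed: int) -> Optional[StageModel]:
    all_keys = sorted({inst.key for insts in ts.positives.values()
                       for inst in insts}
                      | {inst.key for inst in ts.none_pos})
    if not all_keys:
        return None
    # negatives' keys are a subset of positives ∪ none_pos by construction
    vec = DictVectorizer(sparse=True)
    X_all = vec.fit_transform([fv_of[k] for k in all_keys])
    row = {k: i for i, k in enumerate(all_keys)}

    def rows(insts: Sequence[Instance]):
        idx = [row[i.key] for i in insts]
        return X_all[idx] if idx else sparse.csr_matrix(
            (0, X_all.shape[1]))

    classifiers = {}
    labels = []
    for j, label in enumerate(sorted(ts.positives)):
        clf = _fit_binary(rows(ts.positives[label]),
                          rows(ts.negatives[label]), config, seed + j)
        if clf is None:
            # no usable negatives: constant positive scorer
            logger.info("stage %s type %s trained without negatives; "
                        "using a constant scorer", stage, label)
            clf = _ConstScorer(1.0)
        classifiers[label] = clf
        labels.append(label)
    none_clf = _fit_binary(rows(ts.none_pos), rows(ts.none_neg), config,
                           seed + 7919)
    if not labels:
        return None
    return StageModel(stage, vec, classifiers, none_clf, labels)


class _ConstScorer:
    def __init__(self, value: float):
        self.value = value

    def decision_function(self, X):
        return np.full(X.shape[0], self.value)


@dataclass
class PreparedData:
    """Gold candidates and supporting tables for a training corpus set."""

    corpora: list[Corpus]
    lexicon: TriggerLexicon
    scopes: dict[str, CorpusScope]
    filters: OverlapFilters
    head_types: set[str]
    instances: dict[str, dict[str, list[Instance]]]  # corpus -> stage
    docs: dict[str, Document]
    doc_domain: dict[str, str]


def prepare_training(corpora: Sequence[Corpus],
                     config: Optional[TrainConfig] = None) -> PreparedData:
    """Build lexicon, scopes, filters and gold candidates for a corpus set."""
    config = config or TrainConfig()
    train_corpora = sorted(corpora, key=lambda c: c.name)
    lexicon = build_trigger_lexicon(train_corpora)
    scopes = {c.name: compute_scope(c, ("train",)) for c in train_corpora}
    filters = build_filters(train_corpora, scopes, lexicon)
    head_types = set().union(*(s.event_types for s in scopes.values()),
                             set())
    instances: dict[str, dict[str, list[Instance]]] = {}
    docs: dict[str, Document] = {}
    doc_domain: dict[str, str] = {}
    for c in train_corpora:
        instances[c.name] = collect_gold_instances(
            c, lexicon, filters, head_types, config)
        for d in c.docs(("train",)):
            docs[d.doc_id] = d
            doc_domain[d.doc_id] = c.domain_of(d.doc_id)
    return PreparedData(train_corpora, lexicon, scopes, filters, head_types,
                        instances, docs, doc_domain)


def build_training_sets(prepared: PreparedData,
                        filtered: bool) -> dict[str, TrainingSet]:
    """Per-stage training sets; ``filtered`` selects Multiple vs Merge."""
    out = {}
    for stage in STAGES:
        per_corpus = {name: prepared.instances[name][stage]
                      for name in prepared.instances}
        out[stage] = assemble_training_sets(per_corpus, prepared.filters,
                                            stage, filtered=filtered)
    return out


def train(strategy: str, corpora: Sequence[Corpus],
          target: Optional[str] = None, seed: int = 0,
          config: Optional[TrainConfig] = None) -> ModelSet:
    """Train a :class:`ModelSet` under one of the five strategies."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    config = config or TrainConfig()
    by_name = {c.name: c for c in corpora}
    if strategy in ("single", "stacking"):
        if target is None:
            raise ValueError(f"strategy {strategy!r} requires a target "
                             "corpus")
        if target not in by_name:
            raise ValueError(f"target corpus {target!r} not in corpus set")
        train_corpora = [by_name[target]]
    else:
        train_corpora = sorted(corpora, key=lambda c: c.name)

    aux = None
    if strategy == "stacking":
        aux = {c.name: train("single", [c], target=c.name, seed=seed,
                             config=config)
               for c in corpora if c.name != target}

    prepared = prepare_training(train_corpora, config)
    lexicon, filters = prepared.lexicon, prepared.filters
    head_types = prepared.head_types
    docs, doc_domain = prepared.docs, prepared.doc_domain

    domains: Optional[tuple[str, ...]] = None
    if strategy == "easyadapt":
        domains = tuple(sorted({c.domain_of(doc_id)
                                for c in train_corpora
                                for doc_id, sp in c.splits.items()
                                if sp == "train"}))

    filtered = strategy == "multiple"
    training_sets = build_training_sets(prepared, filtered)
    stage_models: dict[str, StageModel] = {}
    for stage in STAGES:
        ts = training_sets[stage]
        if ts.excluded_types:
            logger.info("stage %s: types without positives excluded: %s",
                        stage, ts.excluded_types)
        fv_of: dict[tuple, Mapping[str, float]] = {}
        uniq: dict[tuple, Instance] = {}
        for pool in list(ts.positives.values()) + [ts.none_pos]:
            for inst in pool:
                uniq.setdefault(inst.key, inst)
        for key, inst in uniq.items():
            fv = featurize(inst, docs[inst.doc_id], config.features)
            if strategy == "easyadapt":
                fv = easyadapt_augment(fv, doc_domain[inst.doc_id],
                                       domains or ())
            fv_of[key] = fv
        if strategy == "stacking" and aux:
            keys = sorted(uniq)
            insts = [uniq[k] for k in keys]
            for aux_name in sorted(aux):
                aux_model = aux[aux_name]
                if stage not in aux_model.stage_models:
                    continue
                preds = aux_model.score_stage(stage, insts, docs)
                for k, (scores, none_score) in zip(keys, preds):
                    lab = resolve_label(scores, none_score,
                                        config.threshold)
                    fv_of[k] = dict(fv_of[k])
                    fv_of[k][f"stack:{aux_name}:{lab}"] = 1.0
        model = _train_stage(stage, ts, fv_of, config, seed)
        if model is not None:
            stage_models[stage] = model

    return ModelSet(strategy=strategy, stage_models=stage_models,
                    lexicon=lexicon, filters=filters, head_types=head_types,
                    config=config, target=target, domains=domains, aux=aux)
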