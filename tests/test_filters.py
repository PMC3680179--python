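"""Negative-instance filtering: filter construction, admissibility and
training-set assembly, checked against literal brute-force oracles."""

from dataclasses import replace

import pytest

from eventweave.corpus import Corpus, compute_scope
from eventweave.filters import (admissible_negative_relation,
                                admissible_negative_span,
                                assemble_training_sets, build_filters)
from eventweave.instances import (RelationInstance, SpanInstance,
                                  build_trigger_lexicon)
from eventweave.standoff import NONE_LABEL, read_document
from eventweave.strategies import build_training_sets, prepare_training
from eventweave.synthetic import generate, random_scenario, \
    standard_scenarios

from oracles import oracle_relation_sets, oracle_span_sets


def _ge_like():
    """Annotates Binding ('bind') but leaves 'methylation' unannotated."""
    txt = "TP53 binds MDM2 after methylation of human STAT3 .\n"
    a1 = ("T1\tProtein 0 4\tTP53\nT2\tProtein 11 15\tMDM2\n"
          "T3\tProtein 43 48\tSTAT3\n")
    a2 = "T4\tBinding 5 10\tbinds\nE1\tBinding:T4 Theme:T1 Theme:T2\n"
    c = Corpus(name="GE")
    c.add(read_document("ge1", txt, a1, a2), "train")
    return c


def _epi_like():
    """Annotates Methylation ('methylation') but leaves 'binds'
    unannotated."""
    txt = "The methylation of STAT3 binds attention .\n"
    a1 = "T1\tProtein 19 24\tSTAT3\n"
    a2 = ("T2\tMethylation 4 15\tmethylation\n"
          "E1\tMethylation:T2 Theme:T1\n")
    c = Corpus(name="EPI")
    c.add(read_document("epi1", txt, a1, a2), "train")
    return c


@pytest.fixture()
def two_corpus_filters():
    corpora = [_ge_like(), _epi_like()]
    scopes = {c.name: compute_scope(c) for c in corpora}
    lex = build_trigger_lexicon(corpora)
    return corpora, build_filters(corpora, scopes, lex)


def test_per_corpus_filters_exclude_foreign_types(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    # EPI's span filter excludes "bind"; GE's excludes "methylation"
    assert "bind" not in filters.span_by_corpus["EPI"]
    assert "methylation" in filters.span_by_corpus["EPI"]
    assert "methylation" not in filters.span_by_corpus["GE"]
    # GE's combo filter lacks (Methylation, Protein)
    assert ("Methylation", "Protein") not in filters.pairs_by_corpus["GE"]
    assert ("Methylation", "Protein") in filters.pairs_by_corpus["EPI"]


def test_single_corpus_filter_is_union_of_type_filters():
    corpus = _ge_like()
    scopes = {"GE": compute_scope(corpus)}
    filters = build_filters([corpus], scopes)
    expected = set().union(*filters.span_by_type.values())
    assert filters.span_by_corpus["GE"] == expected
    assert filters.pairs_by_corpus["GE"] == filters.global_pairs


def test_never_positive_word_is_not_a_negative(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    # "human" is never annotated anywhere -> inadmissible in every corpus
    for name in ("GE", "EPI"):
        inst = SpanInstance("d", name, 0, "human", "human")
        assert not admissible_negative_span(inst, filters)


def test_foreign_trigger_word_is_not_a_negative(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    # "bind" unannotated in the EPI-scoped corpus: not a negative there,
    # but a valid negative in the GE-scoped corpus
    inst_epi = SpanInstance("d", "EPI", 0, "binds", "bind")
    inst_ge = SpanInstance("d", "GE", 0, "binds", "bind")
    assert not admissible_negative_span(inst_epi, filters)
    assert admissible_negative_span(inst_ge, filters)


def test_foreign_type_combination_is_not_a_negative(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    meth_in_ge = RelationInstance("d", "GE", (0, 4), "Methylation",
                                  (10, 15), "Protein", "stat3", True)
    meth_in_epi = RelationInstance("d", "EPI", (0, 4), "Methylation",
                                   (10, 15), "Protein", "stat3", True)
    bind_in_ge = RelationInstance("d", "GE", (0, 4), "Binding",
                                  (10, 15), "Protein", "stat3", True)
    assert not admissible_negative_relation(meth_in_ge, filters)
    assert admissible_negative_relation(meth_in_epi, filters)
    assert admissible_negative_relation(bind_in_ge, filters)


def test_untyped_argument_falls_back_to_surface(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    # an argument with no semantic type is matched by base form instead
    inst = RelationInstance("d", "GE", (0, 4), "Binding", (10, 15), None,
                            "mdm2", False)
    assert not admissible_negative_relation(inst, filters)


def test_assembled_sets_respect_figure_style_configuration():
    corpora = [_ge_like(), _epi_like()]
    prep = prepare_training(corpora)
    ts = build_training_sets(prep, filtered=True)["span"]
    # "methylation" tokens from the GE-scoped corpus are not NONE instances
    ge_negs = {i.base for i in ts.filtered_negatives["GE"]}
    assert "methylation" not in ge_negs
    epi_negs = {i.base for i in ts.filtered_negatives["EPI"]}
    assert "bind" not in epi_negs
    # raw closed-world negatives did contain them
    assert "methylation" in {i.base for i in ts.raw_negatives["GE"]}
    assert "bind" in {i.base for i in ts.raw_negatives["EPI"]}
    # positives are pooled across corpora without filtering
    assert set(ts.positives) == {"Binding", "Methylation"}


def test_training_set_invariants_hold(disjoint_corpora):
    prep = prepare_training(list(disjoint_corpora))
    sets = build_training_sets(prep, filtered=True)
    for stage, ts in sets.items():
        pos_keys = {i.key for insts in ts.positives.values()
                    for i in insts}
        for corpus, negs in ts.filtered_negatives.items():
            raw_keys = {i.key for i in ts.raw_negatives[corpus]}
            neg_keys = {i.key for i in negs}
            # N_i subset of N_i' and sound w.r.t. positives
            assert neg_keys <= raw_keys
            assert not (neg_keys & pos_keys)
        # P_neg and N_neg compose exactly as defined
        assert {i.key for i in ts.none_pos} == {
            i.key for negs in ts.filtered_negatives.values()
            for i in negs}
        assert {i.key for i in ts.none_neg} == pos_keys
        for label in ts.labels:
            assert not ({i.key for i in ts.positives[label]}
                        & {i.key for i in ts.negatives[label]})


@pytest.mark.parametrize("seed", range(41, 45))
def test_no_annotated_positive_in_any_filtered_negative_set(seed):
    corpora = generate(random_scenario(seed))
    prep = prepare_training(list(corpora))
    for stage, ts in build_training_sets(prep, filtered=True).items():
        gold_pos = {i.key for insts in prep.instances.values()
                    for i in insts[stage] if i.gold != NONE_LABEL}
        for negs in ts.filtered_negatives.values():
            assert not ({i.key for i in negs} & gold_pos)


def test_identical_scopes_make_multiple_equal_merge(identical_corpora):
    prep = prepare_training(list(identical_corpora))
    multiple = build_training_sets(prep, filtered=True)
    merge = build_training_sets(prep, filtered=False)
    for stage in multiple:
        a, b = multiple[stage], merge[stage]
        assert sorted(i.key for p in a.positives.values() for i in p) == \
            sorted(i.key for p in b.positives.values() for i in p)
        assert set(a.negatives) == set(b.negatives)
        for label in a.negatives:
            assert sorted(i.key for i in a.negatives[label]) == \
                sorted(i.key for i in b.negatives[label])
        assert sorted(i.key for i in a.none_pos) == \
            sorted(i.key for i in b.none_pos)


def test_adding_a_corpus_never_shrinks_positives_or_shared_negatives(
        disjoint_corpora):
    a, b = disjoint_corpora
    prep_one = prepare_training([a])
    prep_two = prepare_training([a, b])
    one = build_training_sets(prep_one, filtered=True)
    two = build_training_sets(prep_two, filtered=True)
    for stage in one:
        for label, pos in one[stage].positives.items():
            keys_one = {i.key for i in pos}
            keys_two = {i.key for i in two[stage].positives.get(label, [])}
            assert keys_one <= keys_two
        # negatives admitted from corpus a for shared types never vanish
        neg_a_one = {i.key for i in one[stage].filtered_negatives["A"]}
        neg_a_two = {i.key for i in two[stage].filtered_negatives["A"]}
        assert neg_a_one <= neg_a_two


@pytest.mark.parametrize("seed", range(51, 55))
@pytest.mark.parametrize("filtered", [True, False])
def test_span_and_relation_sets_match_brute_force(seed, filtered):
    """Steps 1-6 match an independent literal enumeration."""
    cfg = replace(random_scenario(seed), docs_per_corpus=6,
                  sentences_per_doc=3)
    corpora = generate(cfg)
    prep = prepare_training(list(corpora))
    sets = build_training_sets(prep, filtered=filtered)

    o_pos, o_neg, o_np, o_nn = oracle_span_sets(list(corpora), filtered)
    ts = sets["span"]
    assert {l: sorted(i.key for i in v)
            for l, v in ts.positives.items()} == \
        {l: sorted(v) for l, v in o_pos.items()}
    assert {l: sorted(i.key for i in v)
            for l, v in ts.negatives.items()} == \
        {l: sorted(v) for l, v in o_neg.items()}
    assert sorted(i.key for i in ts.none_pos) == sorted(o_np)
    assert sorted(i.key for i in ts.none_neg) == sorted(o_nn)

    o_pos, o_neg, o_np, o_nn = oracle_relation_sets(list(corpora),
                                                    filtered)
    ts = sets["relation"]
    assert {l: sorted(i.key for i in v)
            for l, v in ts.positives.items()} == \
        {l: sorted(v) for l, v in o_pos.items()}
    assert {l: sorted(i.key for i in v)
            for l, v in ts.negatives.items()} == \
        {l: sorted(v) for l, v in o_neg.items()}
    assert sorted(i.key for i in ts.none_pos) == sorted(o_np)


def test_structure_negatives_follow_signature_filter(disjoint_corpora):
    """Structure-stage filtering applies the literal signature rule."""
    prep = prepare_training(list(disjoint_corpora))
    ts = build_training_sets(prep, filtered=True)["structure"]
    for corpus, negs in ts.raw_negatives.items():
        scope = prep.scopes[corpus]
        in_scope_sigs = {s for s in prep.filters.global_sigs
                        if s[0] in scope.event_types}
        expected = [i.key for i in negs if i.signature in in_scope_sigs]
        assert sorted(i.key for i in ts.filtered_negatives[corpus]) == \
            sorted(expected)


def test_hedge_stage_is_never_filtered(hedge_corpora):
    prep = prepare_training(list(hedge_corpora))
    ts = build_training_sets(prep, filtered=True)["hedge"]
    for corpus in ts.raw_negatives:
        assert [i.key for i in ts.filtered_negatives[corpus]] == \
            [i.key for i in ts.raw_negatives[corpus]]


def test_filters_serialize_to_sidecar_text(two_corpus_filters):
    _corpora, filters = two_corpus_filters
    text = filters.to_text()
    assert "span\tBinding\tbind" in text
    assert "corpus-span\tEPI\tmethylation" in text
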