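"""Scopes, normalization rules and transferable-event accounting."""

import pytest

from eventweave.corpus import (Corpus, NormalizationRules, compute_scope,
                               count_transferable, normalize_corpus,
                               transfer_matrix)
from eventweave.standoff import read_document
from eventweave.synthetic import generate, random_scenario

from oracles import oracle_scope, oracle_transferable


def _mini_corpus(name="C", a2_extra=""):
    txt = "MDM2 mediates the phosphorylation of TP53 .\n"
    a1 = "T1\tProtein 0 4\tMDM2\nT2\tProtein 37 41\tTP53\n"
    a2 = ("T3\tPhosphorylation 18 33\tphosphorylation\n"
          "E1\tPhosphorylation:T3 Theme:T2 Cause:T1\n" + a2_extra)
    corpus = Corpus(name=name)
    corpus.add(read_document("d1", txt, a1, a2), "train")
    return corpus


def test_scope_lists_exactly_the_observed_types():
    scope = compute_scope(_mini_corpus())
    assert scope.event_types == {"Phosphorylation"}
    assert scope.entity_types == {"Protein"}
    assert scope.role_types == {"Theme", "Cause"}
    assert scope.relation_combos == {
        ("Phosphorylation", "Theme", "Protein"),
        ("Phosphorylation", "Cause", "Protein")}
    # no Methylation annotated -> no Methylation combos
    assert all(t != "Methylation" for t, _r, _a in scope.relation_combos)


def test_scope_requires_nonempty_selection():
    with pytest.raises(ValueError):
        compute_scope(_mini_corpus(), ())


@pytest.mark.parametrize("seed", [11, 12])
def test_scope_matches_brute_force_enumeration(seed):
    for corpus in generate(random_scenario(seed)):
        scope = compute_scope(corpus, ("train", "devel"))
        ent, span, ev, roles, combos, sigs = oracle_scope(
            corpus, ("train", "devel"))
        assert scope.entity_types == ent
        assert scope.span_types == span
        assert scope.event_types == ev
        assert scope.role_types == roles
        assert scope.relation_combos == combos
        assert scope.structure_signatures == sigs


def test_scope_monotone_under_added_documents(disjoint_corpora):
    corpus = disjoint_corpora[0]
    small = Corpus(name="part")
    docs = corpus.docs(("train",))
    for d in docs[:5]:
        small.add(d, "train")
    big = Corpus(name="all")
    for d in docs:
        big.add(d, "train")
    s_small, s_big = compute_scope(small), compute_scope(big)
    assert s_small.entity_types <= s_big.entity_types
    assert s_small.event_types <= s_big.event_types
    assert s_small.relation_combos <= s_big.relation_combos
    assert set(s_small.structure_signatures) <= set(
        s_big.structure_signatures)


def test_event_type_rename_relabels_trigger_and_event():
    txt = "MDM2 mediates the catalysis of TP53 .\n"
    a1 = "T1\tProtein 0 4\tMDM2\nT2\tProtein 31 35\tTP53\n"
    a2 = ("T3\tCatalysis 18 27\tcatalysis\n"
          "E1\tCatalysis:T3 Theme:T2 Cause:T1\n")
    corpus = Corpus(name="mTOR-like")
    corpus.add(read_document("d1", txt, a1, a2), "train")
    rules = NormalizationRules(
        event_type_map={"Catalysis": "Positive_regulation"})
    out = normalize_corpus(corpus, rules)
    doc = out.documents["d1"]
    assert doc.events[0].type == "Positive_regulation"
    assert doc.triggers[0].type == "Positive_regulation"


def test_role_renames_and_drops():
    txt = "MDM2 mediates the transport of TP53 .\n"
    a1 = "T1\tProtein 0 4\tMDM2\nT2\tProtein 31 35\tTP53\n"
    a2 = ("T3\tLocalization 18 27\ttransport\n"
          "E1\tLocalization:T3 Theme1:T2 toLoc:T1 fromLoc:T1\n")
    corpus = Corpus(name="C")
    corpus.add(read_document("d1", txt, a1, a2), "train")
    rules = NormalizationRules(role_map={"toLoc": "ToLoc",
                                         "Theme1": "Theme"},
                               roles_to_drop={"fromLoc", "product"})
    out = normalize_corpus(corpus, rules)
    roles = [r for r, _ in out.documents["d1"].events[0].args]
    assert roles == ["Theme", "ToLoc"]


def test_empty_rules_are_identity_and_idempotent(identical_corpora):
    corpus = identical_corpora[0]
    out = normalize_corpus(corpus, NormalizationRules())
    assert {d: c.text for d, c in out.documents.items()} == {
        d: c.text for d, c in corpus.documents.items()}
    rules = NormalizationRules(event_type_map={"Binding": "Complexing"},
                               role_map={"Theme": "Participant"})
    once = normalize_corpus(corpus, rules)
    twice = normalize_corpus(once, rules)
    for doc_id in once.documents:
        a, b = once.documents[doc_id], twice.documents[doc_id]
        assert [e.type for e in a.events] == [e.type for e in b.events]
        assert [e.args for e in a.events] == [e.args for e in b.events]


def test_singleton_structure_removal_drops_unique_training_structures():
    # two Phosphorylation Theme-only events (kept) and one Theme+Cause
    # event whose structure occurs once in training (dropped)
    txt1 = "The phosphorylation of TP53 was observed .\n"
    a1_1 = "T1\tProtein 23 27\tTP53\n"
    a2_1 = ("T2\tPhosphorylation 4 19\tphosphorylation\n"
            "E1\tPhosphorylation:T2 Theme:T1\n")
    txt2 = "MDM2 undergoes phosphorylation by TP53 .\n"
    a1_2 = "T1\tProtein 0 4\tMDM2\nT2\tProtein 34 38\tTP53\n"
    a2_2 = ("T3\tPhosphorylation 15 30\tphosphorylation\n"
            "E1\tPhosphorylation:T3 Theme:T1\n"
            "E2\tPhosphorylation:T3 Theme:T1 Cause:T2\n")
    corpus = Corpus(name="C")
    corpus.add(read_document("d1", txt1, a1_1, a2_1), "train")
    corpus.add(read_document("d2", txt2, a1_2, a2_2), "train")
    out = normalize_corpus(corpus,
                           NormalizationRules(
                               drop_singleton_structures=True))
    kept = [e for d in out.documents.values() for e in d.events]
    assert len(kept) == 2
    assert all(len(e.args) == 1 for e in kept)


def test_transferability_requires_recursive_type_coverage(nested_corpora):
    a, b = nested_corpora
    scope_b = compute_scope(b, ("train", "devel"))
    # a Regulation over a Binding inner event cannot transfer to B, whose
    # scope lacks Binding, even though Regulation itself is shared
    for doc in a.docs(("train",)):
        evs = doc.event_by_id()
        idx = doc.ann_index()
        for ev in doc.events:
            inner_types = {evs[ref].type for _r, ref in ev.args
                           if ref in evs}
            if "Binding" in inner_types:
                single = Corpus(name="one")
                single.add(doc, "train")
                n_rec = count_transferable(single, scope_b,
                                           ("train",), recursive=True)
                n_typ = count_transferable(single, scope_b,
                                           ("train",), recursive=False)
                assert n_rec <= n_typ
                return
    pytest.skip("no nested Binding event in this sample")


def test_self_transfer_is_total(disjoint_corpora):
    for corpus in disjoint_corpora:
        scope = compute_scope(corpus, ("train", "devel"))
        n = count_transferable(corpus, scope, ("train", "devel"))
        total = sum(len(d.events) for d in corpus.docs(("train", "devel")))
        assert n == total


@pytest.mark.parametrize("seed", [21, 22])
def test_transferable_counts_match_brute_force(seed):
    corpora = generate(random_scenario(seed))
    for src in corpora:
        for tgt in corpora:
            if src.name == tgt.name:
                continue
            got = count_transferable(
                src, compute_scope(tgt, ("train", "devel")),
                ("train", "devel"))
            assert got == oracle_transferable(src, tgt)


def test_transfer_matrix_sum_and_ratio(disjoint_corpora):
    mat = transfer_matrix(list(disjoint_corpora))
    names = [c.name for c in disjoint_corpora]
    for name in names:
        col = mat.loc[names, name].dropna()
        assert mat.loc["SUM", name] == col.sum()
        own = sum(len(d.events)
                  for c in disjoint_corpora if c.name == name
                  for d in c.docs(("train", "devel")))
        assert mat.loc["RATIO", name] == pytest.approx(
            mat.loc["SUM", name] / own)


def test_normalization_rules_from_dict_carries_ptm_collapse():
    rules = NormalizationRules.from_dict({
        "event_type_map": {"Catalysis": "Positive_regulation"},
        "roles_to_drop": ["fromLoc"],
        "ptm_collapse": {"Methylation": "PTM"},
    })
    assert rules.event_type_map == {"Catalysis": "Positive_regulation"}
    assert rules.roles_to_drop == {"fromLoc"}
    # ptm collapse is carried for the classifier label space, not applied
    # to stored corpora
    corpus = _mini_corpus()
    out = normalize_corpus(corpus, rules)
    assert out.documents["d1"].events[0].type == "Phosphorylation"
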