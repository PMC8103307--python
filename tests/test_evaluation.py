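import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from famhx.evaluation import (MatchSpec, attribute_accuracy, evaluate_entities,
                              evaluate_relations, f1_from_pr, micro_prf,
                              sweep_thresholds)
from famhx.model import (Category, Entity, FamilyMemberAttrs,
                         LivingStatusAttrs, ObservationAttrs, Relation,
                         RelationType)
from famhx.preprocess import preprocess
from famhx.rules import load_cue_lexicon, load_family_lexicon
from famhx.synthetic import GenConfig, generate_corpus


def test_micro_prf_basics():
    assert micro_prf(5, 5, 5) == (50.0, 50.0, 50.0)
    assert micro_prf(0, 0, 0) == (0.0, 0.0, 0.0)
    assert micro_prf(0, 3, 7) == (0.0, 0.0, 0.0)
    assert micro_prf(10, 0, 0) == (100.0, 100.0, 100.0)


@settings(deadline=None, derandomize=True)
@given(p=st.floats(0, 100), r=st.floats(0, 100))
def test_f1_properties(p, r):
    f = f1_from_pr(p, r)
    assert f == f1_from_pr(r, p)
    assert f <= max(p, r) + 0.005  # slack for 2-decimal report rounding
    assert f1_from_pr(p, p) == pytest.approx(p, abs=0.01)


def _fm(doc, name, side="NA"):
    return Entity(doc, Category.FAMILY_MEMBER, name,
                  attrs=FamilyMemberAttrs(name, side))


def _obs(doc, text, negation="Non_Negated"):
    return Entity(doc, Category.OBSERVATION, text,
                  attrs=ObservationAttrs(negation))


def test_observation_partial_word_match():
    report = evaluate_entities([_obs("d", "cancer")], [_obs("d", "breast cancer")])
    assert report.categories["Observation"].tp == 1


def test_observation_no_shared_word_is_miss():
    report = evaluate_entities([_obs("d", "diabetes")], [_obs("d", "breast cancer")])
    c = report.categories["Observation"]
    assert (c.tp, c.fp, c.fn) == (0, 1, 1)


def test_family_side_enforced_unless_ignored():
    sys = [_fm("d", "Uncle", "Maternal")]
    ref = [_fm("d", "Uncle", "Paternal")]
    strict = evaluate_entities(sys, ref).categories["FamilyMember"]
    assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
    relaxed = evaluate_entities(sys, ref, MatchSpec(ignore_side=True))
    assert relaxed.categories["FamilyMember"].tp == 1


def test_identical_sets_score_perfectly():
    sys = [_fm("d", "Mother"), _obs("d", "diabetes")]
    report = evaluate_entities(sys, list(sys))
    p, r, f = report.overall.prf
    assert (p, r, f) == (100.0, 100.0, 100.0)


def _ls_rel(doc, name, side, score):
    fm = _fm(doc, name, side)
    ls = Entity(doc, Category.LIVING_STATUS, "status",
                attrs=LivingStatusAttrs(score))
    return Relation(doc, RelationType.FM_LIVING_STATUS, fm, ls, score=score)


def _obs_rel(doc, name, side, text, negation="Non_Negated"):
    return Relation(doc, RelationType.FM_OBSERVATION, _fm(doc, name, side),
                    _obs(doc, text, negation), negation=negation)


def test_wrong_score_counts_against_unless_ignored():
    sys, ref = [_ls_rel("d", "Mother", "NA", 2)], [_ls_rel("d", "Mother", "NA", 0)]
    strict = evaluate_relations(sys, ref).categories["LivingStatus"]
    assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
    relaxed = evaluate_relations(sys, ref, MatchSpec(ignore_living_status=True))
    assert relaxed.categories["LivingStatus"].tp == 1


def test_wrong_negation_counts_against_unless_ignored():
    sys = [_obs_rel("d", "Aunt", "Maternal", "colon cancer", "Negated")]
    ref = [_obs_rel("d", "Aunt", "Maternal", "colon cancer", "Non_Negated")]
    assert evaluate_relations(sys, ref).categories["Observation"].tp == 0
    assert evaluate_relations(
        sys, ref, MatchSpec(ignore_negation=True)).categories["Observation"].tp == 1


def test_empty_system_output_scores_zero():
    report = evaluate_relations([], [_ls_rel("d", "Mother", "NA", 0)])
    p, r, _ = report.overall.prf
    assert (p, r) == (0.0, 0.0)


def test_overall_counts_are_category_sums():
    sys = [_fm("d", "Mother"), _obs("d", "diabetes"), _obs("d", "anxiety")]
    ref = [_fm("d", "Mother"), _obs("d", "diabetes"), _fm("d", "Father")]
    report = evaluate_entities(sys, ref)
    overall = report.overall
    assert overall.tp == sum(c.tp for c in report.categories.values())
    assert overall.fp == sum(c.fp for c in report.categories.values())
    assert overall.fn == sum(c.fn for c in report.categories.values())


def _perturbed_relations(rng, gold):
    out = []
    for r in gold:
        side = r.family_member.attrs.side
        if side != "NA" and rng.random() < 0.3:
            side = "Maternal" if side == "Paternal" else "Paternal"
        fm = _fm(r.doc_id, r.family_member.attrs.normalized_name, side)
        if r.type is RelationType.FM_LIVING_STATUS:
            score = r.score
            if rng.random() < 0.3:
                score = int(rng.choice([0, 2, 4]))
            out.append(Relation(r.doc_id, r.type, fm, r.other, score=score))
        else:
            neg = r.negation
            if rng.random() < 0.3:
                neg = "Negated" if neg == "Non_Negated" else "Non_Negated"
            out.append(Relation(r.doc_id, r.type, fm, r.other, negation=neg))
    return out


def test_ignoring_attributes_never_lowers_true_positives(small_corpus):
    _, _, gold = small_corpus
    rng = np.random.default_rng(23)
    noisy = _perturbed_relations(rng, gold)
    base = evaluate_relations(noisy, gold).overall
    for spec in (MatchSpec(ignore_side=True),
                 MatchSpec(ignore_living_status=True),
                 MatchSpec(ignore_negation=True),
                 MatchSpec(True, True, True)):
        relaxed = evaluate_relations(noisy, gold, spec).overall
        assert relaxed.tp >= base.tp
        assert relaxed.fp <= base.fp and relaxed.fn <= base.fn


def test_attribute_accuracy_counts_injected_failures(lexicon, cues):
    docs = {}
    entities, relations = [], []
    # two normalizable family members, one unknown kin word
    text = "His twin has diabetes. His dad has cancer. Paternal uncle is well."
    doc = preprocess(text, "d")
    docs["d"] = doc

    def ent(phrase, name, side):
        start = text.index(phrase)
        return Entity("d", Category.FAMILY_MEMBER, phrase, start,
                      start + len(phrase), attrs=FamilyMemberAttrs(name, side))

    entities = [ent("twin", "Brother", "NA"),       # dictionary miss
                ent("dad", "Father", "NA"),
                ent("uncle", "Uncle", "Maternal")]  # cue says Paternal: wrong
    acc = attribute_accuracy(docs, entities, relations, lexicon, cues)
    assert acc["normalization"] == pytest.approx(round(100 * 2 / 3, 2))
    assert acc["side"] == pytest.approx(50.0)  # of the 2 normalizable ones


def test_attribute_accuracy_on_consistent_gold(small_corpus, lexicon, cues):
    docs, entities, relations = small_corpus
    acc = attribute_accuracy({d.doc_id: d for d in docs}, entities, relations,
                             lexicon, cues)
    for task, value in acc.items():
        assert value == 100.0, task


class TestThresholdSweep:
    def _predictions(self, rng, gold):
        preds = []
        for _ in range(4):
            kept = [e for e in gold if rng.random() < 0.8]
            preds.append(kept)
        return preds

    @staticmethod
    def _attach(gold):
        by_key = {e.key(): e for e in gold}
        return lambda ents: [by_key[e.key()] for e in ents]

    def test_reports_match_independent_evaluation(self, small_corpus):
        from famhx.voting import (EnsembleConfig, collect_votes, rank_models,
                                  resolve_entities)
        docs, gold, _ = small_corpus
        gold = [e for e in gold if e.category is Category.FAMILY_MEMBER]
        rng = np.random.default_rng(3)
        preds = self._predictions(rng, gold)
        attach = self._attach(gold)
        sweep = sweep_thresholds(preds, gold, attach=attach,
                                 thresholds=range(1, 5))
        votes, ranking = collect_votes(preds), rank_models(preds)
        last_pool = None
        for t, (report, pool) in sweep.items():
            resolved = resolve_entities(votes, ranking, EnsembleConfig(t))
            direct = evaluate_entities(attach(resolved), gold)
            assert report.to_dict() == direct.to_dict()
            if last_pool is not None:
                assert pool <= last_pool
            last_pool = pool

    def test_identical_models_give_flat_curves(self, small_corpus):
        _, gold, _ = small_corpus
        gold = [e for e in gold if e.category is Category.FAMILY_MEMBER]
        preds = [list(gold)] * 4
        sweep = sweep_thresholds(preds, gold, attach=self._attach(gold),
                                 thresholds=range(1, 5))
        reports = [rep.to_dict() for rep, _ in sweep.values()]
        assert all(r == reports[0] for r in reports)
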