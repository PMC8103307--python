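import numpy as np
import pytest

from famhx.model import (Category, Document, Entity, FamilyMemberAttrs,
                         Relation, RelationType)
from famhx.preprocess import preprocess
from famhx.relations import (LinearRelationModel, assemble_relations,
                             classify_pairs, extract_features,
                             generate_candidate_pairs, hash_features,
                             logistic_gradient, train_relation_model)

from oracles import numeric_gradient


def _ent(doc, cat, text, start, attrs=None):
    return Entity(doc.doc_id, Category(cat), text, start, start + len(text),
                  attrs=attrs)


def _find(doc, cat, phrase, attrs=None):
    start = doc.text.index(phrase)
    return _ent(doc, cat, phrase, start, attrs)


class TestCandidatePairs:
    def test_single_fm_ls_pair(self):
        doc = preprocess("Mother is deceased.", "d")
        ents = [_find(doc, "FamilyMember", "Mother"),
                _find(doc, "LivingStatus", "deceased")]
        pairs = generate_candidate_pairs(ents, doc, mode="test")
        assert len(pairs) == 1
        assert pairs[0].type is RelationType.FM_LIVING_STATUS

    def test_cross_product_count_without_newlines(self):
        doc = preprocess(
            "Mother and father and sister share diabetes and anxiety today.", "d")
        ents = [_find(doc, "FamilyMember", "Mother"),
                _find(doc, "FamilyMember", "father"),
                _find(doc, "FamilyMember", "sister"),
                _find(doc, "Observation", "diabetes"),
                _find(doc, "Observation", "anxiety")]
        pairs = generate_candidate_pairs(ents, doc, mode="test")
        assert len(pairs) == 6

    def test_negative_across_newline_dropped_positive_kept(self):
        doc = preprocess("Mother is well.\nDiabetes was noted.", "d")
        fm = _find(doc, "FamilyMember", "Mother")
        obs = _find(doc, "Observation", "Diabetes")
        gold = [Relation("d", RelationType.FM_OBSERVATION, fm, obs,
                         negation="Non_Negated")]
        as_negative = generate_candidate_pairs([fm, obs], doc, mode="train",
                                               gold_relations=[])
        assert as_negative == []
        as_positive = generate_candidate_pairs([fm, obs], doc, mode="train",
                                               gold_relations=gold)
        assert len(as_positive) == 1 and as_positive[0].label is True
        at_test = generate_candidate_pairs([fm, obs], doc, mode="test")
        assert at_test == []

    def test_train_mode_requires_gold(self):
        doc = preprocess("Mother is well.", "d")
        with pytest.raises(ValueError, match="gold"):
            generate_candidate_pairs([], doc, mode="train")


class TestFeatures:
    def test_window_truncated_at_document_start(self):
        doc = preprocess("Mother has diabetes today.", "d")
        fm = _find(doc, "FamilyMember", "Mother")
        obs = _find(doc, "Observation", "diabetes")
        pairs = generate_candidate_pairs([fm, obs], doc, mode="test")
        feats = extract_features(pairs[0], doc, [fm, obs])
        assert not any(f.startswith("fm_l7=") for f in feats)
        assert [f for f in feats if f.startswith("btw=")] == ["btw=has"]

    def test_family_members_between_pair_are_counted(self):
        doc = preprocess("Mother and father both had cancer.", "d")
        mother = _find(doc, "FamilyMember", "Mother")
        father = _find(doc, "FamilyMember", "father")
        obs = _find(doc, "Observation", "cancer")
        pair = generate_candidate_pairs([mother, obs], doc, mode="test")[0]
        feats = extract_features(pair, doc, [mother, father, obs])
        assert "fm_between=1" in feats
        pair2 = generate_candidate_pairs([father, obs], doc, mode="test")[0]
        assert "fm_between=0" in extract_features(pair2, doc,
                                                  [mother, father, obs])

    def test_between_words_match_slicing_oracle(self, small_corpus):
        docs, entities, _ = small_corpus
        rng = np.random.default_rng(5)
        checked = 0
        for doc in docs:
            ents = [e for e in entities if e.doc_id == doc.doc_id]
            pairs = generate_candidate_pairs(ents, doc, mode="test")
            for pair in pairs:
                if rng.random() > 0.3:
                    continue
                feats = extract_features(pair, doc, ents)
                got = [f[4:] for f in feats if f.startswith("btw=")]
                lo = min(pair.family_member.end, pair.other.end)
                hi = max(pair.family_member.start, pair.other.start)
                expected = [t.text.lower() for s in doc.sentences
                            for t in s.tokens if t.start >= lo and t.end <= hi]
                assert got == expected
                checked += 1
        assert checked > 20


class TestOnlineGradientDescent:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        model = LinearRelationModel()
        model.weights = np.zeros(model.weights.shape)
        for _ in range(5):
            feats = [f"w={rng.integers(100)}" for _ in range(8)]
            idx = hash_features(feats)
            model.weights[idx] = rng.normal(size=len(idx))
            model.bias = float(rng.normal())
            y = int(rng.integers(2))

            def loss():
                p = model.probability(idx)
                return -(y * np.log(p) + (1 - y) * np.log(1 - p))

            sub = model.weights[idx].copy()

            def loss_wrt_sub():
                model.weights[idx] = sub
                return loss()

            num = numeric_gradient(loss_wrt_sub, sub)
            model.weights[idx] = sub
            ana, ana_b = logistic_gradient(model, idx, y)
            denom = np.maximum(1e-8, np.abs(num) + np.abs(ana))
            assert np.all(np.abs(num - ana) / denom <= 1e-6)

    def test_linearly_separable_toy_set_is_learned(self):
        examples = ([(["sig=yes", f"id={i}"], True) for i in range(5)]
                    + [(["sig=no", f"id={i+5}"], False) for i in range(5)])
        model = train_relation_model(examples, passes=100, seed=0)
        for feats, label in examples:
            assert (model.probability(hash_features(feats)) >= 0.5) == label

    def test_identical_features_predict_class_prior(self):
        examples = [(["same=1"], True)] * 3 + [(["same=1"], False)] * 1
        model = train_relation_model(examples, passes=200, seed=0)
        assert model.probability(hash_features(["same=1"])) == pytest.approx(
            0.75, abs=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_relation_model([(["a"], True), (["b"], True)])

    def test_zero_weight_model_ties_to_related(self):
        doc = preprocess("Mother has diabetes.", "d")
        fm = _find(doc, "FamilyMember", "Mother")
        obs = _find(doc, "Observation", "diabetes")
        pairs = generate_candidate_pairs([fm, obs], doc, mode="test")
        feats = [extract_features(p, doc, [fm, obs]) for p in pairs]
        results = classify_pairs(LinearRelationModel(), pairs, feats)
        assert all(p == 0.5 and related for _, related, p in results)

    def test_classification_is_deterministic(self):
        examples = [(["a", "b"], True), (["c"], False), (["a"], True),
                    (["c", "d"], False)]
        m1 = train_relation_model(examples, passes=50, seed=3)
        m2 = train_relation_model(examples, passes=50, seed=3)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias


class TestAssembly:
    def test_scores_and_negation_attached(self, cues):
        doc = preprocess("Father is deceased. No family history of cancer.", "d")
        fm = _find(doc, "FamilyMember", "Father",
                   FamilyMemberAttrs("Father", "NA"))
        ls = _find(doc, "LivingStatus", "deceased")
        obs = _find(doc, "Observation", "cancer")
        pairs = generate_candidate_pairs([fm, ls, obs], doc, mode="test")
        rels = assemble_relations(pairs, {"d": doc}, cues)
        by_type = {r.type: r for r in rels}
        assert by_type[RelationType.FM_LIVING_STATUS].score == 0
        assert by_type[RelationType.FM_OBSERVATION].negation == "Negated"

    def test_duplicate_pairs_collapse(self, cues):
        doc = preprocess("Mother and mother have diabetes.", "d")
        attrs = FamilyMemberAttrs("Mother", "NA")
        fm1 = _find(doc, "FamilyMember", "Mother", attrs)
        start2 = doc.text.index("mother")
        fm2 = _ent(doc, "FamilyMember", "mother", start2, attrs)
        obs = _find(doc, "Observation", "diabetes")
        pairs = generate_candidate_pairs([fm1, fm2, obs], doc, mode="test")
        rels = assemble_relations(pairs, {"d": doc}, cues)
        assert len(rels) == 1
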