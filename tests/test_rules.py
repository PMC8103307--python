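import numpy as np
import pytest

from famhx.model import Category, Entity
from famhx.preprocess import preprocess
from famhx.rules import (assign_family_side, detect_negation,
                         match_family_members, normalize_family_member,
                         score_living_status)

from oracles import negation_scope_oracle


class TestFamilyMemberMatching:
    def test_kin_noun_is_matched(self, lexicon):
        doc = preprocess("His daughter is well.", "d")
        ents = match_family_members(doc, lexicon)
        assert [(e.text, e.category) for e in ents] == \
            [("daughter", Category.FAMILY_MEMBER)]

    def test_kin_verb_is_not_matched(self, lexicon):
        doc = preprocess("They will father a child.", "d")
        assert "father" not in [e.text for e in match_family_members(doc, lexicon)]

    def test_excluded_relatives_never_match(self, lexicon):
        doc = preprocess("Her spouse has asthma and her nephew has migraines.", "d")
        assert match_family_members(doc, lexicon) == []


class TestNormalization:
    @pytest.mark.parametrize("surface,expected", [
        ("his dad", "Father"),
        ("three uncles", "Uncle"),
        ("Maternal grandfather", "Grandfather"),
        ("mom", "Mother"),
        ("2 sisters", "Sister"),
    ])
    def test_surface_forms(self, lexicon, surface, expected):
        assert normalize_family_member(surface, lexicon) == expected

    def test_unknown_term_surfaces_as_none(self, lexicon):
        assert normalize_family_member("twin", lexicon) is None

    @pytest.mark.parametrize("text,target,expected", [
        ("His mother has a sister with colon cancer.", "sister", "Aunt"),
        ("His mother's sister had breast cancer.", "sister", "Aunt"),
        ("Her father's brother is deceased.", "brother", "Uncle"),
        ("His mother's mother had a stroke.", "mother", "Grandmother"),
    ])
    def test_nested_kinship_composes(self, lexicon, text, target, expected):
        doc = preprocess(text, "d")
        start = text.rindex(target)
        assert normalize_family_member(
            target, lexicon, doc.sentences[0], start) == expected

    def test_coordination_does_not_compose(self, lexicon):
        text = "Mother and father are healthy."
        doc = preprocess(text, "d")
        assert normalize_family_member(
            "father", lexicon, doc.sentences[0], text.index("father")) == "Father"

    def test_idempotent_at_string_level(self, lexicon):
        for name in set(lexicon.terms.values()):
            assert normalize_family_member(name, lexicon) == name


class TestFamilySide:
    def test_cue_inside_entity_text(self, cues):
        assert assign_family_side("paternal grandmother", "Grandmother", cues) \
            == "Paternal"

    def test_first_degree_is_always_na(self, cues):
        text = "His maternal relatives include his mother."
        doc = preprocess(text, "d")
        assert assign_family_side("mother", "Mother", cues, doc.sentences[0],
                                  text.index("mother")) == "NA"

    def test_sentence_expansion(self, cues):
        text = "On the mother's side a cousin has cancer."
        doc = preprocess(text, "d")
        assert assign_family_side("cousin", "Cousin", cues, doc.sentences[0],
                                  text.index("cousin")) == "Maternal"

    def test_no_cue_defaults_to_na(self, cues):
        text = "A cousin has cancer."
        doc = preprocess(text, "d")
        assert assign_family_side("cousin", "Cousin", cues, doc.sentences[0],
                                  text.index("cousin")) == "NA"

    def test_never_sided_for_first_degree_gold(self, small_corpus, cues, lexicon):
        docs, entities, _ = small_corpus
        doc_map = {d.doc_id: d for d in docs}
        for e in entities:
            if e.category is not Category.FAMILY_MEMBER:
                continue
            norm = normalize_family_member(
                e.text, lexicon, doc_map[e.doc_id].sentence_at(e.start), e.start)
            side = assign_family_side(
                e.text, norm, cues, doc_map[e.doc_id].sentence_at(e.start), e.start)
            if e.attrs.degree == "first":
                assert side == "NA"


class TestLivingStatusScore:
    @pytest.mark.parametrize("phrase,score", [
        ("passed away", 0),
        ("deceased", 0),
        ("no longer living", 0),
        ("alive and well", 4),
        ("healthy", 4),
        ("good general health", 4),
        ("lives in Ohio", 2),
        ("alive", 2),
    ])
    def test_scoring_rule(self, cues, phrase, score):
        assert score_living_status(phrase, cues) == score

    def test_not_alive_takes_precedence_over_healthy(self, cues):
        assert score_living_status("was healthy until she passed away", cues) == 0

    def test_range_is_always_valid(self, cues):
        rng = np.random.default_rng(0)
        words = ["alive", "well", "deceased", "healthy", "ohio", "passed",
                 "away", "fine", "living", "no", "longer"]
        for _ in range(200):
            phrase = " ".join(rng.choice(words, size=rng.integers(1, 5)))
            assert score_living_status(phrase, cues) in (0, 2, 4)

    def test_empty_phrase_rejected(self, cues):
        with pytest.raises(ValueError):
            score_living_status("", cues)


def _obs(doc, word):
    start = doc.text.index(word)
    return Entity("d", Category.OBSERVATION, word, start, start + len(word))


class TestNegation:
    def test_no_family_history_trigger(self, cues):
        doc = preprocess("No family history of diabetes.", "d")
        assert detect_negation(doc.sentences[0], _obs(doc, "diabetes"), cues) \
            == "Negated"

    def test_plain_statement_not_negated(self, cues):
        doc = preprocess("Mother has diabetes.", "d")
        assert detect_negation(doc.sentences[0], _obs(doc, "diabetes"), cues) \
            == "Non_Negated"

    def test_scope_terminates_at_conjunction(self, cues):
        doc = preprocess("Patient denies cancer but confirms diabetes.", "d")
        sent = doc.sentences[0]
        assert detect_negation(sent, _obs(doc, "cancer"), cues) == "Negated"
        assert detect_negation(sent, _obs(doc, "diabetes"), cues) == "Non_Negated"

    def test_scope_window_limits_reach(self, cues):
        doc = preprocess(
            "Not significant for one two three four five six diabetes.", "d")
        assert detect_negation(doc.sentences[0], _obs(doc, "diabetes"), cues) \
            == "Non_Negated"

    def test_fuzzed_scopes_match_token_walk_oracle(self, cues):
        rng = np.random.default_rng(42)
        filler = ["history", "of", "significant", "cancer", "possible",
                  "chronic", "recent", "severe", "and"]
        triggers = [list(t.split()) for t in cues.negation_triggers]
        terms = set(cues.negation_terminators)
        for _ in range(300):
            words = list(rng.choice(filler, size=rng.integers(2, 9)))
            if rng.random() < 0.7:
                trig = list(rng.choice(cues.negation_triggers, size=1))[0]
                pos = int(rng.integers(0, len(words) + 1))
                words[pos:pos] = trig.split()
            if rng.random() < 0.4:
                words.insert(int(rng.integers(0, len(words) + 1)), "but")
            obs_idx = int(rng.integers(0, len(words)))
            words[obs_idx] = "diabetes"
            text = " ".join(words)
            doc = preprocess(text, "d")
            sent = doc.sentences[0]
            obs_idx_tok = next(i for i, t in enumerate(sent.tokens)
                               if t.text == "diabetes")
            obs = _obs(doc, "diabetes")
            expected = negation_scope_oracle(
                [t.text.lower() for t in sent.tokens], triggers, terms,
                obs_idx_tok)
            got = detect_negation(sent, obs, cues)
            assert got == ("Negated" if expected else "Non_Negated")
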