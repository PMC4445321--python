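import random

import pytest

from connmine.corpus_io import Sentence
from connmine.ner import Mention, match_lexical
from connmine.relations import (
    ExtractorConfig,
    candidate_pairs,
    extract_filter,
    extract_kernel,
    extract_rules,
    load_rules,
    pair_features,
    train_kernel,
)
from connmine.synthetic_corpus import SimConfig, generate_kernel_training, toy_lexicon


def sent(text: str) -> Sentence:
    return Sentence(doc_id="d", index=0, start=0, end=len(text), text=text)


def mentions_for(s: Sentence, lex) -> list[Mention]:
    return match_lexical(s, lex)


class TestCandidatePairs:
    def test_three_distinct_regions(self, bg_lexicon):
        s = sent("the thalamus, the hypothalamus and the subthalamic nucleus")
        assert len(candidate_pairs(s, mentions_for(s, bg_lexicon))) == 3

    def test_same_region_twice_no_pair(self, bg_lexicon):
        s = sent("the thalamus and again the thalamus")
        assert candidate_pairs(s, mentions_for(s, bg_lexicon)) == []

    def test_combinatorial_count(self):
        rng = random.Random(4)
        for _ in range(30):
            n = rng.randint(0, 8)
            ms = [Mention("d", 0, i * 10, i * 10 + 5, f"r{i}", f"R{i}", "lexical") for i in range(n)]
            s = sent(" " * (n * 10 + 5))
            assert len(candidate_pairs(s, ms)) == n * (n - 1) // 2

    def test_unresolved_mentions_excluded(self):
        ms = [
            Mention("d", 0, 0, 4, "aaaa", "R1", "lexical"),
            Mention("d", 0, 10, 14, "bbbb", None, "statistical"),
        ]
        assert candidate_pairs(sent(" " * 20), ms) == []


class TestFilter:
    def test_conjunction_sentence_rejected(self, bg_lexicon, extractor_cfg):
        s = sent(
            "Their responses to stimulation of both the cerebellar nuclei (CN) and the entopeduncular nucleus (ENT) were examined."
        )
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        assert len(pairs) == 1
        assert extract_filter(s, pairs, extractor_cfg) == []

    def test_connective_sentence_retained(self, bg_lexicon, extractor_cfg):
        s = sent("The entopeduncular nucleus invades the hypothalamus also with a loose plexus of wooly fibers.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        (cm,) = extract_filter(s, pairs, extractor_cfg)
        assert cm.pair_key == ("GPI", "HY")
        assert cm.extractor == "FILTER" and cm.confidence == pytest.approx(0.45)
        assert cm.evidence_text == s.text

    def test_single_mention_no_candidates(self, bg_lexicon, extractor_cfg):
        s = sent("the thalamus was large")
        assert extract_filter(s, candidate_pairs(s, mentions_for(s, bg_lexicon)), extractor_cfg) == []

    def test_all_filters_off_is_cooccurrence_baseline(self, bg_lexicon):
        cfg = ExtractorConfig(conjunction_filter=False, list_filter=False, negation_filter=False)
        s = sent("Both the thalamus and the hypothalamus were examined.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        assert len(extract_filter(s, pairs, cfg)) == len(pairs) == 1

    def test_list_context_filter(self, bg_lexicon, extractor_cfg):
        s = sent("The thalamus, hypothalamus, subthalamic nucleus and substantia nigra were sampled.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        assert len(pairs) == 6
        assert extract_filter(s, pairs, extractor_cfg) == []

    def test_negation_filter(self, bg_lexicon, extractor_cfg):
        s = sent("The thalamus showed no projection to the hypothalamus.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        assert extract_filter(s, pairs, extractor_cfg) == []
        cfg = ExtractorConfig(negation_filter=False)
        assert len(extract_filter(s, pairs, cfg)) == 1


class TestRules:
    def test_rule_template_distributes_conjuncts(self, bg_lexicon, extractor_cfg):
        s = sent("We observed a projection from the region A to the region C and the region D.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        got = sorted(cm.pair_key for cm in extract_rules(s, pairs, extractor_cfg))
        assert got == [("A", "C"), ("A", "D")]

    def test_projects_to_template(self, bg_lexicon, extractor_cfg):
        s = sent("The STN projects to the GPi.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        (cm,) = extract_rules(s, pairs, extractor_cfg)
        assert cm.pair_key == ("GPI", "STN")
        assert cm.confidence == pytest.approx(0.72)

    def test_no_connective_no_match(self, bg_lexicon, extractor_cfg):
        s = sent("The thalamus and the hypothalamus were compared.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        assert extract_rules(s, pairs, extractor_cfg) == []

    def test_nine_rules_shipped(self):
        rules = load_rules()
        assert len(rules) == 9
        assert len({r.rule_id for r in rules}) == 9

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("The thalamus receives afferents from the subthalamic nucleus.", ("STN", "TH")),
            ("Efferents from the subthalamic nucleus terminate in the thalamus.", ("STN", "TH")),
            ("Afferents to the thalamus originate in the subthalamic nucleus.", ("STN", "TH")),
            ("The subthalamic nucleus sends axons to the thalamus.", ("STN", "TH")),
            ("A connection between the thalamus and the hypothalamus was shown.", ("HY", "TH")),
            ("The thalamus is reciprocally connected with the hypothalamus.", ("HY", "TH")),
            ("The subthalamic nucleus innervates the thalamus.", ("STN", "TH")),
        ],
    )
    def test_each_template_family(self, bg_lexicon, extractor_cfg, text, expected):
        s = sent(text)
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        got = {cm.pair_key for cm in extract_rules(s, pairs, extractor_cfg)}
        assert expected in got

    def test_rules_subset_of_candidates(self, bg_lexicon, extractor_cfg):
        rng = random.Random(7)
        regions = ["thalamus", "hypothalamus", "subthalamic nucleus", "substantia nigra", "cerebellar nuclei"]
        for _ in range(50):
            words = [rng.choice(regions + ["projects", "to", "from", "the", "and", "was", "studied"]) for _ in range(8)]
            s = sent(" ".join(words) + ".")
            pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
            keys = {p.pair_key for p in pairs}
            for cm in extract_rules(s, pairs, extractor_cfg):
                assert cm.pair_key in keys

    def test_extractors_independent(self, bg_lexicon):
        s = sent("The STN projects to the GPi.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        on = ExtractorConfig()
        off = ExtractorConfig(conjunction_filter=False, list_filter=False, negation_filter=False)
        # changing FILTER switches does not alter RULES output
        assert [c.pair_key for c in extract_rules(s, pairs, on)] == [
            c.pair_key for c in extract_rules(s, pairs, off)
        ]


@pytest.fixture(scope="module")
def setup():
    lex = toy_lexicon()
    cfg = SimConfig(seed=21)
    labeled = generate_kernel_training(cfg, lex, n_positive=500, n_negative=500)
    return lex, train_kernel(labeled, seed=21)


class TestKernel:
    def test_heldout_accuracy(self, setup):
        lex, model = setup
        held = generate_kernel_training(SimConfig(seed=22), lex, n_positive=100, n_negative=100)
        X = model.vectorizer.transform([f for f, _ in held])
        pred = model.clf.predict(X)
        acc = sum(int(p == y) for p, (_, y) in zip(pred, held)) / len(held)
        assert acc >= 0.9

    def test_emits_with_kernel_confidence(self, setup, extractor_cfg):
        lex, model = setup
        a = lex["R00"].preferred_name
        b = lex["R09"].preferred_name
        s = sent(f"The {a} projects to the {b}.")
        pairs = candidate_pairs(s, match_lexical(s, lex))
        (cm,) = extract_kernel(s, pairs, model, extractor_cfg)
        assert cm.extractor == "KERNEL" and cm.confidence == pytest.approx(0.60)

    def test_no_pairs_empty(self, setup, extractor_cfg):
        lex, model = setup
        assert extract_kernel(sent("Nothing here."), [], model, extractor_cfg) == []

    def test_untrained_model_error(self, extractor_cfg, bg_lexicon):
        s = sent("The STN projects to the GPi.")
        pairs = candidate_pairs(s, mentions_for(s, bg_lexicon))
        with pytest.raises(ValueError):
            extract_kernel(s, pairs, None, extractor_cfg)

    def test_single_class_training_error(self):
        with pytest.raises(ValueError):
            train_kernel([({"bias": 1.0}, 1), ({"bias": 1.0}, 1)], seed=0)

    def test_determinism(self, setup):
        lex, model = setup
        labeled = generate_kernel_training(SimConfig(seed=21), lex, n_positive=500, n_negative=500)
        model2 = train_kernel(labeled, seed=21)
        held = generate_kernel_training(SimConfig(seed=23), lex, n_positive=50, n_negative=50)
        X1 = model.vectorizer.transform([f for f, _ in held])
        X2 = model2.vectorizer.transform([f for f, _ in held])
        assert (model.clf.predict_proba(X1) == model2.clf.predict_proba(X2)).all()
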