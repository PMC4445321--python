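import random

import pytest

from connmine.corpus_io import Document, Sentence, tokenize
from connmine.lexicon import RegionEntry, RegionLexicon
from connmine.ner import (
    AbbreviationRegistry,
    Mention,
    annotate_document,
    match_lexical,
    merge_mentions,
    register_abbreviations,
    tag_statistical,
    train_tagger,
)
from connmine.synthetic_corpus import SimConfig, generate_tagger_training, toy_lexicon

ARTICLES = {"the", "a", "an"}


def make_sentence(text: str) -> Sentence:
    return Sentence(doc_id="d", index=0, start=0, end=len(text), text=text)


def oracle_spans(sentence: Sentence, lex: RegionLexicon, max_len: int = 8) -> list[tuple[int, int]]:
    """Brute force: enumerate every token subsequence up to max_len, keep
    the lexicon members, then select maximal non-overlapping matches with
    leftmost-longest priority."""
    toks = tokenize(sentence)
    cands = []
    for i in range(len(toks)):
        if toks[i].text.lower() in ARTICLES or not any(c.isalnum() for c in toks[i].text):
            continue
        for j in range(i + 1, min(len(toks), i + max_len) + 1):
            if not any(c.isalnum() for c in toks[j - 1].text):
                continue
            surface = sentence.text[toks[i].start : toks[j - 1].end]
            if lex.lookup(surface):
                cands.append((toks[i].start, toks[j - 1].end))
    chosen: list[tuple[int, int]] = []
    while cands:
        best = min(cands, key=lambda c: (c[0], -c[1]))
        chosen.append(best)
        cands = [c for c in cands if c[1] <= best[0] or c[0] >= best[1]]
    return sorted(chosen)


def random_instance(rng: random.Random) -> tuple[Sentence, RegionLexicon]:
    words = ["alpha", "beta", "gamma", "delta", "nucleus", "area", "complex", "field"]
    names = set()
    for _ in range(rng.randint(2, 6)):
        n = rng.randint(1, 3)
        names.add(" ".join(rng.choice(words) for _ in range(n)))
    lex = RegionLexicon(
        [RegionEntry(f"R{k}", name) for k, name in enumerate(sorted(names))], source_order=["t"]
    )
    sent_words = []
    for _ in range(rng.randint(3, 14)):
        r = rng.random()
        if r < 0.5:
            sent_words.append(rng.choice(words))
        elif r < 0.65:
            sent_words.append(rng.choice(["the", "a", "of", "to", "and"]))
        else:
            sent_words.append(rng.choice(["projects", "was", "studied", ",", "("]))
    return make_sentence(" ".join(sent_words)), lex


class TestLexicalMatch:
    def test_evidence_style_sentence(self, bg_lexicon):
        s = make_sentence(
            "The entopeduncular nucleus invades the hypothalamus also with a loose plexus of wooly fibers"
        )
        surfaces = [m.surface for m in match_lexical(s, bg_lexicon)]
        assert surfaces == ["entopeduncular nucleus", "hypothalamus"]

    def test_no_lexicon_term(self, bg_lexicon):
        assert match_lexical(make_sentence("Nothing relevant here"), bg_lexicon) == []

    def test_longest_match_wins(self, bg_lexicon):
        s = make_sentence("the internal globus pallidus was targeted")
        (m,) = match_lexical(s, bg_lexicon)
        assert m.surface == "internal globus pallidus"
        assert m.region_id == "GPI"

    def test_equals_brute_force_oracle_on_random_instances(self):
        rng = random.Random(12345)
        for _ in range(300):
            sent, lex = random_instance(rng)
            got = [(m.start, m.end) for m in match_lexical(sent, lex)]
            assert got == oracle_spans(sent, lex), sent.text

    def test_mentions_never_overlap(self):
        rng = random.Random(99)
        for _ in range(100):
            sent, lex = random_instance(rng)
            ms = match_lexical(sent, lex)
            for a, b in zip(ms, ms[1:]):
                assert a.end <= b.start


class TestAbbreviations:
    def test_binding_carries_to_later_sentences(self, bg_lexicon):
        doc = Document(
            "d",
            "Neurons of the entopeduncular nucleus (ENT) were examined carefully. The ENT projects to the thalamus.",
        )
        per_sent = annotate_document(doc, bg_lexicon)
        second = per_sent[1][1]
        assert any(m.surface == "ENT" and m.region_id == "GPI" for m in second)

    def test_lowercase_parenthetical_not_bound(self, bg_lexicon):
        s = make_sentence("the hypothalamus (and) more text")
        reg = AbbreviationRegistry()
        register_abbreviations(s, match_lexical(s, bg_lexicon), reg)
        assert len(reg) == 0

    def test_document_local_binding_shadows_lexicon(self, bg_lexicon):
        # "SN" is a lexicon synonym of substantia nigra, but this document
        # redefines it as an abbreviation of the subthalamic nucleus
        doc = Document(
            "d",
            "We recorded the subthalamic nucleus (SN) in ten animals. The SN was active.",
        )
        per_sent = annotate_document(doc, bg_lexicon)
        (m,) = [m for m in per_sent[1][1] if m.surface == "SN"]
        assert m.region_id == "STN"


class TestMerge:
    def mk(self, start, end, source, rid=None):
        return Mention("d", 0, start, end, "x", rid, source)

    def test_disjoint_sorted(self):
        lx = [self.mk(0, 5, "lexical", "R1")]
        stat = [self.mk(10, 14, "statistical")]
        assert [m.start for m in merge_mentions(lx, stat)] == [0, 10]

    def test_identical_span_lexical_wins(self):
        lx = [self.mk(0, 5, "lexical", "R1")]
        stat = [self.mk(0, 5, "statistical")]
        (m,) = merge_mentions(lx, stat)
        assert m.source == "lexical"

    def test_containing_statistical_dropped(self):
        lx = [self.mk(3, 8, "lexical", "R1")]
        stat = [self.mk(0, 12, "statistical")]
        (m,) = merge_mentions(lx, stat)
        assert m.source == "lexical" and (m.start, m.end) == (3, 8)


@pytest.fixture(scope="module")
def trained():
    lex = toy_lexicon()
    data = generate_tagger_training(SimConfig(seed=11), lex, n_sentences=200)
    return lex, data, train_tagger(data, seed=11, lex=lex)


class TestTagger:
    def test_fit_capacity_on_training_set(self, trained):
        lex, data, model = trained
        tp = fp = fn = 0
        for sent, labs in data:
            pred = model.predict_labels(tokenize(sent), lex)
            for p, g in zip(pred, labs):
                if g != "O" and p == g:
                    tp += 1
                elif g == "O" and p != "O":
                    fp += 1
                elif g != "O" and p != g:
                    fn += 1
        assert 2 * tp / (2 * tp + fp + fn) >= 0.95

    def test_empty_training_set_errors(self):
        with pytest.raises(ValueError):
            train_tagger([], seed=0)

    def test_misaligned_labels_error(self):
        s = make_sentence("two tokens")
        with pytest.raises(ValueError, match="misalign"):
            train_tagger([(s, ["O"])], seed=0)

    def test_determinism(self, trained):
        lex, data, model = trained
        model2 = train_tagger(data, seed=11, lex=lex)
        held = generate_tagger_training(SimConfig(seed=77), lex, n_sentences=30)
        for sent, _ in held:
            toks = tokenize(sent)
            assert model.predict_labels(toks, lex) == model2.predict_labels(toks, lex)

    def test_generalizes_to_unseen_compound_name(self, trained):
        lex, _, model = trained
        text = "The contralateral prepositus hypoglossal nucleus projects to the medial tegmental nucleus."
        ms = tag_statistical(make_sentence(text), model, lex)
        assert any(m.surface == "contralateral prepositus hypoglossal nucleus" for m in ms)

    def test_decoded_spans_valid_and_disjoint(self, trained):
        lex, _, model = trained
        ms = tag_statistical(make_sentence("The alpha beta gamma was studied."), model, lex)
        for a, b in zip(ms, ms[1:]):
            assert a.end <= b.start
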