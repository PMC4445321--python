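import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from connmine.aggregate import ConnectivityDB, build_db, dedup, matrix, query_region, score
from connmine.relations import ConnectionMention


def cm(pair=("A", "B"), doc="d1", idx=0, extractor="FILTER", conf=0.45):
    a, b = sorted(pair)
    return ConnectionMention(
        region_a=a, region_b=b, doc_id=doc, sentence_index=idx,
        evidence_text="some sentence", extractor=extractor, confidence=conf,
    )


class TestDedup:
    def test_max_confidence_wins(self):
        items = [cm(extractor="FILTER", conf=0.45), cm(extractor="RULES", conf=0.72)]
        (kept,) = dedup(items)
        assert kept.extractor == "RULES"

    def test_tie_prefers_rules_over_kernel(self):
        items = [cm(extractor="KERNEL", conf=0.6), cm(extractor="RULES", conf=0.6)]
        (kept,) = dedup(items)
        assert kept.extractor == "RULES"

    def test_empty(self):
        assert dedup([]) == []

    def test_different_sentences_not_merged(self):
        items = [cm(idx=0), cm(idx=1), cm(doc="d2", idx=0)]
        assert len(dedup(items)) == 3


class TestScore:
    def test_empty_zero(self):
        assert score([]) == 0

    def test_two_rules_mentions(self):
        assert score([cm(idx=0, extractor="RULES", conf=0.72), cm(idx=1, extractor="RULES", conf=0.72)]) == 1

    def test_three_mixed(self):
        items = [
            cm(idx=0, extractor="RULES", conf=0.72),
            cm(idx=1, extractor="KERNEL", conf=0.60),
            cm(idx=2, extractor="FILTER", conf=0.45),
        ]
        assert score(items) == 2  # round(1.77)

    def test_mixed_pair_keys_error(self):
        with pytest.raises(ValueError):
            score([cm(("A", "B")), cm(("A", "C"), idx=1)])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.sampled_from([0.45, 0.60, 0.72]), max_size=30))
    def test_round_half_away_matches_direct_arithmetic(self, confs):
        items = [cm(idx=i, conf=c) for i, c in enumerate(confs)]
        total = sum(confs)
        assert score(items) == int(math.floor(total + 0.5))

    def test_monotone_under_adding_mentions(self):
        rng = random.Random(3)
        items = []
        prev = 0
        for i in range(40):
            items.append(cm(idx=i, conf=rng.choice([0.45, 0.6, 0.72])))
            s = score(items)
            assert s >= prev
            prev = s


class TestBuildDB:
    def test_single_mention(self, bg_lexicon):
        db = build_db([cm(("TH", "HY"))], bg_lexicon)
        ((key, rec),) = db.records.items()
        assert key == ("HY", "TH") and rec.n_mentions == 1

    def test_per_pair_counts(self, bg_lexicon):
        items = [
            cm(("TH", "HY"), doc="d1"),
            cm(("TH", "HY"), doc="d2"),
            cm(("TH", "STN"), doc="d3"),
        ]
        db = build_db(items, bg_lexicon)
        assert db.records[("HY", "TH")].n_mentions == 2
        assert db.records[("STN", "TH")].n_mentions == 1

    def test_conservation_of_mentions(self, bg_lexicon):
        rng = random.Random(8)
        pools = [("TH", "HY"), ("TH", "STN"), ("GPI", "STN")]
        items = [cm(rng.choice(pools), doc=f"d{rng.randint(0, 5)}", idx=rng.randint(0, 3)) for _ in range(60)]
        db = build_db(items, bg_lexicon)
        assert sum(r.n_mentions for r in db.records.values()) == len(dedup(items))
        for r in db.records.values():
            assert r.score <= r.n_mentions
            assert r.score >= int(math.floor(0.45 * r.n_mentions + 0.5))

    def test_unknown_region_errors(self, bg_lexicon):
        with pytest.raises(ValueError, match="NOPE"):
            build_db([cm(("NOPE", "TH"))], bg_lexicon)

    def test_export_round_trip_and_determinism(self, bg_lexicon, tmp_path):
        items = [cm(("TH", "HY"), doc="d1"), cm(("TH", "STN"), doc="d2", extractor="RULES", conf=0.72)]
        db = build_db(items, bg_lexicon)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        db.save(p1)
        build_db(items, bg_lexicon).save(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = ConnectivityDB.load(p1)
        assert back.to_dict() == db.to_dict()


class TestQueryAndMatrix:
    @pytest.fixture()
    def db(self, bg_lexicon):
        items = (
            [cm(("A", "TH"), doc=f"d{i}", extractor="RULES", conf=0.72) for i in range(4)]  # score 3
            + [cm(("A", "HY"), doc="x", extractor="KERNEL", conf=0.60)]  # score 1 (hypothalamus)
            + [cm(("A", "STN"), doc=f"e{i}", extractor="RULES", conf=0.72) for i in range(4)]  # score 3
        )
        return build_db(items, bg_lexicon)

    def test_region_with_no_records(self, bg_lexicon, db):
        assert query_region(db, "CBN", bg_lexicon) == []

    def test_rank_and_name_tie_break(self, bg_lexicon, db):
        got = query_region(db, "A", bg_lexicon)
        # TH and STN tie at score 3: "subthalamic nucleus" < "thalamus"
        assert got == [("STN", 3), ("TH", 3), ("HY", 1)]

    def test_unknown_region_errors(self, bg_lexicon, db):
        with pytest.raises(KeyError):
            query_region(db, "NOPE", bg_lexicon)

    def test_matrix_symmetric_zero_diagonal(self, db):
        m = matrix(db, top_n=4)
        assert (m.values == m.values.T).all()
        assert all(m.loc[r, r] == 0 for r in m.index)

    def test_matrix_topn_larger_than_regions(self, db):
        m = matrix(db, top_n=100)
        assert set(m.index) == {"A", "TH", "STN", "HY"}

    def test_empty_db_empty_matrix(self):
        assert matrix(ConnectivityDB(records={}), top_n=3).empty
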