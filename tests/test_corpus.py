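"""Corpus reading, cleaning, filtering and quartile behavior."""

import json

import numpy as np
import pandas as pd
import pytest

from stylesalience.corpus import (
    CleaningRules,
    CorpusFormatError,
    LabelValidationError,
    clean_corpus,
    export_features,
    filter_min_words,
    read_corpus,
    word_count_quartile,
    write_corpus,
)
from .conftest import make_corpus

RECORDS = [
    {"post_id": "p1", "user_id": "u1", "label": "A", "platform": "x", "text": "hello there friend"},
    {"post_id": "p2", "user_id": "u1", "label": "B", "platform": "x", "text": "more words here now"},
    {"post_id": "p3", "user_id": "u2", "label": "A", "platform": "x", "text": "yet another post"},
    {"post_id": "p4", "user_id": "u3", "label": "B", "platform": "x", "text": "short one"},
    {"post_id": "p5", "user_id": "u4", "label": "A", "platform": "x", "text": "final message text"},
]


def _write_jsonl(path, records):
    path.write_text("\n".join(json.dumps(r) for r in records), encoding="utf-8")


def _write_csv(path, records):
    pd.DataFrame.from_records(records).to_csv(path, index=False)


class TestReadCorpus:
    def test_reads_jsonl(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, RECORDS[:3])
        corpus = read_corpus(p, label_set=("A", "B"))
        assert len(corpus) == 3
        assert list(corpus.posts["post_id"]) == ["p1", "p2", "p3"]
        assert list(corpus.posts["word_count"]) == [3, 4, 3]

    def test_csv_and_jsonl_agree(self, tmp_path):
        pj, pc = tmp_path / "c.jsonl", tmp_path / "c.csv"
        _write_jsonl(pj, RECORDS)
        _write_csv(pc, RECORDS)
        a = read_corpus(pj, label_set=("A", "B")).posts
        b = read_corpus(pc, label_set=("A", "B")).posts
        cols = ["post_id", "user_id", "label", "text", "word_count"]
        pd.testing.assert_frame_equal(a[cols], b[cols])

    def test_unknown_label_named_in_error(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, RECORDS + [dict(RECORDS[0], post_id="p9", label="C")])
        with pytest.raises(LabelValidationError, match="C"):
            read_corpus(p, label_set=("A", "B"))

    def test_malformed_jsonl_names_line(self, tmp_path):
        p = tmp_path / "c.jsonl"
        p.write_text(json.dumps(RECORDS[0]) + "\n{not json\n", encoding="utf-8")
        with pytest.raises(CorpusFormatError, match="line 2"):
            read_corpus(p, label_set=("A", "B"))

    def test_missing_text_rejected_and_reported(self, tmp_path):
        p = tmp_path / "c.jsonl"
        _write_jsonl(p, RECORDS + [{"post_id": "p9", "user_id": "u9", "label": "A", "text": None}])
        corpus = read_corpus(p, label_set=("A", "B"))
        assert len(corpus) == 5
        assert corpus.provenance["rejected_missing_text"] == 1

    def test_duplicate_post_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_corpus([("p1", "u1", "A", "one two"), ("p1", "u2", "B", "three four")])

    def test_round_trip_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        _write_jsonl(p1, RECORDS)
        c1 = read_corpus(p1, label_set=("A", "B"))
        write_corpus(c1, p2)
        c2 = read_corpus(p2, label_set=("A", "B"))
        cols = ["post_id", "user_id", "label", "text", "word_count"]
        pd.testing.assert_frame_equal(c1.posts[cols], c2.posts[cols])


class TestCleaning:
    RULES = CleaningRules(
        admin_message_patterns=("message withdrawn", "message deleted.*"),
        bot_author_patterns=(r"bot$",),
        drop_wordless=True,
    )

    def test_admin_message_removed(self):
        corpus = make_corpus(
            [("p1", "u1", "A", "Message withdrawn"), ("p2", "u2", "B", "a real post here")]
        )
        cleaned, report = clean_corpus(corpus, self.RULES)
        assert list(cleaned.posts["post_id"]) == ["p2"]
        assert report.n_admin_removed == 1

    def test_admin_quote_mid_text_survives(self):
        corpus = make_corpus([("p1", "u1", "A", "they said Message withdrawn to me")])
        cleaned, _ = clean_corpus(corpus, self.RULES)
        assert len(cleaned) == 1

    def test_emoji_only_post_removed(self):
        corpus = make_corpus([("p1", "u1", "A", "\U0001F44D"), ("p2", "u2", "B", "words here")])
        cleaned, report = clean_corpus(corpus, self.RULES)
        assert report.n_wordless_removed == 1
        assert list(cleaned.posts["post_id"]) == ["p2"]

    def test_bot_author_removed(self):
        corpus = make_corpus([("p1", "helperbot", "A", "beep boop words"), ("p2", "u2", "B", "hi all")])
        cleaned, report = clean_corpus(corpus, self.RULES)
        assert report.n_bot_removed == 1
        assert list(cleaned.posts["user_id"]) == ["u2"]

    def test_empty_rules_identity(self):
        corpus = make_corpus([("p1", "u1", "A", "anything at all")])
        rules = CleaningRules(drop_wordless=False)
        cleaned, report = clean_corpus(corpus, rules)
        pd.testing.assert_frame_equal(cleaned.posts, corpus.posts)
        assert report.n_output == report.n_input

    def test_cleaning_is_idempotent(self):
        corpus = make_corpus(
            [
                ("p1", "u1", "A", "Message withdrawn"),
                ("p2", "spambot", "B", "posted by a bot"),
                ("p3", "u3", "A", "??!"),
                ("p4", "u4", "B", "genuine words in here"),
            ]
        )
        once, _ = clean_corpus(corpus, self.RULES)
        twice, report = clean_corpus(once, self.RULES)
        pd.testing.assert_frame_equal(once.posts, twice.posts)
        assert report.n_input == report.n_output


class TestFiltering:
    def _length_corpus(self, lengths, label_cycle=("A", "B")):
        rows = []
        for i, n in enumerate(lengths):
            rows.append((f"p{i}", f"u{i}", label_cycle[i % 2], " ".join(["word"] * n)))
        return make_corpus(rows)

    def test_cutoff_retains_at_or_above(self):
        corpus = self._length_corpus([10, 24, 25, 40])
        kept = filter_min_words(corpus, 25)
        assert sorted(kept.posts["word_count"]) == [25, 40]

    def test_min_one_is_identity_on_clean_corpus(self):
        corpus = self._length_corpus([3, 7, 12])
        pd.testing.assert_frame_equal(filter_min_words(corpus, 1).posts, corpus.posts)

    def test_monotone_in_cutoff(self):
        corpus = self._length_corpus(list(range(1, 60)))
        k1 = set(filter_min_words(corpus, 10).posts["post_id"])
        k2 = set(filter_min_words(corpus, 30).posts["post_id"])
        assert k2 <= k1

    def test_quartile_cutoff_keeps_75_percent(self):
        corpus = self._length_corpus(list(range(1, 101)))
        q1 = word_count_quartile(corpus)
        kept = filter_min_words(corpus, q1)
        assert len(kept) == 75


class TestQuartile:
    def test_uniform_1_to_100(self):
        corpus = TestFiltering()._length_corpus(list(range(1, 101)))
        # median-unbiased (Hyndman-Fan 8): h = (n + 1/3)p + 1/3 = 25.417
        assert word_count_quartile(corpus) == pytest.approx(25.4167, abs=1e-3)

    def test_constant_lengths(self):
        corpus = TestFiltering()._length_corpus([30, 30, 30, 30])
        assert word_count_quartile(corpus) == 30

    def test_four_values_between_first_two(self):
        corpus = TestFiltering()._length_corpus([10, 20, 30, 40])
        q1 = word_count_quartile(corpus)
        assert 10 <= q1 <= 20
        # brute-force: every numpy quantile convention stays in [10, 20]
        data = np.array([10, 20, 30, 40])
        for method in (
            "inverted_cdf", "averaged_inverted_cdf", "closest_observation",
            "interpolated_inverted_cdf", "hazen", "weibull", "linear",
            "median_unbiased", "normal_unbiased",
        ):
            assert 10 <= np.percentile(data, 25, method=method) <= 20

    def test_empty_corpus_errors(self):
        corpus = TestFiltering()._length_corpus([5])
        with pytest.raises(ValueError):
            word_count_quartile(corpus.subset(corpus.posts["word_count"] > 99))


class TestExport:
    def test_export_drops_text_and_user_ids(self, tmp_path):
        corpus = make_corpus([("p1", "alice", "A", "i love this"), ("p2", "bob", "B", "not so much here")])
        out = export_features(corpus, tmp_path / "f.csv")
        assert "text" not in out.columns
        assert "user_id" not in out.columns
        assert set(out["user_hash"]) != {"alice", "bob"}
        assert out.shape[0] == 2 and {"posemo", "wps", "exclam"} <= set(out.columns)

    def test_export_text_requires_flag(self, tmp_path):
        corpus = make_corpus([("p1", "alice", "A", "i love this")])
        out = export_features(corpus, tmp_path / "f.csv", include_text=True)
        assert "text" in out.columns
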