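"""Shared fixtures: tiny hand-built corpora and a session-scoped synthetic
study corpus + trained ensemble reused across evaluation tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from stylesalience.corpus import Corpus
from stylesalience.features import CategoryDictionary
from stylesalience.model import TrainingConfig, train
from stylesalience.schema import WORD_CATEGORIES
from stylesalience.synthetic import generate_scenario


def make_dictionary(**overrides) -> CategoryDictionary:
    """A dictionary with every canonical category present (empty unless
    overridden) — convenient for hand-count tests."""
    categories = {cat: [] for cat in WORD_CATEGORIES}
    categories.update(overrides)
    return CategoryDictionary(categories)


def make_corpus(rows, label_set=("A", "B")) -> Corpus:
    """Build a corpus from (post_id, user_id, label, text) tuples or dicts."""
    records = []
    for row in rows:
        if isinstance(row, dict):
            rec = dict(row)
        else:
            rec = dict(zip(("post_id", "user_id", "label", "text"), row))
        rec.setdefault("platform", "test")
        rec.setdefault("timestamp", pd.NaT)
        records.append(rec)
    return Corpus(posts=pd.DataFrame.from_records(records), label_set=label_set)


@pytest.fixture(scope="session")
def study1():
    """Two-forum synthetic corpus with the default identity contrast,
    plus its extracted features."""
    corpus, truth = generate_scenario("study1_between", seed=101)
    features = corpus.features()
    return corpus, truth, features


@pytest.fixture(scope="session")
def study1_model(study1):
    corpus, _, features = study1
    cfg = TrainingConfig(
        positive_label="feminist", n_subsets=10, subset_size=5000,
        min_words=25, seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train(corpus, cfg, features=features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
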