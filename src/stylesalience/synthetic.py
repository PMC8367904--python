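"""Synthetic forum corpora with controlled stylistic structure.

The generator emits real token streams (not feature vectors), so
tokenisation, dictionary matching, cleaning and cutoff logic are all
exercised end to end. Each post's words are drawn from a deterministic
pseudo-word vocabulary whose words are tagged with canonical style
categories; per-token emission logits combine

* a base rate per category,
* an identity effect (log-odds shift, signed toward the post's salient
  identity) — the signal the classifier should learn,
* a stable per-user random effect — the trait confound the
  within-participant design controls for,
* an optional platform shift, and
* an optional per-period drift multiplier on the identity effect for a
  tagged user subgroup (the longitudinal scenario).

Sentence lengths and terminator choice are also configurable so the
``wps`` and ``exclam`` features can carry signal. Ground truth (salient
identity per post, user effects, groups, anchors) is returned alongside
the corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .corpus import UNLABELED, Corpus
from .features import CategoryDictionary
from .schema import WORD_CATEGORIES

_VOWELS = "aeiou"
_CONSONANTS = "bdfgklmnprstvz"
_LEXICON_SEED = 424242
_WORDS_PER_CATEGORY = 40
_N_FILLER = 800
_SECOND_CATEGORY_RATE = 0.15


def _pseudo_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < n:
        n_syll = int(rng.integers(2, 5))
        w = "".join(
            _CONSONANTS[rng.integers(len(_CONSONANTS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syll)
        )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def _build_lexicon() -> tuple[dict[str, list[str]], list[str]]:
    """Deterministic synthetic vocabulary: ~1,240 category words (15%
    carrying a second category) plus ~800 category-free filler words."""
    rng = np.random.default_rng(_LEXICON_SEED)
    taken: set[str] = set()
    categories = {
        cat: _pseudo_words(rng, _WORDS_PER_CATEGORY, taken) for cat in WORD_CATEGORIES
    }
    # give a fraction of words a second category, as real dictionaries do
    cats = list(WORD_CATEGORIES)
    for cat in cats:
        for w in categories[cat]:
            if rng.random() < _SECOND_CATEGORY_RATE:
                other = cats[rng.integers(len(cats))]
                if other != cat and w not in categories[other]:
                    categories[other].append(w)
    filler = _pseudo_words(rng, _N_FILLER, taken)
    return categories, filler


_LEXICON_CACHE: tuple[dict[str, list[str]], list[str]] | None = None


def synthetic_lexicon() -> tuple[dict[str, list[str]], list[str]]:
    global _LEXICON_CACHE
    if _LEXICON_CACHE is None:
        _LEXICON_CACHE = _build_lexicon()
    return _LEXICON_CACHE


def synthetic_dictionary() -> CategoryDictionary:
    """CategoryDictionary matching the synthetic vocabulary."""
    categories, _ = synthetic_lexicon()
    return CategoryDictionary(categories, schema_version="stylesalience-44/synthetic")


#: The informal-vs-intellectual contrast injected by default: negative
#: shifts make a category more frequent when the first (e.g. parent)
#: identity is salient, positive shifts favour the second (e.g. feminist).
DEFAULT_IDENTITY_EFFECT: dict[str, float] = {
    "posemo": -0.8,
    "incl": -0.8,
    "nonflu": -0.8,
    "assent": -0.8,
    "shehe": -0.8,
    "negemo": 0.8,
    "article": 0.8,
    "cause": 0.8,
    "insight": 0.8,
    "swear": 0.8,
    "exclam": -0.8,
    "wps": 3.0,
}


@dataclass
class SyntheticConfig:
    """Study conditions for a generated corpus.

    ``identity_effect`` maps categories (plus the specials ``exclam`` and
    ``wps``) to log-odds shifts, signed toward ``labels[1]``; each post
    receives half the shift in the direction of its salient identity.
    ``confound_effect`` is applied as a *user-level* stable trait aligned
    with the home forum of single-membership users (the confound the
    within-participant design neutralises). ``platform_shift`` perturbs
    every post. Drift fields switch generation to the longitudinal
    scenario. ``seed`` fully determines the output.
    """

    labels: tuple[str, str] = ("parent", "feminist")
    platform: str = "synthetic"
    seed: int = 0
    # population
    n_users_a: int = 650
    n_users_b: int = 450
    n_dual_users: int = 160
    posts_per_user_mean: float = 7.0      # per forum; counts are 1 + Poisson(mean - 1)
    # post shape
    length_median: float = 40.0
    length_sigma: float = 0.6
    length_min: int = 3
    wps_mean: float = 12.0
    wps_sd: float = 4.0
    exclam_base_logit: float = -1.75      # P(! terminator) ~ 0.15 at baseline
    qmark_prob: float = 0.05
    # emission structure
    base_category_logit: float = -3.4
    base_logit_overrides: dict[str, float] = field(default_factory=dict)
    identity_effect: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IDENTITY_EFFECT)
    )
    user_effect_sd: float = 0.4
    confound_effect: dict[str, float] = field(default_factory=dict)
    platform_shift: dict[str, float] = field(default_factory=dict)
    # additive perturbation of the identity *contrast* itself: venues
    # express the same identities somewhat differently, which (unlike a
    # class-symmetric base-rate shift) genuinely degrades rank-based AUC
    platform_effect_shift: dict[str, float] = field(default_factory=dict)
    # experimental scenario (one document per topic per user)
    topics: tuple[str, ...] | None = None
    n_experiment_users: int = 43
    experiment_length_median: float = 80.0
    # longitudinal drift scenario
    drift_multipliers: tuple[float, ...] | None = None   # tagged group, per period
    drift_group: str = "pnd"
    n_drift_users: int = 25
    n_control_users: int = 60
    n_periods: int = 4
    posts_per_period_mean: float = 4.0
    anchor_year: int = 2019

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 2:
            raise ValueError("labels must be two distinct identities")
        if self.length_median < self.length_min:
            raise ValueError("length_median must be >= length_min")
        if self.user_effect_sd < 0:
            raise ValueError("user_effect_sd must be >= 0")
        if self.posts_per_user_mean < 1:
            raise ValueError("posts_per_user_mean must be >= 1")


@dataclass
class GroundTruth:
    """Injected effects behind a generated corpus."""

    identity_effect: dict[str, float]
    post_salience: list[str]
    user_effects: dict[str, np.ndarray]
    groups: dict[str, str] = field(default_factory=dict)
    anchors: dict[str, str] = field(default_factory=dict)
    config: SyntheticConfig | None = None

    def save(self, path: str | Path) -> None:
        data = {
            "identity_effect": self.identity_effect,
            "post_salience": self.post_salience,
            "user_effects": {u: v.tolist() for u, v in self.user_effects.items()},
            "groups": self.groups,
            "anchors": self.anchors,
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(data), encoding="utf-8")


def emission_probabilities(
    config: SyntheticConfig,
    salient: str | None = None,
    multiplier: float = 1.0,
) -> dict[str, float]:
    """Expected per-token category probabilities (including ``filler``)
    for a post with the given salient identity and no user effect."""
    logits = _category_logits(config, salient, multiplier, user=None)
    weights = np.exp(np.append(logits, 0.0))
    p = weights / weights.sum()
    out = {cat: float(p[i]) for i, cat in enumerate(WORD_CATEGORIES)}
    out["filler"] = float(p[-1])
    return out


def _effect_vector(effect: Mapping[str, float]) -> np.ndarray:
    vec = np.zeros(len(WORD_CATEGORIES))
    for cat, delta in effect.items():
        if cat in ("exclam", "wps"):
            continue
        if cat not in WORD_CATEGORIES:
            raise ValueError(f"unknown category {cat!r} in effect specification")
        vec[WORD_CATEGORIES.index(cat)] = delta
    return vec


def _category_logits(
    config: SyntheticConfig,
    salient: str | None,
    multiplier: float,
    user: np.ndarray | None,
) -> np.ndarray:
    logits = np.full(len(WORD_CATEGORIES), config.base_category_logit)
    for cat, v in config.base_logit_overrides.items():
        logits[WORD_CATEGORIES.index(cat)] = v
    if salient is not None:
        sign = 1.0 if salient == config.labels[1] else -1.0
        effect = _effect_vector(config.identity_effect) + _effect_vector(
            config.platform_effect_shift
        )
        logits += sign * multiplier * 0.5 * effect
    logits += _effect_vector(config.platform_shift)
    if user is not None:
        logits += user
    return logits


class _Emitter:
    """Stateful token emitter bound to one config."""

    def __init__(self, config: SyntheticConfig) -> None:
        categories, filler = synthetic_lexicon()
        self.config = config
        self.pools = [np.array(categories[cat], dtype=object) for cat in WORD_CATEGORIES]
        self.filler = np.array(filler, dtype=object)

    def post_text(
        self,
        rng: np.random.Generator,
        salient: str | None,
        user: np.ndarray | None,
        multiplier: float = 1.0,
        n_words: int | None = None,
    ) -> str:
        cfg = self.config
        if n_words is None:
            n_words = max(
                cfg.length_min,
                int(round(rng.lognormal(np.log(cfg.length_median), cfg.length_sigma))),
            )
        logits = _category_logits(cfg, salient, multiplier, user)
        weights = np.exp(np.append(logits, 0.0))
        counts = rng.multinomial(n_words, weights / weights.sum())

        chunks = [
            rng.choice(self.pools[c], size=k) for c, k in enumerate(counts[:-1]) if k
        ]
        if counts[-1]:
            chunks.append(rng.choice(self.filler, size=counts[-1]))
        words = np.concatenate(chunks)
        rng.shuffle(words)

        sign = 0.0
        if salient is not None:
            sign = 1.0 if salient == cfg.labels[1] else -1.0
        exclam_effect = cfg.identity_effect.get("exclam", 0.0) + cfg.platform_effect_shift.get("exclam", 0.0)
        wps_effect = cfg.identity_effect.get("wps", 0.0) + cfg.platform_effect_shift.get("wps", 0.0)
        exclam_logit = (
            cfg.exclam_base_logit
            + sign * multiplier * 0.5 * exclam_effect
            + cfg.platform_shift.get("exclam", 0.0)
        )
        wps_mu = (
            cfg.wps_mean
            + sign * multiplier * 0.5 * wps_effect
            + cfg.platform_shift.get("wps", 0.0)
        )
        p_exclam = float(expit(exclam_logit))

        parts, i = [], 0
        while i < n_words:
            n_sent = max(1, int(round(rng.normal(wps_mu, cfg.wps_sd))))
            chunk = words[i : i + n_sent]
            i += n_sent
            u = rng.random()
            term = "!" if u < p_exclam else ("?" if u < p_exclam + cfg.qmark_prob else ".")
            parts.append(" ".join(chunk) + term)
        return " ".join(parts)


def _user_effect(
    rng: np.random.Generator, config: SyntheticConfig, home: str | None
) -> np.ndarray:
    eff = rng.normal(0.0, config.user_effect_sd, size=len(WORD_CATEGORIES))
    if home is not None and config.confound_effect:
        sign = 1.0 if home == config.labels[1] else -1.0
        eff = eff + sign * 0.5 * _effect_vector(config.confound_effect)
    return eff


def generate(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    """Generate a corpus under the configured study conditions.

    Dispatches on the config shape: drift multipliers produce the
    longitudinal scenario, topics produce the experimental scenario,
    otherwise a two-forum corpus with partial dual membership is produced.
    """
    if config.drift_multipliers is not None:
        return _generate_longitudinal(config)
    if config.topics is not None:
        return _generate_experiment(config)
    return _generate_forums(config)


def _generate_forums(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    emitter = _Emitter(config)
    label_a, label_b = config.labels

    users: list[tuple[str, str | None, list[str]]] = []   # (user_id, home, forums)
    for i in range(config.n_users_a):
        users.append((f"ua{i:05d}", label_a, [label_a]))
    for i in range(config.n_users_b):
        users.append((f"ub{i:05d}", label_b, [label_b]))
    for i in range(config.n_dual_users):
        users.append((f"ud{i:05d}", None, [label_a, label_b]))

    records, salience, user_effects = [], [], {}
    pid = 0
    for user_id, home, forums in users:
        ueff = _user_effect(rng, config, home)
        user_effects[user_id] = ueff
        for forum in forums:
            n_posts = 1 + rng.poisson(max(config.posts_per_user_mean - 1, 0.0))
            for _ in range(n_posts):
                text = emitter.post_text(rng, salient=forum, user=ueff)
                records.append(
                    {
                        "post_id": f"p{pid:07d}",
                        "user_id": user_id,
                        "label": forum,
                        "platform": config.platform,
                        "timestamp": pd.NaT,
                        "text": text,
                    }
                )
                salience.append(forum)
                pid += 1

    corpus = Corpus(
        posts=pd.DataFrame.from_records(records),
        label_set=config.labels,
        provenance={"generator": "synthetic-forums", "seed": config.seed, "dictionary": "synthetic"},
    )
    truth = GroundTruth(
        identity_effect=dict(config.identity_effect),
        post_salience=salience,
        user_effects=user_effects,
        config=config,
    )
    return corpus, truth


def _generate_experiment(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    emitter = _Emitter(config)
    n = config.n_experiment_users
    conditions = np.array(
        [config.labels[0]] * (n // 2) + [config.labels[1]] * (n - n // 2), dtype=object
    )
    rng.shuffle(conditions)

    records, salience, user_effects = [], [], {}
    pid = 0
    for i in range(n):
        user_id = f"ux{i:04d}"
        ueff = _user_effect(rng, config, home=None)
        user_effects[user_id] = ueff
        cond = str(conditions[i])
        for topic in config.topics or ():
            n_words = max(
                25,
                int(round(rng.lognormal(np.log(config.experiment_length_median), 0.3))),
            )
            text = emitter.post_text(rng, salient=cond, user=ueff, n_words=n_words)
            records.append(
                {
                    "post_id": f"e{pid:05d}",
                    "user_id": user_id,
                    "label": cond,
                    "platform": "experiment",
                    "timestamp": pd.NaT,
                    "text": text,
                    "topic": topic,
                }
            )
            salience.append(cond)
            pid += 1

    corpus = Corpus(
        posts=pd.DataFrame.from_records(records),
        label_set=config.labels,
        provenance={"generator": "synthetic-experiment", "seed": config.seed, "dictionary": "synthetic"},
    )
    truth = GroundTruth(
        identity_effect=dict(config.identity_effect),
        post_salience=salience,
        user_effects=user_effects,
        config=config,
    )
    return corpus, truth


def _generate_longitudinal(config: SyntheticConfig) -> tuple[Corpus, GroundTruth]:
    rng = np.random.default_rng(config.seed)
    emitter = _Emitter(config)
    label_a = config.labels[0]
    multipliers = tuple(config.drift_multipliers or ())
    if len(multipliers) != config.n_periods:
        raise ValueError("drift_multipliers must have one entry per period")

    records, salience = [], []
    user_effects, groups, anchors = {}, {}, {}
    pid = 0
    n_total = config.n_drift_users + config.n_control_users
    for i in range(n_total):
        tagged = i < config.n_drift_users
        user_id = f"{'up' if tagged else 'un'}{i:04d}"
        groups[user_id] = config.drift_group if tagged else "control"
        ueff = _user_effect(rng, config, home=None)
        user_effects[user_id] = ueff
        anchor_month = int(rng.integers(1, 13))
        anchors[user_id] = f"{config.anchor_year}-{anchor_month:02d}-15"
        for period in range(1, config.n_periods + 1):
            mult = multipliers[period - 1] if tagged else 1.0
            n_posts = 1 + rng.poisson(max(config.posts_per_period_mean - 1, 0.0))
            month = anchor_month + period - 1
            year = config.anchor_year + (month - 1) // 12
            month = (month - 1) % 12 + 1
            for _ in range(n_posts):
                day = int(rng.integers(1, 28))
                text = emitter.post_text(rng, salient=label_a, user=ueff, multiplier=mult)
                records.append(
                    {
                        "post_id": f"t{pid:06d}",
                        "user_id": user_id,
                        "label": UNLABELED,
                        "platform": config.platform,
                        "timestamp": pd.Timestamp(year=year, month=month, day=day),
                        "text": text,
                    }
                )
                salience.append(label_a)
                pid += 1

    corpus = Corpus(
        posts=pd.DataFrame.from_records(records),
        label_set=config.labels,
        provenance={"generator": "synthetic-longitudinal", "seed": config.seed, "dictionary": "synthetic"},
    )
    truth = GroundTruth(
        identity_effect=dict(config.identity_effect),
        post_salience=salience,
        user_effects=user_effects,
        groups=groups,
        anchors=anchors,
        config=config,
    )
    return corpus, truth


def scenario_library() -> dict[str, SyntheticConfig]:
    """Named presets mirroring the protocol's study designs."""
    base = SyntheticConfig()
    return {
        # two forums, partial dual membership, informal-vs-intellectual signal
        "study1_between": base,
        # no identity signal at all: the permutation/chance baseline
        "null": replace(base, identity_effect={}),
        # zero identity effect but strong stable user traits aligned with
        # forum membership: between-user evaluation looks good, the
        # within-participant design exposes the confound
        "study2_confounded": replace(
            base,
            identity_effect={},
            confound_effect={
                "posemo": -1.2, "incl": -1.2, "nonflu": -1.2, "assent": -1.2,
                "shehe": -1.2, "negemo": 1.2, "article": 1.2, "cause": 1.2,
                "insight": 1.2, "swear": 1.2,
            },
            n_users_a=400,
            n_users_b=400,
            n_dual_users=150,
            posts_per_user_mean=4.0,
        ),
        # identity signal intact overall, but the venue expresses the
        # contrast differently on half the signal categories (dampened
        # contrast), shifts some base rates, and hosts shorter posts — the
        # mechanisms that make classifiers travel imperfectly across venues
        "study3_platform": replace(
            base,
            platform="platform_b",
            platform_effect_shift={
                "posemo": 0.5, "article": -0.5, "insight": -0.5,
                "nonflu": 0.5, "swear": -0.5, "exclam": 0.5,
            },
            platform_shift={"adverb": 0.5, "time": -0.5},
            length_median=28.0,
            n_users_a=250,
            n_users_b=250,
            n_dual_users=200,
            posts_per_user_mean=4.0,
        ),
        # 43 dual-identity participants, 3 topics, salience manipulated
        # between subjects; style signal is topic-independent by construction
        "study4_experiment": replace(
            base,
            topics=("climate", "objectification", "mealtimes"),
            n_experiment_users=43,
        ),
        # two groups over four monthly periods; the tagged group's identity
        # effect declines after period 1, the control group's stays flat
        "study5_drift": replace(
            base,
            drift_multipliers=(1.0, 0.75, 0.5, 0.25),
            n_drift_users=25,
            n_control_users=60,
            n_periods=4,
            posts_per_period_mean=4.0,
        ),
    }


def generate_scenario(name: str, seed: int = 0) -> tuple[Corpus, GroundTruth]:
    presets = scenario_library()
    if name not in presets:
        raise KeyError(f"unknown scenario {name!r}; available: {sorted(presets)}")
    return generate(replace(presets[name], seed=seed))
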