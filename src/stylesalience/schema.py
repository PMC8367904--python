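"""Canonical 44-feature style schema.

The schema covers three kinds of features:

* structural: words per sentence (``wps``) and the share of long words
  (``sixltr``, words of six or more letters);
* closed-vocabulary word categories, counted against a dictionary of
  lowercase word patterns and expressed as percent of words;
* punctuation classes, counted per character and expressed as percent of
  words (they may exceed 100 for punctuation-heavy text).

Topical categories (family, work, money, ...) are deliberately absent: the
classifiers built on this schema are meant to pick up *how* a text is
written, not what it is about.
"""

from __future__ import annotations

#: Structural features (not dictionary-counted).
STRUCTURAL_FEATURES: tuple[str, ...] = ("wps", "sixltr")

#: Dictionary-counted word categories, percent-of-words units.
WORD_CATEGORIES: tuple[str, ...] = (
    "funct",     # function words (umbrella)
    "i",         # first person singular
    "we",        # first person plural
    "you",       # second person
    "shehe",     # third person singular
    "they",      # third person plural
    "ipron",     # impersonal pronouns
    "article",
    "preps",     # prepositions
    "auxverb",   # auxiliary verbs
    "adverb",
    "conj",      # conjunctions
    "verb",      # common verbs
    "past",
    "present",
    "future",
    "quant",     # quantifiers
    "number",
    "time",
    "posemo",    # positive emotion
    "negemo",    # negative emotion
    "swear",
    "negation",
    "assent",
    "insight",
    "cause",     # causation
    "discrep",   # discrepancy (should/would/could)
    "tentat",    # tentative
    "incl",      # inclusive
    "excl",      # exclusive
    "nonflu",    # non-fluencies (er, um, hmm)
)

#: Punctuation classes, percent-of-words units.
PUNCTUATION_FEATURES: tuple[str, ...] = (
    "period",
    "comma",
    "colon",
    "semic",
    "qmark",
    "exclam",
    "dash",
    "quote",
    "apostro",
    "parenth",
    "otherp",
)

#: Full canonical feature order. Exactly 44 entries.
FEATURE_NAMES: tuple[str, ...] = (
    STRUCTURAL_FEATURES + WORD_CATEGORIES + PUNCTUATION_FEATURES
)

N_FEATURES: int = len(FEATURE_NAMES)
assert N_FEATURES == 44

#: Topical category names that the default schema refuses to include.
KNOWN_TOPICAL_CATEGORIES: frozenset[str] = frozenset(
    {
        "family", "friend", "friends", "work", "money", "leisure", "home",
        "relig", "death", "health", "body", "sexual", "achieve", "school",
    }
)

SCHEMA_VERSION = "stylesalience-44/1.0"
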