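"""Tokenisation and closed-vocabulary style-feature extraction.

Every document is mapped to the 44-dimensional canonical style vector of
:mod:`stylesalience.schema`: word-category rates (percent of words),
punctuation rates (percent of words), the share of long words (``sixltr``)
and mean sentence length (``wps``). Word matching is dictionary-based and
case-insensitive; a word may count toward several categories.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    FEATURE_NAMES,
    KNOWN_TOPICAL_CATEGORIES,
    N_FEATURES,
    PUNCTUATION_FEATURES,
    SCHEMA_VERSION,
    WORD_CATEGORIES,
)


class SchemaError(ValueError):
    """An external feature table does not conform to the canonical schema."""


# Words are maximal alphabetic runs, optionally joined by internal
# apostrophes ("don't" is one word). Digits and underscores never join.
_WORD_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*")
_SENTENCE_RE = re.compile(r"[.!?…]+")

_PUNCT_CLASS = {
    ".": "period", "…": "period",
    ",": "comma",
    ":": "colon",
    ";": "semic",
    "?": "qmark",
    "!": "exclam",
    "-": "dash", "–": "dash", "—": "dash",
    '"': "quote", "“": "quote", "”": "quote", "`": "quote",
    "'": "apostro", "’": "apostro", "‘": "apostro",
    "(": "parenth", ")": "parenth", "[": "parenth", "]": "parenth",
}


@dataclass(frozen=True)
class TokenizedText:
    words: tuple[str, ...]
    sentence_count: int
    punct_counts: dict[str, int]

    @property
    def word_count(self) -> int:
        return len(self.words)


def tokenize(text: str) -> TokenizedText:
    """Split ``text`` into lowercase word tokens, sentences and punctuation.

    Sentences are delimited by runs of terminators (``. ! ? …``); any text
    containing at least one word counts as at least one sentence. Single
    quotes always tally as apostrophes. Punctuation characters outside the
    named classes fall into ``otherp``; non-punctuation symbols (emoji,
    currency signs) are ignored.
    """
    lowered = text.replace("’", "'").lower()
    words = tuple(_WORD_RE.findall(lowered))
    sentences = len(_SENTENCE_RE.findall(text))
    if words and sentences == 0:
        sentences = 1

    punct = {name: 0 for name in PUNCTUATION_FEATURES}
    for ch in text:
        cls = _PUNCT_CLASS.get(ch)
        if cls is None and unicodedata.category(ch).startswith("P"):
            cls = "otherp"
        if cls is not None:
            punct[cls] += 1
    return TokenizedText(words=words, sentence_count=sentences, punct_counts=punct)


class CategoryDictionary:
    """Closed-vocabulary dictionary mapping lowercase patterns to categories.

    Patterns are literal words or trailing-``*`` prefix wildcards. The
    dictionary must resolve every canonical word category; topical
    categories (family, work, money, ...) are rejected unless
    ``allow_topical=True`` — the schema is style-only by design.
    """

    def __init__(
        self,
        categories: Mapping[str, Sequence[str]],
        schema_version: str = SCHEMA_VERSION,
        allow_topical: bool = False,
    ) -> None:
        canonical = set(WORD_CATEGORIES)
        topical_present = sorted(set(categories) & KNOWN_TOPICAL_CATEGORIES)
        if topical_present and not allow_topical:
            raise ValueError(
                "topical categories are excluded from the style schema "
                f"(got {topical_present}); pass allow_topical=True to override"
            )
        unknown = sorted(
            set(categories) - canonical - KNOWN_TOPICAL_CATEGORIES
        )
        if unknown:
            raise ValueError(f"unknown categories: {unknown}")
        missing = sorted(canonical - set(categories))
        if missing:
            raise ValueError(f"dictionary must cover all word categories; missing {missing}")

        self.schema_version = schema_version
        self.categories: dict[str, tuple[str, ...]] = {}
        self._exact: dict[str, list[str]] = {}
        self._prefixes: list[tuple[str, str]] = []
        for cat, patterns in categories.items():
            seen: set[str] = set()
            for pat in patterns:
                if pat != pat.lower():
                    raise ValueError(f"pattern {pat!r} in {cat!r} must be lowercase")
                if "*" in pat and (not pat.endswith("*") or pat.count("*") > 1):
                    raise ValueError(f"wildcard only allowed as trailing '*': {pat!r}")
                if pat in seen:
                    raise ValueError(f"duplicate pattern {pat!r} in {cat!r}")
                seen.add(pat)
                if pat.endswith("*"):
                    self._prefixes.append((pat[:-1], cat))
                else:
                    self._exact.setdefault(pat, []).append(cat)
            self.categories[cat] = tuple(patterns)
        self._cache: dict[str, tuple[str, ...]] = {}

    def match(self, word: str) -> tuple[str, ...]:
        """Categories the (lowercase) word counts toward."""
        hit = self._cache.get(word)
        if hit is None:
            cats = list(self._exact.get(word, ()))
            for prefix, cat in self._prefixes:
                if word.startswith(prefix) and cat not in cats:
                    cats.append(cat)
            hit = tuple(cats)
            self._cache[word] = hit
        return hit

    def words_in(self, category: str, min_len: int = 1) -> list[str]:
        """Literal (non-wildcard) words of a category; handy for generators."""
        return [
            p for p in self.categories[category]
            if not p.endswith("*") and len(p) >= min_len
        ]


_DEFAULT: CategoryDictionary | None = None


def default_dictionary() -> CategoryDictionary:
    """The packaged open dictionary (see :mod:`stylesalience.lexicon`)."""
    global _DEFAULT
    if _DEFAULT is None:
        from .lexicon import DEFAULT_CATEGORY_WORDS

        _DEFAULT = CategoryDictionary(DEFAULT_CATEGORY_WORDS)
    return _DEFAULT


@dataclass(frozen=True)
class StyleVector:
    """One document's 44 canonical style features plus count metadata."""

    values: np.ndarray
    word_count: int
    sentence_count: int

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {self.values.shape}")

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))


def extract(text: str, dictionary: CategoryDictionary | None = None) -> StyleVector:
    """Compute the canonical style vector of a single document.

    Word-category and punctuation values are ``100 * count / word_count``;
    ``sixltr`` is the percentage of words with six or more letters; ``wps``
    is ``word_count / sentence_count``. Zero-word text is a contract error:
    such posts should have been removed by corpus cleaning.
    """
    if dictionary is None:
        dictionary = default_dictionary()
    tok = tokenize(text)
    if tok.word_count == 0:
        raise ValueError(
            "cannot extract style features from text without words; "
            "run clean_corpus with drop_wordless=True first"
        )
    return _vector_from_tokens(tok, dictionary)


def _vector_from_tokens(tok: TokenizedText, dictionary: CategoryDictionary) -> StyleVector:
    n = tok.word_count
    counts = dict.fromkeys(WORD_CATEGORIES, 0)
    sixltr = 0
    for word in tok.words:
        if sum(ch != "'" for ch in word) >= 6:
            sixltr += 1
        for cat in dictionary.match(word):
            counts[cat] += 1

    values = np.empty(N_FEATURES)
    values[0] = n / tok.sentence_count                      # wps
    values[1] = 100.0 * sixltr / n                          # sixltr
    for j, cat in enumerate(WORD_CATEGORIES, start=2):
        values[j] = 100.0 * counts[cat] / n
    offset = 2 + len(WORD_CATEGORIES)
    for j, cls in enumerate(PUNCTUATION_FEATURES, start=offset):
        values[j] = 100.0 * tok.punct_counts[cls] / n
    return StyleVector(values=values, word_count=n, sentence_count=tok.sentence_count)


def extract_table(
    texts: Iterable[str], dictionary: CategoryDictionary | None = None
) -> pd.DataFrame:
    """Style vectors for a collection of documents as a feature table."""
    if dictionary is None:
        dictionary = default_dictionary()
    rows = [extract(t, dictionary).values for t in texts]
    return pd.DataFrame(rows, columns=list(FEATURE_NAMES))


@dataclass
class SchemaReport:
    n_accepted: int
    n_rejected: int
    rejected_index: list = field(default_factory=list)
    reasons: dict = field(default_factory=dict)


def validate_schema(
    table: pd.DataFrame, alias_map: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, SchemaReport]:
    """Validate an externally computed feature table against the schema.

    ``alias_map`` renames foreign column names to canonical ones (e.g.
    ``{"WPS": "wps", "SemiC": "semic"}``). Rows violating range invariants
    (word-category or sixltr outside [0, 100], negative punctuation,
    non-positive wps, non-finite values) are rejected and reported; a
    missing canonical feature with no alias raises :class:`SchemaError`.
    """
    df = table.rename(columns=dict(alias_map or {}))
    missing = [name for name in FEATURE_NAMES if name not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing canonical features: {missing}")
    df = df.loc[:, list(FEATURE_NAMES)].astype(float)

    reasons: dict = {}
    finite = np.isfinite(df.to_numpy()).all(axis=1)
    pct_cols = ["sixltr", *WORD_CATEGORIES]
    in_range = (
        (df[pct_cols] >= 0).all(axis=1)
        & (df[pct_cols] <= 100).all(axis=1)
        & (df[list(PUNCTUATION_FEATURES)] >= 0).all(axis=1)
        & (df["wps"] > 0)
    )
    ok = finite & in_range.to_numpy()
    for idx in df.index[~ok]:
        row = df.loc[idx]
        if not np.isfinite(row.to_numpy()).all():
            reasons[idx] = "non-finite value"
        elif row["wps"] <= 0:
            reasons[idx] = "wps must be positive"
        else:
            bad = [
                c for c in pct_cols if not (0 <= row[c] <= 100)
            ] + [c for c in PUNCTUATION_FEATURES if row[c] < 0]
            reasons[idx] = f"out-of-range: {bad}"
    report = SchemaReport(
        n_accepted=int(ok.sum()),
        n_rejected=int((~ok).sum()),
        rejected_index=list(df.index[~ok]),
        reasons=reasons,
    )
    return df.loc[ok], report


def read_dictionary(path: str | Path, allow_topical: bool = False) -> CategoryDictionary:
    """Read a dictionary from the documented open format.

    YAML files (``.yml``/``.yaml``) hold a mapping ``category -> [patterns]``.
    Plain-text files hold ``[category]`` header lines followed by one
    pattern per line; blank lines and ``#`` comments are ignored.
    """
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        import yaml

        data = yaml.safe_load(path.read_text(encoding="utf-8"))
        return CategoryDictionary(data, allow_topical=allow_topical)
    categories: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1].strip()
            categories.setdefault(current, [])
        elif current is None:
            raise ValueError(f"{path}:{lineno}: pattern before any [category] header")
        else:
            categories[current].append(line)
    return CategoryDictionary(categories, allow_topical=allow_topical)


def write_dictionary(dictionary: CategoryDictionary, path: str | Path) -> None:
    path = Path(path)
    lines = []
    for cat, patterns in dictionary.categories.items():
        lines.append(f"[{cat}]")
        lines.extend(patterns)
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")


def read_liwc_dic(
    path: str | Path,
    name_map: Mapping[str, str] | None = None,
    allow_topical: bool = False,
) -> CategoryDictionary:
    """Convert a LIWC-layout ``.dic`` file (``%``-delimited header of
    numeric category ids, then ``word<TAB>id...`` lines) to a
    :class:`CategoryDictionary`. Users must own a license for the file
    itself; only the layout is handled here. ``name_map`` translates the
    file's category names to canonical ones; unmapped categories are
    dropped.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    try:
        start = lines.index("%")
        end = lines.index("%", start + 1)
    except ValueError as exc:
        raise ValueError("not a LIWC .dic layout: missing % header delimiters") from exc

    id_to_name: dict[str, str] = {}
    for line in lines[start + 1 : end]:
        parts = line.split()
        if len(parts) >= 2:
            raw = parts[1].lower()
            name = (name_map or {}).get(raw, raw)
            id_to_name[parts[0]] = name

    categories: dict[str, list[str]] = {c: [] for c in WORD_CATEGORIES}
    for line in lines[end + 1 :]:
        parts = line.split()
        if len(parts) < 2:
            continue
        word = parts[0].lower()
        for cid in parts[1:]:
            name = id_to_name.get(cid)
            if name in categories and word not in categories[name]:
                categories[name].append(word)
            elif name in KNOWN_TOPICAL_CATEGORIES and allow_topical:
                categories.setdefault(name, [])
                if word not in categories[name]:
                    categories[name].append(word)
    return CategoryDictionary(categories, allow_topical=allow_topical)
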