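"""Reading, validating, cleaning and filtering forum-post corpora.

A corpus is a table of posts from exactly two declared identity forums
(plus optionally unlabeled application data). Cleaning removes platform
administrative messages, self-identified bot authors and wordless posts
(emoji-only, pictures); filtering drops posts below a word-count cutoff.
Exports are anonymised by default: feature vectors and hashed user ids,
never raw text.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import CategoryDictionary, default_dictionary, extract_table, tokenize

REQUIRED_COLUMNS = ("post_id", "user_id", "label", "text")
OPTIONAL_COLUMNS = ("platform", "timestamp")
UNLABELED = "unlabeled"


class CorpusFormatError(ValueError):
    """A corpus file could not be parsed."""


class LabelValidationError(ValueError):
    """A corpus contains labels outside the declared label set."""


@dataclass
class Corpus:
    """An ordered collection of posts with a declared pair of labels."""

    posts: pd.DataFrame
    label_set: tuple[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.label_set)) != 2:
            raise ValueError("label_set must contain exactly two distinct labels")
        self.label_set = (str(self.label_set[0]), str(self.label_set[1]))
        missing = [c for c in REQUIRED_COLUMNS if c not in self.posts.columns]
        if missing:
            raise ValueError(f"posts table missing required columns: {missing}")
        if self.posts["post_id"].duplicated().any():
            dupes = self.posts.loc[self.posts["post_id"].duplicated(), "post_id"]
            raise ValueError(f"duplicate post_id values: {sorted(set(dupes))[:5]}")
        offending = sorted(
            set(self.posts["label"]) - set(self.label_set) - {UNLABELED}
        )
        if offending:
            raise LabelValidationError(
                f"labels {offending} are not in the declared label set {self.label_set}"
            )
        if "word_count" not in self.posts.columns:
            self.posts = self.posts.assign(
                word_count=[tokenize(t).word_count for t in self.posts["text"]]
            )
        self.posts = self.posts.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def labels(self) -> pd.Series:
        return self.posts["label"]

    def label_counts(self) -> dict[str, int]:
        vc = self.labels.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in self.label_set}

    def dual_users(self) -> list[str]:
        """User ids with at least one post under each of the two labels."""
        a, b = self.label_set
        by_user = self.posts.groupby("user_id")["label"].agg(set)
        return sorted(u for u, labs in by_user.items() if a in labs and b in labs)

    def subset(self, mask) -> "Corpus":
        return Corpus(
            posts=self.posts.loc[mask].copy(),
            label_set=self.label_set,
            provenance=dict(self.provenance),
        )

    def preferred_dictionary(self) -> CategoryDictionary:
        """The dictionary this corpus should be extracted with.

        Synthetic corpora record their pseudo-word dictionary in the
        provenance; everything else uses the packaged default.
        """
        if self.provenance.get("dictionary") == "synthetic":
            from .synthetic import synthetic_dictionary

            return synthetic_dictionary()
        return default_dictionary()

    def features(self, dictionary: CategoryDictionary | None = None) -> pd.DataFrame:
        """Style-feature table aligned with ``posts`` (row for row)."""
        table = extract_table(self.posts["text"], dictionary or self.preferred_dictionary())
        table.index = self.posts.index
        return table


def read_corpus(
    path: str | Path,
    label_set: Sequence[str],
    format: str | None = None,
) -> Corpus:
    """Read a corpus from JSONL or CSV.

    The format is inferred from the suffix unless given. Records with
    missing/empty text are rejected; their count is recorded in
    ``provenance["rejected_missing_text"]``. Unknown labels raise
    :class:`LabelValidationError` naming the offenders; malformed files
    raise :class:`CorpusFormatError` naming the line.
    """
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    if fmt == "jsonl":
        records = []
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
        df = pd.DataFrame.from_records(records)
    elif fmt == "csv":
        try:
            df = pd.read_csv(path, dtype={"post_id": str, "user_id": str})
        except pd.errors.ParserError as exc:
            raise CorpusFormatError(f"{path}: malformed CSV: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'jsonl' or 'csv')")

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required columns {missing}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "platform" else pd.NaT
    df["post_id"] = df["post_id"].astype(str)
    df["user_id"] = df["user_id"].astype(str)
    if df["timestamp"].notna().any():
        df["timestamp"] = pd.to_datetime(df["timestamp"])

    bad_text = df["text"].isna() | ~df["text"].map(lambda t: isinstance(t, str))
    n_rejected = int(bad_text.sum())
    df = df.loc[~bad_text]
    return Corpus(
        posts=df.reset_index(drop=True),
        label_set=tuple(label_set),
        provenance={"path": str(path), "format": fmt, "rejected_missing_text": n_rejected},
    )


def write_corpus(corpus: Corpus, path: str | Path, format: str | None = None) -> None:
    """Write the full corpus (including raw text) to JSONL or CSV.

    This writer is for pipeline intermediates; anonymised sharing goes
    through :func:`export_features`, which drops text and user ids.
    """
    path = Path(path)
    fmt = format or ("jsonl" if path.suffix in {".jsonl", ".json"} else "csv")
    cols = [c for c in (*REQUIRED_COLUMNS, *OPTIONAL_COLUMNS, "word_count") if c in corpus.posts.columns]
    df = corpus.posts[cols].copy()
    if "timestamp" in df.columns and df["timestamp"].notna().any():
        df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%d")
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in df.to_dict(orient="records"):
                rec = {k: (None if pd.isna(v) else v) for k, v in rec.items() if k != "word_count" or v is not None}
                fh.write(json.dumps(rec, ensure_ascii=False) + "\n")
    else:
        df.to_csv(path, index=False)


def hash_user_id(user_id: str, salt: str = "stylesalience") -> str:
    return hashlib.sha256((salt + ":" + user_id).encode("utf-8")).hexdigest()[:12]


def export_features(
    corpus: Corpus,
    path: str | Path,
    dictionary: CategoryDictionary | None = None,
    include_text: bool = False,
    salt: str = "stylesalience",
) -> pd.DataFrame:
    """Export an anonymised derived dataset: features + labels.

    By default the export contains hashed user ids, labels, word counts and
    the 44 style features — never the original text or raw user ids, so the
    file can be shared without exposing posts to search-engine re-identification.
    """
    table = corpus.features(dictionary)
    out = pd.DataFrame(
        {
            "post_id": corpus.posts["post_id"],
            "user_hash": [hash_user_id(u, salt) for u in corpus.posts["user_id"]],
            "label": corpus.posts["label"],
            "word_count": corpus.posts["word_count"],
        }
    )
    out = pd.concat([out, table], axis=1)
    if include_text:
        out.insert(4, "text", corpus.posts["text"])
    path = Path(path)
    if path.suffix == ".jsonl":
        out.to_json(path, orient="records", lines=True)
    else:
        out.to_csv(path, index=False)
    return out


@dataclass
class CleaningRules:
    """Rules for removing non-member and wordless posts.

    ``admin_message_patterns`` are regexes matched (case-insensitively)
    against the *whole trimmed text*, so genuine posts quoting an admin
    notice mid-text survive. ``bot_author_patterns`` are searched in the
    user id. Rule application is idempotent.
    """

    admin_message_patterns: tuple[str, ...] = ()
    bot_author_patterns: tuple[str, ...] = ()
    drop_wordless: bool = True

    def __post_init__(self) -> None:
        self._admin = [re.compile(p, re.IGNORECASE) for p in self.admin_message_patterns]
        self._bots = [re.compile(p, re.IGNORECASE) for p in self.bot_author_patterns]

    def is_admin_message(self, text: str) -> bool:
        stripped = text.strip()
        return any(rx.fullmatch(stripped) for rx in self._admin)

    def is_bot_author(self, user_id: str) -> bool:
        return any(rx.search(user_id) for rx in self._bots)


#: Rules matching the platform-withdrawal notices seen on parenting forums.
DEFAULT_CLEANING_RULES = CleaningRules(
    admin_message_patterns=(
        r"message withdrawn.*",
        r"message deleted.*",
        r"\[?post removed by moderators?\]?",
    ),
    bot_author_patterns=(r"bot$", r"^automoderator$"),
    drop_wordless=True,
)


@dataclass
class CleaningReport:
    n_input: int
    n_admin_removed: int
    n_bot_removed: int
    n_wordless_removed: int
    n_output: int
    empty_result: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def clean_corpus(corpus: Corpus, rules: CleaningRules) -> tuple[Corpus, CleaningReport]:
    """Remove admin messages, bot authors and (optionally) wordless posts."""
    df = corpus.posts
    admin = df["text"].map(rules.is_admin_message)
    bot = df["user_id"].map(rules.is_bot_author) & ~admin
    wordless = pd.Series(False, index=df.index)
    if rules.drop_wordless:
        wordless = (df["word_count"] == 0) & ~admin & ~bot
    keep = ~(admin | bot | wordless)
    report = CleaningReport(
        n_input=len(df),
        n_admin_removed=int(admin.sum()),
        n_bot_removed=int(bot.sum()),
        n_wordless_removed=int(wordless.sum()),
        n_output=int(keep.sum()),
        empty_result=bool(keep.sum() == 0),
    )
    return corpus.subset(keep), report


def filter_min_words(corpus: Corpus, min_words: float) -> Corpus:
    """Retain exactly the posts with ``word_count >= min_words``.

    ``min_words`` may be fractional (e.g. a computed quartile); retention
    is monotone in the cutoff.
    """
    if min_words < 1:
        raise ValueError("min_words must be >= 1")
    return corpus.subset(corpus.posts["word_count"] >= min_words)


def word_count_quartile(corpus: Corpus, q: float = 25.0) -> float:
    """Lower quartile (default) of post word counts.

    Uses the median-unbiased linear-interpolation convention
    (Hyndman–Fan type 8, ``numpy`` method ``"median_unbiased"``).
    """
    if len(corpus) == 0:
        raise ValueError("cannot compute quartiles of an empty corpus")
    return float(
        np.percentile(corpus.posts["word_count"].to_numpy(), q, method="median_unbiased")
    )
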