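"""Longitudinal salience trajectories.

Application of a trained classifier to timestamped posts: posts are binned
into calendar periods relative to a per-user anchor event (e.g. month of
birth/due date), each user-period's posts are aggregated into one document,
and the ensemble assigns a salience probability per user-period. Group
trajectories can then be compared at any period with Welch's t-test and
Cohen's d.

The classifier is relative by construction: a declining probability for one
identity cannot be distinguished from a rising salience of the contrast
identity. Trajectories should be read as relative salience only.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .corpus import Corpus
from .features import CategoryDictionary, extract
from .model import EnsembleModel


def build_periods(
    corpus: Corpus,
    anchors: Mapping[str, object],
    n_periods: int = 4,
    period_months: int = 1,
) -> pd.Series:
    """Assign each post to a calendar period relative to its user's anchor.

    Period 1 spans the anchor's calendar month (with ``period_months=1``);
    period ``k`` covers months ``(k-1)*period_months`` onward. Posts before
    the anchor month or beyond period ``n_periods`` get ``<NA>``. Users are
    included as long as they have at least one post in the window — full
    coverage of every period is not required.

    Returns an integer series aligned with ``corpus.posts``. Raises if any
    user in the corpus lacks an anchor or a timestamp.
    """
    posts = corpus.posts
    if "timestamp" not in posts.columns or posts["timestamp"].isna().any():
        missing = sorted(
            posts.loc[posts.get("timestamp", pd.Series(pd.NaT, index=posts.index)).isna(), "user_id"].unique()
        )
        raise ValueError(f"posts without timestamps for users: {missing[:10]}")
    missing_anchor = sorted(set(posts["user_id"]) - set(anchors))
    if missing_anchor:
        raise ValueError(f"no anchor date for users: {missing_anchor[:10]}")

    ts = pd.to_datetime(posts["timestamp"])
    month_index = ts.dt.year * 12 + ts.dt.month
    anchor_ts = pd.to_datetime(posts["user_id"].map(dict(anchors)))
    anchor_month = anchor_ts.dt.year * 12 + anchor_ts.dt.month
    offset = (month_index - anchor_month) // period_months
    period = offset + 1
    period[(period < 1) | (period > n_periods)] = pd.NA
    return period.astype("Int64")


def score_trajectories(
    model: EnsembleModel,
    corpus: Corpus,
    periods: pd.Series,
    groups: Mapping[str, str] | None = None,
    dictionary: CategoryDictionary | None = None,
    method: str = "concat",
) -> pd.DataFrame:
    """Salience probability per user-period.

    ``method="concat"`` (default) concatenates the period's posts into one
    document, extracts one style vector and makes one ensemble prediction —
    matching the idea of scoring aggregated posts and stabilising
    short-post noise. ``method="mean"`` averages per-post probabilities
    instead. Returns a table with columns ``user_id``, ``period``,
    ``n_posts``, ``total_words``, ``probability`` and ``group`` (empty
    string where no group tag is provided). User-periods whose aggregated
    text has no words are omitted.
    """
    if method not in {"concat", "mean"}:
        raise ValueError("method must be 'concat' or 'mean'")
    dictionary = dictionary or corpus.preferred_dictionary()
    posts = corpus.posts.assign(_period=periods)
    posts = posts[posts["_period"].notna()]
    rows = []
    for (user, per), grp in posts.groupby(["user_id", "_period"], sort=True):
        texts = list(grp["text"])
        total_words = int(grp["word_count"].sum())
        if total_words == 0:
            continue
        if method == "concat":
            vec = extract(" ".join(texts), dictionary)
            prob = float(model.predict_proba(vec))
        else:
            probs = [
                float(model.predict_proba(extract(t, dictionary)))
                for t, wc in zip(grp["text"], grp["word_count"])
                if wc > 0
            ]
            prob = float(np.mean(probs))
        rows.append(
            {
                "user_id": user,
                "period": int(per),
                "n_posts": len(texts),
                "total_words": total_words,
                "probability": prob,
                "group": (groups or {}).get(user, ""),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Welch's t-test plus Cohen's d for two groups of probabilities."""

    t: float
    df: float
    p: float
    d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    d_flagged: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def welch_cohen(a, b) -> GroupComparison:
    """Welch's unequal-variance t (Welch–Satterthwaite df) and Cohen's d.

    The sign convention is ``a - b``: positive t/d mean group ``a`` scores
    higher. Cohen's d uses the pooled SD; when both groups are constant
    the d is flagged (returned as NaN).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    na, nb = len(a), len(b)
    diff = float(a.mean() - b.mean())
    const_a = np.ptp(a) == 0
    const_b = np.ptp(b) == 0
    degenerate = const_a or const_b

    if const_a and const_b:
        # no within-group variation at all: t/d are 0 for identical means,
        # undefined otherwise
        t = 0.0 if diff == 0 else float("nan")
        return GroupComparison(
            t=t, df=float(na + nb - 2), p=1.0 if diff == 0 else float("nan"),
            d=0.0 if diff == 0 else float("nan"),
            mean_a=float(a.mean()), mean_b=float(b.mean()),
            n_a=na, n_b=nb, d_flagged=diff != 0,
        )

    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return GroupComparison(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        d=float(diff / pooled),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=na,
        n_b=nb,
        d_flagged=bool(degenerate),
    )


def group_compare(
    table: pd.DataFrame, period: int, tag: str, group_column: str = "group"
) -> GroupComparison:
    """Compare tagged vs untagged users' probabilities at one period.

    Group ``a`` is every user *not* carrying ``tag``; group ``b`` is the
    tagged subgroup, so a positive t/d means the untagged group scores
    higher (e.g. intact salience vs a declining subgroup).
    """
    at = table[table["period"] == period]
    b = at.loc[at[group_column] == tag, "probability"]
    a = at.loc[at[group_column] != tag, "probability"]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >=2 users per group at period {period}; got {len(a)} vs {len(b)}"
        )
    return welch_cohen(a.to_numpy(), b.to_numpy())


def plot_trajectories(table: pd.DataFrame, path, group_column: str = "group") -> None:
    """Period vs group-mean probability, shaded by +-1 SE."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for grp, sub in table.groupby(group_column):
        agg = sub.groupby("period")["probability"].agg(["mean", "sem"])
        label = str(grp) if str(grp) else "all"
        ax.plot(agg.index, agg["mean"], marker="o", label=label)
        ax.fill_between(
            agg.index, agg["mean"] - agg["sem"], agg["mean"] + agg["sem"], alpha=0.25
        )
    ax.set_xlabel("period")
    ax.set_ylabel("salience probability")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
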