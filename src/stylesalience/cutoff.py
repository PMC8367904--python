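"""Word-count-cutoff selection: AUC versus minimum post length.

Very short posts carry little stylistic signal, but discarding them costs
generalizability. This module fits the ensemble at each candidate cutoff
and reports training (in-subset) and test (out-of-bag) AUC together with
retention, producing the plot-ready trade-off curve; the default
recommendation removes the lower word-count quartile of the corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .corpus import Corpus, word_count_quartile
from .model import TrainingConfig, train


def default_cutoff_grid(corpus: Corpus, fine_until: int = 50, coarse_step: int = 5) -> list[int]:
    """Candidate cutoffs 1..P90 of word counts: unit steps up to
    ``fine_until``, then steps of ``coarse_step``."""
    p90 = int(np.percentile(corpus.posts["word_count"], 90, method="median_unbiased"))
    grid = list(range(1, min(fine_until, p90) + 1))
    grid += list(range(fine_until + coarse_step, p90 + 1, coarse_step))
    return grid or [1]


def auc_by_cutoff(
    corpus: Corpus,
    cfg: TrainingConfig,
    cutoffs: list[int] | None = None,
    features: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit the ensemble at each cutoff and tabulate AUC and retention.

    Columns: ``cutoff``, ``n_retained``, ``train_auc`` (mean in-subset),
    ``test_auc`` (mean out-of-bag), ``flagged`` (True where fewer than two
    posts per label survived, in which case the AUCs are NaN). Features
    are extracted once and reused across cutoffs.
    """
    if cutoffs is None:
        cutoffs = default_cutoff_grid(corpus)
    if sorted(cutoffs) != list(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    if features is None:
        features = corpus.features()

    rows = []
    for k in cutoffs:
        retained = int((corpus.posts["word_count"] >= k).sum())
        row = {"cutoff": k, "n_retained": retained, "train_auc": np.nan,
               "test_auc": np.nan, "flagged": False}
        cfg_k = replace(cfg, min_words=k)
        try:
            model = train(corpus, cfg_k, features=features)
        except ValueError:
            row["flagged"] = True
        else:
            rep = model.training_report()
            row["train_auc"] = float(rep["train_auc"].mean())
            row["test_auc"] = float(rep["oob_auc"].mean())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CutoffRecommendation:
    cutoff: int
    rule: str
    rationale: dict


def recommend_cutoff(
    table: pd.DataFrame,
    corpus: Corpus,
    rule: str = "lower_quartile",
    min_retention: float = 0.75,
) -> CutoffRecommendation:
    """Recommend a word-count cutoff.

    ``lower_quartile`` (default): keep the most informative 75% of posts
    by removing the first word-count quartile; a fractional quartile is
    rounded up so at least 75% of posts are retained. ``max_test_auc``:
    the cutoff with the best out-of-bag AUC among those retaining at least
    ``min_retention`` of the posts (ties go to the smaller cutoff).
    """
    if table.empty:
        raise ValueError("cutoff table is empty")
    n_total = len(corpus)
    if rule == "lower_quartile":
        q1 = word_count_quartile(corpus)
        cutoff = int(q1) if float(q1).is_integer() else int(math.ceil(q1))
        retention = float((corpus.posts["word_count"] >= cutoff).mean())
        return CutoffRecommendation(
            cutoff=cutoff,
            rule=rule,
            rationale={"q1": q1, "retention": retention},
        )
    if rule == "max_test_auc":
        ok = table.loc[
            (~table["flagged"]) & (table["n_retained"] >= min_retention * n_total)
        ]
        if ok.empty:
            raise ValueError(f"no cutoff retains at least {min_retention:.0%} of posts")
        best = ok.loc[ok["test_auc"].idxmax()]
        return CutoffRecommendation(
            cutoff=int(best["cutoff"]),
            rule=rule,
            rationale={
                "test_auc": float(best["test_auc"]),
                "retention": float(best["n_retained"] / n_total),
                "min_retention": min_retention,
            },
        )
    raise ValueError(f"unknown rule {rule!r}")


def plot_cutoff_curve(table: pd.DataFrame, path, q1: float | None = None) -> None:
    """Cutoff on x, training/test AUC on y, vertical line at Q1."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(table["cutoff"], table["train_auc"], label="training (in-subset)")
    ax.plot(table["cutoff"], table["test_auc"], label="test (out-of-bag)")
    if q1 is not None:
        ax.axvline(q1, linestyle="--", color="grey", label=f"Q1 = {q1:g}")
    ax.axhline(0.5, linestyle=":", color="grey")
    ax.set_xlabel("word-count cutoff")
    ax.set_ylabel("AUC")
    ax.set_ylim(0.4, 1.0)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
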