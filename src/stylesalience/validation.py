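"""Evaluation designs for salience classifiers.

Implements the validation ladder around a trained ensemble:

* ROC/AUC with asymptotic (Hanley–McNeil, optionally DeLong) uncertainty;
* within-participant cross-validation — one random post per identity forum
  per dual-membership user, repeated over rounds, so stable user traits
  cannot explain classification success;
* cross-platform within-user testing (same mechanics, held-out platform);
* per-topic experimental evaluation with asymptotic 95% CIs;
* confusion matrices and ROC-based sample-size planning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score, roc_curve

from .corpus import Corpus
from .model import EnsembleModel


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve: P(score+ > score-) + 0.5 * P(tie).

    ``labels`` are binary (1/True = positive class). Equivalent to the
    normalized rank-sum statistic. Raises if only one class is present.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both classes to be present")
    return float(roc_auc_score(y, s))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Asymptotic SE of the AUC (Hanley & McNeil 1982 approximation)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def delong_se(scores, labels) -> float:
    """DeLong (1988) nonparametric SE of the AUC."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise ValueError("DeLong SE needs at least 2 items per class")
    # placement values
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    return float(np.sqrt(var))


def auc_ci(
    auc: float,
    n_pos: int,
    n_neg: int,
    level: float = 0.95,
    scores=None,
    labels=None,
    method: str = "hanley_mcneil",
) -> tuple[float, float, float]:
    """(SE, lower, upper) asymptotic CI for an AUC, truncated to [0, 1]."""
    if method == "hanley_mcneil":
        se = hanley_mcneil_se(auc, n_pos, n_neg)
    elif method == "delong":
        if scores is None or labels is None:
            raise ValueError("DeLong CI needs the raw scores and labels")
        se = delong_se(scores, labels)
    else:
        raise ValueError(f"unknown CI method {method!r}")
    z = norm.ppf(0.5 + level / 2)
    return se, max(0.0, auc - z * se), min(1.0, auc + z * se)


def confusion_matrix(scores, labels, threshold: float = 0.5) -> dict[str, int]:
    """2x2 confusion counts at a probability threshold.

    Scores at or above the threshold predict the positive class (ties go
    to positive). Keys: tp, fn, fp, tn.
    """
    y = np.asarray(labels).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    return {
        "tp": int(np.sum(pred & y)),
        "fn": int(np.sum(~pred & y)),
        "fp": int(np.sum(pred & ~y)),
        "tn": int(np.sum(~pred & ~y)),
    }


@dataclass
class ValidationReport:
    """Summary of one evaluation design.

    ``se_rounds`` is the SE of the mean across CV rounds; ``se_members``
    the SE across ensemble members; ``se_auc`` the Hanley–McNeil SE of the
    mean AUC at the design's evaluation size, which also captures the
    sampling noise shared across rounds (rounds reuse the same users, so
    ``se_rounds`` alone understates uncertainty). The 95% CI uses the
    combined SE ``sqrt(se_rounds**2 + se_auc**2)``.
    """

    design: str
    rounds: int
    per_round_aucs: list[float]
    mean_auc: float
    se_rounds: float
    se_members: float
    se_auc: float
    ci95: tuple[float, float]
    roc_points: list[tuple[float, float]]
    confusion: dict[str, int]
    n_users: int
    n_posts: int
    notes: dict = field(default_factory=dict)

    @property
    def combined_se(self) -> float:
        parts = [v for v in (self.se_rounds, self.se_auc) if np.isfinite(v)]
        return float(np.sqrt(np.sum(np.square(parts)))) if parts else float("nan")

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"round": range(len(self.per_round_aucs)), "auc": self.per_round_aucs})


def _round_report(
    design: str,
    per_round: list[float],
    member_aucs: list[float],
    pooled_scores: np.ndarray,
    pooled_y: np.ndarray,
    n_users: int,
    n_posts: int,
    eval_n_pos: int,
    eval_n_neg: int,
    notes: dict | None = None,
) -> ValidationReport:
    per_round = [float(a) for a in per_round]
    mean_auc = float(np.mean(per_round))
    se_rounds = (
        float(np.std(per_round, ddof=1) / np.sqrt(len(per_round)))
        if len(per_round) > 1
        else float("nan")
    )
    se_members = (
        float(np.std(member_aucs, ddof=1) / np.sqrt(len(member_aucs)))
        if len(member_aucs) > 1
        else float("nan")
    )
    se_auc = hanley_mcneil_se(min(max(mean_auc, 1e-6), 1 - 1e-6), eval_n_pos, eval_n_neg)
    se_comb = float(np.sqrt(np.nansum([se_rounds**2 if np.isfinite(se_rounds) else 0.0, se_auc**2])))
    z = norm.ppf(0.975)
    fpr, tpr, _ = roc_curve(pooled_y, pooled_scores)
    return ValidationReport(
        design=design,
        rounds=len(per_round),
        per_round_aucs=per_round,
        mean_auc=mean_auc,
        se_rounds=se_rounds,
        se_members=se_members,
        se_auc=se_auc,
        ci95=(max(0.0, mean_auc - z * se_comb), min(1.0, mean_auc + z * se_comb)),
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
        confusion=confusion_matrix(pooled_scores, pooled_y),
        n_users=n_users,
        n_posts=n_posts,
        notes=notes or {},
    )


def within_user_cv(
    model: EnsembleModel,
    corpus: Corpus,
    rounds: int = 20,
    seed: int = 0,
    features: pd.DataFrame | None = None,
    design: str = "within_user",
) -> ValidationReport:
    """Within-participant cross-validation.

    Each round draws, for every user who posted under *both* labels,
    exactly one random post per label, scores them with the ensemble, and
    records the AUC. Repeating over rounds (default 20) averages over the
    post draw. Each round uses a dedicated random stream derived from
    ``(seed, round)``, so adding rounds never changes earlier rounds.
    """
    dual = corpus.dual_users()
    if len(dual) < 2:
        raise ValueError(
            "within-participant validation requires at least two users with "
            "posts under both labels; this design controls for stable user "
            "traits by comparing posts written by the same people"
        )
    if features is None:
        features = corpus.features()
    posts = corpus.posts
    y_all = (posts["label"] == model.positive_label).to_numpy()

    # per (user, label) row indices, precomputed once
    idx_by_user_label: dict[tuple[str, str], np.ndarray] = {
        (u, lab): grp.index.to_numpy()
        for (u, lab), grp in posts[posts["user_id"].isin(dual)].groupby(
            ["user_id", "label"], sort=True
        )
        if lab in corpus.label_set
    }
    all_probs = model.predict_proba(features)
    member_probs = model.member_probas(features)

    per_round, member_aucs_rounds = [], []
    pooled_scores, pooled_y = [], []
    for r in range(rounds):
        rng = np.random.default_rng([seed, r])
        rows = []
        for u in dual:
            for lab in corpus.label_set:
                choices = idx_by_user_label[(u, lab)]
                rows.append(int(choices[rng.integers(len(choices))]))
        rows = np.array(rows)
        y = y_all[rows]
        per_round.append(roc_auc(all_probs[rows], y))
        member_aucs_rounds.append(
            [roc_auc(member_probs[k, rows], y) for k in range(member_probs.shape[0])]
        )
        pooled_scores.append(all_probs[rows])
        pooled_y.append(y)

    member_means = list(np.mean(member_aucs_rounds, axis=0))
    return _round_report(
        design=design,
        per_round=per_round,
        member_aucs=member_means,
        pooled_scores=np.concatenate(pooled_scores),
        pooled_y=np.concatenate(pooled_y),
        n_users=len(dual),
        n_posts=int(posts["user_id"].isin(dual).sum()),
        eval_n_pos=len(dual),
        eval_n_neg=len(dual),
        notes={"member_mean_aucs": member_means},
    )


def cross_platform_test(
    model: EnsembleModel,
    corpus: Corpus,
    rounds: int = 20,
    seed: int = 0,
    features: pd.DataFrame | None = None,
) -> ValidationReport:
    """Within-user evaluation on a corpus from a different platform.

    The corpus must have been cleaned and cutoff-filtered with the same
    rules as the training data; mechanics are identical to
    :func:`within_user_cv`, the report is tagged ``cross_platform``.
    """
    return within_user_cv(
        model, corpus, rounds=rounds, seed=seed, features=features, design="cross_platform"
    )


@dataclass
class ExperimentalReport:
    """Per-topic evaluation of experimentally manipulated salience."""

    table: pd.DataFrame           # topic, n, auc, se, ci_low, ci_high
    reports: dict[str, ValidationReport]
    skipped: list[str]

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "skipped": self.skipped,
            "reports": {k: v.to_dict() for k, v in self.reports.items()},
        }


def experimental_eval(
    model: EnsembleModel,
    corpus: Corpus,
    topic_column: str = "topic",
    features: pd.DataFrame | None = None,
    ci_method: str = "hanley_mcneil",
) -> ExperimentalReport:
    """Evaluate the classifier per topic with asymptotic 95% CIs.

    ``corpus.posts`` must carry a topic tag column. For each topic the
    documents are scored with the ensemble and the AUC is reported with
    its asymptotic SE and 95% CI. Topics with only one class present are
    skipped and listed in the report.
    """
    if topic_column not in corpus.posts.columns:
        raise ValueError(f"corpus has no {topic_column!r} column")
    if features is None:
        features = corpus.features()
    probs = model.predict_proba(features)
    y_all = (corpus.posts["label"] == model.positive_label).to_numpy()

    rows, reports, skipped = [], {}, []
    for topic, grp in corpus.posts.groupby(topic_column, sort=True):
        rows_idx = grp.index.to_numpy()
        y = y_all[rows_idx]
        if len(np.unique(y)) < 2:
            skipped.append(str(topic))
            continue
        s = probs[rows_idx]
        auc = roc_auc(s, y)
        n_pos, n_neg = int(y.sum()), int((~y.astype(bool)).sum())
        se, lo, hi = auc_ci(auc, n_pos, n_neg, scores=s, labels=y, method=ci_method)
        rows.append(
            {"topic": topic, "n": len(y), "auc": auc, "se": se, "ci_low": lo, "ci_high": hi}
        )
        fpr, tpr, _ = roc_curve(y, s)
        reports[str(topic)] = ValidationReport(
            design="experimental",
            rounds=1,
            per_round_aucs=[auc],
            mean_auc=auc,
            se_rounds=float("nan"),
            se_members=float("nan"),
            se_auc=se,
            ci95=(lo, hi),
            roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
            confusion=confusion_matrix(s, y),
            n_users=int(grp["user_id"].nunique()),
            n_posts=len(y),
        )
    return ExperimentalReport(table=pd.DataFrame(rows), reports=reports, skipped=skipped)


# -- sample-size planning ---------------------------------------------------


def _auc_variance(auc: float, n_pos: int, n_neg: int, model: str) -> float:
    if model == "hanley_mcneil":
        return hanley_mcneil_se(auc, n_pos, n_neg) ** 2
    if model == "binormal":
        # Obuchowski's binormal-model variance with equal class SDs.
        a = norm.ppf(auc) * np.sqrt(2.0)
        ratio = n_neg / n_pos
        return float(
            (0.0099 * np.exp(-(a**2) / 4.0))
            * ((5 * a**2 + 8) + (a**2 + 8) / ratio)
            / n_neg
        )
    raise ValueError(f"unknown variance model {model!r}")


def auc_test_power(
    target_auc: float,
    n_pos: int,
    n_neg: int,
    alpha: float = 0.05,
    sided: str = "two",
    variance_model: str = "hanley_mcneil",
) -> float:
    """Analytic power of the z-test of AUC = 0.5 when the true AUC is
    ``target_auc``."""
    z_a = norm.ppf(1 - alpha / (2 if sided == "two" else 1))
    v0 = _auc_variance(0.5, n_pos, n_neg, variance_model)
    va = _auc_variance(target_auc, n_pos, n_neg, variance_model)
    z = (target_auc - 0.5 - z_a * np.sqrt(v0)) / np.sqrt(va)
    return float(norm.cdf(z))


@dataclass
class SampleSizeResult:
    total_n: int
    n_pos: int
    n_neg: int
    target_auc: float
    power: float
    alpha: float
    sided: str
    variance_model: str
    achieved_power: float

    def to_dict(self) -> dict:
        return asdict(self)


def sample_size_for_auc(
    target_auc: float,
    power: float = 0.80,
    alpha: float = 0.05,
    allocation_ratio: float = 1.0,
    sided: str = "two",
    variance_model: str = "hanley_mcneil",
    max_total: int = 1_000_000,
) -> SampleSizeResult:
    """Smallest total N detecting AUC = ``target_auc`` against 0.5.

    ``allocation_ratio`` is n_neg / n_pos (1 = equal allocation). The
    variance model and sidedness are explicit options, echoed in the
    result, because published calculators differ in these choices.
    """
    if not 0.5 < target_auc < 1:
        raise ValueError("target_auc must be in (0.5, 1)")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must be in (0, 1)")
    if sided not in {"one", "two"}:
        raise ValueError("sided must be 'one' or 'two'")

    n_pos = 2
    while True:
        n_neg = max(2, int(np.ceil(allocation_ratio * n_pos)))
        if n_pos + n_neg > max_total:
            raise ValueError("sample size exceeds max_total; parameters infeasible")
        achieved = auc_test_power(target_auc, n_pos, n_neg, alpha, sided, variance_model)
        if achieved >= power:
            return SampleSizeResult(
                total_n=n_pos + n_neg,
                n_pos=n_pos,
                n_neg=n_neg,
                target_auc=target_auc,
                power=power,
                alpha=alpha,
                sided=sided,
                variance_model=variance_model,
                achieved_power=achieved,
            )
        n_pos += 1
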