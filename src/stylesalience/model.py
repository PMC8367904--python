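"""Bootstrap ensemble of standardized logistic-regression salience classifiers.

The classifier follows the protocol's training recipe: draw balanced random
subsets of posts (half per identity label), z-standardize the 44 style
features within each subset, fit a plain maximum-likelihood logistic
regression of the label on all features, and repeat for ``n_subsets``
bootstrap rounds. The ensemble's salience probability for a text is the
mean of the member probabilities; coefficients are summarised as the mean
standardized coefficient with its standard error across members.

Out-of-bag evaluation defines the "test" performance: each member is scored
on the posts outside its own training subset.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .corpus import Corpus
from .features import StyleVector
from .schema import FEATURE_NAMES, N_FEATURES, SCHEMA_VERSION

MODEL_FORMAT_VERSION = "1"


@dataclass
class TrainingConfig:
    """Configuration of the bootstrap training procedure.

    Defaults mirror the protocol's reference settings: 20 bootstrap subsets
    of 100,000 posts each, balanced between the two identities, with posts
    under 25 words excluded. ``subset_size`` shrinks automatically (with a
    warning) when a corpus cannot supply ``subset_size/2`` posts per label.
    No regularization is applied by default so coefficients stay
    interpretable; set ``l2_C`` for perfectly separable toy data.
    """

    positive_label: str
    n_subsets: int = 20
    subset_size: int = 100_000
    balanced: bool = True
    min_words: int = 25
    seed: int = 0
    l2_C: float | None = None
    max_iter: int = 1000
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.balanced and self.subset_size % 2:
            raise ValueError("subset_size must be even when balanced")


@dataclass
class EnsembleMember:
    intercept: float
    coef: np.ndarray          # length 44; zero for features dropped as zero-variance
    means: np.ndarray         # standardization means on this member's subset
    sds: np.ndarray           # standardization SDs; 0 marks a dropped feature
    train_auc: float
    oob_auc: float
    n_oob: int

    def decision(self, X: np.ndarray) -> np.ndarray:
        mask = self.sds > 0
        Z = (X[:, mask] - self.means[mask]) / self.sds[mask]
        return self.intercept + Z @ self.coef[mask]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return expit(self.decision(X))


@dataclass
class EnsembleModel:
    """A trained bootstrap ensemble oriented toward ``positive_label``."""

    members: list[EnsembleMember]
    positive_label: str
    label_set: tuple[str, str]
    feature_names: tuple[str, ...] = FEATURE_NAMES
    schema_version: str = SCHEMA_VERSION
    config: TrainingConfig | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def negative_label(self) -> str:
        a, b = self.label_set
        return b if self.positive_label == a else a

    def _as_matrix(self, vectors) -> np.ndarray:
        if isinstance(vectors, StyleVector):
            X = vectors.values[None, :]
        elif isinstance(vectors, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in vectors.columns]
            if missing:
                raise ValueError(f"feature table missing {missing}")
            X = vectors.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.atleast_2d(np.asarray(vectors, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"schema mismatch: expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X

    def predict_proba(self, vectors) -> np.ndarray | float:
        """Ensemble probability that ``positive_label`` is salient.

        Accepts a single :class:`StyleVector` (returns a float) or a
        feature table / 2-D array (returns an array). Each member
        standardizes with its own stored means/SDs; the ensemble
        probability is the mean over members.
        """
        X = self._as_matrix(vectors)
        probs = np.mean([m.predict_proba(X) for m in self.members], axis=0)
        if isinstance(vectors, StyleVector):
            return float(probs[0])
        return probs

    def member_probas(self, vectors) -> np.ndarray:
        """Per-member probabilities, shape (n_members, n_documents)."""
        X = self._as_matrix(vectors)
        return np.vstack([m.predict_proba(X) for m in self.members])

    def coefficients_summary(self) -> pd.DataFrame:
        """Mean standardized coefficient and SE per feature, sorted by |mean|.

        Positive coefficients push probabilities toward ``positive_label``.
        With a single member the SE column is NaN (flagged unavailable).
        """
        coefs = np.vstack([m.coef for m in self.members])
        mean = coefs.mean(axis=0)
        if len(self.members) >= 2:
            se = coefs.std(axis=0, ddof=1) / np.sqrt(len(self.members))
        else:
            se = np.full(mean.shape, np.nan)
        out = pd.DataFrame(
            {"mean_coef": mean, "se": se}, index=list(self.feature_names)
        )
        return out.reindex(out["mean_coef"].abs().sort_values(ascending=False).index)

    def training_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "member": range(len(self.members)),
                "train_auc": [m.train_auc for m in self.members],
                "oob_auc": [m.oob_auc for m in self.members],
                "n_oob": [m.n_oob for m in self.members],
            }
        )

    def mean_oob_auc(self) -> tuple[float, float]:
        """Mean out-of-bag AUC across members and its SE (sd/sqrt(m))."""
        aucs = np.array([m.oob_auc for m in self.members if np.isfinite(m.oob_auc)])
        if len(aucs) == 0:
            return float("nan"), float("nan")
        se = aucs.std(ddof=1) / np.sqrt(len(aucs)) if len(aucs) > 1 else float("nan")
        return float(aucs.mean()), float(se)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "schema_version": self.schema_version,
            "feature_names": list(self.feature_names),
            "positive_label": self.positive_label,
            "label_set": list(self.label_set),
            "config": asdict(self.config) if self.config else None,
            "provenance": self.provenance,
            "members": [
                {
                    "intercept": m.intercept,
                    "coef": m.coef.tolist(),
                    "means": m.means.tolist(),
                    "sds": m.sds.tolist(),
                    "train_auc": m.train_auc,
                    "oob_auc": m.oob_auc,
                    "n_oob": m.n_oob,
                }
                for m in self.members
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def from_dict(cls, data: dict) -> "EnsembleModel":
        if data.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {data.get('format_version')!r}")
        members = [
            EnsembleMember(
                intercept=float(m["intercept"]),
                coef=np.asarray(m["coef"], dtype=float),
                means=np.asarray(m["means"], dtype=float),
                sds=np.asarray(m["sds"], dtype=float),
                train_auc=float(m["train_auc"]),
                oob_auc=float(m["oob_auc"]),
                n_oob=int(m["n_oob"]),
            )
            for m in data["members"]
        ]
        cfg = TrainingConfig(**data["config"]) if data.get("config") else None
        return cls(
            members=members,
            positive_label=data["positive_label"],
            label_set=tuple(data["label_set"]),
            feature_names=tuple(data["feature_names"]),
            schema_version=data["schema_version"],
            config=cfg,
            provenance=data.get("provenance", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EnsembleModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def _safe_auc(y: np.ndarray, scores: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, scores))


def train(
    corpus: Corpus,
    cfg: TrainingConfig,
    features: pd.DataFrame | None = None,
) -> EnsembleModel:
    """Train the bootstrap logistic ensemble on a labeled corpus.

    ``features`` may be supplied to avoid re-extraction (it must align row
    for row with ``corpus.posts``); otherwise the default dictionary is
    used. Posts below ``cfg.min_words`` words are excluded first. Each
    bootstrap round draws a balanced subset without replacement (within the
    round), standardizes on that subset, fits, and records in-subset
    (training) and out-of-bag AUC.
    """
    if cfg.positive_label not in corpus.label_set:
        raise ValueError(
            f"positive_label {cfg.positive_label!r} not in label set {corpus.label_set}"
        )
    if features is None:
        features = corpus.features()
    if len(features) != len(corpus.posts):
        raise ValueError("features must align row-for-row with corpus.posts")

    labeled = corpus.posts["label"].isin(corpus.label_set).to_numpy()
    long_enough = (corpus.posts["word_count"] >= cfg.min_words).to_numpy()
    keep = labeled & long_enough
    X = features.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)[keep]
    y = (corpus.posts["label"].to_numpy()[keep] == cfg.positive_label).astype(int)

    counts = {lab: int((corpus.posts["label"].to_numpy()[keep] == lab).sum()) for lab in corpus.label_set}
    absent = [lab for lab, n in counts.items() if n == 0]
    if absent:
        raise ValueError(f"label(s) {absent} absent after filtering at {cfg.min_words} words")
    if min(counts.values()) < 2:
        raise ValueError(f"need at least 2 posts per label, got {counts}")

    half = cfg.subset_size // 2
    n_min = min(counts.values())
    if cfg.balanced and half > n_min:
        warnings.warn(
            f"subset_size/2={half} exceeds the smaller class ({n_min} posts); "
            f"shrinking to {n_min} per label",
            stacklevel=2,
        )
        half = n_min

    # draw by corpus label order (not positive/negative) so that swapping
    # positive_label yields the same subsets with flipped outcomes
    labels_kept = corpus.posts["label"].to_numpy()[keep]
    a_idx = np.flatnonzero(labels_kept == corpus.label_set[0])
    b_idx = np.flatnonzero(labels_kept == corpus.label_set[1])
    members: list[EnsembleMember] = []
    for s in range(cfg.n_subsets):
        rng = np.random.default_rng([cfg.seed, s])
        if cfg.balanced:
            idx = np.concatenate(
                [
                    rng.choice(a_idx, size=half, replace=False),
                    rng.choice(b_idx, size=half, replace=False),
                ]
            )
        else:
            size = min(cfg.subset_size, len(y))
            idx = rng.choice(len(y), size=size, replace=False)
        members.append(_fit_member(X, y, idx, cfg))

    return EnsembleModel(
        members=members,
        positive_label=cfg.positive_label,
        label_set=corpus.label_set,
        config=cfg,
        provenance={
            "n_posts_used": int(keep.sum()),
            "label_counts": counts,
            "subset_half": half,
        },
    )


def _fit_member(X: np.ndarray, y: np.ndarray, idx: np.ndarray, cfg: TrainingConfig) -> EnsembleMember:
    Xs, ys = X[idx], y[idx]
    means = Xs.mean(axis=0)
    sds = Xs.std(axis=0, ddof=0)
    mask = sds > 0
    Z = (Xs[:, mask] - means[mask]) / sds[mask]

    # C=inf is plain (unpenalized) maximum likelihood
    C = cfg.l2_C if cfg.l2_C is not None else np.inf
    clf = LogisticRegression(C=C, max_iter=cfg.max_iter, tol=cfg.tol)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*onverge.*")
        clf.fit(Z, ys)

    coef = np.zeros(N_FEATURES)
    coef[mask] = clf.coef_[0]
    sds_out = np.where(mask, sds, 0.0)
    member = EnsembleMember(
        intercept=float(clf.intercept_[0]),
        coef=coef,
        means=means,
        sds=sds_out,
        train_auc=float("nan"),
        oob_auc=float("nan"),
        n_oob=0,
    )
    member.train_auc = _safe_auc(ys, member.predict_proba(Xs))
    oob = np.setdiff1d(np.arange(len(y)), idx, assume_unique=False)
    if len(oob):
        member.oob_auc = _safe_auc(y[oob], member.predict_proba(X[oob]))
        member.n_oob = int(len(oob))
    return member


def permute_labels(corpus: Corpus, seed: int) -> Corpus:
    """Randomly permute the identity labels of the labeled posts.

    Used for null-calibration checks: a classifier trained on permuted
    labels should score at chance (AUC 0.5) out of bag.
    """
    rng = np.random.default_rng(seed)
    posts = corpus.posts.copy()
    labeled = posts["label"].isin(corpus.label_set).to_numpy()
    values = posts.loc[labeled, "label"].to_numpy()
    posts.loc[labeled, "label"] = rng.permutation(values)
    return Corpus(posts=posts, label_set=corpus.label_set, provenance=dict(corpus.provenance))
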