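"""Alternating-decision-tree MAE classifier, MaGIC filters and dataset QC.

The classifier is a boosted alternating decision tree (ADTree) over two
features, the H3K27me3 and H3K36me3 gene-body quantile ranks.  An ADTree
consists of a root prediction value plus an ordered list of splitter nodes;
each node carries a precondition (a path of earlier decisions), a threshold
condition on one feature, and a prediction value for each branch.  A gene's
score is the root prediction plus the prediction values of every node whose
precondition it satisfies; the sign of the score gives the class (MAE on
strictly positive scores).  Training follows the boosting construction: at
each round the (precondition, condition) pair minimizing

    Z = 2*(sqrt(W+(p&c) W-(p&c)) + sqrt(W+(p&~c) W-(p&~c))) + W(~p)

is added, with prediction values 0.5*ln((W+ + 1)/(W- + 1)) on each branch
(the +1 smoothing bounds predictions on pure nodes), and example weights are
multiplied by exp(-y * prediction).

After classification, the MaGIC filters remove genes whose chromatin
signature is unreliable: genes shorter than 2.5 kb and genes below median
expression.  A dataset-level QC requires sufficient dynamic range of the two
marks before any calls are made.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from magic_mae.gene_body_signal import QRANK_SCALE_TAG

logger = logging.getLogger(__name__)

FEATURES = ("k27_qrank", "k36_qrank")

MODEL_FORMAT_VERSION = 1


class QcError(RuntimeError):
    """Raised when a dataset fails the dynamic-range QC and force is off."""


@dataclass(frozen=True)
class ADTreeNode:
    """One splitter: precondition path, feature <= threshold, two predictions."""

    node_id: int
    precondition: tuple[tuple[int, bool], ...]  # ((node_id, branch), ...)
    feature: int  # index into FEATURES
    threshold: float
    pred_true: float
    pred_false: float


@dataclass
class QcResult:
    n_low27_high36: int
    n_high27_low36: int
    n_low27_low36: int
    n_high27_high36: int

    @property
    def passed(self) -> bool:
        favorable = self.n_low27_high36 + self.n_high27_low36
        unfavorable = self.n_low27_low36 + self.n_high27_high36
        return favorable >= 1.5 * unfavorable

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            self.n_low27_high36,
            self.n_high27_low36,
            self.n_low27_low36,
            self.n_high27_high36,
        )


def _log_odds(w_pos: float, w_neg: float) -> float:
    return 0.5 * np.log((w_pos + 1.0) / (w_neg + 1.0))


class ADTreeClassifier(ClassifierMixin, BaseEstimator):
    """Alternating decision tree classifier (two-class boosting).

    Parameters
    ----------
    n_boost : int, default 10
        Number of boosting rounds, i.e. maximum number of splitter nodes.
    feature_scale_tag : str
        Tag recording the feature scale the model was trained on; models are
        refused at prediction time if applied to features on another scale.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels; the MAE (positive) class is ``positive_class_``.
    root_prediction_ : float
    nodes_ : list of ADTreeNode
    weight_sums_ : list of float
        Total example weight after initialization and after every boosting
        round; non-increasing by construction.
    """

    def __init__(self, n_boost: int = 10, feature_scale_tag: str = QRANK_SCALE_TAG):
        self.n_boost = n_boost
        self.feature_scale_tag = feature_scale_tag

    # -- training ----------------------------------------------------------

    def fit(self, X, y):
        if self.n_boost < 1:
            raise ValueError(f"n_boost must be >= 1, got {self.n_boost}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(
                f"training set must contain exactly 2 classes, got {list(classes)}"
            )
        self.classes_ = classes
        self.positive_class_ = "MAE" if "MAE" in classes else classes[1]
        self.n_features_in_ = X.shape[1]
        ypm = np.where(y == self.positive_class_, 1.0, -1.0)

        w = np.ones(X.shape[0])
        self.weight_sums_ = [float(w.sum())]
        wp, wn = w[ypm > 0].sum(), w[ypm < 0].sum()
        self.root_prediction_ = float(_log_odds(wp, wn))
        w *= np.exp(-ypm * self.root_prediction_)
        self.weight_sums_.append(float(w.sum()))

        # preconditions: list of (path, boolean mask over samples)
        preconds: list[tuple[tuple, np.ndarray]] = [
            ((), np.ones(X.shape[0], dtype=bool))
        ]
        self.nodes_: list[ADTreeNode] = []
        pos = ypm > 0

        for round_no in range(1, self.n_boost + 1):
            w_total = w.sum()
            best = None  # (Z, pre_idx, feat, threshold)
            no_split_z = np.inf
            for pre_idx, (_, mask) in enumerate(preconds):
                w_notp = w_total - w[mask].sum()
                wp_p = w[mask & pos].sum()
                wn_p = w[mask & ~pos].sum()
                no_split_z = min(no_split_z, 2.0 * np.sqrt(wp_p * wn_p) + w_notp)
                for feat in range(X.shape[1]):
                    z, thr = self._best_threshold(
                        X[mask, feat], w[mask], pos[mask], w_notp
                    )
                    if thr is not None and (best is None or z < best[0] - 1e-15):
                        best = (z, pre_idx, feat, thr)
            if best is None or best[0] >= no_split_z - 1e-12:
                logger.info(
                    "boosting stopped at round %d: no split improves Z", round_no
                )
                break
            z, pre_idx, feat, thr = best
            path, mask = preconds[pre_idx]
            cond = X[:, feat] <= thr
            m_true = mask & cond
            m_false = mask & ~cond
            pred_true = _log_odds(w[m_true & pos].sum(), w[m_true & ~pos].sum())
            pred_false = _log_odds(w[m_false & pos].sum(), w[m_false & ~pos].sum())
            node = ADTreeNode(
                node_id=round_no,
                precondition=path,
                feature=feat,
                threshold=float(thr),
                pred_true=float(pred_true),
                pred_false=float(pred_false),
            )
            self.nodes_.append(node)
            w[m_true] *= np.exp(-ypm[m_true] * pred_true)
            w[m_false] *= np.exp(-ypm[m_false] * pred_false)
            self.weight_sums_.append(float(w.sum()))
            preconds.append((path + ((round_no, True),), m_true))
            preconds.append((path + ((round_no, False),), m_false))
        return self

    @staticmethod
    def _best_threshold(x, w, pos, w_notp):
        """Best Z over midpoint thresholds of the masked feature values."""
        if x.size == 0:
            return np.inf, None
        order = np.argsort(x, kind="mergesort")
        xs = x[order]
        ws = w[order]
        wpos = np.where(pos[order], ws, 0.0)
        wneg = np.where(~pos[order], ws, 0.0)
        cp = np.cumsum(wpos)
        cn = np.cumsum(wneg)
        # candidate cut after position i where xs[i] < xs[i+1]
        cuts = np.nonzero(xs[:-1] < xs[1:])[0]
        if cuts.size == 0:
            return np.inf, None
        wp_c, wn_c = cp[cuts], cn[cuts]
        wp_nc, wn_nc = cp[-1] - wp_c, cn[-1] - wn_c
        z = 2.0 * (np.sqrt(wp_c * wn_c) + np.sqrt(wp_nc * wn_nc)) + w_notp
        i = int(np.argmin(z))
        thr = 0.5 * (xs[cuts[i]] + xs[cuts[i] + 1])
        return float(z[i]), float(thr)

    # -- prediction --------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """ADTree score: root prediction + predictions of all satisfied nodes."""
        check_is_fitted(self, "root_prediction_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        cond = np.empty((n, len(self.nodes_)), dtype=bool)
        for j, node in enumerate(self.nodes_):
            cond[:, j] = X[:, node.feature] <= node.threshold
        scores = np.full(n, self.root_prediction_)
        for j, node in enumerate(self.nodes_):
            sat = np.ones(n, dtype=bool)
            for node_id, branch in node.precondition:
                sat &= cond[:, node_id - 1] == branch
            scores[sat] += np.where(cond[sat, j], node.pred_true, node.pred_false)
        return scores

    def predict(self, X) -> np.ndarray:
        """MAE on strictly positive score; a score of exactly 0 is BAE."""
        scores = self.decision_function(X)
        neg = self.classes_[self.classes_ != self.positive_class_][0]
        return np.where(scores > 0, self.positive_class_, neg)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "root_prediction_")
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "model": "adtree",
            "n_boost": self.n_boost,
            "feature_scale_tag": self.feature_scale_tag,
            "features": list(FEATURES[: self.n_features_in_]),
            "classes": [str(c) for c in self.classes_],
            "positive_class": str(self.positive_class_),
            "root_prediction": self.root_prediction_,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "precondition": [[i, b] for i, b in n.precondition],
                    "feature": FEATURES[n.feature],
                    "threshold": n.threshold,
                    "pred_true": n.pred_true,
                    "pred_false": n.pred_false,
                }
                for n in self.nodes_
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ADTreeClassifier":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        model = cls(n_boost=d["n_boost"], feature_scale_tag=d["feature_scale_tag"])
        model.classes_ = np.array(d["classes"])
        model.positive_class_ = d["positive_class"]
        model.n_features_in_ = len(d["features"])
        model.root_prediction_ = float(d["root_prediction"])
        model.nodes_ = [
            ADTreeNode(
                node_id=n["node_id"],
                precondition=tuple((int(i), bool(b)) for i, b in n["precondition"]),
                feature=FEATURES.index(n["feature"]),
                threshold=float(n["threshold"]),
                pred_true=float(n["pred_true"]),
                pred_false=float(n["pred_false"]),
            )
            for n in d["nodes"]
        ]
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "ADTreeClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# module-level operations (thin wrappers over the estimator)


def train_adtree(training: pd.DataFrame, n_boost: int = 10) -> ADTreeClassifier:
    """Train an ADTree on a labeled table (k27_qrank, k36_qrank, label)."""
    X = training[["k27_qrank", "k36_qrank"]].to_numpy(float)
    return ADTreeClassifier(n_boost=n_boost).fit(X, training["label"].to_numpy())


def classify(model: ADTreeClassifier, features: pd.DataFrame) -> pd.DataFrame:
    """Score each gene and call MAE (score > 0) or BAE."""
    if model.feature_scale_tag != QRANK_SCALE_TAG:
        raise ValueError(
            f"model feature scale {model.feature_scale_tag!r} does not match "
            f"the feature table scale {QRANK_SCALE_TAG!r}"
        )
    missing = features[["k27_qrank", "k36_qrank"]].isna().any(axis=1)
    if missing.any():
        logger.warning("%d genes with missing features skipped", int(missing.sum()))
    feats = features.loc[~missing]
    scores = model.decision_function(feats[["k27_qrank", "k36_qrank"]].to_numpy(float))
    return pd.DataFrame(
        {
            "gene_id": feats["gene_id"].to_numpy(),
            "score": scores,
            "call": np.where(scores > 0, "MAE", "BAE"),
        }
    )


def apply_filters(
    calls: pd.DataFrame,
    features: pd.DataFrame,
    min_length_bp: int = 2500,
    expr_qrank_threshold: float = 0.5,
) -> pd.DataFrame:
    """Apply the post-classification MaGIC filters.

    Genes shorter than ``min_length_bp`` (chromatin signature unreliable) are
    marked short_gene; genes below median expression (expr_qrank < 0.5,
    inclusive keep at exactly the median) are marked low_expression.  Other
    genes keep their classifier call as final_call; filtered genes become
    not_assessed.
    """
    merged = calls.merge(
        features[["gene_id", "length_bp", "expr_qrank"]], on="gene_id", how="left"
    )
    filtered = np.where(
        merged["length_bp"] < min_length_bp,
        "short_gene",
        np.where(merged["expr_qrank"] < expr_qrank_threshold, "low_expression", "kept"),
    )
    out = merged[["gene_id", "score", "call"]].copy()
    out["filtered"] = filtered
    out["final_call"] = np.where(filtered == "kept", merged["call"], "not_assessed")
    return out


def qc_dynamic_range(features: pd.DataFrame) -> QcResult:
    """Dataset dynamic-range QC on the two marks.

    Genes are split into four groups at the median normalized enrichment of
    each mark; the dataset passes when the two anti-correlated groups
    (low27/high36 and high27/low36) outnumber the two remaining groups by at
    least 50%.
    """
    if len(features) < 4:
        raise ValueError("QC requires at least 4 genes")
    k27 = features["k27_norm"].to_numpy(float)
    k36 = features["k36_norm"].to_numpy(float)
    hi27 = k27 > np.median(k27)
    hi36 = k36 > np.median(k36)
    return QcResult(
        n_low27_high36=int(np.sum(~hi27 & hi36)),
        n_high27_low36=int(np.sum(hi27 & ~hi36)),
        n_low27_low36=int(np.sum(~hi27 & ~hi36)),
        n_high27_high36=int(np.sum(hi27 & hi36)),
    )


def run_magic(
    features: pd.DataFrame,
    model: ADTreeClassifier,
    min_length_bp: int = 2500,
    expr_qrank_threshold: float = 0.5,
    force: bool = False,
) -> tuple[pd.DataFrame, QcResult]:
    """Full MaGIC pipeline: QC gate, classify, filter.

    Refuses to produce calls on a dataset that fails the dynamic-range QC
    unless ``force`` is set (a warning is emitted in that case).
    """
    qc = qc_dynamic_range(features)
    if not qc.passed:
        msg = (
            "dataset failed dynamic-range QC: counts "
            f"(low27/high36={qc.n_low27_high36}, high27/low36={qc.n_high27_low36}, "
            f"low27/low36={qc.n_low27_low36}, high27/high36={qc.n_high27_high36})"
        )
        if not force:
            raise QcError(msg)
        logger.warning("%s — proceeding because force=True", msg)
    calls = apply_filters(
        classify(model, features),
        features,
        min_length_bp=min_length_bp,
        expr_qrank_threshold=expr_qrank_threshold,
    )
    summary = calls["final_call"].value_counts()
    logger.info(
        "MaGIC calls: %d MAE, %d BAE, %d filtered",
        summary.get("MAE", 0),
        summary.get("BAE", 0),
        summary.get("not_assessed", 0),
    )
    return calls, qc
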