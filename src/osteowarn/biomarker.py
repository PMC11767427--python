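"""Random-forest biomarker selection and paired AUC comparison.

Control-vs-osteopenia classification: a 70/30 stratified split, a first
forest on the candidate (differential) metabolites, selection of features
whose normalized impurity importance reaches the threshold (default 5%),
a second forest on the selected panel, and test-set ROC/AUC with a
DeLong variance-based 95% CI.  Competing panels scored on the identical
test samples are compared with DeLong's paired AUC test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

N_TREES = 500  # conventional forest size; sqrt(p) features per split, no depth limit


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong AUC estimates and covariance for k correlated classifiers.

    ``scores`` is (k, n); returns (aucs shape (k,), covariance (k, k)).
    """
    y_true = np.asarray(y_true)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    pos = scores[:, y_true == 1]
    neg = scores[:, y_true == 0]
    m, n = pos.shape[1], neg.shape[1]
    if m == 0 or n == 0:
        raise ValueError("both outcome classes must be present")
    k = scores.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    sx = np.cov(v01) if m > 1 else np.zeros((k, k))
    sy = np.cov(v10) if n > 1 else np.zeros((k, k))
    cov = np.atleast_2d(sx) / m + np.atleast_2d(sy) / n
    return aucs, cov


def delong_auc_ci(y_true, scores, level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong variance-based Wald confidence interval."""
    aucs, cov = _delong(np.asarray(y_true), np.asarray(scores)[None, :])
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    return float(aucs[0]), max(0.0, aucs[0] - zq * se), min(1.0, aucs[0] + zq * se)


def delong_paired_test(y_true, scores_a, scores_b) -> tuple[float, float, float]:
    """Paired DeLong test for two classifiers on the same test samples.

    Returns (delta_auc = AUC_a - AUC_b, z, two-sided p).
    """
    scores = np.vstack([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    aucs, cov = _delong(np.asarray(y_true), scores)
    delta = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        return delta, 0.0, 1.0
    z = delta / np.sqrt(var)
    return delta, float(z), float(2 * stats.norm.sf(abs(z)))


def split_train_test(
    labels: pd.Series, fraction: float = 0.70, seed: int = 0
) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified split: round(fraction * n) per class."""
    classes = labels.unique()
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in sorted(map(str, classes)):
        ids = labels.index[labels.astype(str) == c].to_numpy()
        if len(ids) < 4:
            raise ValueError(f"class {c!r} has {len(ids)} samples; need >= 4")
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        train.extend(ids[perm[:n_train]])
        test.extend(ids[perm[n_train:]])
    return pd.Index(train), pd.Index(test)


@dataclass
class BiomarkerPanel:
    """Selected metabolites with importances and test-set performance."""

    selected: list[str]
    importance_pct: pd.Series      # over all candidate features, sums to 100
    train_ids: pd.Index
    test_ids: pd.Index
    roc: pd.DataFrame              # fpr, tpr, threshold
    auc: float
    auc_ci: tuple[float, float]
    test_scores: pd.Series         # P(class 1) on the test samples
    y_test: pd.Series
    fallback: bool = False


def train_select_retrain(
    x: pd.DataFrame,
    y: pd.Series,
    threshold: float = 0.05,
    seed: int = 0,
    fraction: float = 0.70,
    train_ids: pd.Index | None = None,
    test_ids: pd.Index | None = None,
    n_trees: int = N_TREES,
) -> BiomarkerPanel:
    """Forest -> importance cut -> retrained forest -> test ROC/AUC.

    ``threshold`` is the minimum normalized importance share (0.05 = 5%)
    over all candidate features.  If nothing reaches it, the top 3
    features are kept with a logged warning.  Selection sees training
    data only; test labels are touched only for the final evaluation.
    """
    if x.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    y = y.loc[x.index]
    if train_ids is None or test_ids is None:
        train_ids, test_ids = split_train_test(y, fraction=fraction, seed=seed)
    if len(pd.Index(train_ids).intersection(test_ids)):
        raise ValueError("train and test sets overlap")

    rf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                random_state=seed)
    rf.fit(x.loc[train_ids], y.loc[train_ids])
    shares = pd.Series(rf.feature_importances_ * 100.0, index=x.columns)
    selected = shares.index[shares >= threshold * 100.0].tolist()
    fallback = False
    if not selected:
        selected = shares.sort_values(ascending=False).index[:3].tolist()
        fallback = True
        logger.warning("no feature reached the %.0f%% importance cut; "
                       "falling back to the top 3", threshold * 100)

    rf2 = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 random_state=seed + 1)
    rf2.fit(x.loc[train_ids, selected], y.loc[train_ids])
    pos = rf2.classes_[-1]
    probs = rf2.predict_proba(x.loc[test_ids, selected])[:, -1]
    y_test = (y.loc[test_ids] == pos).astype(int)
    fpr, tpr, thr = roc_curve(y_test, probs)
    auc, lo, hi = delong_auc_ci(y_test.to_numpy(), probs)
    return BiomarkerPanel(
        selected=selected,
        importance_pct=shares,
        train_ids=pd.Index(train_ids),
        test_ids=pd.Index(test_ids),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        auc=auc,
        auc_ci=(lo, hi),
        test_scores=pd.Series(probs, index=test_ids, name="score"),
        y_test=y_test,
        fallback=fallback,
    )


def compare_auc(panel_a: BiomarkerPanel, panel_b: BiomarkerPanel) -> tuple[float, float, float]:
    """DeLong paired AUC comparison of two panels on the same test set.

    Returns (delta_auc, z, two-sided p); errors if the test sets differ.
    """
    if set(panel_a.test_ids) != set(panel_b.test_ids):
        raise ValueError("panels were scored on different test samples")
    ids = panel_a.test_ids
    y = panel_a.y_test.loc[ids]
    if not y.equals(panel_b.y_test.loc[ids]):
        raise ValueError("panels disagree on test labels")
    return delong_paired_test(
        y.to_numpy(),
        panel_a.test_scores.loc[ids].to_numpy(),
        panel_b.test_scores.loc[ids].to_numpy(),
    )
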