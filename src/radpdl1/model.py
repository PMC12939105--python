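"""Training-only standardization, LASSO selection, and the confidence-gated
self-training loop around the feature-tokenizer transformer.

Leakage discipline is the organizing principle: the standardizer, the LASSO
support and every decision threshold are fitted on training rows only and
frozen; pseudo-labels are drawn from a pool whose patient ids are checked to
be disjoint from both the labeled training set and any test set, and a
violation is a hard error rather than a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

from .nn import FTTransformer, FTTransformerConfig

logger = logging.getLogger(__name__)

DEFAULT_GATE = (0.2, 0.8)


# ----------------------------------------------------------------- split

def split_cohort(patient_ids, labels, train_fraction: float = 0.8,
                 seed: int = 0) -> tuple[list, list]:
    """Patient-level stratified train/test split.

    Returns disjoint id lists with per-class sizes within rounding of the
    requested fraction.
    """
    ids = np.asarray(patient_ids)
    y = np.asarray(labels).astype(int)
    if ids.size != y.size:
        raise ValueError("ids and labels must align")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        members = ids[y == cls]
        if members.size < 2:
            raise ValueError(f"class {cls} has fewer than 2 patients")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    assert not set(train) & set(test)
    return train, test


# ----------------------------------------------------------- standardizer

@dataclass
class Standardizer:
    """Per-feature affine map to zero mean / unit SD, fitted on train rows.

    Constant columns (SD = 0) are dropped with a logged warning; the kept
    column names are recorded so application is by-name and order-stable.
    """

    mean_: np.ndarray = field(default=None)
    sd_: np.ndarray = field(default=None)
    columns_: list[str] = field(default=None)

    def fit(self, X: pd.DataFrame) -> "Standardizer":
        if len(X) < 2:
            raise ValueError("need at least 2 training rows")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        # tolerance catches float-representation jitter of constant columns
        keep = sd > 1e-10 * (mean.abs() + 1.0)
        dropped = list(X.columns[~keep])
        if dropped:
            logger.warning("dropping %d constant feature(s): %s",
                           len(dropped), dropped[:5])
        self.columns_ = list(X.columns[keep])
        self.mean_ = mean[keep].to_numpy()
        self.sd_ = sd[keep].to_numpy()
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("standardizer is not fitted")
        missing = set(self.columns_) - set(X.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)[:5]}")
        Z = (X[self.columns_].to_numpy(dtype=np.float64) - self.mean_) / self.sd_
        return pd.DataFrame(Z, index=X.index, columns=self.columns_)


# ----------------------------------------------------------------- LASSO

@dataclass
class LassoSelection:
    lambda_grid: np.ndarray
    chosen_lambda: float
    support: list[str]
    coefficients: pd.Series
    cv_deviance: np.ndarray


def lasso_select(train_X: pd.DataFrame, train_y, n_folds: int = 5,
                 seed: int = 0, n_lambdas: int = 30) -> LassoSelection:
    """L1-penalized logistic selection with per-lambda cross-validation.

    The penalty grid is log-spaced from the smallest lambda that zeroes
    every coefficient down by three decades.  The chosen lambda is the
    largest one whose mean CV binomial deviance is within one standard
    error of the minimum (the standard parsimony rule; exact ties also
    resolve toward the larger, sparser lambda).  Folds are drawn from
    training rows only.
    """
    y = np.asarray(train_y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are all one class")
    X = train_X.to_numpy(dtype=np.float64)
    n = X.shape[0]

    # lambda_max: smallest penalty with empty support (standard KKT bound)
    pbar = y.mean()
    lam_max = np.abs(X.T @ (y - pbar)).max() / n
    lambda_grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_dev = np.zeros((n_folds, n_lambdas))
    for f, (tr, va) in enumerate(skf.split(X, y)):
        for i, lam in enumerate(lambda_grid):
            clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                     C=1.0 / (lam * len(tr)),
                                     max_iter=2000, random_state=seed)
            clf.fit(X[tr], y[tr])
            p = clf.predict_proba(X[va])[:, 1]
            fold_dev[f, i] = log_loss(y[va], p, labels=[0, 1])
    deviance = fold_dev.mean(axis=0)
    se = fold_dev.std(axis=0, ddof=1) / np.sqrt(n_folds)

    best = int(deviance.argmin())
    # largest lambda within one SE of the minimum (grid is descending)
    chosen_idx = int(np.flatnonzero(
        deviance <= deviance[best] + se[best])[0])
    lam = float(lambda_grid[chosen_idx])

    final = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                               C=1.0 / (lam * n), max_iter=5000,
                               random_state=seed)
    final.fit(X, y)
    coef = pd.Series(final.coef_.ravel(), index=train_X.columns)
    support = list(coef.index[coef != 0])
    logger.info("LASSO selected %d/%d features at lambda=%.4g",
                len(support), X.shape[1], lam)
    return LassoSelection(lambda_grid, lam, support, coef[coef != 0],
                          deviance)


# --------------------------------------------------------- trained model

def save_model(model: "TrainedModel", path) -> None:
    """Serialize a trained model (weights + standardizer + selection +
    config + threshold) into one checkpoint file."""
    import pickle
    from pathlib import Path
    with Path(path).open("wb") as fh:
        pickle.dump(model, fh)


def load_model(path) -> "TrainedModel":
    import pickle
    from pathlib import Path
    with Path(path).open("rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, TrainedModel):
        raise ValueError(f"{path} is not a radpdl1 model checkpoint")
    return model

@dataclass
class PseudoLabelSet:
    ids: list
    labels: np.ndarray
    confidences: np.ndarray
    tau_lo: float
    tau_hi: float

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class TrainedModel:
    """Everything needed to score a new lesion's feature vector.

    The probabilistic output of ``predict_scores`` is the rad-PDL1 score.
    """

    standardizer: Standardizer
    selection: LassoSelection
    net: FTTransformer
    decision_threshold: float = 0.5
    pseudo_label_record: PseudoLabelSet | None = None

    def predict_scores(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.standardizer.transform(X)
        return self.net.predict_proba(Z[self.selection.support].to_numpy())

    def predict_class(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_scores(X) >= self.decision_threshold).astype(int)


def train_supervised(train_X: pd.DataFrame, train_y,
                     config: FTTransformerConfig = FTTransformerConfig(),
                     standardizer: Standardizer | None = None,
                     selection: LassoSelection | None = None) -> TrainedModel:
    """Standardize -> LASSO-select -> train the transformer on labeled rows.

    A pre-fitted standardizer/selection pair (e.g. from an earlier stage of
    the same run) is reused as-is; otherwise both are fitted here, on the
    supplied training rows only.
    """
    y = np.asarray(train_y).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 8:
        warnings.warn("fewer than 8 patients in a class; training may be "
                      "unstable", stacklevel=2)
    if standardizer is None:
        standardizer = Standardizer().fit(train_X)
    Z = standardizer.transform(train_X)
    if selection is None:
        selection = lasso_select(Z, y, seed=config.seed)
    support = selection.support
    if not support:
        raise ValueError("LASSO selected no features; signal too weak for "
                         "the transformer stage")
    net = FTTransformer(len(support), config)
    net.fit(Z[support].to_numpy(), y)
    return TrainedModel(standardizer, selection, net)


def pseudo_label(model: TrainedModel, unlabeled_X: pd.DataFrame,
                 tau_lo: float = DEFAULT_GATE[0],
                 tau_hi: float = DEFAULT_GATE[1]) -> PseudoLabelSet:
    """Confidence-gated pseudo-labels for an unlabeled pool.

    Instances scored at or below ``tau_lo`` get label 0, at or above
    ``tau_hi`` get label 1; the band in between (the neighbourhood of the
    decision boundary, where classifier errors concentrate) is discarded.
    """
    if not tau_lo < 0.5 < tau_hi:
        raise ValueError("gate must satisfy tau_lo < 0.5 < tau_hi")
    scores = model.predict_scores(unlabeled_X)
    keep = (scores <= tau_lo) | (scores >= tau_hi)
    ids = list(np.asarray(unlabeled_X.index)[keep])
    labels = (scores[keep] >= tau_hi).astype(int)
    return PseudoLabelSet(ids, labels, scores[keep], tau_lo, tau_hi)


def self_train(labeled_X: pd.DataFrame, labeled_y,
               unlabeled_X: pd.DataFrame,
               config: FTTransformerConfig = FTTransformerConfig(),
               tau_lo: float = DEFAULT_GATE[0],
               tau_hi: float = DEFAULT_GATE[1],
               test_ids=None,
               fine_tune_lr_factor: float = 0.1,
               pseudo_weight: float = 1.0,
               n_rounds: int = 1) -> TrainedModel:
    """Self-training: supervised fit, pseudo-label, fine-tune.

    One round by default; ``n_rounds > 1`` repeats the pseudo-label +
    fine-tune step with the pool re-scored by the updated model.
    ``test_ids`` (if given) are held-out patients; any overlap between them
    or the labeled ids and the unlabeled pool raises immediately.  With an
    empty pool (or an empty gate result) the supervised model is returned
    unchanged.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    lab_ids = set(labeled_X.index)
    unlab_ids = set(unlabeled_X.index)
    overlap = lab_ids & unlab_ids
    if overlap:
        raise ValueError(f"unlabeled pool overlaps labeled ids: "
                         f"{sorted(overlap)[:5]}")
    if test_ids is not None:
        overlap = set(test_ids) & unlab_ids
        if overlap:
            raise ValueError(f"unlabeled pool overlaps test ids: "
                             f"{sorted(overlap)[:5]} (leakage)")
        overlap = set(test_ids) & lab_ids
        if overlap:
            raise ValueError(f"labeled training set overlaps test ids: "
                             f"{sorted(overlap)[:5]} (leakage)")

    model = train_supervised(labeled_X, labeled_y, config)
    if len(unlabeled_X) == 0:
        return model

    y = np.asarray(labeled_y).astype(int)
    Z_lab = model.standardizer.transform(labeled_X)[model.selection.support]
    for _ in range(n_rounds):
        pseudo = pseudo_label(model, unlabeled_X, tau_lo, tau_hi)
        model.pseudo_label_record = pseudo
        if len(pseudo) == 0:
            logger.info("confidence gate kept no pseudo-labels; returning "
                        "the supervised model")
            return model
        Z_pse = model.standardizer.transform(
            unlabeled_X.loc[pseudo.ids])[model.selection.support]
        X_all = np.vstack([Z_lab.to_numpy(), Z_pse.to_numpy()])
        y_all = np.concatenate([y, pseudo.labels])
        w_all = np.concatenate([np.ones(len(y)),
                                np.full(len(pseudo), pseudo_weight)])
        model.net.fit(X_all, y_all, sample_weight=w_all,
                      learning_rate=(config.learning_rate
                                     * fine_tune_lr_factor),
                      reset=False)
    return model
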