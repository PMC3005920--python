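"""RBF-kernel SVM training, cross-validated grid search and evaluation.

Peptide pools are encoded (binary or BFE), an RBF support-vector classifier
is fitted, and (C, gamma) are chosen by stratified k-fold cross-validated
accuracy over a log2 grid.  For the BFE scheme the profile pair is re-built
inside every fold from that fold's training portion only, so the held-out
fold never leaks into the profiles; the final model's profiles come from the
full training set.

Predictions use the raw SVM decision value with the natural sign rule:
score > 0 calls the peptide an epitope.  Reports carry the confusion counts
at that threshold, sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP),
accuracy Acc = (TP+TN)/total (as percentages) and the threshold-independent
area under the ROC curve.  No feature scaling is applied — binary features
are already in {0, 1} and BFE features in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets_io import Peptide, PeptidePool, write_report
from .encoding import BFEProfilePair, build_bfe_profiles, encode_pool, \
    load_profiles, save_profiles

#: Canonical libsvm-guide search grids (log2 steps of 2).
DEFAULT_C_GRID = [2.0 ** e for e in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0 ** e for e in range(-15, 4, 2)]


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyper-parameters.

    C trades margin width against training error; gamma sets the RBF
    kernel's capacity (larger gamma, narrower basis functions).
    """

    C: float = 1.0
    gamma: float = 0.5
    kernel: str = "rbf"
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass
class TrainedModel:
    """A fitted SVM plus everything needed to encode new peptides."""

    clf: SVC
    config: SVMConfig
    scheme: str
    peptide_length: int
    profiles: BFEProfilePair | None = None

    def __post_init__(self) -> None:
        if (self.scheme == "bfe") != (self.profiles is not None):
            raise ValueError("profiles must be present iff scheme is 'bfe'")


@dataclass
class MetricsReport:
    """Confusion counts at threshold 0 and the derived metrics.

    Sn, Sp and Acc are percentages; auroc is in [0, 1] and None when the
    truth vector contains a single class (undefined, never reported as 0).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sn: float
    sp: float
    acc: float
    auroc: float | None

    def to_frame(self) -> pd.DataFrame:
        d = asdict(self)
        d["auroc"] = np.nan if self.auroc is None else self.auroc
        return pd.DataFrame([d])


def _pools_to_xy(pos_pool: PeptidePool, neg_pool: PeptidePool):
    seqs = pos_pool.sequences + neg_pool.sequences
    y = np.array([1] * len(pos_pool) + [0] * len(neg_pool))
    return seqs, y


def _encode_split(seqs: list[str], scheme: str,
                  profiles: BFEProfilePair | None) -> np.ndarray:
    pool = PeptidePool([Peptide(s) for s in seqs])
    return encode_pool(pool, scheme, profiles)


def grid_search_cv(pos_pool: PeptidePool, neg_pool: PeptidePool,
                   scheme: str = "bfe",
                   C_grid: list[float] | None = None,
                   gamma_grid: list[float] | None = None,
                   folds: int = 10, seed: int = 0,
                   pseudocount: float = 0.0) -> tuple[SVMConfig, pd.DataFrame]:
    """Select (C, gamma) maximizing mean cross-validated accuracy.

    Folds are a seeded stratified partition, so every example is held out
    exactly once.  BFE profiles are re-estimated from each fold's training
    portion.  Ties are broken by smallest C, then smallest gamma.  Returns
    the winning config and the full CV results table.
    """
    C_grid = sorted(C_grid or DEFAULT_C_GRID)
    gamma_grid = sorted(gamma_grid or DEFAULT_GAMMA_GRID)
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    if pos_pool.length != neg_pool.length:
        raise ValueError("pool length mismatch")
    seqs, y = _pools_to_xy(pos_pool, neg_pool)
    if len(seqs) < folds:
        raise ValueError(f"{len(seqs)} examples cannot fill {folds} folds")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(seqs)), y))

    # pre-encode per fold once; grid points only re-fit the SVM
    fold_data = []
    for train_idx, test_idx in splits:
        train_seqs = [seqs[i] for i in train_idx]
        test_seqs = [seqs[i] for i in test_idx]
        profiles = None
        if scheme == "bfe":
            profiles = build_bfe_profiles(
                PeptidePool([Peptide(seqs[i]) for i in train_idx if y[i] == 1]),
                PeptidePool([Peptide(seqs[i]) for i in train_idx if y[i] == 0]),
                pseudocount)
        Xtr = _encode_split(train_seqs, scheme, profiles)
        Xte = _encode_split(test_seqs, scheme, profiles)
        fold_data.append((Xtr, y[train_idx], Xte, y[test_idx]))

    rows = []
    best = None  # (acc, C, gamma) with smallest-C/gamma tie-break
    for C in C_grid:
        for gamma in gamma_grid:
            accs = []
            for Xtr, ytr, Xte, yte in fold_data:
                clf = SVC(C=C, gamma=gamma, kernel="rbf")
                clf.fit(Xtr, ytr)
                accs.append(float(np.mean(clf.predict(Xte) == yte)))
            mean_acc = float(np.mean(accs))
            rows.append({"C": C, "gamma": gamma, "cv_accuracy": mean_acc})
            if best is None or mean_acc > best[0] + 1e-12:
                best = (mean_acc, C, gamma)
    results = pd.DataFrame(rows)
    config = SVMConfig(C=best[1], gamma=best[2], cv_folds=folds, seed=seed)
    return config, results


def train(pos_pool: PeptidePool, neg_pool: PeptidePool, scheme: str,
          config: SVMConfig, pseudocount: float = 0.0) -> TrainedModel:
    """Fit the final classifier on the entire training set.

    BFE profiles are built from these training pools only and stored on the
    model for encoding unseen peptides.
    """
    if len(pos_pool) == 0 or len(neg_pool) == 0:
        raise ValueError("training requires examples of both classes")
    if pos_pool.length != neg_pool.length:
        raise ValueError("pool length mismatch")
    profiles = None
    if scheme == "bfe":
        profiles = build_bfe_profiles(pos_pool, neg_pool, pseudocount)
    seqs, y = _pools_to_xy(pos_pool, neg_pool)
    X = _encode_split(seqs, scheme, profiles)
    clf = SVC(C=config.C, gamma=config.gamma, kernel=config.kernel,
              random_state=config.seed)
    clf.fit(X, y)
    return TrainedModel(clf=clf, config=config, scheme=scheme,
                        peptide_length=pos_pool.length, profiles=profiles)


def predict(model: TrainedModel, pool: PeptidePool):
    """Score peptides with the SVM decision function.

    Returns (scores, labels): continuous decision values and the sign-rule
    labels ("positive" iff score > 0).
    """
    if len(pool) and pool.length != model.peptide_length:
        raise ValueError(
            f"peptide length {pool.length} != model length {model.peptide_length}")
    X = encode_pool(pool, model.scheme, model.profiles)
    scores = model.clf.decision_function(X)
    labels = np.where(scores > 0, "positive", "negative")
    return scores, labels


def evaluate(scores: np.ndarray, truth: np.ndarray) -> MetricsReport:
    """Compute the metrics report from decision scores and 0/1 truth.

    Confusion counts use the score > 0 threshold.  AUROC is computed by
    midrank over the continuous scores and is None (not 0) when the truth
    vector has a single class.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    pred = (scores > 0).astype(int)
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    sn = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
    sp = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    acc = 100.0 * (tp + tn) / len(truth)
    auroc = None
    if len(np.unique(truth)) == 2:
        auroc = float(roc_auc_score(truth, scores))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn,
                         sn=sn, sp=sp, acc=acc, auroc=auroc)


def evaluate_pools(model: TrainedModel, pos_pool: PeptidePool,
                   neg_pool: PeptidePool) -> MetricsReport:
    """Predict a labeled positive/negative test pair and report metrics."""
    scores_pos, _ = predict(model, pos_pool)
    scores_neg, _ = predict(model, neg_pool)
    scores = np.concatenate([scores_pos, scores_neg])
    truth = np.array([1] * len(pos_pool) + [0] * len(neg_pool))
    return evaluate(scores, truth)


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Persist as JSON metadata + profile TSVs + classifier blob."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "scheme": model.scheme,
        "peptide_length": model.peptide_length,
        "C": model.config.C,
        "gamma": model.config.gamma,
        "kernel": model.config.kernel,
        "cv_folds": model.config.cv_folds,
        "seed": model.config.seed,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model.clf, directory / "classifier.joblib")
    if model.profiles is not None:
        save_profiles(model.profiles, directory)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    clf = joblib.load(directory / "classifier.joblib")
    profiles = None
    if meta["scheme"] == "bfe":
        profiles = load_profiles(directory)
    config = SVMConfig(C=meta["C"], gamma=meta["gamma"], kernel=meta["kernel"],
                       cv_folds=meta["cv_folds"], seed=meta["seed"])
    return TrainedModel(clf=clf, config=config, scheme=meta["scheme"],
                        peptide_length=meta["peptide_length"], profiles=profiles)


def write_metrics_report(report: MetricsReport, path: str | Path,
                         params: dict | None = None) -> None:
    write_report(report.to_frame(), path, params)
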