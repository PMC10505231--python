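"""Evaluation harness: regression and classification metrics with the
repeated-split protocol.

Slide-level FC predictions are scored with the coefficient of
determination (R^2); the deletion/codeletion calls with ROC AUC,
1000-replicate bootstrap 95% confidence intervals, and confusion-matrix
metrics (accuracy, precision, recall, F1) at the Youden-optimal cutoff.
The full protocol repeats a stratified 60/20/20 train/validation/test
split (Monte-Carlo cross-validation) several times — ten by default — and
reports per-split and averaged metrics.

A note on the split design: disjoint K folds cannot each provide a 20%
validation *and* a 20% test partition, so the repeated-split protocol
draws an independent stratified 60/20/20 split per repetition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .bags import FeatureBag
from .estimator import TrainConfig, estimate_fc, train_fc_estimator
from .fusion import predict_proba, train_logistic
from .synthetic import GroundTruth, TumorType

OLIGO = TumorType.OLIGODENDROGLIOMA


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def r_squared(truth, predictions) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    truth = np.asarray(truth, dtype=np.float64)
    predictions = np.asarray(predictions, dtype=np.float64)
    if truth.shape != predictions.shape or truth.size < 2:
        raise ValueError("need >= 2 aligned truth/prediction pairs")
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 is undefined for constant truth")
    ss_res = float(np.sum((truth - predictions) ** 2))
    return 1.0 - ss_res / ss_tot


def roc_auc(labels, scores) -> float:
    """Probability that a random positive outranks a random negative
    (ties counted half)."""
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def bootstrap_ci(
    labels,
    scores,
    metric: Callable = roc_auc,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a metric.

    Resampling is stratified by class so every replicate retains both
    classes; a replicate on which the metric still fails is redrawn.
    Deterministic in ``seed``.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    metric(labels, scores)  # must be computable on the full sample
    rng = np.random.default_rng(seed)
    groups = [np.nonzero(labels == v)[0] for v in np.unique(labels)]
    stats = np.empty(n_boot)
    for b in range(n_boot):
        for _attempt in range(100):
            idx = np.concatenate([rng.choice(g, size=g.size, replace=True) for g in groups])
            try:
                stats[b] = metric(labels[idx], scores[idx])
                break
            except ValueError:
                continue
        else:
            raise RuntimeError("bootstrap replicate kept failing the metric")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def best_cutoff(labels, scores) -> float:
    """Cutoff maximizing Youden's J (sensitivity + specificity - 1).

    Candidates are the midpoints between consecutive distinct observed
    scores (the single observed value when all scores tie); ties in J
    resolve to the lowest cutoff. A call is positive when
    ``score >= cutoff``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        return float(uniq[0])
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    best_j, best_c = -np.inf, candidates[0]
    for c in candidates:
        calls = scores >= c
        tp = int(np.sum(calls & (labels == 1)))
        tn = int(np.sum(~calls & (labels == 0)))
        j = tp / n_pos + tn / n_neg - 1.0
        if j > best_j:
            best_j, best_c = j, float(c)
    return best_c


def confusion_metrics(labels, calls) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) with the oligodendroglioma class
    positive; zero-denominator cases return 0 with a warning."""
    labels = np.asarray(labels, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int64)
    if labels.shape != calls.shape:
        raise ValueError("labels and calls must align")
    tp = int(np.sum((calls == 1) & (labels == 1)))
    tn = int(np.sum((calls == 0) & (labels == 0)))
    fp = int(np.sum((calls == 1) & (labels == 0)))
    fn = int(np.sum((calls == 0) & (labels == 1)))
    accuracy = (tp + tn) / labels.size

    def safe(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning 0")
            return 0.0
        return num / den

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "F1") if (precision + recall) else 0.0
    return accuracy, precision, recall, f1


# ---------------------------------------------------------------------------
# instance-level localization
# ---------------------------------------------------------------------------


def localization_auc(
    bags: Sequence[FeatureBag],
    truths: Sequence[GroundTruth],
    patch_scores: Sequence[np.ndarray],
    arm: str,
) -> float:
    """How well patch scores localize the planted tumor patches.

    Patches are pooled across slides and ranked by the absolute deviation
    of their score from the pooled median score. Positives are tumor
    patches on slides where ``arm`` is deleted; negatives are non-tumor
    patches on every slide (tumor patches of intact-arm slides carry no
    arm signal and are excluded). Returns the ROC AUC of that ranking.
    """
    devs, labels = [], []
    pooled = np.concatenate([np.asarray(s, dtype=np.float64) for s in patch_scores])
    median = float(np.median(pooled))
    for bag, truth, scores in zip(bags, truths, patch_scores):
        deleted = truth.deleted_1p if arm == "1p" else truth.deleted_19q
        tumor = np.zeros(bag.n_patches, dtype=bool)
        tumor[list(truth.tumor_patch_indices)] = True
        dev = np.abs(np.asarray(scores) - median)
        devs.append(dev[~tumor])
        labels.append(np.zeros(int((~tumor).sum()), dtype=int))
        if deleted:
            devs.append(dev[tumor])
            labels.append(np.ones(int(tumor.sum()), dtype=int))
    return roc_auc(np.concatenate(labels), np.concatenate(devs))


# ---------------------------------------------------------------------------
# the repeated-split protocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """Settings of the repeated stratified 60/20/20 split protocol."""

    n_splits: int = 10
    train_frac: float = 0.6
    val_frac: float = 0.2
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        test_frac = 1.0 - self.train_frac - self.val_frac
        if min(self.train_frac, self.val_frac, test_frac) <= 0:
            raise ValueError("train/val/test fractions must all be positive")


@dataclass
class EvalReport:
    """Per-split and averaged metrics of one protocol run."""

    splits: pd.DataFrame
    mean: dict[str, float]
    n_bootstrap: int
    ci_level: float
    split_seeds: list[int]
    localization_auc_1p: float = float("nan")
    localization_auc_19q: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "mean": self.mean,
                "splits": self.splits.to_dict(orient="records"),
                "n_bootstrap": self.n_bootstrap,
                "ci_level": self.ci_level,
                "split_seeds": self.split_seeds,
                "localization_auc_1p": self.localization_auc_1p,
                "localization_auc_19q": self.localization_auc_19q,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(payload)
        return payload


def _stratified_split(indices, strata, config: ProtocolConfig, seed: int):
    """One stratified 60/20/20 split; redrawn if any part loses a class."""
    test_frac = 1.0 - config.train_frac - config.val_frac
    for attempt in range(20):
        try:
            train, rest = train_test_split(
                indices,
                train_size=config.train_frac,
                stratify=strata,
                random_state=(seed + attempt) % 2**31,
            )
            val, test = train_test_split(
                rest,
                test_size=test_frac / (test_frac + config.val_frac),
                stratify=strata[rest],
                random_state=(seed + attempt) % 2**31,
            )
        except ValueError:
            continue
        parts = (train, val, test)
        if all(len(np.unique(strata[p])) == 2 for p in parts):
            return train, val, test
        warnings.warn(f"split attempt {attempt} lost a class; redrawing")
    raise RuntimeError("could not draw a split with both classes in every part")


def run_protocol(
    cohort: Sequence[tuple[FeatureBag, GroundTruth]],
    config: ProtocolConfig | None = None,
) -> EvalReport:
    """Run the full repeated-split evaluation on a labeled cohort.

    Per split: both arm estimators are trained on the training partition
    (validation partition steers early stopping), the logistic fusion is
    fitted on the training partition's estimator outputs, and all metrics
    are computed on the untouched test partition, with bootstrap CIs on
    the fused AUC. Deterministic in ``config.seed``.
    """
    config = config or ProtocolConfig()
    if len(cohort) < 10:
        raise ValueError("protocol needs a cohort of >= 10 slides")
    bags = [bag for bag, _ in cohort]
    truths = [t for _, t in cohort]
    y = np.array([int(t.tumor_type == OLIGO) for t in truths])
    if len(np.unique(y)) < 2:
        raise ValueError("both tumor types must be present")
    fc = {
        "1p": np.array([t.fc_1p for t in truths]),
        "19q": np.array([t.fc_19q for t in truths]),
    }
    indices = np.arange(len(cohort))

    ss = np.random.SeedSequence(config.seed)
    split_seeds = [int(s) for s in ss.generate_state(config.n_splits)]
    rows = []
    loc: dict[str, list[float]] = {"1p": [], "19q": []}
    for split_i, split_seed in enumerate(split_seeds):
        train, val, test = _stratified_split(indices, y, config, split_seed % 2**31)
        params = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # label-clip warnings are expected
            for arm in ("1p", "19q"):
                tc_seed = int(np.random.SeedSequence(split_seed, spawn_key=(0 if arm == "1p" else 1,)).generate_state(1)[0] % 2**31)
                tc = TrainConfig(**{**vars(config.train_config), "seed": tc_seed})
                params[arm], _ = train_fc_estimator(
                    [bags[i] for i in train],
                    fc[arm][train],
                    [bags[i] for i in val],
                    fc[arm][val],
                    tc,
                    arm=arm,
                )

        def outputs(part):
            est = {arm: [] for arm in ("1p", "19q")}
            scores = {arm: [] for arm in ("1p", "19q")}
            for i in part:
                for arm in ("1p", "19q"):
                    e, s = estimate_fc(bags[i], params[arm])
                    est[arm].append(e)
                    scores[arm].append(s)
            return {a: np.array(v) for a, v in est.items()}, scores

        est_train, _ = outputs(train)
        est_test, scores_test = outputs(test)
        logit = train_logistic(
            np.column_stack([est_train["1p"], est_train["19q"]]),
            y[train],
            seed=split_seed % 2**31,
        )
        prob_test = np.array(
            [
                predict_proba(a, b, logit)
                for a, b in zip(est_test["1p"], est_test["19q"])
            ]
        )
        cutoff = best_cutoff(y[test], prob_test)
        calls = (prob_test >= cutoff).astype(int)
        acc, prec, rec, f1 = confusion_metrics(y[test], calls)
        ci_lo, ci_hi = bootstrap_ci(
            y[test],
            prob_test,
            roc_auc,
            n_boot=config.n_bootstrap,
            level=config.ci_level,
            seed=split_seed % 2**31,
        )
        rows.append(
            {
                "split": split_i,
                "r2_1p": r_squared(np.minimum(fc["1p"][test], 0.999), est_test["1p"]),
                "r2_19q": r_squared(np.minimum(fc["19q"][test], 0.999), est_test["19q"]),
                "auc_1p": roc_auc(y[test], 1.0 - est_test["1p"]),
                "auc_19q": roc_auc(y[test], 1.0 - est_test["19q"]),
                "auc_fused": roc_auc(y[test], prob_test),
                "auc_fused_ci_low": ci_lo,
                "auc_fused_ci_high": ci_hi,
                "accuracy": acc,
                "precision": prec,
                "recall": rec,
                "f1": f1,
                "best_cutoff": cutoff,
                "coef_1p": logit.coef_1p,
                "coef_19q": logit.coef_19q,
            }
        )
        # instance localization needs planted-patch ground truth, which real
        # (non-synthetic) cohorts do not carry
        if any(truths[i].tumor_patch_indices for i in test):
            for arm in ("1p", "19q"):
                loc[arm].append(
                    localization_auc(
                        [bags[i] for i in test],
                        [truths[i] for i in test],
                        scores_test[arm],
                        arm,
                    )
                )

    splits = pd.DataFrame(rows)
    mean = {k: float(splits[k].mean()) for k in splits.columns if k != "split"}
    return EvalReport(
        splits=splits,
        mean=mean,
        n_bootstrap=config.n_bootstrap,
        ci_level=config.ci_level,
        split_seeds=split_seeds,
        localization_auc_1p=float(np.mean(loc["1p"])) if loc["1p"] else float("nan"),
        localization_auc_19q=float(np.mean(loc["19q"])) if loc["19q"] else float("nan"),
    )
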