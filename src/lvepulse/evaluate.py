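"""Classification metrics, ROC/AUC, and end-to-end pipeline orchestration.

Metrics follow the standard confusion-matrix definitions with LVE as the
positive class:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    recall    = TP / (TP + FN)
    precision = TP / (TP + FP)
    F1        = 2 * precision * recall / (precision + recall)

The ROC curve sweeps every distinct score threshold (TPR = TP/(TP+FN)
against FPR = FP/(FP+TN)); tied scores enter the curve as one group, so
the trapezoidal AUC coincides with the rank-average Mann-Whitney
formulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PredictionSet, POSITIVE_LABEL

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "RocCurve",
    "confusion",
    "classification_metrics",
    "per_class_report",
    "roc_auc",
    "PipelineConfig",
    "run_pipeline",
]


@dataclass
class ConfusionMatrix:
    """TP/TN/FP/FN counts with LVE as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same outcomes with the negative class treated as positive."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


def confusion(predictions: PredictionSet) -> ConfusionMatrix:
    """Confusion counts from a prediction set (positive class: LVE)."""
    if len(predictions) == 0:
        raise ValueError("empty prediction set")
    truth = np.asarray(predictions.y_true) == POSITIVE_LABEL
    pred = np.asarray(predictions.y_pred) == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(truth & pred)),
        tn=int(np.sum(~truth & ~pred)),
        fp=int(np.sum(~truth & pred)),
        fn=int(np.sum(truth & ~pred)),
    )


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, precision, recall and F1; undefined ratios are None."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else None
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else None
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    return {"accuracy": accuracy, "precision": precision,
            "recall": recall, "f1": f1}


def per_class_report(cm: ConfusionMatrix, round_to: int | None = 2) -> pd.DataFrame:
    """Per-class precision/recall/F1 table, each class in turn as positive.

    Display rounding is two decimals, round-half-even.
    """
    rows = []
    for name, mat in (("non_lve", cm.swapped()), ("lve", cm)):
        m = classification_metrics(mat)
        rows.append({"class": name, "precision": m["precision"],
                     "recall": m["recall"], "f1": m["f1"],
                     "support": mat.tp + mat.fn})
    df = pd.DataFrame(rows)
    if round_to is not None:
        for col in ("precision", "recall", "f1"):
            df[col] = df[col].round(round_to)
    return df


@dataclass
class RocCurve:
    """ROC sweep points (descending thresholds) and the trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(predictions: PredictionSet) -> RocCurve:
    """ROC curve and AUC from a prediction set's scores.

    Thresholds descend over the distinct scores; tied scores move the
    operating point in one step, and the trapezoidal rule then counts
    each tied positive-negative pair as half, matching the rank-average
    U-statistic convention.
    """
    y = np.asarray(predictions.y_true) == POSITIVE_LABEL
    scores = np.asarray(predictions.scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = y[order]

    thresholds, tpr, fpr = [], [0.0], [0.0]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(sorted_pos[i:j].sum())
        fp += (j - i) - int(sorted_pos[i:j].sum())
        thresholds.append(sorted_scores[i])
        tpr.append(tp / n_pos)
        fpr.append(fp / n_neg)
        i = j
    tpr_arr = np.array(tpr)
    fpr_arr = np.array(fpr)
    auc = float(np.trapezoid(tpr_arr, fpr_arr))
    return RocCurve(np.array(thresholds), tpr_arr, fpr_arr, auc)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of the full generate -> ... -> report pipeline."""

    generator: "GeneratorConfig" = None  # type: ignore[assignment]
    classifier: "ClassifierConfig" = None  # type: ignore[assignment]
    regressor: "DenseNetConfig" = None  # type: ignore[assignment]
    kmeans_k: int = 2
    make_plots: bool = True


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "generator": asdict(config.generator),
        "classifier": asdict(config.classifier),
        "regressor": asdict(config.regressor),
        "kmeans_k": config.kmeans_k,
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _numeric_hash(report: dict) -> str:
    blob = json.dumps(report, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis end to end on a synthetic cohort.

    Stages: cohort generation, preprocessing, screening, harmonic
    analysis with group testing, weighted-forest classification (with
    baselines' configs left to the CLI), dense-net LVDdI regression, and
    metric reporting. Every stage's tabular output is persisted under
    ``outdir``; a manifest records the seeds, configuration hash, and a
    hash of the numeric report for reproducibility checks.
    """
    from . import __version__
    from .synthetic import generate_cohort, write_subject_table, write_recordings
    from .preprocessing import preprocess_cohort, cycles_to_frame
    from .screening import screen
    from .harmonics import (subject_power_table, group_comparison_table,
                            representative_waveform)
    from .classify import (build_features, split_dataset, train_classifier,
                           cross_validate, predict)
    from .regress import (train_regressor, predict_lvddi, mape_accuracy,
                          bland_altman, regression_as_classifier)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    timings: dict = {}

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                logger.info("stage %s: started", name)
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                dt = time.perf_counter() - self_inner.t0
                timings[name] = dt
                if exc_type is not None:
                    logger.error("stage %s: FAILED after %.2fs", name, dt)
                    raise RuntimeError(f"pipeline stage '{name}' failed") from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False
        return _Timer()

    with stage("generate"):
        subjects, recordings = generate_cohort(config.generator)
        write_subject_table(subjects, outdir / "subjects.csv")
        write_recordings(recordings, outdir / "recordings.csv")

    with stage("preprocess"):
        cycles = preprocess_cohort(recordings)
        cycles_to_frame(cycles).to_csv(outdir / "normalized_cycles.csv",
                                       index=False)

    with stage("screen"):
        screened = screen(subjects, cycles_by_subject=cycles)
        screened.to_frame().to_csv(outdir / "screened.csv", index=False)
        report["screening"] = {
            "n_total": len(subjects),
            "n_qualified": len(screened.qualified),
            "n_excluded": len(screened.excluded),
            "n_lve": screened.n_lve,
            "n_non_lve": screened.n_non_lve,
        }

    with stage("harmonics"):
        q_ids = set(screened.qualified["subject_id"])
        q_cycles = {sid: c for sid, c in cycles.items() if sid in q_ids}
        powers = subject_power_table(q_cycles)
        powers.to_csv(outdir / "subject_harmonics.csv", index=False)
        labels = screened.labels
        g1_ids = labels[labels == "non_lve"].index
        g2_ids = labels[labels == "lve"].index
        table = group_comparison_table(
            powers[powers.subject_id.isin(g1_ids)],
            powers[powers.subject_id.isin(g2_ids)],
        )
        table.to_csv(outdir / "group_comparison.csv", index=False)
        report["harmonics"] = {
            "group_means_non_lve": table["non_lve_mean"].tolist(),
            "group_means_lve": table["lve_mean"].tolist(),
            "p_values": table["p_value"].tolist(),
        }

    with stage("representative_waveforms"):
        rep = {
            sid: representative_waveform(
                [c for c in q_cycles[sid] if c.valid],
                k=config.kmeans_k, seed=config.classifier.seed)
            for sid in sorted(q_cycles)
        }

    with stage("classify"):
        features = build_features(rep, power_table=powers,
                                  mode=config.classifier.features)
        X_tr, X_te, y_tr, y_te = split_dataset(
            features, labels, config.classifier.test_fraction,
            config.classifier.seed)
        model = train_classifier(X_tr, y_tr, config.classifier)
        preds = predict(model, X_te, y_true=y_te,
                        threshold=config.classifier.score_threshold)
        preds.to_frame().to_csv(outdir / "classifier_predictions.csv",
                                index=False)
        cm = confusion(preds)
        metrics = classification_metrics(cm)
        roc = roc_auc(preds)
        cv = cross_validate(features, labels, config.classifier)
        report["classification"] = {
            "model_kind": config.classifier.model_kind,
            "confusion": asdict(cm),
            "accuracy": metrics["accuracy"],
            "auc": roc.auc,
            "cv_mean_accuracy": cv["mean_accuracy"],
            "cv_mean_auc": cv["mean_auc"],
        }
        per_class_report(cm).to_csv(outdir / "classification_report.csv",
                                    index=False)

    with stage("regress"):
        qualified = screened.qualified.set_index("subject_id")
        lvddi = qualified.loc[features.index, "lvddi_mm_m2"]
        sexes = qualified.loc[features.index, "sex"]
        reg_model, history = train_regressor(
            features.loc[X_tr.index], lvddi.loc[X_tr.index], config.regressor)
        history.to_csv(outdir / "loss_history.csv", index=False)
        pred = predict_lvddi(reg_model, features.loc[X_te.index])
        pd.DataFrame({
            "subject_id": X_te.index,
            "measured_lvddi": lvddi.loc[X_te.index].to_numpy(),
            "predicted_lvddi": pred,
        }).to_csv(outdir / "regression_predictions.csv", index=False)
        mape, acc = mape_accuracy(lvddi.loc[X_te.index], pred)
        ba = bland_altman(lvddi.loc[X_te.index], pred)
        reg_preds = regression_as_classifier(
            pred, sexes.loc[X_te.index], subject_ids=X_te.index,
            y_true=labels.loc[X_te.index])
        reg_cm = confusion(reg_preds)
        reg_metrics = classification_metrics(reg_cm)
        reg_roc = roc_auc(reg_preds)
        ba_summary = {
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "lower_limit": ba.lower_limit,
            "upper_limit": ba.upper_limit,
            "fraction_within_limits": ba.fraction_within_limits,
        }
        (outdir / "bland_altman.json").write_text(
            json.dumps(ba_summary, indent=2))
        report["regression"] = {
            "mape_percent": mape,
            "accuracy_1_minus_mape": acc,
            "confusion_accuracy": reg_metrics["accuracy"],
            "auc": reg_roc.auc,
            "bland_altman": ba_summary,
            "final_train_mse": float(history["train_mse"].iloc[-1]),
        }

    if config.make_plots:
        with stage("plots"):
            _write_plots(outdir, cm, roc, ba, history)

    report = _round_floats(report)
    manifest = {
        "package_version": __version__,
        "seeds": {
            "generator": config.generator.seed,
            "classifier": config.classifier.seed,
            "regressor": config.regressor.seed,
        },
        "config_hash": _config_hash(config),
        "numeric_hash": _numeric_hash(report),
        "stage_timings_s": _round_floats(timings, 3),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _write_plots(outdir: Path, cm: ConfusionMatrix, roc: RocCurve,
                 ba, history: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    mat = np.array([[cm.tn, cm.fp], [cm.fn, cm.tp]])
    ax.imshow(mat, cmap="Blues")
    for (i, j), v in np.ndenumerate(mat):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], ["non-LVE", "LVE"])
    ax.set_yticks([0, 1], ["non-LVE", "LVE"])
    ax.set_xlabel("Predicted")
    ax.set_ylabel("Measured")
    fig.savefig(outdir / "confusion_matrix.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(roc.fpr, roc.tpr, marker=".")
    ax.plot([0, 1], [0, 1], ls="--", c="gray")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"AUC = {roc.auc:.2f}")
    fig.savefig(outdir / "roc_curve.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.scatter(ba.means, ba.differences, s=12)
    for yline in (ba.mean_difference, ba.lower_limit, ba.upper_limit):
        ax.axhline(yline, ls="--", c="gray")
    ax.set_xlabel("Mean of measured and predicted LVDdI (mm/m$^2$)")
    ax.set_ylabel("Difference (predicted - measured)")
    fig.savefig(outdir / "bland_altman.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    ax.plot(history["epoch"], history["train_mse"], label="train")
    if history["val_mse"].notna().any():
        ax.plot(history["epoch"], history["val_mse"], label="validation")
    ax.set_xlabel("Epoch")
    ax.set_ylabel("MSE (mm/m$^2$)$^2$")
    ax.legend()
    fig.savefig(outdir / "loss_curve.png", dpi=120)
    plt.close(fig)
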