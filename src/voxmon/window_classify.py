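"""5-min-window featurization, baseline normalization, and paired-LOOCV LASSO
classification of hyperfunctional vocal behavior.

Frame streams are cut into non-overlapping 5-min windows (6000 frames of
50 ms); windows with at least 30 voiced frames (0.5% phonation time) are
kept.  Univariate statistics of voiced-frame SPL and f0 (mean, SD, skewness,
kurtosis, 5th/95th percentile) plus percent phonation are computed per
window, and normalized counterparts express each statistic in units of SD of
its baseline distribution over the first half of the monitored day.

Classification trains one L1-regularized logistic regression (LASSO) per
leave-one-pair-out fold: each fold holds out one patient-control pair, labels
every held-out 5-min window at probability > 0.5, and calls a subject a
patient when more than a proportion tau of their windows are patient-labeled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .frame_features import FrameFeatureRecord

__all__ = [
    "WindowFeatureVector",
    "ClassifierReport",
    "build_windows",
    "daily_profile",
    "window_statistics",
    "normalize_stats",
    "featurize_day",
    "fit_lasso",
    "loocv_paired",
    "subject_decision",
    "subject_proportions",
    "evaluate",
    "sweep_threshold",
    "coefficient_table",
    "STAT_NAMES",
]

STAT_NAMES = ("mean", "sd", "skew", "kurtosis", "p5", "p95")

#: Feature columns used by the classifier by default: raw and normalized
#: SPL/f0 statistics plus percent phonation.
def default_feature_columns() -> list:
    cols = [f"spl_{s}" for s in STAT_NAMES] + [f"f0_{s}" for s in STAT_NAMES]
    cols += ["percent_phonation"]
    cols += ["norm_" + c for c in cols]
    return cols


@dataclass
class WindowFeatureVector:
    subject_id: str
    day_index: int
    window_index: int
    t_start: float
    n_voiced_frames: int
    stats: dict            # raw statistics
    norm_stats: dict = field(default_factory=dict)  # SD-unit counterparts
    label: Optional[int] = None


@dataclass
class ClassifierReport:
    window_probs: pd.DataFrame     # subject_id, pair_id, label, prob, pred
    proportions: pd.DataFrame      # subject_id, label, proportion, pred
    tau: float
    accuracy: float
    auc_mean: float
    auc_sd: float
    f_score: float
    sensitivity: float
    specificity: float
    coefficients: pd.DataFrame


def build_windows(frames: Sequence[FrameFeatureRecord],
                  window_s: float = 300.0, frame_s: float = 0.050,
                  min_voiced: int = 30,
                  subject_id: str = "", day_index: int = 0) -> list[WindowFeatureVector]:
    """Cut a frame stream into non-overlapping 5-min windows and compute raw
    statistics; windows with fewer than ``min_voiced`` voiced frames are
    excluded.  A trailing partial window is dropped."""
    per_window = int(round(window_s / frame_s))
    out = []
    n_windows = len(frames) // per_window
    for w in range(n_windows):
        chunk = frames[w * per_window : (w + 1) * per_window]
        n_voiced = sum(1 for f in chunk if f.voiced)
        if n_voiced < min_voiced:
            continue
        out.append(WindowFeatureVector(
            subject_id=subject_id, day_index=day_index, window_index=w,
            t_start=chunk[0].t_start, n_voiced_frames=n_voiced,
            stats=window_statistics(chunk),
        ))
    return out


def window_statistics(frames: Sequence[FrameFeatureRecord]) -> dict:
    """Raw univariate statistics of voiced-frame SPL and f0 plus percent
    phonation.

    Skewness and kurtosis use the standard moment formulas (kurtosis is the
    raw, non-excess convention: 3 for a normal distribution); percentiles use
    linear interpolation.  Zero-variance inputs report 0 skew/kurtosis.
    """
    voiced = [f for f in frames if f.voiced]
    out = {"percent_phonation": 100.0 * len(voiced) / len(frames) if frames else 0.0}
    for name, values in (("spl", [f.spl for f in voiced]),
                         ("f0", [f.f0 for f in voiced])):
        v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
        if v.size == 0:
            for s in STAT_NAMES:
                out[f"{name}_{s}"] = math.nan
            continue
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        if sd == 0.0:
            skew = kurt = 0.0
        else:
            skew = float(sps.skew(v))
            kurt = float(sps.kurtosis(v, fisher=False))
        out[f"{name}_mean"] = float(np.mean(v))
        out[f"{name}_sd"] = sd
        out[f"{name}_skew"] = skew
        out[f"{name}_kurtosis"] = kurt
        out[f"{name}_p5"] = float(np.percentile(v, 5))
        out[f"{name}_p95"] = float(np.percentile(v, 95))
    return out


def normalize_stats(windows: Sequence[WindowFeatureVector],
                    mode: Literal["pooled", "hourly"] = "pooled",
                    window_s: float = 300.0) -> list[WindowFeatureVector]:
    """Attach SD-unit normalized statistics relative to each day's baseline.

    The baseline for a subject-day is the set of windows whose start time
    falls in the first half of that day's monitored span.  ``pooled`` takes
    the mean/SD across all baseline windows; ``hourly`` averages per-hour
    means/SDs ("an average hour").  A zero baseline SD yields 0 (flagged by
    being exactly 0); days with fewer than 2 baseline windows get no
    normalized features.
    """
    by_day: dict = {}
    for w in windows:
        by_day.setdefault((w.subject_id, w.day_index), []).append(w)
    for (_, _), ws in by_day.items():
        t0 = min(w.t_start for w in ws)
        t1 = max(w.t_start for w in ws) + window_s
        half = t0 + (t1 - t0) / 2
        base = [w for w in ws if w.t_start < half]
        if len(base) < 2:
            continue
        keys = ws[0].stats.keys()
        base_mean, base_sd = {}, {}
        for k in keys:
            if mode == "pooled":
                vals = np.array([b.stats[k] for b in base], dtype=float)
                base_mean[k] = float(np.nanmean(vals))
                base_sd[k] = float(np.nanstd(vals, ddof=1))
            else:
                hours: dict = {}
                for b in base:
                    hours.setdefault(int((b.t_start - t0) // 3600), []).append(b.stats[k])
                means = [np.nanmean(v) for v in hours.values()]
                sds = [np.nanstd(v, ddof=1) for v in hours.values() if len(v) > 1]
                base_mean[k] = float(np.mean(means))
                base_sd[k] = float(np.mean(sds)) if sds else 0.0
        for w in ws:
            w.norm_stats = {}
            for k in keys:
                sd = base_sd[k]
                if not np.isfinite(w.stats[k]):
                    w.norm_stats["norm_" + k] = math.nan
                elif sd > 0:
                    w.norm_stats["norm_" + k] = (w.stats[k] - base_mean[k]) / sd
                else:
                    w.norm_stats["norm_" + k] = 0.0
    return list(windows)


def featurize_day(frames: Sequence[FrameFeatureRecord], subject_id: str = "",
                  day_index: int = 0, **kw) -> pd.DataFrame:
    """Windows -> normalized -> flat DataFrame, one row per included window."""
    ws = normalize_stats(build_windows(frames, subject_id=subject_id,
                                       day_index=day_index, **kw))
    rows = []
    for w in ws:
        row = {"subject_id": w.subject_id, "day_index": w.day_index,
               "window_index": w.window_index, "t_start": w.t_start,
               "n_voiced_frames": w.n_voiced_frames}
        row.update(w.stats)
        row.update(w.norm_stats)
        rows.append(row)
    return pd.DataFrame(rows)


def daily_profile(frames: Sequence[FrameFeatureRecord],
                  window_s: float = 300.0, frame_s: float = 0.050) -> pd.DataFrame:
    """Daylong voice-use profile as a table: per 5-min window, the median and
    95th percentile of each voiced-frame feature plus percent phonation —
    the tabular form of a clinician's day-profile plot."""
    per_window = int(round(window_s / frame_s))
    rows = []
    feature_names = ("spl", "f0", "ac_peak", "tilt", "lh_ratio", "cpp")
    for w in range(len(frames) // per_window):
        chunk = frames[w * per_window:(w + 1) * per_window]
        voiced = [f for f in chunk if f.voiced]
        row = {"t_start": chunk[0].t_start,
               "percent_phonation": 100.0 * len(voiced) / len(chunk)}
        for name in feature_names:
            vals = np.array([getattr(f, name) for f in voiced], dtype=float)
            vals = vals[np.isfinite(vals)]
            row[f"{name}_median"] = float(np.median(vals)) if vals.size else math.nan
            row[f"{name}_p95"] = float(np.percentile(vals, 95)) if vals.size else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float = 1.0) -> LogisticRegression:
    """L1-penalized logistic regression at penalty strength ``lam``
    (sklearn's ``C = 1/lam``).  Features should be standardized on training
    data by the caller."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; cannot fit a classifier")
    model = LogisticRegression(l1_ratio=1.0, C=1.0 / lam, solver="liblinear",
                               max_iter=1000)
    model.fit(X, y)
    return model


def _select_lambda_cv(X, y, pair_ids, lambdas, seed: int) -> float:
    """Inner 5-fold CV over pairs with the 1-SE rule: the strongest penalty
    whose mean validation AUC is within one SE of the best."""
    rng = np.random.default_rng(seed)
    pairs = np.unique(pair_ids)
    perm = rng.permutation(pairs)
    folds = np.array_split(perm, min(5, len(pairs)))
    scores = np.full((len(lambdas), len(folds)), np.nan)
    for j, fold_pairs in enumerate(folds):
        val = np.isin(pair_ids, fold_pairs)
        if len(np.unique(y[~val])) < 2 or len(np.unique(y[val])) < 2:
            continue
        mu, sd = X[~val].mean(0), X[~val].std(0)
        sd[sd == 0] = 1.0
        Xtr, Xva = (X[~val] - mu) / sd, (X[val] - mu) / sd
        for i, lam in enumerate(lambdas):
            m = fit_lasso(Xtr, y[~val], lam)
            p = m.predict_proba(Xva)[:, 1]
            scores[i, j] = roc_auc_score(y[val], p)
    mean = np.nanmean(scores, axis=1)
    se = np.nanstd(scores, axis=1, ddof=1) / math.sqrt(scores.shape[1])
    best = int(np.nanargmax(mean))
    cutoff = mean[best] - se[best]
    # lambdas assumed sorted descending (strongest first)
    for i in range(len(lambdas)):
        if mean[i] >= cutoff:
            return float(lambdas[i])
    return float(lambdas[best])


def loocv_paired(features: pd.DataFrame, feature_columns: Optional[list] = None,
                 lam: Optional[float] = None, seed: int = 0):
    """Leave-one-pair-out cross-validation of the window-level LASSO.

    ``features`` needs columns ``subject_id, pair_id, label`` plus the
    feature columns.  Each fold trains on all windows from the other pairs
    (standardized on the training split) and predicts all windows of the
    held-out pair.  ``lam=None`` selects the penalty per fold by inner
    5-fold CV with the 1-SE rule; a fixed ``lam`` gives a fully reproducible
    path.

    Returns ``(window_probs DataFrame, fold_models list)``; each fold model
    is a dict with the pair id, coefficients, intercept and lambda.
    """
    feature_columns = feature_columns or [
        c for c in features.columns
        if c not in ("subject_id", "pair_id", "label", "window_index",
                     "day_index", "t_start", "n_voiced_frames")
    ]
    pair_ids = features["pair_id"].to_numpy()
    pairs = np.unique(pair_ids)
    for p in pairs:
        groups = features.loc[features.pair_id == p, "label"].unique()
        if set(groups) != {0, 1}:
            raise ValueError(f"pair {p} is incomplete (labels {sorted(groups)})")
    X_all = features[feature_columns].to_numpy(dtype=float)
    X_all = np.nan_to_num(X_all, nan=0.0)
    y_all = features["label"].to_numpy(dtype=int)
    lambdas = np.geomspace(10.0, 0.01, 10)  # strongest penalty first
    prob_rows, models = [], []
    for p in pairs:
        test = pair_ids == p
        Xtr, ytr = X_all[~test], y_all[~test]
        mu, sd = Xtr.mean(0), Xtr.std(0)
        sd[sd == 0] = 1.0
        lam_p = lam if lam is not None else _select_lambda_cv(
            (Xtr - mu) / sd, ytr, pair_ids[~test], lambdas, seed + int(p))
        model = fit_lasso((Xtr - mu) / sd, ytr, lam_p)
        probs = model.predict_proba((X_all[test] - mu) / sd)[:, 1]
        sub = features.loc[test, ["subject_id", "pair_id", "label"]].copy()
        sub["prob"] = probs
        sub["pred"] = (probs > 0.5).astype(int)
        prob_rows.append(sub)
        models.append({
            "pair_id": p, "lambda": lam_p,
            "coef": dict(zip(feature_columns, model.coef_[0])),
            "intercept": float(model.intercept_[0]),
        })
    return pd.concat(prob_rows, ignore_index=True), models


def subject_decision(window_labels, tau: float = 0.5) -> int:
    """Patient (1) iff strictly more than proportion ``tau`` of the subject's
    windows carry a patient label."""
    labels = np.asarray(window_labels)
    if labels.size == 0:
        raise ValueError("no labeled windows")
    return int(labels.mean() > tau)


def subject_proportions(window_probs: pd.DataFrame) -> pd.DataFrame:
    """Per-subject proportion of patient-labeled windows."""
    g = window_probs.groupby("subject_id").agg(
        label=("label", "first"), proportion=("pred", "mean"))
    return g.reset_index()


def evaluate(window_probs: pd.DataFrame, models: list,
             tau: float = 0.5) -> ClassifierReport:
    """Subject-level metrics at window-proportion threshold ``tau``:
    accuracy, F-score, sensitivity (patients), specificity (controls), and
    the per-fold AUC over held-out window probabilities (mean, SD)."""
    props = subject_proportions(window_probs)
    props["pred"] = (props["proportion"] > tau).astype(int)
    y, yhat = props["label"].to_numpy(), props["pred"].to_numpy()
    tp = int(((y == 1) & (yhat == 1)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * sens / (prec + sens)) if prec + sens > 0 else 0.0
    aucs = []
    for p, sub in window_probs.groupby("pair_id"):
        if len(sub["label"].unique()) == 2:
            aucs.append(roc_auc_score(sub["label"], sub["prob"]))
    return ClassifierReport(
        window_probs=window_probs, proportions=props, tau=tau,
        accuracy=float((y == yhat).mean()),
        auc_mean=float(np.mean(aucs)) if aucs else math.nan,
        auc_sd=float(np.std(aucs, ddof=1)) if len(aucs) > 1 else math.nan,
        f_score=f1, sensitivity=sens, specificity=spec,
        coefficients=coefficient_table(models),
    )


def sweep_threshold(proportions: pd.DataFrame, step: float = 0.01):
    """Accuracy at each candidate tau on a grid; returns ``(tau*, curve)``
    where ties go to the smallest tau."""
    taus = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    y = proportions["label"].to_numpy()
    prop = proportions["proportion"].to_numpy()
    acc = np.array([np.mean((prop > t).astype(int) == y) for t in taus])
    best = int(np.argmax(acc))  # argmax returns the first (smallest) maximizer
    return float(taus[best]), pd.DataFrame({"tau": taus, "accuracy": acc})


def coefficient_table(models: list) -> pd.DataFrame:
    """Summarize per-fold LASSO coefficients: association counts (folds with
    positive = patient-associated vs negative = control-associated sign),
    beta mean (SD), and odds ratio exp(beta) mean with a 95% range across
    folds."""
    if not models:
        return pd.DataFrame()
    feats = list(models[0]["coef"].keys())
    rows = []
    for f in feats:
        betas = np.array([m["coef"][f] for m in models])
        ors = np.exp(betas)
        rows.append({
            "feature": f,
            "patient_count": int((betas > 0).sum()),
            "control_count": int((betas < 0).sum()),
            "beta_mean": float(betas.mean()),
            "beta_sd": float(betas.std(ddof=1)) if len(betas) > 1 else 0.0,
            "odds_ratio_mean": float(ors.mean()),
            "odds_ratio_lo": float(np.percentile(ors, 2.5)),
            "odds_ratio_hi": float(np.percentile(ors, 97.5)),
        })
    df = pd.DataFrame(rows)
    return df.sort_values("beta_mean", ascending=False, ignore_index=True)
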