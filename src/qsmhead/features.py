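"""First-order tumor susceptibility features, statistics, and the
proliferation classifier.

Feature extraction runs over all GTV voxels and separately over the
paramagnetic (chi > 0) and diamagnetic (chi < 0) subsets.  The
interquartile coefficient of variation (ICV) is defined as
(P75 - P25) / (P75 + P25) — the quartile coefficient of dispersion —
switchable to IQR/median; percentiles use linear interpolation between
order statistics.

The analysis stage mirrors a small-cohort proliferation study:
Kruskal-Wallis comparison of tumor vs healthy-tissue features, Spearman
correlation of features against the Ki-67 index (exact permutation
p-values for small n), two-stage feature selection (correlation filter +
redundancy filter, optional third feature via recursive feature
elimination), and a nested cross-validation classifier (leave-one-out
outer loop, 3-fold grid-search inner loop) of the Ki-67 < 5 % low vs
>= 5 % high classes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FIRST_ORDER_FEATURES",
    "extract_first_order_features",
    "cohort_feature_table",
    "compare_gtv_vs_reference",
    "correlate_with_ki67",
    "select_classifier_features",
    "nested_cv_classify",
    "ClassifierReport",
    "KI67_THRESHOLD",
]

#: Ki-67 low/high proliferation threshold, percent.
KI67_THRESHOLD = 5.0

FIRST_ORDER_FEATURES = [
    "mean", "median", "max", "min", "std", "sem", "iqr", "icv", "cv",
    "skewness", "kurtosis", "p25", "p75", "mad_mean", "mad_median", "energy",
]


def _moment_stat(fn, x: np.ndarray, min_n: int) -> float:
    if x.size < min_n or np.ptp(x) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(fn(x))


def _stats_vector(x: np.ndarray, icv_convention: str) -> dict[str, float]:
    if x.size == 0:
        return {k: np.nan for k in FIRST_ORDER_FEATURES}
    p25, p75 = np.percentile(x, [25, 75])  # linear interpolation
    med = float(np.median(x))
    std = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    mean = float(np.mean(x))
    if icv_convention == "quartile_dispersion":
        icv = (p75 - p25) / (p75 + p25) if (p75 + p25) != 0 else np.nan
    elif icv_convention == "iqr_over_median":
        icv = (p75 - p25) / med if med != 0 else np.nan
    else:
        raise ValueError(f"unknown ICV convention {icv_convention!r}")
    return {
        "mean": mean,
        "median": med,
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "std": std,
        "sem": std / np.sqrt(x.size),
        "iqr": float(p75 - p25),
        "icv": float(icv) if np.isfinite(icv) else np.nan,
        "cv": std / mean if mean != 0 else np.nan,
        "skewness": _moment_stat(stats.skew, x, 3),
        "kurtosis": _moment_stat(stats.kurtosis, x, 4),
        "p25": float(p25),
        "p75": float(p75),
        "mad_mean": float(np.mean(np.abs(x - mean))),
        "mad_median": float(np.median(np.abs(x - med))),
        "energy": float(np.sum(x**2)),
    }


def extract_first_order_features(chi: np.ndarray, gtv_mask: np.ndarray,
                                 voxel_size=(1.0, 1.0, 1.0),
                                 icv_convention: str = "quartile_dispersion"
                                 ) -> dict[str, float]:
    """First-order statistics of GTV susceptibility per sign subset.

    Keys are ``<stat>_<subset>`` with subset in {all, pos, neg}; empty
    subsets yield NaN markers.  ``volume_mm3`` is the GTV volume.
    """
    gtv_mask = np.asarray(gtv_mask, dtype=bool)
    if not gtv_mask.any():
        raise ValueError("GTV mask is empty")
    vals = np.asarray(chi, dtype=float)[gtv_mask]
    out = {}
    for subset, sel in (("all", vals),
                        ("pos", vals[vals > 0]),
                        ("neg", vals[vals < 0])):
        for k, v in _stats_vector(sel, icv_convention).items():
            out[f"{k}_{subset}"] = v
    out["volume_mm3"] = float(gtv_mask.sum() * np.prod(voxel_size))
    return out


def cohort_feature_table(cohort, voxel_size=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Per-patient feature table (id, ki67, features) from a synthetic cohort."""
    rows = []
    for i, (ki, vox) in enumerate(zip(cohort.ki67, cohort.gtv_voxel_samples)):
        feats = {}
        for subset, sel in (("all", vox), ("pos", vox[vox > 0]), ("neg", vox[vox < 0])):
            for k, v in _stats_vector(np.asarray(sel), "quartile_dispersion").items():
                feats[f"{k}_{subset}"] = v
        feats["volume_mm3"] = float(len(vox) * np.prod(voxel_size))
        rows.append({"patient_id": f"P{i:03d}", "ki67": float(ki), **feats})
    return pd.DataFrame(rows)


def compare_gtv_vs_reference(group_features: dict[str, pd.DataFrame],
                             alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis test per feature across structure groups.

    ``group_features`` maps group name (GTV, WM, GM, CSF ...) to a
    per-subject feature DataFrame.  Requires >= 2 groups with >= 3
    subjects each.  Features identical across all observations get a NaN
    statistic marker.
    """
    if len(group_features) < 2:
        raise ValueError("need >= 2 groups")
    for name, df in group_features.items():
        if len(df) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 subjects")
    features = sorted(set.intersection(*(set(df.columns) for df in group_features.values())))
    rows = []
    for feat in features:
        samples = [df[feat].dropna().to_numpy() for df in group_features.values()]
        if any(s.size == 0 for s in samples):
            rows.append({"feature": feat, "H": np.nan, "p": np.nan,
                         "significant": False})
            continue
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            rows.append({"feature": feat, "H": np.nan, "p": np.nan,
                         "significant": False})
            continue
        H, p = stats.kruskal(*samples)
        rows.append({"feature": feat, "H": float(H), "p": float(p),
                     "significant": bool(p < alpha)})
    return pd.DataFrame(rows)


def _exact_spearman_p(x_rank: np.ndarray, y_rank: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full permutation null of the Spearman statistic."""
    n = len(x_rank)
    xc = x_rank - x_rank.mean()
    yc = y_rank - y_rank.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    total = 0
    chunk = []
    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            rhos = (xc[np.array(chunk)] * yc[None, :]).sum(axis=1) / denom
            count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
            total += len(chunk)
            chunk = []
    if chunk:
        rhos = (xc[np.array(chunk)] * yc[None, :]).sum(axis=1) / denom
        count += int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())
        total += len(chunk)
    return count / total


def correlate_with_ki67(table: pd.DataFrame, feature: str, subset: str = "all",
                        exact_max_n: int = 10) -> dict[str, float]:
    """Spearman correlation of one feature (per sign subset) with Ki-67.

    Returns tie-aware rho, the asymptotic two-sided p, and — for
    n <= ``exact_max_n`` — the exact full-permutation p as well.
    """
    col = feature if feature in table.columns else f"{feature}_{subset}"
    if col not in table.columns:
        raise KeyError(f"feature {col!r} not in table")
    sub = table[["ki67", col]].dropna()
    if len(sub) < 5:
        raise ValueError("need >= 5 complete pairs")
    x = sub[col].to_numpy()
    y = sub["ki67"].to_numpy()
    if np.ptp(x) == 0:
        return {"spearman_rho": np.nan, "p": np.nan, "p_exact": np.nan, "n": len(sub)}
    rho, p_asym = stats.spearmanr(x, y)
    out = {"spearman_rho": float(rho), "p": float(p_asym), "n": len(sub)}
    if len(sub) <= exact_max_n:
        xr = stats.rankdata(x)
        yr = stats.rankdata(y)
        out["p_exact"] = _exact_spearman_p(xr, yr, rho)
    else:
        out["p_exact"] = np.nan
    return out


def select_classifier_features(table: pd.DataFrame,
                               rho_threshold: float = 0.8,
                               p_threshold: float = 0.05,
                               redundancy_threshold: float = 0.7,
                               n_extra: int = 1, seed: int = 0) -> list[str]:
    """Two-stage feature selection.

    Stage 1: keep features with |Spearman rho| >= ``rho_threshold`` and
    p < ``p_threshold`` against Ki-67, then greedily pick two that are
    mutually non-redundant (inter-feature |Spearman| < 0.7), ordered by
    |rho| descending with lexicographic tie-break.  Stage 2 (optional):
    add ``n_extra`` features chosen by recursive feature elimination with
    a linear model on standardized features.
    """
    feat_cols = [c for c in table.columns if c not in ("patient_id", "ki67")]
    scores = {}
    for c in feat_cols:
        sub = table[["ki67", c]].dropna()
        if len(sub) < 5 or np.ptp(sub[c].to_numpy()) == 0:
            continue
        rho, p = stats.spearmanr(sub[c], sub["ki67"])
        if np.isfinite(rho) and abs(rho) >= rho_threshold and p < p_threshold:
            scores[c] = abs(rho)
    if len(scores) < 2:
        near = sorted(scores, key=lambda c: -scores[c])
        raise ValueError(f"fewer than two features pass the filter; "
                         f"near-misses: {near}")
    ranked = sorted(scores, key=lambda c: (-scores[c], c))
    selected = [ranked[0]]
    for c in ranked[1:]:
        r, _ = stats.spearmanr(table[selected[0]].dropna(), table[c].dropna())
        if abs(r) < redundancy_threshold:
            selected.append(c)
            break
    if len(selected) < 2:
        raise ValueError("no non-redundant second feature "
                         f"(candidates: {ranked})")
    if n_extra > 0:
        from sklearn.feature_selection import RFE
        from sklearn.linear_model import LogisticRegression
        from sklearn.preprocessing import StandardScaler

        X = table[feat_cols].dropna(axis=1).to_numpy()
        cols = [c for c in feat_cols if c in table[feat_cols].dropna(axis=1).columns]
        y = (table["ki67"].to_numpy() >= KI67_THRESHOLD).astype(int)
        Xs = StandardScaler().fit_transform(X)
        rfe = RFE(LogisticRegression(max_iter=1000, random_state=seed),
                  n_features_to_select=len(selected) + n_extra)
        rfe.fit(Xs, y)
        extras = [c for c, keep in zip(cols, rfe.support_) if keep and c not in selected]
        if not extras:
            order = np.argsort(rfe.ranking_)
            extras = [cols[i] for i in order if cols[i] not in selected]
        selected.extend(extras[:n_extra])
    return selected


@dataclass
class ClassifierReport:
    """Pooled leave-one-out performance per model."""

    features: list[str]
    metrics: dict = dc_field(default_factory=dict)       # model -> metric dict
    importances: dict = dc_field(default_factory=dict)   # model -> {feature: score}
    predictions: pd.DataFrame | None = None
    skipped_folds: dict = dc_field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, m in self.metrics.items():
            rows.append({"model": model, **m,
                         **{f"imp_{k}": v for k, v in self.importances[model].items()}})
        return pd.DataFrame(rows)


def _model_grid(seed: int):
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.svm import SVC

    return {
        "logistic": (LogisticRegression(max_iter=2000, random_state=seed),
                     {"clf__C": [0.1, 1.0, 10.0]}),
        "svm": (SVC(kernel="linear", random_state=seed),
                {"clf__C": [0.1, 1.0, 10.0]}),
        "random_forest": (None, {"clf__max_depth": [2, 4],
                                 "clf__n_estimators": [50]}),
        "gradient_boosting": (None, {"clf__learning_rate": [0.1, 0.3],
                                     "clf__n_estimators": [40]}),
    }


def nested_cv_classify(table: pd.DataFrame, features: list[str],
                       models=("logistic", "svm", "random_forest", "gradient_boosting"),
                       seed: int = 0) -> ClassifierReport:
    """Nested cross-validation of the low/high proliferation classifier.

    Outer leave-one-out loop; inner stratified 3-fold grid search;
    feature scaling (zero mean / unit variance) fit strictly inside each
    training fold via a pipeline.  Importances come from Gini impurity
    decrease (tree models) or normalized absolute coefficients (linear
    models), refit on the full cohort with the most frequently selected
    hyperparameters.
    """
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.metrics import precision_recall_fscore_support
    from sklearn.model_selection import GridSearchCV, LeaveOneOut, StratifiedKFold
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler

    sub = table[features + ["ki67"]].dropna()
    if len(sub) < 5:
        raise ValueError("need >= 5 subjects")
    X = sub[features].to_numpy()
    y = (sub["ki67"].to_numpy() >= KI67_THRESHOLD).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both Ki-67 classes must be present")

    def make_pipe(name):
        if name == "logistic":
            from sklearn.linear_model import LogisticRegression
            clf = LogisticRegression(max_iter=2000, random_state=seed)
        elif name == "svm":
            from sklearn.svm import SVC
            clf = SVC(kernel="linear", random_state=seed)
        elif name == "random_forest":
            clf = RandomForestClassifier(random_state=seed)
        elif name == "gradient_boosting":
            clf = GradientBoostingClassifier(random_state=seed)
        else:
            raise ValueError(f"unknown model {name!r}")
        return Pipeline([("scaler", StandardScaler()), ("clf", clf)])

    grids = _model_grid(seed)
    report = ClassifierReport(features=list(features))
    pred_rows = []
    for name in models:
        grid = grids[name][1]
        y_pred = np.full(len(y), -1)
        skipped = []
        for i, (tr, te) in enumerate(LeaveOneOut().split(X)):
            if len(np.unique(y[tr])) < 2:
                skipped.append(i)
                warnings.warn(f"fold {i}: one class absent from training; skipped",
                              stacklevel=2)
                continue
            n_inner = min(3, np.bincount(y[tr]).min())
            inner = StratifiedKFold(n_splits=max(2, n_inner), shuffle=True,
                                    random_state=seed)
            gs = GridSearchCV(make_pipe(name), grid, cv=inner, scoring="accuracy")
            gs.fit(X[tr], y[tr])
            y_pred[te] = gs.predict(X[te])
        valid = y_pred >= 0
        acc = float((y_pred[valid] == y[valid]).mean()) if valid.any() else np.nan
        prec, rec, f1, _ = precision_recall_fscore_support(
            y[valid], y_pred[valid], labels=[1, 0], zero_division=0)
        report.metrics[name] = {
            "accuracy": acc,
            "precision_high": float(prec[0]), "precision_low": float(prec[1]),
            "recall_high": float(rec[0]), "recall_low": float(rec[1]),
            "f1_high": float(f1[0]), "f1_low": float(f1[1]),
        }
        report.skipped_folds[name] = skipped
        for i, (p, t) in enumerate(zip(y_pred, y)):
            pred_rows.append({"model": name, "fold": i, "true": int(t),
                              "pred": int(p) if p >= 0 else None})

        # importances from a full-cohort refit with the same inner search
        n_inner = min(3, np.bincount(y).min())
        inner = StratifiedKFold(n_splits=max(2, n_inner), shuffle=True,
                                random_state=seed)
        gs = GridSearchCV(make_pipe(name), grid, cv=inner, scoring="accuracy")
        gs.fit(X, y)
        clf = gs.best_estimator_.named_steps["clf"]
        if hasattr(clf, "feature_importances_"):
            imp = np.asarray(clf.feature_importances_, dtype=float)
        else:
            imp = np.abs(np.asarray(clf.coef_, dtype=float).ravel())
        total = imp.sum()
        imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
        report.importances[name] = {f: float(v) for f, v in zip(features, imp)}

    report.predictions = pd.DataFrame(pred_rows)
    return report
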