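"""Toxicity model building and paired automated-vs-manual comparison.

The workflow mirrors a standard small-cohort delta-radiomics analysis:

1. Rank features by random-forest Gini (mean impurity decrease)
   importance, pooling every BED bin of a feature and aggregating the
   per-column importances by maximum.
2. Greedily drop features whose |Spearman correlation| with an
   already-kept, higher-ranked feature exceeds 0.8 (strictly).
3. Keep up to the top seven survivors; a paired manual/automated
   comparison is constrained to the same feature set for both arms.
4. Per BED bin, fit leave-one-out logistic regression (standardized and
   median-imputed within each training fold) to obtain one out-of-fold
   probability per patient; summarize the AUC with 1000 stratified
   bootstrap resamples of the (score, label) pairs (median + 95%
   percentile CI).
5. Compare the paired manual and automated LOOCV score vectors per bin
   with the DeLong correlated-ROC test (two-sided, threshold 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .longitudinal import split_column_name


@dataclass(frozen=True)
class AnalysisConfig:
    correlation_threshold: float = 0.8
    max_features: int = 7
    n_bootstrap: int = 1000
    alpha: float = 0.05
    rf_n_trees: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if self.max_features < 1 or self.n_bootstrap < 1:
            raise ValueError("max_features and n_bootstrap must be >= 1")


@dataclass
class ModelResult:
    endpoint: str
    contour_type: str
    bed_bin: int
    selected_features: list[str]
    loocv_scores: np.ndarray
    labels: np.ndarray
    auc_point: float
    auc_distribution: np.ndarray
    auc_median: float
    auc_ci: tuple[float, float]
    converged: bool = True


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    variance_of_difference: float
    z: float
    p_two_sided: float


class DegenerateScoresError(ValueError):
    """Score vectors admit no variance estimate but have unequal AUCs."""


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------


def _impute_median(X: pd.DataFrame, medians: pd.Series | None = None) -> tuple[pd.DataFrame, pd.Series]:
    med = X.median() if medians is None else medians
    med = med.fillna(0.0)  # all-missing column: neutral fill
    return X.fillna(med), med


def gini_importance_ranking(
    X: pd.DataFrame, y: pd.Series, config: AnalysisConfig
) -> list[tuple[str, float]]:
    """Random-forest Gini importance per feature, pooled over BED bins.

    Columns named ``feature@binK`` are aggregated to ``feature`` by taking
    the maximum column importance; covariate columns stand alone.  Missing
    cells are median-imputed before fitting.  Returns a descending
    (feature, importance) list, deterministic given ``config.seed``.
    """
    yv = np.asarray(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("outcome has a single class; cannot rank features")
    Xi, _ = _impute_median(X)
    rf = RandomForestClassifier(
        n_estimators=config.rf_n_trees, random_state=config.seed, n_jobs=1
    )
    rf.fit(Xi.values, yv)
    col_imp = pd.Series(rf.feature_importances_, index=X.columns)
    agg: dict[str, float] = {}
    for col, imp in col_imp.items():
        feat, _ = split_column_name(col)
        agg[feat] = max(agg.get(feat, 0.0), float(imp))
    return sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))


def _pooled_feature_values(X: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per feature, values stacked over (patient, bin); covariates repeat per bin."""
    feats: dict[str, dict[int | None, pd.Series]] = {}
    bins: set[int] = set()
    for col in X.columns:
        feat, b = split_column_name(col)
        feats.setdefault(feat, {})[b] = X[col]
        if b is not None:
            bins.add(b)
    all_bins = sorted(bins) or [1]
    out = {}
    for feat, cols in feats.items():
        stacked = []
        for b in all_bins:
            if None in cols:  # covariate: constant across bins
                stacked.append(cols[None].values)
            elif b in cols:
                stacked.append(cols[b].values)
            else:
                stacked.append(np.full(len(X), np.nan))
        out[feat] = np.concatenate(stacked)
    return out


def correlation_filter(
    ranking: list[tuple[str, float]], X: pd.DataFrame, config: AnalysisConfig
) -> list[str]:
    """Greedy rank-order pass dropping features Spearman-correlated > threshold.

    Correlations use pooled-bin values with pairwise-complete observations.
    A tie at exactly the threshold keeps the feature (strict inequality).
    """
    pooled = _pooled_feature_values(X)
    kept: list[str] = []
    for feat, _score in ranking:
        v = pooled[feat]
        drop = False
        for k in kept:
            w = pooled[k]
            ok = ~(np.isnan(v) | np.isnan(w))
            if ok.sum() < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho = stats.spearmanr(v[ok], w[ok]).statistic
            if np.isfinite(rho) and abs(rho) > config.correlation_threshold:
                drop = True
                break
        if not drop:
            kept.append(feat)
    return kept


def select_top(surviving: list[str], config: AnalysisConfig) -> list[str]:
    """First min(max_features, len) survivors, in rank order."""
    if not surviving:
        raise ValueError("no surviving features to select from")
    return surviving[: config.max_features]


# ---------------------------------------------------------------------------
# per-bin models
# ---------------------------------------------------------------------------


def _fit_logistic(Xtr, ytr, C):
    clf = LogisticRegression(penalty="l2", C=C, solver="lbfgs", max_iter=2000)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(Xtr, ytr)
        converged = not any(issubclass(x.category, ConvergenceWarning) for x in w)
    return clf, converged


def loocv_scores(X_bin: pd.DataFrame, y: pd.Series, ridge_c: float = 1.0) -> tuple[np.ndarray, bool]:
    """Leave-one-out out-of-fold scores from logistic regression.

    Each training fold is median-imputed and standardized on its own
    statistics.  The model is first fit near-unpenalized (C = 1e6); if any
    fold fails to converge (typically perfect separation), all folds are
    refit uniformly with the documented ridge penalty (C = ``ridge_c``).

    Each score is the held-out predicted probability minus the training
    fold's class prevalence.  Pooling raw LOO probabilities is pessimistic
    (leaving out a positive lowers the fitted base rate, depressing that
    patient's score); centering by the fold prevalence removes this
    label-linked shift while leaving informative rankings intact.

    Returns (scores, used_unpenalized_fit).
    """
    yv = np.asarray(y).astype(int)
    if len(np.unique(yv)) < 2 or min(np.bincount(yv)) < 2:
        raise ValueError("need >= 2 patients per class for LOOCV")
    n = len(yv)

    def run(C):
        scores = np.empty(n)
        all_ok = True
        for i in range(n):
            tr = np.ones(n, dtype=bool)
            tr[i] = False
            Xtr, med = _impute_median(X_bin.iloc[tr])
            mu, sd = Xtr.mean(), Xtr.std(ddof=0).replace(0.0, 1.0)
            Ztr = ((Xtr - mu) / sd).values
            Xte, _ = _impute_median(X_bin.iloc[[i]], med)
            Zte = ((Xte - mu) / sd).values
            clf, ok = _fit_logistic(Ztr, yv[tr], C)
            all_ok &= ok
            p = clf.predict_proba(Zte)[0, list(clf.classes_).index(1)]
            scores[i] = p - yv[tr].mean()
        return scores, all_ok

    scores, ok = run(1e6)
    if not ok:
        scores, _ = run(ridge_c)
        return scores, False
    return scores, True


def mann_whitney_auc(scores, labels) -> float:
    """AUC as P(score+ > score-) + 0.5 P(tie), via midranks."""
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels).astype(int)
    n1, n0 = int((yv == 1).sum()), int((yv == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[yv == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def bootstrap_auc(
    scores, labels, config: AnalysisConfig
) -> tuple[np.ndarray, float, tuple[float, float]]:
    """Stratified bootstrap of the (score, label) pairs.

    Positives and negatives are resampled with replacement within class, so
    every resample retains both classes.  Returns (distribution, median,
    95% percentile CI), deterministic given ``config.seed``.
    """
    s = np.asarray(scores, dtype=float)
    yv = np.asarray(labels).astype(int)
    pos, neg = np.where(yv == 1)[0], np.where(yv == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(config.seed)
    aucs = np.empty(config.n_bootstrap)
    for b in range(config.n_bootstrap):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = mann_whitney_auc(s[idx], yv[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return aucs, float(np.median(aucs)), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# DeLong correlated-ROC test
# ---------------------------------------------------------------------------


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Structural components V10 (per positive), V01 (per negative), and AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank placements: V10_i = P(neg < pos_i) + 0.5 P(neg == pos_i)
    diff = pos[:, None] - neg[None, :]
    v10 = ((diff > 0).sum(axis=1) + 0.5 * (diff == 0).sum(axis=1)) / n
    v01 = ((diff > 0).sum(axis=0) + 0.5 * (diff == 0).sum(axis=0)) / m
    return v10, v01, float(v10.mean())


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Two-sided DeLong test for equality of two correlated AUCs.

    Both score vectors are evaluated on the same patients; the covariance
    of the AUC difference comes from the empirical covariance of the
    placement values (structural components).
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    yv = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != yv.shape:
        raise ValueError("paired score vectors must align with labels")
    m = int((yv == 1).sum())
    n = int((yv == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placements(sa, yv)
    v10b, v01b, auc_b = _placements(sb, yv)
    d10 = v10a - v10b
    d01 = v01a - v01b
    var = (np.var(d10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(d01, ddof=1) / n if n > 1 else 0.0
    )
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return DelongResult(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise DegenerateScoresError("zero variance of AUC difference with unequal AUCs")
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(auc_a, auc_b, float(var), float(z), float(min(p, 1.0)))


# ---------------------------------------------------------------------------
# contour-consistency QA
# ---------------------------------------------------------------------------


def spearman_bh_consistency(
    features_a: pd.DataFrame, features_b: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature Spearman agreement between two contour arms across patients.

    ``features_a``/``features_b`` are patients x features tables on the same
    patients (e.g. manual vs automated at fraction 1).  P-values are
    Benjamini-Hochberg adjusted over the feature family; ``significant``
    means adjusted p < alpha.  Constant features get NaN rho and are not
    counted in the family.
    """
    if not features_a.index.equals(features_b.index):
        features_b = features_b.loc[features_a.index]
    if len(features_a) < 3:
        raise ValueError("need >= 3 paired patients")
    rows = []
    for feat in features_a.columns:
        a = features_a[feat].values.astype(float)
        b = features_b[feat].values.astype(float)
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 3 or np.unique(a[ok]).size < 2 or np.unique(b[ok]).size < 2:
            rows.append((feat, np.nan, np.nan))
            continue
        res = stats.spearmanr(a[ok], b[ok])
        rows.append((feat, float(res.statistic), float(res.pvalue)))
    df = pd.DataFrame(rows, columns=["feature", "rho", "p"]).set_index("feature")
    padj = np.full(len(df), np.nan)
    testable = df["p"].notna().values
    if testable.any():
        padj[testable] = multipletests(df["p"].values[testable], method="fdr_bh")[1]
    df["p_adjusted"] = padj
    df["significant"] = df["p_adjusted"] < alpha
    return df


# ---------------------------------------------------------------------------
# endpoint-level orchestration
# ---------------------------------------------------------------------------


def _bins_of(X: pd.DataFrame) -> list[int]:
    return sorted({b for _, b in map(split_column_name, X.columns) if b is not None})


def _bin_design(X: pd.DataFrame, features: list[str], bed_bin: int) -> pd.DataFrame:
    cols = []
    for f in features:
        binned = f"{f}@bin{bed_bin}"
        if binned in X.columns:
            cols.append(binned)
        elif f in X.columns:  # covariate
            cols.append(f)
    return X[cols]


def fit_bin_model(
    X: pd.DataFrame,
    y: pd.Series,
    features: list[str],
    bed_bin: int,
    config: AnalysisConfig,
    endpoint: str = "",
    contour_type: str = "",
) -> ModelResult:
    """LOOCV logistic model for one BED bin on the selected features."""
    Xb = _bin_design(X, features, bed_bin)
    scores, unpenalized = loocv_scores(Xb, y)
    auc_point = mann_whitney_auc(scores, y)
    dist, med, ci = bootstrap_auc(scores, y, config)
    return ModelResult(
        endpoint=endpoint,
        contour_type=contour_type,
        bed_bin=bed_bin,
        selected_features=list(features),
        loocv_scores=scores,
        labels=np.asarray(y).astype(int),
        auc_point=auc_point,
        auc_distribution=dist,
        auc_median=med,
        auc_ci=ci,
        converged=unpenalized,
    )


@dataclass
class EndpointAnalysis:
    endpoint: str
    selected_features: list[str]
    ranking: list[tuple[str, float]]
    models: dict[tuple[str, int], ModelResult] = field(default_factory=dict)
    delong: dict[int, DelongResult] = field(default_factory=dict)
    snapshot: dict[str, ModelResult] = field(default_factory=dict)
    skipped_bins: list[int] = field(default_factory=list)


def run_endpoint_analysis(
    X_manual: pd.DataFrame,
    X_auto: pd.DataFrame,
    y: pd.Series,
    endpoint: str,
    config: AnalysisConfig,
    snapshot_features: dict[str, pd.DataFrame] | None = None,
) -> EndpointAnalysis:
    """Paired manual/automated per-bin models with DeLong comparison.

    Feature selection runs once, on the manual matrix with all BED bins
    pooled; both arms then use the identical feature set.  Bins with fewer
    than two patients per class (or failing model fits) are skipped.  If
    ``snapshot_features`` maps contour type to a patients x features table
    of fraction-1 (planning-style) raw features, a snapshot model per arm
    is fit on the selected features' baseline values.
    """
    ranking = gini_importance_ranking(X_manual, y, config)
    surviving = correlation_filter(ranking, X_manual, config)
    selected = select_top(surviving, config)
    out = EndpointAnalysis(endpoint=endpoint, selected_features=selected, ranking=ranking)
    yv = np.asarray(y).astype(int)
    if min(np.bincount(yv, minlength=2)) < 2:
        raise ValueError("need >= 2 patients per class")
    bins = sorted(set(_bins_of(X_manual)) & set(_bins_of(X_auto)))
    for b in bins:
        try:
            rm = fit_bin_model(X_manual, y, selected, b, config, endpoint, "manual")
            ra = fit_bin_model(X_auto, y, selected, b, config, endpoint, "automated")
        except ValueError:
            out.skipped_bins.append(b)
            continue
        out.models[("manual", b)] = rm
        out.models[("automated", b)] = ra
        out.delong[b] = delong_test(ra.loocv_scores, rm.loocv_scores, y)
    if snapshot_features:
        for arm, table in snapshot_features.items():
            cols = [f for f in selected if f in table.columns]
            if not cols:
                continue
            scores, unpen = loocv_scores(table.loc[y.index, cols], y)
            dist, med, ci = bootstrap_auc(scores, y, config)
            out.snapshot[arm] = ModelResult(
                endpoint=endpoint,
                contour_type=arm,
                bed_bin=0,
                selected_features=cols,
                loocv_scores=scores,
                labels=yv,
                auc_point=mann_whitney_auc(scores, y),
                auc_distribution=dist,
                auc_median=med,
                auc_ci=ci,
                converged=unpen,
            )
    return out
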