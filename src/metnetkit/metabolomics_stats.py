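"""Metabolomics preprocessing and differential statistics.

Pipeline order is enforced through the table's scale flag:

    raw --filter_missing--> raw --impute_half_min--> imputed
        --range_scale--> range-scaled

RSD QC runs on raw/imputed values; Welch / ANOVA / PCA / Ward clustering
require the range-scaled table (fold changes are always computed on the
imputed raw values, which the scaled table retains).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OmicsTable",
    "DifferentialResult",
    "PCAResult",
    "GroupEllipse",
    "RsdReport",
    "Dendrogram",
    "LogFcDistribution",
    "filter_missing",
    "impute_half_min",
    "range_scale",
    "welch_de",
    "anova_de",
    "compute_rsd",
    "run_pca",
    "ward_cluster",
    "logfc_distribution",
    "differential_pipeline",
    "results_frame",
]

logger = logging.getLogger(__name__)

SCALES = ("raw", "imputed", "range-scaled")


@dataclass
class OmicsTable:
    """Features x samples abundance matrix with condition labels.

    ``values`` holds features as rows and samples as columns; missing
    cells are NaN.  ``conditions`` maps each sample id to its condition
    label.  ``raw`` carries the imputed pre-scaling matrix once the
    table has been range-scaled (fold changes are computed from it).
    """

    values: pd.DataFrame
    conditions: pd.Series
    scale: str = "raw"
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale flag {self.scale!r}")
        if list(self.values.columns) != list(self.conditions.index):
            self.conditions = self.conditions.reindex(self.values.columns)
        if self.conditions.isna().any():
            bad = list(self.conditions.index[self.conditions.isna()])
            raise ValueError(f"samples without condition label: {bad[:5]}")
        if self.values.index.duplicated().any():
            dup = list(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dup[:5]}")
        if self.scale in ("raw", "imputed"):
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[~np.isnan(arr)] <= 0):
                raise ValueError("raw/imputed abundances must be positive where present")

    # -- convenience ---------------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def group_columns(self, condition: str) -> list[str]:
        cols = [s for s in self.samples if self.conditions[s] == condition]
        if not cols:
            raise KeyError(f"no samples with condition {condition!r}")
        return cols

    def condition_labels(self) -> list[str]:
        seen: list[str] = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen

    def subset_conditions(self, labels: Iterable[str]) -> "OmicsTable":
        labels = list(labels)
        cols = [s for s in self.samples if self.conditions[s] in labels]
        return OmicsTable(
            values=self.values[cols],
            conditions=self.conditions[cols],
            scale=self.scale,
            raw=self.raw[cols] if self.raw is not None else None,
        )

    def _require_scale(self, *allowed: str, op: str) -> None:
        if self.scale not in allowed:
            raise ValueError(
                f"{op} requires a table at scale {allowed}, got {self.scale!r}; "
                "pipeline order is filter -> impute -> range-scale -> tests"
            )


@dataclass(frozen=True)
class DifferentialResult:
    feature: str
    mean_a: float
    mean_b: float
    log2_fold_change: float
    statistic: float
    df: float
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class GroupEllipse:
    condition: str
    center: tuple[float, float]
    # semi-axis lengths of the 95% ellipse and the rotation of the major axis
    semi_axes: tuple[float, float]
    angle_rad: float


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    explained_variance_ratio: np.ndarray
    ellipses: list[GroupEllipse]


@dataclass
class RsdReport:
    per_feature: pd.DataFrame  # features x groups, RSD = sd/mean
    group_medians: pd.Series


@dataclass
class Dendrogram:
    linkage_matrix: np.ndarray  # scipy linkage format
    labels: list[str]
    leaf_order: list[str]

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assignments = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(a) for a in assignments)))


@dataclass
class LogFcDistribution:
    log2fc: pd.Series
    median: float
    sign_test_p: float


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def filter_missing(
    t: OmicsTable, max_missing_frac: float = 0.5, mode: str = "all-groups"
) -> OmicsTable:
    """Drop features by per-condition missingness.

    ``all-groups`` (default): a feature is removed only when its missing
    fraction exceeds *max_missing_frac* in **every** condition group, so
    compounds detected in even one condition survive.  ``any-group``:
    removed as soon as one group exceeds the threshold.
    """
    t._require_scale("raw", op="filter_missing")
    if mode not in ("all-groups", "any-group"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = t.condition_labels()
    frac = pd.DataFrame(index=t.features, columns=labels, dtype=float)
    for label in labels:
        cols = t.group_columns(label)
        frac[label] = t.missing_mask[cols].mean(axis=1)
    exceeded = frac.gt(max_missing_frac)
    removed = exceeded.all(axis=1) if mode == "all-groups" else exceeded.any(axis=1)
    dropped = list(t.values.index[removed])
    if dropped:
        logger.info("filter_missing removed %d feature(s): %s", len(dropped), dropped[:10])
    return OmicsTable(
        values=t.values.loc[~removed],
        conditions=t.conditions,
        scale="raw",
    )


def impute_half_min(t: OmicsTable) -> OmicsTable:
    """Replace missing cells with half the feature's minimum observed value."""
    t._require_scale("raw", op="impute_half_min")
    values = t.values.copy()
    mins = values.min(axis=1, skipna=True)
    dead = mins.isna()
    if dead.any():
        raise ValueError(
            "feature(s) with zero observed values (run filter_missing first): "
            f"{list(values.index[dead])[:5]}"
        )
    fill = mins / 2.0
    values = values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
    return OmicsTable(values=values, conditions=t.conditions, scale="imputed")


def range_scale(t: OmicsTable) -> OmicsTable:
    """Per-feature scaling x' = (x - mean) / (max - min).

    Zero-range features become all-zeros (logged).  The imputed raw
    matrix is kept on the result for fold-change computation.
    """
    t._require_scale("imputed", op="range_scale")
    values = t.values
    mean = values.mean(axis=1)
    span = values.max(axis=1) - values.min(axis=1)
    flat = span == 0
    if flat.any():
        logger.warning(
            "range_scale: %d zero-range feature(s) set to zeros: %s",
            int(flat.sum()),
            list(values.index[flat])[:10],
        )
    safe_span = span.replace(0, np.nan)
    scaled = values.sub(mean, axis=0).div(safe_span, axis=0)
    scaled.loc[flat] = 0.0
    return OmicsTable(values=scaled, conditions=t.conditions, scale="range-scaled", raw=values)


# ---------------------------------------------------------------------------
# differential statistics
# ---------------------------------------------------------------------------


def _welch_row(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """(t, df, p) with explicit degenerate-case conventions."""
    na, nb = len(a), len(b)
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if ma == mb:
            return 0.0, float(na + nb - 2), 1.0
        logger.warning("welch_de: zero variance in both groups with unequal means; p=0")
        return np.inf if ma > mb else -np.inf, float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    tstat = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return float(tstat), float(df), float(min(1.0, p))


def _log2fc(raw: pd.DataFrame, cols_a: list[str], cols_b: list[str]) -> pd.Series:
    mean_a = raw[cols_a].mean(axis=1)
    mean_b = raw[cols_b].mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(mean_b / mean_a)


def welch_de(
    t: OmicsTable,
    group_a: str,
    group_b: str,
    fdr_threshold: float = 0.1,
) -> list[DifferentialResult]:
    """Per-feature Welch's t-test (group A vs B) with BH FDR.

    The test runs on the range-scaled values; the reported means and
    log2 fold change (B over A) come from the imputed raw values.
    Results are ordered as the table's features.
    """
    t._require_scale("range-scaled", op="welch_de")
    cols_a = t.group_columns(group_a)
    cols_b = t.group_columns(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    raw = t.raw if t.raw is not None else t.values
    l2fc = _log2fc(raw, cols_a, cols_b)

    rows = []
    for feat in t.features:
        a = t.values.loc[feat, cols_a].to_numpy(dtype=float)
        b = t.values.loc[feat, cols_b].to_numpy(dtype=float)
        tstat, df, p = _welch_row(a, b)
        rows.append((feat, tstat, df, p))
    pvals = np.array([r[3] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    mean_a = raw[cols_a].mean(axis=1)
    mean_b = raw[cols_b].mean(axis=1)
    return [
        DifferentialResult(
            feature=feat,
            mean_a=float(mean_a[feat]),
            mean_b=float(mean_b[feat]),
            log2_fold_change=float(l2fc[feat]),
            statistic=tstat,
            df=df,
            p_value=p,
            q_value=float(q),
            significant=bool(q < fdr_threshold),
        )
        for (feat, tstat, df, p), q in zip(rows, qvals)
    ]


def anova_de(
    t: OmicsTable,
    groups: Sequence[str],
    fdr_threshold: float = 0.1,
) -> list[DifferentialResult]:
    """One-way ANOVA across >= 3 condition groups with BH FDR.

    Reported means/log2FC contrast the last group over the first.
    """
    t._require_scale("range-scaled", op="anova_de")
    if len(groups) < 3:
        raise ValueError("anova_de needs >= 3 groups (use welch_de for 2)")
    group_cols = {g: t.group_columns(g) for g in groups}
    for g, cols in group_cols.items():
        if len(cols) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    k = len(groups)
    n_total = sum(len(c) for c in group_cols.values())
    df_between = k - 1
    df_within = n_total - k
    raw = t.raw if t.raw is not None else t.values
    cols_a, cols_b = group_cols[groups[0]], group_cols[groups[-1]]
    l2fc = _log2fc(raw, cols_a, cols_b)
    mean_a = raw[cols_a].mean(axis=1)
    mean_b = raw[cols_b].mean(axis=1)

    rows = []
    for feat in t.features:
        samples = [t.values.loc[feat, cols].to_numpy(dtype=float) for cols in group_cols.values()]
        grand = np.concatenate(samples).mean()
        ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
        ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
        if ssw == 0:
            if ssb == 0:
                f, p = 0.0, 1.0
            else:
                logger.warning("anova_de: zero within-group variance for %r; p=0", feat)
                f, p = np.inf, 0.0
        else:
            f = (ssb / df_between) / (ssw / df_within)
            p = float(stats.f.sf(f, df_between, df_within))
        rows.append((feat, float(f), p))
    pvals = np.array([r[2] for r in rows])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        DifferentialResult(
            feature=feat,
            mean_a=float(mean_a[feat]),
            mean_b=float(mean_b[feat]),
            log2_fold_change=float(l2fc[feat]),
            statistic=f,
            df=float(df_between),
            p_value=p,
            q_value=float(q),
            significant=bool(q < fdr_threshold),
        )
        for (feat, f, p), q in zip(rows, qvals)
    ]


def compute_rsd(t: OmicsTable, grouping: Sequence[str] | None = None) -> RsdReport:
    """Per-feature, per-group relative standard deviation (sd/mean).

    Uses sample sd (n-1).  Cells with zero group mean are excluded with
    a warning.  Group medians are taken across features.
    """
    t._require_scale("raw", "imputed", op="compute_rsd")
    labels = list(grouping) if grouping is not None else t.condition_labels()
    per_feature = pd.DataFrame(index=t.features, columns=labels, dtype=float)
    for label in labels:
        cols = t.group_columns(label)
        block = t.values[cols]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = mean == 0
        if zero.any():
            logger.warning(
                "compute_rsd: zero mean for %d feature(s) in group %r; RSD undefined",
                int(zero.sum()),
                label,
            )
        per_feature[label] = (sd / mean.replace(0, np.nan)).astype(float)
    medians = per_feature.median(axis=0, skipna=True)
    return RsdReport(per_feature=per_feature, group_medians=medians)


def run_pca(t: OmicsTable, n_components: int = 2) -> PCAResult:
    """PCA of samples in feature space, with 95% group ellipses.

    Samples are observations, features variables (the table is already
    feature-scaled).  Ellipses come from each condition group's score
    covariance on the first two components, at the chi-square 2-df 95%
    quantile; groups with < 3 samples get no ellipse.
    """
    t._require_scale("range-scaled", op="run_pca")
    X = t.values.to_numpy(dtype=float).T  # samples x features
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise ValueError("run_pca needs >= 2 samples")
    if n_components > min(n_samples, n_features):
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, features)="
            f"{min(n_samples, n_features)}"
        )
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores_df = pd.DataFrame(scores, index=t.samples, columns=comp_names)
    loadings_df = pd.DataFrame(model.components_.T, index=t.features, columns=comp_names)

    ellipses: list[GroupEllipse] = []
    if n_components >= 2:
        chi2_95 = stats.chi2.ppf(0.95, df=2)
        for label in t.condition_labels():
            cols = t.group_columns(label)
            pts = scores_df.loc[cols, ["PC1", "PC2"]].to_numpy()
            if len(pts) < 3:
                continue
            center = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False)
            eigvals, eigvecs = np.linalg.eigh(cov)
            order = np.argsort(eigvals)[::-1]
            eigvals, eigvecs = eigvals[order], eigvecs[:, order]
            semi = np.sqrt(np.clip(eigvals, 0, None) * chi2_95)
            angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
            ellipses.append(
                GroupEllipse(
                    condition=label,
                    center=(float(center[0]), float(center[1])),
                    semi_axes=(float(semi[0]), float(semi[1])),
                    angle_rad=angle,
                )
            )
    return PCAResult(
        scores=scores_df,
        loadings=loadings_df,
        explained_variance_ratio=model.explained_variance_ratio_,
        ellipses=ellipses,
    )


def ward_cluster(t: OmicsTable, axis: str = "features") -> Dendrogram:
    """Ward-linkage agglomerative clustering on Euclidean distances.

    *axis* picks whether features or samples are clustered.  Items are
    presented to the linkage in lexicographic id order so equal-distance
    merges break ties identically on every run.
    """
    t._require_scale("range-scaled", op="ward_cluster")
    if axis == "features":
        frame = t.values
    elif axis == "samples":
        frame = t.values.T
    else:
        raise ValueError(f"axis must be 'features' or 'samples', got {axis!r}")
    if len(frame) < 2:
        raise ValueError("ward_cluster needs >= 2 items")
    frame = frame.sort_index()
    labels = list(frame.index)
    Z = linkage(frame.to_numpy(dtype=float), method="ward", metric="euclidean")
    order = [labels[i] for i in leaves_list(Z)]
    return Dendrogram(linkage_matrix=Z, labels=labels, leaf_order=order)


def logfc_distribution(t: OmicsTable, group_a: str, group_b: str) -> LogFcDistribution:
    """Per-feature log2 fold change (B over A) with median and sign-test p.

    Runs on imputed raw values (or the retained raw matrix of a scaled
    table).  The sign test is an exact two-sided binomial test on the
    number of positive fold changes among the nonzero ones.
    """
    if t.scale == "range-scaled":
        if t.raw is None:
            raise ValueError("scaled table lacks its raw matrix")
        raw = t.raw
    else:
        t._require_scale("imputed", "raw", op="logfc_distribution")
        raw = t.values
    cols_a = t.group_columns(group_a)
    cols_b = t.group_columns(group_b)
    l2fc = _log2fc(raw, cols_a, cols_b)
    nonzero = l2fc[l2fc != 0]
    if len(nonzero) == 0:
        p = 1.0
    else:
        p = float(stats.binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5).pvalue)
    return LogFcDistribution(log2fc=l2fc, median=float(l2fc.median()), sign_test_p=p)


def differential_pipeline(
    t: OmicsTable,
    group_a: str,
    group_b: str,
    max_missing_frac: float = 0.5,
    missing_filter_mode: str = "all-groups",
    fdr_threshold: float = 0.1,
) -> list[DifferentialResult]:
    """Full two-group contrast: subset -> filter -> impute -> scale -> Welch+BH.

    The table is restricted to the two condition groups before the
    missingness filter, so "missing per condition" is judged on the
    groups actually contrasted.
    """
    sub = t.subset_conditions([group_a, group_b])
    sub = filter_missing(sub, max_missing_frac=max_missing_frac, mode=missing_filter_mode)
    sub = impute_half_min(sub)
    sub = range_scale(sub)
    return welch_de(sub, group_a, group_b, fdr_threshold=fdr_threshold)


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of differential results (TSV-ready)."""
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "mean_a": [r.mean_a for r in results],
            "mean_b": [r.mean_b for r in results],
            "log2fc": [r.log2_fold_change for r in results],
            "stat": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
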