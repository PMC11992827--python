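"""Serum-metabolomics preprocessing, differential-metabolite screening and
random-forest biomarker panel selection.

The filter chain runs in a fixed order — missingness filter with mean
imputation, QC relative-standard-deviation filter, low-variance filter, then
sum normalization / log10 / mean-centering — and each stage appends its
survivor count to the table's provenance log.  The differential screen keeps
features with PLS-DA VIP > 1, Welch t-test p < 0.05 and bidirectional fold
change max(FC, 1/FC) > 1 between two sample groups.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .model import rank_auc

logger = logging.getLogger("ctpdn")


@dataclass
class PeakTable:
    """Peak-intensity matrix (features in rows, samples in columns) with
    sample group labels and QC flags.  ``NaN`` encodes a missing intensity,
    distinct from a measured zero.  ``pre_log`` holds the sum-normalized but
    un-logged intensities once :func:`normalize_table` has run (fold changes
    are computed on that scale)."""

    intensities: pd.DataFrame
    groups: pd.Series
    is_qc: pd.Series
    mz: pd.Series | None = None
    rt: pd.Series | None = None
    pre_log: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        samples = list(self.intensities.columns)
        if list(self.groups.index) != samples or list(self.is_qc.index) != samples:
            raise ValueError("group/QC annotations must be indexed by the sample columns")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    def biological_samples(self) -> list[str]:
        return [s for s in self.intensities.columns if not self.is_qc[s]]

    def qc_samples(self) -> list[str]:
        return [s for s in self.intensities.columns if self.is_qc[s]]

    def _derive(self, intensities: pd.DataFrame, stage: str, pre_log=None) -> "PeakTable":
        return PeakTable(
            intensities=intensities,
            groups=self.groups, is_qc=self.is_qc,
            mz=self.mz.loc[intensities.index] if self.mz is not None else None,
            rt=self.rt.loc[intensities.index] if self.rt is not None else None,
            pre_log=pre_log,
            log=self.log + [f"{stage}: {intensities.shape[0]} features"],
        )


# ---------------------------------------------------------------------------
# I/O: TSV with '#group' and '#qc' annotation rows


def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "#group" not in df.index or "#qc" not in df.index:
        raise ValueError(f"{path}: peak table needs '#group' and '#qc' annotation rows")
    groups = df.loc["#group"].astype(str)
    is_qc = df.loc["#qc"].astype(str).str.lower().isin(("1", "true", "yes"))
    mz = rt = None
    data = df.drop(index=["#group", "#qc"])
    if "#mz" in data.index:
        mz = data.loc["#mz"]
        data = data.drop(index="#mz")
    body = data.astype(float)
    with np.errstate(invalid="ignore"):
        if (body.to_numpy() < 0).any():
            raise ValueError(f"{path}: negative raw intensity")
    if mz is not None:
        mz = mz.astype(float)
    return PeakTable(intensities=body, groups=groups, is_qc=is_qc, mz=mz)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    header = pd.DataFrame(
        [table.groups.astype(str), table.is_qc.astype(int).astype(str)],
        index=["#group", "#qc"],
    )
    pd.concat([header, table.intensities]).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filter chain


def filter_missing(table: PeakTable, max_missing: float = 0.8) -> PeakTable:
    """Drop features missing in more than ``max_missing`` of the samples;
    impute the remaining missing values with the feature's observed mean."""
    X = table.intensities
    frac = X.isna().mean(axis=1)
    kept = X[frac <= max_missing]
    imputed = kept.apply(lambda row: row.fillna(row.mean()), axis=1)
    return table._derive(imputed, f"missing<= {max_missing:g} + mean imputation")


def filter_qc_rsd(table: PeakTable, max_rsd: float = 0.20) -> PeakTable:
    """Drop features whose relative standard deviation (sd/mean) across the
    pooled-QC injections exceeds ``max_rsd``; undefined RSD (QC mean 0) also
    drops the feature."""
    qc = table.qc_samples()
    if len(qc) < 2:
        raise ValueError("QC-RSD filter needs at least two QC samples")
    Xqc = table.intensities[qc]
    mean = Xqc.mean(axis=1)
    sd = Xqc.std(axis=1, ddof=1)
    undefined = mean == 0
    if undefined.any():
        logger.warning(
            "QC mean 0 for feature(s) %s: RSD undefined, removed",
            ", ".join(map(str, table.intensities.index[undefined])),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = sd / mean
    keep = (~undefined) & (rsd <= max_rsd)
    return table._derive(table.intensities[keep], f"QC RSD<= {max_rsd:g}")


def filter_low_sd(table: PeakTable, drop_fraction: float = 0.40) -> PeakTable:
    """Drop the ``drop_fraction`` of features with the lowest standard
    deviation over the biological samples; ceil(0.6 F) features survive at
    the default.  Ties resolve by feature id (the earlier id survives)."""
    if not 0.0 <= drop_fraction < 1.0:
        raise ValueError("drop_fraction must be in [0, 1)")
    X = table.intensities
    n_keep = math.ceil((1.0 - drop_fraction) * X.shape[0])
    sd = X[table.biological_samples()].std(axis=1, ddof=1)
    order = sorted(X.index, key=lambda f: (-sd[f], str(f)))
    kept_ids = set(order[:n_keep])
    kept = X[[f in kept_ids for f in X.index]]
    return table._derive(kept, f"SD filter drop {drop_fraction:g}")


def normalize_table(table: PeakTable, autoscale: bool = False) -> PeakTable:
    """Sum-normalize each sample (to the median sample total), log10 with a
    pseudo-count of half the minimum positive intensity, then mean-center
    each feature (``autoscale`` additionally scales to unit variance)."""
    X = table.intensities
    totals = X.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total intensity")
    pre_log = X / totals * float(np.median(totals))
    positive = pre_log.to_numpy()[pre_log.to_numpy() > 0]
    pseudo = 0.5 * positive.min() if positive.size else 1.0
    logged = np.log10(pre_log + pseudo)
    centered = logged.sub(logged.mean(axis=1), axis=0)
    if autoscale:
        sd = centered.std(axis=1, ddof=1).replace(0, 1.0)
        centered = centered.div(sd, axis=0)
    stage = "sum-normalize + log10 + center" + (" + autoscale" if autoscale else "")
    return table._derive(centered, stage, pre_log=pre_log)


# ---------------------------------------------------------------------------
# differential screen


def pls_da_vip(table: PeakTable, groups: tuple[str, str], n_components: int = 2) -> pd.Series:
    """Variable importance in projection from a PLS-DA fit of the two groups.

    The class indicator is regressed on the (preprocessed) feature matrix by
    NIPALS partial least squares; VIP_j = sqrt(p * sum_a SS_a (w_aj/|w_a|)^2
    / sum_a SS_a) where SS_a is the y-variance captured by component a.  The
    mean of VIP^2 over features is exactly 1.
    """
    samples = [s for s in table.biological_samples() if table.groups[s] in groups]
    if not samples:
        raise ValueError(f"no samples in groups {groups}")
    X = table.intensities[samples].to_numpy(dtype=float).T  # samples x features
    y = np.array([1.0 if table.groups[s] == groups[1] else 0.0 for s in samples])
    if len(set(y)) < 2:
        raise ValueError("PLS-DA needs samples from both groups")
    n, p = X.shape
    A = max(1, min(n_components, n - 1, p))
    pls = PLSRegression(n_components=A, scale=False)
    pls.fit(X, y - y.mean())

    W = pls.x_weights_  # p x A
    T = pls.x_scores_  # n x A
    Q = pls.y_loadings_  # 1 x A
    ss = (T ** 2).sum(axis=0) * (Q.ravel() ** 2)
    if ss.sum() == 0:
        logger.warning("PLS-DA captured no class variance; VIP set to 0")
        return pd.Series(0.0, index=table.intensities.index)
    wnorm2 = (W ** 2).sum(axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    vip2 = p * ((W ** 2) / wnorm2) @ ss / ss.sum()
    return pd.Series(np.sqrt(vip2), index=table.intensities.index)


def differential_screen(
    table: PeakTable,
    groups: tuple[str, str] = ("Con", "Mod"),
    vip_min: float = 1.0,
    p_max: float = 0.05,
    fc_min: float = 1.0,
    n_components: int = 2,
) -> pd.DataFrame:
    """Screen features that differ between two groups.

    A feature passes when VIP > ``vip_min`` AND the two-sided Welch t-test on
    the log-scale intensities gives p < ``p_max`` AND the bidirectional fold
    change max(FC, 1/FC) exceeds ``fc_min``, where FC is the ratio of group
    mean intensities (groups[1]/groups[0]) on the pre-log normalized scale.
    Requires :func:`normalize_table` to have run (it records that scale).
    """
    if table.pre_log is None:
        raise ValueError("differential_screen requires a normalized table (run normalize_table)")
    a_samples = [s for s in table.biological_samples() if table.groups[s] == groups[0]]
    b_samples = [s for s in table.biological_samples() if table.groups[s] == groups[1]]
    if len(a_samples) < 2 or len(b_samples) < 2:
        raise ValueError("each group needs at least two samples")

    vip = pls_da_vip(table, groups, n_components)
    Xa = table.intensities[a_samples].to_numpy(dtype=float)
    Xb = table.intensities[b_samples].to_numpy(dtype=float)
    pvals = stats.ttest_ind(Xb, Xa, axis=1, equal_var=False).pvalue

    mean_a = table.pre_log[a_samples].mean(axis=1)
    mean_b = table.pre_log[b_samples].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (mean_b / mean_a).to_numpy()
    fc_bi = np.where(np.isfinite(fc) & (fc > 0), np.maximum(fc, 1.0 / fc), np.inf)

    out = pd.DataFrame({
        "feature_id": table.feature_ids,
        "vip": vip.to_numpy(),
        "p": pvals,
        "fc": fc,
        "passes": (vip.to_numpy() > vip_min) & (pvals < p_max) & (fc_bi > fc_min),
    })
    if table.mz is not None:
        out["mz"] = table.mz.to_numpy()
    return out


# ---------------------------------------------------------------------------
# biomarker panels


@dataclass
class BiomarkerPanel:
    features: list[str]  # ranked, most important first
    cv_accuracy: float
    cv_auc: float
    seed: int = 0

    def to_jsonable(self) -> dict:
        return {
            "features": self.features,
            "cv_accuracy": self.cv_accuracy,
            "cv_auc": self.cv_auc,
            "seed": self.seed,
        }


def _rank_by_forest_importance(X, y, seed, n_splits=5, n_estimators=200) -> np.ndarray:
    """Mean random-forest importance over stratified CV training folds."""
    imp = np.zeros(X.shape[1])
    n_splits = min(n_splits, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for train, _ in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        rf.fit(X[train], y[train])
        imp += rf.feature_importances_
    return imp / n_splits


def rf_biomarker_panel(
    table: PeakTable,
    groups: tuple[str, str] = ("Con", "Mod"),
    k: int = 10,
    seed: int = 0,
    n_splits: int = 5,
    n_estimators: int = 200,
    evaluate: bool = True,
) -> BiomarkerPanel:
    """Select a top-``k`` biomarker panel by random-forest importance and
    evaluate it with nested cross validation.

    The reported accuracy and rank-AUC come from an outer stratified CV in
    which, for each split, features are re-ranked on the training fold alone
    and a fresh forest is fitted on that fold's top-k — so the panel metrics
    never see their own test samples during selection (no leakage).  The
    returned panel itself is ranked on all samples.
    """
    samples = [s for s in table.biological_samples() if table.groups[s] in groups]
    X = table.intensities[samples].to_numpy(dtype=float).T
    y = np.array([int(table.groups[s] == groups[1]) for s in samples])
    if len(y) < 10:
        raise ValueError("biomarker selection needs at least 10 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both groups must be present")
    k = min(k, X.shape[1])
    feature_ids = np.array(table.feature_ids)

    cv_accuracy = cv_auc = float("nan")
    if evaluate:
        outer = StratifiedKFold(
            n_splits=min(n_splits, int(np.bincount(y).min())), shuffle=True, random_state=seed
        )
        pooled_pred = np.empty(len(y), dtype=int)
        pooled_score = np.empty(len(y), dtype=float)
        for train, test in outer.split(X, y):
            imp = _rank_by_forest_importance(X[train], y[train], seed, n_splits, n_estimators)
            top = np.argsort(-imp, kind="stable")[:k]
            rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
            rf.fit(X[np.ix_(train, top)], y[train])
            pooled_pred[test] = rf.predict(X[np.ix_(test, top)])
            pooled_score[test] = rf.predict_proba(X[np.ix_(test, top)])[:, 1]
        cv_accuracy = float(np.mean(pooled_pred == y))
        cv_auc = rank_auc(pooled_score, y)

    importance = _rank_by_forest_importance(X, y, seed, n_splits, n_estimators)
    panel_idx = np.argsort(-importance, kind="stable")[:k]
    return BiomarkerPanel(
        features=[str(f) for f in feature_ids[panel_idx]],
        cv_accuracy=cv_accuracy,
        cv_auc=cv_auc,
        seed=seed,
    )


def intersect_panels(panel_a, panel_b) -> list[str]:
    """Features common to both panels, in ``panel_a``'s rank order."""
    a = panel_a.features if isinstance(panel_a, BiomarkerPanel) else list(panel_a)
    b = set(panel_b.features if isinstance(panel_b, BiomarkerPanel) else panel_b)
    return [f for f in a if f in b]
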