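"""Quantifying background noise: PC-covariate correlations and comparisons.

The central diagnostic asks how strongly each principal component of the
feature table tracks each sample covariate (study, sequencing center, age,
...). Continuous covariates use the absolute Pearson correlation with the
PC scores; categorical covariates use the first canonical correlation
between the scores and the dummy-coded levels, which for a single score
vector equals sqrt(R^2) of the OLS regression of scores on the dummies.
Canonical correlations are non-negative by construction, so the matrix
lives in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FeatureTableError, SampleMetadata
from .corrections import PCModel

logger = logging.getLogger("mbnoise")


@dataclass
class CorrelationMatrix:
    pc_index: list[int]                # 1-based
    covariate_names: list[str]
    correlations: np.ndarray           # n_pcs x n_covariates, in [0, 1]
    p_values: np.ndarray
    test_used: np.ndarray              # "pearson-t" | "F" | "constant" per cell

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.correlations,
            index=[f"PC{i}" for i in self.pc_index],
            columns=self.covariate_names,
        )


def _continuous_correlation(scores: np.ndarray, covariate: np.ndarray):
    r, p = stats.pearsonr(scores, covariate)
    return abs(float(r)), float(p)


def _categorical_correlation(scores: np.ndarray, labels: np.ndarray):
    """First canonical correlation of one score vector vs dummy-coded labels.

    Computed as sqrt(R^2) from OLS of scores on (intercept + L-1 dummies);
    p-value from the regression F-test.
    """
    levels = pd.unique(labels)
    n = len(scores)
    dummies = np.stack([(labels == lv).astype(float) for lv in levels[1:]], axis=1) \
        if len(levels) > 1 else np.empty((n, 0))
    X = np.column_stack([np.ones(n), dummies])
    beta, *_ = np.linalg.lstsq(X, scores, rcond=None)
    fitted = X @ beta
    ss_tot = float(((scores - scores.mean()) ** 2).sum())
    ss_res = float(((scores - fitted) ** 2).sum())
    df_model = X.shape[1] - 1
    df_resid = n - X.shape[1]
    if ss_tot == 0 or df_model == 0 or df_resid <= 0:
        return 0.0, 1.0
    r2 = max(0.0, 1 - ss_res / ss_tot)
    if ss_res <= 0:
        return 1.0, float(stats.f.sf(np.inf, df_model, df_resid))
    f_stat = (ss_tot - ss_res) / df_model / (ss_res / df_resid)
    return float(np.sqrt(r2)), float(stats.f.sf(f_stat, df_model, df_resid))


def pc_covariate_correlation(
    model: PCModel,
    meta: SampleMetadata,
    covariates: list[str] | None = None,
    n_pcs: int = 15,
) -> CorrelationMatrix:
    """Correlation of the top PCs with each covariate, with significance.

    Constant covariates get correlation 0 with p=1 and a warning rather
    than an error, so a screening run over many covariates never aborts.
    """
    n_pcs = min(n_pcs, model.n_components)
    if n_pcs < 1:
        raise FeatureTableError("model has no components")
    if covariates is None:
        covariates = [c for c in meta.data.columns]
    samples = model.sample_ids or meta.sample_ids
    corr = np.zeros((n_pcs, len(covariates)))
    pvals = np.ones((n_pcs, len(covariates)))
    tests = np.empty((n_pcs, len(covariates)), dtype=object)
    for j, cov in enumerate(covariates):
        series = meta.column(cov, samples)
        kind = meta.type_of(cov)
        if kind == "continuous":
            vec = series.to_numpy(float)
            constant = np.ptp(vec) == 0
        else:
            vec = series.astype(str).to_numpy()
            constant = len(pd.unique(vec)) < 2
        for i in range(n_pcs):
            scores = model.scores[:, i]
            if constant or np.ptp(scores) == 0:
                warnings.warn(f"covariate {cov!r} (or PC{i + 1}) is constant; correlation set to 0")
                corr[i, j], pvals[i, j], tests[i, j] = 0.0, 1.0, "constant"
            elif kind == "continuous":
                corr[i, j], pvals[i, j] = _continuous_correlation(scores, vec)
                tests[i, j] = "pearson-t"
            else:
                corr[i, j], pvals[i, j] = _categorical_correlation(scores, vec)
                tests[i, j] = "F"
    return CorrelationMatrix(
        pc_index=list(range(1, n_pcs + 1)),
        covariate_names=list(covariates),
        correlations=corr,
        p_values=pvals,
        test_used=tests,
    )


@dataclass
class PairedComparison:
    statistic: float
    p_value: float
    median_before: float
    median_after: float
    n_pairs: int
    n_nonzero: int


def compare_correlation_distributions(
    before: CorrelationMatrix,
    after: CorrelationMatrix,
    covariate_subset: list[str] | None = None,
) -> PairedComparison:
    """One-sided paired Wilcoxon signed-rank on matched (PC, covariate) cells.

    Tests whether the "after" correlations are stochastically greater than
    the "before" correlations. Zero differences are dropped; the exact null
    distribution is used for <= 25 informative pairs, the normal
    approximation with continuity correction above that.
    """
    if before.pc_index != after.pc_index:
        raise FeatureTableError("correlation matrices have different PC grids")
    cols = covariate_subset or before.covariate_names
    if set(cols) - set(before.covariate_names) or set(cols) - set(after.covariate_names):
        raise FeatureTableError("covariate subset not present in both matrices")
    bi = [before.covariate_names.index(c) for c in cols]
    ai = [after.covariate_names.index(c) for c in cols]
    b = before.correlations[:, bi].ravel()
    a = after.correlations[:, ai].ravel()
    diff = a - b
    nonzero = int((diff != 0).sum())
    if nonzero < 5:
        raise FeatureTableError(
            f"only {nonzero} non-tied pairs; the signed-rank test is uninformative below 5"
        )
    method = "exact" if nonzero <= 25 else "approx"
    res = stats.wilcoxon(
        a, b, alternative="greater", zero_method="wilcox", method=method, correction=True
    )
    return PairedComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_before=float(np.median(b)),
        median_after=float(np.median(a)),
        n_pairs=len(diff),
        n_nonzero=nonzero,
    )


def variance_explained_summary(model: PCModel, top: int):
    """Per-component variance fractions of the leading PCs and their sum."""
    if not 1 <= top <= model.n_components:
        raise FeatureTableError(f"top={top} out of range [1, {model.n_components}]")
    fractions = model.variance_fraction[:top]
    return fractions.copy(), float(fractions.sum())
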