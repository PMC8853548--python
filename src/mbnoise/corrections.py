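"""Supervised and unsupervised background-noise correction.

Supervised methods use the study/batch label (and optionally further
covariates): batch mean centering (BMC), direct covariate correction (DCC,
per-feature OLS residuals), limma-style linear batch removal with an
optional protected phenotype term, parametric empirical-Bayes ComBat, and
percentile normalization against within-batch controls.

The unsupervised method removes the projection of CLR-transformed data onto
its top principal components, either a fixed number ``p`` or a ``p`` tuned
by phenotype-prediction performance on a validation split. Multiplicative
per-study bias is additive in CLR space and concentrates in the top PCs, so
regressing them out strips study structure without using the study label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core_io import FeatureTable, FeatureTableError, SampleMetadata, closure
from .transforms import inverse_clr

logger = logging.getLogger("mbnoise")

COMBAT_CONV_TOL = 1e-6
COMBAT_MAX_ITER = 500


# ---------------------------------------------------------------------------
# designs and result containers
# ---------------------------------------------------------------------------

@dataclass
class BatchDesign:
    """One-hot indicator design for a categorical batch/study label."""

    batch_labels: np.ndarray          # per-sample labels, aligned with the table
    levels: list                       # unique levels, in order of first appearance
    dummy_matrix: np.ndarray           # n_samples x n_levels one-hot

    @classmethod
    def from_labels(cls, labels, min_per_batch: int = 1, allow_single_batch: bool = False):
        labels = np.asarray(pd.Series(labels).astype(str))
        levels = list(pd.unique(labels))
        if len(levels) < 2 and not allow_single_batch:
            raise FeatureTableError(
                "batch design needs >= 2 batch levels (pass allow_single_batch for "
                "degenerate global centering)"
            )
        dummy = np.stack([(labels == lv).astype(float) for lv in levels], axis=1)
        counts = dummy.sum(axis=0)
        small = [lv for lv, c in zip(levels, counts) if c < min_per_batch]
        if small:
            raise FeatureTableError(
                f"batch levels {small} have fewer than {min_per_batch} samples"
            )
        return cls(batch_labels=labels, levels=levels, dummy_matrix=dummy)

    @classmethod
    def from_metadata(cls, meta: SampleMetadata, samples: list[str] | None = None, **kw):
        if meta.batch_col is None:
            raise FeatureTableError("metadata has no designated batch column")
        return cls.from_labels(meta.column(meta.batch_col, samples).to_numpy(), **kw)

    @property
    def n_batches(self) -> int:
        return len(self.levels)

    def batch_index(self, level) -> np.ndarray:
        return np.flatnonzero(self.batch_labels == str(level))


@dataclass
class PCModel:
    """Principal components of a feature table (unscaled, mean-centered)."""

    scores: np.ndarray            # n_samples x K
    loadings: np.ndarray          # n_features x K, orthonormal columns
    variance_fraction: np.ndarray  # length K
    feature_means: np.ndarray     # length n_features
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def transform(self, table: FeatureTable) -> np.ndarray:
        """Project new samples on the fitted loadings (centered by the fitted means)."""
        return (table.values - self.feature_means) @ self.loadings


@dataclass
class CorrectionResult:
    corrected: FeatureTable
    method: str
    params: dict
    removed_components: PCModel | None = None
    beta: np.ndarray | None = None


def _result(table: FeatureTable, values, space, method, params, **kw) -> CorrectionResult:
    out = table.with_values(values, space, f"{method}({params})")
    return CorrectionResult(corrected=out, method=method, params=params, **kw)


# ---------------------------------------------------------------------------
# supervised corrections
# ---------------------------------------------------------------------------

def bmc(table: FeatureTable, design: BatchDesign) -> CorrectionResult:
    """Batch mean centering: subtract each batch's per-feature mean."""
    if len(design.batch_labels) != table.n_samples:
        raise FeatureTableError("batch design is not aligned with the table")
    values = table.values.copy()
    for lv in design.levels:
        idx = design.batch_index(lv)
        if idx.size == 0:
            raise FeatureTableError(f"batch level {lv!r} has no samples after alignment")
        values[idx] -= values[idx].mean(axis=0)
    return _result(table, values, "generic", "bmc", {"n_batches": design.n_batches})


def _design_matrix(meta: SampleMetadata, covariates: list[str], samples: list[str]):
    """Intercept + dummy-expanded categoricals + continuous columns."""
    columns = [np.ones(len(samples))]
    names = ["intercept"]
    for cov in covariates:
        series = meta.column(cov, samples)
        if meta.type_of(cov) == "categorical":
            levels = list(pd.unique(series.astype(str)))
            for lv in levels[1:]:  # drop first level (absorbed by intercept)
                columns.append((series.astype(str) == lv).to_numpy(float))
                names.append(f"{cov}[{lv}]")
        else:
            columns.append(series.to_numpy(float))
            names.append(cov)
    return np.stack(columns, axis=1), names


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r, piv = linalg.qr(design, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        aliased = sorted(names[piv[i]] for i in range(len(names)) if i >= rank or diag[i] < tol)
        raise FeatureTableError(f"design matrix is rank deficient; aliased columns: {aliased}")


def dcc(table: FeatureTable, meta: SampleMetadata, covariates: list[str]) -> CorrectionResult:
    """Direct covariate correction: per-feature OLS residuals on the covariate design."""
    design, names = _design_matrix(meta, covariates, table.sample_ids)
    _check_full_rank(design, names)
    beta, *_ = np.linalg.lstsq(design, table.values, rcond=None)
    residuals = table.values - design @ beta
    return _result(
        table, residuals, "generic", "dcc", {"covariates": list(covariates)}, beta=beta
    )


def linear_batch_removal(
    table: FeatureTable,
    design: BatchDesign,
    meta: SampleMetadata | None = None,
    protect: str | None = None,
) -> CorrectionResult:
    """Remove the fitted batch contribution, optionally protecting a phenotype term.

    The batch and (if given) phenotype terms are fitted jointly; only the
    intercept and batch coefficients are subtracted, so the protected
    phenotype contribution survives the correction. With ``protect=None``
    this reduces exactly to :func:`dcc` on the batch label.
    """
    n = table.n_samples
    columns = [np.ones(n)]
    names = ["intercept"]
    for lv in design.levels[1:]:
        columns.append(design.dummy_matrix[:, design.levels.index(lv)])
        names.append(f"batch[{lv}]")
    n_batch_cols = len(columns)
    if protect is not None:
        if meta is None:
            raise FeatureTableError("protect requires metadata")
        prot_design, prot_names = _design_matrix(meta, [protect], table.sample_ids)
        columns.extend(prot_design[:, 1:].T)
        names.extend(prot_names[1:])
    X = np.stack(columns, axis=1)
    _check_full_rank(X, names)
    beta, *_ = np.linalg.lstsq(X, table.values, rcond=None)
    corrected = table.values - X[:, :n_batch_cols] @ beta[:n_batch_cols]
    space_out = "log" if table.space == "log" else "generic"
    return _result(
        table, corrected, space_out, "limma",
        {"n_batches": design.n_batches, "protect": protect}, beta=beta,
    )


def combat(table: FeatureTable, design: BatchDesign, mode: str = "parametric") -> CorrectionResult:
    """Parametric empirical-Bayes location-scale batch adjustment (ComBat).

    The model for feature g in batch i is ``x = alpha_g + gamma_ig +
    delta_ig * eps``; batch locations ``gamma`` get a normal prior and batch
    scales ``delta^2`` an inverse-gamma prior, both with method-of-moments
    hyperparameters pooled across features, solved by the standard
    iterative conditional posterior-mean updates.
    """
    if mode != "parametric":
        raise FeatureTableError("only parametric ComBat is implemented")
    if len(design.batch_labels) != table.n_samples:
        raise FeatureTableError("batch design is not aligned with the table")
    for lv in design.levels:
        if design.batch_index(lv).size < 3:
            raise FeatureTableError(f"ComBat requires >= 3 samples per batch; {lv!r} is smaller")

    X = table.values  # n x G
    n, G = X.shape
    batch_idx = [design.batch_index(lv) for lv in design.levels]
    n_batches = len(batch_idx)
    sizes = np.array([len(ix) for ix in batch_idx], float)

    batch_means = np.stack([X[ix].mean(axis=0) for ix in batch_idx])  # B x G
    grand_mean = (sizes / n) @ batch_means                            # G
    fitted = np.empty_like(X)
    for bm, ix in zip(batch_means, batch_idx):
        fitted[ix] = bm
    pooled_var = ((X - fitted) ** 2).mean(axis=0)                     # G
    if np.any(pooled_var == 0):
        bad = [table.feature_ids[i] for i in np.flatnonzero(pooled_var == 0)][:5]
        raise FeatureTableError(f"features with zero overall variance: {bad}")
    sd = np.sqrt(pooled_var)
    Z = (X - grand_mean) / sd

    gamma_hat = np.stack([Z[ix].mean(axis=0) for ix in batch_idx])    # B x G
    # ddof=0 matches the pooled-variance divisor, making two identical
    # batches an exact fixed point of the adjustment
    delta_hat = np.stack([Z[ix].var(axis=0, ddof=0) for ix in batch_idx])
    zero_scale = delta_hat <= 0   # zero within-batch variance: location-only adjustment
    if zero_scale.any():
        logger.warning(
            "ComBat: %d feature-batch cells have zero within-batch variance; "
            "scale adjustment skipped for them", int(zero_scale.sum()),
        )

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for b in range(n_batches):
        g_hat, d_hat = gamma_hat[b], delta_hat[b].copy()
        d_hat[zero_scale[b]] = 1.0
        if G < 2:
            # hyperpriors need pooling across features; degenerate to per-feature estimates
            gamma_star[b], delta_star[b] = g_hat, d_hat
            continue
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        if t2 == 0 or s2 == 0:
            gamma_star[b], delta_star[b] = g_hat, d_hat
            continue
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        nb = sizes[b]
        ssq = ((Z[batch_idx[b]] - g_hat) ** 2).sum(axis=0) + nb * g_hat**2  # sum (z - .)^2 base
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for it in range(COMBAT_MAX_ITER):
            g_old, d_old = g_new, d_new
            g_new = (t2 * nb * g_hat + d_old * g_bar) / (t2 * nb + d_old)
            sum2 = ssq - 2 * g_new * nb * g_hat + nb * g_new**2
            d_new = (0.5 * sum2 + b_prior) / (nb / 2 + a_prior - 1)
            change = max(
                np.max(np.abs(g_new - g_old)), np.max(np.abs(d_new - d_old))
            )
            if change < COMBAT_CONV_TOL:
                break
        else:
            raise FeatureTableError(
                f"ComBat EB updates did not converge in {COMBAT_MAX_ITER} iterations "
                f"for batch {design.levels[b]!r}"
            )
        gamma_star[b], delta_star[b] = g_new, d_new
    delta_star[zero_scale] = 1.0

    adjusted = np.empty_like(Z)
    for b, ix in enumerate(batch_idx):
        adjusted[ix] = (Z[ix] - gamma_star[b]) / np.sqrt(delta_star[b])
    out = adjusted * sd + grand_mean
    # per-feature adjustment breaks the clr zero-sum invariant, so clr input
    # comes back tagged generic; back-transform with assume="clr"
    space_out = "log" if table.space == "log" else "generic"
    return _result(table, out, space_out, "combat", {"n_batches": n_batches, "mode": mode})


def percentile_normalize(
    table: FeatureTable, design: BatchDesign, control_mask
) -> CorrectionResult:
    """Replace each value by its percentile in the batch's control distribution.

    Within each batch, a value v for a feature maps to
    ``100 * (#controls < v + 0.5 * #controls == v) / n_controls`` (midrank
    tie convention); controls are ranked against themselves. The output is
    rank-based and therefore invariant to any strictly monotone per-feature
    within-batch transformation of the input.
    """
    control_mask = np.asarray(control_mask, dtype=bool)
    if control_mask.shape != (table.n_samples,):
        raise FeatureTableError("control mask is not aligned with the table")
    values = np.empty_like(table.values)
    for lv in design.levels:
        idx = design.batch_index(lv)
        ctrl = idx[control_mask[idx]]
        if ctrl.size == 0:
            raise FeatureTableError(f"batch {lv!r} has no control samples")
        C = table.values[ctrl]                       # nc x F
        V = table.values[idx]                        # nb x F
        below = (C[None, :, :] < V[:, None, :]).sum(axis=1)
        ties = (C[None, :, :] == V[:, None, :]).sum(axis=1)
        values[idx] = 100.0 * (below + 0.5 * ties) / ctrl.size
    return _result(
        table, values, "generic", "percentile_normalization",
        {"n_batches": design.n_batches},
    )


# ---------------------------------------------------------------------------
# PCA correction
# ---------------------------------------------------------------------------

def fit_pca(table: FeatureTable, K: int) -> PCModel:
    """Covariance (unscaled) PCA of the mean-centered table via SVD.

    Sign convention: each loading column's largest-magnitude entry is made
    positive, which fixes the reflection ambiguity deterministically.
    """
    max_k = min(table.n_samples - 1, table.n_features)
    if not 1 <= K <= max_k:
        raise FeatureTableError(f"K={K} out of range [1, {max_k}]")
    means = table.values.mean(axis=0)
    centered = table.values - means
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total_ss = (s**2).sum()
    U, s, Vt = U[:, :K], s[:K], Vt[:K]
    flip = np.sign(Vt[np.arange(K), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    return PCModel(
        scores=U * s,
        loadings=Vt.T,
        variance_fraction=s**2 / total_ss if total_ss > 0 else np.zeros(K),
        feature_means=means,
        sample_ids=list(table.sample_ids),
        feature_ids=list(table.feature_ids),
    )


def pca_correct_fixed(
    table: FeatureTable, p: int, model: PCModel | None = None, restore_means: bool = True
) -> CorrectionResult:
    """Remove the projection onto the top ``p`` principal components.

    With ``model`` given (fitted on training data), the table is centered
    with the model's feature means and projected on the model's loadings —
    no refit happens, which keeps train/test corrections leak-free.
    ``p=0`` is the identity.
    """
    if table.space not in ("clr", "generic", "log"):
        raise FeatureTableError(f"pca_correct_fixed expects clr/log/generic data, got {table.space!r}")
    if p == 0:
        return _result(table, table.values.copy(), table.space, "pca_fixed", {"p": 0})
    if model is None:
        model = fit_pca(table, K=p)
    if p > model.n_components:
        raise FeatureTableError(f"p={p} exceeds the {model.n_components} fitted components")
    centered = table.values - model.feature_means
    load = model.loadings[:, :p]
    corrected = centered - (centered @ load) @ load.T
    if restore_means:
        corrected = corrected + model.feature_means
    space = table.space if restore_means else "generic"
    return _result(
        table, corrected, space, "pca_fixed", {"p": p, "restore_means": restore_means},
        removed_components=model,
    )


@dataclass
class TunedPCAResult:
    correction: CorrectionResult
    chosen_p: int
    p_grid: list[int]
    metrics: dict[int, float]


def pca_correct_tuned(
    train: FeatureTable,
    validation: FeatureTable,
    meta: SampleMetadata,
    p_grid=None,
    estimator=None,
    metric: str | None = None,
    random_state: int | None = None,
) -> TunedPCAResult:
    """Tune the number of removed PCs by validation prediction performance.

    For each ``p`` the PCA is fitted on the training table only; the
    validation table is centered with the training means and projected on
    the training loadings. The predictor (fixed hyperparameters) is trained
    on corrected training data and scored on corrected validation data by
    AUC (binary phenotype) or Pearson r (continuous). The smallest ``p``
    achieving the maximal metric is chosen.
    """
    from sklearn.base import clone
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score

    if meta.phenotype_col is None:
        raise FeatureTableError("metadata has no designated phenotype column")
    if set(train.sample_ids) & set(validation.sample_ids):
        raise FeatureTableError("train and validation samples overlap")
    if validation.n_samples == 0:
        raise FeatureTableError("validation set is empty")
    y_train = meta.column(meta.phenotype_col, train.sample_ids).to_numpy()
    y_val = meta.column(meta.phenotype_col, validation.sample_ids).to_numpy()
    if metric is None:
        metric = "auc" if meta.type_of(meta.phenotype_col) == "categorical" else "pearson"
    if metric == "auc":
        y_train = pd.factorize(pd.Series(y_train).astype(str), sort=True)[0]
        y_val_codes, _ = pd.factorize(pd.Series(y_val).astype(str), sort=True)
        if len(np.unique(y_val_codes)) < 2:
            raise FeatureTableError("validation set has a single phenotype class")
        y_val = y_val_codes
    else:
        y_train = y_train.astype(float)
        y_val = y_val.astype(float)
    if estimator is None:
        estimator = RandomForestClassifier(
            n_estimators=100, criterion="entropy", random_state=random_state
        )
    max_p = min(train.n_samples - 1, train.n_features) - 1
    if p_grid is None:
        p_grid = list(range(1, 21))
    p_grid = sorted({int(p) for p in p_grid if int(p) <= max_p})
    if not p_grid:
        raise FeatureTableError("p_grid is empty after capping at the data rank")

    model = fit_pca(train, K=max(max(p_grid), 1))
    metrics: dict[int, float] = {}
    for p in p_grid:
        corr_train = pca_correct_fixed(train, p, model=model)
        corr_val = pca_correct_fixed(validation, p, model=model)
        est = clone(estimator)
        est.fit(corr_train.corrected.values, y_train)
        if metric == "auc":
            score = est.predict_proba(corr_val.corrected.values)[:, 1]
            metrics[p] = float(roc_auc_score(y_val, score))
        else:
            pred = est.predict(corr_val.corrected.values)
            if np.std(pred) == 0:
                metrics[p] = 0.0
            else:
                metrics[p] = float(np.corrcoef(pred, y_val)[0, 1])
    best = max(metrics.values())
    chosen_p = min(p for p, v in metrics.items() if v == best)  # smallest p on ties
    return TunedPCAResult(
        correction=pca_correct_fixed(train, chosen_p, model=model),
        chosen_p=chosen_p,
        p_grid=list(p_grid),
        metrics=metrics,
    )


def to_relative_abundance(result, assume: str | None = None) -> FeatureTable:
    """Back-transform corrected data to relative abundance.

    log space: elementwise natural exponent, then closure; clr space:
    inverse CLR (softmax). Generic tables need an explicit ``assume``
    ("log" or "clr") declaring which back-transform applies.
    """
    table = result.corrected if isinstance(result, CorrectionResult) else result
    space = table.space if table.space in ("log", "clr") else assume
    if space == "clr":
        return inverse_clr(table)
    if space == "log":
        expd = table.with_values(np.exp(table.values), "counts", "exp")
        return closure(expd)
    raise FeatureTableError(
        f"no declared back-transform for space {table.space!r}; expected log or clr"
    )
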