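"""Benchmark procedures: titration false-positive experiment and phenotype
prediction with leave-one-dataset-out (LODO) or pooled cross-validation.

Titration: cases and controls are drawn from one study, and the controls
are progressively replaced by controls from a second study. Because the
replacement controls differ only by study, any association that appears
relative to the unmixed baseline is a spurious, study-driven discovery;
counting such "new associations" across mixing proportions measures how
well a correction suppresses confounded false positives.

Prediction: a random-forest classifier (binary phenotype, AUC) or a linear
regression (continuous phenotype, Pearson r) is tuned on a validation split
and scored on a held-out study (LODO) or a held-out 20% (pooled 56/24/20).
All correction parameters are fitted on training samples only and applied
forward, never refitted on validation or test data.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import (
    FeatureTable,
    FeatureTableError,
    SampleMetadata,
    closure,
    prevalence_filter,
)
from .corrections import (
    BatchDesign,
    PCModel,
    bmc,
    combat,
    fit_pca,
    linear_batch_removal,
    pca_correct_fixed,
    percentile_normalize,
    to_relative_abundance,
)
from .transforms import add_pseudocount, clr_transform, inverse_clr, pseudocount_value

logger = logging.getLogger("mbnoise")

#: the random-forest hyperparameter grid tuned on validation AUC
DEFAULT_RF_GRID = [
    {"n_estimators": n, "criterion": "entropy", "min_samples_split": s, "min_samples_leaf": l}
    for n, s, l in itertools.product((100, 1000, 1500), (2, 5, 10), (1, 5, 10))
]

DEFAULT_RIDGE_GRID = (0.0, 1e-2, 1.0, 100.0)
DEFAULT_TITRATION_PROPORTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)


# ---------------------------------------------------------------------------
# differential abundance
# ---------------------------------------------------------------------------

def differential_abundance(
    table: FeatureTable,
    labels,
    q_threshold: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Per-feature two-sided Wilcoxon rank-sum with Benjamini-Hochberg FDR.

    ``labels`` is a per-sample binary vector (any two values). The exact
    rank-sum null distribution is used when the table is tie-free and the
    groups are small; otherwise the normal approximation with tie and
    continuity correction. A feature is significant iff q < ``q_threshold``.
    """
    labels = np.asarray(pd.Series(labels).astype(str))
    if labels.shape[0] != table.n_samples:
        raise FeatureTableError("labels are not aligned with the table")
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise FeatureTableError(f"labels must be binary, got {len(classes)} classes")
    idx1, idx0 = labels == classes[0], labels == classes[1]
    if idx1.sum() < 3 or idx0.sum() < 3:
        raise FeatureTableError("each class needs >= 3 samples for the rank-sum test")
    x, y = table.values[idx1], table.values[idx0]
    if method == "auto":
        has_ties = bool(np.any(np.diff(np.sort(table.values, axis=0), axis=0) == 0))
        method = "asymptotic" if has_ties or table.n_samples > 60 else "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features yield harmless tie warnings
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, axis=0)
    pvals = np.atleast_1d(res.pvalue).astype(float)
    pvals[~np.isfinite(pvals)] = 1.0
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame(
        {
            "statistic": np.atleast_1d(res.statistic).astype(float),
            "p": pvals,
            "q": qvals,
            "significant": qvals < q_threshold,
        },
        index=table.feature_ids,
    )


# ---------------------------------------------------------------------------
# correction pipelines (titration + prediction)
# ---------------------------------------------------------------------------

@dataclass
class PipelineSpec:
    """Transform + correction recipe applied inside the benchmarks.

    ``correction``: none | bmc | dcc | limma | combat | percentile |
    pca_fixed. BMC/DCC operate on relative abundances; limma/ComBat on
    ln(relative + pseudocount); PCA correction on CLR coordinates with the
    result mapped back through the inverse CLR.
    """

    correction: str = "none"
    n_pcs: int = 3
    pseudocount_factor: float = 0.65
    min_prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.correction not in (
            "none", "bmc", "dcc", "limma", "combat", "percentile", "pca_fixed"
        ):
            raise FeatureTableError(f"unknown correction {self.correction!r}")


def apply_pipeline(
    rel_table: FeatureTable,
    batch_labels,
    spec: PipelineSpec,
    control_mask=None,
) -> FeatureTable:
    """Run transform -> correct -> back-transform on a relative-abundance table.

    Returns a table suitable for rank-based differential-abundance testing:
    relative abundance where a back-transform exists, otherwise the
    corrected values themselves (ranks are what the test consumes).
    Prevalence filtering is applied to the raw relative table first, since
    zero replacement would otherwise make a presence/absence filter vacuous.
    """
    n_batches = len(pd.unique(pd.Series(batch_labels).astype(str)))
    single = n_batches < 2
    if spec.correction == "none":
        return rel_table
    if spec.correction in ("bmc", "dcc"):
        # BMC and DCC on a single categorical covariate coincide; both act on
        # relative abundances directly
        design = BatchDesign.from_labels(batch_labels, allow_single_batch=True)
        return bmc(rel_table, design).corrected
    if spec.correction in ("limma", "combat"):
        logged = add_pseudocount(rel_table, spec.pseudocount_factor)
        logged = logged.with_values(np.log(logged.values), "log", "ln")
        if single:
            corrected = logged  # nothing to remove from one batch
        else:
            design = BatchDesign.from_labels(batch_labels)
            if spec.correction == "limma":
                corrected = linear_batch_removal(logged, design).corrected
            else:
                corrected = combat(logged, design).corrected
        return to_relative_abundance(corrected, assume="log")
    if spec.correction == "percentile":
        if control_mask is None:
            raise FeatureTableError("percentile normalization needs a control mask")
        design = BatchDesign.from_labels(batch_labels, allow_single_batch=True)
        return percentile_normalize(rel_table, design, control_mask).corrected
    # pca_fixed
    clr = clr_transform(add_pseudocount(rel_table, spec.pseudocount_factor))
    p = min(spec.n_pcs, min(clr.n_samples - 1, clr.n_features) - 1)
    corrected = pca_correct_fixed(clr, p).corrected
    return inverse_clr(corrected)


class FittedPipeline:
    """Leak-free train-fitted pipeline for the prediction harness.

    ``fit`` learns everything data-dependent from the training samples
    only: the prevalence mask, the zero-replacement pseudocount, and (for
    PCA correction) the feature means and loadings. ``transform`` applies
    those frozen parameters to any table. Batch mean centering is applied
    per batch of the transformed table using that batch's own label-free
    means, so a study never seen during training can still be centered.
    Supported corrections: none, bmc, pca_fixed.
    """

    def __init__(self, spec: PipelineSpec | None = None):
        self.spec = spec or PipelineSpec()
        if self.spec.correction not in ("none", "bmc", "pca_fixed"):
            raise FeatureTableError(
                f"correction {self.spec.correction!r} is not supported inside prediction "
                "(reference-distribution methods need labels or batch refits)"
            )
        self.feature_keep_: np.ndarray | None = None
        self.pseudocount_: float | None = None
        self.pca_model_: PCModel | None = None

    def fit(self, table: FeatureTable, meta: SampleMetadata | None = None) -> "FittedPipeline":
        rel = closure(table) if table.space == "counts" else table
        prevalence = (rel.values > 0).mean(axis=0)
        self.feature_keep_ = np.flatnonzero(prevalence >= self.spec.min_prevalence)
        if self.feature_keep_.size == 0:
            raise FeatureTableError("prevalence filter removed every feature on train")
        rel = rel.select_features(self.feature_keep_)
        rel = closure(rel)
        self.pseudocount_ = pseudocount_value(rel, self.spec.pseudocount_factor)
        clr = clr_transform(add_pseudocount(rel, value=self.pseudocount_))
        if self.spec.correction == "pca_fixed":
            k = min(self.spec.n_pcs, min(clr.n_samples - 1, clr.n_features) - 1)
            self.pca_model_ = fit_pca(clr, K=k)
        return self

    def fitted_params(self) -> dict[str, np.ndarray]:
        out = {
            "feature_keep": np.asarray(self.feature_keep_),
            "pseudocount": np.asarray([self.pseudocount_]),
        }
        if self.pca_model_ is not None:
            out["feature_means"] = self.pca_model_.feature_means
            out["loadings"] = self.pca_model_.loadings
        return out

    def transform(self, table: FeatureTable, batch_labels=None) -> np.ndarray:
        if self.feature_keep_ is None:
            raise FeatureTableError("pipeline is not fitted")
        rel = closure(table) if table.space == "counts" else table
        rel = closure(rel.select_features(self.feature_keep_))
        clr = clr_transform(add_pseudocount(rel, value=self.pseudocount_))
        if self.spec.correction == "none":
            return clr.values
        if self.spec.correction == "bmc":
            if batch_labels is None:
                raise FeatureTableError("bmc application needs batch labels")
            design = BatchDesign.from_labels(batch_labels, allow_single_batch=True)
            return bmc(clr, design).corrected.values
        p = self.pca_model_.n_components
        return pca_correct_fixed(clr, p, model=self.pca_model_).corrected.values


# ---------------------------------------------------------------------------
# titration
# ---------------------------------------------------------------------------

@dataclass
class TitrationResult:
    study_pair: tuple[str, str]
    proportions: list[float]
    replicates: int
    counts: np.ndarray                 # replicates x proportions, new-association counts
    baseline_sets: list[set[str]]      # per replicate
    titrated_sets: list[list[set[str]]]

    @property
    def mean_new_associations(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"proportion": self.proportions, "mean_new_associations": self.mean_new_associations}
        )


def run_titration(
    table: FeatureTable,
    meta: SampleMetadata,
    study1: str,
    study2: str,
    pipeline: PipelineSpec | None = None,
    proportions=DEFAULT_TITRATION_PROPORTIONS,
    replicates: int = 5,
    q_threshold: float = 0.05,
    seed: int | None = None,
    case_label: str | None = None,
) -> TitrationResult:
    """Control-titration false-positive experiment between two studies.

    Per replicate, ``m`` cases and ``m`` controls are drawn from study 1
    (``m`` = the minimum class size over the two studies' available case
    and control pools). At each mixing proportion f, ``round(f*m)`` of the
    drawn study-1 controls are replaced by study-2 controls (nested across
    proportions, so larger f strictly extends the replacement), the full
    pipeline is re-run, and significant features not in the replicate's
    proportion-0 baseline set are counted as new associations.
    """
    pipeline = pipeline or PipelineSpec()
    if meta.phenotype_col is None or meta.batch_col is None:
        raise FeatureTableError("metadata must designate phenotype and batch columns")
    rng = np.random.default_rng(seed)
    pheno = meta.column(meta.phenotype_col, table.sample_ids).astype(str).to_numpy()
    study = meta.column(meta.batch_col, table.sample_ids).astype(str).to_numpy()
    classes = sorted(pd.unique(pheno))
    if len(classes) != 2:
        raise FeatureTableError("titration requires a binary phenotype")
    case = case_label if case_label is not None else classes[0]
    control = [c for c in classes if c != case][0]

    def pool(st, ph):
        return np.flatnonzero((study == st) & (pheno == ph))

    cases1, controls1, controls2 = pool(study1, case), pool(study1, control), pool(study2, control)
    cases2 = pool(study2, case)
    sizes = [cases1.size, controls1.size, controls2.size] + ([cases2.size] if cases2.size else [])
    m = int(min(sizes))
    if m < 6:
        raise FeatureTableError(f"titration sample size m={m} < 6; pools too small")
    proportions = sorted(float(f) for f in proportions)
    if any(not 0 <= f <= 1 for f in proportions):
        raise FeatureTableError("proportions must lie in [0, 1]")
    if round(max(proportions) * m) > controls2.size:
        raise FeatureTableError("study-2 control pool too small for the requested proportions")

    rel_full = closure(table) if table.space == "counts" else table
    counts = np.zeros((replicates, len(proportions)))
    baseline_sets, titrated_sets = [], []
    for r in range(replicates):
        draw_cases = rng.choice(cases1, size=m, replace=False)
        draw_ctrl1 = rng.permutation(rng.choice(controls1, size=m, replace=False))
        draw_ctrl2 = rng.permutation(controls2)

        def significant_at(f: float) -> set[str]:
            k = int(round(f * m))
            ctrl = np.concatenate([draw_ctrl2[:k], draw_ctrl1[k:]]).astype(int)
            idx = np.concatenate([draw_cases, ctrl])
            sub = closure(rel_full.select_samples(idx))
            sub = prevalence_filter(sub, pipeline.min_prevalence)
            labels = pheno[idx]
            batches = study[idx]
            corrected = apply_pipeline(
                sub, batches, pipeline, control_mask=(labels == control)
            )
            da = differential_abundance(corrected, labels, q_threshold=q_threshold)
            return set(da.index[da["significant"]])

        base = significant_at(0.0)
        per_prop = []
        for j, f in enumerate(proportions):
            sig = base if f == 0.0 else significant_at(f)
            per_prop.append(sig)
            counts[r, j] = len(sig - base)
        baseline_sets.append(base)
        titrated_sets.append(per_prop)
    return TitrationResult(
        study_pair=(study1, study2),
        proportions=list(proportions),
        replicates=replicates,
        counts=counts,
        baseline_sets=baseline_sets,
        titrated_sets=titrated_sets,
    )


# ---------------------------------------------------------------------------
# prediction harness
# ---------------------------------------------------------------------------

@dataclass
class Fold:
    name: str
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]


@dataclass
class FoldResult:
    fold: str
    metric: float
    best_params: dict


@dataclass
class PredictionResult:
    scheme: str
    metric_name: str
    folds: list[FoldResult]
    seeds: list[int] = field(default_factory=list)

    @property
    def metrics(self) -> np.ndarray:
        return np.array([f.metric for f in self.folds if np.isfinite(f.metric)])

    def confidence_interval(self):
        vals = self.metrics
        return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))

    def summary(self) -> dict:
        vals = self.metrics
        lo, hi = self.confidence_interval() if len(vals) else (np.nan, np.nan)
        return {
            "scheme": self.scheme,
            "metric": self.metric_name,
            "n_folds": len(vals),
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "ci_2.5": lo,
            "ci_97.5": hi,
        }


def _strata(meta: SampleMetadata, sample_ids):
    """Stratification labels: phenotype classes, or quartile bins if continuous."""
    series = meta.column(meta.phenotype_col, list(sample_ids))
    if meta.type_of(meta.phenotype_col) == "categorical":
        return series.astype(str).to_numpy()
    return pd.qcut(series.astype(float), q=4, labels=False, duplicates="drop").to_numpy().astype(str)


def lodo_splits(
    meta: SampleMetadata,
    unit_col: str | None = None,
    train_frac: float = 0.7,
    seed: int | None = None,
) -> list[Fold]:
    """One fold per study: that study is the test set; the rest is split
    train/validation (default 70/30), stratified by phenotype (quartiles
    for a continuous phenotype). Folds whose test study contains a single
    phenotype class are skipped with a warning."""
    from sklearn.model_selection import train_test_split

    unit_col = unit_col or meta.batch_col
    if unit_col is None:
        raise FeatureTableError("no unit/batch column for LODO splitting")
    units = meta.column(unit_col).astype(str)
    levels = list(pd.unique(units))
    if len(levels) < 2:
        raise FeatureTableError("LODO needs >= 2 studies")
    binary = meta.type_of(meta.phenotype_col) == "categorical"
    folds = []
    for i, unit in enumerate(levels):
        test_ids = list(units.index[units == unit])
        rest_ids = list(units.index[units != unit])
        if binary:
            test_classes = pd.unique(meta.column(meta.phenotype_col, test_ids).astype(str))
            if len(test_classes) < 2:
                warnings.warn(f"LODO fold {unit!r} has a single phenotype class; skipped")
                continue
        strata = _strata(meta, rest_ids)
        train_ids, val_ids = train_test_split(
            rest_ids,
            train_size=train_frac,
            stratify=strata,
            random_state=None if seed is None else seed + i,
        )
        folds.append(Fold(name=unit, train_ids=list(train_ids), val_ids=list(val_ids),
                          test_ids=test_ids))
    if not folds:
        raise FeatureTableError("every LODO fold was skipped")
    return folds


def _fold_matrices(fold: Fold, table: FeatureTable, meta: SampleMetadata,
                   pipeline: PipelineSpec | None):
    pos = {s: i for i, s in enumerate(table.sample_ids)}
    parts = {}
    pip = FittedPipeline(pipeline)
    train_tab = table.select_samples([pos[s] for s in fold.train_ids])
    pip.fit(train_tab, meta)
    for name, ids in (("train", fold.train_ids), ("val", fold.val_ids), ("test", fold.test_ids)):
        sub = table.select_samples([pos[s] for s in ids])
        batches = meta.column(meta.batch_col, ids).astype(str).to_numpy() \
            if meta.batch_col else None
        parts[name] = pip.transform(sub, batch_labels=batches)
    return parts, pip


def train_eval_binary(
    fold: Fold,
    table: FeatureTable,
    meta: SampleMetadata,
    pipeline: PipelineSpec | None = None,
    grid=None,
    seed: int | None = None,
) -> FoldResult:
    """Grid-tuned random forest: hyperparameters by validation AUC, scored on test.

    The forest follows the fixed settings max_depth=None and
    max_features=sqrt(n_features); the tuned axes are tree count, minimum
    samples per split and per leaf (entropy criterion throughout).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.metrics import roc_auc_score

    grid = grid or DEFAULT_RF_GRID
    parts, _ = _fold_matrices(fold, table, meta, pipeline)
    y = {
        name: pd.factorize(
            meta.column(meta.phenotype_col, ids).astype(str), sort=True
        )[0]
        for name, ids in (("train", fold.train_ids), ("val", fold.val_ids),
                          ("test", fold.test_ids))
    }
    if len(np.unique(y["test"])) < 2:
        warnings.warn(f"fold {fold.name!r}: single-class test set; skipped")
        return FoldResult(fold=fold.name, metric=np.nan, best_params={})
    best_auc, best_params = -np.inf, None
    for params in grid:
        rf = RandomForestClassifier(
            **params, max_depth=None, max_features="sqrt", random_state=seed
        )
        rf.fit(parts["train"], y["train"])
        auc = roc_auc_score(y["val"], rf.predict_proba(parts["val"])[:, 1])
        if auc > best_auc:
            best_auc, best_params = auc, params
    rf = RandomForestClassifier(
        **best_params, max_depth=None, max_features="sqrt", random_state=seed
    )
    rf.fit(parts["train"], y["train"])
    test_auc = roc_auc_score(y["test"], rf.predict_proba(parts["test"])[:, 1])
    return FoldResult(fold=fold.name, metric=float(test_auc), best_params=dict(best_params))


def train_eval_continuous(
    fold: Fold,
    table: FeatureTable,
    meta: SampleMetadata,
    pipeline: PipelineSpec | None = None,
    ridge_grid=DEFAULT_RIDGE_GRID,
    seed: int | None = None,
) -> FoldResult:
    """Linear phenotype regression; optional ridge penalty tuned on validation.

    lambda=0 is plain least squares; the penalized options exist because
    feature counts routinely exceed sample counts. The metric is the
    Pearson correlation between predicted and true phenotype on test.
    """
    from sklearn.linear_model import LinearRegression, Ridge

    parts, _ = _fold_matrices(fold, table, meta, pipeline)
    y = {
        name: meta.column(meta.phenotype_col, ids).astype(float).to_numpy()
        for name, ids in (("train", fold.train_ids), ("val", fold.val_ids),
                          ("test", fold.test_ids))
    }

    def fit_model(lam):
        model = LinearRegression() if lam == 0 else Ridge(alpha=lam)
        model.fit(parts["train"], y["train"])
        return model

    def score(model, part, target):
        pred = model.predict(parts[part])
        if np.std(pred) == 0 or np.std(target) == 0:
            return 0.0, pred
        return float(np.corrcoef(pred, target)[0, 1]), pred

    best_r, best_lam = -np.inf, None
    for lam in ridge_grid:
        r, _ = score(fit_model(lam), "val", y["val"])
        if r > best_r:
            best_r, best_lam = r, lam
    model = fit_model(best_lam)
    r_test, pred = score(model, "test", y["test"])
    if np.std(pred) == 0:
        warnings.warn(f"fold {fold.name!r}: zero-variance predictions; r set to 0")
    return FoldResult(fold=fold.name, metric=r_test, best_params={"ridge_lambda": best_lam})


def pooled_splits(
    meta: SampleMetadata,
    n_folds: int = 5,
    seed: int | None = None,
    unit_col: str | None = None,
) -> list[Fold]:
    """Pooled 56/24/20 splits via stratified K-fold: each fold's held-out 20%
    is the test set and the remaining 80% is split 70/30 into train and
    validation, stratifying on (study, phenotype) so study composition is
    similar across partitions."""
    from sklearn.model_selection import StratifiedKFold, train_test_split

    unit_col = unit_col or meta.batch_col
    ids = np.array(meta.sample_ids)
    pheno_strata = _strata(meta, list(ids))
    strata = pheno_strata if unit_col is None else np.char.add(
        meta.column(unit_col, list(ids)).astype(str).to_numpy(), pheno_strata
    )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=None if seed is None else seed)
    folds = []
    for i, (rest_idx, test_idx) in enumerate(skf.split(ids, strata)):
        train_ids, val_ids = train_test_split(
            ids[rest_idx],
            train_size=0.7,
            stratify=strata[rest_idx],
            random_state=None if seed is None else seed + i,
        )
        folds.append(Fold(name=f"fold{i}", train_ids=list(train_ids),
                          val_ids=list(val_ids), test_ids=list(ids[test_idx])))
    return folds


def repeated_cv(
    table: FeatureTable,
    meta: SampleMetadata,
    scheme: str = "lodo",
    task: str = "binary",
    pipeline: PipelineSpec | None = None,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed: int | None = None,
    grid=None,
) -> PredictionResult:
    """Repeated cross-validated prediction under the LODO or pooled scheme.

    LODO holds out one whole study per fold; repeats redraw the 70/30
    train/validation split and the forest seed. The pooled scheme is
    stratified ``n_folds``-fold CV (test 20%, remainder split 70/30 into
    56/24), repeated ``n_repeats`` times for percentile confidence
    intervals.
    """
    if scheme not in ("lodo", "pooled_56_24_20"):
        raise FeatureTableError(f"unknown scheme {scheme!r}")
    evaluate = train_eval_binary if task == "binary" else train_eval_continuous
    results, seeds = [], []
    base = 0 if seed is None else int(seed)
    for rep in range(n_repeats):
        rep_seed = (base + 1009 * rep) % (2**31 - 1)
        seeds.append(rep_seed)
        folds = (
            lodo_splits(meta, seed=rep_seed)
            if scheme == "lodo"
            else pooled_splits(meta, n_folds=n_folds, seed=rep_seed)
        )
        for fold in folds:
            kw = {"grid": grid} if (task == "binary" and grid is not None) else {}
            res = evaluate(fold, table, meta, pipeline=pipeline, seed=rep_seed, **kw)
            res = FoldResult(fold=f"rep{rep}:{res.fold}", metric=res.metric,
                             best_params=res.best_params)
            results.append(res)
    return PredictionResult(
        scheme=scheme,
        metric_name="AUC" if task == "binary" else "pearson_r",
        folds=results,
        seeds=seeds,
    )


@dataclass
class MethodComparison:
    statistic: float
    p_value: float
    min_attainable_p: float
    annotation: str | None


def compare_methods(results_a, results_b, alternative: str = "greater") -> MethodComparison:
    """One-sided Wilcoxon rank-sum between two metric vectors.

    With only a handful of folds the smallest attainable one-sided p-value,
    ``1 / C(n+m, n)``, may exceed 0.05; the comparison is annotated when
    significance is unattainable at that sample size.
    """
    a, b = np.asarray(results_a, float), np.asarray(results_b, float)
    if len(a) < 3 or len(b) < 3:
        raise FeatureTableError("need >= 3 metric values per group")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    min_p = 1.0 / float(math.comb(len(a) + len(b), len(a)))
    annotation = (
        f"minimum attainable one-sided p = {min_p:.3g}; p < 0.05 is unattainable "
        "at these sample sizes"
        if min_p >= 0.05
        else None
    )
    return MethodComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        min_attainable_p=min_p,
        annotation=annotation,
    )
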