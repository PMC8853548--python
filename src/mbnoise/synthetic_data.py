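"""Synthetic multi-study compositional count data with known ground truth.

The generator emulates the situation the correction methods target: several
studies measuring the same community, each imposing its own per-feature
multiplicative bias (wet-lab protocol, primer, pipeline), with a phenotype
that may be partially or completely confounded with study membership.

Generative model, all in natural-log space before closure:

1. feature baseline log-abundance  b_f ~ Normal(0, baseline_logmean_sd^2);
2. per-feature per-study bias      s_{f,k} ~ Normal(0, bias_sd_k^2) —
   feature-specific, because a bias common to all features cancels under
   closure and would produce no batch effect;
3. phenotype: binary via a study-dependent Bernoulli whose case probability
   moves from 0.5 (confounding_rho=0) to 0/1 alternating by study
   (confounding_rho=1); continuous via a study mean shift scaled by rho
   plus unit noise;
4. the ``n_differential`` planted features gain ``effect_logfold`` x
   phenotype in log space;
5. per-sample log-normal noise with sd ``sample_noise_sd``; composition by
   closure of the exponentiated log-abundances;
6. counts ~ Multinomial(library size, composition), library sizes
   gamma-Poisson (negative-binomially) dispersed around
   ``library_size_mean``.

Sparsity arises naturally from multinomial sampling of skewed compositions;
``zero_inflation`` optionally zeroes a further fraction of cells for
harsher regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import FeatureTable, FeatureTableError, SampleMetadata


@dataclass
class SimulationConfig:
    """Parameters of the multi-study generator (defaults: a two-study,
    moderately biased case-control design with strong planted effects)."""

    n_studies: int = 2
    samples_per_study: int = 50
    n_features: int = 200
    baseline_logmean_sd: float = 1.0
    bias_sd: float | list[float] = 1.0          # sigma of log-normal multiplicative study bias
    n_differential: int = 20
    effect_logfold: float = float(np.log(4))    # ln fold-change added to cases
    effect_balanced: bool = True                 # half enriched, half depleted in cases
    phenotype_type: str = "binary"
    confounding_rho: float = 0.0                 # 0: balanced; 1: phenotype == study
    sample_noise_sd: float = 0.3
    library_size_mean: float = 20000.0
    library_size_dispersion: float = 0.3         # squared CV of library sizes
    zero_inflation: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_differential > self.n_features:
            raise FeatureTableError("n_differential exceeds n_features")
        if not 0 <= self.confounding_rho <= 1:
            raise FeatureTableError("confounding_rho must lie in [0, 1]")
        if self.phenotype_type not in ("binary", "continuous"):
            raise FeatureTableError(f"unknown phenotype_type {self.phenotype_type!r}")
        bias = np.atleast_1d(np.asarray(self.bias_sd, float))
        if bias.size == 1:
            bias = np.repeat(bias, self.n_studies)
        if bias.size != self.n_studies:
            raise FeatureTableError("bias_sd must be scalar or one value per study")
        if np.any(bias < 0) or self.baseline_logmean_sd < 0 or self.sample_noise_sd < 0:
            raise FeatureTableError("standard deviations must be non-negative")
        if not 0 <= self.zero_inflation < 1:
            raise FeatureTableError("zero_inflation must lie in [0, 1)")
        if self.library_size_mean <= 0 or self.library_size_dispersion < 0:
            raise FeatureTableError("library size parameters must be positive")
        self._bias_sd_vec = bias


@dataclass
class GroundTruth:
    differential_features: set[str]
    log_bias: np.ndarray                 # n_studies x n_features
    phenotype: np.ndarray                # per-sample true phenotype
    effect_sizes: dict[str, float] = field(default_factory=dict)


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[FeatureTable, SampleMetadata, GroundTruth]:
    """Draw one multi-study count table with metadata and ground truth.

    ``seed`` overrides ``config.seed``; identical config + seed gives
    bit-identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_total = config.n_studies * config.samples_per_study
    F = config.n_features

    feature_ids = [f"F{i:04d}" for i in range(F)]
    sample_ids = [
        f"S{k}_{j:03d}" for k in range(config.n_studies) for j in range(config.samples_per_study)
    ]
    study = np.repeat([f"study{k}" for k in range(config.n_studies)], config.samples_per_study)
    study_index = np.repeat(np.arange(config.n_studies), config.samples_per_study)

    baseline = rng.normal(0.0, config.baseline_logmean_sd, size=F)
    log_bias = np.stack(
        [rng.normal(0.0, config._bias_sd_vec[k], size=F) for k in range(config.n_studies)]
    )

    # phenotype, with study confounding controlled by rho
    rho = config.confounding_rho
    study_sign = np.where(study_index % 2 == 0, 1.0, -1.0)
    if config.phenotype_type == "binary":
        p_case = 0.5 + 0.5 * rho * study_sign
        phenotype = (rng.random(n_total) < p_case).astype(float)
    else:
        phenotype = rho * study_sign + rng.normal(0.0, 1.0, size=n_total)

    # plant effects on the less abundant half of the features (disease-associated
    # taxa are typically not the community dominants); this also keeps the
    # planted signal from commandeering the composition's total mass
    eligible = np.sort(np.argsort(baseline)[: max(F // 2, config.n_differential)])
    diff_idx = rng.choice(eligible, size=config.n_differential, replace=False)
    effect = np.zeros(F)
    if config.effect_balanced:
        # half enriched, half depleted in cases: keeps the planted signal from
        # dragging the geometric mean and leaking into null features via closure
        signs = np.where(np.arange(diff_idx.size) % 2 == 0, 1.0, -1.0)
    else:
        signs = np.ones(diff_idx.size)
    effect[diff_idx] = config.effect_logfold * signs

    log_abund = (
        baseline[None, :]
        + log_bias[study_index]
        + phenotype[:, None] * effect[None, :]
        + rng.normal(0.0, config.sample_noise_sd, size=(n_total, F))
    )
    comp = np.exp(log_abund - log_abund.max(axis=1)[:, None])
    comp /= comp.sum(axis=1)[:, None]

    # gamma-Poisson library sizes (negative binomial around the mean)
    if config.library_size_dispersion > 0:
        shape = 1.0 / config.library_size_dispersion
        lib = rng.poisson(rng.gamma(shape, config.library_size_mean / shape, size=n_total))
    else:
        lib = rng.poisson(config.library_size_mean, size=n_total)
    lib = np.maximum(lib, 1)
    counts = np.stack([rng.multinomial(lib[i], comp[i]) for i in range(n_total)]).astype(float)

    if config.zero_inflation > 0:
        counts[rng.random(counts.shape) < config.zero_inflation] = 0.0
        # keep every sample non-empty
        for i in np.flatnonzero(counts.sum(axis=1) == 0):
            counts[i] = rng.multinomial(lib[i], comp[i]).astype(float)

    table = FeatureTable(
        sample_ids=sample_ids,
        feature_ids=feature_ids,
        values=counts,
        space="counts",
        transform_log=["simulate_dataset"],
    )
    pheno_col = (
        pd.Series(np.where(phenotype > 0, "case", "control"), index=sample_ids)
        if config.phenotype_type == "binary"
        else pd.Series(phenotype, index=sample_ids)
    )
    meta = SampleMetadata(
        data=pd.DataFrame({"phenotype": pheno_col, "study": study}, index=sample_ids),
        column_types={
            "phenotype": "categorical" if config.phenotype_type == "binary" else "continuous",
            "study": "categorical",
        },
        phenotype_col="phenotype",
        batch_col="study",
    )
    truth = GroundTruth(
        differential_features={feature_ids[i] for i in diff_idx},
        log_bias=log_bias,
        phenotype=phenotype,
        effect_sizes={feature_ids[i]: float(e) for i, e in zip(diff_idx, effect[diff_idx])},
    )
    return table, meta, truth


def evaluate_against_truth(significant, truth: GroundTruth, all_features) -> dict:
    """Confusion counts and rates of a significant-feature call set."""
    significant = set(significant)
    all_features = list(all_features)
    unknown = significant - set(all_features)
    if unknown:
        raise FeatureTableError(f"unknown feature ids: {sorted(unknown)[:5]}")
    positives = truth.differential_features & set(all_features)
    negatives = set(all_features) - positives
    tp = len(significant & positives)
    fp = len(significant & negatives)
    return {
        "true_positive_count": tp,
        "false_positive_count": fp,
        "TPR": tp / len(positives) if positives else 0.0,
        "FPR": fp / len(negatives) if negatives else 0.0,
    }
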