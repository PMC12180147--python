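"""Preset study configurations and end-to-end benchmark runners.

These fix the synthetic-cohort conditions used to exercise the whole
pipeline at desk scale and are shared by the test suite, the CLI
examples and the reproduction script:

* ``pair_config_weak`` / ``pair_config_strong`` / ``pair_config_null``
  — two-group classification problems whose Bayes-optimal AUC has a
  closed form (about 0.760, 0.943 and exactly 0.5), used to calibrate
  the repeated-holdout harness against the analytic oracle.
* ``height_config`` — a height-regression cohort in which a +13 cm sex
  effect reaches the model only through sex-crosstalk-carrying CSLV
  features, plus a sparse heritable CNV signal; the analytic sex AUC
  from the crosstalk alone is about 0.996, mirroring near-perfect
  sex classification from autosomal dosage features.
* ``importance_config`` — an 88-feature cohort with classification
  signal spread evenly over 20 segments, for checking that permutation
  importance is diffuse rather than concentrated.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import bench
from .bench import TaskSpec, build_task, default_recipe, grouped_mean_curve, model_search, permutation_importance, repeated_holdout, split_counts
from .segments import compute_cslv, filter_complete
from .simulate import GroupSpec, HeightModel, SimConfig, simulate_cohort


def _two_group(label_a="A", label_b="B", **kwargs) -> SimConfig:
    delta_a = kwargs.pop("delta_a")
    return SimConfig(
        groups=[GroupSpec(label_a, 0.5, delta_a), GroupSpec(label_b, 0.5, 0.0)],
        sex_crosstalk=0.0,
        **kwargs,
    )


def pair_config_weak(n_samples: int = 2000, seed: int = 0) -> SimConfig:
    """One segment, shift difference 0.01, CSLV noise sd 0.01 (sigma=0.2
    over 400 markers): analytic AUC = Phi(1/sqrt(2)) ~ 0.760."""
    return _two_group(
        delta_a=0.01,
        n_samples=n_samples,
        chromosomes=(1,),
        markers_per_chromosome=400,
        segments_per_chromosome=1,
        lrr_noise_sd=0.2,
        seed=seed,
    )


def pair_config_strong(n_samples: int = 2000, seed: int = 0) -> SimConfig:
    """20 segments each with standardized shift d=0.5: analytic AUC =
    Phi(sqrt(5)/sqrt(2)) ~ 0.943."""
    return _two_group(
        delta_a=0.005,  # 0.5 * (0.2 / sqrt(400))
        n_samples=n_samples,
        chromosomes=(1, 2, 3, 4, 5),
        markers_per_chromosome=1600,
        segments_per_chromosome=4,
        lrr_noise_sd=0.2,
        seed=seed,
    )


def pair_config_null(n_samples: int = 2000, seed: int = 0) -> SimConfig:
    """Labels independent of features: analytic AUC exactly 0.5."""
    cfg = pair_config_weak(n_samples=n_samples, seed=seed)
    cfg.groups[0].delta = 0.0
    return cfg


def height_config(n_samples: int = 4000, seed: int = 0) -> SimConfig:
    """Height-regression cohort: 88 features, +13 cm male effect carried
    only by crosstalk on 8 segments, heritable CNV signal (rate 0.02)
    weighted at 20 cm per LRR unit on 20 segments, residual sd 6 cm."""
    crosstalk = {f"chr{c}_1": 0.04 for c in range(1, 9)}
    gamma = {f"chr{c}_2": 20.0 for c in range(1, 21)}
    return SimConfig(
        n_samples=n_samples,
        lrr_noise_sd=0.15,
        sex_crosstalk=crosstalk,
        cnv_rate=0.02,
        height=HeightModel(intercept=165.0, beta_sex=13.0, beta_age=-0.06,
                           gamma=gamma, resid_sd=6.0),
        seed=seed,
    )


def importance_config(n_samples: int = 2000, seed: int = 0) -> SimConfig:
    """88 features, two groups separated by d=0.5 on the first 20
    segments (chr1_1 .. chr5_4) and nothing elsewhere."""
    signal_labels = [f"chr{c}_{q}" for c in range(1, 6) for q in range(1, 5)]
    delta = {lab: 0.01 for lab in signal_labels}  # 0.5 * (0.2 / sqrt(100))
    return SimConfig(
        n_samples=n_samples,
        markers_per_chromosome=400,
        lrr_noise_sd=0.2,
        groups=[GroupSpec("A", 0.5, delta), GroupSpec("B", 0.5, 0.0)],
        sex_crosstalk=0.0,
        seed=seed,
    )


def cohort_features(config: SimConfig):
    """Simulate, featurize and complete-case filter a cohort."""
    cohort = simulate_cohort(config)
    table = compute_cslv(cohort.lrr, cohort.manifest, cohort.scheme)
    return cohort, filter_complete(table)


def run_pair_benchmark(config: SimConfig, n_repeats: int = 5) -> bench.RepeatedAuc:
    """Repeated-holdout AUC for a two-group preset, using the default
    regularized-logistic recipe (the Bayes-optimal family here)."""
    cohort, features = cohort_features(config)
    labels = [g.label for g in config.groups]
    spec = TaskSpec(
        mode=bench.CLASSIFICATION,
        positive=labels[0],
        negative=labels[1],
        n_repeats=n_repeats,
        seed=config.seed,
    )
    table = build_task(features, cohort.phenotypes, spec)
    recipe = default_recipe(bench.CLASSIFICATION, seed=config.seed)
    return repeated_holdout(table, recipe, spec)


def run_height_benchmark(config: SimConfig, n_groups: int = 50, trial_budget: int = 4,
                         cv_folds: int = 5):
    """Full height pipeline on a preset cohort.

    Model search (trial-budgeted, with stacked ensembles) on the
    training fraction, prediction on the held-out fraction, then the
    grouped-mean curve.  Returns (leaderboard, curve, spearman rho of
    group index vs mean actual height, gap ratio).

    The gap ratio compares the largest consecutive jump in group mean
    actual height (the between-sex gap when the model separates the
    sexes) with the median of the remaining jumps (the within-sex
    group-to-group step).
    """
    cohort, features = cohort_features(config)
    spec = TaskSpec(
        mode=bench.REGRESSION,
        cv_folds=cv_folds,
        trial_budget=trial_budget,
        seed=config.seed,
    )
    table = build_task(features, cohort.phenotypes, spec)
    n = len(table)
    n_train, _ = split_counts(n, spec.train_fraction)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(9,)))
    perm = rng.permutation(n)
    train, test = table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]
    leaderboard, model = model_search(train, spec)
    predicted = model.predict(test.drop(columns=[spec.target]))
    actual = test[spec.target].to_numpy()
    curve = grouped_mean_curve(predicted, actual, n_groups=n_groups)
    means = curve.table["mean_actual"].to_numpy()
    rho = float(spearmanr(curve.table["group"], means).statistic)
    jumps = np.diff(means)
    gap = float(np.max(jumps))
    others = np.delete(jumps, np.argmax(jumps))
    step = float(np.median(np.abs(others)))
    gap_ratio = gap / step if step > 0 else np.inf
    return leaderboard, curve, rho, gap_ratio


def run_importance_benchmark(config: SimConfig, n_repeats: int = 5):
    """Fit the default classifier on the training fraction and compute
    held-out permutation importance; returns (report, max share of the
    total positive importance mass held by any single feature)."""
    cohort, features = cohort_features(config)
    labels = [g.label for g in config.groups]
    spec = TaskSpec(
        mode=bench.CLASSIFICATION, positive=labels[0], negative=labels[1],
        seed=config.seed,
    )
    table = build_task(features, cohort.phenotypes, spec)
    n = len(table)
    n_train, _ = split_counts(n, spec.train_fraction)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(9,)))
    perm = rng.permutation(n)
    train, test = table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]
    recipe = default_recipe(bench.CLASSIFICATION, seed=config.seed)
    recipe.fit(train.drop(columns=["label"]), train["label"].to_numpy())
    report = permutation_importance(
        recipe, test.drop(columns=["label"]), test["label"].to_numpy(),
        metric="auc", n_repeats=n_repeats, seed=config.seed,
    )
    mass = report.table["importance_mean"].clip(lower=0.0)
    total = float(mass.sum())
    max_share = float(mass.max() / total) if total > 0 else 0.0
    return report, max_share
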