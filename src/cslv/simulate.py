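"""Synthetic SNP-array cohorts with segment-level dosage structure.

The generator produces a marker manifest, a log-R-ratio matrix, a
phenotype table and the ground truth behind them.  Marker-level LRR for
sample *i* at marker *j* is

    lrr[i, j] = delta_group(i)[seg(j)] + crosstalk[seg(j)] * male_i
                + delta_cnv(i, seg(j)) + eps_ij,     eps ~ N(0, sigma^2)

i.e. each sample's expected LRR is constant within a segment ("truth
segment mean") and per-marker noise sits on top.  The components:

* **groups** — phenomenological dosage-shift classes (not ancestry
  models): each sample belongs to one group, which contributes a fixed
  per-segment shift vector.
* **sex crosstalk** — a small additive shift on a subset of autosomal
  segments applied to males only, emulating the empirical fact that
  autosomal array intensities leak information about Y-chromosome
  presence (probe design).
* **CNV events** — per (sample, segment) with probability ``cnv_rate``,
  copy number 1 or 3 equiprobably, shifting the whole segment by the
  conventional attenuated LRR values (-0.45 for one copy, +0.30 for
  three).

Height follows a linear model on sex, age-cohort (older people are
shorter on average) and a weighted sum of the truth segment means
(the heritable dosage signal), plus Gaussian residual.

Randomness: every draw comes from a stream keyed by
``SeedSequence(seed, spawn_key=(component, sample_index))``, so growing
the cohort never perturbs earlier samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io import canonical_manifest
from .segments import SegmentScheme, make_segments
from . import io as cslv_io

_COMPONENT = {"phenotype": 0, "cnv": 1, "noise": 2}


@dataclass
class GroupSpec:
    """A dosage-shift class: label, mixing proportion, per-segment shift.

    ``delta`` may be a scalar (applied to every segment), a mapping from
    segment label to shift, or a full vector over the segment scheme.
    """

    label: str
    proportion: float
    delta: float | Mapping[str, float] | Sequence[float] = 0.0


@dataclass
class HeightModel:
    """Linear height model, all coefficients in cm.

    ``beta_age`` is cm per year relative to the midpoint of the age
    range; ``gamma`` weights the truth segment means (cm per LRR unit)
    — the heritable contribution.
    """

    intercept: float = 165.0
    beta_sex: float = 13.0
    beta_age: float = -0.06
    gamma: float | Mapping[str, float] | Sequence[float] = 0.0
    resid_sd: float = 6.0


@dataclass
class SimConfig:
    """Full description of a synthetic cohort.

    Defaults give a neutral 2,000-sample cohort on all 22 autosomes with
    100 markers per chromosome, four segments per chromosome (88
    features) and per-marker noise sd 0.15, so segment means scatter
    with sd 0.15 / sqrt(25) = 0.03 — the order of magnitude seen on
    real arrays.  The default sex crosstalk is +0.02 on the first
    segment of chromosomes 1-8.
    """

    n_samples: int = 2000
    chromosomes: tuple[int, ...] = tuple(range(1, 23))
    markers_per_chromosome: int = 100
    segments_per_chromosome: int = 4
    lrr_noise_sd: float = 0.15
    groups: list[GroupSpec] = field(
        default_factory=lambda: [GroupSpec("pop", 1.0, 0.0)]
    )
    sex_crosstalk: float | Mapping[str, float] | Sequence[float] | None = None
    male_fraction: float = 0.5
    cnv_rate: float = 0.0
    cnv_shift: Mapping[int, float] = field(
        default_factory=lambda: {1: -0.45, 3: 0.30}
    )
    height: HeightModel = field(default_factory=HeightModel)
    age_range: tuple[float, float] = (21.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.lrr_noise_sd < 0 or self.height.resid_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not 0 <= self.cnv_rate <= 1:
            raise ValueError("cnv_rate must be in [0, 1]")
        total = sum(g.proportion for g in self.groups)
        if not np.isclose(total, 1.0):
            raise ValueError(f"group proportions must sum to 1, got {total}")
        if any(c not in range(1, 23) for c in self.chromosomes):
            raise ValueError("chromosomes must be a subset of 1-22")

    # -- derived structure -------------------------------------------------

    def manifest(self) -> pd.DataFrame:
        """Deterministic manifest: evenly spaced markers per chromosome."""
        rows = []
        for c in sorted(self.chromosomes):
            for i in range(self.markers_per_chromosome):
                rows.append((f"m{c:02d}_{i:05d}", c, 1 + i * 1000))
        return canonical_manifest(
            pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp"])
        )

    def scheme(self) -> SegmentScheme:
        return make_segments(self.manifest(), k=self.segments_per_chromosome)

    def expand(self, value, name: str) -> np.ndarray:
        """Normalize a scalar / per-label mapping / vector to a full
        per-segment vector in scheme order."""
        labels = self.scheme().labels
        if value is None:
            value = 0.0
        if np.isscalar(value):
            return np.full(len(labels), float(value))
        if isinstance(value, Mapping):
            unknown = set(value) - set(labels)
            if unknown:
                raise ValueError(f"{name}: unknown segment labels {sorted(unknown)}")
            return np.array([float(value.get(lab, 0.0)) for lab in labels])
        vec = np.asarray(value, dtype=float)
        if vec.shape != (len(labels),):
            raise ValueError(
                f"{name}: expected {len(labels)} per-segment values, got {vec.shape}"
            )
        return vec


def default_crosstalk(
    config: SimConfig, shift: float = 0.02, n_segments: int = 8
) -> dict[str, float]:
    """Male-specific shift on the first segment of the first chromosomes."""
    chroms = sorted(config.chromosomes)[:n_segments]
    return {f"chr{c}_1": shift for c in chroms}


@dataclass
class SimulatedCohort:
    """A simulated cohort plus its ground truth."""

    manifest: pd.DataFrame
    lrr: pd.DataFrame
    phenotypes: pd.DataFrame
    #: per-sample per-segment true mean shift (group + sex + CNV)
    truth: pd.DataFrame
    #: per-sample heritable height contribution (gamma . truth row), cm
    genetic_height: pd.Series
    scheme: SegmentScheme
    config: SimConfig


def _rng(seed: int, component: str, sample_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed, spawn_key=(_COMPONENT[component], sample_index)
        )
    )


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Draw a cohort from ``config`` (fully reproducible from its seed)."""
    manifest = config.manifest()
    scheme = config.scheme()
    n_seg = scheme.n_segments
    n_markers = len(manifest)
    seg_sizes = scheme.marker_counts()
    if seg_sizes.sum() != n_markers:
        raise AssertionError("scheme does not cover the manifest")

    deltas = np.stack([config.expand(g.delta, f"group {g.label}") for g in config.groups])
    crosstalk = (
        config.expand(config.sex_crosstalk, "sex_crosstalk")
        if config.sex_crosstalk is not None
        else config.expand(default_crosstalk(config), "sex_crosstalk")
    )
    gamma = config.expand(config.height.gamma, "gamma")
    proportions = np.cumsum([g.proportion for g in config.groups])
    a_lo, a_hi = config.age_range
    age_mid = 0.5 * (a_lo + a_hi)
    cnv_copies = sorted(config.cnv_shift)

    n = config.n_samples
    lrr = np.empty((n, n_markers))
    truth = np.empty((n, n_seg))
    sample_ids = [f"S{i:06d}" for i in range(n)]
    sexes, labels, ages, heights, genetic = [], [], [], [], []

    for i in range(n):
        ph = _rng(config.seed, "phenotype", i)
        g_idx = int(np.searchsorted(proportions, ph.random(), side="right"))
        g_idx = min(g_idx, len(config.groups) - 1)
        male = ph.random() < config.male_fraction
        age = ph.uniform(a_lo, a_hi)
        resid = ph.normal(0.0, config.height.resid_sd) if config.height.resid_sd else 0.0

        cn = _rng(config.seed, "cnv", i)
        u_event = cn.random(n_seg)
        u_copy = cn.random(n_seg)
        cnv_delta = np.zeros(n_seg)
        if config.cnv_rate > 0:
            hit = u_event < config.cnv_rate
            copies = np.where(u_copy < 0.5, cnv_copies[0], cnv_copies[-1])
            shifts = np.array([config.cnv_shift[c] for c in copies])
            cnv_delta[hit] = shifts[hit]

        seg_mean = deltas[g_idx] + crosstalk * male + cnv_delta
        truth[i] = seg_mean
        noise = (
            _rng(config.seed, "noise", i).normal(0.0, config.lrr_noise_sd, n_markers)
            if config.lrr_noise_sd > 0
            else np.zeros(n_markers)
        )
        lrr[i] = np.repeat(seg_mean, seg_sizes) + noise

        g_height = float(gamma @ seg_mean)
        h = (
            config.height.intercept
            + config.height.beta_sex * male
            + config.height.beta_age * (age - age_mid)
            + g_height
            + resid
        )
        sexes.append("male" if male else "female")
        labels.append(config.groups[g_idx].label)
        ages.append(age)
        heights.append(h)
        genetic.append(g_height)

    lrr_df = pd.DataFrame(lrr, index=sample_ids, columns=manifest["marker_id"])
    lrr_df.index.name = "sample_id"
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sexes,
            "group_label": labels,
            "age": ages,
            "height": heights,
        }
    )
    truth_df = pd.DataFrame(truth, index=sample_ids, columns=scheme.labels)
    truth_df.index.name = "sample_id"
    return SimulatedCohort(
        manifest=manifest,
        lrr=lrr_df,
        phenotypes=phenotypes,
        truth=truth_df,
        genetic_height=pd.Series(genetic, index=sample_ids, name="genetic_height"),
        scheme=scheme,
        config=config,
    )


def expected_pair_auc(config: SimConfig, label_pair: tuple[str, str] | None = None) -> float:
    """Bayes-optimal AUC for separating two groups on CSLV features.

    Valid only for the pure two-group Gaussian problem: no CNV events
    and no sex crosstalk.  With per-segment shift difference d_seg =
    (delta_1 - delta_2)[seg] and CSLV noise sd sigma / sqrt(m_seg), the
    optimal linear discriminant achieves

        AUC = Phi(D / sqrt(2)),   D^2 = sum_seg (d_seg * sqrt(m_seg) / sigma)^2.
    """
    if config.cnv_rate > 0:
        raise ValueError("closed form invalid when CNV events are active")
    crosstalk = (
        config.expand(config.sex_crosstalk, "sex_crosstalk")
        if config.sex_crosstalk is not None
        else config.expand(default_crosstalk(config), "sex_crosstalk")
    )
    if np.any(crosstalk != 0):
        raise ValueError("closed form invalid when sex crosstalk is active")
    if label_pair is None:
        if len(config.groups) != 2:
            raise ValueError("label_pair required unless exactly two groups")
        g1, g2 = config.groups
    else:
        by_label = {g.label: g for g in config.groups}
        g1, g2 = by_label[label_pair[0]], by_label[label_pair[1]]
    diff = config.expand(g1.delta, g1.label) - config.expand(g2.delta, g2.label)
    m_seg = config.scheme().marker_counts()
    sigma = config.lrr_noise_sd
    if sigma == 0:
        return 1.0 if np.any(diff != 0) else 0.5
    d = diff * np.sqrt(m_seg) / sigma
    big_d = float(np.sqrt(np.sum(d**2)))
    return float(norm.cdf(big_d / np.sqrt(2.0)))


def write_cohort(cohort: SimulatedCohort, directory) -> None:
    """Write a cohort as four text files (long LRR TSV, manifest TSV,
    phenotype CSV, truth CSV).  ``read_lrr_long`` on the output
    reproduces the in-memory matrix exactly."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cslv_io.write_lrr_long(
        cohort.lrr, cohort.manifest, directory / "lrr_long.tsv", baf=0.5
    )
    cslv_io.write_manifest(cohort.manifest, directory / "manifest.tsv")
    cslv_io.write_phenotypes(cohort.phenotypes, directory / "phenotypes.csv")
    truth = cohort.truth.copy()
    truth.insert(0, "sample_id", truth.index)
    truth.to_csv(directory / "truth.csv", index=False, float_format="%.17g")


# -- JSON config (CLI) -----------------------------------------------------


def config_to_json(config: SimConfig) -> str:
    payload = asdict(config)
    payload["cnv_shift"] = {str(k): v for k, v in config.cnv_shift.items()}
    return json.dumps(payload, indent=2, sort_keys=True)


def config_from_json(text: str) -> SimConfig:
    payload = json.loads(text)
    payload["groups"] = [GroupSpec(**g) for g in payload.get("groups", [])]
    if "height" in payload:
        payload["height"] = HeightModel(**payload["height"])
    if "cnv_shift" in payload:
        payload["cnv_shift"] = {int(k): v for k, v in payload["cnv_shift"].items()}
    for key in ("chromosomes", "age_range"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return SimConfig(**payload)
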