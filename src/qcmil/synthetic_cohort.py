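"""Synthetic cohort generator with the statistical structure MIL assumes.

Each bag stands for one slide. Its instances are cell-feature vectors built
from three components that mirror what makes slide-level cytology screening
hard:

* a patient-specific baseline ``mu_b ~ N(0, baseline_sd^2 I)`` shared by all
  cells of the slide — cells that look borderline in one patient are typical
  in another;
* extreme abnormal-cell rarity — positive bags carry a small fraction of
  abnormal cells (clinically as low as 1 in 10,000; emulated at desk scale
  with a default rate of 0.05 over bags of 50-200 cells, with at least one
  abnormal cell forced into every positive bag), each offset by
  ``effect_size`` along a cohort-wide unit direction ``u``;
* quality corruption — a fraction of patches is drawn from a "bad"
  metric regime (blur, artifacts, uneven stain) and their features receive
  extra heavy noise, so low quality scores co-occur with degraded features;
  a sub-fraction of the corrupted patches are *artifact mimics* whose
  features are additionally offset along the abnormal direction at a random
  partial strength — dye clumps and debris that look like abnormal cells to
  a feature extractor and inflate the false-positive rate of any
  quality-blind model. That coupling is what gives quality screening and
  quality weighting a measurable effect.

Optionally the normal population is a mixture of ``n_normal_subtypes``
latent morphological subtypes (cohort-wide offsets, slide-specific mixture
proportions), the structure the prototype count K of the comparison module
is meant to capture.

All randomness derives from ``cfg.seed``; cohort-wide structure (``u``,
subtype offsets) is shared across the train/validation/test splits of the
same seed while per-split sampling is independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bag_model import ABNORMAL, NORMAL, Bag, Cohort
from .quality_screening import QualityMetrics, ScreeningConfig, compute_quality_score

_SPLIT_STREAM = {"train": 1, "validation": 2, "test": 3}


@dataclass
class SimulationConfig:
    """Cohort-generation settings; defaults are the package's study conditions."""

    n_bags: int = 200
    instances_per_bag: tuple[int, int] = (50, 200)
    abnormal_bag_fraction: float = 0.5
    abnormal_instance_rate: float = 0.05   # rarity of abnormal cells in positive bags
    n_normal_per_bag: int = 32             # normals guaranteed clean for the reference
    effect_size: float = 36.0              # abnormal offset magnitude (delta)
    baseline_sd: float = 0.8               # patient baseline scale
    noise_sd: float = 1.0                  # per-cell feature noise
    quality_corrupt_fraction: float = 0.2
    quality_noise_sd: float = 2.0          # extra feature noise on corrupted patches
    mimic_fraction: float = 0.3            # corrupted patches that mimic abnormality
    mimic_strength: tuple[float, float] = (0.3, 1.0)  # mimic offset, units of delta
    M: int = 64
    seed: int = 42
    n_normal_subtypes: int = 1             # latent normal morphologies
    subtype_sd: float = 6.0                # subtype offset scale
    subtype_alpha: float = 0.3             # Dirichlet concentration of per-bag mixes
    subtype_borderline_max: float = 0.7    # max subtype drift along the abnormal
    #   direction, in units of effect_size (borderline-normal morphologies)

    def __post_init__(self) -> None:
        lo, hi = self.instances_per_bag
        if lo < 1 or hi < lo:
            raise ValueError("instances_per_bag must be a range with min >= 1")
        if not 0.0 <= self.abnormal_bag_fraction <= 1.0:
            raise ValueError("abnormal_bag_fraction must lie in [0, 1]")
        if not 0.0 < self.abnormal_instance_rate <= 1.0:
            raise ValueError("abnormal_instance_rate must lie in (0, 1]")
        if not 0.0 <= self.quality_corrupt_fraction <= 1.0:
            raise ValueError("quality_corrupt_fraction must lie in [0, 1]")
        if not 0.0 <= self.mimic_fraction <= 1.0:
            raise ValueError("mimic_fraction must lie in [0, 1]")
        glo, ghi = self.mimic_strength
        if glo < 0 or ghi < glo:
            raise ValueError("mimic_strength must be a nonnegative range")
        if (self.effect_size <= 0 or self.noise_sd <= 0
                or self.quality_noise_sd <= 0 or self.baseline_sd < 0):
            raise ValueError("scale parameters out of range")
        if self.M < 1 or self.n_bags < 0 or self.n_normal_per_bag < 0:
            raise ValueError("M must be >= 1, counts >= 0")
        if self.n_normal_subtypes < 1:
            raise ValueError("n_normal_subtypes must be >= 1")
        if self.subtype_borderline_max < 0:
            raise ValueError("subtype_borderline_max must be >= 0")


def _good_metrics(rng: np.random.Generator, n: int,
                  sat: float) -> QualityMetrics:
    return QualityMetrics(
        cellularity=rng.uniform(sat, 3.0 * sat, n),
        clarity=rng.uniform(0.7, 1.0, n),
        artifact_fraction=rng.uniform(0.0, 0.15, n),
        stain_uniformity=rng.uniform(0.7, 1.0, n),
    )


def _bad_metrics(rng: np.random.Generator, n: int,
                 sat: float) -> QualityMetrics:
    # composite score range (0, ~0.45]: mostly below a 0.3 threshold, with a
    # tail that slips past screening and is left to quality weighting
    return QualityMetrics(
        cellularity=rng.uniform(0.0, 0.5 * sat, n),
        clarity=rng.uniform(0.0, 0.3, n),
        artifact_fraction=rng.uniform(0.45, 1.0, n),
        stain_uniformity=rng.uniform(0.0, 0.45, n),
    )


def generate_cohort(cfg: SimulationConfig, split_tag: str = "train",
                    n_bags: int | None = None,
                    screening: ScreeningConfig | None = None
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate one cohort split plus its ground-truth table.

    Positive bags are allocated deterministically (exact count
    ``round(n_bags * abnormal_bag_fraction)``), each guaranteed at least one
    abnormal instance; negative bags contain none. The returned truth table
    has columns ``bag_id, patch_id, true_cell_label, corrupted_flag``.
    """
    if split_tag not in _SPLIT_STREAM:
        raise ValueError(f"invalid split_tag {split_tag!r}")
    screening = screening or ScreeningConfig()
    n_bags = cfg.n_bags if n_bags is None else int(n_bags)

    # cohort-wide structure is shared by every split of the same seed
    struct_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.seed, 0)))
    u = struct_rng.normal(size=cfg.M)
    u /= np.linalg.norm(u)
    G = cfg.n_normal_subtypes
    if G == 1:
        subtype_offsets = np.zeros((1, cfg.M))
    else:
        subtype_offsets = struct_rng.normal(scale=cfg.subtype_sd,
                                            size=(G, cfg.M))
        # borderline subtypes drift part-way along the abnormal direction
        beta = struct_rng.uniform(0.0, cfg.subtype_borderline_max, G)
        subtype_offsets += (beta * cfg.effect_size)[:, None] * u

    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.seed, _SPLIT_STREAM[split_tag])))

    n_pos = int(round(n_bags * cfg.abnormal_bag_fraction))
    bag_labels = np.zeros(n_bags, dtype=int)
    bag_labels[:n_pos] = 1
    rng.shuffle(bag_labels)

    lo, hi = cfg.instances_per_bag
    prefix = {"train": "tr", "validation": "va", "test": "te"}[split_tag]

    bags: list[Bag] = []
    truth_rows: list[tuple] = []
    for b in range(n_bags):
        bag_id = f"{prefix}{b:04d}"
        K = int(rng.integers(lo, hi + 1))
        y = int(bag_labels[b])

        n_ab = 0
        if y == 1:
            n_ab = max(1, int(rng.binomial(K, cfg.abnormal_instance_rate)))
            n_ab = min(n_ab, K)
        is_ab = np.zeros(K, dtype=bool)
        is_ab[rng.choice(K, size=n_ab, replace=False)] = True

        mu_b = rng.normal(scale=cfg.baseline_sd, size=cfg.M)
        pi_b = (np.ones(1) if G == 1 else
                rng.dirichlet(np.full(G, cfg.subtype_alpha)))
        subtype = rng.choice(G, size=K, p=pi_b)

        # all cells inherit the slide baseline and a latent normal subtype
        # context; abnormal cells are additionally offset along u
        X = mu_b + rng.normal(scale=cfg.noise_sd, size=(K, cfg.M))
        X += subtype_offsets[subtype]
        X[is_ab] += cfg.effect_size * u

        corrupted = rng.random(K) < cfg.quality_corrupt_fraction
        # guarantee a clean normal pool for the per-slide reference
        normal_idx = np.flatnonzero(~is_ab)
        protect = normal_idx[:cfg.n_normal_per_bag]
        corrupted[protect] = False
        n_bad = int(corrupted.sum())
        X[corrupted] += rng.normal(scale=cfg.quality_noise_sd,
                                   size=(n_bad, cfg.M))
        # artifact mimics: corrupted patches partially offset along the
        # abnormal direction (debris that resembles abnormal cells)
        mimic = corrupted & (rng.random(K) < cfg.mimic_fraction)
        glo, ghi = cfg.mimic_strength
        gamma = rng.uniform(glo, ghi, int(mimic.sum()))
        X[mimic] += (cfg.effect_size * gamma)[:, None] * u

        good = _good_metrics(rng, K - n_bad, screening.cellularity_saturation)
        bad = _bad_metrics(rng, n_bad, screening.cellularity_saturation)
        quality = np.empty(K)
        quality[~corrupted] = compute_quality_score(good, screening)
        quality[corrupted] = compute_quality_score(bad, screening)
        quality = np.clip(quality, 0.0, 1.0)

        labels = [ABNORMAL if a else NORMAL for a in is_ab]
        patch_ids = [f"{bag_id}-p{i:04d}" for i in range(K)]
        bags.append(Bag(bag_id=bag_id, features=X, qualities=quality,
                        cell_labels=labels, patch_ids=patch_ids, label=y))
        truth_rows.extend(
            (bag_id, patch_ids[i], labels[i], bool(corrupted[i]),
             bool(mimic[i]))
            for i in range(K))

    cohort = Cohort(bags=bags, C=2, M=cfg.M, split_tag=split_tag)
    cohort.validate()
    truth = pd.DataFrame(truth_rows, columns=[
        "bag_id", "patch_id", "true_cell_label", "corrupted_flag",
        "mimic_flag"])
    return cohort, truth


def generate_splits(cfg: SimulationConfig, n_val: int = 0,
                    n_test: int | None = None,
                    screening: ScreeningConfig | None = None
                    ) -> dict[str, tuple[Cohort, pd.DataFrame]]:
    """Generate train (cfg.n_bags), optional validation, and test splits.

    The test split defaults to half the training size. All splits share the
    cohort-wide abnormal direction and subtype structure of ``cfg.seed``.
    """
    n_test = cfg.n_bags // 2 if n_test is None else int(n_test)
    out = {"train": generate_cohort(cfg, "train", screening=screening)}
    if n_val > 0:
        out["validation"] = generate_cohort(cfg, "validation", n_bags=n_val,
                                            screening=screening)
    if n_test > 0:
        out["test"] = generate_cohort(cfg, "test", n_bags=n_test,
                                      screening=screening)
    return out


def describe_cohort(cohort: Cohort) -> pd.DataFrame:
    """Tidy summary: bag counts by label, instance counts by cell label,
    and quality-score quantiles. Empty cohort -> zero-row table."""
    rows: list[tuple[str, str, float]] = []
    labels = cohort.labels
    for lab in sorted(set(labels.tolist())):
        rows.append(("bags_by_label", str(lab), int((labels == lab).sum())))
    cell_counts: dict[str, int] = {}
    qualities: list[np.ndarray] = []
    for bag in cohort.bags:
        for cl in bag.cell_labels:
            cell_counts[cl] = cell_counts.get(cl, 0) + 1
        if bag.K:
            qualities.append(bag.qualities)
    for cl in sorted(cell_counts):
        rows.append(("instances_by_cell_label", cl, cell_counts[cl]))
    if qualities:
        q = np.concatenate(qualities)
        for p in (0, 25, 50, 75, 100):
            rows.append(("quality_quantile", f"q{p}",
                         float(np.percentile(q, p))))
    return pd.DataFrame(rows, columns=["section", "key", "value"])
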