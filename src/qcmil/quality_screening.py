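"""Patch quality scoring and the quality initial screening module (QISM).

A patch's composite quality score in [0, 1] is a weighted arithmetic mean of
normalized sub-metric scores (clarity, freedom from artifacts, stain
uniformity, saturating cellularity). Screening keeps only the instances whose
score strictly exceeds a conservative threshold; everything downstream sees
the surviving instances.

Pixel-level quality assessment (blur estimation, artifact segmentation, stain
deconvolution) is out of scope: this module aggregates already-computed
sub-metrics, which is exactly what the synthetic generator produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bag_model import Bag


@dataclass
class QualityMetrics:
    """Sub-metric stack for one patch. Fields may be scalars or equal-length arrays."""

    cellularity: float | np.ndarray      # nonnegative cell-count proxy
    clarity: float | np.ndarray          # in [0, 1]
    artifact_fraction: float | np.ndarray  # in [0, 1]
    stain_uniformity: float | np.ndarray   # in [0, 1]

    def validate(self) -> None:
        cell = np.asarray(self.cellularity, dtype=float)
        if np.any(cell < 0) or not np.all(np.isfinite(cell)):
            raise ValueError("cellularity must be finite and >= 0")
        for name in ("clarity", "artifact_fraction", "stain_uniformity"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ScreeningConfig:
    """Threshold and aggregation weights for quality screening.

    ``weights`` are per-sub-metric, ordered (clarity, artifact, uniformity,
    cellularity), nonnegative, summing to 1. ``threshold`` is the conservative
    quality cut-off; only scores strictly above it survive screening.
    ``cellularity_saturation`` is the count at which the cellularity sub-score
    reaches 1.
    """

    threshold: float = 0.3
    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cellularity_saturation: float = 50.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0):
            raise ValueError("weights must be 4 nonnegative reals")
        if abs(float(w.sum()) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.cellularity_saturation <= 0:
            raise ValueError("cellularity_saturation must be positive")


def compute_quality_score(metrics: QualityMetrics,
                          config: ScreeningConfig | None = None
                          ) -> float | np.ndarray:
    """Aggregate sub-metrics into a composite score in [0, 1].

    score = w_clar*clarity + w_art*(1 - artifact_fraction)
          + w_uni*stain_uniformity + w_cell*min(cellularity/saturation, 1)

    Monotone nondecreasing in clarity, uniformity and cellularity, and
    nonincreasing in artifact_fraction; 1-Lipschitz in each bounded
    sub-metric when the weights are <= 1.
    """
    config = config or ScreeningConfig()
    metrics.validate()
    w = np.asarray(config.weights, dtype=float)
    sub = np.stack(np.broadcast_arrays(
        np.asarray(metrics.clarity, dtype=float),
        1.0 - np.asarray(metrics.artifact_fraction, dtype=float),
        np.asarray(metrics.stain_uniformity, dtype=float),
        np.minimum(np.asarray(metrics.cellularity, dtype=float)
                   / config.cellularity_saturation, 1.0),
    ))
    score = np.tensordot(w, sub, axes=(0, 0))
    return float(score) if score.ndim == 0 else score


def screen_bag(bag: Bag, config: ScreeningConfig | None = None
               ) -> tuple[Bag, int]:
    """Keep only instances with quality strictly above the threshold.

    Returns the screened bag (order preserved, label unchanged; K may drop
    to 0) and the number of removed instances, so K_kept + removed == K.
    """
    config = config or ScreeningConfig()
    keep = bag.qualities > config.threshold
    kept = Bag(
        bag_id=bag.bag_id,
        features=bag.features[keep],
        qualities=bag.qualities[keep],
        cell_labels=[lab for lab, k in zip(bag.cell_labels, keep) if k],
        patch_ids=[pid for pid, k in zip(bag.patch_ids, keep) if k],
        label=bag.label,
    )
    return kept, int(bag.K - kept.K)
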