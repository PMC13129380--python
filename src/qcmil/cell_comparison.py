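"""Normal-abnormal cell comparative enhancement (CFCM) and the SupCon loss.

Pathologists judge a suspicious cell against prototypical normal cells from
the *same* slide, because baseline cell morphology differs across patients.
This module mirrors that: per slide, K-means over the normal-cell features
yields cluster centers, their average is the patient-specific normal
reference ``r``, and suspected-abnormal features are enhanced by their
difference from ``r`` (which cancels any per-slide additive baseline
exactly). An instance-level supervised contrastive (SupCon) loss on
l2-normalized embeddings measures intra-class compactness versus inter-class
separation:

    L = sum_{i in I, P(i) nonempty} (1/|P(i)|) sum_{p in P(i)}
            -log[ exp(z_i.z_p / tau) / sum_{a in A(i)} exp(z_i.z_a / tau) ]

where P(i) are the other same-class embeddings, A(i) all other embeddings,
and tau a temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

_ZERO_NORM_EPS = 1e-12


class NoPositivePairsError(ValueError):
    """Every anchor's positive set P(i) is empty (all labels distinct)."""


@dataclass
class NormalReference:
    """Per-slide normal prototypes: K-means centers and their average ``r``."""

    centers: np.ndarray     # (K_eff, M); possibly 0 rows
    reference: np.ndarray   # (M,)
    k_clusters: int         # requested K (the Fig.-style hyperparameter)

    def validate(self) -> None:
        if self.centers.shape[0]:
            if not np.allclose(self.reference, self.centers.mean(axis=0),
                               atol=1e-9):
                raise ValueError(
                    "reference must equal the unweighted mean of centers")


def cluster_normals(features: np.ndarray, k_clusters: int, seed: int = 0,
                    reference: str = "center_mean") -> NormalReference:
    """K-means (Lloyd, k-means++ seeding, fixed seed) over normal-cell features.

    Uses ``K_eff = min(k_clusters, n_features)`` centers; with no normal
    cells at all, falls back to an empty center set and a zero reference so
    that enhancement degrades gracefully to the identity.

    ``reference='center_mean'`` (default) averages the cluster centers,
    robust to cluster-size imbalance; ``reference='global_mean'`` averages
    all normal features directly.
    """
    if k_clusters < 1:
        raise ValueError("k_clusters must be >= 1")
    if reference not in ("center_mean", "global_mean"):
        raise ValueError(f"unknown reference rule {reference!r}")
    features = np.asarray(features, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D (n, M) array")
    if not np.all(np.isfinite(features)):
        raise ValueError("non-finite normal-cell features")

    n, M = features.shape
    if n == 0:
        return NormalReference(np.empty((0, M)), np.zeros(M), k_clusters)

    k_eff = min(k_clusters, n)
    km = KMeans(n_clusters=k_eff, init="k-means++", n_init=1,
                algorithm="lloyd", random_state=seed)
    km.fit(features)
    centers = np.asarray(km.cluster_centers_, dtype=float)
    if reference == "center_mean":
        ref = centers.mean(axis=0)
    else:
        ref = features.mean(axis=0)
    return NormalReference(centers, ref, k_clusters)


def enhance_instances(features: np.ndarray, ref: NormalReference,
                      mode: str = "difference") -> np.ndarray:
    """Enhance suspected-abnormal features against the normal prototypes.

    mode='difference':     e_i = x_i - r   (length M; cancels per-slide
                           baselines exactly)
    mode='concat':         e_i = [x_i ; x_i - r]   (length 2M)
    mode='nearest_center': e_i = x_i - c_(nearest prototype)   (length M;
                           each cell is compared against its most similar
                           normal prototype, so a larger prototype set can
                           absorb more normal-cell diversity)

    With no prototypes available (``centers`` empty) every mode degrades to
    the identity (difference against the zero reference).
    """
    if mode not in ("difference", "concat", "nearest_center"):
        raise ValueError(f"unknown enhancement mode {mode!r}")
    features = np.asarray(features, dtype=float)
    M = ref.reference.shape[0]
    if features.size == 0:
        return np.empty((0, 2 * M if mode == "concat" else M))
    if features.shape[1] != M:
        raise ValueError(
            f"feature dimension {features.shape[1]} != reference "
            f"dimension {M}")
    if mode == "nearest_center":
        if ref.centers.shape[0] == 0:
            return features.copy()
        d2 = ((features[:, None, :] - ref.centers[None]) ** 2).sum(axis=2)
        # ties resolve to the lowest center index (argmin convention)
        return features - ref.centers[d2.argmin(axis=1)]
    diff = features - ref.reference
    return np.concatenate([features, diff], axis=1) if mode == "concat" else diff


def l2_normalize(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project vectors onto the unit sphere.

    Accepts one vector or a stack of row vectors. Vectors with norm below
    1e-12 are returned as zero vectors with their exclusion flag set, so the
    caller can drop them from contrastive batches.
    """
    v = np.asarray(v, dtype=float)
    single = v.ndim == 1
    mat = v[None, :] if single else v
    norms = np.linalg.norm(mat, axis=1)
    degenerate = norms <= _ZERO_NORM_EPS
    out = np.where(degenerate[:, None], 0.0,
                   mat / np.where(degenerate, 1.0, norms)[:, None])
    if single:
        return out[0], degenerate[0]
    return out, degenerate


@dataclass
class ContrastiveBatch:
    """Unit-norm embeddings with class labels and a temperature tau > 0."""

    embeddings: np.ndarray  # (n, d), rows unit-norm
    labels: np.ndarray      # (n,)
    temperature: float = 0.1

    def validate(self) -> None:
        z = np.asarray(self.embeddings, dtype=float)
        y = np.asarray(self.labels)
        if z.ndim != 2 or y.shape != (z.shape[0],):
            raise ValueError("embeddings (n, d) and labels (n,) required")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        norms = np.linalg.norm(z, axis=1)
        if z.shape[0] and np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ValueError("embeddings must be unit-norm (within 1e-6)")


def supcon_loss(batch: ContrastiveBatch, with_grad: bool = False
                ) -> float | tuple[float, np.ndarray]:
    """Supervised contrastive loss over a batch, log-sum-exp stabilized.

    Anchors whose positive set is empty are skipped; if *every* anchor has an
    empty positive set a :class:`NoPositivePairsError` is raised. With
    ``with_grad=True`` also returns dL/dZ (the analytic gradient with respect
    to the embedding matrix, treating rows as free vectors).
    """
    batch.validate()
    Z = np.asarray(batch.embeddings, dtype=float)
    y = np.asarray(batch.labels)
    tau = float(batch.temperature)
    n = Z.shape[0]
    if n < 2:
        raise NoPositivePairsError("need at least 2 embeddings")

    sim = (Z @ Z.T) / tau                          # (n, n)
    eye = np.eye(n, dtype=bool)
    pos = (y[:, None] == y[None, :]) & ~eye        # P(i) membership
    n_pos = pos.sum(axis=1)
    anchors = n_pos > 0
    if not np.any(anchors):
        raise NoPositivePairsError("no positive pairs: all labels distinct")

    # log sum_{a in A(i)} exp(sim_ia), A(i) = everyone but i
    neg_inf = -np.inf
    sim_masked = np.where(eye, neg_inf, sim)
    m = sim_masked.max(axis=1, keepdims=True)
    exps = np.exp(sim_masked - m)
    lse = (m[:, 0] + np.log(exps.sum(axis=1)))     # (n,)

    # per-anchor mean of -(sim_ip - lse_i) over positives
    per_anchor = np.zeros(n)
    per_anchor[anchors] = (
        lse[anchors] - (sim * pos).sum(axis=1)[anchors] / n_pos[anchors])
    loss = float(per_anchor[anchors].sum())

    if not with_grad:
        return loss

    # dL/dsim = sum over anchors i of softmax_i (denominator) minus the
    # uniform positive mass (numerator), symmetrized because sim is Z Z^T.
    soft = exps / exps.sum(axis=1, keepdims=True)  # rows: softmax over A(i)
    dsim = np.zeros((n, n))
    dsim[anchors] = soft[anchors]
    dsim[anchors] -= pos[anchors] / n_pos[anchors, None]
    grad = (dsim @ Z + dsim.T @ Z) / tau
    return loss, grad
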