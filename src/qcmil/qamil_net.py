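"""Quality-aware attention-based multiple instance learning (QA-MIL).

One slide is a bag ``X = x_1..x_K`` of cell features with patch quality
scores ``S = s_1..s_K``. The network:

1. quality-weights instances,           x'_i = s_i * x_i
2. scores each instance,                a = softmax_k( w^T relu(LN(V x'_k)) )
3. pools a bag representation,          z = sum_k a_k x'_k
4. classifies,                          p = softmax(U z + b)

and is trained on the joint objective L = lam * L_bag + (1 - lam) * L_supcon
with L_bag the cross-entropy of the bag label. Upstream, each bag is
optionally screened by quality threshold (QISM) and its instances enhanced
against the slide's normal-cell prototype reference (CFCM); the three
ablation switches in :class:`~qcmil.config.MilConfig` turn these stages off
individually.

The parameter set is small (two linear maps, a layer norm's affine terms,
a linear head), so forward and backward passes are written explicitly in
NumPy and optimized with Adam; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cell_comparison as cc
from .bag_model import ABNORMAL, NORMAL, UNKNOWN, Bag, Cohort
from .config import CfcmConfig, MilConfig, RunConfig
from .quality_screening import ScreeningConfig, screen_bag

_LN_EPS = 1e-5
_PROB_FLOOR = 1e-12


class EmptyBagError(ValueError):
    """Attention weights requested for a bag with no instances."""


@dataclass
class AttentionParams:
    """Attention-scorer parameters: V (L x M), w (L,), and LayerNorm affine."""

    V: np.ndarray
    w: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray

    @property
    def L(self) -> int:
        return self.V.shape[0]

    @property
    def M(self) -> int:
        return self.V.shape[1]

    def validate(self) -> None:
        L, M = self.V.shape
        if self.w.shape != (L,) or self.gamma.shape != (L,) \
                or self.beta.shape != (L,):
            raise ValueError("attention parameter shapes inconsistent")
        for arr in (self.V, self.w, self.gamma, self.beta):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite attention parameters")


@dataclass
class BagPrediction:
    """Model output for one bag."""

    bag_id: str
    z: np.ndarray          # bag representation (M,)
    attention: np.ndarray  # per-kept-instance weights, sum to 1 (empty if K=0)
    probs: np.ndarray      # class probabilities (C,)
    patch_ids: list[str] = field(default_factory=list)
    empty_after_screening: bool = False

    @property
    def predicted_label(self) -> int:
        return int(np.argmax(self.probs))


def quality_weight(features: np.ndarray, qualities: np.ndarray) -> np.ndarray:
    """Scale each instance feature by its scalar quality score."""
    features = np.asarray(features, dtype=float)
    qualities = np.asarray(qualities, dtype=float)
    if features.shape[0] != qualities.shape[0]:
        raise ValueError("features and qualities length mismatch")
    return features * qualities[:, None]


def attention_weights(features: np.ndarray,
                      params: AttentionParams) -> np.ndarray:
    """Softmax attention over the instances of one bag.

    a_k = softmax_k( w^T max(LayerNorm(V x_k), 0) ), the softmax taken
    across the K instances so the weights form a probability vector.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] == 0:
        raise EmptyBagError("empty bag")
    t = _attention_scores(features, params)
    t = t - t.max()
    e = np.exp(t)
    return e / e.sum()


def _attention_scores(features: np.ndarray,
                      params: AttentionParams) -> np.ndarray:
    H = features @ params.V.T
    mu = H.mean(axis=1, keepdims=True)
    var = H.var(axis=1, keepdims=True)
    nrm = (H - mu) / np.sqrt(var + _LN_EPS)
    ln = params.gamma * nrm + params.beta
    return np.maximum(ln, 0.0) @ params.w


def aggregate(features: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Pooled bag representation z = sum_k a_k x_k."""
    features = np.asarray(features, dtype=float)
    attention = np.asarray(attention, dtype=float)
    if features.shape[0] != attention.shape[0]:
        raise ValueError("features and attention length mismatch")
    return attention @ features


def classify(z: np.ndarray, U: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear head + softmax: p = softmax(U z + b)."""
    logits = U @ np.asarray(z, dtype=float) + b
    logits = logits - logits.max()
    e = np.exp(logits)
    return e / e.sum()


def bag_loss(probs: np.ndarray, y: int) -> float:
    """Cross-entropy of the bag label, floored away from log(0)."""
    probs = np.asarray(probs, dtype=float)
    if not 0 <= y < probs.shape[0]:
        raise ValueError("label outside class range")
    return float(-np.log(max(probs[y], _PROB_FLOOR)))


def total_loss(l_bag: float, l_supcon: float, lam: float) -> float:
    """Joint objective L = lam * L_bag + (1 - lam) * L_supcon."""
    return lam * l_bag + (1.0 - lam) * l_supcon


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class QAMILModel:
    attn: AttentionParams
    U: np.ndarray            # (C, M)
    b: np.ndarray            # (C,)
    quality_cfg: ScreeningConfig
    cfcm_cfg: CfcmConfig
    mil_cfg: MilConfig
    M_in: int                # raw feature width of cohort inputs
    class_prior: np.ndarray  # training class frequencies (C,)

    @property
    def C(self) -> int:
        return self.U.shape[0]

    def prepare_bag(self, bag: Bag) -> tuple[np.ndarray, np.ndarray,
                                             list[str], bool]:
        """Screen, enhance and quality-weight one bag.

        Returns (model-input features, qualities, patch_ids of the kept MIL
        instances, emptied-by-screening flag). The per-slide normal
        reference is rebuilt from the bag's own normal-labeled instances, so
        inference needs no instance labels (an unlabeled bag simply gets the
        zero reference and enhancement degrades to the identity).
        """
        mil = self.mil_cfg
        if bag.M != self.M_in:
            raise ValueError(f"bag {bag.bag_id!r}: feature width {bag.M} != "
                             f"model input width {self.M_in}")
        kept = bag
        if mil.use_qism:
            kept, _ = screen_bag(bag, self.quality_cfg)
        if mil.include_normals_in_bag:
            sel = np.ones(kept.K, dtype=bool)
        else:
            sel = np.array([lab != NORMAL for lab in kept.cell_labels],
                           dtype=bool)
        X = kept.features[sel]
        S = kept.qualities[sel]
        pids = [p for p, s in zip(kept.patch_ids, sel) if s]
        if X.shape[0] == 0:
            return X, S, pids, True

        if mil.use_cfcm:
            normals = kept.features[
                np.array([lab == NORMAL for lab in kept.cell_labels],
                         dtype=bool)]
            ref = cc.cluster_normals(normals, self.cfcm_cfg.k_clusters,
                                     seed=self.cfcm_cfg.seed,
                                     reference=self.cfcm_cfg.reference)
            X = cc.enhance_instances(X, ref, mode=self.cfcm_cfg.mode)
        if mil.use_qam:
            X = quality_weight(X, S)
        return X, S, pids, False

    def predict(self, bag: Bag) -> BagPrediction:
        """Forward pass on one bag; an emptied bag gets the flagged
        training-prior prediction with an empty attention vector."""
        X, _, pids, empty = self.prepare_bag(bag)
        if empty:
            return BagPrediction(
                bag_id=bag.bag_id, z=np.zeros(self.attn.M),
                attention=np.empty(0), probs=self.class_prior.copy(),
                patch_ids=[], empty_after_screening=True)
        a = attention_weights(X, self.attn)
        z = aggregate(X, a)
        p = classify(z, self.U, self.b)
        return BagPrediction(bag_id=bag.bag_id, z=z, attention=a, probs=p,
                             patch_ids=pids)

    def predict_cohort(self, cohort: Cohort) -> list[BagPrediction]:
        return [self.predict(bag) for bag in cohort.bags]

    def decision_scores(self, cohort: Cohort) -> np.ndarray:
        """P(class 1) per bag — the slide-level abnormality score."""
        return np.array([pred.probs[1] for pred in self.predict_cohort(cohort)])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        import dataclasses as _dc
        return {
            "V": self.attn.V.tolist(), "w": self.attn.w.tolist(),
            "gamma": self.attn.gamma.tolist(), "beta": self.attn.beta.tolist(),
            "U": self.U.tolist(), "b": self.b.tolist(),
            "quality": _dc.asdict(self.quality_cfg),
            "cfcm": _dc.asdict(self.cfcm_cfg),
            "mil": _dc.asdict(self.mil_cfg),
            "M_in": self.M_in,
            "class_prior": self.class_prior.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QAMILModel":
        quality = ScreeningConfig(**{**d["quality"],
                                     "weights": tuple(d["quality"]["weights"])})
        return cls(
            attn=AttentionParams(V=np.array(d["V"]), w=np.array(d["w"]),
                                 gamma=np.array(d["gamma"]),
                                 beta=np.array(d["beta"])),
            U=np.array(d["U"]), b=np.array(d["b"]),
            quality_cfg=quality, cfcm_cfg=CfcmConfig(**d["cfcm"]),
            mil_cfg=MilConfig(**d["mil"]), M_in=int(d["M_in"]),
            class_prior=np.array(d["class_prior"]),
        )

    def save(self, path: str) -> None:
        import json
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str) -> "QAMILModel":
        import json
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _init_model(M: int, C: int, cfg: RunConfig,
                class_prior: np.ndarray) -> QAMILModel:
    mil, L = cfg.mil, cfg.mil.L
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(mil.seed, 0)))
    M_model = 2 * M if (mil.use_cfcm and cfg.cfcm.mode == "concat") else M
    attn = AttentionParams(
        V=rng.normal(scale=np.sqrt(2.0 / M_model), size=(L, M_model)),
        w=rng.normal(scale=1.0 / np.sqrt(L), size=L),
        gamma=np.ones(L), beta=np.zeros(L))
    U = rng.normal(scale=0.01, size=(C, M_model))
    b = np.zeros(C)
    return QAMILModel(attn=attn, U=U, b=b, quality_cfg=cfg.quality,
                      cfcm_cfg=cfg.cfcm, mil_cfg=mil, M_in=M,
                      class_prior=class_prior)


def _batch_loss_and_grads(Xc: np.ndarray, starts: np.ndarray,
                          ys: np.ndarray, model: QAMILModel,
                          ) -> tuple[float, dict[str, np.ndarray]]:
    """Mean bag cross-entropy and parameter gradients over a minibatch.

    The minibatch's bags are concatenated into one (N, M) matrix with
    contiguous segments; segment reductions use ``ufunc.reduceat``.
    """
    V, w = model.attn.V, model.attn.w
    gamma, beta = model.attn.gamma, model.attn.beta
    U, b = model.U, model.b
    B = len(starts)
    sizes = np.diff(np.append(starts, Xc.shape[0]))
    seg = np.repeat(np.arange(B), sizes)

    # forward
    H = Xc @ V.T
    mu = H.mean(axis=1, keepdims=True)
    var = H.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    nrm = (H - mu) * inv
    ln = gamma * nrm + beta
    R = np.maximum(ln, 0.0)
    t = R @ w
    tmax = np.maximum.reduceat(t, starts)
    e = np.exp(t - tmax[seg])
    esum = np.add.reduceat(e, starts)
    a = e / esum[seg]
    Z = np.add.reduceat(a[:, None] * Xc, starts, axis=0)
    logits = Z @ U.T + b
    logits -= logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    P = expl / expl.sum(axis=1, keepdims=True)
    picked = np.maximum(P[np.arange(B), ys], _PROB_FLOOR)
    loss = float(-np.log(picked).mean())

    # backward
    dlogits = P.copy()
    dlogits[np.arange(B), ys] -= 1.0
    dlogits /= B
    dU = dlogits.T @ Z
    db = dlogits.sum(axis=0)
    dZ = dlogits @ U
    dz_rows = dZ[seg]
    da = (Xc * dz_rows).sum(axis=1)
    inner = np.add.reduceat(a * da, starts)
    dt = a * (da - inner[seg])
    dR = dt[:, None] * w[None, :]
    dw = R.T @ dt
    dln = dR * (ln > 0.0)
    dgamma = (dln * nrm).sum(axis=0)
    dbeta = dln.sum(axis=0)
    dnrm = dln * gamma
    dH = inv * (dnrm - dnrm.mean(axis=1, keepdims=True)
                - nrm * (dnrm * nrm).mean(axis=1, keepdims=True))
    dV = dH.T @ Xc
    return loss, {"V": dV, "w": dw, "gamma": dgamma, "beta": dbeta,
                  "U": dU, "b": db}


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _supcon_embeddings(model: QAMILModel, bag: Bag
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm instance embeddings + labels for the contrastive term."""
    cfcm, mil = model.cfcm_cfg, model.mil_cfg
    kept = bag
    if mil.use_qism:
        kept, _ = screen_bag(bag, model.quality_cfg)
    labs = np.array(kept.cell_labels)
    known = labs != UNKNOWN
    X = kept.features[known]
    labs = labs[known]
    if X.shape[0] == 0:
        return np.empty((0, bag.M)), labs
    if cfcm.apply_supcon_to == "enhanced":
        normals = kept.features[np.array(kept.cell_labels) == NORMAL]
        ref = cc.cluster_normals(normals, cfcm.k_clusters, seed=cfcm.seed,
                                 reference=cfcm.reference)
        # concat would double the width; embeddings use the plain difference
        emb_mode = "difference" if cfcm.mode == "concat" else cfcm.mode
        X = cc.enhance_instances(X, ref, mode=emb_mode)
    Z, degenerate = cc.l2_normalize(X)
    return Z[~degenerate], labs[~degenerate]


def _cohort_supcon(model: QAMILModel, cohort: Cohort,
                   rng: np.random.Generator) -> float:
    """Contrastive loss over a capped subsample of labeled instances.

    With no trainable encoder below the embeddings this value is a fixed
    diagnostic of the enhanced embedding space, so it is evaluated once per
    training run and logged every epoch.
    """
    Zs, ys = [], []
    for bag in cohort.bags:
        Z, labs = _supcon_embeddings(model, bag)
        Zs.append(Z)
        ys.append(labs)
    if not Zs:
        return float("nan")
    Z = np.concatenate(Zs)
    y = np.concatenate(ys)
    cap = model.mil_cfg.supcon_batch_cap
    if Z.shape[0] > cap:
        idx = rng.choice(Z.shape[0], size=cap, replace=False)
        Z, y = Z[idx], y[idx]
    if Z.shape[0] < 2:
        return float("nan")
    try:
        batch = cc.ContrastiveBatch(Z, y, temperature=model.cfcm_cfg.tau)
        return float(cc.supcon_loss(batch))
    except cc.NoPositivePairsError:
        return float("nan")


def train(cohort: Cohort, cfg: RunConfig | None = None,
          val_cohort: Cohort | None = None
          ) -> tuple[QAMILModel, pd.DataFrame]:
    """Train the QA-MIL model on a cohort.

    Per bag: (QISM) threshold-screen, build the per-slide normal reference,
    (CFCM) enhance, (QAM) quality-weight, attention-pool, classify; optimize
    the joint loss with Adam over shuffled minibatches of bags, all
    randomness seeded from ``cfg.mil.seed``. With ``use_cfcm`` off the model
    runs on raw features and lambda is forced to 1 (no contrastive term).

    Returns the trained model and a per-epoch history table with columns
    ``epoch, loss, loss_bag, loss_supcon, val_auc``.
    """
    cfg = cfg or RunConfig()
    mil = cfg.mil
    cohort.validate()
    if cohort.C < 2:
        raise ValueError("training requires at least 2 bag classes")

    counts = np.bincount(cohort.labels, minlength=cohort.C).astype(float)
    if cohort.n_bags == 0:
        raise ValueError("empty training cohort")
    prior = counts / counts.sum()
    model = _init_model(cohort.M, cohort.C, cfg, prior)

    prepared: list[tuple[np.ndarray, int]] = []
    kept_labels = []
    for bag in cohort.bags:
        X, _, _, empty = model.prepare_bag(bag)
        if empty:
            continue
        prepared.append((X, bag.label))
        kept_labels.append(bag.label)
    if not prepared:
        raise ValueError("empty training set after screening")
    present = np.bincount(np.array(kept_labels), minlength=cohort.C)
    if np.any(present == 0):
        missing = int(np.argmin(present))
        raise ValueError(f"no bags of class {missing} remain after screening")

    lam = mil.lam if mil.use_cfcm else 1.0
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(mil.seed, 1)))
    l_supcon = (_cohort_supcon(model, cohort, rng) if mil.use_cfcm
                else float("nan"))
    supcon_term = 0.0 if (not mil.use_cfcm or np.isnan(l_supcon)) else l_supcon

    params = {"V": model.attn.V, "w": model.attn.w, "gamma": model.attn.gamma,
              "beta": model.attn.beta, "U": model.U, "b": model.b}
    opt = _Adam(params, lr=mil.lr)

    val_scores_fn = None
    if val_cohort is not None and val_cohort.n_bags > 0:
        from .evaluation_suite import roc_auc  # local import: avoids cycle

        def val_scores_fn() -> float:
            labels = val_cohort.labels
            if len(set(labels.tolist())) < 2:
                return float("nan")
            return roc_auc(labels, model.decision_scores(val_cohort))

    n = len(prepared)
    order = np.arange(n)
    history = []
    for epoch in range(mil.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for s in range(0, n, mil.batch_bags):
            idx = order[s:s + mil.batch_bags]
            Xs = [prepared[i][0] for i in idx]
            ys = np.array([prepared[i][1] for i in idx])
            sizes = np.array([x.shape[0] for x in Xs])
            starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
            Xc = np.concatenate(Xs, axis=0)
            l_bag, grads = _batch_loss_and_grads(Xc, starts, ys, model)
            if not np.isfinite(l_bag):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch start {s}")
            # lambda scales the only gradient-producing term
            opt.step({k: lam * g for k, g in grads.items()})
            epoch_losses.append(l_bag)
        mean_bag = float(np.mean(epoch_losses))
        history.append({
            "epoch": epoch,
            "loss": total_loss(mean_bag, supcon_term, lam),
            "loss_bag": mean_bag,
            "loss_supcon": l_supcon,
            "val_auc": val_scores_fn() if val_scores_fn else float("nan"),
        })
    return model, pd.DataFrame(history)
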