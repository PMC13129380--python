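"""Classification metrics with confidence intervals, rater agreement, and
the experiment designs (ablation grid, prototype-count sweep).

AUC uses the rank (Mann-Whitney) formulation with the half-tie convention;
its confidence interval uses the DeLong structural-components variance
estimator, the standard nonparametric approach for correlated ROC
statistics. Accuracy/sensitivity/specificity intervals use the percentile
bootstrap (1,000 case resamples by default). Fleiss' kappa measures
chance-corrected agreement among >= 2 raters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss

from .config import RunConfig
from .qamil_net import QAMILModel, train
from .synthetic_cohort import SimulationConfig, generate_splits


@dataclass
class MetricsReport:
    """Point estimates with 95% CIs for one method on one test set."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    accuracy_ci: tuple[float, float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    method_tag: str = ""
    auc_ci_degenerate: bool = False

    def validate(self) -> None:
        for point, (lo, hi) in [
                (self.accuracy, self.accuracy_ci),
                (self.sensitivity, self.sensitivity_ci),
                (self.specificity, self.specificity_ci),
                (self.auc, self.auc_ci)]:
            if not math.isnan(point) and not (lo - 1e-12 <= point <= hi + 1e-12):
                raise ValueError("CI does not contain the point estimate")


def confusion_metrics(labels: np.ndarray, predicted: np.ndarray
                      ) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from binary labels/predictions.

    Sensitivity is NaN when there are no positives, specificity NaN when
    there are no negatives.
    """
    labels = np.asarray(labels, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if labels.shape != predicted.shape:
        raise ValueError("labels and predictions length mismatch")
    n = labels.size
    if n == 0:
        raise ValueError("empty input")
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    tn = int(np.sum((labels == 0) & (predicted == 0)))
    n_pos = int(np.sum(labels == 1))
    n_neg = n - n_pos
    accuracy = (tp + tn) / n
    sensitivity = tp / n_pos if n_pos else float("nan")
    specificity = tn / n_neg if n_neg else float("nan")
    return accuracy, sensitivity, specificity


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC by mid-rank Mann-Whitney; ties count 1/2. Needs both classes."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores length mismatch")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    r_pos = float(ranks[labels == 1].sum())
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _delong_components(labels: np.ndarray, scores: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the structural components V10 (per positive), V01 (per negative)."""
    pos = np.asarray(scores, dtype=float)[np.asarray(labels) == 1]
    neg = np.asarray(scores, dtype=float)[np.asarray(labels) == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_ci(labels: np.ndarray, scores: np.ndarray, level: float = 0.95
              ) -> tuple[float, float, float, bool]:
    """DeLong AUC confidence interval.

    Returns (auc, ci_low, ci_high, degenerate). With zero estimated variance
    (e.g. perfect separation) the CI collapses to the point estimate and the
    degeneracy flag is set. The interval is truncated to [0, 1].
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    auc, v10, v01 = _delong_components(labels, scores)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    if var <= 0.0 or m < 2 or n < 2:
        return auc, auc, auc, True
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(var)
    return auc, max(0.0, auc - half), min(1.0, auc + half), False


def delong_paired_test(labels: np.ndarray, scores_a: np.ndarray,
                       scores_b: np.ndarray) -> tuple[float, float, float]:
    """Paired DeLong comparison of two score vectors on the same cases.

    Returns (auc_a - auc_b, z statistic, two-sided p). The covariance uses
    the paired structural components.
    """
    auc_a, v10_a, v01_a = _delong_components(labels, scores_a)
    auc_b, v10_b, v01_b = _delong_components(labels, scores_b)
    m, n = v10_a.size, v01_a.size
    if m < 2 or n < 2:
        raise ValueError("need >= 2 cases per class for the paired test")
    s10 = np.cov(v10_a, v10_b, ddof=1)
    s01 = np.cov(v01_a, v01_b, ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    delta = auc_a - auc_b
    if var <= 0.0:
        return delta, float("inf") if delta else 0.0, 0.0 if delta else 1.0
    z = delta / math.sqrt(var)
    return delta, z, float(2.0 * stats.norm.sf(abs(z)))


def bootstrap_ci(metric_fn, labels: np.ndarray, values: np.ndarray,
                 n_boot: int = 1000, level: float = 0.95, seed: int = 0,
                 max_retries: int = 100) -> tuple[float, float, float]:
    """Percentile bootstrap CI over case resampling.

    ``metric_fn(labels, values) -> float`` may return NaN (or raise
    ValueError) on a degenerate resample, e.g. a single-class draw; such
    resamples are redrawn up to ``max_retries`` times each.
    """
    labels = np.asarray(labels)
    values = np.asarray(values)
    if labels.shape[0] != values.shape[0] or labels.shape[0] == 0:
        raise ValueError("labels and values must be equal-length, nonempty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    point = float(metric_fn(labels, values))
    rng = np.random.default_rng(seed)
    n = labels.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    est = np.empty(n_boot)
    for bidx in range(n_boot):
        rows = idx[bidx]
        for attempt in range(max_retries + 1):
            try:
                val = float(metric_fn(labels[rows], values[rows]))
            except ValueError:
                val = float("nan")
            if not math.isnan(val):
                break
            rows = rng.integers(0, n, size=n)
        est[bidx] = val
    est = est[~np.isnan(est)]
    if est.size == 0:
        raise ValueError("all bootstrap resamples were degenerate")
    alpha = 1.0 - level
    lo, hi = np.percentile(est, [100 * alpha / 2.0, 100 * (1 - alpha / 2.0)])
    return point, float(lo), float(hi)


def fleiss_kappa(ratings: np.ndarray) -> float:
    """Fleiss' kappa from a subjects x categories count table.

    Every subject must be rated by the same number of raters (>= 2).
    When all raters agree on every subject the observed agreement is 1 and
    kappa is 1, including the degenerate case where only one category was
    ever used (the 0/0 limit).
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("ratings must be a (subjects, categories>=2) table")
    row_sums = table.sum(axis=1)
    if np.any(row_sums != row_sums[0]):
        raise ValueError("unequal rater counts across subjects")
    n_raters = row_sums[0]
    if n_raters < 2:
        raise ValueError("need >= 2 raters per subject")
    # observed per-subject agreement; short-circuit the 0/0 case where the
    # marginal expected agreement is also 1 (a single category used)
    p_bar = float(np.mean((np.sum(table * (table - 1), axis=1))
                          / (n_raters * (n_raters - 1))))
    p_cat = table.sum(axis=0) / table.sum()
    p_e = float(np.sum(p_cat ** 2))
    if p_e >= 1.0:
        return 1.0 if p_bar >= 1.0 else float("nan")
    return float(_sm_fleiss(table, method="fleiss"))


# ---------------------------------------------------------------------------
# experiment runners
# ---------------------------------------------------------------------------

def evaluate_model(model: QAMILModel, cohort, n_boot: int = 1000,
                   level: float = 0.95, seed: int = 0,
                   method_tag: str = "") -> MetricsReport:
    """Full metrics report for a trained model on a labeled cohort."""
    labels = cohort.labels
    preds = model.predict_cohort(cohort)
    predicted = np.array([p.predicted_label for p in preds])
    scores = np.array([p.probs[1] for p in preds])

    def _acc(y, p):
        return confusion_metrics(y, p)[0]

    def _sens(y, p):
        return confusion_metrics(y, p)[1]

    def _spec(y, p):
        return confusion_metrics(y, p)[2]

    acc, sens, spec = confusion_metrics(labels, predicted)
    auc, lo, hi, degen = delong_ci(labels, scores, level)
    acc_ci = bootstrap_ci(_acc, labels, predicted, n_boot, level, seed)[1:]
    sens_ci = bootstrap_ci(_sens, labels, predicted, n_boot, level, seed + 1)[1:]
    spec_ci = bootstrap_ci(_spec, labels, predicted, n_boot, level, seed + 2)[1:]
    report = MetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, auc=auc,
        accuracy_ci=acc_ci, sensitivity_ci=sens_ci, specificity_ci=spec_ci,
        auc_ci=(lo, hi), n_pos=int((labels == 1).sum()),
        n_neg=int((labels == 0).sum()), method_tag=method_tag,
        auc_ci_degenerate=degen)
    report.validate()
    return report


def _run_once(sim_cfg: SimulationConfig, run_cfg: RunConfig, seed: int
              ) -> dict[str, float]:
    """Generate a seeded cohort pair, train, and measure on the test split."""
    sim = replace(sim_cfg, seed=seed)
    mil = replace(run_cfg.mil, seed=seed)
    cfg = replace(run_cfg, mil=mil)
    splits = generate_splits(sim, screening=cfg.quality)
    model, _ = train(splits["train"][0], cfg)
    test = splits["test"][0]
    preds = model.predict_cohort(test)
    predicted = np.array([p.predicted_label for p in preds])
    scores = np.array([p.probs[1] for p in preds])
    acc, sens, spec = confusion_metrics(test.labels, predicted)
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "auc": roc_auc(test.labels, scores)}

# The six switch combinations of the component-ablation design:
# baseline, each module alone, screening+comparison, and the full model.
ABLATION_GRID: tuple[tuple[str, bool, bool, bool], ...] = (
    ("baseline", False, False, False),
    ("qism", True, False, False),
    ("cfcm", False, True, False),
    ("qam", False, False, True),
    ("qism+cfcm", True, True, False),
    ("qism+cfcm+qam", True, True, True),
)


def run_ablation(sim_cfg: SimulationConfig, run_cfg: RunConfig,
                 seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Train the six-configuration ablation grid on matched seeded cohorts.

    Returns one row per (seed, configuration) with the four test metrics.
    """
    rows = []
    for seed in seeds:
        for name, qism, cfcm, qam in ABLATION_GRID:
            mil = replace(run_cfg.mil, use_qism=qism, use_cfcm=cfcm,
                          use_qam=qam)
            cfg = replace(run_cfg, mil=mil)
            metrics = _run_once(sim_cfg, cfg, seed)
            rows.append({"seed": seed, "config": name, "use_qism": qism,
                         "use_cfcm": cfcm, "use_qam": qam, **metrics})
    return pd.DataFrame(rows)


def summarize_ablation(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of each metric per ablation configuration."""
    out = table.groupby("config", sort=False)[
        ["accuracy", "sensitivity", "specificity", "auc"]].agg(["mean", "std"])
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    return out.reset_index()


def sweep_k(sim_cfg: SimulationConfig, run_cfg: RunConfig,
            k_values: tuple[int, ...] = (2, 4, 8, 12, 16),
            seeds: tuple[int, ...] = (0, 1, 2, 3, 4)) -> pd.DataFrame:
    """Sweep the normal-prototype count K of the comparison module."""
    if not k_values:
        raise ValueError("k_values must be nonempty")
    rows = []
    for seed in seeds:
        for k in k_values:
            cfcm = replace(run_cfg.cfcm, k_clusters=int(k))
            cfg = replace(run_cfg, cfcm=cfcm)
            metrics = _run_once(sim_cfg, cfg, seed)
            rows.append({"seed": seed, "k_clusters": int(k),
                         "accuracy": metrics["accuracy"],
                         "auc": metrics["auc"]})
    return pd.DataFrame(rows)


def export_attention_report(model: QAMILModel, cohort) -> pd.DataFrame:
    """Per-instance attention table: (bag_id, patch_id, quality,
    attention_weight, cell_label) for every instance kept by the model."""
    quality_by_patch = {}
    label_by_patch = {}
    for bag in cohort.bags:
        for i in range(bag.K):
            quality_by_patch[bag.patch_ids[i]] = float(bag.qualities[i])
            label_by_patch[bag.patch_ids[i]] = bag.cell_labels[i]
    rows = []
    for bag in cohort.bags:
        pred = model.predict(bag)
        for pid, a in zip(pred.patch_ids, pred.attention):
            rows.append({"bag_id": bag.bag_id, "patch_id": pid,
                         "quality": quality_by_patch[pid],
                         "attention_weight": float(a),
                         "cell_label": label_by_patch[pid]})
    return pd.DataFrame(rows, columns=["bag_id", "patch_id", "quality",
                                       "attention_weight", "cell_label"])
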