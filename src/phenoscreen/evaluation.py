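"""Validity assessment of the screening models.

Rule-out screening machinery: ROC analysis, cutoff selection at a 95%
target sensitivity on the derivation sample, leave-one-out and 10-times
twofold cross-validation (with the phenotyping refit inside every training
fold for the augmented model, so no information leaks from test patients
into the cluster structure), and the diagnostic-metric panel — sensitivity,
specificity, predictive values, likelihood ratios, posttest odds and
probabilities (the Fagan-nomogram quantities), and the diagnostic odds
ratio.  Also includes the symptom-count comparator rule from the AASM
clinical algorithm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta, norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .cohort import Cohort

__all__ = [
    "proportion_ci",
    "roc_and_auc",
    "delong_auc_ci",
    "choose_cutoff",
    "DiagnosticMetrics",
    "diagnostic_metrics",
    "dor_from_sens_spec",
    "PosttestResult",
    "posttest",
    "aasm_rule",
    "ValidationReport",
    "cross_validate",
]


# --------------------------------------------------------------------------
# Proportion confidence intervals
# --------------------------------------------------------------------------


def proportion_ci(
    x: int, n: int, alpha: float = 0.05, method: str = "wilson-cc"
) -> tuple[float, float]:
    """95% CI for a binomial proportion.

    ``wilson-cc`` (default) is the Wilson score interval with continuity
    correction (Newcombe), the convention that reproduces this package's
    reference frequency tables; ``clopper-pearson`` is the exact
    beta-quantile interval.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    if method == "clopper-pearson":
        lo = 0.0 if x == 0 else float(beta.ppf(alpha / 2, x, n - x + 1))
        hi = 1.0 if x == n else float(beta.ppf(1 - alpha / 2, x + 1, n - x))
        return lo, hi
    if method == "wilson-cc":
        z = float(norm.ppf(1 - alpha / 2))
        p = x / n
        q = 1 - p
        if x == 0:
            lo = 0.0
        else:
            lo = (
                2 * n * p + z * z - 1 - z * sqrt(z * z - 2 - 1 / n + 4 * p * (n * q + 1))
            ) / (2 * (n + z * z))
        if x == n:
            hi = 1.0
        else:
            hi = (
                2 * n * p + z * z + 1 + z * sqrt(z * z + 2 - 1 / n + 4 * p * (n * q - 1))
            ) / (2 * (n + z * z))
        return max(lo, 0.0), min(hi, 1.0)
    raise ValueError(f"unknown CI method {method!r}")


# --------------------------------------------------------------------------
# ROC / AUC
# --------------------------------------------------------------------------


def roc_and_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC curve (thresholds swept over the unique scores) and trapezoid AUC,
    which equals the normalized Mann-Whitney U statistic with ties counted
    half.  Returns (fpr, tpr, thresholds, auc)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("need at least one positive and one negative")
    fpr, tpr, thr = roc_curve(labels, scores)
    return fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr))


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def delong_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC with its DeLong 95% CI (clipped to [0, 1])."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    aucv = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n  # structural components over positives
    v01 = 1 - (all_r[m:] - neg_r) / m
    s = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    z = float(norm.ppf(1 - alpha / 2))
    half = z * sqrt(max(s, 0.0))
    return float(aucv), (max(aucv - half, 0.0), min(aucv + half, 1.0))


def choose_cutoff(scores, labels, target_sensitivity: float = 0.95) -> int:
    """Rule-out cutoff on the derivation sample: the largest integer-percent
    threshold whose sensitivity (score strictly above threshold = positive)
    still meets the target.  If no threshold meets the target the lowest
    threshold is returned with a warning."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    if pos.size == 0:
        raise ValueError("no positives")
    for c in range(99, -1, -1):
        if (pos > c / 100).mean() >= target_sensitivity:
            return c
    warnings.warn("no cutoff achieves the target sensitivity; returning 0")
    return 0


# --------------------------------------------------------------------------
# Diagnostic metric panel
# --------------------------------------------------------------------------


@dataclass
class DiagnosticMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    dor: float
    cutoff: int | None = None
    auc: float | None = None
    cis: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "tp", "fp", "tn", "fn", "sensitivity", "specificity", "accuracy",
                "ppv", "npv", "lr_pos", "lr_neg", "dor", "cutoff", "auc",
            )
        }
        d["cis"] = {k: list(v) for k, v in self.cis.items()}
        return d


def _log_ratio_ci(value: float, se: float, z: float) -> tuple[float, float]:
    if not np.isfinite(value) or value <= 0 or not np.isfinite(se):
        return (np.nan, np.nan)
    return float(value * np.exp(-z * se)), float(value * np.exp(z * se))


def dor_from_sens_spec(sensitivity: float, specificity: float) -> float:
    """Diagnostic odds ratio implied by a (sensitivity, specificity) pair:
    DOR = LR+ / LR- = [sens/(1-spec)] / [(1-sens)/spec]."""
    lr_pos = sensitivity / (1 - specificity)
    lr_neg = (1 - sensitivity) / specificity
    return lr_pos / lr_neg


def diagnostic_metrics(
    tp: int,
    fp: int,
    tn: int,
    fn: int,
    cutoff: int | None = None,
    auc: float | None = None,
    ci_method: str = "wilson-cc",
) -> DiagnosticMetrics:
    """Full validity panel from a confusion matrix.

    LR and DOR confidence intervals use the log method; the DOR falls back
    to the Haldane +0.5 correction on all four counts when any count is 0
    (in which case the LR identity DOR = LR+/LR- no longer applies exactly).
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("negative counts")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("empty class margin")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + fp + tn + fn)
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    with np.errstate(divide="ignore"):
        lr_pos = sens / (1 - spec) if spec < 1 else np.inf
        lr_neg = (1 - sens) / spec if spec > 0 else np.inf
    if min(tp, fp, tn, fn) == 0:
        a, b, c, d = tp + 0.5, fp + 0.5, tn + 0.5, fn + 0.5
        dor = (a * c) / (b * d)
    else:
        dor = lr_pos / lr_neg
    z = float(norm.ppf(0.975))
    cis = {
        "sensitivity": proportion_ci(tp, tp + fn, method=ci_method),
        "specificity": proportion_ci(tn, tn + fp, method=ci_method),
        "accuracy": proportion_ci(tp + tn, tp + fp + tn + fn, method=ci_method),
    }
    if tp + fp:
        cis["ppv"] = proportion_ci(tp, tp + fp, method=ci_method)
    if tn + fn:
        cis["npv"] = proportion_ci(tn, tn + fn, method=ci_method)
    if min(tp, fp, tn, fn) > 0:
        se_lp = sqrt(1 / tp - 1 / (tp + fn) + 1 / fp - 1 / (fp + tn))
        se_ln = sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        se_dor = sqrt(1 / tp + 1 / fp + 1 / tn + 1 / fn)
        cis["lr_pos"] = _log_ratio_ci(lr_pos, se_lp, z)
        cis["lr_neg"] = _log_ratio_ci(lr_neg, se_ln, z)
        cis["dor"] = _log_ratio_ci(dor, se_dor, z)
    return DiagnosticMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, accuracy=acc, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, dor=dor, cutoff=cutoff, auc=auc, cis=cis,
    )


# --------------------------------------------------------------------------
# Posttest probabilities (Fagan nomogram)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PosttestResult:
    pretest_probability: float
    pretest_odds: float
    posttest_odds: float
    posttest_probability: float


def posttest(pretest_probability: float, lr: float) -> PosttestResult:
    """Carry a pretest probability through a likelihood ratio:
    odds = p/(1-p), posttest odds = odds * LR, back to a probability."""
    if not 0 < pretest_probability < 1:
        raise ValueError("pretest probability must be in (0, 1)")
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    pre_odds = pretest_probability / (1 - pretest_probability)
    post_odds = pre_odds * lr
    return PosttestResult(
        pretest_probability=pretest_probability,
        pretest_odds=pre_odds,
        posttest_odds=post_odds,
        posttest_probability=post_odds / (1 + post_odds),
    )


# --------------------------------------------------------------------------
# AASM step-2 comparator rule
# --------------------------------------------------------------------------


def aasm_rule(record) -> bool:
    """Symptom-count risk rule from the AASM clinical algorithm: excessive
    daytime sleepiness AND at least two of {habitual loud snoring, witnessed
    apnea or gasping/choking, diagnosed hypertension}.  Missing values count
    as absent."""
    values = record.values if hasattr(record, "values") and not isinstance(record, dict) else record

    def yes(var: str) -> bool:
        v = values.get(var)
        return v == "yes"

    if not yes("daytime_sleepiness"):
        return False
    criteria = [
        yes("snoring"),
        yes("witnessed_apneas") or yes("gasping_choking"),
        yes("arterial_hypertension"),
    ]
    return sum(criteria) >= 2


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------

_PANEL = (
    "auc", "sensitivity", "specificity", "accuracy", "ppv", "npv",
    "lr_pos", "lr_neg", "dor",
)


@dataclass
class ValidationReport:
    scheme: str  # "derivation" | "loo" | "10x2cv"
    model_kind: str
    cutoff: int
    seed: int
    estimates: dict[str, float]
    cis: dict[str, tuple[float, float]]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    fold_estimates: pd.DataFrame | None = None
    pooled: DiagnosticMetrics | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "model_kind": self.model_kind,
                "cutoff": self.cutoff,
                "seed": self.seed,
                "estimates": self.estimates,
                "cis": {k: list(v) for k, v in self.cis.items()},
                "roc_fpr": np.asarray(self.roc_fpr).tolist(),
                "roc_tpr": np.asarray(self.roc_tpr).tolist(),
                "fold_estimates": None
                if self.fold_estimates is None
                else self.fold_estimates.to_dict(orient="list"),
                "pooled": None if self.pooled is None else self.pooled.as_dict(),
            },
            indent=2,
        )


def _fit_and_score(
    train: Cohort,
    test: Cohort,
    model_kind: str,
    predictors: Sequence[str],
    cluster_variables: Sequence[str],
    k_fine: int,
    alpha: float,
    ward_variant: str,
    normalize: bool,
    phenotype_as_evidence: bool = False,
) -> np.ndarray:
    """Fit one fold's model on ``train`` and return OSA posteriors on ``test``.

    For the augmented model the phenotyping (weights, dendrogram,
    aggregation) is refit on the training OSA patients; training patients
    get their cluster phenotype (OSA) or affinity assignment (healthy).  At
    prediction time the phenotype node is marginalized out by default (model
    B then acts as a phenotype-stratified mixture over the predictors);
    ``phenotype_as_evidence=True`` instead enters each test patient's
    affinity-assigned phenotype as evidence.
    """
    from .bayes_classifier import fit_model_a, fit_model_b, posterior_osa
    from .phenotyping import assign_phenotypes, fit_phenotypes

    if model_kind == "A":
        model = fit_model_a(train, predictors, alpha=alpha)
        phen_test = [None] * test.n
    elif model_kind == "B":
        cm = fit_phenotypes(
            train, cluster_variables, k_fine=k_fine,
            ward_variant=ward_variant, normalize=normalize,
        )
        train_phen = np.empty(train.n, dtype=object)
        osa_mask = train.data["osa"].astype(int).to_numpy() == 1
        train_phen[osa_mask] = cm.phenotypes
        if (~osa_mask).any():
            train_phen[~osa_mask] = assign_phenotypes(train.subset(~osa_mask), cm)
        model = fit_model_b(train, predictors, train_phen, alpha=alpha)
        if phenotype_as_evidence:
            phen_test = assign_phenotypes(test, cm)
        else:
            phen_test = [None] * test.n
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    scores = np.empty(test.n)
    for i in range(test.n):
        row = test.data.iloc[i]
        evidence = {
            v: row[v] for v in predictors if v in test.data.columns and pd.notna(row[v])
        }
        scores[i] = posterior_osa(model, evidence, phenotype_evidence=phen_test[i])
    return scores


def _panel_from_scores(scores, labels, cutoff: int) -> dict[str, float]:
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(scores) > cutoff / 100
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    m = diagnostic_metrics(tp, fp, tn, fn, cutoff=cutoff)
    *_, aucv = roc_and_auc(scores, labels)
    return {
        "auc": aucv,
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "accuracy": m.accuracy,
        "ppv": m.ppv,
        "npv": m.npv,
        "lr_pos": m.lr_pos,
        "lr_neg": m.lr_neg,
        "dor": m.dor,
    }


def _stratified_halves(labels: np.ndarray, rng: np.random.Generator):
    idx_a, idx_b = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        idx_a.extend(idx[:half])
        idx_b.extend(idx[half:])
    return np.sort(np.asarray(idx_a)), np.sort(np.asarray(idx_b))


def cross_validate(
    cohort: Cohort,
    model_kind: str,
    scheme: str = "10x2cv",
    seed: int = 0,
    predictors: Sequence[str] | None = None,
    cluster_variables: Sequence[str] | None = None,
    k_fine: int = 10,
    target_sensitivity: float = 0.95,
    alpha: float = 1.0,
    ward_variant: str = "ward.D",
    normalize: bool = False,
    phenotype_as_evidence: bool = False,
    n_repetitions: int = 10,
) -> ValidationReport:
    """Internal validation of model A or B.

    The cutoff is chosen once on the derivation-sample ROC (largest integer
    percent with sensitivity >= target).  ``scheme="loo"`` pools the n
    held-out posteriors into one ROC and metric panel with count-based CIs;
    ``scheme="10x2cv"`` runs seeded repetitions of stratified half/half
    splits, reports the mean of the per-fold (2 per repetition) panels, and
    normal-approximation CIs across folds.
    """
    if cluster_variables is None:
        cluster_variables = [
            v for v in cohort.variables if not cohort.schema[v].exclusion_flag
        ]
    if predictors is None:
        predictors = list(cluster_variables)
    labels = cohort.data["osa"].to_numpy().astype(int)
    if labels.min() == labels.max():
        raise ValueError("cohort has a single outcome class")

    # derivation-sample model and rule-out cutoff
    derivation_scores = _fit_and_score(
        cohort, cohort, model_kind, predictors, cluster_variables,
        k_fine, alpha, ward_variant, normalize, phenotype_as_evidence,
    )
    cutoff = choose_cutoff(derivation_scores, labels, target_sensitivity)

    if scheme == "derivation":
        scores, score_labels = derivation_scores, labels
    elif scheme == "loo":
        scores = np.empty(cohort.n)
        for i in range(cohort.n):
            mask = np.ones(cohort.n, dtype=bool)
            mask[i] = False
            scores[i] = _fit_and_score(
                cohort.subset(mask), cohort.subset(~mask), model_kind,
                predictors, cluster_variables, k_fine, alpha, ward_variant,
                normalize, phenotype_as_evidence,
            )[0]
        score_labels = labels
    elif scheme == "10x2cv":
        rng = np.random.default_rng(seed)
        folds: list[dict[str, float]] = []
        for _rep in range(n_repetitions):
            half_a, half_b = _stratified_halves(labels, rng)
            for tr_idx, te_idx in ((half_a, half_b), (half_b, half_a)):
                tr_mask = np.zeros(cohort.n, dtype=bool)
                tr_mask[tr_idx] = True
                if labels[tr_idx].min() == labels[tr_idx].max():
                    warnings.warn("single-class training fold skipped")
                    continue
                s = _fit_and_score(
                    cohort.subset(tr_mask), cohort.subset(~tr_mask), model_kind,
                    predictors, cluster_variables, k_fine, alpha,
                    ward_variant, normalize, phenotype_as_evidence,
                )
                folds.append(_panel_from_scores(s, labels[te_idx], cutoff))
        fold_df = pd.DataFrame(folds)
        z = float(norm.ppf(0.975))
        estimates, cis = {}, {}
        for metric in _PANEL:
            vals = fold_df[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            estimates[metric] = float(vals.mean())
            se = float(vals.std(ddof=1) / sqrt(len(vals))) if len(vals) > 1 else 0.0
            cis[metric] = (estimates[metric] - z * se, estimates[metric] + z * se)
        fpr, tpr, _, _ = roc_and_auc(derivation_scores, labels)
        return ValidationReport(
            scheme=scheme, model_kind=model_kind, cutoff=cutoff, seed=seed,
            estimates=estimates, cis=cis, roc_fpr=fpr, roc_tpr=tpr,
            fold_estimates=fold_df,
        )
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    # pooled evaluation (derivation or loo)
    fpr, tpr, _, aucv = roc_and_auc(scores, score_labels)
    aucv, auc_ci = delong_auc_ci(scores, score_labels)
    pred = scores > cutoff / 100
    tp = int((pred & (score_labels == 1)).sum())
    fp = int((pred & (score_labels == 0)).sum())
    tn = int((~pred & (score_labels == 0)).sum())
    fn = int((~pred & (score_labels == 1)).sum())
    pooled = diagnostic_metrics(tp, fp, tn, fn, cutoff=cutoff, auc=aucv)
    estimates = {m: getattr(pooled, m) for m in _PANEL if m != "auc"}
    estimates["auc"] = aucv
    cis = dict(pooled.cis)
    cis["auc"] = auc_ci
    return ValidationReport(
        scheme=scheme, model_kind=model_kind, cutoff=cutoff, seed=seed,
        estimates=estimates, cis=cis, roc_fpr=fpr, roc_tpr=tpr, pooled=pooled,
    )
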