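"""Discrete Bayesian network classifiers for OSA screening.

Model A is a naive Bayes classifier: the binary OSA outcome is the sole
parent of every categorical predictor.  Model B augments it with a 3-state
severity-phenotype node added as a parent of *all* predictors, so each
predictor's conditional probability table is indexed by the 6 (outcome,
phenotype) parent configurations; the phenotype node captures the
interactions among predictors that the naive model ignores.  Conditional
probability tables are estimated by Laplace-smoothed counts, and inference
is exact enumeration over the outcome and (when unobserved) the phenotype —
predictors are leaves, so absent evidence marginalizes out for free.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PHENOTYPES, Cohort

__all__ = ["BayesModel", "fit_model_a", "fit_model_b", "posterior_osa"]


@dataclass
class BayesModel:
    """Discrete network with structure A (naive) or B (phenotype-augmented).

    ``cpts[var]`` has shape ``(n_categories, 2)`` for structure A and
    ``(n_categories, 2, 3)`` for structure B, with axes (category, osa
    status[, phenotype]); every column over categories sums to 1.
    ``p_phenotype`` is the phenotype node's CPT: by default the phenotype is
    a root with a free marginal (shape ``(3,)``); with the optional
    outcome -> phenotype arc it is ``(3, 2)`` columns P(phenotype | OSA).
    """

    structure: str  # "A" | "B"
    predictors: tuple[str, ...]
    categories: dict[str, tuple[str, ...]]
    p_osa: np.ndarray  # shape (2,): P(OSA=0), P(OSA=1)
    cpts: dict[str, np.ndarray]
    alpha: float = 1.0
    p_phenotype: np.ndarray | None = None
    phenotype_arc: bool = False  # True: phenotype CPT is P(phenotype | OSA)

    def __post_init__(self) -> None:
        if self.structure not in ("A", "B"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if abs(self.p_osa.sum() - 1.0) > 1e-9:
            raise ValueError("P(OSA) must sum to 1")
        for var in self.predictors:
            cpt = self.cpts[var]
            want = (len(self.categories[var]), 2) + ((3,) if self.structure == "B" else ())
            if cpt.shape != want:
                raise ValueError(f"{var}: CPT shape {cpt.shape}, expected {want}")
            if np.abs(cpt.sum(axis=0) - 1.0).max() > 1e-9:
                raise ValueError(f"{var}: CPT columns must sum to 1")
            if self.alpha > 0 and (cpt <= 0).any():
                raise ValueError(f"{var}: zero probability despite smoothing")
        if self.structure == "B":
            p = self.p_phenotype
            want = (3, 2) if self.phenotype_arc else (3,)
            if p is None or p.shape != want:
                raise ValueError(f"phenotype CPT must have shape {want}")
            if np.abs(p.sum(axis=0) - 1.0).max() > 1e-9:
                raise ValueError("phenotype CPT columns must sum to 1")

    def to_json(self) -> str:
        return json.dumps(
            {
                "structure": self.structure,
                "predictors": list(self.predictors),
                "categories": {k: list(v) for k, v in self.categories.items()},
                "p_osa": self.p_osa.tolist(),
                "cpts": {k: v.tolist() for k, v in self.cpts.items()},
                "alpha": self.alpha,
                "p_phenotype": None
                if self.p_phenotype is None
                else self.p_phenotype.tolist(),
                "phenotype_arc": self.phenotype_arc,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BayesModel":
        d = json.loads(text)
        return cls(
            structure=d["structure"],
            predictors=tuple(d["predictors"]),
            categories={k: tuple(v) for k, v in d["categories"].items()},
            p_osa=np.asarray(d["p_osa"]),
            cpts={k: np.asarray(v) for k, v in d["cpts"].items()},
            alpha=d["alpha"],
            p_phenotype=None
            if d["p_phenotype"] is None
            else np.asarray(d["p_phenotype"]),
            phenotype_arc=d["phenotype_arc"],
        )

    def to_dot(self) -> str:
        lines = ["digraph {", '  OSA [shape=doublecircle];']
        if self.structure == "B":
            lines.append("  phenotype;")
        for var in self.predictors:
            lines.append(f'  OSA -> "{var}";')
            if self.structure == "B":
                lines.append(f'  phenotype -> "{var}";')
        if self.structure == "B" and self.phenotype_arc:
            lines.append("  OSA -> phenotype;")
        lines.append("}")
        return "\n".join(lines)


def _check_predictors(cohort: Cohort, predictors: Sequence[str]) -> tuple[str, ...]:
    missing = [p for p in predictors if p not in cohort.data.columns]
    if missing:
        raise ValueError(f"predictors absent from cohort: {missing}")
    return tuple(predictors)


def fit_model_a(
    cohort: Cohort, predictors: Sequence[str], alpha: float = 1.0
) -> BayesModel:
    """Naive Bayes: P(OSA) from outcome frequency (unsmoothed), and
    P(x_j = v | OSA = s) = (count + alpha) / (total + alpha * n_categories)."""
    predictors = _check_predictors(cohort, predictors)
    y = cohort.data["osa"].to_numpy().astype(int)
    p_osa = np.array([(y == 0).mean(), (y == 1).mean()])
    cpts = {}
    for var in predictors:
        cats = cohort.schema[var].categories
        cpt = np.empty((len(cats), 2))
        for s in (0, 1):
            col = cohort.data.loc[y == s, var]
            counts = np.array([(col == c).sum() for c in cats], dtype=float)
            cpt[:, s] = (counts + alpha) / (counts.sum() + alpha * len(cats))
        cpts[var] = cpt
    return BayesModel(
        structure="A",
        predictors=predictors,
        categories={v: cohort.schema[v].categories for v in predictors},
        p_osa=p_osa,
        cpts=cpts,
        alpha=alpha,
    )


def fit_model_b(
    cohort: Cohort,
    predictors: Sequence[str],
    phenotypes: Sequence[str],
    alpha: float = 1.0,
    phenotype_arc: bool = False,
) -> BayesModel:
    """Phenotype-augmented classifier: every predictor has parents
    {OSA, phenotype}; each of the 6 parent configurations gets its own
    Laplace-smoothed category distribution.

    The phenotype node is by default a root whose marginal is the frequency
    of assigned phenotypes over all patients (it influences the outcome only
    through the predictors); ``phenotype_arc=True`` instead fits
    P(phenotype | OSA) with an explicit outcome -> phenotype arc.
    """
    predictors = _check_predictors(cohort, predictors)
    phen = np.asarray(phenotypes, dtype=object)
    if len(phen) != cohort.n:
        raise ValueError("need one assigned phenotype per patient")
    unknown = set(phen) - set(PHENOTYPES)
    if unknown:
        raise ValueError(f"unknown phenotype states {unknown}")
    y = cohort.data["osa"].to_numpy().astype(int)
    p_osa = np.array([(y == 0).mean(), (y == 1).mean()])

    phen_idx = np.array([PHENOTYPES.index(p) for p in phen])
    if phenotype_arc:
        p_phen = np.empty((3, 2))
        for s in (0, 1):
            counts = np.bincount(phen_idx[y == s], minlength=3).astype(float)
            p_phen[:, s] = (counts + alpha) / (counts.sum() + 3 * alpha)
    else:
        counts = np.bincount(phen_idx, minlength=3).astype(float)
        p_phen = (counts + alpha) / (counts.sum() + 3 * alpha)

    cpts = {}
    for var in predictors:
        cats = cohort.schema[var].categories
        cpt = np.empty((len(cats), 2, 3))
        for s in (0, 1):
            for k in range(3):
                rows = (y == s) & (phen_idx == k)
                if not rows.any():
                    warnings.warn(
                        f"{var}: no rows for (osa={s}, phenotype={PHENOTYPES[k]}); "
                        "column is uniform from smoothing"
                    )
                col = cohort.data.loc[rows, var]
                counts = np.array([(col == c).sum() for c in cats], dtype=float)
                cpt[:, s, k] = (counts + alpha) / (counts.sum() + alpha * len(cats))
        cpts[var] = cpt
    return BayesModel(
        structure="B",
        predictors=predictors,
        categories={v: cohort.schema[v].categories for v in predictors},
        p_osa=p_osa,
        cpts=cpts,
        alpha=alpha,
        p_phenotype=p_phen,
        phenotype_arc=phenotype_arc,
    )


def posterior_osa(
    model: BayesModel,
    evidence: Mapping[str, str],
    phenotype_evidence: str | None = None,
) -> float:
    """P(OSA = 1 | evidence), by exact enumeration.

    Evidence is a partial map from predictor names to categories; absent
    predictors marginalize out exactly because every predictor is a leaf.
    For structure B the phenotype may be entered as evidence (the usual mode:
    the assigned phenotype of the tested individual) or left unobserved, in
    which case it is summed out.
    """
    for var, val in evidence.items():
        if var not in model.categories:
            raise ValueError(f"unknown predictor {var!r}")
        if val not in model.categories[var]:
            raise ValueError(f"{var}: invalid category {val!r}")
    if model.structure == "A":
        if phenotype_evidence is not None:
            raise ValueError("model A has no phenotype node")
        log_joint = np.log(model.p_osa.copy())
        for var, val in evidence.items():
            ci = model.categories[var].index(val)
            log_joint += np.log(model.cpts[var][ci, :])
        joint = np.exp(log_joint - log_joint.max())
        return float(joint[1] / joint.sum())

    # structure B: enumerate (osa, phenotype)
    if model.phenotype_arc:
        log_pp = np.log(model.p_phenotype)  # (3, 2): phenotype x osa
    else:
        log_pp = np.log(model.p_phenotype)[:, None] * np.ones((3, 2))
    if phenotype_evidence is not None:
        if phenotype_evidence not in PHENOTYPES:
            raise ValueError(f"invalid phenotype state {phenotype_evidence!r}")
        keep = PHENOTYPES.index(phenotype_evidence)
    else:
        keep = None
    log_joint = np.log(model.p_osa)[None, :] + log_pp  # (phenotype, osa)
    for var, val in evidence.items():
        ci = model.categories[var].index(val)
        log_joint += np.log(model.cpts[var][ci, :, :]).T  # (phenotype, osa)
    if keep is not None:
        log_joint = log_joint[keep : keep + 1, :]
    m = log_joint.max()
    joint = np.exp(log_joint - m).sum(axis=0)  # sum over phenotype
    return float(joint[1] / joint.sum())
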