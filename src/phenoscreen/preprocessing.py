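"""Discretization, variable screening, and stepwise k-NN imputation.

The analysis consumes purely categorical data: raw clinical measurements are
banded with standard cutoffs (age, BMI, gender-specific neck and abdominal
circumference, Epworth Sleepiness Scale, AHI).  Variables with more than 80%
missing entries are removed; the remainder are screened for univariate
association with the outcome at the 20% significance level (chi-square, or an
exact test when expected counts are small) and missing entries are imputed by
majority vote among the 10 nearest neighbours in a stepwise schedule that
starts from complete, outcome-associated variables.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import exp
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency, random_table

from .cohort import Cohort, VariableSchema, severity_of_ahi

__all__ = [
    "classify_ahi",
    "discretize",
    "drop_high_missing",
    "ScreeningResult",
    "univariate_screen",
    "fisher_exact_rxc",
    "impute_stepwise_knn",
    "select_cluster_variables",
]


def classify_ahi(ahi: float) -> str:
    """Severity band of an AHI: 0-4 normal, 5-14 mild, 15-29 moderate, >=30 severe."""
    return severity_of_ahi(ahi)


# --------------------------------------------------------------------------
# Discretization of raw measurements
# --------------------------------------------------------------------------

# "increased" circumference means strictly above the normal bound (cm)
_NECK_NORMAL_MAX = {"female": 37.0, "male": 41.0}
_ABDOMINAL_NORMAL_MAX = {"female": 80.0, "male": 94.0}


def discretize(raw: Mapping[str, float], gender: str | None = None) -> dict[str, str]:
    """Band raw clinical measurements into the categorical scheme.

    Supported keys: ``age`` (years; 20-44 / 45-64 / 65-90), ``bmi`` (kg/m2;
    normal <25 / overweight 25-30 / obese >=30), ``neck`` and ``abdominal``
    circumference (cm; gender-specific normal/increased cutoffs), ``ess``
    (Epworth score 0-24; 0-10 normal, 11-24 excessive).  Circumferences are
    left out of the result when gender is unknown.
    """
    out: dict[str, str] = {}
    for key, value in raw.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            continue
        if key == "age":
            if not 18 <= value <= 120:
                raise ValueError(f"implausible age {value}")
            out[key] = "20-44" if value <= 44 else ("45-64" if value <= 64 else "65-90")
        elif key == "bmi":
            if not 10 <= value <= 80:
                raise ValueError(f"implausible BMI {value}")
            out[key] = "normal" if value < 25 else ("overweight" if value < 30 else "obese")
        elif key in ("neck", "abdominal"):
            if gender is None:
                continue  # cannot apply gender-specific cutoff
            if gender not in ("female", "male"):
                raise ValueError(f"unknown gender {gender!r}")
            bound = (_NECK_NORMAL_MAX if key == "neck" else _ABDOMINAL_NORMAL_MAX)[gender]
            out[key] = "increased" if value > bound else "normal"
        elif key == "ess":
            if not 0 <= value <= 24:
                raise ValueError(f"Epworth score {value} outside 0-24")
            out[key] = "normal" if value <= 10 else "excessive"
        else:
            raise KeyError(f"no discretization rule for {key!r}")
    return out


# --------------------------------------------------------------------------
# High-missingness removal
# --------------------------------------------------------------------------


def drop_high_missing(
    cohort: Cohort, threshold: float = 0.80
) -> tuple[Cohort, list[str]]:
    """Remove variables whose missing proportion is strictly above ``threshold``."""
    frac = cohort.missing_fraction()
    dropped = [v for v in cohort.variables if frac[v] > threshold]
    return cohort.drop_variables(dropped), dropped


# --------------------------------------------------------------------------
# Univariate screening: chi-square / Fisher exact
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableScreen:
    variable: str
    test: str  # "chi-square" | "fisher" | "untestable"
    p_value: float
    significant: bool


@dataclass
class ScreeningResult:
    alpha: float
    contrast: str
    results: dict[str, VariableScreen]

    def significant_variables(self) -> list[str]:
        return [v for v, r in self.results.items() if r.significant]

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "contrast": self.contrast,
                "results": [
                    {
                        "variable": r.variable,
                        "test": r.test,
                        "p_value": r.p_value,
                        "significant": r.significant,
                    }
                    for r in self.results.values()
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScreeningResult":
        d = json.loads(text)
        return cls(
            alpha=d["alpha"],
            contrast=d["contrast"],
            results={
                r["variable"]: VariableScreen(
                    r["variable"], r["test"], r["p_value"], r["significant"]
                )
                for r in d["results"]
            },
        )


def _log_table_prob(table: np.ndarray, lgn: np.ndarray) -> float:
    """Log probability of an r x c table under fixed margins (hypergeometric)."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    return float(lgn[rows].sum() + lgn[cols].sum() - lgn[n] - lgn[table].sum())


def fisher_exact_rxc(
    table,
    max_tables: int = 200_000,
    mc_samples: int = 20_000,
    mc_seed: int = 20210622,
) -> float:
    """Two-sided Fisher exact test for an r x c contingency table.

    Sums, over all tables with the observed margins, the probabilities of
    tables no more probable than the observed one (the Freeman-Halton
    extension of Fisher's test; for 2x2 it coincides with the classic
    two-sided test).  When the enumeration would be too large, the p-value is
    estimated by seeded Monte Carlo over margin-preserving random tables.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("negative cell count")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    lgn = gammaln(np.arange(n + 2) + 1.0)  # lgn[k] = log k!
    logp_obs = _log_table_prob(table, lgn)
    tol = 1e-7

    # enumeration size bound: free cells are all but the last row and column
    bound = 1.0
    for ri in rows[:-1]:
        for cj in cols[:-1]:
            bound *= min(ri, cj) + 1
            if bound > max_tables:
                break
        if bound > max_tables:
            break

    if bound <= max_tables:
        r, c = table.shape
        total = 0.0
        cell_lg_rowsum = np.zeros(r)  # accumulated log-factorials per filled row

        def recurse(i: int, j: int, row_rem: np.ndarray, col_rem: np.ndarray, lg_acc: float):
            nonlocal total
            if i == r - 1:
                # last row forced by column remainders
                if (col_rem < 0).any():
                    return
                logp = (
                    lgn[rows].sum()
                    + lgn[cols].sum()
                    - lgn[n]
                    - lg_acc
                    - lgn[col_rem].sum()
                )
                if logp <= logp_obs + tol:
                    total += exp(logp)
                return
            if j == c - 1:
                x = row_rem[i]
                if x < 0 or x > col_rem[j]:
                    return
                col_rem = col_rem.copy()
                col_rem[j] -= x
                recurse(i + 1, 0, row_rem, col_rem, lg_acc + lgn[x])
                return
            hi = min(row_rem[i], col_rem[j])
            for x in range(hi + 1):
                rr = row_rem.copy()
                cc = col_rem.copy()
                rr[i] -= x
                cc[j] -= x
                recurse(i, j + 1, rr, cc, lg_acc + lgn[x])

        recurse(0, 0, rows.copy(), cols.copy(), 0.0)
        return min(total, 1.0)

    # Monte Carlo fallback (Patefield sampling of margin-fixed tables)
    dist = random_table(rows, cols)
    samples = dist.rvs(mc_samples, random_state=np.random.default_rng(mc_seed))
    logps = (
        lgn[rows].sum()
        + lgn[cols].sum()
        - lgn[n]
        - lgn[samples.astype(int)].sum(axis=(1, 2))
    )
    hits = int((logps <= logp_obs + tol).sum())
    return (1 + hits) / (1 + mc_samples)


def _contingency(cohort: Cohort, variable: str, contrast: str) -> np.ndarray:
    """Categories x outcome-levels table on non-missing rows."""
    if contrast == "severity":
        sub = cohort.data[cohort.data["osa"].astype(int) == 1]
        levels = ["mild", "moderate", "severe"]
        outcome = sub["severity"]
    elif contrast == "osa":
        sub = cohort.data
        levels = [0, 1]
        outcome = sub["osa"].astype(int)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    observed = sub[variable].notna()
    tab = pd.crosstab(sub.loc[observed, variable], outcome[observed])
    tab = tab.reindex(columns=levels, fill_value=0)
    return tab.to_numpy()


def univariate_screen(
    cohort: Cohort, alpha: float = 0.20, contrast: str = "severity"
) -> ScreeningResult:
    """Screen every predictor for association with the outcome.

    ``contrast="severity"`` tests the 3-level severity distribution among OSA
    patients (the published convention); ``contrast="osa"`` tests the binary
    OSA status across the whole cohort.  Chi-square without continuity
    correction is used unless any expected cell count is below 5, in which
    case the Fisher exact test is applied.  Variables with a single observed
    category are flagged untestable and non-significant.
    """
    results: dict[str, VariableScreen] = {}
    for var in cohort.variables:
        tab = _contingency(cohort, var, contrast)
        tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            results[var] = VariableScreen(var, "untestable", 1.0, False)
            continue
        expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        if (expected < 5).any():
            p = fisher_exact_rxc(tab)
            test = "fisher"
        else:
            p = float(chi2_contingency(tab, correction=False).pvalue)
            test = "chi-square"
        results[var] = VariableScreen(var, test, p, bool(p < alpha))
    return ScreeningResult(alpha=alpha, contrast=contrast, results=results)


def select_cluster_variables(
    screen_original: ScreeningResult,
    screen_imputed: ScreeningResult,
    schema: Mapping[str, VariableSchema],
) -> list[str]:
    """Variables significant in BOTH screens, minus exclusion-flagged ones."""
    both = set(screen_original.significant_variables()) & set(
        screen_imputed.significant_variables()
    )
    return [v for v in schema if v in both and not schema[v].exclusion_flag]


# --------------------------------------------------------------------------
# Stepwise k-NN majority-vote imputation
# --------------------------------------------------------------------------


def _encode(cohort: Cohort, variables: Sequence[str]) -> np.ndarray:
    """Integer-code the predictor block; -1 marks missing."""
    n = cohort.n
    X = np.full((n, len(variables)), -1, dtype=int)
    for j, var in enumerate(variables):
        cats = list(cohort.schema[var].categories)
        col = cohort.data[var]
        obs = col.notna().to_numpy()
        X[obs, j] = pd.Categorical(col[obs], categories=cats).codes
    return X


def _impute_one_variable(
    X: np.ndarray,
    target_col: int,
    dist_cols: Sequence[int],
    k: int,
    global_counts: np.ndarray,
    variable: str,
) -> None:
    """Fill missing entries of one column in place by k-NN majority vote.

    Neighbour distance is the simple matching proportion over the shared
    observed entries of ``dist_cols``; rows with no shared observed variable
    are pushed to the maximal distance.  Vote ties go to the globally more
    frequent category, then the lexicographically-first (lowest code).
    """
    dist_cols = [c for c in dist_cols if c != target_col]
    missing_rows = np.flatnonzero(X[:, target_col] < 0)
    donor_rows = np.flatnonzero(X[:, target_col] >= 0)
    if missing_rows.size == 0:
        return
    if donor_rows.size == 0:
        warnings.warn(f"{variable}: no observed values to impute from; filling mode")
        X[missing_rows, target_col] = int(np.argmax(global_counts))
        return
    if donor_rows.size < k:
        warnings.warn(
            f"{variable}: only {donor_rows.size} donors available for k={k}"
        )
    D = np.asarray(dist_cols, dtype=int)
    donors = X[np.ix_(donor_rows, D)]
    donor_obs = donors >= 0
    for i in missing_rows:
        row = X[i, D]
        shared = (row >= 0) & donor_obs
        mismatch = (donors != row) & shared
        nshared = shared.sum(axis=1)
        with np.errstate(invalid="ignore"):
            dist = np.where(nshared > 0, mismatch.sum(axis=1) / np.maximum(nshared, 1), 1.0)
        order = np.lexsort((donor_rows, dist))
        nn = donor_rows[order[: min(k, donor_rows.size)]]
        votes = np.bincount(X[nn, target_col], minlength=global_counts.size)
        tied = np.flatnonzero(votes == votes.max())
        if tied.size > 1:  # break toward the globally more frequent category,
            g = global_counts[tied]  # then the first in category order
            tied = tied[g == g.max()]
        X[i, target_col] = int(tied[0])


def impute_stepwise_knn(
    cohort: Cohort, screening: ScreeningResult, k: int = 10
) -> Cohort:
    """Stepwise k-nearest-neighbour majority-vote imputation.

    Schedule (high-missingness variables are assumed already dropped):
    incomplete variables are ranked ascending by missing proportion; the
    first pass imputes incomplete *outcome-associated* variables using
    distances over the complete, outcome-associated variables (each imputed
    variable immediately joins the distance set); the second pass imputes the
    remaining incomplete variables one at a time in rank order, each using
    all currently complete or imputed variables.  Observed cells are never
    altered; imputed cells are flagged in ``imputed_mask``.
    """
    out = cohort.copy()
    variables = out.variables
    col_of = {v: j for j, v in enumerate(variables)}
    X = _encode(out, variables)
    was_missing = X < 0

    frac = out.missing_fraction()
    incomplete = [v for v in variables if frac[v] > 0]
    incomplete.sort(key=lambda v: (frac[v], variables.index(v)))
    complete = [v for v in variables if frac[v] == 0]
    sig = set(screening.significant_variables())

    global_counts = {
        v: np.bincount(
            X[X[:, col_of[v]] >= 0, col_of[v]],
            minlength=len(out.schema[v].categories),
        )
        for v in variables
    }

    # pass-1 distance set: complete outcome-associated variables; when the
    # cohort has none (every variable is incomplete), distances fall back to
    # the observed entries of all outcome-associated variables, then to all
    # complete variables, then to everything.
    dist_set = [v for v in complete if v in sig]
    if not dist_set:
        dist_set = [v for v in variables if v in sig] or list(complete) or list(variables)
        warnings.warn(
            "no complete outcome-associated variables; distances use observed "
            f"entries of {len(dist_set)} fallback variables"
        )

    for v in [v for v in incomplete if v in sig]:
        _impute_one_variable(
            X, col_of[v], [col_of[u] for u in dist_set], k, global_counts[v], v
        )
        if v not in dist_set:
            dist_set.append(v)

    dist_set = complete + [v for v in incomplete if v in sig]
    for v in [v for v in incomplete if v not in sig]:
        _impute_one_variable(
            X, col_of[v], [col_of[u] for u in dist_set], k, global_counts[v], v
        )
        dist_set.append(v)

    for v in variables:
        cats = np.asarray(out.schema[v].categories, dtype=object)
        out.data[v] = cats[X[:, col_of[v]]]
    out.imputed_mask = pd.DataFrame(was_missing, columns=variables)
    return out
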