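"""Severity phenotyping: OR-weighted distance, Ward clustering, aggregation.

Among OSA patients, each selected categorical variable is weighted by its
crude odds ratio for the *severe* outcome level; the dissimilarity between
two patients is the weighted mismatch (Hamming) sum over the selected
variables.  Hierarchical clustering with Ward linkage (the classic
Lance-Williams recursion applied to the raw dissimilarities, the ``ward.D``
convention; ``ward.D2`` available) yields a dendrogram that is cut into 10
fine clusters; the fine clusters are aggregated into 3 severity phenotypes —
by default following the dendrogram's own 3-cluster cut, with a 1-D k-means
grouping of the fine-cluster median AHIs as the alternative — and labelled
low / medium / high by ascending pooled median AHI.  Any patient — healthy
ones included — is then assigned to the phenotype with minimal mean distance
to its members.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from .cohort import PHENOTYPES, Cohort, PatientRecord
from .evaluation import proportion_ci

__all__ = [
    "WeightVector",
    "ClusterModel",
    "crude_or_severe",
    "compute_weights",
    "patient_distance",
    "distance_matrix",
    "ward_dendrogram",
    "aggregate_medians",
    "cut_and_aggregate",
    "fit_phenotypes",
    "assign_phenotype",
    "assign_phenotypes",
    "describe_clusters",
]


# --------------------------------------------------------------------------
# Crude odds-ratio weights
# --------------------------------------------------------------------------


def crude_or_severe(cohort: Cohort, variable: str) -> float:
    """Crude odds ratio of a variable for the severe OSA level.

    Computed on OSA patients from the 2x2 cross-product of (positive category
    vs rest) x (severe vs non-severe), with the Haldane-Anscombe +0.5
    correction applied to all cells when any cell is zero.  Multi-category
    variables are binarized at their schema's ``positive_category`` (the
    top-severity band, e.g. obese, age 65-90); the full categories still
    enter the mismatch distance.
    """
    sub = cohort.data[cohort.data["osa"].astype(int) == 1]
    obs = sub[variable].notna()
    values = sub.loc[obs, variable]
    if values.nunique() < 2:
        raise ValueError(f"{variable}: constant among OSA patients, OR undefined")
    pos = values == cohort.schema[variable].positive_category
    severe = (sub.loc[obs, "severity"] == "severe").to_numpy()
    a = int((pos & severe).sum())  # present, severe
    b = int((~pos & severe).sum())  # absent, severe
    c = int((pos & ~severe).sum())  # present, non-severe
    d = int((~pos & ~severe).sum())  # absent, non-severe
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


@dataclass(frozen=True)
class WeightVector:
    """Per-variable crude-OR weights over the selected variables."""

    variables: tuple[str, ...]
    weights: np.ndarray  # > 0, finite

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.variables),):
            raise ValueError("weights/variables length mismatch")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("weights must be positive and finite")
        object.__setattr__(self, "weights", w)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.variables, self.weights.tolist()))


def compute_weights(cohort: Cohort, variables: Sequence[str]) -> WeightVector:
    """Crude-OR weight for each selected variable; constant variables are
    excluded with a warning (their OR is undefined)."""
    names, weights = [], []
    for var in variables:
        try:
            weights.append(crude_or_severe(cohort, var))
            names.append(var)
        except ValueError as err:
            warnings.warn(str(err))
    return WeightVector(tuple(names), np.asarray(weights))


# --------------------------------------------------------------------------
# Weighted mismatch distance
# --------------------------------------------------------------------------


def _record_values(p) -> Mapping[str, str]:
    return p.values if isinstance(p, PatientRecord) else p


def patient_distance(a, b, w: WeightVector, normalize: bool = False) -> float:
    """d(a, b) = sum_j w_j * 1[a_j != b_j] over the selected variables.

    ``normalize=True`` divides by the total weight, mapping distances to
    [0, 1].  Missing selected values are an error: imputation is upstream.
    """
    va, vb = _record_values(a), _record_values(b)
    total = 0.0
    for var, wj in zip(w.variables, w.weights):
        xa, xb = va.get(var), vb.get(var)
        if xa is None or xb is None or pd.isna(xa) or pd.isna(xb):
            raise ValueError(f"missing value for selected variable {var!r}")
        if xa != xb:
            total += wj
    return total / w.weights.sum() if normalize else total


def _encode_block(
    frame: pd.DataFrame, cohort_schema, variables: Sequence[str]
) -> np.ndarray:
    X = np.empty((len(frame), len(variables)), dtype=int)
    for j, var in enumerate(variables):
        cats = list(cohort_schema[var].categories)
        codes = pd.Categorical(frame[var], categories=cats).codes
        if (codes < 0).any():
            raise ValueError(f"missing or out-of-schema value in {var!r}")
        X[:, j] = codes
    return X


def distance_matrix(
    cohort: Cohort, w: WeightVector, normalize: bool = False
) -> np.ndarray:
    """Pairwise weighted-mismatch distances for all patients of a cohort."""
    X = _encode_block(cohort.data, cohort.schema, w.variables)
    dm = np.zeros((len(X), len(X)))
    for j, wj in enumerate(w.weights):
        mism = X[:, None, j] != X[None, :, j]
        dm += wj * mism
    if normalize:
        dm /= w.weights.sum()
    return dm


# --------------------------------------------------------------------------
# Ward linkage (Lance-Williams on raw dissimilarities)
# --------------------------------------------------------------------------


def ward_dendrogram(dm: np.ndarray, variant: str = "ward.D") -> np.ndarray:
    """Agglomerate a dissimilarity matrix with Ward linkage.

    ``ward.D`` applies the Lance-Williams Ward update directly to the
    supplied dissimilarities (the convention of classic hclust);
    ``ward.D2`` applies it to their squares and reports square-root heights.
    Returns a linkage matrix in the standard (left, right, height, size)
    format with heights made non-decreasing.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(dm).any() or (dm < 0).any():
        raise ValueError("distances must be non-negative and finite")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if variant not in ("ward.D", "ward.D2"):
        raise ValueError(f"unknown Ward variant {variant!r}")

    D = dm.copy()
    if variant == "ward.D2":
        D = D**2
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    sizes = np.ones(n)
    ids = np.arange(n)
    Z = np.zeros((n - 1, 4))
    big = np.inf
    for t in range(n - 1):
        M = np.where(active[:, None] & active[None, :], D, big)
        i, j = np.unravel_index(np.argmin(M), M.shape)  # first minimum, row-major
        if i > j:
            i, j = j, i
        h = M[i, j]
        k = active.copy()
        k[[i, j]] = False
        denom = sizes[i] + sizes[j] + sizes[k]
        D[i, k] = (
            (sizes[i] + sizes[k]) * D[i, k] + (sizes[j] + sizes[k]) * D[j, k] - sizes[k] * h
        ) / denom
        D[k, i] = D[i, k]
        Z[t] = (min(ids[i], ids[j]), max(ids[i], ids[j]), h, sizes[i] + sizes[j])
        sizes[i] += sizes[j]
        active[j] = False
        ids[i] = n + t
    if variant == "ward.D2":
        Z[:, 2] = np.sqrt(Z[:, 2])
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])
    return Z


# --------------------------------------------------------------------------
# Fine cut and 10 -> 3 aggregation
# --------------------------------------------------------------------------


def _kmeans_1d_3(values: np.ndarray) -> list[np.ndarray]:
    """Exact 3-means on a 1-D array: optimal clusters are contiguous in sorted
    order, so enumerate the two split points and minimize within-group SSE.
    Returns the index groups (into ``values``) ordered by group mean."""
    order = np.argsort(values, kind="stable")
    s = values[order]
    m = len(s)
    best, best_sse = None, np.inf
    for c1, c2 in combinations(range(1, m), 2):
        sse = 0.0
        for seg in (s[:c1], s[c1:c2], s[c2:]):
            sse += float(((seg - seg.mean()) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse, best = sse, (c1, c2)
    c1, c2 = best
    return [order[:c1], order[c1:c2], order[c2:]]


@dataclass
class ClusterModel:
    """Fitted phenotyping model: weights, dendrogram, fine clusters, the
    10 -> 3 aggregation, and the clustered OSA reference patients."""

    weights: WeightVector
    normalize: bool
    linkage: np.ndarray
    fine_labels: np.ndarray  # 1..k_fine per reference patient
    fine_medians: dict[int, float]
    aggregation_map: dict[int, str]  # fine cluster -> phenotype
    phenotypes: np.ndarray  # phenotype per reference patient
    reference_values: pd.DataFrame  # selected-variable block of OSA patients
    reference_ids: list[str]
    categories: dict[str, tuple[str, ...]]

    def phenotype_median_ahi(self, ahi: np.ndarray | None = None) -> dict[str, float]:
        if ahi is None:
            ahi = self._reference_ahi
        return {
            p: float(np.median(np.asarray(ahi)[self.phenotypes == p]))
            for p in PHENOTYPES
            if (self.phenotypes == p).any()
        }

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "variables": list(self.weights.variables),
                "weights": self.weights.weights.tolist(),
                "normalize": self.normalize,
                "linkage": self.linkage.tolist(),
                "fine_labels": self.fine_labels.tolist(),
                "fine_medians": {str(k): v for k, v in self.fine_medians.items()},
                "aggregation_map": {str(k): v for k, v in self.aggregation_map.items()},
                "phenotypes": self.phenotypes.tolist(),
                "reference_values": self.reference_values.to_dict(orient="list"),
                "reference_ids": self.reference_ids,
                "categories": {k: list(v) for k, v in self.categories.items()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClusterModel":
        d = json.loads(text)
        return cls(
            weights=WeightVector(tuple(d["variables"]), np.asarray(d["weights"])),
            normalize=d["normalize"],
            linkage=np.asarray(d["linkage"]),
            fine_labels=np.asarray(d["fine_labels"], dtype=int),
            fine_medians={int(k): v for k, v in d["fine_medians"].items()},
            aggregation_map={int(k): v for k, v in d["aggregation_map"].items()},
            phenotypes=np.asarray(d["phenotypes"], dtype=object),
            reference_values=pd.DataFrame(d["reference_values"]),
            reference_ids=list(d["reference_ids"]),
            categories={k: tuple(v) for k, v in d["categories"].items()},
        )

    def to_newick(self) -> str:
        """Dendrogram as a newick string (leaf names = reference ids)."""
        n = len(self.fine_labels)
        Z = self.linkage

        def node(idx: int, parent_h: float) -> str:
            if idx < n:
                return f"{self.reference_ids[idx]}:{parent_h:.6g}"
            row = Z[idx - n]
            h = row[2]
            left = node(int(row[0]), h)
            right = node(int(row[1]), h)
            return f"({left},{right}):{max(parent_h - h, 0.0):.6g}"

        root_h = Z[-1, 2]
        row = Z[-1]
        return f"({node(int(row[0]), root_h)},{node(int(row[1]), root_h)});"


def aggregate_medians(medians: np.ndarray) -> list[np.ndarray]:
    """Group fine-cluster median AHIs into 3 bands by exact 1-D k-means on
    the log scale (AHI is a right-skewed rate).  Reproduces the reference
    grouping {8, 10}, {12, 13, 14}, {31, 34}."""
    medians = np.asarray(medians, dtype=float)
    return _kmeans_1d_3(np.log(np.maximum(medians, 0.5)))


def cut_and_aggregate(
    linkage: np.ndarray,
    ahi: np.ndarray,
    k_fine: int = 10,
    aggregation: str = "tree",
) -> tuple[np.ndarray, dict[int, float], dict[int, str], np.ndarray]:
    """Cut the dendrogram into ``k_fine`` clusters and aggregate to 3
    severity phenotypes.

    ``aggregation="tree"`` (default) groups the fine clusters by cutting the
    same dendrogram at 3 — the hierarchical aggregation the fine cut is
    nested in — and names the groups by their median AHI.
    ``aggregation="medians"`` instead groups the fine-cluster median AHIs by
    exact 1-D k-means; this mirrors a by-inspection grouping of the printed
    medians but is fragile when cluster medians are noisy (small clusters,
    heavy-tailed severe AHIs).

    Returns (fine labels, fine-cluster medians, fine -> phenotype map,
    phenotype per patient).  Phenotypes are named low / medium / high by
    ascending pooled median AHI.  With fewer than 3 distinct medians the
    median mode falls back to a tertile split of the fine clusters.
    """
    n = linkage.shape[0] + 1
    if k_fine > n:
        raise ValueError(f"k_fine={k_fine} exceeds {n} observations")
    ahi = np.asarray(ahi)
    fine = fcluster(linkage, t=k_fine, criterion="maxclust")
    labels = np.unique(fine)
    medians = {int(c): float(np.median(ahi[fine == c])) for c in labels}
    med_values = np.asarray([medians[int(c)] for c in labels], dtype=float)

    if len(labels) < 3:
        raise ValueError("fewer than 3 fine clusters; cannot form 3 phenotypes")
    if aggregation not in ("tree", "medians"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    groups: list[np.ndarray] | None = None
    if aggregation == "tree":
        coarse = fcluster(linkage, t=3, criterion="maxclust")
        groups = []
        for g in np.unique(coarse):
            members = np.unique(fine[coarse == g])  # fine cuts nest in coarse
            groups.append(np.flatnonzero(np.isin(labels, members)))
        if len(groups) < 3:
            warnings.warn("3-cut produced fewer than 3 groups; median fallback")
            groups = None
        else:
            # a severity phenotype must actually order severity: if the
            # 3-cut's pooled medians tie, group by the medians instead
            pooled = sorted(
                float(np.median(ahi[np.isin(fine, labels[g])])) for g in groups
            )
            if not (pooled[0] < pooled[1] < pooled[2]):
                warnings.warn(
                    "3-cut phenotypes do not order median AHI; median fallback"
                )
                groups = None
    if groups is None:
        if len(np.unique(med_values)) < 3:
            warnings.warn("fewer than 3 distinct fine-cluster medians; tertile fallback")
            order = np.argsort(med_values, kind="stable")
            groups = [g for g in np.array_split(order, 3)]
        else:
            groups = aggregate_medians(med_values)

    # order groups by pooled median AHI, then name low/medium/high
    pooled = []
    for g in groups:
        members = np.isin(fine, labels[g])
        pooled.append(float(np.median(ahi[members])))
    group_order = np.argsort(pooled, kind="stable")
    aggregation: dict[int, str] = {}
    for rank, gi in enumerate(group_order):
        for c in labels[groups[gi]]:
            aggregation[int(c)] = PHENOTYPES[rank]
    phenotypes = np.asarray([aggregation[int(c)] for c in fine], dtype=object)
    return fine, medians, aggregation, phenotypes


def fit_phenotypes(
    cohort: Cohort,
    variables: Sequence[str],
    k_fine: int = 10,
    ward_variant: str = "ward.D",
    normalize: bool = False,
    aggregation: str = "tree",
) -> ClusterModel:
    """End-to-end phenotyping on the OSA patients of an imputed cohort:
    crude-OR weights -> weighted mismatch distances -> Ward dendrogram ->
    fine cut -> 3 severity phenotypes."""
    osa = cohort.subset(cohort.data["osa"].astype(int).to_numpy() == 1)
    w = compute_weights(osa, variables)
    dm = distance_matrix(osa, w, normalize=normalize)
    Z = ward_dendrogram(dm, variant=ward_variant)
    ahi = osa.data["ahi"].to_numpy()
    fine, medians, agg_map, phenotypes = cut_and_aggregate(
        Z, ahi, k_fine=k_fine, aggregation=aggregation
    )
    model = ClusterModel(
        weights=w,
        normalize=normalize,
        linkage=Z,
        fine_labels=fine,
        fine_medians=medians,
        aggregation_map=agg_map,
        phenotypes=phenotypes,
        reference_values=osa.data[list(w.variables)].copy(),
        reference_ids=[str(x) for x in osa.data.get("id", range(osa.n))],
        categories={v: cohort.schema[v].categories for v in w.variables},
    )
    model._reference_ahi = ahi
    return model


# --------------------------------------------------------------------------
# Affinity-based phenotype assignment
# --------------------------------------------------------------------------


def _reference_codes(model: ClusterModel) -> np.ndarray:
    X = np.empty((len(model.reference_values), len(model.weights.variables)), dtype=int)
    for j, var in enumerate(model.weights.variables):
        codes = pd.Categorical(
            model.reference_values[var], categories=list(model.categories[var])
        ).codes
        X[:, j] = codes
    return X


def assign_phenotype(p, model: ClusterModel, method: str = "mean"):
    """Assign one patient to the phenotype of minimal affinity.

    Affinity to a phenotype is the mean weighted-mismatch distance from the
    patient to that phenotype's reference patients (``method="medoid"`` uses
    the distance to the phenotype medoid instead).  Ties break toward the
    lower-severity phenotype, the conservative choice for a screening tool.
    Returns ``(phenotype, affinities)`` with all three affinities.
    """
    values = _record_values(p)
    row = {v: values.get(v) for v in model.weights.variables}
    frame = pd.DataFrame([row])
    aff = _affinities(frame, model, method=method)[0]
    best = int(np.argmin(aff))  # argmin takes the first = lowest-severity on ties
    return PHENOTYPES[best], dict(zip(PHENOTYPES, aff.tolist()))


def _affinities(frame: pd.DataFrame, model: ClusterModel, method: str = "mean") -> np.ndarray:
    ref = _reference_codes(model)
    schema_like = {
        v: type("S", (), {"categories": model.categories[v]})
        for v in model.weights.variables
    }
    X = _encode_block(frame, schema_like, model.weights.variables)
    w = model.weights.weights
    total = w.sum() if model.normalize else 1.0
    out = np.empty((len(X), 3))
    for k, phen in enumerate(PHENOTYPES):
        members = ref[model.phenotypes == phen]
        if members.size == 0:
            raise ValueError(f"phenotype {phen!r} has no reference patients")
        # (n_query, n_members) weighted mismatch
        d = np.zeros((len(X), len(members)))
        for j in range(len(w)):
            d += w[j] * (X[:, None, j] != members[None, :, j])
        d /= total
        if method == "mean":
            out[:, k] = d.mean(axis=1)
        elif method == "medoid":
            # medoid = member with minimal total distance to its own cluster
            within = np.zeros((len(members), len(members)))
            for j in range(len(w)):
                within += w[j] * (members[:, None, j] != members[None, :, j])
            medoid = int(np.argmin(within.sum(axis=1)))
            out[:, k] = d[:, medoid]
        else:
            raise ValueError(f"unknown affinity method {method!r}")
    return out


def assign_phenotypes(
    cohort: Cohort, model: ClusterModel, method: str = "mean"
) -> np.ndarray:
    """Vectorized affinity assignment for every patient of a cohort."""
    frame = cohort.data[list(model.weights.variables)]
    aff = _affinities(frame, model, method=method)
    return np.asarray(PHENOTYPES, dtype=object)[np.argmin(aff, axis=1)]


# --------------------------------------------------------------------------
# Per-phenotype description
# --------------------------------------------------------------------------


def describe_clusters(
    cohort: Cohort, model: ClusterModel, ci_method: str = "wilson-cc"
) -> pd.DataFrame:
    """Per-phenotype frequency table with 95% CIs for the OSA patients.

    One row per (phenotype, variable, category): count, group size,
    proportion and its 95% CI, plus severity-distribution rows and the
    phenotype median AHI."""
    osa = cohort.subset(cohort.data["osa"].astype(int).to_numpy() == 1)
    if osa.n != len(model.phenotypes):
        raise ValueError("model was not fitted on this cohort's OSA patients")
    rows = []
    for phen in PHENOTYPES:
        mask = model.phenotypes == phen
        group = osa.data[mask]
        n = int(mask.sum())
        for var in model.weights.variables:
            for cat in model.categories[var]:
                x = int((group[var] == cat).sum())
                lo, hi = proportion_ci(x, n, method=ci_method)
                rows.append(
                    dict(
                        phenotype=phen,
                        variable=var,
                        category=cat,
                        count=x,
                        n=n,
                        proportion=x / n,
                        ci_low=lo,
                        ci_high=hi,
                    )
                )
        for sev in ("mild", "moderate", "severe"):
            x = int((group["severity"] == sev).sum())
            lo, hi = proportion_ci(x, n, method=ci_method)
            rows.append(
                dict(
                    phenotype=phen,
                    variable="ahi_severity",
                    category=sev,
                    count=x,
                    n=n,
                    proportion=x / n,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
        rows.append(
            dict(
                phenotype=phen,
                variable="median_ahi",
                category="",
                count=n,
                n=n,
                proportion=float(np.median(group["ahi"])),
                ci_low=np.nan,
                ci_high=np.nan,
            )
        )
    return pd.DataFrame(rows)
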