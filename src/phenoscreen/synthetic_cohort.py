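"""Seedable synthetic OSA cohort generator.

The study cohort behind this package (318 referred patients, 207 with OSA)
was never deposited, so every downstream stage is exercised on synthetic
cohorts that emulate its published structure: three latent severity
phenotypes (low / medium / high) with phenotype-conditional categorical
predictor distributions, phenotype-conditional AHI severity mixtures, and
per-variable missingness at the reported rates.

The default :class:`GeneratorSpec` is parameterized directly from the
published per-cluster frequency tables: phenotype weights 74/104/29 among the
207 OSA patients and 25/79/7 among the 111 healthy patients; per-variable
category counts per (phenotype, status); severity mixtures per phenotype
(e.g. 51/18/5 mild/moderate/severe in the low phenotype); and per-variable
missingness from the reported missing-data column (0% for gender up to 97%
for bariatric surgery).

Sampling model: for each patient, (1) OSA status comes from the fixed group
sizes, (2) a latent phenotype is drawn from the status-specific weights,
(3) each predictor is drawn independently from its (phenotype, status)
category distribution, (4) a severity band is drawn from the phenotype's
mixture (healthy patients are always in the normal band) and an integer AHI
is drawn uniformly within the band.  The latent phenotype is stored as
hidden ground truth for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import (
    PHENOTYPES,
    SEVERITIES,
    Cohort,
    VariableSchema,
    severity_of_ahi,
)

__all__ = [
    "GeneratorSpec",
    "default_schema",
    "default_generator_spec",
    "generate_cohort",
    "inject_missingness",
]

YN = ("no", "yes")

# status axis order used throughout: column 0 = healthy, column 1 = OSA
STATUS_HEALTHY, STATUS_OSA = 0, 1

# --- published per-phenotype counts -----------------------------------------
# (low, medium, high) group sizes
_N_OSA = (74, 104, 29)
_N_HEALTHY = (25, 79, 7)

# For each variable: category list, then per-status per-phenotype counts of
# each category.  Binary variables list the "yes" count only.
_OSA_COUNTS = {
    "gender": {"male": (51, 72, 24)},
    "age": {"20-44": (6, 12, 0), "45-64": (46, 59, 7), "65-90": (22, 33, 22)},
    "bmi": {"normal": (13, 3, 0), "overweight": (15, 50, 9), "obese": (46, 51, 20)},
    "nonrepairing_sleep": {"yes": (34, 57, 10)},
    "nocturia": {"yes": (14, 104, 29)},
    "stroke": {"yes": (34, 88, 27)},
    "arterial_hypertension": {"yes": (54, 96, 29)},
    "pulmonary_hypertension": {"yes": (9, 2, 6)},
    "congestive_heart_failure": {"yes": (4, 1, 23)},
    "arrhythmias": {"yes": (4, 1, 12)},
    "pacemaker": {"yes": (0, 4, 6)},
    "respiratory_changes": {"yes": (35, 28, 18)},
    "diabetes": {"yes": (37, 69, 29)},
    "dyslipidemia": {"yes": (57, 94, 29)},
}

_HEALTHY_COUNTS = {
    "gender": {"male": (10, 39, 2)},
    "age": {"20-44": (16, 15, 0), "45-64": (7, 47, 2), "65-90": (2, 17, 5)},
    "bmi": {"normal": (4, 6, 1), "overweight": (11, 40, 2), "obese": (10, 33, 4)},
    "nonrepairing_sleep": {"yes": (18, 51, 3)},
    "nocturia": {"yes": (0, 54, 6)},
    "stroke": {"yes": (1, 66, 6)},
    "arterial_hypertension": {"yes": (14, 78, 7)},
    "pulmonary_hypertension": {"yes": (0, 1, 2)},
    "congestive_heart_failure": {"yes": (0, 0, 7)},
    "arrhythmias": {"yes": (0, 1, 2)},
    "pacemaker": {"yes": (0, 1, 0)},
    "respiratory_changes": {"yes": (7, 34, 5)},
    "diabetes": {"yes": (0, 55, 7)},
    "dyslipidemia": {"yes": (16, 75, 6)},
}

# Screening-only variables that are described only at the whole-cohort level:
# prevalence among OSA patients from the reported totals; the healthy-arm
# prevalences are not published and are fixed here once at plausible lower
# values (see docs/methods.md), configurable through the spec.
_SCREENING_PREVALENCE = {  # variable: (healthy, osa)
    "witnessed_apneas": (0.40, 109 / 169),
    "daytime_sleepiness": (0.50, 109 / 197),
    "snoring": (0.85, 187 / 201),
    "gasping_choking": (0.40, 67 / 154),
    "bariatric_surgery": (0.03, 0.03),
}

# Reported per-variable missingness proportions.
_MISSING_RATE = {
    "gender": 0.0,
    "age": 0.0,
    "bmi": 0.184,
    "nonrepairing_sleep": 0.116,
    "nocturia": 0.343,
    "stroke": 0.787,
    "arterial_hypertension": 0.232,
    "pulmonary_hypertension": 0.435,
    "congestive_heart_failure": 0.333,
    "arrhythmias": 0.522,
    "pacemaker": 0.560,
    "respiratory_changes": 0.106,
    "diabetes": 0.522,
    "dyslipidemia": 0.285,
    "witnessed_apneas": 0.184,
    "daytime_sleepiness": 0.048,
    "snoring": 0.029,
    "gasping_choking": 0.256,
    "bariatric_surgery": 0.97,
}

# Severity mixture (mild, moderate, severe) per phenotype among OSA patients.
_SEVERITY_COUNTS = {
    "low": (51, 18, 5),
    "medium": (54, 24, 26),
    "high": (6, 8, 15),
}


def default_schema() -> dict[str, VariableSchema]:
    """Variable schemas for the default synthetic cohort.

    The 14 cluster-candidate variables plus the screening-only variables
    (witnessed apneas is exclusion-flagged: univariately significant in the
    study but kept out of the cluster hierarchy because it depends on
    third-party reporting).
    """
    roles = {
        "gender": "demographic",
        "age": "demographic",
        "bmi": "exam",
        "nonrepairing_sleep": "history",
        "nocturia": "history",
        "stroke": "comorbidity",
        "arterial_hypertension": "comorbidity",
        "pulmonary_hypertension": "comorbidity",
        "congestive_heart_failure": "comorbidity",
        "arrhythmias": "comorbidity",
        "pacemaker": "comorbidity",
        "respiratory_changes": "comorbidity",
        "diabetes": "comorbidity",
        "dyslipidemia": "comorbidity",
        "witnessed_apneas": "history",
        "daytime_sleepiness": "history",
        "snoring": "history",
        "gasping_choking": "history",
        "bariatric_surgery": "comorbidity",
    }
    cats = {
        "gender": ("female", "male"),
        "age": ("20-44", "45-64", "65-90"),
        "bmi": ("normal", "overweight", "obese"),
    }
    schema = {}
    for name, role in roles.items():
        schema[name] = VariableSchema(
            name=name,
            categories=cats.get(name, YN),
            role=role,
            exclusion_flag=(name == "witnessed_apneas"),
            positive_category={"gender": "male", "age": "65-90", "bmi": "obese"}.get(name),
        )
    return schema


@dataclass
class GeneratorSpec:
    """Full parameterization of the synthetic cohort generator.

    ``category_probs[var]`` has shape ``(3 phenotypes, 2 statuses,
    n_categories)`` with status axis (healthy, osa); every trailing slice is a
    probability simplex.
    """

    n_osa: int
    n_healthy: int
    phenotype_weights_osa: tuple[float, float, float]
    phenotype_weights_healthy: tuple[float, float, float]
    category_probs: dict[str, np.ndarray]
    severity_mix_per_phenotype: dict[str, tuple[float, float, float]]
    ahi_band_per_severity: dict[str, tuple[int, int]]
    missing_rate: dict[str, float]
    missing_mechanism: str = "MCAR"
    mar_healthy_factor: float = 1.3
    seed: int = 0
    schema: dict[str, VariableSchema] = field(default_factory=default_schema)
    # Within-band AHI decay: P(AHI = lo + k | band) proportional to r^k.
    # AHI is right-skewed within bands; the defaults reproduce the reference
    # per-phenotype medians (10 / 14 / 31).  r = 1 recovers a uniform band.
    ahi_within_band_decay: dict[str, float] = field(
        default_factory=lambda: {"normal": 0.85, "mild": 0.85, "moderate": 0.9, "severe": 0.9}
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_osa < 0 or self.n_healthy < 0:
            raise ValueError("negative group size")
        if self.n_osa + self.n_healthy == 0:
            raise ValueError("empty cohort requested")
        for name, w in (
            ("phenotype_weights_osa", self.phenotype_weights_osa),
            ("phenotype_weights_healthy", self.phenotype_weights_healthy),
        ):
            if abs(sum(w) - 1.0) > 1e-9 or min(w) < 0:
                raise ValueError(f"{name} is not a simplex: {w}")
        for var, probs in self.category_probs.items():
            probs = np.asarray(probs, dtype=float)
            if var not in self.schema:
                raise ValueError(f"{var}: probabilities given but no schema")
            ncat = len(self.schema[var].categories)
            if probs.shape != (3, 2, ncat):
                raise ValueError(f"{var}: expected shape (3, 2, {ncat}), got {probs.shape}")
            if (probs < 0).any() or np.abs(probs.sum(axis=-1) - 1.0).max() > 1e-9:
                raise ValueError(f"{var}: category distributions must sum to 1")
        for phen, mix in self.severity_mix_per_phenotype.items():
            if abs(sum(mix) - 1.0) > 1e-9 or min(mix) < 0:
                raise ValueError(f"severity mix for {phen} is not a simplex")
        for var, rate in self.missing_rate.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{var}: missing rate {rate} outside [0, 1]")
        if self.missing_mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown missing mechanism {self.missing_mechanism!r}")
        for sev, r in self.ahi_within_band_decay.items():
            if not 0 < r <= 1:
                raise ValueError(f"{sev}: within-band decay must be in (0, 1]")
        bands = [self.ahi_band_per_severity[s] for s in SEVERITIES]
        for (lo, hi), (lo2, _hi2) in zip(bands, bands[1:]):
            if not (lo <= hi and hi + 1 == lo2):
                raise ValueError("AHI bands must be disjoint, ordered, integer-contiguous")

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        d = {
            "n_osa": self.n_osa,
            "n_healthy": self.n_healthy,
            "phenotype_weights_osa": list(self.phenotype_weights_osa),
            "phenotype_weights_healthy": list(self.phenotype_weights_healthy),
            "category_probs": {
                k: np.asarray(v).tolist() for k, v in self.category_probs.items()
            },
            "severity_mix_per_phenotype": {
                k: list(v) for k, v in self.severity_mix_per_phenotype.items()
            },
            "ahi_band_per_severity": {
                k: list(v) for k, v in self.ahi_band_per_severity.items()
            },
            "missing_rate": dict(self.missing_rate),
            "ahi_within_band_decay": dict(self.ahi_within_band_decay),
            "missing_mechanism": self.missing_mechanism,
            "mar_healthy_factor": self.mar_healthy_factor,
            "seed": self.seed,
            "schema": [v.to_dict() for v in self.schema.values()],
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorSpec":
        d = json.loads(text)
        return cls(
            n_osa=d["n_osa"],
            n_healthy=d["n_healthy"],
            phenotype_weights_osa=tuple(d["phenotype_weights_osa"]),
            phenotype_weights_healthy=tuple(d["phenotype_weights_healthy"]),
            category_probs={
                k: np.asarray(v, dtype=float) for k, v in d["category_probs"].items()
            },
            severity_mix_per_phenotype={
                k: tuple(v) for k, v in d["severity_mix_per_phenotype"].items()
            },
            ahi_band_per_severity={
                k: tuple(v) for k, v in d["ahi_band_per_severity"].items()
            },
            missing_rate=d["missing_rate"],
            ahi_within_band_decay=d.get(
                "ahi_within_band_decay",
                {"normal": 0.85, "mild": 0.85, "moderate": 0.9, "severe": 0.9},
            ),
            missing_mechanism=d["missing_mechanism"],
            mar_healthy_factor=d["mar_healthy_factor"],
            seed=d["seed"],
            schema={s["name"]: VariableSchema.from_dict(s) for s in d["schema"]},
        )


def _category_probs_from_counts(schema: Mapping[str, VariableSchema]) -> dict[str, np.ndarray]:
    probs: dict[str, np.ndarray] = {}
    for var, vs in schema.items():
        ncat = len(vs.categories)
        arr = np.zeros((3, 2, ncat))
        if var in _OSA_COUNTS:
            for status, counts_tab, ns in (
                (STATUS_OSA, _OSA_COUNTS, _N_OSA),
                (STATUS_HEALTHY, _HEALTHY_COUNTS, _N_HEALTHY),
            ):
                counts = np.zeros((3, ncat))
                for cat, per_phen in counts_tab[var].items():
                    counts[:, vs.categories.index(cat)] = per_phen
                if ncat == 2:  # binary: "no" is the complement
                    counts[:, 0] = np.asarray(ns) - counts[:, 1]
                arr[:, status, :] = counts / np.asarray(ns)[:, None]
        else:
            p_healthy, p_osa = _SCREENING_PREVALENCE[var]
            arr[:, STATUS_HEALTHY, :] = (1 - p_healthy, p_healthy)
            arr[:, STATUS_OSA, :] = (1 - p_osa, p_osa)
        probs[var] = arr
    return probs


def default_generator_spec(seed: int = 0) -> GeneratorSpec:
    """The study-conditions generator: 207 OSA / 111 healthy patients with
    phenotype weights, per-variable frequencies, severity mixtures and
    missingness rates taken from the published cohort tables."""
    schema = default_schema()
    return GeneratorSpec(
        n_osa=207,
        n_healthy=111,
        phenotype_weights_osa=tuple(n / sum(_N_OSA) for n in _N_OSA),
        phenotype_weights_healthy=tuple(n / sum(_N_HEALTHY) for n in _N_HEALTHY),
        category_probs=_category_probs_from_counts(schema),
        severity_mix_per_phenotype={
            phen: tuple(c / sum(counts) for c in counts)
            for phen, counts in _SEVERITY_COUNTS.items()
        },
        # severe band truncated at 120 events/hour for sampling (physiological
        # ceiling; the bands themselves are open-ended above 30)
        ahi_band_per_severity={
            "normal": (0, 4),
            "mild": (5, 14),
            "moderate": (15, 29),
            "severe": (30, 120),
        },
        missing_rate=dict(_MISSING_RATE),
        seed=seed,
        schema=schema,
    )


def generate_cohort(spec: GeneratorSpec, seed: int | None = None) -> Cohort:
    """Draw a complete cohort (no missingness) from the generator spec.

    The returned cohort stores the latent phenotype of every patient in the
    ``true_phenotype`` column; it is hidden ground truth for recovery tests
    and is never consumed by the analysis pipeline itself.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_osa + spec.n_healthy
    status = np.concatenate([np.ones(spec.n_osa, int), np.zeros(spec.n_healthy, int)])

    phen_idx = np.empty(n, dtype=int)
    osa_mask = status == 1
    phen_idx[osa_mask] = rng.choice(3, size=spec.n_osa, p=spec.phenotype_weights_osa)
    phen_idx[~osa_mask] = rng.choice(
        3, size=spec.n_healthy, p=spec.phenotype_weights_healthy
    )

    data: dict[str, object] = {"id": [f"p{i:05d}" for i in range(n)]}
    for var, vs in spec.schema.items():
        probs = np.asarray(spec.category_probs[var], dtype=float)
        ncat = probs.shape[-1]
        # inverse-CDF draw per patient from its (phenotype, status) simplex
        cdf = np.cumsum(probs[phen_idx, status, :], axis=1)
        u = rng.random(n)
        codes = (u[:, None] > cdf).sum(axis=1).clip(0, ncat - 1)
        data[var] = np.asarray(vs.categories, dtype=object)[codes]

    # severity then AHI uniform over the band's integers
    severity = np.empty(n, dtype=object)
    severity[~osa_mask] = "normal"
    mixes = np.stack(
        [np.asarray(spec.severity_mix_per_phenotype[p]) for p in PHENOTYPES]
    )
    osa_sev_idx = np.empty(n, dtype=int)
    cdf = np.cumsum(mixes[phen_idx[osa_mask]], axis=1)
    u = rng.random(int(osa_mask.sum()))
    osa_sev_idx[osa_mask] = (u[:, None] > cdf).sum(axis=1).clip(0, 2)
    sev_names = np.asarray(["mild", "moderate", "severe"], dtype=object)
    severity[osa_mask] = sev_names[osa_sev_idx[osa_mask]]

    ahi = np.empty(n, dtype=int)
    for sev in SEVERITIES:
        lo, hi = spec.ahi_band_per_severity[sev]
        m = severity == sev
        r = float(spec.ahi_within_band_decay.get(sev, 1.0))
        p = r ** np.arange(hi - lo + 1)
        ahi[m] = lo + rng.choice(len(p), size=int(m.sum()), p=p / p.sum())

    data["ahi"] = ahi
    data["severity"] = severity
    data["osa"] = status
    data["true_phenotype"] = np.asarray(PHENOTYPES, dtype=object)[phen_idx]
    df = pd.DataFrame(data)
    assert all(severity_of_ahi(a) == s for a, s in zip(ahi, severity))
    return Cohort(df, spec.schema)


def inject_missingness(
    cohort: Cohort, spec: GeneratorSpec, seed: int | None = None
) -> Cohort:
    """Mask predictor entries per the spec's per-variable missingness rates.

    MCAR masks every entry independently at the variable's rate; the MAR
    option multiplies the rate by ``mar_healthy_factor`` for healthy patients
    (comorbidities are under-recorded in healthier charts).  Outcome columns
    are never masked; pre-masking values are retained in ``truth`` so
    imputation can be scored.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    out = cohort.copy()
    truth = out.predictor_frame().copy()
    healthy = out.data["osa"].to_numpy().astype(int) == 0
    for var in out.variables:
        rate = float(spec.missing_rate.get(var, 0.0))
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{var}: missing rate {rate} outside [0, 1]")
        rates = np.full(out.n, rate)
        if spec.missing_mechanism == "MAR":
            rates[healthy] = np.minimum(rate * spec.mar_healthy_factor, 1.0)
        mask = rng.random(out.n) < rates
        col = out.data[var].to_numpy(dtype=object)
        col[mask] = np.nan
        out.data[var] = col
    out.truth = truth
    return out
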