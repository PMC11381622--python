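"""Seeded synthetic cohort generator.

Emits cohorts with the statistical structure the topographic model assumes:
cluster structure in a 2-D latent space mapped smoothly (low-order
polynomial mixture) into high dimensions with spherical Gaussian noise, a
fraction of positively skewed columns, investigative variables correlated
with the planted clusters, and injectable missingness.  Schema presets name
the columns after the two cohort layouts the pipeline targets: a biobank-like
table of 67 modelling variables (40 genomic principal-component columns plus
27 biological sample assays) and an ICU-like table of 21 vitals/lab columns.
Only the names and column counts are emulated - no distributional claims
about the real cohorts are made.

A ``heavy_tails`` switch replaces the Gaussian observation noise with
Student-t noise, deliberately violating the model's spherical-Gaussian
assumption for qualitative robustness checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable, Role, VType, VariableMeta

__all__ = ["CohortSpec", "generate_cohort", "inject_missingness",
           "UKB_LIKE_NAMES", "MIMIC_LIKE_NAMES"]

_UKB_BIOLOGY = [
    "alanine_aminotransferase", "albumin", "alkaline_phosphatase",
    "apolipoprotein_a", "apolipoprotein_b", "aspartate_aminotransferase",
    "c_reactive_protein", "calcium", "cholesterol", "creatinine",
    "cystatin_c", "direct_bilirubin", "gamma_glutamyltransferase", "glucose",
    "hba1c", "hdl_cholesterol", "igf1", "ldl_direct", "lipoprotein_a",
    "phosphate", "shbg", "testosterone", "total_bilirubin", "total_protein",
    "triglycerides", "urate", "urea",
]

#: 67 modelling columns: 40 genomic principal components + 27 assays.
UKB_LIKE_NAMES = [f"pc{i}" for i in range(1, 41)] + _UKB_BIOLOGY

#: 21 vitals/lab modelling columns.
MIMIC_LIKE_NAMES = [
    "heart_rate", "respiratory_rate", "temperature", "sbp", "dbp", "mbp",
    "spo2", "glucose", "hemoglobin", "hematocrit", "platelet_count", "wbc",
    "sodium", "potassium", "chloride", "bicarbonate", "bun", "creatinine",
    "calcium", "magnesium", "phosphate",
]

_INVESTIGATIVE_POOLS = {
    "generic": [],
    "ukb_like": ["sex", "age", "bmi", "alcohol_intake", "physical_activity",
                 "waist_circumference", "smoking_status"],
    "mimic_like": ["sex", "age", "gcs_total", "icu_los_days",
                   "invasive_ventilation", "aki", "ards"],
}


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    ``cluster_separation`` is the distance between adjacent latent blob
    centres in units of the within-blob standard deviation (fixed at 1), so
    ``cluster_separation=10`` with ``noise_sd=1`` is a 10:1
    separation-to-noise regime.
    """

    n_subjects: int = 1000
    n_dims: int | None = None            # None -> schema default (generic: 10)
    n_clusters: int = 3
    cluster_separation: float = 10.0
    noise_sd: float = 1.0
    skewed_fraction: float = 0.2
    missing_rate_var: float = 0.0        # fraction of columns given above-threshold missingness
    missing_rate_cell: float = 0.02
    n_investigative: int = 5
    investigative_effect: float = 1.0
    schema: str = "generic"
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("skewed_fraction", "missing_rate_var", "missing_rate_cell"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be >= 0")
        if self.schema not in {"generic", "ukb_like", "mimic_like"}:
            raise ValueError(f"unknown schema {self.schema!r}")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def modelling_names(self) -> list[str]:
        if self.schema == "ukb_like":
            return list(UKB_LIKE_NAMES)
        if self.schema == "mimic_like":
            return list(MIMIC_LIKE_NAMES)
        d = self.n_dims if self.n_dims is not None else 10
        return [f"var{i:03d}" for i in range(1, d + 1)]


def _latent_centres(n_clusters: int, separation: float, rng) -> np.ndarray:
    if n_clusters == 1:
        return np.zeros((1, 2))
    # equally spaced on a circle whose chord between neighbours = separation
    radius = separation / (2.0 * np.sin(np.pi / n_clusters))
    angles = 2.0 * np.pi * np.arange(n_clusters) / n_clusters + rng.uniform(0, 2 * np.pi)
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def _smooth_features(z: np.ndarray) -> np.ndarray:
    """Low-order polynomial feature map of latent points: linear terms
    dominate, mild quadratics bend the manifold."""
    z1, z2 = z[:, 0], z[:, 1]
    c = 0.1
    return np.column_stack([z1, z2, c * z1**2, c * z2**2, c * z1 * z2])


def generate_cohort(spec: CohortSpec) -> tuple[CohortTable, np.ndarray]:
    """Draw a cohort table plus the planted cluster labels.

    Latent points come from ``n_clusters`` unit-sd Gaussian blobs separated
    by ``cluster_separation``; a seeded smooth random map lifts them to the
    modelling dimensions, spherical noise of sd ``noise_sd`` is added, a
    ``skewed_fraction`` of columns is exponentiated to induce positive skew,
    and investigative columns get planted-label mean shifts of
    ``investigative_effect`` within-group standard deviations (the first one
    is a binary categorical with label-dependent prevalence).  Deterministic
    per seed.
    """
    rng = np.random.default_rng(spec.seed)
    names = spec.modelling_names
    D, N, C = len(names), spec.n_subjects, spec.n_clusters

    labels = rng.integers(0, C, size=N)
    centres = _latent_centres(C, spec.cluster_separation, rng)
    latent_sd = 1.5 if C == 1 else 1.0
    z = centres[labels] + rng.normal(0.0, latent_sd, size=(N, 2))

    F = _smooth_features(z)
    A = rng.normal(size=(F.shape[1], D)) / np.sqrt(F.shape[1])
    if spec.heavy_tails:
        noise = spec.noise_sd * rng.standard_t(df=3, size=(N, D))
    else:
        noise = rng.normal(0.0, spec.noise_sd, size=(N, D))
    X = F @ A + noise

    n_skew = int(round(spec.skewed_fraction * D))
    skew_cols = rng.choice(D, size=n_skew, replace=False) if n_skew else np.array([], int)
    for j in skew_cols:
        s = X[:, j].std()
        if s > 0:
            X[:, j] = np.exp(X[:, j] / (2.0 * s))

    df = pd.DataFrame(X, columns=names,
                      index=[f"S{i:06d}" for i in range(N)])
    variables = [VariableMeta(n, Role.MODELLING, VType.CONTINUOUS) for n in names]

    pool = _INVESTIGATIVE_POOLS[spec.schema]
    inv_names = (pool + [f"inv{i:02d}" for i in range(1, spec.n_investigative + 1)]
                 )[: spec.n_investigative]
    for j, iname in enumerate(inv_names):
        if j == 0:
            # binary categorical with label-dependent prevalence
            p = np.clip(0.5 + 0.15 * spec.investigative_effect
                        * (labels - (C - 1) / 2.0), 0.05, 0.95)
            df[iname] = (rng.random(N) < p).astype(float)
            variables.append(VariableMeta(iname, Role.INVESTIGATIVE, VType.CATEGORICAL))
        else:
            shift = spec.investigative_effect * labels.astype(float)
            df[iname] = shift + rng.normal(0.0, 1.0, size=N)
            variables.append(VariableMeta(iname, Role.INVESTIGATIVE, VType.CONTINUOUS))

    return CohortTable(data=df, variables=variables), labels


def inject_missingness(table: CohortTable, spec: CohortSpec) -> CohortTable:
    """Set modelling cells missing completely at random.

    ``missing_rate_cell`` applies to every modelling column;
    ``missing_rate_var`` of the modelling columns are instead elevated to 40%
    missingness so downstream filters have something to drop.  Deterministic
    per seed (an independent stream from the cohort draw).
    """
    rng = np.random.default_rng([spec.seed, 7])
    df = table.data.copy()
    mod = table.modelling_names
    n_elev = int(round(spec.missing_rate_var * len(mod)))
    elevated = set(rng.choice(len(mod), size=n_elev, replace=False).tolist())
    for j, name in enumerate(mod):
        rate = 0.4 if j in elevated else spec.missing_rate_cell
        if rate <= 0:
            continue
        mask = rng.random(table.n_subjects) < rate
        col = df[name].to_numpy(dtype=float)
        col[mask] = np.nan
        df[name] = col
    return table.with_data(df)
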