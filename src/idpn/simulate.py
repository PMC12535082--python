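"""Synthetic cohorts with controllable correlation-perturbation structure.

Controls are drawn from a Gaussian copula: a latent multivariate normal
with a chosen base correlation matrix, pushed through strictly monotone
per-feature marginal transforms.  Because the transforms are monotone they
preserve latent ranks exactly, so the cohort's Spearman structure is
governed by the latent correlations in closed form
(rho_S = (6/pi) arcsin(r/2) for normal marginals).

A patient is a control-like latent draw displaced along the *discordant*
direction of each of its subgroup's target edges (one coordinate pushed
up, the other down), so adding that single respondent to the controls
shifts the sample Spearman correlation of those edges.  The achieved shift
is always measured by rebuilding both correlation matrices from raw data,
never assumed from the requested displacement.  NSSI severity is coupled
to the total achieved perturbation:

    severity = baseline + coupling * sum_e |achieved dSCC_e| + noise,

truncated to [0, 192] (the instrument's maximum) and rounded.

The default scenario — 300 controls and 120 patients in two subgroups
(70/50) with disjoint 4-edge target sets and different displacement
magnitudes — mirrors the regime the method is meant for (controls greatly
outnumbering features, a handful of high-prevalence perturbed edges, two
latent subtypes, severity higher in the more perturbed subtype).
Displacements were calibrated once by simulation so that planted edges
exceed the Bonferroni cutoff for the large majority of patients, then
frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FLAG_COL, ID_COL, SEVERITY_COL
from .instruments import NSSI_SEVERITY_MAX
from .network import spearman_matrix

Edge = tuple[str, str]


@dataclass(frozen=True)
class Marginal:
    """Strictly monotone (affine) latent-to-feature transform, with optional
    support bounds; values outside the bounds are clipped with a warning."""

    loc: float = 0.0
    scale: float = 1.0
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("marginal scale must be positive")

    def transform(self, z: np.ndarray) -> np.ndarray:
        x = self.loc + self.scale * np.asarray(z, dtype=float)
        if self.lower is not None or self.upper is not None:
            clipped = np.clip(x, self.lower, self.upper)
            if not np.array_equal(clipped, x):
                import warnings

                warnings.warn(
                    "values outside the marginal support were clipped", stacklevel=2
                )
            x = clipped
        return x


@dataclass(frozen=True)
class SubgroupSpec:
    name: str
    n_patients: int
    edges: tuple[Edge, ...]
    displacement: float


@dataclass(frozen=True)
class CohortSpec:
    n_controls: int = 300
    feature_names: tuple[str, ...] = FEATURE_NAMES
    base_correlation: np.ndarray | None = None
    marginals: dict[str, Marginal] = field(default_factory=dict)
    subgroups: tuple[SubgroupSpec, ...] = ()
    severity_baseline: float = 5.0
    severity_coupling: float = 1200.0
    severity_noise_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n_controls < 30:
            raise ValueError("need at least 30 controls")
        p = len(self.feature_names)
        R = self.base_correlation if self.base_correlation is not None else np.eye(p)
        R = np.asarray(R, dtype=float)
        if R.shape != (p, p):
            raise ValueError("base correlation shape does not match feature count")
        if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("base correlation must be symmetric with unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w.min() <= 0:
            raise ValueError(
                f"base correlation not positive definite (smallest eigenvalue {w.min():.3g})"
            )
        object.__setattr__(self, "base_correlation", R)
        for sg in self.subgroups:
            for a, b in sg.edges:
                if a not in self.feature_names or b not in self.feature_names:
                    raise ValueError(f"subgroup {sg.name}: unknown feature in edge ({a}, {b})")
                if a == b:
                    raise ValueError(f"subgroup {sg.name}: self-edge ({a}, {b})")

    @property
    def n_patients(self) -> int:
        return sum(sg.n_patients for sg in self.subgroups)

    def _cholesky(self) -> np.ndarray:
        return np.linalg.cholesky(self.base_correlation)

    def _marginal(self, name: str) -> Marginal:
        return self.marginals.get(name, Marginal())

    def edge_indices(self, edges: tuple[Edge, ...]) -> list[tuple[int, int]]:
        names = list(self.feature_names)
        return [(names.index(a), names.index(b)) for a, b in edges]


# Default two-subtype scenario.  Planted edges are feature-disjoint so each
# displacement acts on its own pair; base correlation 0.6 within each planted
# pair (block-diagonal, hence positive definite) and 0 elsewhere.
_SUBGROUP_1_EDGES: tuple[Edge, ...] = (
    ("SAS", "SDS"),
    ("Neuroticism", "Extraversion"),
    ("Openness", "Agreeableness"),
    ("Conscientiousness", "Cohesion"),
)
_SUBGROUP_2_EDGES: tuple[Edge, ...] = (
    ("Expressiveness", "Conflict"),
    ("Independence", "Achievement Orientation"),
    ("Intellectual-Cultural Orientation", "Active-Recreational Orientation"),
    ("Moral-Religious Emphasis", "Organization"),
)

# Scale-typical locations/spreads: Zung standard scores, 12-item NEO sums,
# 9-item binary FES sums.
_DEFAULT_MARGINALS = {
    "SAS": Marginal(45.0, 10.0),
    "SDS": Marginal(48.0, 10.0),
    **{d: Marginal(36.0, 7.0) for d in FEATURE_NAMES[2:7]},
    **{d: Marginal(5.0, 2.0) for d in FEATURE_NAMES[7:]},
}


def default_cohort_spec(
    n_controls: int = 300,
    n_subgroup_1: int = 70,
    n_subgroup_2: int = 50,
    displacement_1: float = 2.5,
    displacement_2: float = 3.5,
    base_edge_correlation: float = 0.6,
    severity_coupling: float = 1200.0,
) -> CohortSpec:
    """The default two-subtype scenario used throughout the test suite."""
    p = len(FEATURE_NAMES)
    R = np.eye(p)
    names = list(FEATURE_NAMES)
    for a, b in _SUBGROUP_1_EDGES + _SUBGROUP_2_EDGES:
        i, j = names.index(a), names.index(b)
        R[i, j] = R[j, i] = base_edge_correlation
    return CohortSpec(
        n_controls=n_controls,
        base_correlation=R,
        marginals=dict(_DEFAULT_MARGINALS),
        subgroups=(
            SubgroupSpec("subgroup_1", n_subgroup_1, _SUBGROUP_1_EDGES, displacement_1),
            SubgroupSpec("subgroup_2", n_subgroup_2, _SUBGROUP_2_EDGES, displacement_2),
        ),
        severity_coupling=severity_coupling,
    )


def _latent_draws(spec: CohortSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    L = spec._cholesky()
    return rng.standard_normal((n, len(spec.feature_names))) @ L.T


def _to_features(spec: CohortSpec, latent: np.ndarray) -> np.ndarray:
    cols = [
        spec._marginal(name).transform(latent[:, k])
        for k, name in enumerate(spec.feature_names)
    ]
    return np.column_stack(cols)


def generate_controls(spec: CohortSpec, seed: int | np.random.Generator) -> pd.DataFrame:
    """Feature table of NSSI-free controls drawn from the base copula."""
    rng = np.random.default_rng(seed)
    latent = _latent_draws(spec, spec.n_controls, rng)
    X = _to_features(spec, latent)
    table = pd.DataFrame(X, columns=list(spec.feature_names))
    table.insert(0, ID_COL, [f"C{i:04d}" for i in range(spec.n_controls)])
    table[FLAG_COL] = False
    table[SEVERITY_COL] = 0
    return table


def generate_patient(
    spec: CohortSpec,
    controls: pd.DataFrame,
    subgroup: SubgroupSpec,
    rng: np.random.Generator,
    patient_id: str = "P0000",
    control_scc: np.ndarray | None = None,
) -> tuple[pd.Series, dict]:
    """One patient plus their ground-truth record.

    The patient's latent draw is displaced discordantly on each target
    edge; the achieved dSCC on those edges is then measured exactly by
    rebuilding the Spearman matrices of controls versus controls + patient.
    """
    names = list(spec.feature_names)
    latent = _latent_draws(spec, 1, rng)[0]
    for i, j in spec.edge_indices(subgroup.edges):
        latent[i] += subgroup.displacement
        latent[j] -= subgroup.displacement
    x = _to_features(spec, latent[None, :])[0]

    Xc = controls[names].to_numpy(dtype=float)
    if control_scc is None:
        control_scc = spearman_matrix(Xc, spec.feature_names)
    scc_plus = spearman_matrix(np.vstack([Xc, x]), spec.feature_names)
    achieved = {
        (a, b): float(scc_plus[i, j] - control_scc[i, j])
        for (a, b), (i, j) in zip(subgroup.edges, spec.edge_indices(subgroup.edges))
    }
    total = sum(abs(v) for v in achieved.values())
    severity = spec.severity_baseline + spec.severity_coupling * total
    severity += rng.normal(0.0, spec.severity_noise_sd)
    severity = int(round(float(np.clip(severity, 0, NSSI_SEVERITY_MAX))))

    profile = pd.Series({ID_COL: patient_id, **dict(zip(names, x))})
    profile[FLAG_COL] = True
    profile[SEVERITY_COL] = severity
    truth = {
        "patient_id": patient_id,
        "subgroup": subgroup.name,
        "severity": severity,
        "achieved_delta": achieved,
    }
    return profile, truth


@dataclass(frozen=True)
class GroundTruth:
    """Generator ground truth: subgroup labels and measured edge shifts."""

    patients: pd.DataFrame  # patient_id, subgroup, severity
    edges: pd.DataFrame  # patient_id, feature_i, feature_j, achieved_delta

    def planted_edges(self) -> set[Edge]:
        return set(zip(self.edges["feature_i"], self.edges["feature_j"]))


def generate_cohort(
    spec: CohortSpec, seed: int | np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Controls plus patients across subgroups, with ground truth.

    Reproducible given the seed; patient ids are P0001.. in subgroup order.
    """
    rng = np.random.default_rng(seed)
    controls = generate_controls(spec, rng)
    control_scc = (
        spearman_matrix(
            controls[list(spec.feature_names)].to_numpy(dtype=float), spec.feature_names
        )
        if spec.subgroups
        else None
    )
    rows, truth_rows, edge_rows = [], [], []
    counter = 0
    for sg in spec.subgroups:
        for _ in range(sg.n_patients):
            counter += 1
            profile, truth = generate_patient(
                spec, controls, sg, rng,
                patient_id=f"P{counter:04d}", control_scc=control_scc,
            )
            rows.append(profile)
            truth_rows.append(
                {k: truth[k] for k in ("patient_id", "subgroup", "severity")}
            )
            for (a, b), v in truth["achieved_delta"].items():
                edge_rows.append(
                    {
                        "patient_id": truth["patient_id"],
                        "feature_i": a,
                        "feature_j": b,
                        "achieved_delta": v,
                    }
                )
    if rows:
        table = pd.concat([controls, pd.DataFrame(rows)], ignore_index=True)
    else:
        table = controls.copy()
    table[FLAG_COL] = table[FLAG_COL].astype(bool)
    table[SEVERITY_COL] = table[SEVERITY_COL].astype(int)
    truth = GroundTruth(
        patients=pd.DataFrame(
            truth_rows, columns=["patient_id", "subgroup", "severity"]
        ),
        edges=pd.DataFrame(
            edge_rows, columns=["patient_id", "feature_i", "feature_j", "achieved_delta"]
        ),
    )
    return table, truth
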