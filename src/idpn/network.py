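"""Per-patient correlation-perturbation networks.

The method quantifies how a single patient deviates the pairwise Spearman
correlation structure of a normative cohort:

1. *Reference network*: the Spearman correlation matrix ``SCC_n`` over the
   n controls.
2. *Perturbed network*: ``SCC_{n+1}``, the same matrix recomputed from raw
   data after adding one patient.  It is always recomputed from scratch —
   rank statistics admit no exact incremental update.
3. *Individual differential network*: per edge (i, j),

       z = dSCC / ((1 - SCC_n^2) / (n - 1)),   dSCC = SCC_{n+1} - SCC_n

   with two-sided p-values from the standard normal tail and Bonferroni
   correction over the m = p(p-1)/2 unique edges (136 for 17 features).

The denominator is the ratio form (the influence scale of a single added
observation), the method's canonical choice; a square-root variant is
exposed for sensitivity analysis via ``formula="sqrt"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import (
    FEATURE_NAMES,
    FLAG_COL,
    ID_COL,
    edge_list,
    feature_matrix,
    n_edges,
)

FORMULAS = ("ratio", "sqrt")


def spearman_matrix(X: np.ndarray, feature_names: tuple[str, ...] | None = None) -> np.ndarray:
    """Spearman rank correlation matrix of a respondents x features matrix.

    Ties receive average ranks (the standard convention).  A feature with
    zero rank variance makes its correlations undefined and raises.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D respondents x features matrix")
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need at least 3 respondents, got {n}")
    ranks = stats.rankdata(X, axis=0)
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        names = feature_names or tuple(f"feature_{k}" for k in range(p))
        bad = [names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant features (correlation undefined): {bad}")
    scc = np.corrcoef(ranks, rowvar=False)
    scc = np.clip((scc + scc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(scc, 1.0)
    return scc


@dataclass(frozen=True)
class ReferenceNetwork:
    """Spearman correlation matrix over the n controls."""

    feature_names: tuple[str, ...]
    scc: np.ndarray
    n: int

    def __post_init__(self) -> None:
        p = len(self.feature_names)
        if self.scc.shape != (p, p):
            raise ValueError("correlation matrix shape does not match features")
        if self.n < 3:
            raise ValueError("reference network needs at least 3 controls")

    @property
    def n_edges(self) -> int:
        return n_edges(len(self.feature_names))


@dataclass(frozen=True)
class IDPN:
    """One patient's differential network.

    ``z`` is symmetric with zero diagonal and shares its sign with
    ``delta`` entrywise.  ``evaluable`` is False on edges where the
    reference correlation is exactly +/-1 (zero denominator); such edges
    carry NaN z and p and are never significant.
    """

    patient_id: object
    delta: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sig: np.ndarray
    evaluable: np.ndarray
    alpha: float
    m_edges: int
    n_controls: int


def build_reference_network(
    controls: pd.DataFrame, feature_names: tuple[str, ...] = FEATURE_NAMES
) -> ReferenceNetwork:
    """Reference network from a feature table of controls (nssi_flag False)."""
    if FLAG_COL in controls.columns and controls[FLAG_COL].any():
        flagged = controls.loc[controls[FLAG_COL], ID_COL].tolist()
        raise ValueError(
            f"controls must be NSSI-free; flagged respondents: {flagged[:5]}"
        )
    X = feature_matrix(controls, feature_names)
    scc = spearman_matrix(X, feature_names)
    return ReferenceNetwork(feature_names=tuple(feature_names), scc=scc, n=len(controls))


def _z_denominator(scc: np.ndarray, n: int, formula: str) -> np.ndarray:
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}")
    denom = (1.0 - scc**2) / (n - 1)
    if formula == "sqrt":
        denom = np.sqrt(denom)
    return denom


def compute_idpn(
    ref: ReferenceNetwork,
    controls: pd.DataFrame,
    patient: pd.Series | pd.DataFrame,
    alpha: float = 0.05,
    m_edges: int | None = None,
    formula: str = "ratio",
) -> IDPN:
    """Differential network of one patient against the reference cohort.

    The perturbed matrix is rebuilt from the raw values of the n + 1
    respondents.  Bonferroni corrects over ``m_edges`` tests (default: all
    unique edges of the network).
    """
    if isinstance(patient, pd.DataFrame):
        if len(patient) != 1:
            raise ValueError("patient must be a single row")
        patient = patient.iloc[0]
    if ID_COL in controls.columns and patient.get(ID_COL) is not None:
        if (controls[ID_COL] == patient[ID_COL]).any():
            raise ValueError(f"patient {patient[ID_COL]!r} is among the controls")
    names = ref.feature_names
    Xc = feature_matrix(controls, names)
    if len(Xc) != ref.n:
        raise ValueError("reference network was not built from these controls")
    xp = patient[list(names)].to_numpy(dtype=float)
    scc_plus = spearman_matrix(np.vstack([Xc, xp]), names)
    delta = scc_plus - ref.scc

    m = m_edges if m_edges is not None else ref.n_edges
    evaluable = np.abs(ref.scc) < 1.0
    np.fill_diagonal(evaluable, False)
    denom = _z_denominator(ref.scc, ref.n, formula)
    z = np.full_like(delta, np.nan)
    z[evaluable] = delta[evaluable] / denom[evaluable]
    np.fill_diagonal(z, 0.0)
    p = np.full_like(delta, np.nan)
    with np.errstate(invalid="ignore"):
        p[evaluable] = 2.0 * stats.norm.sf(np.abs(z[evaluable]))
    np.fill_diagonal(p, 1.0)
    sig = np.zeros_like(evaluable)
    sig[evaluable] = p[evaluable] < alpha / m
    return IDPN(
        patient_id=patient.get(ID_COL),
        delta=delta,
        z=z,
        p=p,
        sig=sig,
        evaluable=evaluable,
        alpha=alpha,
        m_edges=m,
        n_controls=ref.n,
    )


def batch_idpn(
    controls: pd.DataFrame,
    patients: pd.DataFrame,
    alpha: float = 0.05,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    m_edges: int | None = None,
    formula: str = "ratio",
    ref: ReferenceNetwork | None = None,
) -> list[IDPN]:
    """One differential network per patient, all against the same reference."""
    if ID_COL in controls.columns and ID_COL in patients.columns:
        overlap = set(controls[ID_COL]) & set(patients[ID_COL])
        if overlap:
            raise ValueError(f"respondent ids in both sets: {sorted(overlap)[:5]}")
    if ref is None:
        ref = build_reference_network(controls, feature_names)
    return [
        compute_idpn(ref, controls, row, alpha=alpha, m_edges=m_edges, formula=formula)
        for _, row in patients.iterrows()
    ]


def idpn_edge_table(idpns: list[IDPN], ref: ReferenceNetwork) -> pd.DataFrame:
    """Long-format edge table: one row per (patient, edge)."""
    names = ref.feature_names
    edges = edge_list(names)
    rows = []
    for net in idpns:
        for i, j in edges:
            rows.append(
                {
                    "patient_id": net.patient_id,
                    "feature_i": names[i],
                    "feature_j": names[j],
                    "scc_ref": ref.scc[i, j],
                    "scc_perturbed": ref.scc[i, j] + net.delta[i, j],
                    "delta": net.delta[i, j],
                    "z": net.z[i, j],
                    "p": net.p[i, j],
                    "significant": bool(net.sig[i, j]),
                    "evaluable": bool(net.evaluable[i, j]),
                }
            )
    return pd.DataFrame(rows)
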