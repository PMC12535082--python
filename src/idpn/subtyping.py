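"""Patient subtyping from differential-network edges.

Pipeline: count, per edge, how many patients show a Bonferroni-significant
perturbation; keep edges above a prevalence threshold; Z-standardize the
selected per-patient z-scores; choose k with the elbow rule on the
within-cluster sum of squares (WSS); cluster with K-means; sanity-check
collinearity (VIF) and validate with Fisher's linear discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .network import IDPN, ReferenceNetwork
from .features import edge_list

Edge = tuple[str, str]


def edge_prevalence(idpns: list[IDPN], ref: ReferenceNetwork) -> pd.DataFrame:
    """Per-edge count and fraction of patients with a significant perturbation."""
    if not idpns:
        raise ValueError("need at least one patient network")
    ns = {net.n_controls for net in idpns}
    if len(ns) > 1:
        raise ValueError("patient networks come from different reference networks")
    names = ref.feature_names
    edges = edge_list(names)
    counts = np.zeros(len(edges), dtype=int)
    for net in idpns:
        for e, (i, j) in enumerate(edges):
            counts[e] += bool(net.sig[i, j])
    n_pat = len(idpns)
    return pd.DataFrame(
        {
            "feature_i": [names[i] for i, _ in edges],
            "feature_j": [names[j] for _, j in edges],
            "count": counts,
            "fraction": counts / n_pat,
            "n_patients": n_pat,
        }
    )


def select_edges(
    prevalence: pd.DataFrame,
    min_fraction: float | None = None,
    min_count: int | None = None,
) -> list[Edge]:
    """Edges significant in at least the threshold number of patients.

    When both thresholds are given the stricter applies.  Output is ordered
    by descending count, then lexicographic feature pair — invariant to
    patient ordering.
    """
    if min_fraction is None and min_count is None:
        raise ValueError("give min_fraction and/or min_count")
    n_pat = int(prevalence["n_patients"].iloc[0])
    threshold = 0
    if min_count is not None:
        threshold = max(threshold, int(min_count))
    if min_fraction is not None:
        threshold = max(threshold, int(np.ceil(min_fraction * n_pat)))
    kept = prevalence[prevalence["count"] >= threshold]
    if kept.empty:
        raise ValueError(
            f"no edge is significant in >= {threshold} of {n_pat} patients; "
            "lower min_count/min_fraction"
        )
    kept = kept.sort_values(
        ["count", "feature_i", "feature_j"], ascending=[False, True, True]
    )
    return list(zip(kept["feature_i"], kept["feature_j"]))


def patient_z_table(
    idpns: list[IDPN], ref: ReferenceNetwork, edges: list[Edge]
) -> pd.DataFrame:
    """Patients x selected-edges table of raw (unstandardized) z-scores."""
    names = list(ref.feature_names)
    idx = {(a, b): (names.index(a), names.index(b)) for a, b in edges}
    data = {
        f"{a}-{b}": [net.z[idx[(a, b)]] for net in idpns] for a, b in edges
    }
    out = pd.DataFrame(data)
    out.insert(0, "patient_id", [net.patient_id for net in idpns])
    return out


@dataclass(frozen=True)
class StandardizationParams:
    columns: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[list(self.columns)] = (table[list(self.columns)] - self.mean) / self.sd
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        out[list(self.columns)] = table[list(self.columns)] * self.sd + self.mean
        return out


def standardize(z_table: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Column-wise (x - mean)/SD over patients; parameters stored for reuse.

    Uses the population (ddof=0) standard deviation, so standardized
    columns have mean 0 and SD 1 exactly.
    """
    cols = [c for c in z_table.columns if c != "patient_id"]
    if len(z_table) < 2:
        raise ValueError("need at least 2 patients to standardize")
    X = z_table[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    if constant:
        raise ValueError(f"constant columns cannot be standardized: {constant}")
    params = StandardizationParams(columns=tuple(cols), mean=mean, sd=sd)
    return params.transform(z_table), params


def _data_matrix(data: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        cols = [c for c in data.columns if c != "patient_id"]
        return data[cols].to_numpy(dtype=float)
    return np.asarray(data, dtype=float)


def wss_curve(
    data: pd.DataFrame | np.ndarray,
    k_range: range | list[int],
    seed: int | None = None,
    restarts: int = 10,
    max_iter: int = 40,
) -> dict[int, float]:
    """Best-of-restarts K-means within-cluster sum of squares for each k."""
    X = _data_matrix(data)
    ks = sorted(k_range)
    if ks[-1] > len(X):
        raise ValueError(f"k up to {ks[-1]} exceeds the {len(X)} patients")
    out: dict[int, float] = {}
    for k in ks:
        km = KMeans(
            n_clusters=k,
            n_init=restarts,
            max_iter=max_iter,
            random_state=seed,
            algorithm="lloyd",
        ).fit(X)
        out[k] = float(km.inertia_)
    return out


def elbow_select_k(
    data: pd.DataFrame | np.ndarray,
    k_range: range | list[int] = range(1, 9),
    seed: int | None = None,
    restarts: int = 10,
    max_iter: int = 40,
) -> tuple[int, dict[int, float]]:
    """Choose k at the knee of the WSS curve.

    The knee is the interior k maximizing the discrete second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1); the full curve is returned so the
    choice can be inspected or overridden.
    """
    wss = wss_curve(data, k_range, seed=seed, restarts=restarts, max_iter=max_iter)
    ks = sorted(wss)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values for the elbow rule")
    second_diff = {
        ks[i]: wss[ks[i - 1]] - 2 * wss[ks[i]] + wss[ks[i + 1]]
        for i in range(1, len(ks) - 1)
    }
    chosen = max(second_diff, key=lambda k: (second_diff[k], -k))
    return chosen, wss


@dataclass(frozen=True)
class ClusterModel:
    selected_edges: tuple[Edge, ...]
    k: int
    assignments: pd.Series  # index: patient_id, values: 1..k
    centroids: np.ndarray
    inertia: float
    iterations_run: int
    seed: int | None
    wss_by_k: dict[int, float] | None = None

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_index()


def kmeans_cluster(
    data: pd.DataFrame,
    k: int,
    max_iter: int = 40,
    seed: int | None = None,
    restarts: int = 10,
    severity: pd.Series | np.ndarray | None = None,
    selected_edges: tuple[Edge, ...] = (),
    wss_by_k: dict[int, float] | None = None,
) -> ClusterModel:
    """Lloyd's K-means on standardized data, best of ``restarts`` inits.

    When per-patient NSSI severity is supplied, labels are renumbered so
    cluster 1 has the lowest mean severity — a stable "Group 1 / Group 2"
    convention across seeds.
    """
    X = _data_matrix(data)
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} invalid for {len(X)} patients")
    km = KMeans(
        n_clusters=k,
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    labels = km.labels_
    centroids = km.cluster_centers_
    if severity is not None and k > 1:
        sev = np.asarray(severity, dtype=float)
        means = [sev[labels == c].mean() for c in range(k)]
        order = np.argsort(means, kind="stable")
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]
        centroids = centroids[order]
    ids = (
        data["patient_id"].to_numpy()
        if isinstance(data, pd.DataFrame) and "patient_id" in data.columns
        else np.arange(len(X))
    )
    assignments = pd.Series(labels + 1, index=pd.Index(ids, name="patient_id"), name="cluster")
    return ClusterModel(
        selected_edges=tuple(selected_edges),
        k=k,
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
        iterations_run=int(km.n_iter_),
        seed=seed,
        wss_by_k=wss_by_k,
    )


def vif_check(data: pd.DataFrame | np.ndarray, flag_threshold: float = 3.0) -> pd.DataFrame:
    """Variance inflation factor of each column regressed on the others.

    VIF_j = 1/(1 - R^2_j); perfectly collinear columns get infinite VIF
    (flagged), never an exception.
    """
    X = _data_matrix(data)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} patients for {p} columns")
    cols = (
        [c for c in data.columns if c != "patient_id"]
        if isinstance(data, pd.DataFrame)
        else [f"col_{j}" for j in range(p)]
    )
    Xc = X - X.mean(axis=0)
    vifs = []
    for j in range(p):
        y = Xc[:, j]
        A = np.delete(Xc, j, axis=1)
        coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        tss = float(y @ y)
        rss = float(resid @ resid)
        if tss == 0 or rss / tss < 1e-12:
            vifs.append(np.inf)
        else:
            vifs.append(1.0 / (rss / tss))
    out = pd.DataFrame({"column": cols, "vif": vifs})
    out["flagged"] = ~(out["vif"] < flag_threshold)
    return out


def lda_validate(
    data: pd.DataFrame | np.ndarray,
    assignments: pd.Series | np.ndarray,
    cv_folds: int | None = None,
    seed: int | None = None,
) -> dict:
    """Fisher linear discriminant check of a clustering.

    Fits an LDA on (data, cluster labels) and reports resubstitution
    accuracy — accuracy on the same sample the discriminant was fitted on —
    plus the per-cluster confusion counts.  Resubstitution overstates
    out-of-sample accuracy, so a stratified cross-validated accuracy is
    reported as well when ``cv_folds`` is given.
    """
    X = _data_matrix(data)
    y = np.asarray(assignments)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    if (counts < 2).any():
        small = labels[counts < 2].tolist()
        raise ValueError(f"clusters with fewer than 2 members: {small}")
    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)
    pred = lda.predict(X)
    accuracy = float((pred == y).mean())
    confusion = pd.crosstab(
        pd.Series(y, name="cluster"), pd.Series(pred, name="predicted")
    )
    result = {"accuracy": accuracy, "confusion": confusion}
    if cv_folds:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        scores = cross_val_score(LinearDiscriminantAnalysis(), X, y, cv=skf)
        result["cv_accuracy"] = float(scores.mean())
    return result
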