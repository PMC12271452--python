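"""Gender-stratified K-Means with bootstrapped k-selection and stability checks.

The cluster count for each gender stratum is chosen by bootstrapping
agglomerative hierarchical clustering on small stratified subsamples (default
500 repeats of 1% subsamples) and maximising the mean silhouette score, with
Davies-Bouldin and Calinski-Harabasz recorded for corroboration.  Subsamples
are made representative by first clustering the whole stratum into a large
number of K-Means strata (default 1000) and sampling equally from each.

Stability is assessed three ways: bootstrap K-Means replicates matched
one-to-one to the final centroids with the Hungarian algorithm on cosine
distances; cluster cohesion (median cosine distance to centroid) of members
assigned from age-spliced medical histories versus final histories; and the
comorbidity-pair similarity check implemented in :mod:`ehrclust.evaluation`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.metrics.pairwise import cosine_distances

from ehrclust.synthetic import PatientRecord

logger = logging.getLogger(__name__)


def cosine_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """1 - cosine similarity, the distance used throughout validation."""
    return cosine_distances(np.atleast_2d(a), np.atleast_2d(b))


# ---------------------------------------------------------------------------
# Representative subsampling


def precluster_for_sampling(
    embeddings: np.ndarray, k: int = 1000, seed: int = 0
) -> np.ndarray:
    """Label each point with one of ``k`` K-Means sampling strata."""
    embeddings = np.asarray(embeddings)
    if k > embeddings.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points {embeddings.shape[0]}")
    km = KMeans(n_clusters=k, n_init=1, random_state=seed)
    return km.fit_predict(embeddings)


def stratified_sample(
    strata: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Equal-allocation stratified sample of ``fraction`` of all points.

    The total sample size is split equally across strata (rounding down),
    with the remainder assigned round-robin; strata smaller than their quota
    contribute all their members and the shortfall is redistributed.
    Returns sorted point indices.
    """
    strata = np.asarray(strata)
    n = strata.size
    labels = np.unique(strata)
    total = max(int(np.floor(fraction * n)), 1)
    base = total // labels.size
    quotas = {lab: base for lab in labels}
    for lab in labels[: total - base * labels.size]:
        quotas[lab] += 1
    chosen: list[np.ndarray] = []
    shortfall = 0
    for lab in labels:
        members = np.flatnonzero(strata == lab)
        take = min(quotas[lab], members.size)
        shortfall += quotas[lab] - take
        chosen.append(rng.choice(members, size=take, replace=False))
    if shortfall:
        pool = np.setdiff1d(np.arange(n), np.concatenate(chosen), assume_unique=False)
        if pool.size:
            extra = rng.choice(pool, size=min(shortfall, pool.size), replace=False)
            chosen.append(extra)
    return np.sort(np.concatenate(chosen))


# ---------------------------------------------------------------------------
# Cluster-number selection


@dataclass
class KSelectionReport:
    """Bootstrapped internal-validity metrics per candidate cluster count."""

    table: pd.DataFrame  # columns k, silhouette_mean/sd, db_mean/sd, ch_mean/sd
    chosen_k: int
    replicates: int
    fraction: float
    skipped_replicates: int = 0


def select_optimal_k(
    embeddings: np.ndarray,
    k_range: Sequence[int],
    replicates: int = 500,
    fraction: float = 0.01,
    n_sampling_strata: int = 1000,
    linkage_method: str = "ward",
    seed: int = 0,
    strata: np.ndarray | None = None,
) -> KSelectionReport:
    """Choose k by bootstrapped agglomerative clustering on stratified subsamples.

    Each replicate draws an equal-allocation stratified subsample, builds a
    Ward agglomerative hierarchy on length-normalised embeddings, cuts it at
    every candidate k, and records silhouette, Davies-Bouldin and
    Calinski-Harabasz scores.  The chosen k maximises the mean silhouette
    across replicates (ties break to the smaller k).
    """
    embeddings = np.asarray(embeddings, dtype=float)
    n = embeddings.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    sub_n = max(int(np.floor(fraction * n)), 1)
    if k_range[0] < 2 or k_range[-1] >= sub_n:
        raise ValueError("k_range must lie within [2, subsample size)")
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = precluster_for_sampling(
            embeddings, k=min(n_sampling_strata, n), seed=seed
        )
    norms = np.linalg.norm(embeddings, axis=1, keepdims=True)
    unit = embeddings / np.maximum(norms, 1e-12)

    scores: dict[int, dict[str, list[float]]] = {
        k: {"silhouette": [], "db": [], "ch": []} for k in k_range
    }
    skipped = 0
    for _ in range(replicates):
        idx = stratified_sample(strata, fraction, rng)
        X = unit[idx]
        if np.allclose(X, X[0]):
            skipped += 1
            logger.info("degenerate subsample (all identical points); replicate skipped")
            continue
        Z = linkage(X, method=linkage_method)
        for k in k_range:
            labels = fcluster(Z, t=k, criterion="maxclust")
            if np.unique(labels).size < 2:
                continue
            scores[k]["silhouette"].append(silhouette_score(X, labels))
            scores[k]["db"].append(davies_bouldin_score(X, labels))
            scores[k]["ch"].append(calinski_harabasz_score(X, labels))

    rows = []
    for k in k_range:
        s = scores[k]
        rows.append(
            {
                "k": k,
                "silhouette_mean": float(np.mean(s["silhouette"])) if s["silhouette"] else np.nan,
                "silhouette_sd": float(np.std(s["silhouette"])) if s["silhouette"] else np.nan,
                "davies_bouldin_mean": float(np.mean(s["db"])) if s["db"] else np.nan,
                "davies_bouldin_sd": float(np.std(s["db"])) if s["db"] else np.nan,
                "calinski_harabasz_mean": float(np.mean(s["ch"])) if s["ch"] else np.nan,
                "calinski_harabasz_sd": float(np.std(s["ch"])) if s["ch"] else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["silhouette_mean"].idxmax(), "k"] if table["silhouette_mean"].notna().any() else k_range[0]
    # ties break to the smallest k among maximisers
    max_sil = table["silhouette_mean"].max()
    ties = table.loc[np.isclose(table["silhouette_mean"], max_sil), "k"]
    chosen = int(ties.min()) if len(ties) else int(best)
    return KSelectionReport(
        table=table,
        chosen_k=chosen,
        replicates=replicates,
        fraction=fraction,
        skipped_replicates=skipped,
    )


# ---------------------------------------------------------------------------
# Final clustering


@dataclass
class ClusterModel:
    """Fitted K-Means for one gender stratum."""

    k: int
    centroids: np.ndarray  # (k, dim)
    stratum: str
    seed: int
    inertia: float = np.nan

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")

    def assign(self, embeddings: np.ndarray, metric: str = "euclidean") -> np.ndarray:
        embeddings = np.atleast_2d(embeddings)
        if metric == "cosine":
            d = cosine_distances(embeddings, self.centroids)
        else:
            d = np.linalg.norm(
                embeddings[:, None, :] - self.centroids[None, :, :], axis=-1
            )
        return d.argmin(axis=1)


def fit_final_kmeans(
    embeddings: np.ndarray, k: int, seed: int = 0, stratum: str = "all", n_init: int = 10
) -> ClusterModel:
    """Standard K-Means at the selected k with multiple seeded restarts."""
    embeddings = np.asarray(embeddings)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > embeddings.shape[0]:
        raise ValueError("k cannot exceed the number of points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(embeddings)
    return ClusterModel(
        k=k,
        centroids=km.cluster_centers_,
        stratum=stratum,
        seed=seed,
        inertia=float(km.inertia_),
    )


def hungarian_match(
    centroids_a: np.ndarray, centroids_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal 1-to-1 centroid matching minimising total cosine distance.

    Returns ``(permutation, distances)`` where ``permutation[i]`` is the row
    of ``centroids_b`` matched to row ``i`` of ``centroids_a`` and
    ``distances[i]`` the cosine distance of that pair.
    """
    a = np.atleast_2d(centroids_a)
    b = np.atleast_2d(centroids_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError("both centroid sets must have the same k")
    cost = cosine_distances(a, b)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(a.shape[0], dtype=int)
    perm[rows] = cols
    return perm, cost[rows, cols]


@dataclass
class StabilityReport:
    """Median matched-centroid cosine distance per final cluster."""

    median_distance: np.ndarray  # (k,)
    all_distances: np.ndarray  # (replicates, k)
    replicates: int
    fraction: float

    @property
    def overall_mean(self) -> float:
        return float(np.mean(self.median_distance))


def bootstrap_stability(
    embeddings: np.ndarray,
    final_model: ClusterModel,
    replicates: int = 100,
    fraction: float = 0.25,
    seed: int = 0,
    strata: np.ndarray | None = None,
    n_sampling_strata: int = 1000,
) -> StabilityReport:
    """Bootstrap K-Means on stratified subsamples and match to final centroids."""
    embeddings = np.asarray(embeddings)
    rng = np.random.default_rng(seed)
    if strata is None:
        strata = precluster_for_sampling(
            embeddings, k=min(n_sampling_strata, embeddings.shape[0]), seed=seed
        )
    dists = np.zeros((replicates, final_model.k))
    for r in range(replicates):
        idx = stratified_sample(strata, fraction, rng)
        km = KMeans(
            n_clusters=final_model.k,
            n_init=1,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(embeddings[idx])
        perm, pair_d = hungarian_match(final_model.centroids, km.cluster_centers_)
        dists[r] = pair_d
    return StabilityReport(
        median_distance=np.median(dists, axis=0),
        all_distances=dists,
        replicates=replicates,
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Temporal stability


def splice_record(record: PatientRecord, age_cutoff: int) -> PatientRecord | None:
    """Truncate a record at an age cutoff for the temporal-stability check.

    Events at ages up to and including ``age_cutoff`` are retained.  The
    patient is ineligible for the cutoff cohort (returns None) if they have
    no records after the cutoff age — e.g. records up to and including age
    64 exclude the patient from the age-65 cohort — or if truncation leaves
    no events.
    """
    if not record.events:
        return None
    last_age = record.age_at(record.events[-1].date)
    if last_age <= age_cutoff:
        return None  # no records after the cutoff age
    kept = [e for e in record.events if record.age_at(e.date) <= age_cutoff]
    if not kept:
        return None  # nothing recorded yet by the cutoff age
    return PatientRecord(
        patient_id=record.patient_id,
        gender=record.gender,
        year_of_birth=record.year_of_birth,
        registration_start=record.registration_start,
        registration_end=record.registration_end,
        events=kept,
        ethnicity=record.ethnicity,
        imd_quintile=record.imd_quintile,
    )


@dataclass
class TemporalCohesionReport:
    """Per-age cluster cohesion versus final-cluster cohesion.

    Cohesion is the median cosine distance of assigned members to their
    centroid; the headline number is the mean absolute difference between
    per-age cohesion and final cohesion, averaged over clusters and ages.
    """

    per_age: pd.DataFrame  # columns: age, cluster, n_assigned, cohesion
    final_cohesion: np.ndarray  # (k,)
    cohesion_difference: pd.DataFrame  # columns: age, cluster, difference

    @property
    def mean_absolute_difference(self) -> float:
        return float(self.cohesion_difference["difference"].abs().mean())


def _median_cohesion(
    embeddings: np.ndarray, labels: np.ndarray, centroids: np.ndarray
) -> np.ndarray:
    k = centroids.shape[0]
    out = np.full(k, np.nan)
    for c in range(k):
        members = embeddings[labels == c]
        if members.size:
            out[c] = float(np.median(cosine_distances(members, centroids[c : c + 1])))
    return out


def temporal_cohesion(
    age_spliced_embeddings: Mapping[int, np.ndarray],
    final_embeddings: np.ndarray,
    final_model: ClusterModel,
) -> TemporalCohesionReport:
    """Assign age-spliced embeddings to nearest centroids and compare cohesion.

    Assignment uses cosine distance to the final centroids, consistent with
    the cohesion metric; ages with empty cohorts are skipped with a log
    entry.
    """
    final_labels = final_model.assign(final_embeddings, metric="cosine")
    final_coh = _median_cohesion(final_embeddings, final_labels, final_model.centroids)
    rows = []
    diff_rows = []
    for age in sorted(age_spliced_embeddings):
        X = np.asarray(age_spliced_embeddings[age])
        if X.size == 0:
            logger.info("age cohort %d is empty; skipped", age)
            continue
        labels = final_model.assign(X, metric="cosine")
        coh = _median_cohesion(X, labels, final_model.centroids)
        for c in range(final_model.k):
            n_assigned = int((labels == c).sum())
            rows.append(
                {"age": age, "cluster": c, "n_assigned": n_assigned, "cohesion": coh[c]}
            )
            if n_assigned and np.isfinite(coh[c]) and np.isfinite(final_coh[c]):
                diff_rows.append(
                    {"age": age, "cluster": c, "difference": coh[c] - final_coh[c]}
                )
    return TemporalCohesionReport(
        per_age=pd.DataFrame(rows, columns=["age", "cluster", "n_assigned", "cohesion"]),
        final_cohesion=final_coh,
        cohesion_difference=pd.DataFrame(diff_rows, columns=["age", "cluster", "difference"]),
    )
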