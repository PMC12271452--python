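"""Cluster characterisation: c-DF-IPF weights, association tests, validation.

DF-IPF adapts TF-IDF to disease presence: for patient p and disease d,

    DFIPF(d, p) = n_{d,p} / sum_{d'} n_{d',p} * ln(|P| / |{p in P : d in p}|)

where n_{d,p} is the binary presence of d in p's record, the denominator is
the patient's disease count, and the log term down-weights population-common
diseases.  Cluster weights average DF-IPF over members and rescale by a
cluster-level inverse frequency:

    c-DFIPF(d, i) = mean DFIPF over cluster i * ln(|K| / |{clusters with d}|)

so a disease frequent in one cluster but rare across clusters scores high.
Natural logarithms are used; the base only rescales weights uniformly.

Associations use 1-vs-all tests per cluster: chi-squared (1 df, no
continuity correction) for binary variables with a signed z = sign(O - E) *
sqrt(chi2), annotated with the symbol scheme ++ (z >= 50), + (10 <= z < 50),
- (-50 < z <= -10), -- (z <= -50); Welch t-tests for continuous variables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)


@dataclass
class DiseaseMatrix:
    """Patients x conditions binary presence matrix over the LTC list."""

    values: np.ndarray  # (n_patients, n_conditions) in {0, 1}
    patient_ids: list[str]
    conditions: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("disease matrix entries must be binary")
        if self.values.shape != (len(self.patient_ids), len(self.conditions)):
            raise ValueError("matrix shape must match ids and condition names")

    @classmethod
    def from_records(cls, records, conditions: Sequence[str], condition_codes: Mapping[str, str]):
        """Build from patient records: presence of each condition's diagnosis code."""
        code_of = {c: condition_codes[c] for c in conditions}
        ids = [r.patient_id for r in records]
        vals = np.zeros((len(ids), len(conditions)), dtype=np.int8)
        for i, r in enumerate(records):
            codes = {e.code for e in r.events if e.source == "diagnosis"}
            for j, c in enumerate(conditions):
                if code_of[c] in codes:
                    vals[i, j] = 1
        return cls(vals, ids, list(conditions))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.conditions)


def dfipf(matrix: DiseaseMatrix) -> pd.DataFrame:
    """Patient-level DF-IPF weights; columns for diseases seen in no patient
    are excluded (and reported), rows for patients with no diseases are zero."""
    X = matrix.values.astype(float)
    n = X.shape[0]
    if n == 0:
        raise ValueError("dfipf requires at least one patient")
    col_pat = X.sum(axis=0)
    empty_cols = [c for c, s in zip(matrix.conditions, col_pat) if s == 0]
    if empty_cols:
        logger.info("diseases with zero patients excluded from DF-IPF: %s", empty_cols)
    keep = col_pat > 0
    X = X[:, keep]
    conditions = [c for c, k in zip(matrix.conditions, keep) if k]
    row_tot = X.sum(axis=1)
    tf = np.divide(X, row_tot[:, None], out=np.zeros_like(X), where=row_tot[:, None] > 0)
    ipf = np.log(n / col_pat[keep])
    return pd.DataFrame(tf * ipf[None, :], index=matrix.patient_ids, columns=conditions)


@dataclass
class CDFIPFMatrix:
    """Clusters x conditions c-DF-IPF weights."""

    weights: pd.DataFrame  # index: cluster id, columns: condition

    def profile(self, cluster: int) -> pd.Series:
        return self.weights.loc[cluster]


def cdfipf(
    dfipf_matrix: pd.DataFrame, assignments: np.ndarray, n_clusters: int | None = None
) -> CDFIPFMatrix:
    """Cluster-averaged DF-IPF rescaled by cluster-level inverse frequency.

    ``assignments`` gives each patient's cluster (0..K-1).  A condition's
    cluster count is the number of clusters with at least one member having
    a positive DF-IPF for it; conditions absent from every cluster are
    excluded with a log entry.
    """
    assignments = np.asarray(assignments)
    if len(assignments) != dfipf_matrix.shape[0]:
        raise ValueError("one assignment per patient required")
    K = int(n_clusters) if n_clusters is not None else int(assignments.max()) + 1
    means = np.zeros((K, dfipf_matrix.shape[1]))
    present = np.zeros((K, dfipf_matrix.shape[1]), dtype=bool)
    V = dfipf_matrix.to_numpy()
    n_nonempty = 0
    for c in range(K):
        members = V[assignments == c]
        if members.shape[0]:
            n_nonempty += 1
            means[c] = members.mean(axis=0)
            present[c] = (members > 0).any(axis=0)
    clusters_with = present.sum(axis=0)
    # A column that is all-zero in the DF-IPF matrix belongs to a ubiquitous
    # disease (absent diseases were already dropped upstream): it is present
    # in every nonempty cluster, so its weight is ln(K/K) = 0, not excluded.
    ubiquitous = ~(V > 0).any(axis=0)
    clusters_with = np.where(ubiquitous, n_nonempty, clusters_with)
    absent = [c for c, s in zip(dfipf_matrix.columns, clusters_with) if s == 0]
    if absent:
        logger.info("conditions absent from all clusters excluded from c-DF-IPF: %s", absent)
    keep = clusters_with > 0
    ipf_k = np.zeros(dfipf_matrix.shape[1])
    ipf_k[keep] = np.log(K / clusters_with[keep])
    weights = pd.DataFrame(
        (means * ipf_k[None, :])[:, keep],
        index=range(K),
        columns=[c for c, k in zip(dfipf_matrix.columns, keep) if k],
    )
    return CDFIPFMatrix(weights=weights)


# ---------------------------------------------------------------------------
# Association testing


def z_symbol(z: float) -> str:
    """Symbol scheme used on the cluster-prevalence heatmaps."""
    if z >= 50:
        return "++"
    if z >= 10:
        return "+"
    if z <= -50:
        return "--"
    if z <= -10:
        return "-"
    return ""


@dataclass
class AssociationReport:
    """Per-cluster 1-vs-all association results for one binary variable."""

    table: pd.DataFrame  # columns: cluster, observed, expected, chi2, z, symbol


def chi2_one_vs_all(variable: np.ndarray, assignments: np.ndarray) -> AssociationReport:
    """1-vs-all chi-squared tests of a binary variable across clusters.

    For each cluster a 2x2 table (in-cluster vs rest x present/absent) gives
    a 1-df chi-squared statistic without continuity correction; the signed
    z-score is sign(observed - expected) * sqrt(chi2), where the expectation
    comes from the pooled prevalence.  Zero-margin tables yield z = 0 and
    are flagged in the ``degenerate`` column.
    """
    variable = np.asarray(variable).astype(float)
    assignments = np.asarray(assignments)
    clusters = np.unique(assignments)
    if clusters.size < 2:
        raise ValueError("chi2_one_vs_all requires at least 2 clusters")
    n = variable.size
    total_pos = variable.sum()
    rows = []
    for c in clusters:
        inside = assignments == c
        n_in = int(inside.sum())
        obs = float(variable[inside].sum())
        exp = total_pos * n_in / n
        table = np.array(
            [
                [obs, n_in - obs],
                [total_pos - obs, (n - n_in) - (total_pos - obs)],
            ]
        )
        degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
        if degenerate:
            chi2 = 0.0
            z = 0.0
        else:
            chi2, _, _, _ = stats.chi2_contingency(table, correction=False)
            z = float(np.sign(obs - exp) * np.sqrt(chi2))
        rows.append(
            {
                "cluster": c,
                "observed": obs,
                "expected": exp,
                "chi2": float(chi2),
                "z": z,
                "symbol": z_symbol(z),
                "degenerate": bool(degenerate),
            }
        )
    return AssociationReport(table=pd.DataFrame(rows))


def ttest_one_vs_all(variable: np.ndarray, assignments: np.ndarray) -> pd.DataFrame:
    """Welch two-sample t-test of each cluster against the rest."""
    variable = np.asarray(variable, dtype=float)
    assignments = np.asarray(assignments)
    rows = []
    for c in np.unique(assignments):
        inside = variable[assignments == c]
        outside = variable[assignments != c]
        if inside.size < 2 or outside.size < 2:
            rows.append({"cluster": c, "t": np.nan, "p": np.nan, "degenerate": True})
            continue
        if inside.std() == 0 and outside.std() == 0:
            rows.append({"cluster": c, "t": np.nan, "p": np.nan, "degenerate": True})
            continue
        t, p = stats.ttest_ind(inside, outside, equal_var=False)
        rows.append({"cluster": c, "t": float(t), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)


def observed_expected_exclusivity(
    matrix: DiseaseMatrix, assignments: np.ndarray
) -> pd.DataFrame:
    """Observed/expected prevalence ratio and exclusivity per cluster x condition.

    O/E is in-cluster prevalence over overall prevalence; exclusivity is the
    fraction of all carriers of the condition who belong to the cluster, so
    it sums to 1 over clusters.  Conditions nobody has are excluded.
    """
    X = matrix.values.astype(float)
    assignments = np.asarray(assignments)
    overall = X.mean(axis=0)
    carriers = X.sum(axis=0)
    keep = carriers > 0
    rows = []
    for c in np.unique(assignments):
        inside = assignments == c
        prev = X[inside].mean(axis=0)
        excl = X[inside].sum(axis=0) / np.maximum(carriers, 1.0)
        for j, cond in enumerate(matrix.conditions):
            if not keep[j]:
                continue
            rows.append(
                {
                    "cluster": c,
                    "condition": cond,
                    "observed_expected": prev[j] / overall[j],
                    "exclusivity": excl[j],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Embedding validation and cross-gender comparison


def comorbidity_similarity(
    token_ids: Sequence[str],
    token_vectors: np.ndarray,
    pairs: Sequence[tuple[str, str]],
    n_random_couples: int = 1000,
    seed: int = 0,
) -> dict:
    """Cosine similarity of established comorbidity pairs vs random couples.

    Returns per-pair similarities, their median, and the similarity
    distribution of random non-pair couples for comparison.  Pairs with a
    missing token are skipped with a log entry.
    """
    index = {t: i for i, t in enumerate(token_ids)}
    vecs = np.asarray(token_vectors)
    sims = []
    kept_pairs = []
    for a, b in pairs:
        if a not in index or b not in index:
            logger.info("comorbidity pair (%s, %s) missing an embedding; skipped", a, b)
            continue
        s = float(cosine_similarity(vecs[index[a]][None], vecs[index[b]][None])[0, 0])
        sims.append(s)
        kept_pairs.append((a, b))
    rng = np.random.default_rng(seed)
    pair_set = {frozenset(p) for p in kept_pairs}
    random_sims: list[float] = []
    n_tokens = len(token_ids)
    attempts = 0
    while len(random_sims) < n_random_couples and n_tokens >= 2 and attempts < 20 * n_random_couples:
        attempts += 1
        i, j = rng.choice(n_tokens, size=2, replace=False)
        if frozenset((token_ids[i], token_ids[j])) in pair_set:
            continue
        random_sims.append(
            float(cosine_similarity(vecs[i][None], vecs[j][None])[0, 0])
        )
    return {
        "pairs": kept_pairs,
        "similarities": np.asarray(sims),
        "median": float(np.median(sims)) if sims else np.nan,
        "random_similarities": np.asarray(random_sims),
        "random_median": float(np.median(random_sims)) if random_sims else np.nan,
    }


def crossgender_similarity(
    cdfipf_female: CDFIPFMatrix, cdfipf_male: CDFIPFMatrix
) -> pd.DataFrame:
    """Pearson correlation between female and male cluster c-DF-IPF profiles.

    Profiles are aligned on shared conditions; a constant profile has an
    undefined correlation and yields NaN (flagged by a log entry).
    """
    shared = [c for c in cdfipf_female.weights.columns if c in cdfipf_male.weights.columns]
    if not shared:
        raise ValueError("no shared conditions between the two c-DF-IPF matrices")
    F = cdfipf_female.weights[shared].to_numpy()
    M = cdfipf_male.weights[shared].to_numpy()
    out = np.full((F.shape[0], M.shape[0]), np.nan)
    for i in range(F.shape[0]):
        for j in range(M.shape[0]):
            if F[i].std() == 0 or M[j].std() == 0:
                logger.info("constant c-DF-IPF profile (f%d, m%d); correlation undefined", i, j)
                continue
            out[i, j] = float(np.corrcoef(F[i], M[j])[0, 1])
    return pd.DataFrame(
        out,
        index=[f"female_{i}" for i in range(F.shape[0])],
        columns=[f"male_{j}" for j in range(M.shape[0])],
    )
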