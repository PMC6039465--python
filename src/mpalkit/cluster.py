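"""Methylation clustering: variance-ranked probe selection, consensus
k-means with cophenetic model selection, silhouette analysis, PCA embedding,
platform probe intersection, and joint reference-cohort lineage
classification (AML-like vs ALL-like).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.cluster import KMeans

from .io import BetaMatrix, ProbeManifest

logger = logging.getLogger("mpalkit")


def select_variable_probes(
    beta: BetaMatrix, n: int | None = None, fraction: float | None = None,
    max_missing_fraction: float = 0.2,
) -> list[str]:
    """Top-``n`` (or top-``fraction``) probes by descending standard deviation
    across samples, ties broken by probe_id.  Probes missing in more than
    ``max_missing_fraction`` of samples are excluded from ranking."""
    if (n is None) == (fraction is None):
        raise ValueError("specify exactly one of n or fraction")
    vals = beta.values
    keep = beta.mask.mean(axis=1) <= max_missing_fraction
    vals = vals.loc[keep]
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0,1]")
        n = max(1, int(round(fraction * len(vals))))
    if n < 1:
        raise ValueError("n must be positive")
    if n > len(vals):
        warnings.warn(f"requested {n} probes but only {len(vals)} available; returning all")
        n = len(vals)
    sd = vals.std(axis=1, ddof=1)
    # two-key sort: descending sd, ascending probe_id on ties
    order = sorted(sd.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in order[:n]]


@dataclass
class ConsensusResult:
    k_values: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cophenetic: dict[int, float]
    labels: dict[int, np.ndarray]
    silhouette: np.ndarray = field(default=None)
    chosen_k: int = 0
    sample_ids: list[str] = field(default_factory=list)


def consensus_kmeans(
    beta_subset: BetaMatrix,
    k_range=range(2, 7),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Consensus k-means clustering of samples over a probe subset.

    Per resample, a ``subsample_fraction`` of samples is drawn without
    replacement and clustered with k-means (k-means++ init, one start,
    per-resample seed); the consensus matrix is the co-clustering count over
    the co-sampling count.  Final labels cut an average-linkage dendrogram of
    1 − consensus at each k; the cophenetic coefficient correlates dendrogram
    distances with 1 − consensus, and chosen_k maximizes it.
    """
    X = beta_subset.values.to_numpy(dtype=float).T  # samples × probes
    n = X.shape[0]
    k_values = [k for k in k_range]
    if any(k < 2 or k > n - 1 for k in k_values):
        raise ValueError("k_range must lie within [2, n_samples-1]")
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    m = max(2, int(round(subsample_fraction * n)))
    rng = np.random.default_rng(seed)
    co_counts = {k: np.zeros((n, n)) for k in k_values}
    sampled = np.zeros((n, n))
    for b in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        sampled[np.ix_(idx, idx)] += 1
        for k in k_values:
            km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                        random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(X[idx])
            for c in range(k):
                members = idx[lab == c]
                co_counts[k][np.ix_(members, members)] += 1
    if (sampled == 0).any():
        raise ValueError("some sample pair was never co-sampled; increase n_resamples")
    result = ConsensusResult(
        k_values=k_values, consensus_matrices={}, cophenetic={}, labels={},
        sample_ids=beta_subset.sample_ids,
    )
    for k in k_values:
        cons = co_counts[k] / sampled
        np.fill_diagonal(cons, 1.0)
        cons = np.clip((cons + cons.T) / 2, 0.0, 1.0)
        result.consensus_matrices[k] = cons
        dist = 1.0 - cons
        np.fill_diagonal(dist, 0.0)
        condensed = squareform(dist, checks=False)
        Z = hierarchy.linkage(condensed, method="average")
        coph = hierarchy.cophenet(Z)
        if np.std(condensed) == 0 or np.std(coph) == 0:
            result.cophenetic[k] = 1.0  # degenerate: perfect (constant) agreement
        else:
            result.cophenetic[k] = float(pearsonr(condensed, coph)[0])
        result.labels[k] = hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
    result.chosen_k = max(result.k_values, key=lambda k: result.cophenetic[k])
    dist = 1.0 - result.consensus_matrices[result.chosen_k]
    np.fill_diagonal(dist, 0.0)
    final_labels = result.labels[result.chosen_k]
    if len(np.unique(final_labels)) < 2:
        # degenerate consensus (e.g. identical samples): no separation to score
        result.silhouette = np.zeros(n)
    else:
        result.silhouette = silhouette_widths(dist, final_labels)[0]
    return result


def silhouette_widths(distance: np.ndarray, labels) -> tuple[np.ndarray, dict]:
    """Per-sample silhouette widths S_i = (b_i − a_i)/max(a_i, b_i) from a
    distance matrix, plus per-cluster means.  Singleton clusters get S_i = 0."""
    D = np.asarray(distance, dtype=float)
    labels = np.asarray(labels)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance must be square symmetric with zero diagonal")
    if len(labels) != D.shape[0]:
        raise ValueError("labels length mismatch")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("k must be ≥2 for silhouette analysis")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in clusters if c != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    per_cluster = {c: float(s[labels == c].mean()) for c in clusters}
    return s, per_cluster


def intersect_platforms(manifest: ProbeManifest) -> list[str]:
    """Probes assayed on both the EPIC and HM450 platforms."""
    out = [p.probe_id for p in manifest.probes if {"EPIC", "HM450"} <= p.platforms]
    if not out:
        raise ValueError("no probes shared between EPIC and HM450")
    return out


def pca_embedding(beta: BetaMatrix, n_components: int = 2) -> pd.DataFrame:
    """Plotting embedding: column-centered exact SVD of samples × probes."""
    X = beta.values.to_numpy(dtype=float).T
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = U[:, :n_components] * S[:n_components]
    return pd.DataFrame(
        pcs, index=beta.sample_ids, columns=[f"PC{i+1}" for i in range(pcs.shape[1])]
    )


@dataclass
class LineageClassification:
    labels: pd.Series  # MPAL sample -> AML_like | ALL_like
    cluster_detail: pd.Series  # MPAL sample -> AML | B_ALL | T_ALL
    cluster_assignments: pd.Series  # all samples -> cluster index


def joint_lineage_classify(
    mpal_beta: BetaMatrix,
    reference_betas: dict[str, BetaMatrix],
    n_probes: int = 10_000,
) -> LineageClassification:
    """Classify MPAL methylomes as AML-like or ALL-like by joint clustering
    with reference AML / B-ALL / T-ALL cohorts.

    The matrices are combined on shared probes, the most variable probes are
    selected on the combined set, samples are clustered agglomeratively
    (distance 1 − Pearson, average linkage) and the dendrogram cut at k = 3;
    each cluster takes the majority lineage of its reference members, and
    MPAL samples inherit their cluster's lineage (B_ALL and T_ALL collapse
    to ALL_like).
    """
    expected = {"AML", "B_ALL", "T_ALL"}
    if set(reference_betas) != expected:
        raise ValueError(f"reference lineages must be exactly {sorted(expected)}")
    shared = mpal_beta.values.index
    for rb in reference_betas.values():
        shared = shared.intersection(rb.values.index)
    if len(shared) == 0:
        raise ValueError("no shared probes across cohorts")
    pieces = [mpal_beta.values.loc[shared]]
    origin = [("MPAL", s) for s in mpal_beta.sample_ids]
    for lineage in sorted(reference_betas):
        rb = reference_betas[lineage]
        pieces.append(rb.values.loc[shared].add_suffix(f"|{lineage}"))
        origin.extend((lineage, s) for s in rb.sample_ids)
    combined = pd.concat(pieces, axis=1)
    sub = select_variable_probes(BetaMatrix(combined), n=min(n_probes, len(shared)))
    X = combined.loc[sub].to_numpy(dtype=float).T
    corr = np.corrcoef(X)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    assign = hierarchy.fcluster(Z, t=3, criterion="maxclust") - 1
    origins = np.array([o[0] for o in origin])
    cluster_lineage = {}
    for c in np.unique(assign):
        refs = origins[(assign == c) & (origins != "MPAL")]
        if len(refs) == 0:
            raise ValueError(f"unanchored cluster {c}: contains no reference samples")
        vals, counts = np.unique(refs, return_counts=True)
        cluster_lineage[c] = vals[np.argmax(counts)]
    mpal_idx = [i for i, o in enumerate(origin) if o[0] == "MPAL"]
    detail = pd.Series(
        {origin[i][1]: cluster_lineage[assign[i]] for i in mpal_idx}, name="lineage_cluster"
    )
    labels = detail.map(lambda l: "AML_like" if l == "AML" else "ALL_like").rename("label")
    assignments = pd.Series(
        assign, index=[f"{o[1]}|{o[0]}" if o[0] != "MPAL" else o[1] for o in origin],
        name="cluster",
    )
    return LineageClassification(labels=labels, cluster_detail=detail, cluster_assignments=assignments)
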