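"""Clustering and gene-selection front-ends with external quality indices.

The converged sample representation Z* feeds K-means (each column of Z*
is one sample's representation vector); the feature matrix G* ranks
genes by the energy of their salient component in G* X.  Cluster quality
is measured against known labels by best-bijection accuracy (ACC),
normalized mutual information (NMI, max-normalized) and the pairwise
F-measure, averaged over repeated K-means restarts as mean +/- variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans


@dataclass
class ClusterEval:
    """Per-run labels and aggregated external indices (population variance)."""

    labels_pred: NDArray[np.int64]
    acc: float
    nmi: float
    f_measure: float
    n_runs: int
    acc_mean: float
    acc_var: float
    nmi_mean: float
    nmi_var: float
    f_mean: float
    f_var: float


@dataclass
class GeneRanking:
    gene_ids: list
    scores: NDArray[np.float64]
    order: NDArray[np.int64]

    def top(self, n: int) -> list:
        return [self.gene_ids[i] for i in self.order[:n]]


def _check_labels(truth, pred) -> tuple[NDArray, NDArray]:
    t = np.asarray(truth).ravel()
    p = np.asarray(pred).ravel()
    if t.shape != p.shape:
        raise ValueError(f"label length mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty label sequences")
    return t, p


def _contingency(truth: NDArray, pred: NDArray) -> NDArray[np.int64]:
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    C = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(C, (ti, pi), 1)
    return C


def clustering_accuracy(truth, pred) -> float:
    """Best-map accuracy: match fraction maximized over label bijections.

    The optimal mapping of predicted cluster names onto true class names
    is found by maximum-weight assignment on the contingency table.
    """
    t, p = _check_labels(truth, pred)
    C = _contingency(t, p)
    rows, cols = linear_sum_assignment(C, maximize=True)
    return float(C[rows, cols].sum()) / t.size


def nmi(truth, pred) -> float:
    """Normalized mutual information MI(T, T-hat) / max(H(T), H(T-hat)).

    Degenerate partitions (either entropy zero) score 0 by convention,
    making the index total.
    """
    t, p = _check_labels(truth, pred)
    C = _contingency(t, p).astype(float)
    n = C.sum()
    pij = C / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h_t = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    h_p = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    denom = max(h_t, h_p)
    if denom == 0:
        return 0.0
    nz = pij > 0
    mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    return float(max(mi, 0.0) / denom)


def pairwise_f_measure(truth, pred) -> float:
    """Harmonic mean of pairwise precision and recall over sample pairs.

    TP counts unordered pairs grouped together in both partitions, FP
    pairs grouped only in the prediction, FN pairs grouped only in the
    truth.  Counting is closed-form from the contingency table.
    """
    t, p = _check_labels(truth, pred)
    if t.size < 2:
        raise ValueError("pairwise F-measure needs at least 2 samples")
    C = _contingency(t, p)

    def _pairs(x):
        return float(np.sum(x * (x - 1) // 2))

    tp = _pairs(C)
    pred_pairs = _pairs(C.sum(axis=0))
    true_pairs = _pairs(C.sum(axis=1))
    fp = pred_pairs - tp
    fn = true_pairs - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _spectral_embedding(Z: NDArray, n_components: int) -> NDArray[np.float64]:
    """Row-normalized leading eigenvectors of the symmetrized affinity.

    The affinity is (|Z| + |Z^T|)/2; the embedding uses the smallest
    eigenvectors of the symmetric-normalized Laplacian (Ng-Jordan-Weiss),
    computed by a deterministic dense eigendecomposition.
    """
    W = 0.5 * (np.abs(Z) + np.abs(Z.T))
    np.fill_diagonal(W, 0.0)
    d = W.sum(axis=1)
    d_inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    L_sym = np.eye(W.shape[0]) - (d_inv_sqrt[:, None] * W) * d_inv_sqrt[None, :]
    vals, vecs = np.linalg.eigh(L_sym)
    emb = vecs[:, :n_components]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    return emb / np.where(norms > 0, norms, 1.0)


def cluster_samples(Z_star, n_clusters: int, n_runs: int = 1, seed: int = 0,
                    representation: str = "affinity") -> list[NDArray[np.int64]]:
    """Repeated seeded K-means on the learned sample representation Z*.

    With ``representation="affinity"`` (default), K-means operates on the
    spectral embedding of the symmetrized affinity (|Z*| + |Z*^T|)/2 —
    the standard way low-rank representations are turned into clusters,
    and the one robust to the sign symmetry of linear subspaces.
    ``representation="columns"`` clusters the raw columns of Z* instead
    (each column being one sample's representation vector).

    Runs use distinct deterministic seeds derived from ``seed`` so
    mean/variance aggregation over restarts is reproducible.
    """
    Z = np.asarray(Z_star, dtype=float)
    n = Z.shape[1]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters={n_clusters} outside [1, {n}]")
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    if representation == "affinity":
        if Z.shape[0] != n:
            raise ValueError("affinity representation needs a square Z*")
        points = _spectral_embedding(Z, n_clusters)
    elif representation == "columns":
        points = Z.T
    else:
        raise ValueError(f"unknown representation {representation!r}")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    labels = []
    for s in run_seeds:
        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(s))
        labels.append(km.fit_predict(points).astype(np.int64))
    return labels


def score_genes(G_star, X, method: str = "rows") -> GeneRanking:
    """Rank genes by the energy the feature matrix G* assigns to them.

    ``method="rows"`` (default) scores gene i by the Euclidean norm of
    row i of G* — how strongly the learned feature manifold loads on
    that gene.  ``method="salient"`` scores by the row norms of the
    reconstructed salient component G* X instead.  Ties are broken by
    row index (stable sort), so rankings are deterministic.
    """
    G = np.asarray(G_star, dtype=float)
    values = np.asarray(getattr(X, "values", X), dtype=float)
    if G.shape[1] != values.shape[0]:
        raise ValueError(
            f"shape mismatch: G* is {G.shape}, X has {values.shape[0]} genes"
        )
    if method == "rows":
        scores = np.linalg.norm(G, axis=1)
    elif method == "salient":
        scores = np.linalg.norm(G @ values, axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(-scores, kind="stable")
    gene_ids = list(getattr(X, "gene_ids", range(values.shape[0])))
    return GeneRanking(gene_ids=gene_ids, scores=scores, order=order)


def aggregate_runs(per_run_labels, truth) -> ClusterEval:
    """Score each K-means run and report mean and population variance."""
    if len(per_run_labels) == 0:
        raise ValueError("need at least one run")
    accs = np.array([clustering_accuracy(truth, p) for p in per_run_labels])
    nmis = np.array([nmi(truth, p) for p in per_run_labels])
    fs = np.array([pairwise_f_measure(truth, p) for p in per_run_labels])
    first = np.asarray(per_run_labels[0], dtype=np.int64)
    return ClusterEval(
        labels_pred=first,
        acc=float(accs[0]),
        nmi=float(nmis[0]),
        f_measure=float(fs[0]),
        n_runs=len(per_run_labels),
        acc_mean=float(accs.mean()),
        acc_var=float(accs.var()),
        nmi_mean=float(nmis.mean()),
        nmi_var=float(nmis.var()),
        f_mean=float(fs.mean()),
        f_var=float(fs.var()),
    )
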