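"""Evaluation suite for (real, generated) expression-matrix pairs.

Per-gene mean correlations (Spearman/Pearson), kernel MMD and a PC-wise
Wasserstein distance, neighbourhood mixing (ILISI), QQ quantile tables,
random-forest and KNN real-vs-generated discriminability, and clustering
agreement (ARI/NMI).  Standard estimators are delegated to scipy and
scikit-learn; MMD and ILISI are computed from their definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (adjusted_rand_score, normalized_mutual_info_score,
                             roc_auc_score)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors

from .io_preprocess import ExpressionMatrix, NormalizedMatrix


class MetricError(ValueError):
    """Undefined or infeasible metric computation."""


Matrix = ExpressionMatrix | NormalizedMatrix | np.ndarray


def _values(m: Matrix) -> np.ndarray:
    if isinstance(m, ExpressionMatrix):
        return m.dense()
    if isinstance(m, NormalizedMatrix):
        return m.values
    return np.asarray(m, dtype=float)


# ---------------------------------------------------------------------------
# correlation of per-gene means
# ---------------------------------------------------------------------------

def gene_means(m: Matrix) -> np.ndarray:
    """Per-gene mean expression over cells."""
    x = _values(m)
    if x.shape[0] < 1:
        raise MetricError("empty matrix")
    return x.mean(axis=0)


def scc(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation of two mean-expression vectors.

    Ties get average ranks (Pearson-on-ranks), which coincides with the
    classical 1 - 6 sum d^2 / (n (n^2 - 1)) formula when there are no ties.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise MetricError("need two equal-length vectors of length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise MetricError("Spearman correlation undefined for a constant vector")
    return float(scipy.stats.spearmanr(a, b).statistic)


def pcc(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson product-moment correlation of two mean-expression vectors."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise MetricError("need two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        raise MetricError("Pearson correlation undefined for zero variance")
    return float(scipy.stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# distribution distances
# ---------------------------------------------------------------------------

def _joint_pca(x: np.ndarray, y: np.ndarray, n_pcs: int
               ) -> tuple[np.ndarray, np.ndarray]:
    """Project both samples with a PCA fitted on their concatenation."""
    n_pcs = min(n_pcs, x.shape[1], x.shape[0] + y.shape[0])
    pca = PCA(n_components=n_pcs, random_state=0)
    both = pca.fit_transform(np.vstack([x, y]))
    return both[: len(x)], both[len(x):]


def _rbf_mmd_from_kernel(K: np.ndarray, n: int, m: int, biased: bool) -> float:
    Kxx, Kyy, Kxy = K[:n, :n], K[n:, n:], K[:n, n:]
    if biased:
        return float(Kxx.mean() + Kyy.mean() - 2 * Kxy.mean())
    sx = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
    sy = (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
    return float(sx + sy - 2 * Kxy.mean())


def _pairwise_sq_dists(z: np.ndarray) -> np.ndarray:
    sq = (z ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * z @ z.T
    np.maximum(d2, 0.0, out=d2)
    return d2


def mmd(real: Matrix, gen: Matrix, n_pcs: int = 50, biased: bool = False,
        bandwidth: float | None = None) -> float:
    """Kernel maximum mean discrepancy between the two cell distributions.

    Both samples are projected by a PCA fitted on their concatenation, then
    a Gaussian-kernel MMD is computed (unbiased U-statistic by default)
    with the bandwidth set by the median heuristic on pooled pairwise
    distances unless given.
    """
    x, y = _values(real), _values(gen)
    if x.shape[0] < 2 or y.shape[0] < 2:
        raise MetricError("need at least 2 cells per sample")
    if n_pcs > x.shape[1]:
        raise MetricError(f"n_pcs={n_pcs} exceeds feature count {x.shape[1]}")
    xp, yp = _joint_pca(x, y, n_pcs)
    z = np.vstack([xp, yp])
    d2 = _pairwise_sq_dists(z)
    if bandwidth is None:
        off = d2[np.triu_indices_from(d2, k=1)]
        med = np.median(off)
        bandwidth = np.sqrt(med / 2) if med > 0 else 1.0
    K = np.exp(-d2 / (2 * bandwidth ** 2))
    return _rbf_mmd_from_kernel(K, len(xp), len(yp), biased)


def mmd_permutation_test(real: Matrix, gen: Matrix, n_pcs: int = 50,
                         n_perms: int = 200, seed: int = 0,
                         biased: bool = False) -> tuple[float, np.ndarray]:
    """Observed MMD plus its label-permutation null distribution.

    The kernel matrix is computed once on the pooled projection; each
    permutation reshuffles the sample assignment, which makes the 200-draw
    null cheap.
    """
    x, y = _values(real), _values(gen)
    xp, yp = _joint_pca(x, y, min(n_pcs, x.shape[1]))
    z = np.vstack([xp, yp])
    d2 = _pairwise_sq_dists(z)
    off = d2[np.triu_indices_from(d2, k=1)]
    med = np.median(off)
    bw = np.sqrt(med / 2) if med > 0 else 1.0
    K = np.exp(-d2 / (2 * bw ** 2))
    n, m = len(xp), len(yp)
    observed = _rbf_mmd_from_kernel(K, n, m, biased)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms)
    for i in range(n_perms):
        perm = rng.permutation(n + m)
        Kp = K[np.ix_(perm, perm)]
        null[i] = _rbf_mmd_from_kernel(Kp, n, m, biased)
    return observed, null


def wasserstein(real: Matrix, gen: Matrix, n_pcs: int = 50) -> float:
    """Mean 1-D Wasserstein-1 distance over the leading joint PCs.

    The sliced, PC-wise form is a declared convention of this package: it
    is deterministic, cheap, and decreases as the generated distribution
    approaches the real one.
    """
    x, y = _values(real), _values(gen)
    xp, yp = _joint_pca(x, y, min(n_pcs, x.shape[1]))
    dists = [scipy.stats.wasserstein_distance(xp[:, j], yp[:, j])
             for j in range(xp.shape[1])]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# neighbourhood mixing
# ---------------------------------------------------------------------------

def ilisi(real: Matrix, gen: Matrix, k_neighbors: int = 30,
          n_pcs: int = 50) -> float:
    """Mean local inverse Simpson index of real/generated mixing in [0, 1].

    Cells are pooled with a real/generated batch label and projected by a
    joint PCA; for each cell the inverse Simpson index 1 / sum_b p_b^2 is
    computed over the batch proportions among its k nearest neighbours and
    min-max normalized as (value - 1) / (B - 1) with B = 2 batches.  Values
    above 0.5 indicate well-interleaved samples; 0 means every
    neighbourhood is single-batch.
    """
    x, y = _values(real), _values(gen)
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise MetricError("both samples must be non-empty")
    if x.shape[0] + y.shape[0] < k_neighbors + 1:
        raise MetricError("not enough pooled cells for k_neighbors")
    xp, yp = _joint_pca(x, y, min(n_pcs, x.shape[1]))
    z = np.vstack([xp, yp])
    batch = np.r_[np.zeros(len(xp), int), np.ones(len(yp), int)]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(z)
    _, idx = nn.kneighbors(z)
    neigh_batch = batch[idx[:, 1:]]          # exclude self
    p1 = neigh_batch.mean(axis=1)
    simpson = p1 ** 2 + (1 - p1) ** 2
    inv = 1.0 / simpson
    return float(np.mean(inv - 1.0))         # (inv - 1) / (B - 1), B = 2


# ---------------------------------------------------------------------------
# quantiles
# ---------------------------------------------------------------------------

def zscore_matrix(values: np.ndarray) -> np.ndarray:
    """Z-score over the entire matrix (single global mean and sd)."""
    v = np.asarray(values, dtype=float)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def qq_quantiles(real_col: np.ndarray, gen_col: np.ndarray,
                 n_quantiles: int = 100) -> np.ndarray:
    """Paired quantiles of two (typically z-scored) vectors.

    Returns an (n_quantiles, 2) array of (q_real, q_gen) at evenly spaced
    probability levels; identical distributions give points on y = x.
    """
    a, b = np.asarray(real_col, float), np.asarray(gen_col, float)
    if a.size == 0 or b.size == 0:
        raise MetricError("empty vector")
    probs = np.linspace(0, 1, n_quantiles)
    return np.column_stack([np.quantile(a, probs), np.quantile(b, probs)])


# ---------------------------------------------------------------------------
# discriminability
# ---------------------------------------------------------------------------

def rf_discriminability(real: Matrix, gen: Matrix, n_folds: int = 5,
                        seed: int = 0, n_estimators: int = 100
                        ) -> dict[str, Any]:
    """Stratified k-fold random-forest real-vs-generated classification.

    Accuracy near 0.5 means the classifier cannot tell the samples apart.
    Returns mean accuracy, AUC, the per-fold trace, and the pooled
    confusion counts (TP/TN/FP/FN with 'real' as the positive class).
    """
    x, y = _values(real), _values(gen)
    if min(len(x), len(y)) < n_folds:
        raise MetricError(f"need >= {n_folds} cells per class for {n_folds} folds")
    X = np.vstack([x, y])
    lab = np.r_[np.ones(len(x), int), np.zeros(len(y), int)]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs, aucs = [], []
    tp = tn = fp = fn = 0
    for tr, te in skf.split(X, lab):
        clf = RandomForestClassifier(n_estimators=n_estimators,
                                     random_state=seed, n_jobs=1)
        clf.fit(X[tr], lab[tr])
        pred = clf.predict(X[te])
        prob = clf.predict_proba(X[te])[:, 1]
        accs.append(float(np.mean(pred == lab[te])))
        aucs.append(float(roc_auc_score(lab[te], prob)))
        tp += int(((pred == 1) & (lab[te] == 1)).sum())
        tn += int(((pred == 0) & (lab[te] == 0)).sum())
        fp += int(((pred == 1) & (lab[te] == 0)).sum())
        fn += int(((pred == 0) & (lab[te] == 1)).sum())
    return {"accuracy": float(np.mean(accs)), "auc": float(np.mean(aucs)),
            "fold_accuracies": accs,
            "confusion": {"tp": tp, "tn": tn, "fp": fp, "fn": fn}}


def knn_discriminability(real: Matrix, gen: Matrix, train_frac: float = 0.7,
                         k: int = 5, seed: int = 0) -> dict[str, Any]:
    """70/30 split KNN real-vs-generated classification (accuracy + AUC)."""
    x, y = _values(real), _values(gen)
    X = np.vstack([x, y])
    lab = np.r_[np.ones(len(x), int), np.zeros(len(y), int)]
    Xtr, Xte, ytr, yte = train_test_split(
        X, lab, train_size=train_frac, random_state=seed, stratify=lab)
    if k > len(Xtr):
        raise MetricError(f"k={k} exceeds training-set size {len(Xtr)}")
    clf = KNeighborsClassifier(n_neighbors=k)
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    prob = clf.predict_proba(Xte)[:, 1]
    return {"accuracy": float(np.mean(pred == yte)),
            "auc": float(roc_auc_score(yte, prob)),
            "n_test": int(len(yte))}


# ---------------------------------------------------------------------------
# clustering agreement
# ---------------------------------------------------------------------------

def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index (contingency-table closed form)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise MetricError("label vectors differ in length")
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information 2 I(U;V) / (H(U) + H(V))."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise MetricError("label vectors differ in length")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def kmeans_cluster(m: Matrix, n_clusters: int, n_pcs: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Convenience clustering hook (k-means on leading PCs).

    The evaluation suite accepts externally produced cluster labels (e.g.
    Leiden partitions); this hook exists so ARI/NMI can be filled without
    an external tool.
    """
    x = _values(m)
    n_pcs = min(n_pcs, x.shape[1], x.shape[0])
    from sklearn.cluster import KMeans

    proj = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    return KMeans(n_clusters=n_clusters, random_state=seed, n_init=10
                  ).fit_predict(proj)


# ---------------------------------------------------------------------------
# aggregate report
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """All suite metrics for one (real, generated) pair, plus settings."""

    scc: float
    pcc: float
    mmd: float
    ilisi: float
    wasserstein: float
    rf_accuracy: float
    knn_accuracy: float
    auc: float
    ari: float | None
    nmi: float | None
    settings: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def evaluate(real: ExpressionMatrix | NormalizedMatrix,
             gen: ExpressionMatrix | NormalizedMatrix,
             n_pcs: int = 50, k_neighbors: int = 30, knn_k: int = 5,
             n_folds: int = 5, seed: int = 0,
             cluster_labels: np.ndarray | None = None) -> MetricsReport:
    """Run the full suite on a (real, generated) pair with matched genes.

    ARI/NMI compare a clustering of the generated cells against their own
    attribute labels: ``cluster_labels`` may supply an external partition
    (e.g. Leiden); otherwise a k-means hook with one cluster per label
    level is used.  They are None when the generated matrix carries no
    labels.
    """
    if list(real.gene_ids) != list(gen.gene_ids):
        missing = set(real.gene_ids) ^ set(gen.gene_ids)
        raise MetricError(f"gene sets differ; mismatched: {sorted(missing)[:10]}")
    xm, ym = gene_means(real), gene_means(gen)
    rf = rf_discriminability(real, gen, n_folds=n_folds, seed=seed)
    knn = knn_discriminability(real, gen, k=knn_k, seed=seed)

    ari_v = nmi_v = None
    gen_labels = gen.combined_labels() if gen.labels else None
    if gen_labels is not None:
        if cluster_labels is None:
            n_clusters = len(set(gen_labels.tolist()))
            cluster_labels = kmeans_cluster(gen, n_clusters, n_pcs=n_pcs,
                                            seed=seed)
        ari_v = ari(cluster_labels, gen_labels)
        nmi_v = nmi(cluster_labels, gen_labels)

    return MetricsReport(
        scc=scc(xm, ym),
        pcc=pcc(xm, ym),
        mmd=mmd(real, gen, n_pcs=min(n_pcs, real.n_genes)),
        ilisi=ilisi(real, gen, k_neighbors=k_neighbors, n_pcs=n_pcs),
        wasserstein=wasserstein(real, gen, n_pcs=n_pcs),
        rf_accuracy=rf["accuracy"],
        knn_accuracy=knn["accuracy"],
        auc=rf["auc"],
        ari=ari_v,
        nmi=nmi_v,
        settings={"n_pcs": n_pcs, "k_neighbors": k_neighbors, "knn_k": knn_k,
                  "n_folds": n_folds, "seed": seed,
                  "mmd_estimator": "unbiased", "bandwidth": "median"},
    )
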