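"""Permutation enrichment, k-NN tissue scores and label-transfer filtering.

Cluster-level enrichment of an attribute (an isotype call, a tissue of
origin, a sample id) is tested by shuffling the per-cell attribute labels
and recomputing the in-cluster attribute proportion; the empirical p uses
the add-one rule so it is never zero.  Local tissue composition in an
embedding is summarised by the fraction of each cell's k nearest
neighbours carrying a reference tissue label.  Cells mapped onto a
reference atlas are filtered by label-transfer confidence, the gap
between the top two prediction scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "EnrichmentResult",
    "permutation_enrichment",
    "knn_tissue_score",
    "label_transfer_confidence",
    "nearest_centroid_scores",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Permutation-test summary for one (cluster, attribute) pair."""

    cluster: object
    attribute: object
    observed_proportion: float
    observed_fold: float         # observed / mean(null proportions)
    p_empirical: float           # (1 + #{null >= observed}) / (n_perm + 1)
    n_perm: int
    null_quantiles: tuple[float, float, float]  # 2.5 / 50 / 97.5 percentiles

    @property
    def log2_fold(self) -> float:
        return float(np.log2(self.observed_fold))


def permutation_enrichment(cells: pd.DataFrame, cluster, attribute_value,
                           cluster_col: str = "cluster",
                           attribute_col: str = "dominant_isotype",
                           n_perm: int = 10_000, seed: int | None = None,
                           permute_unit: str = "cell",
                           sample_col: str = "sample_id",
                           two_sided: bool = False) -> EnrichmentResult:
    """Permutation test for enrichment of an attribute within one cluster.

    The observed statistic is the proportion of cells in ``cluster`` whose
    ``attribute_col`` equals ``attribute_value``.  The null shuffles labels
    ``n_perm`` times: ``permute_unit="cell"`` shuffles the per-cell
    attribute labels (the shuffle used for per-cell sample/isotype labels);
    ``permute_unit="sample"`` permutes the sample-to-attribute assignment,
    keeping cells of a sample together.  One-sided enrichment p by default;
    ``two_sided`` doubles it (capped at 1).
    """
    if cluster_col not in cells.columns or attribute_col not in cells.columns:
        raise ValueError("cluster/attribute columns missing")
    if cells[attribute_col].nunique() < 2:
        raise ValueError("need >= 2 distinct attribute values")
    in_cluster = (cells[cluster_col] == cluster).to_numpy()
    k = int(in_cluster.sum())
    if k == 0:
        raise ValueError(f"cluster {cluster!r} absent")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; empirical p resolution is coarse")
    rng = np.random.default_rng(seed)
    positive = (cells[attribute_col] == attribute_value).to_numpy()
    observed = positive[in_cluster].mean()

    null = np.empty(n_perm)
    if permute_unit == "cell":
        n = len(cells)
        for i in range(n_perm):
            null[i] = positive[rng.choice(n, k, replace=False)].mean()
    elif permute_unit == "sample":
        if sample_col not in cells.columns:
            raise ValueError("sample-level permutation needs a sample column")
        samples = cells[sample_col].to_numpy()
        uniq = pd.unique(samples)
        # attribute value per sample (must be constant within sample)
        sample_attr = {}
        for s in uniq:
            vals = pd.unique(cells.loc[cells[sample_col] == s, attribute_col])
            if len(vals) != 1:
                raise ValueError("attribute varies within a sample; "
                                 "use permute_unit='cell'")
            sample_attr[s] = vals[0]
        attr_vec = np.array([sample_attr[s] == attribute_value for s in uniq])
        sample_idx = pd.Series(np.arange(len(uniq)), index=uniq)[samples].to_numpy()
        in_cluster_idx = sample_idx[in_cluster]
        for i in range(n_perm):
            null[i] = attr_vec[rng.permutation(len(uniq))][in_cluster_idx].mean()
    else:
        raise ValueError(f"unknown permute_unit {permute_unit!r}")

    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    if two_sided:
        p = min(1.0, 2 * p)
    null_mean = float(null.mean())
    fold = observed / null_mean if null_mean > 0 else np.inf
    q = np.percentile(null, [2.5, 50, 97.5])
    return EnrichmentResult(cluster, attribute_value, float(observed),
                            float(fold), float(p), n_perm,
                            (float(q[0]), float(q[1]), float(q[2])))


def knn_tissue_score(coords: np.ndarray, tissue_labels, reference,
                     k: int = 200, scaled: bool = False) -> np.ndarray:
    """Fraction of each cell's k nearest neighbours from the reference tissue.

    Euclidean neighbours in the provided embedding, excluding the cell
    itself; coordinate ties are broken by index.  With ``scaled=True`` the
    score is mapped piecewise-linearly so the global reference-tissue
    fraction lands at 0.5 (the display convention for two-colour plots).
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(tissue_labels)
    n = len(coords)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    is_ref = (labels == reference).astype(float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = idx[:, 1:]  # drop self (first neighbour at distance 0)
    # self can land later among exact-duplicate coordinates; mask it out
    self_mask = neigh == np.arange(n)[:, None]
    if self_mask.any():
        neigh = np.where(self_mask, idx[:, :1], neigh)
    scores = is_ref[neigh].mean(axis=1)
    if not scaled:
        return scores
    f = is_ref.mean()
    if f in (0.0, 1.0):
        return scores
    out = np.where(scores <= f, 0.5 * scores / f, 0.5 + 0.5 * (scores - f) / (1 - f))
    return out


def label_transfer_confidence(score_rows: np.ndarray,
                              labels=None) -> pd.DataFrame:
    """Per-cell label-transfer confidence and top-quartile filter.

    Confidence is the gap between the highest and second-highest prediction
    scores.  ``keep_top_quartile`` flags cells whose confidence reaches the
    75th percentile across cells (ties kept).
    """
    scores = np.asarray(score_rows, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("each cell needs at least two prediction scores")
    order = np.argsort(scores, axis=1)
    top_idx = order[:, -1]
    confidence = (scores[np.arange(len(scores)), top_idx]
                  - scores[np.arange(len(scores)), order[:, -2]])
    threshold = np.percentile(confidence, 75)
    if labels is None:
        labels = np.arange(scores.shape[1])
    labels = np.asarray(labels)
    return pd.DataFrame({
        "confidence": confidence,
        "top_label": labels[top_idx],
        "keep_top_quartile": confidence >= threshold,
    })


def nearest_centroid_scores(features: np.ndarray, centroids: np.ndarray,
                            temperature: float = 1.0) -> np.ndarray:
    """Softmax-of-negative-distance prediction scores (rows sum to 1).

    A deliberately simple nearest-centroid classifier used to produce
    label-transfer-style score vectors for testing and simulation; it is
    not a reference-atlas mapping method.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    d = np.linalg.norm(features[:, None, :] - centroids[None, :, :], axis=2)
    logits = -d / temperature
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)
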