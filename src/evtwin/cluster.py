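"""Unsupervised evaluation of replicate / twin resolution.

Quantifies how well a probe panel separates biological units: if evCpG
variation is real inter-individual signal (not measurement error), technical
replicates of one individual must cluster together; genetically driven
negative-control probes instead group samples by chip batch.  Scoring uses
the adjusted Rand index and cluster purity against a known label scheme, at
k = the number of truth groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score


@dataclass
class ClusterScore:
    ari: float
    purity: float
    k: int
    grouping: str


def hierarchical_clustering(
    beta: pd.DataFrame, k: int, distance: str = "euclidean", linkage_method: str = "average"
):
    """Agglomerative clustering of sample columns.

    Returns ``(tree, labels)``: the scipy linkage matrix and flat integer
    labels from cutting the tree into exactly ``k`` clusters.
    """
    if beta.shape[1] < 2 or beta.shape[0] < 1:
        raise ValueError("need at least 2 samples and 1 probe")
    if not 1 <= k <= beta.shape[1]:
        raise ValueError(f"k={k} out of range for {beta.shape[1]} samples")
    if linkage_method not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    x = beta.to_numpy(dtype=float).T
    tree = linkage(pdist(x, metric=distance), method=linkage_method)
    labels = fcluster(tree, t=k, criterion="maxclust")
    return tree, labels


def replicate_recovery_score(labels, truth, grouping: str = "individual") -> ClusterScore:
    """Adjusted Rand index and purity of flat labels against truth labels."""
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if len(labels) != len(truth):
        raise ValueError("label vectors have different lengths")
    ari = float(adjusted_rand_score(truth, labels))
    purity = 0.0
    for lab in np.unique(labels):
        members = truth[labels == lab]
        _, counts = np.unique(members, return_counts=True)
        purity += counts.max()
    purity /= len(labels)
    return ClusterScore(ari=ari, purity=float(purity), k=len(np.unique(labels)), grouping=grouping)


def select_negative_controls(manifest: pd.DataFrame, n: int, available=None) -> list:
    """The ``n`` most significant reported mQTL probes (rank 1 = best).

    Genetically controlled probes are the natural negative control: co-twins
    share genotype, so these loci must not resolve individuals.  Ties at the
    cutoff are broken by probe id, lexicographically.
    """
    if n == 0:
        return []
    man = manifest.dropna(subset=["mqtl_rank"])
    if available is not None:
        man = man[man["probe_id"].isin(set(available))]
    if len(man) < n:
        raise ValueError(f"only {len(man)} mQTL-annotated probes available, need {n}")
    man = man.sort_values(["mqtl_rank", "probe_id"], kind="stable")
    return man["probe_id"].head(n).tolist()


def classical_mds(beta: pd.DataFrame, k: int = 2):
    """Classical (Torgerson) multi-dimensional scaling of sample columns.

    Double-centers the squared Euclidean distance matrix and embeds on the
    top-``k`` eigenvectors.  Coordinates are centered; each axis is signed so
    its first nonzero loading is positive.  All-equal input yields zero
    coordinates and ``degenerate=True``.
    """
    if beta.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = beta.to_numpy(dtype=float).T
    n = x.shape[0]
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    degenerate = bool(np.allclose(vals, 0.0))
    coords -= coords.mean(axis=0)
    for dim in range(coords.shape[1]):
        nz = np.nonzero(np.abs(coords[:, dim]) > 1e-12)[0]
        if len(nz) and coords[nz[0], dim] < 0:
            coords[:, dim] *= -1
    out = pd.DataFrame(coords, index=beta.columns, columns=[f"mds{i + 1}" for i in range(k)])
    out.attrs["degenerate"] = degenerate
    return out


def save_mds_plot(coords: pd.DataFrame, path, labels=None):
    """Scatter the first two MDS axes to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if labels is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=12)
    else:
        for lab in pd.unique(pd.Series(labels)):
            mask = np.asarray(labels) == lab
            ax.scatter(coords.iloc[mask, 0], coords.iloc[mask, 1], s=12, label=str(lab))
        ax.legend(fontsize=7)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
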