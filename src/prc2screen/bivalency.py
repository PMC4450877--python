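"""Unsupervised promoter chromatin states and their link to PRC2 response.

K-means (k = 10 by default) on concatenated, per-bin standardized
H3K27me3 and H3K4me3 promoter signal partitions genes into chromatin
states; clusters are then re-indexed as CIDs in decreasing order of the
mean expression log2 fold change after SUZ12 knockdown, so CID 1 holds
the most derepressed genes.  Summaries compare the proportion of
siSUZ12-induced genes in CIDs 1-4 versus 5-k, optionally restricted to a
focal pathway, against random-gene-set background profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .chromatin import PromoterSignalMatrix


@dataclass
class BivalencyClustering:
    """Raw K-means assignment plus response-ordered CIDs (1 = most induced)."""

    assignments: pd.DataFrame   # index gene; columns raw_cluster, cid
    cluster_means: pd.Series    # mean siSUZ12 log2FC per CID, non-increasing
    cluster_sizes: pd.Series    # genes per CID
    k: int

    def genes_in_cids(self, cids) -> list[str]:
        mask = self.assignments["cid"].isin(list(cids))
        return list(self.assignments.index[mask])

    def to_tsv(self) -> str:
        lines = ["gene\traw_cluster\tcid"]
        for gene, row in self.assignments.iterrows():
            lines.append(f"{gene}\t{row['raw_cluster']}\t{row['cid']}")
        return "\n".join(lines) + "\n"


def bivalency_features(
    k27: PromoterSignalMatrix, k4: PromoterSignalMatrix
) -> pd.DataFrame:
    """Concatenate per-bin z-scored signal for the two marks.

    Each bin column is standardized within its mark (columns with zero
    variance become all-zero) so the marks' different dynamic ranges do
    not dominate the Euclidean geometry.
    """
    if not k27.values.index.equals(k4.values.index):
        raise ValueError("gene sets of the two marks differ")

    def zscore(df: pd.DataFrame, prefix: str) -> pd.DataFrame:
        arr = df.to_numpy(dtype=float)
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=0)
        out = np.where(sd > 0, (arr - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        cols = [f"{prefix}_{i}" for i in range(arr.shape[1])]
        return pd.DataFrame(out, index=df.index, columns=cols)

    return pd.concat(
        [zscore(k27.values, k27.mark), zscore(k4.values, k4.mark)], axis=1
    )


def kmeans_cluster(
    features: pd.DataFrame, k: int, seed: int = 0, n_restarts: int = 50
) -> pd.Series:
    """Lloyd K-means, Euclidean, best inertia over seeded restarts."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(features):
        raise ValueError("k exceeds the number of genes")
    km = KMeans(
        n_clusters=k,
        n_init=n_restarts,
        random_state=seed % (2**31),
        algorithm="lloyd",
    )
    labels = km.fit_predict(features.to_numpy(dtype=float))
    return pd.Series(labels, index=features.index, name="raw_cluster")


def assign_cids(raw: pd.Series, log2fc: pd.Series) -> BivalencyClustering:
    """Re-index raw clusters as CIDs by decreasing mean siSUZ12 log2FC.

    Ties between equal cluster means break by raw cluster index.  The
    resulting CID sequence 1..k has non-increasing mean log2FC by
    construction (asserted).
    """
    fc = log2fc.reindex(raw.index)
    if fc.isna().any() or not np.isfinite(fc.to_numpy()).all():
        raise ValueError("every clustered gene needs a finite log2FC")
    means = fc.groupby(raw).mean()
    order = sorted(means.index, key=lambda c: (-means[c], c))
    cid_of_raw = {c: i + 1 for i, c in enumerate(order)}
    cids = raw.map(cid_of_raw)
    assignments = pd.DataFrame({"raw_cluster": raw, "cid": cids})
    cluster_means = pd.Series(
        [means[c] for c in order], index=range(1, len(order) + 1), name="mean_log2fc"
    )
    assert (np.diff(cluster_means.to_numpy()) <= 1e-12).all()
    sizes = cids.value_counts().reindex(cluster_means.index, fill_value=0)
    return BivalencyClustering(
        assignments=assignments,
        cluster_means=cluster_means,
        cluster_sizes=sizes,
        k=len(order),
    )


def induced_proportion_by_cid(
    clustering: BivalencyClustering,
    induced: pd.Series,
    split: int = 4,
    restrict_to: list[str] | None = None,
) -> dict[str, float | None]:
    """Proportion of induced genes in CIDs 1..split vs split+1..k.

    ``induced`` is the boolean siSUZ12-induced flag (differential
    probability > 0.9 and log2FC > 0).  ``restrict_to`` limits the
    denominator to a pathway's members.  An empty CID group yields None.
    """
    genes = clustering.assignments.index
    flags = induced.reindex(genes)
    if flags.isna().any():
        raise ValueError("induced flag missing for some clustered genes")
    if restrict_to is not None:
        keep = genes.intersection(restrict_to)
        genes = keep
    cid = clustering.assignments.loc[genes, "cid"]
    flags = flags.loc[genes]
    out: dict[str, float | None] = {}
    for name, mask in (
        (f"cid_1_{split}", cid <= split),
        (f"cid_{split + 1}_{clustering.k}", cid > split),
    ):
        n = int(mask.sum())
        out[name] = None if n == 0 else float(flags[mask].sum() / n)
    return out


def random_geneset_profile(
    matrix: PromoterSignalMatrix,
    n_sets: int,
    set_size: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Background: mean profile of random gene sets drawn without replacement.

    Returns (mean-of-means curve, per-set mean curves of shape
    (n_sets, n_bins)).  ``set_size`` conventionally defaults upstream to
    the median size of the comparison groups.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    n_genes = len(matrix.values)
    if set_size > n_genes:
        raise ValueError("set_size exceeds the gene count")
    rng = np.random.default_rng(seed)
    arr = matrix.values.to_numpy(dtype=float)
    curves = np.empty((n_sets, arr.shape[1]))
    for i in range(n_sets):
        idx = rng.choice(n_genes, size=set_size, replace=False)
        curves[i] = arr[idx].mean(axis=0)
    return curves.mean(axis=0), curves
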