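"""Cross-sample structure: profile clustering and cytoband enrichment.

Clustering uses the correlation dissimilarity d = 1 − Pearson r between
per-probe log2 values and Ward aggregation (Lance–Williams recursion on the
precomputed dissimilarities, as in the classical hclust usage).  Enrichment is
a transparent hypergeometric test of a differential gene list against a
background, per cytoband, with Benjamini–Hochberg correction — a simplified,
self-contained stand-in for web-service gene-set enrichment, not a
reproduction of any particular service.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .normalization import Log2Profile
from .probe_io import GenomeAnnotation
from .segmentation import SegmentedProfile


@dataclass
class ClusterResult:
    sample_ids: list[str]
    linkage: np.ndarray  # scipy (n-1, 4) merge records
    distance: str = "pearson"
    method: str = "ward"

    def cut(self, n_clusters: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights, leaves = sample ids."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = rec(tree.left, tree.dist)
        right = rec(tree.right, tree.dist)
        return f"({left},{right});"


def _profile_matrix(profiles: list[Log2Profile],
                    segmented: list[SegmentedProfile] | None) -> np.ndarray:
    n = len(profiles[0])
    ids = profiles[0].probes["probe_id"]
    for p in profiles[1:]:
        if len(p) != n or not p.probes["probe_id"].equals(ids):
            raise ValueError("profiles must share one probe universe")
    if segmented is None:
        return np.vstack([p.values for p in profiles])
    return np.vstack([s.expand_to_probes(n) for s in segmented])


def cluster_profiles(profiles: list[Log2Profile],
                     segmented: list[SegmentedProfile] | None = None) -> ClusterResult:
    """Hierarchical clustering of log2 profiles (1 − Pearson r, Ward).

    By default clusters on per-probe values; pass matching ``segmented``
    profiles to cluster on segment-mean-expanded values instead.  Constant
    profiles have no defined correlation and are rejected by name.
    """
    if len(profiles) < 3:
        raise ValueError("clustering needs >= 3 profiles")
    mat = _profile_matrix(profiles, segmented)
    sds = mat.std(axis=1)
    for p, sd in zip(profiles, sds):
        if sd == 0:
            raise ValueError(f"constant profile {p.sample_id!r}: Pearson r undefined")
    corr = np.corrcoef(mat)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return ClusterResult([p.sample_id for p in profiles], Z)


def map_genes_to_bands(genes: list[str], ann: GenomeAnnotation) -> dict[str, set[str]]:
    """gene symbol -> set of cytoband names its interval overlaps (>= 1 bp)."""
    coords: dict[str, list[tuple[str, int, int]]] = {}
    for chrom, start, end, name in ann.all_intervals("gene"):
        coords.setdefault(name, []).append((chrom, start, end))
    out: dict[str, set[str]] = {}
    for g in genes:
        bands: set[str] = set()
        for chrom, start, end in coords.get(g, []):
            bands.update(ann.names("cytoband", chrom, start, end))
        if bands:
            out[g] = bands
    return out


def cytoband_enrichment(query: list[str], background: list[str],
                        ann: GenomeAnnotation) -> pd.DataFrame:
    """Hypergeometric cytoband enrichment of ``query`` against ``background``.

    For each band containing at least one query gene: k = query genes in the
    band, K = mappable query size, n = background genes in the band, N =
    mappable background size; p is the upper hypergeometric tail P(X >= k) and
    p_adj the Benjamini–Hochberg adjustment across tested bands.  Rows are
    sorted by p.  A gene overlapping several bands counts in each.
    """
    query_set = set(query)
    if not query_set <= set(background):
        raise ValueError("query must be a subset of background")
    cols = ["cytoband", "k", "K", "n", "N", "p", "p_adj"]
    if not query_set:
        return pd.DataFrame(columns=cols)
    bg_bands = map_genes_to_bands(sorted(set(background)), ann)
    N = len(bg_bands)
    K = sum(1 for g in query_set if g in bg_bands)
    if K == 0:
        return pd.DataFrame(columns=cols)
    band_bg: dict[str, int] = {}
    band_q: dict[str, int] = {}
    for g, bands in bg_bands.items():
        for band in bands:
            band_bg[band] = band_bg.get(band, 0) + 1
            if g in query_set:
                band_q[band] = band_q.get(band, 0) + 1
    rows = []
    for band, k in band_q.items():
        n = band_bg[band]
        p = float(hypergeom.sf(k - 1, N, n, K))
        rows.append({"cytoband": band, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values(["p", "cytoband"], kind="stable").reset_index(drop=True)
    return df[cols]
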