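"""Binary allelic fingerprints and hierarchical clustering of individuals.

Each individual is encoded as a fixed-order bit vector over a selected set
of variants (1 = carries at least one alternate allele; an optional diploid
mode keeps the 0/1/2 allele counts). Distances are the sum of absolute
differences between fingerprints — Hamming counts in binary mode — and
individuals are clustered by complete linkage. Cutting the dendrogram at a
bit depth yields clusters; per-cluster variant enrichment is the base-2
log ratio of carrier frequencies inside vs. outside the cluster, reported
as enriched/depleted past a +/-0.6 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skbio.tree import TreeNode

from famvar.containers import VariantTable

__all__ = [
    "build_fingerprints",
    "fingerprint_distance",
    "Dendrogram",
    "cluster_individuals",
    "cut_clusters",
    "count_identical_pairs",
    "cluster_variant_enrichment",
    "ENRICHMENT_THRESHOLD",
]

#: log2 carrier-frequency ratio past which a variant is enriched/depleted
ENRICHMENT_THRESHOLD = 0.6


def build_fingerprints(table: VariantTable, selection=None,
                       mode: str = "binary") -> pd.DataFrame:
    """Individuals x variants fingerprint matrix.

    ``selection`` is an optional predicate over variant records (e.g.
    ``lambda v: v.consequence != "missense"`` for a loss-of-function
    fingerprint). Variant columns are ordered by (protein, position, alt)
    so the encoding is deterministic. ``mode`` is "binary" (carrier bits)
    or "diploid" (allele counts).
    """
    if mode not in ("binary", "diploid"):
        raise ValueError(f"unknown fingerprint mode {mode!r}")
    selected = table if selection is None else table.subset(selection)
    if len(selected) == 0:
        raise ValueError("fingerprint selection is empty")
    gt = selected.genotypes().T  # individuals x variants
    if mode == "binary":
        gt = (gt > 0).astype(np.int8)
    names = [f"{v.protein}:{v.position}:{v.alt_residue}"
             for v in selected.variants]
    return pd.DataFrame(gt, index=selected.individuals, columns=names)


def fingerprint_distance(a, b) -> int:
    """Sum of absolute differences between two fingerprints."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("fingerprints differ in length")
    return int(np.abs(a - b).sum())


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over individual fingerprints."""

    linkage_matrix: np.ndarray
    labels: list[str]

    def to_newick(self) -> str:
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def cluster_individuals(fingerprints: pd.DataFrame) -> Dendrogram:
    """Complete-linkage hierarchical clustering on city-block distances."""
    if len(fingerprints) < 2:
        raise ValueError("need at least two individuals to cluster")
    d = pdist(fingerprints.to_numpy(), metric="cityblock")
    z = linkage(d, method="complete")
    return Dendrogram(z, list(fingerprints.index))


def cut_clusters(dendrogram: Dendrogram, depth: float) -> pd.Series:
    """Cluster assignment after removing merges above ``depth`` bits."""
    if depth < 0:
        raise ValueError("depth must be non-negative")
    labels = fcluster(dendrogram.linkage_matrix, t=depth,
                      criterion="distance")
    return pd.Series(labels, index=dendrogram.labels, name="cluster")


def count_identical_pairs(fingerprints: pd.DataFrame) -> int:
    """Unordered pairs of individuals at fingerprint distance zero."""
    _, counts = np.unique(fingerprints.to_numpy(), axis=0,
                          return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def cluster_variant_enrichment(
    fingerprints: pd.DataFrame,
    assignment: pd.Series,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> pd.DataFrame:
    """Per-cluster enriched/depleted variants by carrier-frequency log odds.

    For each (cluster, variant): log2 of the carrier frequency inside the
    cluster over the frequency in the rest of the population. Values >= to
    the threshold are "enriched", <= -threshold "depleted". Frequencies of
    zero produce signed infinities (reported, not dropped). The assignment
    may come from :func:`cut_clusters` or be external labels such as
    super-populations.
    """
    if assignment.nunique() < 2:
        raise ValueError("need at least two clusters")
    carriers = (fingerprints.to_numpy() > 0)
    groups = assignment.loc[fingerprints.index].to_numpy()
    rows = []
    for cluster in pd.unique(groups):
        inside = groups == cluster
        n_in, n_out = int(inside.sum()), int((~inside).sum())
        freq_in = carriers[inside].mean(axis=0)
        freq_out = carriers[~inside].mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = np.log2(freq_in / freq_out)
        for j, name in enumerate(fingerprints.columns):
            if freq_in[j] == 0 and freq_out[j] == 0:
                continue
            value = lo[j]
            status = ("enriched" if value >= threshold
                      else "depleted" if value <= -threshold else "none")
            rows.append((cluster, name, n_in, n_out, freq_in[j],
                         freq_out[j], value, status))
    return pd.DataFrame(
        rows,
        columns=["cluster", "variant", "n_in", "n_out", "freq_in",
                 "freq_out", "log_odds", "status"],
    )
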