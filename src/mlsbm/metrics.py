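"""Parcellation comparison and characterization.

Mutual information (in nats) and its normalization 2·MI/(H₁+H₂) compare two
partitions up to relabeling; size-bin summaries and the laterality index
characterize a single parcellation against per-vertex hemisphere metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, MetadataError
from .model import Parcellation

HEMISPHERES = ("left", "right")


@dataclass(frozen=True)
class VertexMetadata:
    """Per-vertex hemisphere label and position in the canonical adjacency
    (traversal) ordering."""

    hemisphere: np.ndarray
    traversal_index: np.ndarray

    def __post_init__(self):
        hemi = np.asarray(self.hemisphere)
        trav = np.asarray(self.traversal_index, dtype=np.int64)
        if hemi.shape != trav.shape or hemi.ndim != 1:
            raise DimensionError("hemisphere and traversal_index must be 1-D, same length")
        if not np.isin(hemi, HEMISPHERES).all():
            bad = sorted(set(hemi.tolist()) - set(HEMISPHERES))
            raise MetadataError(f"hemisphere labels must be in {HEMISPHERES}, got {bad}")
        if not np.array_equal(np.sort(trav), np.arange(trav.size)):
            raise MetadataError("traversal_index must be a permutation of [0, n)")
        object.__setattr__(self, "hemisphere", hemi)
        object.__setattr__(self, "traversal_index", trav)

    @property
    def n_vertices(self) -> int:
        return self.hemisphere.size


def _contingency(z: Parcellation, z2: Parcellation) -> np.ndarray:
    if z.n_vertices != z2.n_vertices:
        raise DimensionError("parcellations cover different numbers of vertices")
    table = np.zeros((z.K, z2.K), dtype=np.int64)
    np.add.at(table, (z.labels, z2.labels), 1)
    return table


def mutual_information(z: Parcellation, z2: Parcellation) -> float:
    """MI in nats from the joint label contingency table; zero-probability
    cells contribute nothing."""
    table = _contingency(z, z2)
    n = table.sum()
    p = table / n
    pr = p.sum(axis=1, keepdims=True)
    pc = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (pr @ pc)[mask])))


def normalized_mutual_information(z: Parcellation, z2: Parcellation) -> float:
    """NMI = 2·MI(z, z′) / (MI(z, z) + MI(z′, z′)) ∈ [0, 1]; 1 iff the
    parcellations are identical up to relabeling.

    If both partitions are single-cluster both self-MIs vanish and the ratio
    is 0/0; since the partitions are then trivially identical we return 1.
    """
    h1 = mutual_information(z, z)
    h2 = mutual_information(z2, z2)
    if h1 + h2 == 0:
        return 1.0
    return 2.0 * mutual_information(z, z2) / (h1 + h2)


@dataclass(frozen=True)
class SizeSummary:
    """Counts of nonempty parcels per size bin plus the size multiset."""

    small: int
    medium: int
    big: int
    sizes: tuple[int, ...]


def parcel_size_summary(
    parcellation: Parcellation,
    small_below: int = 100,
    big_above: int = 1000,
) -> SizeSummary:
    """Bin nonempty parcels as small (< 100 vertices), medium (100–1,000
    inclusive) or big (> 1,000 vertices)."""
    sizes = parcellation.cluster_sizes()
    sizes = sizes[sizes > 0]
    return SizeSummary(
        small=int((sizes < small_below).sum()),
        medium=int(((sizes >= small_below) & (sizes <= big_above)).sum()),
        big=int((sizes > big_above).sum()),
        sizes=tuple(int(s) for s in np.sort(sizes)[::-1]),
    )


@dataclass(frozen=True)
class LateralitySummary:
    """Per-parcel laterality indices and bilaterality flags.

    The index of a parcel is max(N_left, N_right)/(N_left + N_right): 0.5
    means a perfectly bilateral parcel, 1.0 a fully unilateral one. A parcel
    is bilateral iff it has at least one vertex in each hemisphere. The mean
    is unweighted over nonempty parcels.
    """

    per_parcel: pd.DataFrame
    bilateral_count: int
    mean_index: float


def laterality(parcellation: Parcellation, meta: VertexMetadata) -> LateralitySummary:
    if meta.n_vertices != parcellation.n_vertices:
        raise MetadataError("metadata must cover every vertex of the parcellation")
    left = np.bincount(
        parcellation.labels[meta.hemisphere == "left"], minlength=parcellation.K
    )
    right = np.bincount(
        parcellation.labels[meta.hemisphere == "right"], minlength=parcellation.K
    )
    total = left + right
    nonempty = total > 0
    index = np.maximum(left, right)[nonempty] / total[nonempty]
    bilateral = (left > 0) & (right > 0)
    df = pd.DataFrame(
        {
            "parcel": np.arange(parcellation.K)[nonempty],
            "n_left": left[nonempty],
            "n_right": right[nonempty],
            "laterality_index": index,
            "bilateral": bilateral[nonempty],
        }
    ).set_index("parcel")
    return LateralitySummary(
        per_parcel=df,
        bilateral_count=int(bilateral.sum()),
        mean_index=float(index.mean()),
    )
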