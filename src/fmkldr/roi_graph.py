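"""Per-subject ROI-network features from regional anatomical measures.

Each subject's brain is summarized by one scalar measure per region of
interest (ROI) — e.g. cortical gray-matter volume, thickness, surface
area, curvature, folding index, or sub-cortical volume. For every
subject we form a complete weighted graph over the regions: vertices
carry the measures themselves and the edge between regions i and j is
weighted by the reciprocal distance

    w_ij = 1 / (|m_i - m_j| + 1)  in (0, 1],

so regions with similar measure values are strongly connected. The
vertex table V (subjects x regions) and the edge table E (subjects x
region pairs) are emitted as two separate feature views per measure;
with 78 cortical regions E has C(78, 2) = 3003 columns, with 12
sub-cortical regions it has 66.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FeatureMatrix

__all__ = [
    "RegionMeasureTable",
    "ROIGraphFeatures",
    "edge_weight",
    "build_individual_networks",
]


@dataclass
class RegionMeasureTable:
    """Subjects x regions table of one anatomical measure."""

    values: np.ndarray
    subject_ids: list[str]
    region_ids: list[str]
    measure_name: str = "measure"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (subjects x regions)")
        n, r = self.values.shape
        if len(self.subject_ids) != n or len(self.region_ids) != r:
            raise ValueError("id lists do not match matrix dimensions")
        if np.isnan(self.values).any():
            raise ValueError("measure table contains missing values; preprocess first")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ROIGraphFeatures:
    """Vertex (V) and edge (E) feature tables of the individual networks.

    ``pair_index`` lists the region-id pairs (i, j), i < j by region
    position, in the lexicographic order used for E's columns.
    """

    V: FeatureMatrix
    E: FeatureMatrix
    pair_index: list[tuple[str, str]]

    def write_pair_index(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.pair_index, columns=["region_i", "region_j"]).to_csv(
            path, sep=sep, index=False
        )


def edge_weight(m_i: float, m_j: float) -> float:
    """Weight of the edge between two regions with measures m_i, m_j.

    Returns 1 / (|m_i - m_j| + 1), always in (0, 1]; identical measures
    give weight exactly 1.
    """
    return 1.0 / (abs(m_i - m_j) + 1.0)


def build_individual_networks(T: RegionMeasureTable) -> ROIGraphFeatures:
    """Build the complete-graph vertex and edge features for every subject.

    V is the measure table itself; E has one column per unordered region
    pair, ordered lexicographically by region position, holding the
    reciprocal-distance edge weights.
    """
    if T.n_regions < 2:
        raise ValueError("at least 2 regions are required to form edges")
    pairs = list(combinations(range(T.n_regions), 2))
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    # vectorized over subjects: |m_i - m_j| for every pair
    E_vals = 1.0 / (np.abs(T.values[:, i_idx] - T.values[:, j_idx]) + 1.0)

    pair_ids = [(T.region_ids[i], T.region_ids[j]) for i, j in pairs]
    edge_feature_ids = [f"{a}|{b}" for a, b in pair_ids]
    V = FeatureMatrix(T.values.copy(), list(T.subject_ids), list(T.region_ids))
    E = FeatureMatrix(E_vals, list(T.subject_ids), edge_feature_ids)
    return ROIGraphFeatures(V=V, E=E, pair_index=pair_ids)
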