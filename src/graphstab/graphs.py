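"""Residue contact graphs.

A protein variant becomes an undirected graph: one node per residue carrying
a 6-dimensional feature vector (five Z-scored physicochemical properties +
the position's conservation score), and an edge between every residue pair
whose Cα atoms lie within a distance cutoff (10 Å by default, boundary
inclusive).  Each edge is annotated with the Euclidean Cα–Cα distance in Å;
coordinates themselves are not node features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conservation import ConservationProfile
from .io import SequenceRecord, StructureModel
from .properties import ResiduePropertyTable

DEFAULT_RADIUS = 10.0  # Å


@dataclass
class ProteinGraph:
    """Undirected residue graph for one (mutant) sequence.

    Attributes
    ----------
    node_features : (n, 6) float64
    edges : (m, 2) int64 with i < j per row — unordered pairs, no self-loops
    edge_attr : (m,) float64 Cα–Cα distance in Å
    label : optional binary class (active=1 / inactive=0)
    id : text identifier
    """

    node_features: np.ndarray
    edges: np.ndarray
    edge_attr: np.ndarray
    label: Optional[int] = None
    id: str = ""

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_attr = np.asarray(self.edge_attr, dtype=np.float64)
        if self.node_features.ndim != 2 or self.node_features.shape[1] != 6:
            raise ValueError("node_features must be (n, 6)")
        if not np.isfinite(self.node_features).all():
            raise ValueError("non-finite node features")
        if self.edges.shape[0] != self.edge_attr.shape[0]:
            raise ValueError("edges and edge_attr disagree in length")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "label": self.label,
                "node_features": self.node_features.tolist(),
                "edges": self.edges.tolist(),
                "edge_attr": self.edge_attr.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProteinGraph":
        d = json.loads(text)
        return cls(
            node_features=np.array(d["node_features"], dtype=np.float64),
            edges=np.array(d["edges"], dtype=np.int64).reshape(-1, 2),
            edge_attr=np.array(d["edge_attr"], dtype=np.float64),
            label=d.get("label"),
            id=d.get("id", ""),
        )


def featurize_nodes(
    sequence: str,
    property_table: ResiduePropertyTable,
    conservation: ConservationProfile,
) -> np.ndarray:
    """(n, 6) node feature matrix: 5 Z-scored properties + conservation score."""
    if len(conservation) != len(sequence):
        raise ValueError(
            f"conservation profile length {len(conservation)} != sequence "
            f"length {len(sequence)}"
        )
    props = property_table.feature_matrix(sequence)
    return np.column_stack([props, conservation.scores])


def map_to_wt_coords(mutant_sequence: str, structure: StructureModel) -> np.ndarray:
    """Assign each mutant residue the WT Cα coordinates of the same position.

    Point mutations rarely perturb the backbone, so variants inherit the
    wild-type geometry unchanged; only residue identities (hence node
    features) differ.
    """
    if len(mutant_sequence) != len(structure):
        raise ValueError(
            f"mutant length {len(mutant_sequence)} != structure residue count "
            f"{len(structure)}"
        )
    return structure.coords.copy()


def build_residue_graph(
    sequence: str,
    features: np.ndarray,
    coords: np.ndarray,
    radius: float = DEFAULT_RADIUS,
    label: Optional[int] = None,
    graph_id: str = "",
) -> ProteinGraph:
    """Radius graph over Cα coordinates: edge (i, j) iff ‖xi − xj‖ <= radius.

    The cutoff is inclusive so the nominal 10 Å radius is attainable exactly.
    Isolated nodes are permitted.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if coords.shape[0] != len(sequence):
        raise ValueError("coords length != sequence length")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = coords.shape[0]
    if n >= 2:
        dists = squareform(pdist(coords))
        iu, ju = np.triu_indices(n, k=1)
        d = dists[iu, ju]
        keep = d <= radius
        edges = np.column_stack([iu[keep], ju[keep]]).astype(np.int64)
        edge_attr = d[keep]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        edge_attr = np.empty(0, dtype=np.float64)
    return ProteinGraph(
        node_features=features, edges=edges, edge_attr=edge_attr, label=label, id=graph_id
    )


def graph_from_record(
    record: SequenceRecord,
    structure: StructureModel,
    property_table: ResiduePropertyTable,
    conservation: ConservationProfile,
    radius: float = DEFAULT_RADIUS,
) -> ProteinGraph:
    """Full featurization pipeline for one variant record."""
    coords = map_to_wt_coords(record.sequence, structure)
    feats = featurize_nodes(record.sequence, property_table, conservation)
    return build_residue_graph(
        record.sequence, feats, coords, radius=radius, label=record.label,
        graph_id=record.id,
    )
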