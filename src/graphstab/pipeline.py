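"""End-to-end convenience wiring shared by the CLI, tests and scripts."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .conservation import ConservationProfile, compute_conservation
from .graphs import ProteinGraph, graph_from_record
from .io import SequenceRecord, StructureModel, check_structure_matches_wt
from .properties import ResiduePropertyTable, load_property_table


def prepare_graphs(
    wt: SequenceRecord,
    structure: StructureModel,
    records: Sequence[SequenceRecord],
    property_table: Optional[ResiduePropertyTable] = None,
    radius: float = 10.0,
    conservation: Optional[ConservationProfile] = None,
):
    """Featurize a labeled mutant dataset into residue graphs.

    The conservation profile is computed once over the wild type plus every
    input sequence (they are trivially aligned, sharing the WT length) unless
    a precomputed profile is supplied.

    Returns ``(graphs, labels, conservation, property_table)``.
    """
    check_structure_matches_wt(structure, wt)
    if property_table is None:
        property_table = load_property_table()
    if conservation is None:
        conservation = compute_conservation(
            [wt.sequence] + [r.sequence for r in records]
        )
    graphs: list[ProteinGraph] = []
    for rec in records:
        graphs.append(
            graph_from_record(rec, structure, property_table, conservation, radius=radius)
        )
    labels = np.array([r.label for r in records])
    return graphs, labels, conservation, property_table
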