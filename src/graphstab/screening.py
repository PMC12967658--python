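"""Screening (mutation analysis): score candidate mutants with a trained
model and rank them by predicted probability of being active.

The score is a learned classification probability, not a ΔΔG estimate.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationProfile
from .graphs import graph_from_record
from .io import SequenceRecord, StructureModel
from .mutagenesis import MutantCandidate
from .nn import GNNModel, TrainedModel, predict_proba
from .properties import ResiduePropertyTable


def score_candidates(
    model: TrainedModel | GNNModel,
    candidates: Sequence[MutantCandidate],
    structure: StructureModel,
    property_table: ResiduePropertyTable,
    conservation: ConservationProfile,
    radius: float = 10.0,
) -> list[MutantCandidate]:
    """Return candidates annotated with the model's probability of activity.

    Each candidate sequence is mapped onto the wild-type coordinates,
    featurized with the training-time conservation profile (candidates do
    not shift the consensus unless the caller recomputes it) and scored in
    evaluation mode, so duplicate sequences get identical probabilities.
    """
    for c in candidates:
        if len(c.sequence) != len(structure):
            raise ValueError(
                f"candidate {c.label() or '<WT>'}: length {len(c.sequence)} != "
                f"structure residue count {len(structure)}"
            )
    graphs = [
        graph_from_record(
            SequenceRecord(id=c.label() or "WT", sequence=c.sequence),
            structure,
            property_table,
            conservation,
            radius=radius,
        )
        for c in candidates
    ]
    probs = predict_proba(model, graphs)
    return [
        MutantCandidate(c.mutations, c.sequence, c.method, probability=float(p))
        for c, p in zip(candidates, probs)
    ]


def rank_candidates(candidates: Sequence[MutantCandidate]) -> pd.DataFrame:
    """Descending probability; ties broken by lexicographic mutation label;
    1-based rank column."""
    for c in candidates:
        if c.probability is None:
            raise ValueError(f"candidate {c.label()} has not been scored")
    order = sorted(candidates, key=lambda c: (-c.probability, c.label()))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "mutations": [c.label() for c in order],
            "sequence": [c.sequence for c in order],
            "probability": [c.probability for c in order],
            "method": [c.method for c in order],
        }
    )


def rank_and_write(
    candidates: Sequence[MutantCandidate],
    path,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Write the ranked table as CSV (probability printed to 5 decimals).

    ``top_n`` limits the rows written (0 → header only); the full ranking is
    returned either way.  Output is byte-stable for identical inputs.
    """
    df = rank_candidates(candidates)
    out = df if top_n is None else df.head(top_n)
    out = out.copy()
    out["probability"] = out["probability"].map(lambda p: f"{p:.5f}")
    out.to_csv(path, index=False)
    return df
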