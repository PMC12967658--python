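"""Consensus-frequency conservation scores over an (implicitly) aligned set.

Point-mutant sets of one wild-type protein all share the WT length, so the
trivial column-wise alignment is exact and no external aligner is needed.
Ragged inputs must be aligned by the user first (e.g. with MAFFT or Clustal
Omega) and supplied as equal-length sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ConservationProfile:
    """Per-position consensus residue and consensus frequency in [0, 1]."""

    consensus: str
    scores: np.ndarray  # (n,) float64 in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.consensus) != self.scores.shape[0]:
            raise ValueError("consensus length != score length")
        if ((self.scores < 0) | (self.scores > 1)).any():
            raise ValueError("conservation scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.consensus)


def compute_conservation(aligned_sequences: Sequence[str]) -> ConservationProfile:
    """Column-wise consensus frequency: fraction of sequences matching the
    modal residue (ties broken alphabetically, so profiles are deterministic).

    Requires >= 2 equal-length sequences; a score of 1.0 occurs iff a column
    is unanimous.
    """
    seqs = list(aligned_sequences)
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences to compute conservation")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(
            f"sequences have unequal lengths {sorted(lengths)}; provide a "
            "pre-computed multiple sequence alignment"
        )
    n = len(seqs)
    consensus = []
    scores = np.empty(len(seqs[0]), dtype=np.float64)
    for j in range(len(seqs[0])):
        counts = Counter(s[j] for s in seqs)
        best = max(counts.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        # tie-break: among maximal counts pick the alphabetically first residue
        top = best[1]
        residue = min(aa for aa, c in counts.items() if c == top)
        consensus.append(residue)
        scores[j] = top / n
    return ConservationProfile(consensus="".join(consensus), scores=scores)
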