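"""Point-mutation labels: the ``F52G:T51A`` grammar and sequence edits.

Positions are 1-based into the wild-type sequence.  A label names the
wild-type residue, the position, and the replacement (``F52G``); multi-site
mutants join labels with ``:``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .properties import AMINO_ACIDS

_CANONICAL = set(AMINO_ACIDS)
_TOKEN = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single substitution: wild-type residue, 1-based position, new residue."""

    position: int
    wt_aa: str
    new_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in _CANONICAL or self.new_aa not in _CANONICAL:
            raise ValueError(f"non-canonical residue in mutation {self.label()}")
        if self.wt_aa == self.new_aa:
            raise ValueError(
                f"mutation {self.label()} is a silent substitution (wt == new)"
            )
        if self.position < 1:
            raise ValueError(f"mutation position must be >= 1, got {self.position}")

    def label(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label()


def parse_mutation(token: str, wt_sequence: Optional[str] = None) -> Mutation:
    """Parse one ``<AA><int><AA>`` token; optionally validate against the WT."""
    m = _TOKEN.match(token.strip().upper())
    if not m:
        raise ValueError(f"malformed mutation token {token!r} (expected e.g. 'F52G')")
    wt_aa, pos_str, new_aa = m.groups()
    mut = Mutation(position=int(pos_str), wt_aa=wt_aa, new_aa=new_aa)
    if wt_sequence is not None:
        _check_against_wt(mut, wt_sequence)
    return mut


def parse_mutation_set(label: str, wt_sequence: Optional[str] = None) -> list[Mutation]:
    """Parse a ``:``-joined mutation label into a position-sorted list.

    Two mutations at the same position in one set are rejected (a residue
    cannot take two identities at once).
    """
    tokens = [t for t in label.split(":") if t.strip()]
    if not tokens:
        raise ValueError(f"empty mutation label {label!r}")
    muts = [parse_mutation(t, wt_sequence) for t in tokens]
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        dup = sorted({p for p in positions if positions.count(p) > 1})
        raise ValueError(f"duplicate mutation position(s) {dup} in {label!r}")
    return sorted(muts)


def format_mutation_set(mutations: Iterable[Mutation]) -> str:
    """Canonical label: position-sorted, ``:``-joined (empty string for WT)."""
    return ":".join(m.label() for m in sorted(mutations))


def _check_against_wt(mut: Mutation, wt_sequence: str) -> None:
    if mut.position > len(wt_sequence):
        raise ValueError(
            f"mutation {mut.label()}: position {mut.position} beyond WT length "
            f"{len(wt_sequence)}"
        )
    found = wt_sequence[mut.position - 1]
    if found != mut.wt_aa:
        raise ValueError(
            f"mutation {mut.label()}: expected {mut.wt_aa} at {mut.position}, found {found}"
        )


def apply_mutations(wt_sequence: str, mutations: Sequence[Mutation]) -> str:
    """Apply substitutions to the WT sequence (order-independent over distinct positions)."""
    seq = list(wt_sequence)
    for mut in mutations:
        _check_against_wt(mut, wt_sequence)
        seq[mut.position - 1] = mut.new_aa
    return "".join(seq)


def diff_sequences(wt_sequence: str, mutant_sequence: str) -> list[Mutation]:
    """Mutation set (position-sorted) turning the WT into the mutant."""
    if len(wt_sequence) != len(mutant_sequence):
        raise ValueError(
            f"length mismatch: WT {len(wt_sequence)} vs mutant {len(mutant_sequence)}"
        )
    return [
        Mutation(position=i + 1, wt_aa=a, new_aa=b)
        for i, (a, b) in enumerate(zip(wt_sequence, mutant_sequence))
        if a != b
    ]
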