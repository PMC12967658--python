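"""Candidate mutant generation: combinatorial, weighted and evolutionary
strategies, plus decoy (synthetic inactive) creation.

Single mutations are harvested from the active set relative to the wild
type; multi-mutants combine them at distinct positions.  Decoys invert the
physicochemical character (charge sign, hydrophobicity class, or volume
class) of active-mutation residues to populate the negative class when real
inactives are scarce.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import SequenceRecord
from .mutations import Mutation, apply_mutations, diff_sequences, format_mutation_set
from .properties import AMINO_ACIDS


@dataclass
class MutationPool:
    """Unique single mutations from the active set + per-position frequencies."""

    mutations: list[Mutation]
    active_freq: Counter = field(default_factory=Counter)    # position -> count
    inactive_freq: Counter = field(default_factory=Counter)

    def __len__(self) -> int:
        return len(self.mutations)

    def positions(self) -> set[int]:
        return {m.position for m in self.mutations}


@dataclass
class MutantCandidate:
    """A proposed multi-mutant: mutation set, realized sequence, provenance."""

    mutations: tuple[Mutation, ...]
    sequence: str
    method: str  # combinatorial | weighted | evolutionary
    probability: Optional[float] = None

    def label(self) -> str:
        return format_mutation_set(self.mutations)


def extract_unique_mutations(
    active_records: Sequence[SequenceRecord],
    wt_sequence: str,
    inactive_records: Sequence[SequenceRecord] = (),
) -> MutationPool:
    """Harvest the deduplicated union of single mutations carried by the
    active records (positional diff vs WT); frequencies count record
    occurrences per position for both classes.

    An active identical to the WT contributes nothing and is skipped with a
    warning.
    """
    seen: dict[str, Mutation] = {}
    active_freq: Counter = Counter()
    inactive_freq: Counter = Counter()
    for rec in active_records:
        if len(rec.sequence) != len(wt_sequence):
            raise ValueError(
                f"record {rec.id!r}: length {len(rec.sequence)} != WT length {len(wt_sequence)}"
            )
        muts = diff_sequences(wt_sequence, rec.sequence)
        if not muts:
            warnings.warn(f"active record {rec.id!r} is identical to WT; skipped")
            continue
        for m in muts:
            seen.setdefault(m.label(), m)
            active_freq[m.position] += 1
    for rec in inactive_records:
        if len(rec.sequence) != len(wt_sequence):
            raise ValueError(
                f"record {rec.id!r}: length {len(rec.sequence)} != WT length {len(wt_sequence)}"
            )
        for m in diff_sequences(wt_sequence, rec.sequence):
            inactive_freq[m.position] += 1
    pool = sorted(seen.values())
    return MutationPool(mutations=pool, active_freq=active_freq, inactive_freq=inactive_freq)


def _distinct_position_subsets(pool: Sequence[Mutation], k: int):
    for combo in combinations(pool, k):
        if len({m.position for m in combo}) == k:
            yield combo


def generate_combinatorial(
    pool: MutationPool | Sequence[Mutation],
    k: int,
    wt_sequence: Optional[str] = None,
) -> list[MutantCandidate]:
    """All size-k subsets of the pool occupying distinct positions.

    Output order is deterministic: subsets of the position-sorted pool in
    lexicographic order.  Same-position pairs are excluded (a residue cannot
    take two identities at once).
    """
    muts = sorted(pool.mutations if isinstance(pool, MutationPool) else pool)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(muts):
        raise ValueError(f"k={k} exceeds pool size {len(muts)}")
    out = []
    for combo in _distinct_position_subsets(muts, k):
        seq = apply_mutations(wt_sequence, combo) if wt_sequence is not None else ""
        out.append(MutantCandidate(mutations=combo, sequence=seq, method="combinatorial"))
    return out


def position_enrichment_weights(
    active_freq: Counter,
    inactive_freq: Counter,
    pseudocount: float = 1.0,
) -> dict[int, float]:
    """Enrichment weight per position: (active + pc) / (inactive + pc).

    The pseudocount keeps weights finite and makes an unobserved position
    neutral (weight 1).
    """
    positions = set(active_freq) | set(inactive_freq)
    return {
        p: (active_freq.get(p, 0) + pseudocount) / (inactive_freq.get(p, 0) + pseudocount)
        for p in positions
    }


def generate_weighted(
    pool: MutationPool | Sequence[Mutation],
    weights: dict[int, float],
    k: int,
    n_candidates: int,
    seed: int = 0,
    wt_sequence: Optional[str] = None,
) -> list[MutantCandidate]:
    """Sample distinct size-k candidates, each drawn with probability
    proportional to the product of its mutations' position weights.

    Sampling is without replacement over the combinatorial space; if more
    candidates are requested than the space holds, the full space is
    returned with a warning.
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    space = generate_combinatorial(pool, k, wt_sequence=wt_sequence)
    if n_candidates >= len(space):
        if n_candidates > len(space):
            warnings.warn(
                f"requested {n_candidates} candidates but the combinatorial space "
                f"holds only {len(space)}; returning all of them"
            )
        out = [
            MutantCandidate(c.mutations, c.sequence, "weighted") for c in space
        ]
        return out
    w = np.array(
        [np.prod([weights.get(m.position, 1.0) for m in c.mutations]) for c in space],
        dtype=np.float64,
    )
    if (w < 0).any():
        raise ValueError("negative enrichment weight")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(space), size=n_candidates, replace=False, p=w / w.sum())
    chosen = np.sort(chosen)  # deterministic presentation order
    return [
        MutantCandidate(space[i].mutations, space[i].sequence, "weighted") for i in chosen
    ]


def single_point_crossover(parent_a: str, parent_b: str, cut: int) -> str:
    """Child = parent_a[:cut] + parent_b[cut:]; cut in [1, len-1]."""
    if len(parent_a) != len(parent_b):
        raise ValueError("parents of unequal length")
    if not (1 <= cut <= len(parent_a) - 1):
        raise ValueError(f"cut {cut} outside [1, {len(parent_a) - 1}]")
    return parent_a[:cut] + parent_b[cut:]


def generate_evolutionary(
    parent_sequences: Sequence[str],
    scorer: Callable[[str], float],
    wt_sequence: str,
    generations: int = 20,
    population_size: int = 100,
    seed: int = 0,
) -> list[MutantCandidate]:
    """Evolutionary candidate search: fitness-proportional parent selection,
    single-point crossover at a random cut, truncation survival.

    Each generation produces ``population_size`` children; parents + children
    are ranked by ``scorer`` (a sequence -> fitness map in (0, 1)) and the top
    ``population_size`` survive.  The final population is returned sorted by
    fitness (descending), mutation sets re-derived against the wild type.
    """
    parents = [str(s) for s in parent_sequences]
    if len(parents) < 2:
        raise ValueError("need at least 2 parent sequences")
    lengths = {len(s) for s in parents} | {len(wt_sequence)}
    if len(lengths) != 1:
        raise ValueError("parents (and WT) must share one length")
    rng = np.random.default_rng(seed)
    length = len(wt_sequence)

    population = list(parents)
    fitness = np.array([scorer(s) for s in population], dtype=np.float64)
    for _ in range(generations):
        probs = fitness / fitness.sum() if fitness.sum() > 0 else None
        children = []
        for _ in range(population_size):
            ia, ib = rng.choice(len(population), size=2, replace=True, p=probs)
            cut = int(rng.integers(1, length))
            children.append(single_point_crossover(population[ia], population[ib], cut))
        # elitist survival over parents + children keeps the best found so far
        merged = population + children
        merged_fit = np.array([scorer(s) for s in merged], dtype=np.float64)
        order = np.argsort(-merged_fit, kind="stable")[:population_size]
        population = [merged[i] for i in order]
        fitness = merged_fit[order]

    out = []
    for seq, fit in zip(population, fitness):
        muts = tuple(diff_sequences(wt_sequence, seq))
        out.append(
            MutantCandidate(
                mutations=muts, sequence=seq, method="evolutionary", probability=float(fit)
            )
        )
    return out


# ---------------------------------------------------------------------------
# decoys
# ---------------------------------------------------------------------------

#: Property-inverting replacements per residue.  Charge inversion where
#: possible; hydrophobics -> small/polar; small/polar -> bulky hydrophobic.
#: The published scheme is given by example (E->K, F->S/A); this table is a
#: reconstruction guided by those examples and is user-overridable via CSV.
DEFAULT_DECOY_TABLE: dict[str, tuple[str, ...]] = {
    "D": ("K",), "E": ("K",), "K": ("E",), "R": ("E",), "H": ("E",),
    "F": ("S", "A"), "W": ("S", "A"), "Y": ("S", "A"), "L": ("S", "A"),
    "I": ("S", "A"), "V": ("S", "A"), "M": ("S", "A"),
    "S": ("F", "W"), "T": ("F", "W"), "N": ("F", "W"), "Q": ("F", "W"),
    "G": ("F", "W"), "A": ("F", "W"), "C": ("F", "W"), "P": ("F", "W"),
}


def load_decoy_table(path) -> dict[str, tuple[str, ...]]:
    """Read an override decoy table CSV with header ``aa,replacements``
    (replacements ``|``-separated, e.g. ``F,S|A``)."""
    df = pd.read_csv(path, dtype=str)
    if "aa" not in df.columns or "replacements" not in df.columns:
        raise ValueError("decoy table CSV needs columns 'aa' and 'replacements'")
    table = {}
    for _, row in df.iterrows():
        reps = tuple(r.strip() for r in str(row["replacements"]).split("|") if r.strip())
        if not reps:
            raise ValueError(f"no replacements for {row['aa']!r}")
        table[str(row["aa"]).strip()] = reps
    return table


def generate_decoys(
    active_records: Sequence[SequenceRecord],
    wt_sequence: str,
    decoy_table: Optional[dict[str, tuple[str, ...]]] = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Create one inactive decoy per active record by property-inverting the
    residue at every active-mutation position (seeded random choice among
    listed alternatives).  The decoy differs from its source exactly at those
    positions.
    """
    table = DEFAULT_DECOY_TABLE if decoy_table is None else decoy_table
    missing = sorted(set(AMINO_ACIDS) - set(table))
    if missing:
        raise ValueError(f"decoy table missing residues: {missing}")
    rng = np.random.default_rng(seed)
    decoys = []
    for rec in active_records:
        muts = diff_sequences(wt_sequence, rec.sequence)
        if not muts:
            warnings.warn(f"active record {rec.id!r} identical to WT; no decoy made")
            continue
        seq = list(rec.sequence)
        for m in muts:
            current = seq[m.position - 1]
            options = [a for a in table[current] if a != current]
            if not options:
                raise ValueError(f"decoy table maps {current!r} only to itself")
            seq[m.position - 1] = options[int(rng.integers(len(options)))]
        decoys.append(
            SequenceRecord(id=f"{rec.id}_decoy", sequence="".join(seq), label=0)
        )
    return decoys


def candidates_to_dataframe(candidates: Iterable[MutantCandidate]) -> pd.DataFrame:
    """Tabular view: ``mutations,sequence,probability,method``."""
    rows = [
        {
            "mutations": c.label(),
            "sequence": c.sequence,
            "probability": c.probability,
            "method": c.method,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=["mutations", "sequence", "probability", "method"])
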