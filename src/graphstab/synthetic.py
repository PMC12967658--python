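"""Synthetic study system: an ideal α-helix wild type with a planted
physicochemical stability signal.

The generator emulates the structure of a real single-protein mutant
dataset: equal-length point/multi-mutants of one wild type, an active set
carrying conservative substitutions, and an inactive set carrying
property-inverting substitutions at hydrophobic-core positions (the same
logic a decoy generator applies).  A small fraction of labels is flipped so
metrics are non-degenerate.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .io import SequenceRecord, StructureModel, write_fasta, write_mutant_csv, write_pdb

# ideal α-helix parameters
HELIX_RADIUS = 2.3       # Å
HELIX_RISE = 1.5         # Å per residue
HELIX_TWIST = 100.0      # degrees per residue

_CORE_RES = "LIVFM"              # hydrophobic core alphabet
_SURF_RES = "STNQEDKRG"          # surface alphabet
#: conservative (same physicochemical class) substitutions
_CONSERVATIVE = {
    "L": "IVM", "I": "LVM", "V": "ILM", "M": "LIV", "F": "LMV",
    "S": "T", "T": "S", "N": "Q", "Q": "N", "D": "E", "E": "D",
    "K": "R", "R": "K", "G": "A", "H": "KR", "A": "G",
}
#: property-inverting substitutions for a hydrophobic core residue
_INVERTING = "DEKRNQ"


def default_core_positions(wt_length: int) -> frozenset[int]:
    """Heptad-style core: 1-based positions with (i−1) mod 7 in {0, 3}."""
    return frozenset(
        i for i in range(1, wt_length + 1) if (i - 1) % 7 in (0, 3)
    )


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-signal dataset."""

    wt_length: int = 60
    n_active: int = 100
    n_inactive: int = 300
    core_positions: Optional[frozenset[int]] = None
    mutations_per_record: int = 2
    noise_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_length < 2:
            raise ValueError("wt_length must be >= 2")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("n_active and n_inactive must be >= 1")
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.mutations_per_record not in (1, 2):
            raise ValueError("mutations_per_record must be 1 or 2")
        if self.core_positions is None:
            self.core_positions = default_core_positions(self.wt_length)
        else:
            self.core_positions = frozenset(self.core_positions)
            bad = [p for p in self.core_positions if not (1 <= p <= self.wt_length)]
            if bad:
                raise ValueError(f"core positions outside [1, {self.wt_length}]: {bad}")


def make_helix_coords(n: int) -> np.ndarray:
    """Cα coordinates of an ideal α-helix (radius 2.3 Å, rise 1.5 Å/residue,
    100°/residue); consecutive Cα–Cα distances come out ≈3.8 Å."""
    if n < 1:
        raise ValueError("n must be >= 1")
    i = np.arange(n, dtype=np.float64)
    theta = np.deg2rad(HELIX_TWIST) * i
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
    )


@dataclass
class SyntheticDataset:
    wt: SequenceRecord
    structure: StructureModel
    records: list[SequenceRecord]   # actives + inactives, labels possibly noisy
    true_labels: np.ndarray         # planted labels before noise flips
    config: SyntheticConfig = field(repr=False, default=None)  # type: ignore

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)


def make_synthetic_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Draw the wild type, the helix structure and the labeled mutant sets.

    Actives carry conservative substitutions (same residue class) at random
    positions; inactives carry property-inverting substitutions at core
    positions, so with zero noise every inactive has at least one core
    position occupied by a polar or charged residue.  ``noise_rate`` of each
    class has its *label* flipped (sequences untouched).
    """
    rng = np.random.default_rng(config.seed)
    core = sorted(config.core_positions)
    surf = [i for i in range(1, config.wt_length + 1) if i not in config.core_positions]

    wt_seq = [""] * config.wt_length
    for p in range(1, config.wt_length + 1):
        alphabet = _CORE_RES if p in config.core_positions else _SURF_RES
        wt_seq[p - 1] = alphabet[int(rng.integers(len(alphabet)))]
    wt = SequenceRecord(id="WT", sequence="".join(wt_seq))
    structure = StructureModel(
        sequence=wt.sequence, coords=make_helix_coords(config.wt_length), chain_id="A"
    )

    m = config.mutations_per_record
    records: list[SequenceRecord] = []
    true_labels = []
    for i in range(config.n_active):
        positions = rng.choice(config.wt_length, size=m, replace=False) + 1
        seq = list(wt.sequence)
        for p in positions:
            options = _CONSERVATIVE[seq[p - 1]]
            seq[p - 1] = options[int(rng.integers(len(options)))]
        records.append(SequenceRecord(id=f"act_{i:04d}", sequence="".join(seq), label=1))
        true_labels.append(1)
    for i in range(config.n_inactive):
        positions = rng.choice(len(core), size=min(m, len(core)), replace=False)
        seq = list(wt.sequence)
        for ci in positions:
            p = core[ci]
            options = [a for a in _INVERTING if a != seq[p - 1]]
            seq[p - 1] = options[int(rng.integers(len(options)))]
        records.append(SequenceRecord(id=f"ina_{i:04d}", sequence="".join(seq), label=0))
        true_labels.append(0)

    # label noise: flip a fixed, seeded fraction of each class
    n_flip_act = int(round(config.noise_rate * config.n_active))
    n_flip_ina = int(round(config.noise_rate * config.n_inactive))
    flip_act = rng.choice(config.n_active, size=n_flip_act, replace=False)
    flip_ina = rng.choice(config.n_inactive, size=n_flip_ina, replace=False) + config.n_active
    for idx in np.concatenate([flip_act, flip_ina]).astype(int):
        records[idx].label = 1 - records[idx].label

    return SyntheticDataset(
        wt=wt,
        structure=structure,
        records=records,
        true_labels=np.array(true_labels, dtype=int),
        config=config,
    )


def write_fixture_files(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write WT FASTA, Cα-only PDB and the active/inactive mutant CSVs.

    Byte-identical for identical seeds; the files double as
    format-conformance fixtures for the readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wt_fasta": outdir / "wt.fasta",
        "wt_pdb": outdir / "wt.pdb",
        "active_csv": outdir / "active_labeled.csv",
        "inactive_csv": outdir / "inactive_labeled.csv",
    }
    write_fasta([dataset.wt], paths["wt_fasta"])
    write_pdb(dataset.structure, paths["wt_pdb"])
    actives = [r for r in dataset.records if r.label == 1]
    inactives = [r for r in dataset.records if r.label == 0]
    write_mutant_csv(actives, dataset.wt, paths["active_csv"])
    write_mutant_csv(inactives, dataset.wt, paths["inactive_csv"])
    return paths
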