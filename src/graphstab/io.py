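"""Reading and writing the tool's file formats.

FASTA (sequences), PDB (wild-type structure, Cα-only is sufficient) and the
CSV mutant-table dialect with columns ``id,mutations,label`` where
``mutations`` uses the ``F52G:T51A`` grammar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .properties import AMINO_ACIDS

_CANONICAL = set(AMINO_ACIDS)


@dataclass
class SequenceRecord:
    """A named protein sequence with an optional binary stability label.

    ``label`` is 1 for active (stabilizing / more stable), 0 for inactive,
    ``None`` for unlabeled candidates.
    """

    id: str
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, aa in enumerate(self.sequence):
            if aa not in _CANONICAL:
                raise ValueError(
                    f"record {self.id!r}: non-canonical residue {aa!r} at position {i + 1}"
                )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class StructureModel:
    """Cα trace of a single chain: per-residue one-letter codes + coordinates (Å)."""

    sequence: str
    coords: np.ndarray  # (n, 3) float64
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (len(self.sequence), 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite Cα coordinates")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord` (unlabeled).

    Sequences are upper-cased; any character outside the 20 canonical
    one-letter codes raises with the record id and offset.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    """Write records as plain FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_wt_structure(path, chain: Optional[str] = None) -> StructureModel:
    """Read the wild-type Cα trace from a PDB file.

    First model only; one chain (default: first chain encountered); first
    altloc kept; residues in file order, insertion codes followed in order.

    Raises
    ------
    ValueError
        If the chain is absent, or a standard residue lacks a Cα atom (an
        experimental structure or a complete predicted model is required).
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("wt", str(path))
    model = next(structure.get_models())  # first model
    chains = {c.id: c for c in model.get_chains()}
    if not chains:
        raise ValueError(f"no chains found in {path}")
    if chain is None:
        chain_obj = next(iter(chains.values()))
    elif chain in chains:
        chain_obj = chains[chain]
    else:
        raise ValueError(f"chain {chain!r} not found in {path}; have {sorted(chains)}")

    letters = []
    coords = []
    for residue in chain_obj.get_residues():
        hetflag = residue.id[0]
        if hetflag != " ":
            continue  # skip waters / heteroatoms
        resname = residue.get_resname().strip()
        one = protein_letters_3to1.get(resname.upper())
        if one is None or one not in _CANONICAL:
            raise ValueError(
                f"non-canonical residue {resname} at {residue.id} in chain {chain_obj.id}"
            )
        if "CA" not in residue:
            raise ValueError(
                f"residue {resname}{residue.id[1]} in chain {chain_obj.id} lacks a "
                "Cα atom; provide an experimental structure or a predicted model"
            )
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]  # first altloc
        letters.append(one)
        coords.append(atom.get_coord())
    if not letters:
        raise ValueError(f"chain {chain_obj.id} has no standard residues with Cα atoms")
    return StructureModel(
        sequence="".join(letters),
        coords=np.asarray(coords, dtype=np.float64),
        chain_id=chain_obj.id,
    )


def check_structure_matches_wt(structure: StructureModel, wt: SequenceRecord) -> None:
    """Enforce positional identity between the PDB chain and the WT FASTA.

    Coordinate mapping is positional, so a length or identity mismatch is a
    hard error, not a warning.
    """
    if len(structure) != len(wt):
        raise ValueError(
            f"structure has {len(structure)} residues but WT sequence has "
            f"{len(wt)}; they must match position-for-position"
        )
    if structure.sequence != wt.sequence:
        diffs = [
            i + 1
            for i, (a, b) in enumerate(zip(structure.sequence, wt.sequence))
            if a != b
        ]
        raise ValueError(
            f"structure sequence disagrees with WT FASTA at positions {diffs[:10]}"
        )


def write_pdb(structure: StructureModel, path) -> None:
    """Write a minimal Cα-only PDB file (one chain, ATOM records only)."""
    from Bio.SeqUtils import seq3

    with open(path, "w") as fh:
        for i, (aa, xyz) in enumerate(zip(structure.sequence, structure.coords), start=1):
            res3 = seq3(aa).upper()
            fh.write(
                f"ATOM  {i:5d}  CA  {res3} {structure.chain_id}{i:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def read_mutant_csv(path, wt: SequenceRecord, label: Optional[int] = None) -> list[SequenceRecord]:
    """Read a mutant table CSV (``id,mutations,label``) and realize sequences.

    ``mutations`` uses the ``F52G:T51A`` grammar against ``wt``; an empty
    mutations cell means the wild-type sequence itself.  A ``label`` argument
    overrides / supplies the label column (used when active and inactive sets
    live in separate files).
    """
    from .mutations import apply_mutations, parse_mutation_set

    df = pd.read_csv(path, dtype={"id": str, "mutations": str})
    if "id" not in df.columns or "mutations" not in df.columns:
        raise ValueError(f"{path}: mutant CSV needs columns 'id' and 'mutations'")
    records = []
    for _, row in df.iterrows():
        muts_str = row["mutations"]
        if pd.isna(muts_str) or not str(muts_str).strip():
            seq = wt.sequence
        else:
            muts = parse_mutation_set(str(muts_str).strip(), wt.sequence)
            seq = apply_mutations(wt.sequence, muts)
        if label is not None:
            lab = label
        elif "label" in df.columns and not pd.isna(row.get("label")):
            lab = int(row["label"])
        else:
            lab = None
        records.append(SequenceRecord(id=str(row["id"]), sequence=seq, label=lab))
    if not records:
        warnings.warn(f"{path}: empty mutant table")
    return records


def write_mutant_csv(records: Sequence[SequenceRecord], wt: SequenceRecord, path) -> None:
    """Write records as a mutant CSV (``id,mutations,label``) relative to ``wt``."""
    from .mutations import diff_sequences, format_mutation_set

    rows = []
    for rec in records:
        muts = diff_sequences(wt.sequence, rec.sequence)
        rows.append(
            {
                "id": rec.id,
                "mutations": format_mutation_set(muts),
                "label": "" if rec.label is None else rec.label,
            }
        )
    pd.DataFrame(rows, columns=["id", "mutations", "label"]).to_csv(path, index=False)
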