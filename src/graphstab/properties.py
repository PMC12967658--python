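"""Per-residue physicochemical property table and Z-score normalization.

The classifier encodes each residue by five physicochemical descriptors —
Kyte–Doolittle hydropathy, side-chain volume (Å^3), Grantham polarity, net
charge at pH 7 (−1/0/+1) and molecular weight (Da) — plus a per-position
conservation score added downstream.  The five raw columns are Z-scored over
the 20 canonical amino acids before use as node features.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 20 canonical amino acids, alphabetical by one-letter code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

PROPERTY_COLUMNS = ["hydropathy", "volume", "polarity", "charge", "mw"]


@dataclass
class ResiduePropertyTable:
    """Raw and Z-scored physicochemical values for the 20 canonical residues.

    Attributes
    ----------
    raw : pandas.DataFrame
        One row per amino acid (index = one-letter code), columns
        ``hydropathy, volume, polarity, charge, mw``.
    zscored : pandas.DataFrame
        Same shape; each column standardized to mean 0 and *population*
        standard deviation 1 (the table is the full population of canonical
        residues).  Constant columns map to all zeros.
    """

    raw: pd.DataFrame
    zscored: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zscored is None:
            self.zscored = zscore_columns(self.raw)

    def feature_row(self, aa: str) -> np.ndarray:
        """Z-scored 5-vector for one amino acid."""
        if aa not in self.raw.index:
            raise KeyError(f"unknown amino acid {aa!r}")
        return self.zscored.loc[aa].to_numpy(dtype=np.float64)

    def feature_matrix(self, sequence: str) -> np.ndarray:
        """(len(sequence), 5) matrix of Z-scored properties."""
        bad = [i for i, a in enumerate(sequence) if a not in self.raw.index]
        if bad:
            raise ValueError(
                f"unknown residue {sequence[bad[0]]!r} at position {bad[0] + 1}"
            )
        return self.zscored.loc[list(sequence)].to_numpy(dtype=np.float64)


def zscore_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each numeric column with the population standard deviation.

    Columns with zero variance normalize to all zeros rather than NaN.
    """
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=0)
    sd_safe = sd.replace(0.0, 1.0)
    out = (table - mean) / sd_safe
    out.loc[:, sd == 0.0] = 0.0
    return out


def load_property_table(path=None) -> ResiduePropertyTable:
    """Load the amino-acid property CSV (header ``aa,hydropathy,volume,polarity,charge,mw``).

    With no argument the table shipped with the package is used.

    Raises
    ------
    ValueError
        If the table does not cover exactly the 20 canonical amino acids or
        contains non-numeric cells.
    """
    if path is None:
        ref = importlib.resources.files("graphstab.data") / "aa_properties.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if "aa" not in df.columns:
        raise ValueError("property table must have an 'aa' column")
    missing = [c for c in PROPERTY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"property table missing columns: {missing}")
    df = df.set_index("aa")[PROPERTY_COLUMNS]
    absent = sorted(set(AMINO_ACIDS) - set(df.index))
    if absent:
        raise ValueError(f"property table missing amino acids: {absent}")
    extra = sorted(set(df.index) - set(AMINO_ACIDS))
    if extra:
        raise ValueError(f"property table has unknown rows: {extra}")
    if len(df) != 20:
        raise ValueError(f"property table must have 20 rows, got {len(df)}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in property table: {exc}") from exc
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite value in property table")
    # stable canonical row order
    df = df.loc[list(AMINO_ACIDS)]
    return ResiduePropertyTable(raw=df)


def zscore_table(table: ResiduePropertyTable) -> ResiduePropertyTable:
    """Return a table whose ``zscored`` frame is freshly recomputed from ``raw``."""
    return ResiduePropertyTable(raw=table.raw.copy(), zscored=zscore_columns(table.raw))
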