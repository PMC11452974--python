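"""Protein-level TMT quantitation tables and their TSV/CSV readers.

The table is a thin wrapper around a pandas DataFrame whose rows are
proteins (accession, gene symbol, Sum PEP Score, unique-peptide count)
and whose remaining columns are per-channel reporter abundances.  Missing
measurements are NaN.  A provenance list records, append-only, every
filtering/normalization step applied so a result can be traced back to
its raw export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import ChannelDesign

META_COLUMNS = ("accession", "gene_symbol", "sum_pep_score", "unique_peptides")

#: Cell contents parsed as a missing measurement.
NA_TOKENS = ("", "NA", "NaN", "nan", "N/A")


class QuantFormatError(ValueError):
    """Raised when a quant-table file does not match the declared layout."""


@dataclass
class ProteinQuantTable:
    """Protein rows x TMT channel abundances with QC metadata.

    ``data`` holds the meta columns followed by one column per design
    channel (named by reporter label).  Abundances are non-negative
    floats or NaN for missing.  Row order is meaningful and preserved by
    every operation in the package.
    """

    data: pd.DataFrame
    design: ChannelDesign
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing_meta = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing_meta:
            raise QuantFormatError(f"missing metadata columns: {missing_meta}")
        missing_chan = [l for l in self.design.labels if l not in self.data.columns]
        if missing_chan:
            raise QuantFormatError(f"missing channel columns: {missing_chan}")
        dupes = self.data["accession"][self.data["accession"].duplicated()].tolist()
        if dupes:
            raise QuantFormatError(f"duplicate accessions: {sorted(set(dupes))}")
        mat = self.abundance_matrix()
        if np.nanmin(mat, initial=0.0) < 0:
            raise QuantFormatError("negative abundance values present")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def accessions(self) -> pd.Series:
        return self.data["accession"]

    def abundance_matrix(self) -> np.ndarray:
        """(n_proteins, n_channels) float array in design channel order."""
        return self.data.loc[:, list(self.design.labels)].to_numpy(dtype=float)

    def with_abundances(self, matrix: np.ndarray, step: str | None = None) -> "ProteinQuantTable":
        """Copy of the table with a new abundance matrix; optionally record a step."""
        if matrix.shape != (len(self.data), len(self.design.labels)):
            raise ValueError(f"matrix shape {matrix.shape} does not match table")
        data = self.data.copy()
        data.loc[:, list(self.design.labels)] = matrix
        prov = list(self.provenance) + ([step] if step else [])
        return ProteinQuantTable(data, self.design, prov)

    def subset(self, mask: np.ndarray, step: str | None = None) -> "ProteinQuantTable":
        data = self.data.loc[mask].reset_index(drop=True)
        prov = list(self.provenance) + ([step] if step else [])
        return ProteinQuantTable(data, self.design, prov)


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_quant_table(
    path: str | Path,
    column_map: Mapping[str, object],
    design: ChannelDesign,
) -> ProteinQuantTable:
    """Read a Proteome-Discoverer-style protein export.

    ``column_map`` maps each metadata field name (see ``META_COLUMNS``) to
    its file column, and contains a ``"channels"`` sub-mapping from design
    channel label to the file column carrying that channel's abundance.
    Blank/NA cells and exact zeros become missing values (log-scale
    normalization needs strictly positive intensities, and a zero reporter
    intensity is a failed measurement, not a quantity).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_cols = dict(column_map.get("channels", {}))
    for label in design.labels:
        if label not in channel_cols:
            raise QuantFormatError(f"column_map.channels lacks design channel {label!r}")
    for fld in META_COLUMNS:
        if fld not in column_map:
            raise QuantFormatError(f"column_map lacks required field {fld!r}")

    raw = pd.read_csv(path, sep=_delimiter_for(path), dtype=str, keep_default_na=False)
    wanted = {column_map[f] for f in META_COLUMNS} | set(channel_cols.values())
    absent = sorted(c for c in wanted if c not in raw.columns)
    if absent:
        raise QuantFormatError(f"file {path.name} lacks mapped columns: {absent}")

    data = pd.DataFrame(
        {
            "accession": raw[column_map["accession"]],
            "gene_symbol": raw[column_map["gene_symbol"]],
            "sum_pep_score": pd.to_numeric(raw[column_map["sum_pep_score"]], errors="coerce"),
            "unique_peptides": pd.to_numeric(raw[column_map["unique_peptides"]], errors="coerce")
            .fillna(0)
            .astype(int),
        }
    )
    for label in design.labels:
        col = raw[channel_cols[label]].copy()
        col[col.isin(NA_TOKENS)] = "nan"
        vals = pd.to_numeric(col, errors="coerce").astype(float)
        vals[vals == 0.0] = math.nan
        data[label] = vals
    return ProteinQuantTable(data, design, provenance=[f"read:{path.name}"])


def write_quant_table(table: ProteinQuantTable, path: str | Path) -> None:
    """Write meta + channel columns; missing abundances as empty cells."""
    path = Path(path)
    out = table.data.loc[:, list(META_COLUMNS) + list(table.design.labels)]
    out.to_csv(path, sep=_delimiter_for(path), index=False, na_rep="")


def default_column_map(design: ChannelDesign) -> dict[str, object]:
    """Identity mapping for tables written by :func:`write_quant_table`."""
    cmap: dict[str, object] = {f: f for f in META_COLUMNS}
    cmap["channels"] = {l: l for l in design.labels}
    return cmap
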