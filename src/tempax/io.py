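"""Tabular containers for expression and qPCR data with TSV round-trip.

All on-disk formats are plain TSV so that datasets survive text-only
archiving: an expression dataset is three files (matrix, probe annotation,
cell annotation) and a qPCR dataset is a single Ct table in which a Ct of
40 encodes "undetected".
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Ct value recorded for undetected transcripts; also the clipping ceiling.
UNDETECTED_CT = 40.0

PROBE_COLUMNS = ("symbol", "gene_class", "spike_copies")
CELL_COLUMNS = ("stage", "cell_type", "condition")


@dataclasses.dataclass
class ExpressionMatrix:
    """Probes x cells linear-scale signal matrix with annotations.

    Parameters
    ----------
    values
        DataFrame indexed by probe id, one column per cell id, linear-scale
        signal intensities (non-negative).
    probes
        Probe annotation indexed by probe id with columns ``symbol``,
        ``gene_class`` and ``spike_copies`` (NaN for non-spike probes).
    cells
        Cell annotation indexed by cell id with columns ``stage``,
        ``cell_type`` and ``condition``.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.rename_axis(index=None, columns=None)
        self.probes = self.probes.rename_axis(index=None)
        self.cells = self.cells.rename_axis(index=None)
        if not self.values.index.equals(self.probes.index):
            self.probes = self.probes.reindex(self.values.index)
        if not self.values.columns.equals(self.cells.index):
            self.cells = self.cells.reindex(self.values.columns)
        for col in PROBE_COLUMNS:
            if col not in self.probes.columns:
                self.probes[col] = np.nan
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                self.cells[col] = ""

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2(self, floor: float = 1.0) -> pd.DataFrame:
        """Log2 signal with values below ``floor`` clipped up to it.

        The floor maps zero (undetected) signal to log2 value 0 by default,
        keeping downstream statistics finite.
        """
        return np.log2(self.values.clip(lower=floor))

    def subset(
        self,
        probes: Sequence[str] | None = None,
        cells: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        values = self.values
        if probes is not None:
            missing = set(probes) - set(values.index)
            if missing:
                raise KeyError(f"unknown probes: {sorted(missing)}")
            values = values.loc[list(probes)]
        if cells is not None:
            missing = set(cells) - set(values.columns)
            if missing:
                raise KeyError(f"unknown cells: {sorted(missing)}")
            values = values[list(cells)]
        return ExpressionMatrix(
            values=values.copy(),
            probes=self.probes.loc[values.index].copy(),
            cells=self.cells.loc[values.columns].copy(),
        )

    def symbols_to_probes(self, symbols: Iterable[str]) -> list[str]:
        """Map gene symbols to probe ids (first probe per symbol, sorted)."""
        lookup: dict[str, str] = {}
        for pid, sym in sorted(self.probes["symbol"].items()):
            lookup.setdefault(sym, pid)
        out = []
        for sym in symbols:
            if sym not in lookup:
                raise KeyError(f"no probe for symbol {sym!r}")
            out.append(lookup[sym])
        return out

    def write(self, outdir: str | pathlib.Path, prefix: str = "") -> None:
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.values.rename_axis("probe_id").to_csv(
            outdir / f"{prefix}matrix.tsv", sep="\t"
        )
        self.probes.rename_axis("probe_id").to_csv(
            outdir / f"{prefix}probes.tsv", sep="\t"
        )
        self.cells.rename_axis("cell_id").to_csv(
            outdir / f"{prefix}cells.tsv", sep="\t"
        )

    @classmethod
    def read(
        cls,
        matrix: str | pathlib.Path,
        probes: str | pathlib.Path | None = None,
        cells: str | pathlib.Path | None = None,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(matrix, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        if probes is not None:
            probe_df = pd.read_csv(probes, sep="\t", index_col=0)
            probe_df.index = probe_df.index.astype(str)
        else:
            probe_df = pd.DataFrame(index=values.index)
        if cells is not None:
            cell_df = pd.read_csv(cells, sep="\t", index_col=0)
            cell_df.index = cell_df.index.astype(str)
        else:
            cell_df = pd.DataFrame(index=values.columns)
        return cls(values=values, probes=probe_df, cells=cell_df)


@dataclasses.dataclass
class QpcrTable:
    """Genes x cells Ct table; Ct == 40 means undetected."""

    ct: pd.DataFrame

    def __post_init__(self) -> None:
        self.ct = self.ct.rename_axis(index=None, columns=None)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection flags (Ct strictly below the 40-cycle ceiling)."""
        return self.ct < UNDETECTED_CT

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.columns)

    def write(self, path: str | pathlib.Path) -> None:
        self.ct.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | pathlib.Path) -> "QpcrTable":
        ct = pd.read_csv(path, sep="\t", index_col=0)
        ct.index = ct.index.astype(str)
        return cls(ct=ct)
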