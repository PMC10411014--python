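"""Binary gene x genome presence/absence matrices and their on-disk dialects.

The matrix is the central data structure of the pipeline: rows are gene
clusters ("genes"), columns are genome assemblies, and entry (i, j) records
whether gene i was observed in genome j.  Two text dialects are supported: a
plain TSV (genes x genomes, 0/1) and the ``gene_presence_absence.csv`` dialect
produced by Roary, where presence is encoded by a non-empty cell holding the
member sequence identifier.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PresenceAbsenceMatrix"]

# Fixed metadata columns of the Roary gene_presence_absence.csv dialect.
_ROARY_META_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Avg group size nuc",
    "Max group size nuc",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary observations of genes (rows) across genomes (columns)."""

    genes: list[str]
    genomes: list[str]
    entries: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.genomes = [str(g) for g in self.genomes]
        self.entries = np.asarray(self.entries, dtype=np.int8)
        if self.entries.ndim != 2:
            raise ValueError("entries must be a 2-D array")
        m, n = self.entries.shape
        if m != len(self.genes) or n != len(self.genomes):
            raise ValueError(
                f"entries shape {self.entries.shape} does not match "
                f"{len(self.genes)} genes x {len(self.genomes)} genomes"
            )
        if not np.isin(self.entries, (0, 1)).all():
            raise ValueError("entries must be binary (0/1)")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene IDs")
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome IDs")

    # -- basic properties ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_genomes(self) -> int:
        return self.entries.shape[1]

    @property
    def observed_freqs(self) -> np.ndarray:
        """Per-gene fraction of genomes in which the gene was observed."""
        if self.n_genomes == 0:
            return np.zeros(self.n_genes)
        return self.entries.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.genes, columns=self.genomes)

    def select_genomes(self, genomes: list[str]) -> "PresenceAbsenceMatrix":
        """Return a copy restricted to (and ordered by) the given genomes."""
        idx = {g: k for k, g in enumerate(self.genomes)}
        missing = [g for g in genomes if g not in idx]
        if missing:
            raise KeyError(f"unknown genomes: {missing[:5]}")
        cols = [idx[g] for g in genomes]
        return PresenceAbsenceMatrix(list(self.genes), list(genomes), self.entries[:, cols])

    # -- TSV dialect --------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    # -- Roary gene_presence_absence.csv dialect ----------------------------

    def to_roary_csv(self, path) -> None:
        """Write in the Roary dialect; presence encoded as '<gene>_<genome>'."""
        rows = []
        for i, gene in enumerate(self.genes):
            present = self.entries[i] == 1
            row = {
                "Gene": gene,
                "Non-unique Gene name": "",
                "Annotation": "",
                "No. isolates": int(present.sum()),
                "No. sequences": int(present.sum()),
                "Avg sequences per isolate": 1.0 if present.any() else 0.0,
                "Genome Fragment": "",
                "Order within Fragment": "",
                "Accessory Fragment": "",
                "Accessory Order with Fragment": "",
                "QC": "",
                "Min group size nuc": "",
                "Avg group size nuc": "",
                "Max group size nuc": "",
            }
            for j, genome in enumerate(self.genomes):
                row[genome] = f"{gene}_{genome}" if present[j] else ""
            rows.append(row)
        df = pd.DataFrame(rows, columns=_ROARY_META_COLUMNS + self.genomes)
        df.to_csv(path, index=False)

    @classmethod
    def from_roary_csv(cls, path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        meta_cols = [c for c in _ROARY_META_COLUMNS if c in df.columns]
        if "Gene" not in df.columns:
            raise ValueError("not a Roary gene_presence_absence table: no 'Gene' column")
        genome_cols = [c for c in df.columns if c not in meta_cols]
        genes = list(df["Gene"].astype(str))
        entries = (df[genome_cols].to_numpy() != "").astype(np.int8)
        return cls(genes, [str(c) for c in genome_cols], entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return (
            self.genes == other.genes
            and self.genomes == other.genomes
            and np.array_equal(self.entries, other.entries)
        )
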