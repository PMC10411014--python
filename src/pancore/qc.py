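"""Genome quality filtering.

Selects genome assemblies per species by four criteria evaluated against
cohort statistics computed over the species' full input cohort, in a single
pass (no iterative refiltering):

1. contamination strictly below a threshold (default 10%),
2. completeness strictly above a threshold (default 80%),
3. contig count at most `contig_fold` times the species' median contig count,
4. assembly length within `length_sd` population standard deviations of the
   species' mean length.

A species qualifies when at least `min_genomes` of its genomes pass all four
criteria.  For a single-genome species the length criterion is vacuous (the
standard deviation is undefined) and the genome is flagged accordingly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "filter_genomes"]

REQUIRED_COLUMNS = [
    "genome_id",
    "species_id",
    "contamination",
    "completeness",
    "n_contigs",
    "assembly_length",
]

CRITERIA = ("contamination", "completeness", "contigs", "length")


@dataclass
class FilterReport:
    """Outcome of genome filtering: per-species keep sets, per-genome failures."""

    kept: dict[str, set] = field(default_factory=dict)
    rejected: dict[str, list] = field(default_factory=dict)
    qualifying_species: set = field(default_factory=set)
    flags: dict[str, list] = field(default_factory=dict)

    @property
    def kept_genomes(self) -> set:
        out: set = set()
        for s in self.kept.values():
            out |= s
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sp in sorted(self.kept):
            for g in sorted(self.kept[sp]):
                rows.append(
                    {
                        "genome_id": g,
                        "species_id": sp,
                        "kept": True,
                        "failed_criteria": "",
                        "flags": ";".join(self.flags.get(g, [])),
                    }
                )
        species_of = {g: sp for sp, gs in self.kept.items() for g in gs}
        for g, crits in sorted(self.rejected.items()):
            rows.append(
                {
                    "genome_id": g,
                    "species_id": self._rejected_species.get(g, species_of.get(g, "")),
                    "kept": False,
                    "failed_criteria": ";".join(crits),
                    "flags": ";".join(self.flags.get(g, [])),
                }
            )
        return pd.DataFrame(rows)

    _rejected_species: dict = field(default_factory=dict, repr=False)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "n_kept": sum(len(s) for s in self.kept.values()),
            "n_rejected": len(self.rejected),
            "qualifying_species": sorted(self.qualifying_species),
            "kept_per_species": {sp: len(s) for sp, s in sorted(self.kept.items())},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def filter_genomes(
    metadata: pd.DataFrame,
    max_contamination: float = 10.0,
    min_completeness: float = 80.0,
    contig_fold: float = 3.0,
    length_sd: float = 3.0,
    min_genomes: int = 50,
) -> FilterReport:
    """Apply the four quality criteria and the minimum-genomes-per-species rule.

    Cohort statistics (median contig count, mean and population SD of assembly
    length) are computed per species over the full pre-filter cohort.
    """
    if metadata is None or len(metadata) == 0:
        raise ValueError("metadata is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if metadata[REQUIRED_COLUMNS].isna().any().any():
        raise ValueError("metadata contains missing values in required columns")
    if metadata["genome_id"].duplicated().any():
        raise ValueError("duplicate genome IDs in metadata")

    report = FilterReport()
    for sp, cohort in metadata.groupby("species_id", sort=True):
        median_contigs = float(np.median(cohort["n_contigs"]))
        mean_len = float(np.mean(cohort["assembly_length"]))
        sd_len = float(np.std(cohort["assembly_length"], ddof=0)) if len(cohort) > 1 else None
        kept: set = set()
        for row in cohort.itertuples(index=False):
            failed = []
            if not row.contamination < max_contamination:
                failed.append("contamination")
            if not row.completeness > min_completeness:
                failed.append("completeness")
            if not row.n_contigs <= contig_fold * median_contigs:
                failed.append("contigs")
            if sd_len is None:
                report.flags.setdefault(row.genome_id, []).append("length_sd_undefined")
            elif not abs(row.assembly_length - mean_len) <= length_sd * sd_len:
                failed.append("length")
            if failed:
                report.rejected[row.genome_id] = failed
                report._rejected_species[row.genome_id] = sp
            else:
                kept.add(row.genome_id)
        report.kept[sp] = kept
        if len(kept) >= min_genomes:
            report.qualifying_species.add(sp)
    return report
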