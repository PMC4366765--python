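"""Peptide- and protein-level acceptance filtering of PSM exports.

The input is a simplified tab-delimited peptide-spectrum-match (PSM)
export of the kind produced by search-result validation tools (one row
per PSM: run of origin, matched peptide sequence, mapped accession(s),
posterior probabilities, decoy flag). Two gates are applied before any
quantification:

* **peptide gate** -- PSMs below a posterior-probability floor are
  discarded; if the decoy-estimated false discovery rate (FDR) of the
  survivors still exceeds a ceiling, the probability cutoff is raised
  to the smallest observed value that brings the FDR under the ceiling.
* **protein gate** -- per run, proteins below a protein-probability
  floor, or with fewer uniquely mapping peptide sequences than the
  two-peptide rule requires, are dropped.

The FDR estimate is the global decoy ratio ``decoys / targets`` over
the retained set. Protein probabilities are consumed as given in the
export, never recomputed here. A PSM shared by several accessions
contributes to the spectral count of each of them, but only peptides
exclusive to an accession count toward its unique-peptide tally, so
the two-peptide rule keeps its discriminating power.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "PsmRecord",
    "ProteinIdentification",
    "estimate_fdr",
    "filter_peptides",
    "infer_proteins",
    "read_psm_export",
    "write_psm_export",
    "PSM_COLUMNS",
]

#: Column order of the tab-delimited PSM export dialect.
PSM_COLUMNS = [
    "spectrum_id",
    "run_id",
    "peptide_sequence",
    "accessions",
    "peptide_probability",
    "protein_probability",
    "decoy",
]


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match, the unit of identification filtering."""

    spectrum_id: str
    run_id: str
    peptide_sequence: str
    protein_accessions: tuple[str, ...]
    peptide_probability: float
    protein_probability: float = 1.0
    decoy_flag: bool = False

    def __post_init__(self) -> None:
        if not self.protein_accessions:
            raise ValueError(
                f"PSM {self.spectrum_id!r}: protein_accessions must be non-empty"
            )
        for name, p in (
            ("peptide_probability", self.peptide_probability),
            ("protein_probability", self.protein_probability),
        ):
            if not (0.0 <= p <= 1.0) or math.isnan(p):
                raise ValueError(
                    f"PSM {self.spectrum_id!r}: {name} {p!r} outside [0, 1]"
                )


@dataclass(frozen=True)
class ProteinIdentification:
    """A protein accepted in one run, with its evidence summary.

    ``unique_peptides`` counts distinct peptide sequences mapping
    exclusively to this accession within the run; ``spectral_count``
    counts every PSM mapped to it (shared PSMs included).
    """

    accession: str
    run_id: str
    protein_probability: float
    unique_peptides: int
    spectral_count: int


def estimate_fdr(psms: Sequence[PsmRecord]) -> float:
    """Global decoy FDR estimate, decoys / targets, of a PSM set.

    Empty input and all-target input give 0; decoys with no targets
    give ``inf``.
    """
    decoys = sum(1 for p in psms if p.decoy_flag)
    targets = len(psms) - decoys
    if decoys == 0:
        return 0.0
    if targets == 0:
        return math.inf
    return decoys / targets


def filter_peptides(
    psms: Sequence[PsmRecord],
    min_probability: float = 0.90,
    max_fdr: float = 0.001,
) -> list[PsmRecord]:
    """Apply the peptide acceptance gate.

    Retains PSMs with ``peptide_probability >= min_probability``; if the
    decoy-estimated FDR of that set exceeds ``max_fdr``, the probability
    cutoff is raised to the smallest observed probability for which the
    FDR constraint holds (an empty set trivially satisfies it). Input
    order is preserved; the operation is idempotent.
    """
    if not (0.0 <= min_probability <= 1.0):
        raise ValueError(f"min_probability {min_probability!r} outside [0, 1]")
    if not (0.0 < max_fdr <= 1.0):
        raise ValueError(f"max_fdr {max_fdr!r} outside (0, 1]")

    retained = [p for p in psms if p.peptide_probability >= min_probability]
    if estimate_fdr(retained) <= max_fdr:
        return retained
    # Scan candidate cutoffs (observed probabilities) from the bottom up;
    # the decoy ratio is not monotone, so every candidate is checked.
    for cutoff in sorted({p.peptide_probability for p in retained}):
        subset = [p for p in retained if p.peptide_probability >= cutoff]
        if estimate_fdr(subset) <= max_fdr:
            return subset
    return []


def infer_proteins(
    psms: Sequence[PsmRecord],
    min_protein_probability: float = 0.95,
    min_unique_peptides: int = 2,
) -> list[ProteinIdentification]:
    """Apply the protein acceptance gate per run.

    PSMs are grouped by accession within each run (decoy PSMs are
    ignored -- they exist only to estimate the FDR). A protein is
    accepted in a run when its probability reaches
    ``min_protein_probability`` and it has at least
    ``min_unique_peptides`` distinct exclusively mapping peptide
    sequences. Results are sorted by (run_id, accession).
    """
    if min_unique_peptides < 1:
        raise ValueError(
            f"min_unique_peptides must be >= 1, got {min_unique_peptides}"
        )
    if not (0.0 <= min_protein_probability <= 1.0):
        raise ValueError(
            f"min_protein_probability {min_protein_probability!r} outside [0, 1]"
        )

    by_run: dict[str, list[PsmRecord]] = defaultdict(list)
    for psm in psms:
        if not psm.decoy_flag:
            by_run[psm.run_id].append(psm)

    accepted: list[ProteinIdentification] = []
    for run_id, run_psms in by_run.items():
        peptide_owners: dict[str, set[str]] = defaultdict(set)
        by_accession: dict[str, list[PsmRecord]] = defaultdict(list)
        for psm in run_psms:
            for acc in psm.protein_accessions:
                peptide_owners[psm.peptide_sequence].add(acc)
                by_accession[acc].append(psm)
        for acc, rows in by_accession.items():
            exclusive = {
                r.peptide_sequence
                for r in rows
                if peptide_owners[r.peptide_sequence] == {acc}
            }
            probability = max(r.protein_probability for r in rows)
            if probability >= min_protein_probability and len(exclusive) >= min_unique_peptides:
                accepted.append(
                    ProteinIdentification(
                        accession=acc,
                        run_id=run_id,
                        protein_probability=probability,
                        unique_peptides=len(exclusive),
                        spectral_count=len(rows),
                    )
                )
    accepted.sort(key=lambda pid: (pid.run_id, pid.accession))
    return accepted


def read_psm_export(path: str | Path) -> list[PsmRecord]:
    """Read the tab-delimited PSM export dialect into records."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(PSM_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing PSM export columns {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            PsmRecord(
                spectrum_id=row.spectrum_id,
                run_id=row.run_id,
                peptide_sequence=row.peptide_sequence,
                protein_accessions=tuple(row.accessions.split(";")),
                peptide_probability=float(row.peptide_probability),
                protein_probability=float(row.protein_probability),
                decoy_flag=row.decoy == "1",
            )
        )
    return records


def write_psm_export(psms: Iterable[PsmRecord], path: str | Path) -> None:
    """Write records in the tab-delimited PSM export dialect."""
    rows = [
        {
            "spectrum_id": p.spectrum_id,
            "run_id": p.run_id,
            "peptide_sequence": p.peptide_sequence,
            "accessions": ";".join(p.protein_accessions),
            "peptide_probability": f"{p.peptide_probability:.6g}",
            "protein_probability": f"{p.protein_probability:.6g}",
            "decoy": "1" if p.decoy_flag else "0",
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=PSM_COLUMNS).to_csv(path, sep="\t", index=False)
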