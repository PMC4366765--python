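"""Bundled reference tables from the rat UUO urinary-proteomics study.

Three small TSV fixtures transcribe the study's printed tables:

* **T1** -- per-run identified-protein counts: 3 groups (sham-operation,
  UUO 1-week, UUO 3-week) x 3 animals x 3 technical replicates.
* **T2** -- the 7 proteins called significantly changed at UUO 1 week,
  with fold change, post hoc P, ANOVA F and the per-animal spectral
  counts of the sham and UUO 1-week animals.
* **T3** -- the significantly changed proteins at UUO 3 weeks, same
  layout. The study reports 19 such proteins; the transcription
  available to this package preserves 18 of them, and the loader checks
  for exactly those 18 rows.

The transcriptions are exact (including the printed rounding of fold,
P and F) and are integrity-checked by SHA-256 at load time. The
spectral-count columns are the per-animal values the study's statistics
were computed from.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .quantification import CountMatrix, build_count_matrix

__all__ = ["FixtureTable", "load_fixture", "fixture_count_matrix", "TABLE_IDS"]

_TABLES = {
    "T1": (
        "table1_run_identifications.tsv",
        "cd2d434b87165699c2329392fbce53b38851a6f80eec9b11e9a44747453d71c1",
        27,
    ),
    "T2": (
        "table2_uuo1w_differential.tsv",
        "79982910aa2239291308e0de959152e65ce42bb559a8336022cd1fce3b0f67ea",
        7,
    ),
    "T3": (
        "table3_uuo3w_differential.tsv",
        "40761ea3cf0fff47514dee2e1382a6325cb3b6f304d5f5cecc2c7627987a9681",
        18,
    ),
}

TABLE_IDS = tuple(_TABLES)

#: Comparison group whose animals appear in each differential table.
TABLE_COMPARISON = {"T2": "uuo1w", "T3": "uuo3w"}


@dataclass(frozen=True)
class FixtureTable:
    """One reference table: its id and the transcribed rows."""

    table_id: str
    data: pd.DataFrame


def load_fixture(table_id: str) -> FixtureTable:
    """Load and integrity-check a bundled reference table."""
    if table_id not in _TABLES:
        raise KeyError(f"unknown table id {table_id!r}; valid: {TABLE_IDS}")
    filename, expected_sha, expected_rows = _TABLES[table_id]
    raw = (resources.files("spectracount") / "data" / filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != expected_sha:
        raise ValueError(
            f"fixture {filename} is corrupted: sha256 {digest} != {expected_sha}"
        )
    frame = pd.read_csv(resources.files("spectracount") / "data" / filename, sep="\t")
    if len(frame) != expected_rows:
        raise ValueError(
            f"fixture {filename}: expected {expected_rows} rows, got {len(frame)}"
        )
    return FixtureTable(table_id=table_id, data=frame)


def fixture_count_matrix(table_id: str) -> CountMatrix:
    """Build the sham + UUO count matrix of a differential table (T2/T3)."""
    if table_id not in TABLE_COMPARISON:
        raise KeyError(f"count matrix only defined for T2/T3, got {table_id!r}")
    table = load_fixture(table_id)
    uuo = TABLE_COMPARISON[table_id]
    animals = [f"sham_{i}" for i in (1, 2, 3)] + [f"{uuo}_{i}" for i in (1, 2, 3)]
    per_animal = {
        a: dict(zip(table.data["accession"], table.data[a].astype(float)))
        for a in animals
    }
    design = {a: a.rsplit("_", 1)[0] for a in animals}
    return build_count_matrix(per_animal, design)
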