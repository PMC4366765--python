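"""Synthetic spectral-count datasets with known ground truth.

Emulates the study design the analysis assumes: three groups
(sham, uuo1w, uuo3w) x three animals x three technical replicates of
non-negative integer spectral counts, with planted fold-change effects
and optional replicate dropout.

Generative model, per protein and animal:

* the group mean is ``base_mean`` times ``planted_fold`` in affected
  groups (1 elsewhere);
* an animal-level biological effect multiplies the group mean by
  ``exp(N(0, sigma) - sigma^2/2)`` (mean-preserving lognormal;
  ``animal_sigma`` default 0.2, matching the ~20% coefficient of
  variation of the reference tables' UUO triples);
* each technical replicate draws a negative-binomial count around the
  animal mean with dispersion ``r`` (variance ``mu + mu^2/r``; default
  r = 20, i.e. mild overdispersion relative to Poisson -- pass
  ``dispersion=inf`` for a Poisson oracle);
* each replicate count is independently zeroed with probability
  ``dropout_rate``, emulating a protein missing from an injection.

All randomness flows through an explicit integer seed; the same seed
reproduces the dataset byte for byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .identification import PsmRecord
from .quantification import RunCounts

__all__ = [
    "SyntheticTruth",
    "GROUPS",
    "generate_dataset",
    "generate_psm_export",
    "truth_to_frame",
    "write_runs_tsv",
    "read_runs_tsv",
]

GROUPS = ("sham", "uuo1w", "uuo3w")

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters for one simulated protein."""

    accession: str
    base_mean: float
    planted_fold: float = 1.0
    dropout_rate: float = 0.0
    dispersion: float = 20.0
    affected_groups: tuple[str, ...] = ("uuo1w", "uuo3w")

    def __post_init__(self) -> None:
        if self.base_mean <= 0:
            raise ValueError(f"{self.accession}: base_mean must be > 0")
        if self.planted_fold < 1:
            raise ValueError(
                f"{self.accession}: planted_fold must be >= 1 (1 = null)"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError(f"{self.accession}: dropout_rate must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError(f"{self.accession}: dispersion must be > 0")

    @property
    def is_null(self) -> bool:
        return self.planted_fold == 1.0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with given means and size parameters r.

    Infinite r falls back to Poisson (the zero-overdispersion limit).
    """
    counts = np.empty(mean.shape, dtype=np.int64)
    finite = np.isfinite(r)
    if finite.any():
        p = r[finite] / (r[finite] + mean[finite])
        counts[finite] = rng.negative_binomial(r[finite], p)
    if (~finite).any():
        counts[~finite] = rng.poisson(mean[~finite])
    return counts


def generate_dataset(
    truths: Sequence[SyntheticTruth],
    n_animals: int = 3,
    n_replicates: int = 3,
    seed: int | None = None,
    groups: Sequence[str] = GROUPS,
    animal_sigma: float = 0.2,
) -> tuple[list[RunCounts], pd.DataFrame]:
    """Simulate replicate-level spectral counts for a full study design.

    Returns the runs (one ``RunCounts`` per group x animal x replicate,
    animal labels ``<group>_<i>``) and the truth table as a DataFrame
    sharing accession keys with the dataset.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if n_animals < 1 or n_replicates < 1:
        raise ValueError("n_animals and n_replicates must be positive")
    if animal_sigma < 0:
        raise ValueError("animal_sigma must be >= 0")
    if len({t.accession for t in truths}) != len(truths):
        raise ValueError("duplicate accessions in truth list")

    rng = np.random.default_rng(seed)
    accessions = [t.accession for t in truths]
    base = np.array([t.base_mean for t in truths])
    fold = np.array([t.planted_fold for t in truths])
    dropout = np.array([t.dropout_rate for t in truths])
    r = np.array([t.dispersion for t in truths])

    runs: list[RunCounts] = []
    for group in groups:
        affected = np.array([group in t.affected_groups for t in truths])
        group_mean = base * np.where(affected, fold, 1.0)
        for animal in range(1, n_animals + 1):
            effect = np.exp(
                rng.normal(0.0, animal_sigma, size=len(truths))
                - animal_sigma**2 / 2.0
            )
            animal_mean = group_mean * effect
            label = f"{group}_{animal}"
            for rep in range(1, n_replicates + 1):
                counts = _nb_draw(rng, animal_mean, r)
                dropped = rng.random(len(truths)) < dropout
                counts = np.where(dropped, 0, counts)
                runs.append(
                    RunCounts(
                        animal_id=label,
                        replicate_index=rep,
                        counts=dict(zip(accessions, (int(c) for c in counts))),
                    )
                )
    return runs, truth_to_frame(truths)


def truth_to_frame(truths: Sequence[SyntheticTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "accession": [t.accession for t in truths],
            "base_mean": [t.base_mean for t in truths],
            "planted_fold": [t.planted_fold for t in truths],
            "dropout_rate": [t.dropout_rate for t in truths],
            "dispersion": [t.dispersion for t in truths],
            "affected_groups": [";".join(t.affected_groups) for t in truths],
        }
    )


def _peptide(accession: str, index: int, length: int = 9) -> str:
    """Deterministic pseudo-tryptic peptide for a (protein, index) pair."""
    digest = hashlib.sha256(f"pep|{accession}|{index}".encode()).digest()
    state = int.from_bytes(digest[:4], "big")
    rng = np.random.default_rng(state)
    body = "".join(rng.choice(list(_AMINO_ACIDS), size=length - 1))
    return body + "K"


def generate_psm_export(
    run: RunCounts,
    decoy_fraction: float = 0.0,
    peptides_per_protein: int = 3,
    target_beta: tuple[float, float] = (40.0, 2.0),
    decoy_beta: tuple[float, float] = (2.0, 8.0),
    protein_probability: float = 0.99,
    seed: int | None = None,
) -> list[PsmRecord]:
    """Expand one run's counts into PSM rows.

    Each count of ``c`` becomes ``c`` PSM rows cycling through
    ``peptides_per_protein`` distinct synthetic peptide sequences, so a
    protein with ``c >= k`` counts shows exactly ``k`` distinct
    peptides. Peptide probabilities are Beta-distributed (targets high,
    decoys low); decoy rows are appended so that decoys make up
    ``decoy_fraction`` of all rows.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    if not (0.0 <= decoy_fraction <= 0.5):
        raise ValueError("decoy_fraction must be in [0, 0.5]")
    if peptides_per_protein < 1:
        raise ValueError("peptides_per_protein must be >= 1")

    rng = np.random.default_rng(seed)
    run_label = f"{run.animal_id}_{run.replicate_index}"
    psms: list[PsmRecord] = []
    for acc in sorted(run.counts):
        count = run.counts[acc]
        for j in range(count):
            psms.append(
                PsmRecord(
                    spectrum_id=f"{run_label}.{acc}.{j + 1}",
                    run_id=run_label,
                    peptide_sequence=_peptide(acc, j % peptides_per_protein),
                    protein_accessions=(acc,),
                    peptide_probability=float(rng.beta(*target_beta)),
                    protein_probability=protein_probability,
                    decoy_flag=False,
                )
            )
    n_targets = len(psms)
    if decoy_fraction > 0.0 and n_targets > 0:
        n_decoys = round(n_targets * decoy_fraction / (1.0 - decoy_fraction))
        for i in range(n_decoys):
            acc = f"DECOY_{i + 1}"
            psms.append(
                PsmRecord(
                    spectrum_id=f"{run_label}.{acc}.1",
                    run_id=run_label,
                    peptide_sequence=_peptide(acc, 0),
                    protein_accessions=(acc,),
                    peptide_probability=float(rng.beta(*decoy_beta)),
                    protein_probability=0.5,
                    decoy_flag=True,
                )
            )
    return psms


def write_runs_tsv(runs: Sequence[RunCounts], path: str | Path) -> None:
    """Write replicate-level runs as a raw count matrix TSV.

    Columns are ``<group>_<animal>_<replicate>``; rows the union of
    accessions, missing entries 0.
    """
    accessions = sorted({acc for r in runs for acc in r.counts})
    columns = {
        f"{r.animal_id}_{r.replicate_index}": [r.counts.get(a, 0) for a in accessions]
        for r in runs
    }
    frame = pd.DataFrame(columns, index=pd.Index(accessions, name="accession"))
    frame.to_csv(path, sep="\t")


def read_runs_tsv(path: str | Path) -> list[RunCounts]:
    """Read a replicate-level raw count matrix TSV back into runs."""
    frame = pd.read_csv(path, sep="\t", index_col="accession")
    runs = []
    for col in frame.columns:
        animal, rep = col.rsplit("_", 1)
        runs.append(
            RunCounts(
                animal_id=animal,
                replicate_index=int(rep),
                counts={acc: int(v) for acc, v in frame[col].items()},
            )
        )
    return runs
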