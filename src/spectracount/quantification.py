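"""Technical-replicate aggregation and count-matrix assembly.

Each animal's urine sample is injected three times; a protein's
per-animal abundance is the arithmetic mean of its spectral counts over
the three technical replicates, **provided it was observed (count > 0)
in all three**. A protein absent from any replicate gets abundance 0
for that animal -- never a partial mean. No between-sample
normalisation is applied; the downstream fold-change threshold is the
stated compensation for unequal total counts between groups.

Run labels follow the dialect ``<group>_<animal>`` for aggregated
columns and ``<group>_<animal>_<replicate>`` for raw replicate runs,
where the group label itself contains no underscore (``sham``,
``uuo1w``, ``uuo3w``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "RunCounts",
    "CountMatrix",
    "aggregate_technical_replicates",
    "build_count_matrix",
    "count_identified_proteins",
    "parse_run_label",
]

N_TECHNICAL_REPLICATES = 3


@dataclass(frozen=True)
class RunCounts:
    """Spectral counts of one LC-MS/MS injection (one technical replicate)."""

    animal_id: str
    replicate_index: int
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.replicate_index not in (1, 2, 3):
            raise ValueError(
                f"animal {self.animal_id!r}: replicate_index must be 1..3, "
                f"got {self.replicate_index}"
            )
        for acc, c in self.counts.items():
            if c < 0:
                raise ValueError(
                    f"animal {self.animal_id!r}: negative count {c} for {acc!r}"
                )


def parse_run_label(label: str) -> tuple[str, str, int | None]:
    """Split a run/column label into (group, animal_id, replicate or None)."""
    parts = label.split("_")
    if len(parts) >= 3 and parts[-1].isdigit():
        return parts[0], "_".join(parts[:-1]), int(parts[-1])
    return parts[0], label, None


def aggregate_technical_replicates(runs: Sequence[RunCounts]) -> dict[str, float]:
    """Aggregate one animal's three technical replicates.

    Returns accession -> abundance, where abundance is the mean count of
    a protein observed (count > 0) in all three replicates, and 0.0 for
    a protein absent from any replicate.
    """
    animals = {r.animal_id for r in runs}
    if len(animals) != 1:
        raise ValueError(f"replicates span several animals: {sorted(animals)}")
    animal = next(iter(animals))
    if len(runs) != N_TECHNICAL_REPLICATES:
        raise ValueError(
            f"animal {animal!r}: expected {N_TECHNICAL_REPLICATES} technical "
            f"replicates, got {len(runs)}"
        )
    if {r.replicate_index for r in runs} != {1, 2, 3}:
        raise ValueError(f"animal {animal!r}: replicate indices must be 1, 2, 3")

    accessions = set()
    for r in runs:
        accessions.update(r.counts)
    out: dict[str, float] = {}
    for acc in accessions:
        triple = [r.counts.get(acc, 0) for r in runs]
        out[acc] = sum(triple) / 3.0 if all(c > 0 for c in triple) else 0.0
    return out


@dataclass
class CountMatrix:
    """Proteins x animals abundance matrix with a group design.

    ``values`` is indexed by accession (lexicographic) with one column
    per animal label; ``groups`` maps each animal label to its group.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"animals without group label: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("count matrix contains negative values")

    def animals_in_group(self, group: str) -> list[str]:
        return [a for a in self.values.columns if self.groups[a] == group]

    @property
    def group_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.values.columns:
            seen.setdefault(self.groups[a], None)
        return list(seen)

    def to_tsv(self, path: str | Path) -> None:
        frame = self.values.copy()
        frame.index.name = "accession"
        frame.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="accession")
        groups = {col: parse_run_label(col)[0] for col in frame.columns}
        return cls(values=frame.sort_index(), groups=groups)


def build_count_matrix(
    per_animal: Mapping[str, Mapping[str, float]],
    design: Mapping[str, str] | Iterable[tuple[str, str]],
) -> CountMatrix:
    """Assemble per-animal abundance maps into a CountMatrix.

    ``design`` maps animal label -> group label and fixes column order.
    Missing (accession, animal) entries are filled with 0; rows are
    sorted lexicographically by accession.
    """
    if isinstance(design, Mapping):
        pairs = list(design.items())
    else:
        pairs = list(design)
    animals = [a for a, _ in pairs]
    if len(set(animals)) != len(animals):
        dupes = sorted({a for a in animals if animals.count(a) > 1})
        raise ValueError(f"duplicate animal labels in design: {dupes}")
    missing = [a for a in animals if a not in per_animal]
    if missing:
        raise ValueError(f"animals in design without abundances: {missing}")

    accessions = sorted({acc for a in animals for acc in per_animal[a]})
    frame = pd.DataFrame(
        {a: [per_animal[a].get(acc, 0.0) for acc in accessions] for a in animals},
        index=pd.Index(accessions, name="accession"),
        dtype=float,
    )
    return CountMatrix(values=frame, groups=dict(pairs))


def count_identified_proteins(run: RunCounts, accepted: set[str]) -> int:
    """Number of accepted accessions observed (count > 0) in a run."""
    return sum(1 for acc, c in run.counts.items() if acc in accepted and c > 0)
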