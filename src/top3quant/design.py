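"""Study design: which MS runs belong to which condition.

The pipeline compares exactly two conditions (e.g. a tumor-derived and a
normal cell line) measured in replicate injections. A :class:`StudyDesign`
is the single source of truth for run ids, condition labels and replicate
numbering; every reader and statistical routine validates against it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping


@dataclass(frozen=True)
class RunSpec:
    """One MS injection: its id, condition label and replicate number."""

    run_id: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValueError("run_id must be a non-empty string")
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class StudyDesign:
    """Two-condition replicated design.

    Invariants: run ids unique, exactly two condition labels, every
    condition with at least two replicates (the default design uses three,
    matching a 3/3 full-replication filter downstream).
    """

    runs: tuple[RunSpec, ...]

    def __post_init__(self) -> None:
        ids = [r.run_id for r in self.runs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate run_ids in design: {dupes}")
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(
                f"design must have exactly two conditions, got {sorted(conds)}"
            )
        for c in conds:
            if len(self.runs_for(c)) < 2:
                raise ValueError(f"condition {c!r} has fewer than 2 replicates")

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for r in self.runs:
            if r.condition not in seen:
                seen.append(r.condition)
        return seen

    def runs_for(self, condition: str) -> list[str]:
        return [r.run_id for r in self.runs if r.condition == condition]

    def condition_of(self, run_id: str) -> str:
        for r in self.runs:
            if r.run_id == run_id:
                return r.condition
        raise KeyError(f"unknown run_id {run_id!r}")

    def swap_conditions(self) -> "StudyDesign":
        """Return a design with the two condition labels exchanged."""
        a, b = self.conditions
        remap = {a: b, b: a}
        return StudyDesign(
            tuple(RunSpec(r.run_id, remap[r.condition], r.replicate) for r in self.runs)
        )

    @classmethod
    def default(
        cls, n_replicates: int = 3, conditions: tuple[str, str] = ("tumor", "control")
    ) -> "StudyDesign":
        """Two conditions x ``n_replicates`` runs, ids ``<condition>_<i>``."""
        runs = [
            RunSpec(f"{cond}_{i}", cond, i)
            for cond in conditions
            for i in range(1, n_replicates + 1)
        ]
        return cls(tuple(runs))

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "StudyDesign":
        """Build from dicts with keys run_id / condition / replicate."""
        return cls(
            tuple(
                RunSpec(str(r["run_id"]), str(r["condition"]), int(r["replicate"]))
                for r in records
            )
        )
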