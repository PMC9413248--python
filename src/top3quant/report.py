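"""End-of-run summaries and the ligand-conjugation mass balance.

Aggregates the differential classes into a pipeline summary whose counts
must partition the quantified proteins, and implements the bound-ligand
accounting used when a targeting protein (e.g. transferrin) is conjugated
to a nanoparticle: bound = initial - supernatant.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .quantify import ProteinQuantMatrix, QCReport


@dataclass
class ConjugationAccount:
    """Mass balance of a ligand-binding assay (all masses in micrograms)."""

    initial_ligand_mass: float
    supernatant_ligand_mass: float
    bound_ligand_mass: float
    binding_fraction: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"initial {self.initial_ligand_mass:.2f} ug, supernatant "
            f"{self.supernatant_ligand_mass:.2f} ug -> bound "
            f"{self.bound_ligand_mass:.2f} ug ({100 * self.binding_fraction:.1f}%)"
        )


def binding_yield(initial_ug: float, supernatant_ug: float) -> ConjugationAccount:
    """Bound-ligand mass from a magnetic-separation binding assay.

    The ligand left in the supernatant is unbound; the difference from the
    input mass is the nanoparticle-ligand complex. Masses are kept at full
    precision internally; display rounds to 2 decimals.
    """
    if initial_ug <= 0:
        raise ValueError("initial mass must be positive")
    if supernatant_ug < 0:
        raise ValueError("supernatant mass cannot be negative")
    if supernatant_ug > initial_ug:
        raise ValueError(
            f"impossible mass balance: supernatant {supernatant_ug} ug exceeds "
            f"initial {initial_ug} ug"
        )
    bound = initial_ug - supernatant_ug
    return ConjugationAccount(
        initial_ligand_mass=initial_ug,
        supernatant_ligand_mass=supernatant_ug,
        bound_ligand_mass=bound,
        binding_fraction=bound / initial_ug,
    )


@dataclass
class PipelineSummary:
    """Dataset-level counts and QC roll-up; counts partition the proteins."""

    n_peptide_rows: int
    n_proteins_quantified: int
    n_up_tumor: int
    n_up_control: int
    n_unchanged: int
    n_exclusive_tumor: int
    n_exclusive_control: int
    n_decoys_discarded: int
    n_filtered_out: int
    dynamic_range_orders: float
    ppm_within_tolerance_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"value": vars(self)}
        ).rename_axis("quantity")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self
        return (
            f"{s.n_peptide_rows} peptide rows -> {s.n_proteins_quantified} proteins; "
            f"up(tumor)={s.n_up_tumor} up(control)={s.n_up_control} "
            f"unchanged={s.n_unchanged} exclusive={s.n_exclusive_tumor}/"
            f"{s.n_exclusive_control} decoys={s.n_decoys_discarded} "
            f"filtered={s.n_filtered_out}; dynamic range "
            f"{s.dynamic_range_orders:.2f} orders; within-ppm fraction "
            f"{s.ppm_within_tolerance_fraction:.4f}"
        )


def summarize(
    records: pd.DataFrame,
    qc: QCReport | None = None,
    matrix: ProteinQuantMatrix | None = None,
    n_peptide_rows: int | None = None,
    dynamic_range_orders: float | None = None,
) -> PipelineSummary:
    """Aggregate differential records into a :class:`PipelineSummary`.

    The class counts must sum to the number of proteins (a bug trap, not a
    user-facing condition).
    """
    if records.empty:
        raise ValueError("no differential records to summarize")
    counts = records["protein_class"].value_counts().to_dict()
    n_total = int(len(records))
    if matrix is not None and len(matrix.abundance) != n_total:
        raise ValueError(
            f"record count {n_total} does not match matrix protein count "
            f"{len(matrix.abundance)}"
        )
    summary = PipelineSummary(
        n_peptide_rows=int(n_peptide_rows or 0),
        n_proteins_quantified=n_total,
        n_up_tumor=int(counts.get("up_in_tumor", 0)),
        n_up_control=int(counts.get("up_in_control", 0)),
        n_unchanged=int(counts.get("unchanged", 0)),
        n_exclusive_tumor=int(counts.get("exclusive_tumor", 0)),
        n_exclusive_control=int(counts.get("exclusive_control", 0)),
        n_decoys_discarded=int(counts.get("discarded_decoy", 0)),
        n_filtered_out=int(counts.get("filtered_out", 0)),
        dynamic_range_orders=float("nan") if dynamic_range_orders is None
        else float(dynamic_range_orders),
        ppm_within_tolerance_fraction=float("nan") if qc is None or not qc.available
        else qc.fraction_within,
    )
    parts = (summary.n_up_tumor + summary.n_up_control + summary.n_unchanged
             + summary.n_exclusive_tumor + summary.n_exclusive_control
             + summary.n_decoys_discarded + summary.n_filtered_out)
    if parts != n_total:
        raise AssertionError(
            f"class counts ({parts}) do not partition the {n_total} proteins"
        )
    return summary
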