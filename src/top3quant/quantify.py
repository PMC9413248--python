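"""Run normalization, Top3 protein rollup and peptide-level QC.

Top3 (Hi-3) quantification estimates a protein's abundance in one injection
as the arithmetic mean of the MS signal of its three most intense tryptic
peptides in that injection. Normalization happens at the peptide level
before rollup, by median log-ratio to a reference run, so the rollup itself
stays a pure aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import StudyDesign


@dataclass
class NormalizationResult:
    """Per-run scale factors; the reference run has factor exactly 1."""

    scale_factors: pd.Series  # index run_id
    reference_run: str


@dataclass
class ProteinQuantMatrix:
    """Proteins x runs Top3 abundance matrix plus peptide bookkeeping.

    ``abundance`` holds positive reals with NaN for missing cells; a cell is
    missing iff the protein had no measured peptide in that run.
    ``used_peptide_count`` records how many peptides (1-3) entered each
    cell's mean; peptide counts per protein are over the whole table.
    """

    abundance: pd.DataFrame
    peptides_per_protein: pd.Series
    unique_peptides_per_protein: pd.Series
    used_peptide_count: pd.DataFrame

    @property
    def protein_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def write(self, path: str | Path) -> None:
        out = self.abundance.copy()
        out.insert(0, "n_peptides", self.peptides_per_protein)
        out.insert(1, "n_unique_peptides", self.unique_peptides_per_protein)
        out.to_csv(path, sep="\t", index_label="protein_id")


@dataclass
class QCReport:
    """Peptide mass-accuracy QC summary."""

    available: bool
    n_rows: int
    tolerance_ppm: float
    fraction_within: float
    histogram: pd.DataFrame  # bin_left, bin_right, count


def normalize_runs(
    measurements: pd.DataFrame, design: StudyDesign
) -> tuple[pd.DataFrame, NormalizationResult]:
    """Scale every run onto a common intensity level.

    The reference is the run whose total log-intensity is the median across
    runs; every other run is multiplied by exp(-median log-ratio to the
    reference) over peptides observed in both runs, which drives each run's
    median log-ratio to the reference to zero. Runs sharing no peptide with
    the reference fall back to total-intensity scaling.
    """
    for run_id in design.run_ids:
        if not (measurements["run"] == run_id).any():
            raise ValueError(f"run {run_id!r} has zero peptide rows")

    logint = measurements.assign(_log=np.log(measurements["intensity"]))
    totals = logint.groupby("run")["_log"].sum().reindex(design.run_ids)
    target = float(totals.median())
    ref = (totals - target).abs().idxmin()

    key = ["peptide", "protein"]
    ref_log = logint.loc[logint["run"] == ref].set_index(key)["_log"]
    factors = {}
    for run_id in design.run_ids:
        if run_id == ref:
            factors[run_id] = 1.0
            continue
        run_log = logint.loc[logint["run"] == run_id].set_index(key)["_log"]
        shared = run_log.index.intersection(ref_log.index)
        if len(shared):
            m = float((run_log.loc[shared] - ref_log.loc[shared]).median())
        else:
            m = float(math.log(
                measurements.loc[measurements["run"] == run_id, "intensity"].sum()
                / measurements.loc[measurements["run"] == ref, "intensity"].sum()
            ))
        factors[run_id] = math.exp(-m)

    sf = pd.Series(factors, name="scale_factor").reindex(design.run_ids)
    scaled = measurements.copy()
    scaled["intensity"] = scaled["intensity"] * scaled["run"].map(sf).to_numpy()
    return scaled, NormalizationResult(scale_factors=sf, reference_run=str(ref))


def rollup_top3(measurements: pd.DataFrame) -> ProteinQuantMatrix:
    """Aggregate peptide intensities into Top3 protein abundances.

    Per protein x run the three largest peptide intensities are averaged;
    when only one or two peptides were measured, their mean is used and the
    count is recorded in ``used_peptide_count``. Intensity ties break
    lexicographically by peptide sequence for determinism.
    """
    if measurements.empty:
        raise ValueError("empty measurement collection")

    ranked = measurements.sort_values(
        ["protein", "run", "intensity", "peptide"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    top = ranked.groupby(["protein", "run"], sort=True).head(3)
    agg = top.groupby(["protein", "run"])["intensity"].agg(["mean", "size"])
    abundance = agg["mean"].unstack("run")
    used = agg["size"].unstack("run").fillna(0).astype(int)

    per_protein = measurements.groupby("protein")
    n_pep = per_protein["peptide"].nunique()
    n_unique = measurements.loc[measurements["unique"]].groupby("protein")[
        "peptide"
    ].nunique().reindex(abundance.index, fill_value=0)

    run_order = list(dict.fromkeys(measurements["run"]))
    abundance = abundance.reindex(columns=run_order)
    used = used.reindex(columns=run_order, fill_value=0)
    return ProteinQuantMatrix(
        abundance=abundance,
        peptides_per_protein=n_pep.reindex(abundance.index),
        unique_peptides_per_protein=n_unique.astype(int),
        used_peptide_count=used,
    )


def ppm_error(measurements: pd.DataFrame) -> pd.Series:
    """Relative mass error in ppm: 1e6 * (observed - theoretical) / theoretical."""
    return 1e6 * (measurements["mz_observed"] - measurements["mz_theoretical"]) / (
        measurements["mz_theoretical"]
    )


def mass_accuracy_qc(
    measurements: pd.DataFrame, tolerance_ppm: float = 10.0, n_bins: int = 41
) -> QCReport:
    """Fraction of peptide observations within +-``tolerance_ppm`` (inclusive).

    Returns an unavailable report (not an error) when the table carries no
    mass columns, plus a ppm histogram for plotting.
    """
    if not {"mz_observed", "mz_theoretical"}.issubset(measurements.columns):
        return QCReport(False, 0, tolerance_ppm, float("nan"), pd.DataFrame())
    err = ppm_error(measurements).dropna()
    if err.empty:
        return QCReport(False, 0, tolerance_ppm, float("nan"), pd.DataFrame())
    within = float((err.abs() <= tolerance_ppm).mean())
    lim = max(float(err.abs().max()), tolerance_ppm)
    edges = np.linspace(-lim, lim, n_bins + 1)
    counts, _ = np.histogram(err, bins=edges)
    hist = pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:], "count": counts
    })
    return QCReport(True, int(err.size), tolerance_ppm, within, hist)


def dynamic_range(
    matrix: ProteinQuantMatrix,
    scope: str = "global",
    key: str | None = None,
    design: StudyDesign | None = None,
) -> float:
    """Orders of magnitude spanned by Top3 abundances: log10(max / min).

    ``scope`` selects the cells considered: "global" (all), "run" (one
    column, named by ``key``) or "condition" (that condition's columns,
    requires ``design``).
    """
    if scope == "global":
        cells = matrix.abundance.to_numpy().ravel()
    elif scope == "run":
        if key is None or key not in matrix.abundance.columns:
            raise ValueError(f"unknown run {key!r}")
        cells = matrix.abundance[key].to_numpy()
    elif scope == "condition":
        if design is None or key is None:
            raise ValueError("condition scope requires design and key")
        runs = design.runs_for(key)
        if not runs:
            raise ValueError(f"unknown condition {key!r}")
        cells = matrix.abundance[runs].to_numpy().ravel()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    cells = cells[np.isfinite(cells)]
    if cells.size < 2:
        raise ValueError("dynamic range needs at least 2 non-missing cells")
    return float(np.log10(cells.max() / cells.min()))
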