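"""Chained end-to-end run: simulate -> quantify -> diff -> profile -> report.

Glue for the CLI's ``run-all`` and for reproducibility scripts: every stage
is the public library function, and the manifest records inputs, seed,
thresholds and package version so a run can be repeated exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import diffexp, profile, quantify, report, simdata
from .design import StudyDesign


@dataclass
class PipelineResult:
    design: StudyDesign
    truth: simdata.SyntheticTruth
    peptide_table: pd.DataFrame
    normalization: quantify.NormalizationResult
    matrix: quantify.ProteinQuantMatrix
    qc: quantify.QCReport
    records: pd.DataFrame
    zprofile: profile.ZScoreProfile | None
    summary: report.PipelineSummary
    recovery: simdata.RecoveryReport
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    params: simdata.SimParams | None = None,
    design: StudyDesign | None = None,
    thresholds: diffexp.FilterThresholds | None = None,
    normalize: bool = True,
    cluster: bool = True,
) -> PipelineResult:
    """Simulate a study and push it through every analysis stage."""
    params = params or simdata.SimParams()
    design = design or StudyDesign.default()
    thresholds = thresholds or diffexp.FilterThresholds()

    truth = simdata.generate_truth(params)
    table = simdata.simulate_peptide_table(truth, design, params)
    if normalize:
        table_n, norm = quantify.normalize_runs(table, design)
    else:
        table_n = table
        norm = quantify.NormalizationResult(
            scale_factors=pd.Series(1.0, index=design.run_ids),
            reference_run=design.run_ids[0],
        )
    matrix = quantify.rollup_top3(table_n)
    qc = quantify.mass_accuracy_qc(table)
    records = diffexp.apply_filter_cascade(matrix, design, thresholds)
    zprof = profile.profile_matrix(matrix) if cluster else None
    summary = report.summarize(
        records, qc=qc, matrix=matrix, n_peptide_rows=len(table),
        dynamic_range_orders=quantify.dynamic_range(matrix),
    )
    recovery = simdata.recovery_report(
        truth, records, log2_cutoff=thresholds.log2_cutoff, alpha=thresholds.alpha
    )
    try:
        pkg_version = version("top3quant")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {
        "seed": params.seed,
        "sim_params": asdict(params),
        "thresholds": asdict(thresholds),
        "design": [
            {"run_id": r.run_id, "condition": r.condition, "replicate": r.replicate}
            for r in design.runs
        ],
        "normalized": normalize,
        "version": pkg_version,
    }
    return PipelineResult(design=design, truth=truth, peptide_table=table,
                          normalization=norm, matrix=matrix, qc=qc,
                          records=records, zprofile=zprof, summary=summary,
                          recovery=recovery, manifest=manifest)


def write_manifest(result: PipelineResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(result.manifest, fh, sort_keys=False)
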