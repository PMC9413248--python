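"""Differential abundance: the multi-stage filter cascade and volcano calls.

Every quantified protein is pushed through a fixed-order filter trail --
decoy -> replication -> peptide count -> unique peptide -> CV -> ANOVA ->
fold change -- and ends up in exactly one class: up in either condition,
unchanged, exclusive to one condition, a discarded reversed decoy, or
filtered out for failing a quality stage. Defaults mirror the reference
analysis: CV <= 0.30 in both conditions, >= 2 peptides with >= 1 unique,
full (3/3) replication in both conditions for tested proteins, one-way
ANOVA on log2 abundances at alpha = 0.05, and a +-1.2 log2 fold-change
cutoff with inclusive boundaries. No multiple-testing correction is applied
in the cascade (raw ANOVA p-values are thresholded, as in the reference
analysis); Benjamini-Hochberg is available in :mod:`top3quant.enrich`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import StudyDesign
from .quantify import ProteinQuantMatrix

#: fixed order of the filter trail
FILTER_ORDER = ["decoy", "replication", "peptide_count", "unique", "cv",
                "anova", "fold_change"]

CLASSES = ["up_in_tumor", "up_in_control", "unchanged", "exclusive_tumor",
           "exclusive_control", "discarded_decoy", "filtered_out"]


@dataclass(frozen=True)
class FilterThresholds:
    max_cv: float = 0.30
    min_peptides: int = 2
    min_unique: int = 1
    require_full_replication: bool = True
    alpha: float = 0.05
    log2_cutoff: float = 1.2
    decoy_prefix: str = "REV_"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.max_cv <= 0:
            raise ValueError(f"max_cv must be > 0, got {self.max_cv}")
        if self.log2_cutoff < 0:
            raise ValueError(f"log2_cutoff must be >= 0, got {self.log2_cutoff}")
        if self.min_peptides < 1 or self.min_unique < 0:
            raise ValueError("min_peptides >= 1 and min_unique >= 0 required")


def compute_condition_stats(
    matrix: ProteinQuantMatrix, design: StudyDesign
) -> pd.DataFrame:
    """Per protein x condition: mean, sample SD (n-1), CV and replicate count.

    Statistics are computed on the linear-scale Top3 values over non-missing
    cells. Returns a frame with MultiIndex columns (statistic, condition).
    """
    blocks = {}
    for cond in design.conditions:
        sub = matrix.abundance[design.runs_for(cond)]
        n = sub.notna().sum(axis=1)
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        cv = sd / mean
        blocks[("mean", cond)] = mean
        blocks[("sd", cond)] = sd
        blocks[("cv", cond)] = cv
        blocks[("n_obs", cond)] = n
    out = pd.DataFrame(blocks)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["stat", "condition"])
    return out


def anova_per_protein(matrix: ProteinQuantMatrix, design: StudyDesign) -> pd.Series:
    """One-way fixed-effects ANOVA on log2 Top3, two condition groups.

    With two groups F equals the square of the pooled-variance t statistic.
    Proteins observed in fewer than two replicates of either condition get
    NaN (they fail the replication filter instead of being tested).
    Degenerate zero-within-variance cases are deterministic: p = 1 when the
    group means coincide, p = 0 when they differ.
    """
    a_runs, b_runs = (design.runs_for(c) for c in design.conditions)
    a = np.log2(matrix.abundance[a_runs].to_numpy(dtype=float))
    b = np.log2(matrix.abundance[b_runs].to_numpy(dtype=float))

    n1 = np.sum(np.isfinite(a), axis=1)
    n2 = np.sum(np.isfinite(b), axis=1)
    a0 = np.where(np.isfinite(a), a, 0.0)
    b0 = np.where(np.isfinite(b), b, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = a0.sum(axis=1) / n1
        m2 = b0.sum(axis=1) / n2
        ss1 = np.nansum((a - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((b - m2[:, None]) ** 2, axis=1)
        grand = (n1 * m1 + n2 * m2) / (n1 + n2)
    ss_between = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ss_within = ss1 + ss2
    df1, df2 = 1, n1 + n2 - 2

    p = np.full(len(matrix.abundance), np.nan)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df1) / (ss_within / np.maximum(df2, 1))
    deg = ok & (ss_within == 0)
    p[deg & (ss_between > 0)] = 0.0
    p[deg & (ss_between == 0)] = 1.0
    reg = ok & (ss_within > 0)
    p[reg] = stats.f.sf(F[reg], df1, df2[reg])
    return pd.Series(p, index=matrix.abundance.index, name="p_value")


def call_exclusive(
    matrix: ProteinQuantMatrix,
    design: StudyDesign,
    tumor: str = "tumor",
    control: str = "control",
    decoy_prefix: str = "REV_",
) -> pd.Series:
    """Condition-exclusive calls by the strict all-vs-none presence rule.

    A non-decoy protein is exclusive to a condition iff it has a Top3 value
    in every replicate of that condition and in none of the other's; any
    partial pattern is not exclusive. Returns a Series with values
    "exclusive_tumor" / "exclusive_control" for qualifying proteins.
    """
    t_runs, c_runs = design.runs_for(tumor), design.runs_for(control)
    present_t = matrix.abundance[t_runs].notna()
    present_c = matrix.abundance[c_runs].notna()
    is_decoy = matrix.abundance.index.str.startswith(decoy_prefix)
    excl_t = present_t.all(axis=1) & ~present_c.any(axis=1) & ~is_decoy
    excl_c = present_c.all(axis=1) & ~present_t.any(axis=1) & ~is_decoy
    out = pd.Series(index=matrix.abundance.index, dtype=object)
    out[excl_t] = "exclusive_tumor"
    out[excl_c] = "exclusive_control"
    return out.dropna()


def classify_volcano(records: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Volcano classification of cascade survivors (boundaries inclusive).

    up_in_tumor iff log2_ratio >= +cutoff and p <= alpha; up_in_control iff
    log2_ratio <= -cutoff and p <= alpha; otherwise unchanged.
    """
    thresholds.validate()
    rec = records.copy()
    sig = rec["p_value"] <= thresholds.alpha
    up = sig & (rec["log2_ratio"] >= thresholds.log2_cutoff)
    down = sig & (rec["log2_ratio"] <= -thresholds.log2_cutoff)
    rec.loc[:, "protein_class"] = "unchanged"
    rec.loc[up, "protein_class"] = "up_in_tumor"
    rec.loc[down, "protein_class"] = "up_in_control"
    return rec


def apply_filter_cascade(
    matrix: ProteinQuantMatrix,
    design: StudyDesign,
    thresholds: FilterThresholds | None = None,
    tumor: str = "tumor",
    control: str = "control",
) -> pd.DataFrame:
    """Run the full filter cascade and classify every protein.

    Returns one row per protein: per-condition means/CVs/replicate counts,
    tumor/control ratio and its log2, ANOVA p-value, the ordered
    ``filter_trail`` (semicolon-joined ``stage:pass|fail`` up to the first
    failure) and the final ``protein_class``. The ratio numerator/denominator
    conditions default to "tumor"/"control" but any pair of design labels
    may be named.
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    if tumor not in design.conditions or control not in design.conditions:
        raise ValueError(
            f"conditions ({tumor!r}, {control!r}) not both in design "
            f"{design.conditions}"
        )

    stats_ = compute_condition_stats(matrix, design)
    pvals = anova_per_protein(matrix, design)
    exclusive = call_exclusive(matrix, design, tumor, control,
                               thresholds.decoy_prefix)
    n_runs = {c: len(design.runs_for(c)) for c in (tumor, control)}

    mean_t_arr = stats_[("mean", tumor)].to_numpy()
    mean_c_arr = stats_[("mean", control)].to_numpy()
    cv_t_arr = stats_[("cv", tumor)].to_numpy()
    cv_c_arr = stats_[("cv", control)].to_numpy()
    n_t_arr = stats_[("n_obs", tumor)].to_numpy()
    n_c_arr = stats_[("n_obs", control)].to_numpy()
    p_arr = pvals.to_numpy()
    npep_arr = matrix.peptides_per_protein.reindex(matrix.abundance.index).to_numpy()
    nuniq_arr = matrix.unique_peptides_per_protein.reindex(
        matrix.abundance.index).to_numpy()
    exclusive_map = exclusive.to_dict()

    rows = []
    for i, pid in enumerate(matrix.abundance.index):
        trail: list[str] = []
        mean_t = mean_t_arr[i]
        mean_c = mean_c_arr[i]
        cv_t = cv_t_arr[i]
        cv_c = cv_c_arr[i]
        n_t = int(n_t_arr[i])
        n_c = int(n_c_arr[i])
        ratio = mean_t / mean_c if (mean_t > 0 and mean_c > 0) else np.nan
        log2_ratio = np.log2(ratio) if np.isfinite(ratio) else np.nan
        p = p_arr[i]

        rec = dict(protein_id=pid, mean_tumor=mean_t, mean_control=mean_c,
                   cv_tumor=cv_t, cv_control=cv_c, n_obs_tumor=n_t,
                   n_obs_control=n_c,
                   n_peptides=int(npep_arr[i]),
                   n_unique_peptides=int(nuniq_arr[i]),
                   ratio=ratio, log2_ratio=log2_ratio, p_value=p)

        def finish(cls: str) -> dict:
            rec["filter_trail"] = ";".join(trail)
            rec["protein_class"] = cls
            return rec

        # 1. decoy
        if pid.startswith(thresholds.decoy_prefix):
            trail.append("decoy:fail")
            rec.update(ratio=np.nan, log2_ratio=np.nan, p_value=np.nan)
            rows.append(finish("discarded_decoy"))
            continue
        trail.append("decoy:pass")

        # 2. replication (all-vs-none pattern routed to exclusivity)
        if pid in exclusive_map:
            trail.append("replication:exclusive")
            rec.update(ratio=np.nan, log2_ratio=np.nan, p_value=np.nan)
            rows.append(finish(str(exclusive_map[pid])))
            continue
        full = n_t == n_runs[tumor] and n_c == n_runs[control]
        if thresholds.require_full_replication and not full:
            trail.append("replication:fail")
            rows.append(finish("filtered_out"))
            continue
        if not thresholds.require_full_replication and (n_t < 2 or n_c < 2):
            trail.append("replication:fail")
            rows.append(finish("filtered_out"))
            continue
        trail.append("replication:pass")

        # 3. peptide count
        if rec["n_peptides"] < thresholds.min_peptides:
            trail.append("peptide_count:fail")
            rows.append(finish("filtered_out"))
            continue
        trail.append("peptide_count:pass")

        # 4. unique peptides
        if rec["n_unique_peptides"] < thresholds.min_unique:
            trail.append("unique:fail")
            rows.append(finish("filtered_out"))
            continue
        trail.append("unique:pass")

        # 5. CV in both conditions
        if not (cv_t <= thresholds.max_cv and cv_c <= thresholds.max_cv):
            trail.append("cv:fail")
            rows.append(finish("filtered_out"))
            continue
        trail.append("cv:pass")

        # 6/7. ANOVA + fold change decide the volcano class, not survival
        trail.append(f"anova:{'pass' if p <= thresholds.alpha else 'fail'}")
        fc_pass = abs(log2_ratio) >= thresholds.log2_cutoff
        trail.append(f"fold_change:{'pass' if fc_pass else 'fail'}")
        rows.append(finish("survivor"))

    records = pd.DataFrame(rows)
    surv = records["protein_class"] == "survivor"
    if surv.any():
        records.loc[surv, :] = classify_volcano(
            records.loc[surv, :], thresholds
        )
    return records
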