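"""Filter cascade, ANOVA and volcano classification.

The cascade is checked against an independent single-pass reimplementation
(`naive_cascade` below) on hand-built and randomly generated small tables.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from top3quant import (FilterThresholds, SimParams, StudyDesign,
                       anova_per_protein, apply_filter_cascade, call_exclusive,
                       classify_volcano, compute_condition_stats,
                       generate_truth, rollup_top3, simulate_peptide_table)
from top3quant.simdata import noise_free_params

from conftest import matrix_from_dict


# ---------------------------------------------------------------------------
# independent oracle: literal reading of the cascade, no shared code
# ---------------------------------------------------------------------------

def naive_cascade(values: dict, n_pep: dict, n_uniq: dict, design,
                  thr: FilterThresholds) -> dict:
    """values: {protein: {run: abundance or None}} -> {protein: class}."""
    out = {}
    t_runs, c_runs = design.runs_for("tumor"), design.runs_for("control")
    for pid, cells in values.items():
        t = [cells.get(r) for r in t_runs if cells.get(r) is not None]
        c = [cells.get(r) for r in c_runs if cells.get(r) is not None]
        if pid.startswith(thr.decoy_prefix):
            out[pid] = "discarded_decoy"
            continue
        if len(t) == len(t_runs) and len(c) == 0:
            out[pid] = "exclusive_tumor"
            continue
        if len(c) == len(c_runs) and len(t) == 0:
            out[pid] = "exclusive_control"
            continue
        if len(t) < len(t_runs) or len(c) < len(c_runs):
            out[pid] = "filtered_out"
            continue
        if n_pep[pid] < thr.min_peptides or n_uniq[pid] < thr.min_unique:
            out[pid] = "filtered_out"
            continue
        cv_t = np.std(t, ddof=1) / np.mean(t)
        cv_c = np.std(c, ddof=1) / np.mean(c)
        if cv_t > thr.max_cv or cv_c > thr.max_cv:
            out[pid] = "filtered_out"
            continue
        lt, lc = np.log2(t), np.log2(c)
        if np.var(lt) == 0 and np.var(lc) == 0:
            p = 1.0 if np.mean(lt) == np.mean(lc) else 0.0
        else:
            p = sps.f_oneway(lt, lc).pvalue
        log2_ratio = math.log2(np.mean(t) / np.mean(c))
        if p <= thr.alpha and log2_ratio >= thr.log2_cutoff:
            out[pid] = "up_in_tumor"
        elif p <= thr.alpha and log2_ratio <= -thr.log2_cutoff:
            out[pid] = "up_in_control"
        else:
            out[pid] = "unchanged"
    return out


def run_both(values, design, thr=None, n_pep=None, n_uniq=None):
    thr = thr or FilterThresholds()
    matrix = matrix_from_dict(values, design.run_ids)
    if n_pep:
        matrix.peptides_per_protein = pd.Series(n_pep)
        matrix.unique_peptides_per_protein = pd.Series(n_uniq)
    records = apply_filter_cascade(matrix, design, thr)
    got = records.set_index("protein_id")["protein_class"].to_dict()
    expected = naive_cascade(
        {p: {r: (None if pd.isna(v) else v) for r, v in row.items()}
         for p, row in matrix.abundance.iterrows()},
        matrix.peptides_per_protein.to_dict(),
        matrix.unique_peptides_per_protein.to_dict(), design, thr)
    return records, got, expected


class TestConditionStats:
    def test_hand_computed_mean_sd_cv(self, design):
        m = matrix_from_dict(
            {"P1": {"tumor_1": 90.0, "tumor_2": 100.0, "tumor_3": 110.0,
                    "control_1": 100.0, "control_2": 100.0, "control_3": 100.0}},
            design.run_ids)
        stats = compute_condition_stats(m, design)
        assert stats.loc["P1", ("mean", "tumor")] == pytest.approx(100.0)
        assert stats.loc["P1", ("sd", "tumor")] == pytest.approx(10.0)
        assert stats.loc["P1", ("cv", "tumor")] == pytest.approx(0.1)
        assert stats.loc["P1", ("cv", "control")] == 0.0
        assert stats.loc["P1", ("n_obs", "control")] == 3

    def test_partial_replication_counted(self, design):
        m = matrix_from_dict(
            {"P1": {"tumor_1": 90.0, "tumor_2": 100.0,
                    "control_1": 100.0, "control_2": 90.0, "control_3": 95.0}},
            design.run_ids)
        stats = compute_condition_stats(m, design)
        assert stats.loc["P1", ("n_obs", "tumor")] == 2


class TestAnova:
    def _matrix(self, design, tumor, control):
        vals = {"P1": dict(zip(design.runs_for("tumor"), np.exp2(tumor)))}
        vals["P1"].update(dict(zip(design.runs_for("control"), np.exp2(control))))
        return matrix_from_dict(vals, design.run_ids)

    def test_identical_groups_give_p_one(self, design):
        p = anova_per_protein(self._matrix(design, [1, 2, 3], [1, 2, 3]), design)
        assert p.loc["P1"] == pytest.approx(1.0)

    def test_separated_constant_groups_give_p_zero(self, design):
        p = anova_per_protein(self._matrix(design, [0, 0, 0], [5, 5, 5]), design)
        assert p.loc["P1"] == 0.0

    def test_equal_constant_groups_give_p_one(self, design):
        p = anova_per_protein(self._matrix(design, [2, 2, 2], [2, 2, 2]), design)
        assert p.loc["P1"] == 1.0

    def test_matches_pooled_t_test(self, design):
        a, b = [1.0, 1.1, 0.9], [2.0, 2.1, 1.9]
        p = anova_per_protein(self._matrix(design, a, b), design)
        t = sps.ttest_ind(a, b, equal_var=True)
        assert p.loc["P1"] == pytest.approx(t.pvalue, rel=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=3, max_size=3),
           st.lists(st.floats(-5, 5), min_size=3, max_size=3))
    def test_f_equals_t_squared(self, design, a, b):
        if np.var(a) + np.var(b) == 0:
            return
        p = anova_per_protein(self._matrix(design, a, b), design)
        ref = sps.f_oneway(a, b)
        if not np.isfinite(ref.pvalue):  # scipy's own degenerate handling
            return
        assert p.loc["P1"] == pytest.approx(ref.pvalue, rel=1e-6, abs=1e-12)
        t = sps.ttest_ind(a, b, equal_var=True)
        assert ref.statistic == pytest.approx(t.statistic ** 2, rel=1e-9,
                                              abs=1e-12)

    def test_insufficient_replication_gives_nan(self, design):
        m = matrix_from_dict({"P1": {"tumor_1": 4.0, "control_1": 2.0,
                                     "control_2": 3.0, "control_3": 2.0}},
                             design.run_ids)
        assert math.isnan(anova_per_protein(m, design).loc["P1"])


class TestExclusive:
    def test_strict_all_vs_none(self, design):
        m = matrix_from_dict({
            "P1": {"tumor_1": 1.0, "tumor_2": 1.0, "tumor_3": 1.0},  # 3/3 vs 0
            "P2": {"tumor_1": 1.0, "tumor_2": 1.0},                  # 2/3 vs 0
            "P3": {"control_1": 1.0, "control_2": 1.0, "control_3": 1.0},
            "REV_P4": {"tumor_1": 1.0, "tumor_2": 1.0, "tumor_3": 1.0},
        }, design.run_ids)
        calls = call_exclusive(m, design)
        assert calls.to_dict() == {"P1": "exclusive_tumor",
                                   "P3": "exclusive_control"}

    def test_planted_exclusives_recovered_exactly(self, design):
        params = noise_free_params(SimParams(n_proteins=200, seed=13))
        truth = generate_truth(params)
        matrix = rollup_top3(simulate_peptide_table(truth, design, params))
        calls = call_exclusive(matrix, design)
        tr = truth.proteins.set_index("protein_id")
        want_t = set(tr.index[tr["exclusivity"] == "tumor_only"])
        want_c = set(tr.index[tr["exclusivity"] == "control_only"])
        assert set(calls.index[calls == "exclusive_tumor"]) == want_t
        assert set(calls.index[calls == "exclusive_control"]) == want_c


class TestVolcano:
    @pytest.mark.parametrize("log2_ratio,p,expected", [
        (1.3, 0.01, "up_in_tumor"),
        (1.0, 0.001, "unchanged"),       # below the magnitude cutoff
        (-1.2, 0.05, "up_in_control"),   # boundaries inclusive
        (1.2, 0.05, "up_in_tumor"),
        (2.0, 0.06, "unchanged"),        # not significant
    ])
    def test_boundary_rules(self, log2_ratio, p, expected):
        rec = pd.DataFrame([{"protein_id": "P1", "log2_ratio": log2_ratio,
                             "p_value": p}])
        out = classify_volcano(rec, FilterThresholds())
        assert out.loc[0, "protein_class"] == expected


class TestCascade:
    def test_decoy_discarded_despite_perfect_data(self, design):
        vals = {"REV_P9": {r: 100.0 for r in design.run_ids}}
        records, got, expected = run_both(vals, design)
        assert got == {"REV_P9": "discarded_decoy"} == expected
        assert records.loc[0, "filter_trail"] == "decoy:fail"

    def test_single_peptide_protein_fails_at_peptide_stage(self, design):
        vals = {"P1": {r: 100.0 for r in design.run_ids}}
        records, got, _ = run_both(vals, design, n_pep={"P1": 1},
                                   n_uniq={"P1": 1})
        assert got == {"P1": "filtered_out"}
        assert records.loc[0, "filter_trail"].endswith("peptide_count:fail")

    def test_toy_table_fails_each_filter_once(self, design):
        t, c = design.runs_for("tumor"), design.runs_for("control")
        vals = {
            "REV_D": {r: 100.0 for r in design.run_ids},
            "P_repl": {**{r: 100.0 for r in t}, c[0]: 100.0, c[1]: 100.0},
            "P_pep": {r: 100.0 for r in design.run_ids},
            "P_uniq": {r: 100.0 for r in design.run_ids},
            "P_cv": {t[0]: 50.0, t[1]: 100.0, t[2]: 200.0,
                     **{r: 100.0 for r in c}},
            "P_up": {**{r: 400.0 for r in t}, **{r: 100.0 for r in c}},
            "P_flat": {r: 100.0 for r in design.run_ids},
        }
        n_pep = {p: 3 for p in vals}
        n_pep["P_pep"] = 1
        n_uniq = {p: 2 for p in vals}
        n_uniq["P_uniq"] = 0
        _, got, expected = run_both(vals, design, n_pep=n_pep, n_uniq=n_uniq)
        assert got == expected
        assert got == {"REV_D": "discarded_decoy", "P_repl": "filtered_out",
                       "P_pep": "filtered_out", "P_uniq": "filtered_out",
                       "P_cv": "filtered_out", "P_up": "up_in_tumor",
                       "P_flat": "unchanged"}

    def test_every_protein_gets_exactly_one_class(self, design, small_noisy):
        _, _, table = small_noisy
        records = apply_filter_cascade(rollup_top3(table), design)
        assert records["protein_id"].is_unique
        assert records["protein_class"].isin([
            "up_in_tumor", "up_in_control", "unchanged", "exclusive_tumor",
            "exclusive_control", "discarded_decoy", "filtered_out"]).all()
        counts = records["protein_class"].value_counts()
        assert counts.sum() == len(records)

    def test_condition_swap_symmetry(self, design, small_noisy):
        _, _, table = small_noisy
        matrix = rollup_top3(table)
        fwd = apply_filter_cascade(matrix, design).set_index("protein_id")
        rev = apply_filter_cascade(matrix, design, tumor="control",
                                   control="tumor").set_index("protein_id")
        swap = {"up_in_tumor": "up_in_control", "up_in_control": "up_in_tumor",
                "exclusive_tumor": "exclusive_control",
                "exclusive_control": "exclusive_tumor"}
        mapped = fwd["protein_class"].map(lambda c: swap.get(c, c))
        assert (mapped == rev["protein_class"]).all()
        both = np.isfinite(fwd["log2_ratio"]) & np.isfinite(rev["log2_ratio"])
        np.testing.assert_allclose(fwd.loc[both, "log2_ratio"],
                                   -rev.loc[both, "log2_ratio"], atol=1e-12)

    def test_loosening_thresholds_is_monotone(self, design, small_noisy):
        _, _, table = small_noisy
        matrix = rollup_top3(table)

        def n_calls(thr):
            rec = apply_filter_cascade(matrix, design, thr)
            return rec["protein_class"].isin(["up_in_tumor",
                                              "up_in_control"]).sum()

        base = n_calls(FilterThresholds())
        assert n_calls(FilterThresholds(max_cv=0.6)) >= base
        assert n_calls(FilterThresholds(alpha=0.2)) >= base
        assert n_calls(FilterThresholds(log2_cutoff=0.5)) >= base

    def test_invalid_thresholds_rejected(self, design, small_noisy):
        _, _, table = small_noisy
        with pytest.raises(ValueError, match="alpha"):
            apply_filter_cascade(rollup_top3(table), design,
                                 FilterThresholds(alpha=1.5))

    def test_random_tables_match_naive_oracle(self, design):
        rng = np.random.default_rng(2024)
        thr = FilterThresholds()
        for trial in range(60):
            n = int(rng.integers(2, 21))
            vals, n_pep, n_uniq = {}, {}, {}
            for i in range(n):
                pid = (f"REV_P{i}" if rng.random() < 0.15 else f"P{i}")
                row = {}
                for r in design.run_ids:
                    if rng.random() < 0.25:
                        continue  # missing cell
                    row[r] = float(np.round(10 ** rng.uniform(0, 3), 3))
                if not row:
                    continue
                vals[pid] = row
                n_pep[pid] = int(rng.integers(1, 6))
                n_uniq[pid] = int(rng.integers(0, n_pep[pid] + 1))
            if not vals:
                continue
            _, got, expected = run_both(vals, design, thr, n_pep, n_uniq)
            assert got == expected, f"trial {trial}: {got} != {expected}"
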