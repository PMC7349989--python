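"""Selection-cascade behaviour: AUC estimator, gates, and full cascade."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cgimeth.config import RunConfig
from cgimeth.errors import ComputationError, ValidationError
from cgimeth.io import BetaMatrix, CGIKey, SampleSheet
from cgimeth.published import load_selected_cgis
from cgimeth.selection import (
    auc,
    group_means,
    select_biomarkers,
    select_from_summary,
    stage1_filter,
    stage2_filter,
)
from cgimeth.simulate import SimulationConfig, simulate_methylation_cohorts


def brute_force_auc(cases, controls):
    """Exhaustive pair counting: wins + half-ties over all pairs."""
    wins = sum(1.0 for c in cases for k in controls if c > k)
    ties = sum(0.5 for c in cases for k in controls if c == k)
    return (wins + ties) / (len(cases) * len(controls))


scores = st.lists(
    st.floats(-10, 10, allow_nan=False).map(lambda x: round(x, 2)),
    min_size=1,
    max_size=8,
)


class TestAuc:
    def test_worked_examples(self):
        assert auc([0.6, 0.7], [0.1, 0.2]) == 1.0
        # 3 of the 4 (case, control) pairs have case > control
        assert auc([0.5, 0.2], [0.3, 0.1]) == 0.75
        assert auc([0.3, 0.3], [0.3, 0.3]) == 0.5

    def test_empty_group_rejected(self):
        with pytest.raises(ComputationError):
            auc([], [0.1])

    @given(scores, scores)
    def test_matches_exhaustive_pair_counting(self, cases, controls):
        assert auc(cases, controls) == pytest.approx(
            brute_force_auc(cases, controls), abs=1e-12
        )

    @given(scores, scores)
    def test_antisymmetry(self, cases, controls):
        assert auc(cases, controls) + auc(controls, cases) == pytest.approx(1.0)

    @given(scores, scores)
    def test_monotone_transform_invariance(self, cases, controls):
        f = lambda x: np.exp(np.asarray(x) / 4.0) + 3.0  # strictly increasing
        assert auc(f(cases), f(controls)) == pytest.approx(auc(cases, controls))


class TestGroupMeans:
    def test_small_examples(self, small_matrix):
        means = group_means(small_matrix)
        assert means.loc[small_matrix.cgis[0], "mean_tumour"] == pytest.approx(0.55)
        assert means.loc[small_matrix.cgis[0], "mean_normal"] == pytest.approx(0.15)

    def test_matches_independent_recomputation(self, rng):
        """Random 50 x 30 matrix with missing entries, against a one-line oracle."""
        n_cgi, n_tum, n_norm = 50, 15, 15
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": [f"S{i}" for i in range(30)],
                    "group": ["tumour"] * n_tum + ["normal"] * n_norm,
                    "cohort": ["discovery"] * 30,
                }
            )
        )
        values = rng.uniform(size=(n_cgi, 30))
        values[rng.uniform(size=values.shape) < 0.05] = np.nan
        keys = [CGIKey("chr1", 1 + i, 10 + i) for i in range(n_cgi)]
        matrix = BetaMatrix(
            pd.DataFrame(values, index=keys, columns=sheet.sample_ids), sheet
        )
        means = group_means(matrix, missingness_cap=1.0)
        expected_t = np.nanmean(values[:, :n_tum], axis=1)
        expected_n = np.nanmean(values[:, n_tum:], axis=1)
        np.testing.assert_allclose(means["mean_tumour"], expected_t, atol=1e-12)
        np.testing.assert_allclose(means["mean_normal"], expected_n, atol=1e-12)

    def test_delta_beta_consistency(self, small_matrix):
        records = select_biomarkers(small_matrix, _relabel(small_matrix, "validation"))
        lhs = records["delta_beta_discovery"]
        rhs = records["mean_beta_tumour_discovery"] - records["mean_beta_normal_discovery"]
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def _relabel(matrix: BetaMatrix, cohort: str) -> BetaMatrix:
    sheet = SampleSheet(matrix.samples.table.assign(cohort=cohort))
    return BetaMatrix(matrix.values.copy(), sheet)


def _toy_matrix(tumours, normals):
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": [f"T{i}" for i in range(len(tumours))]
                + [f"N{i}" for i in range(len(normals))],
                "group": ["tumour"] * len(tumours) + ["normal"] * len(normals),
                "cohort": ["discovery"] * (len(tumours) + len(normals)),
            }
        )
    )
    key = CGIKey("chr1", 1, 10)
    values = pd.DataFrame(
        [list(tumours) + list(normals)], index=[key], columns=sheet.sample_ids
    )
    return BetaMatrix(values, sheet), key


class TestStageFilters:
    @pytest.mark.parametrize("mean_normal,passes", [(0.24, True), (0.25, False)])
    def test_stage1_strict_boundary(self, mean_normal, passes):
        matrix, key = _toy_matrix([0.5, 0.5], [mean_normal, mean_normal])
        means = group_means(matrix)
        assert stage1_filter(means).loc[key] == passes

    def test_stage2_inclusive_boundaries(self):
        """3/4 tumours above 0.45 (= 75%) and 1/4 normals above 0.25 (= 25%)
        both sit exactly on the inclusive boundary and pass."""
        matrix, key = _toy_matrix([0.5, 0.5, 0.5, 0.2], [0.1, 0.1, 0.1, 0.3])
        assert stage2_filter(matrix).loc[key]
        matrix, key = _toy_matrix([0.46, 0.46, 0.44, 0.44], [0.1, 0.1, 0.1, 0.1])
        assert not stage2_filter(matrix).loc[key]

    def test_stage2_exhaustive_binary_patterns(self):
        """All 2^6 high/low patterns over 3 tumours + 3 normals, against
        brute-force counting."""
        for bits in itertools.product([0, 1], repeat=6):
            tumours = [0.6 if b else 0.3 for b in bits[:3]]
            normals = [0.6 if b else 0.1 for b in bits[3:]]
            matrix, key = _toy_matrix(tumours, normals)
            expected = (
                sum(t > 0.45 for t in tumours) / 3 >= 0.75
                and sum(n > 0.25 for n in normals) / 3 <= 0.25
            )
            assert stage2_filter(matrix).loc[key] == expected, bits


class TestSelectBiomarkers:
    def test_universe_mismatch_lists_difference(self, small_matrix):
        other = _relabel(small_matrix, "validation")
        extra = CGIKey("chr9", 5, 10, "X")
        values = pd.concat(
            [
                other.values,
                pd.DataFrame(
                    [[0.1, 0.1, 0.1, 0.1]], index=[extra], columns=other.values.columns
                ),
            ]
        )
        bigger = BetaMatrix(values, other.samples)
        with pytest.raises(ValidationError, match="chr9:5-10"):
            select_biomarkers(small_matrix, bigger)

    def test_impossible_auc_gate_empties_selection(self):
        cfg = SimulationConfig(seed=1)
        disc, val, _ = simulate_methylation_cohorts(cfg)
        records = select_biomarkers(disc, val, RunConfig(auc_min=1.01))
        assert not records["selected"].any()

    def test_truth_recovery_and_cascade_nesting(self):
        cfg = SimulationConfig(seed=5)
        disc, val, truth = simulate_methylation_cohorts(cfg)
        records = select_biomarkers(disc, val)
        selected = set(records.index[records["selected"]])
        assert selected == set(truth.true_biomarkers)
        s1 = set(records.index[records["pass_stage1"]])
        s2 = set(records.index[records["pass_stage1"] & records["pass_stage2"]])
        assert selected <= s2 <= s1
        # every decoy class is rejected at (or before) its designated gate
        labels = truth.cgi_labels
        assert not (set(labels.index[labels == "decoy_stage1_fail"]) & s1)
        assert not (set(labels.index[labels == "decoy_stage2_fail"]) & s2)
        assert not (set(labels.index[labels == "decoy_auc_fail"]) & selected)

    def test_tightening_thresholds_never_enlarges_selection(self):
        cfg = SimulationConfig(seed=2)
        disc, val, _ = simulate_methylation_cohorts(cfg)
        base = set()
        records = select_biomarkers(disc, val, RunConfig())
        base = set(records.index[records["selected"]])
        tighter = [
            RunConfig(stage1_max_normal_mean=0.15),
            RunConfig(stage2_min_tumour_frac=0.9),
            RunConfig(stage2_max_normal_frac=0.1),
            RunConfig(auc_min=0.99),
        ]
        for cfg_t in tighter:
            rec = select_biomarkers(disc, val, cfg_t)
            assert set(rec.index[rec["selected"]]) <= base


class TestSummaryGate:
    def test_published_auc_columns_select_24(self):
        table = select_from_summary(load_selected_cgis(), auc_min=0.95)
        assert int(table["selected"].sum()) == 24

    def test_higher_gate_empties(self):
        table = select_from_summary(load_selected_cgis(), auc_min=1.01)
        assert int(table["selected"].sum()) == 0
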