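"""Per-mode interpretability criteria and core-slice gene-component ranking."""

import numpy as np
import pytest

import tdfe
from tdfe.hosvd import TuckerFactors, hosvd
from tdfe.selection import (
    SelectionError,
    rank_gene_components,
    score_condition_contrast,
    score_monotonic_time,
    score_replicate_invariance,
    select_components,
)


class TestReplicateInvariance:
    def test_constant_column_scores_zero_and_wins(self):
        u = np.array([[0.577, 0.71], [0.577, -0.71], [0.577, 0.0]])
        out = score_replicate_invariance(u)
        assert out.scores[0] == pytest.approx(0.0, abs=1e-3)
        assert out.best == 1

    def test_constant_beats_contrast(self):
        u = np.column_stack([[0.58, 0.58, 0.58], [0.71, -0.71, 0.0]])
        assert score_replicate_invariance(u).best == 1

    def test_all_zero_column_excluded_with_warning(self):
        u = np.column_stack([[0.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            out = score_replicate_invariance(u)
        assert out.scores[0] is None
        assert out.best == 2

    def test_sign_flip_invariant(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(3, 3))
        flipped = u * np.array([1, -1, 1])
        assert score_replicate_invariance(u).best == score_replicate_invariance(flipped).best


class TestMonotonicTime:
    def test_strictly_decreasing_column_flagged(self):
        u = np.column_stack([[0.9, 0.2, -0.5], [0.5, -0.8, 0.3], [0.1, 0.2, 0.3]])
        out = score_monotonic_time(u, "decreasing")
        assert out.detail["decreasing"] == [True, False, True]
        assert out.detail["increasing"] == [True, False, True]  # either orientation

    def test_non_monotone_column_not_flagged(self):
        u = np.array([[0.5], [-0.8], [0.3]])
        with pytest.raises(SelectionError, match="manually"):
            score_monotonic_time(u, "decreasing")

    def test_orientation_insensitive(self):
        down = np.array([[0.9], [0.2], [-0.5]])
        out_down = score_monotonic_time(np.hstack([down, -down]), "decreasing")
        assert out_down.detail["decreasing"] == [True, True]

    def test_most_pronounced_trend_wins(self):
        # both monotone; second has the larger first-to-last swing
        u = np.column_stack([[0.30, 0.29, 0.28], [0.9, 0.1, -0.8]])
        assert score_monotonic_time(u, "decreasing").best == 2

    def test_direction_either(self):
        u = np.column_stack([[0.1, 0.5, 0.9], [0.3, 0.1, 0.2]])
        assert score_monotonic_time(u, "either").best == 1


class TestConditionContrast:
    def test_opposite_signs_qualify_with_entry_difference_score(self):
        u = np.array([[0.707, 0.707], [-0.707, 0.707]])
        out = score_condition_contrast(u)
        assert out.detail["qualifies"] == [True, False]
        assert out.scores[0] == pytest.approx(1.414)
        assert out.best == 1

    def test_no_contrast_column_errors(self):
        u = np.array([[0.707, 0.6], [0.707, 0.8]])
        with pytest.raises(SelectionError, match="manually"):
            score_condition_contrast(u)


def _factors_with_slice(slice_vec, shape=(4, 3, 3, 2)):
    core = np.zeros((len(slice_vec),) + shape[1:])
    core[:, 0, 1, 1] = slice_vec
    return TuckerFactors(core=core, factors=tuple(np.eye(n) for n in (len(slice_vec),) + shape[1:]))


class TestRankGeneComponents:
    def test_absolute_value_ranking(self):
        f = _factors_with_slice([0.0, 5.0, -7.0, 2.0])
        choice = rank_gene_components(f, 1, 2, 2, top_t=2)
        assert choice.gene_components == [3, 2]

    def test_tie_breaks_to_smaller_index(self):
        f = _factors_with_slice([4.0, -4.0])
        assert rank_gene_components(f, 1, 2, 2, top_t=1).gene_components == [1]

    def test_top_t_capped_by_structural_rank(self):
        f = _factors_with_slice(list(range(30)))
        with pytest.raises(ValueError, match="top_t"):
            rank_gene_components(f, 1, 2, 2, top_t=19)

    def test_deterministic_function_of_inputs(self):
        f = _factors_with_slice([1.0, -3.0, 2.0, 0.5])
        a = rank_gene_components(f, 1, 2, 2, top_t=3)
        b = rank_gene_components(f, 1, 2, 2, top_t=3)
        assert a.gene_components == b.gene_components
        np.testing.assert_array_equal(a.core_slice, b.core_slice)


class TestSelectComponents:
    def _planted_tensor(self, seed=0, n=120):
        cfg = tdfe.SimulationConfig(n_genes=n, n_signal=12, delta=6.0, seed=seed,
                                    extra_genes_last_file=0)
        mats, smap, _ = tdfe.generate_dataset(cfg)
        return tdfe.build_tensor(mats, smap, tdfe.intersect_genes(mats))

    def test_planted_pattern_selects_expected_triple(self):
        f = hosvd(self._planted_tensor())
        choice = select_components(f)
        assert (choice.replicate_component, choice.time_component,
                choice.exposure_component) == (1, 2, 2)
        assert len(choice.gene_components) == 3
        assert "replicate_scores" in choice.criteria_report

    def test_overrides_bypass_criteria(self):
        f = hosvd(self._planted_tensor())
        choice = select_components(f, replicate_component=2, time_component=3,
                                   exposure_component=1, top_t=2)
        assert (choice.replicate_component, choice.time_component,
                choice.exposure_component) == (2, 3, 1)
        assert choice.criteria_report["overridden"]["time"]

    def test_scores_invariant_to_any_column_sign_flip(self):
        f = hosvd(self._planted_tensor(seed=3))
        base = select_components(f)
        rng = np.random.default_rng(1)
        for mode in range(1, 4):  # flip a column in each non-gene factor
            factors = [u.copy() for u in f.factors]
            col = rng.integers(factors[mode].shape[1])
            factors[mode][:, col] *= -1
            # flipping a factor column flips the matching core slab too,
            # keeping the decomposition valid
            core = f.core.copy()
            idx = [slice(None)] * 4
            idx[mode] = col
            core[tuple(idx)] *= -1
            flipped = TuckerFactors(core=core, factors=tuple(factors))
            out = select_components(flipped)
            assert (out.replicate_component, out.time_component,
                    out.exposure_component, out.gene_components) == (
                base.replicate_component, base.time_component,
                base.exposure_component, base.gene_components)

    def test_json_report_round_trip(self, tmp_path):
        f = hosvd(self._planted_tensor(seed=5))
        choice = select_components(f)
        choice.write(tmp_path / "sel.json")
        text = (tmp_path / "sel.json").read_text()
        assert '"replicate_component": 1' in text
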