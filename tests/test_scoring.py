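"""Chi-square gene scoring: statistic, p-values, adjustment, selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tdfe.scoring import (
    GeneScoreTable,
    adjust_p,
    chi_square_p,
    chi_square_statistic,
    score_genes,
    select_genes,
)


def _bh_by_hand(p):
    """Independent step-up oracle: p_(r) -> min_{r' >= r} min(1, p_(r') * m / r')."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestStatistic:
    def test_matches_brute_force_sum_of_squared_z(self, rng):
        u = rng.normal(size=(5, 4))
        stat, sigmas = chi_square_statistic(u, [1, 2])
        for i in range(5):
            expected = sum(
                (u[i, c] / np.sqrt(np.mean(u[:, c] ** 2))) ** 2 for c in (0, 1)
            )
            assert abs(stat[i] - expected) < 1e-12
        np.testing.assert_allclose(sigmas, np.sqrt(np.mean(u[:, :2] ** 2, axis=0)))

    def test_zero_loadings_give_zero_statistic(self):
        u = np.vstack([np.zeros((1, 3)), np.ones((4, 3))])
        stat, _ = chi_square_statistic(u, [1, 2, 3])
        assert stat[0] == 0.0

    def test_loading_equal_to_sigma_gives_one(self):
        col = np.array([2.0, -2.0, 2.0, -2.0])  # sigma about zero = 2
        stat, sigmas = chi_square_statistic(col[:, None], [1])
        assert sigmas[0] == pytest.approx(2.0)
        np.testing.assert_allclose(stat, 1.0)

    def test_scale_invariance(self, rng):
        u = rng.normal(size=(50, 3))
        stat1, _ = chi_square_statistic(u, [1, 3])
        scaled = u.copy()
        scaled[:, 0] *= -17.5
        scaled[:, 2] *= 0.01
        stat2, _ = chi_square_statistic(scaled, [1, 3])
        np.testing.assert_allclose(stat1, stat2, atol=1e-10)

    def test_zero_variance_column_named(self):
        u = np.column_stack([np.zeros(4), np.ones(4)])
        with pytest.raises(ValueError, match="component 1"):
            chi_square_statistic(u, [1, 2])


class TestChiSquareP:
    def test_zero_statistic_gives_one(self):
        assert chi_square_p(np.array([0.0]), 3)[0] == 1.0

    @pytest.mark.parametrize("stat,df", [(3.841, 1), (7.815, 3)])
    def test_standard_critical_values(self, stat, df):
        assert chi_square_p(np.array([stat]), df)[0] == pytest.approx(0.05, abs=5e-4)

    def test_strictly_decreasing_in_statistic(self):
        p = chi_square_p(np.linspace(0, 10, 50), 3)
        assert np.all(np.diff(p) < 0)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            chi_square_p(np.array([-1.0]), 1)


class TestAdjustP:
    def test_bh_hand_computed_step_up(self):
        np.testing.assert_allclose(
            adjust_p(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(adjust_p(np.ones(5)), np.ones(5))

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_p(np.array([0.123])), [0.123])

    def test_matches_independent_step_up_oracle(self, rng):
        p = rng.uniform(size=40)
        np.testing.assert_allclose(adjust_p(p), _bh_by_hand(p), atol=1e-12)

    def test_holm_is_more_conservative_than_bh(self, rng):
        p = rng.uniform(0, 0.2, size=20)
        assert np.all(adjust_p(p, "holm") >= adjust_p(p, "bh") - 1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_p(np.array([1.5]))


class TestScoreGenes:
    def test_adjusted_never_below_raw_and_in_unit_interval(self, rng):
        u = rng.normal(size=(200, 5))
        t = score_genes(u, [1, 2, 3], [f"g{i}" for i in range(200)])
        assert np.all(t.p_adj >= t.p_raw - 1e-15)
        assert np.all((t.p_raw >= 0) & (t.p_raw <= 1))
        assert np.all((t.p_adj >= 0) & (t.p_adj <= 1))
        assert t.df == 3

    def test_selection_strict_at_alpha(self):
        table = GeneScoreTable(
            gene_ids=["a", "b", "c"],
            components=[1],
            loadings=np.zeros((3, 1)),
            sigmas=np.ones(1),
            statistic=np.zeros(3),
            df=1,
            p_raw=np.array([0.01, 0.05, 0.9]),
            p_adj=np.array([0.01, 0.05, 0.9]),
            alpha=0.05,
            adjust_method="bh",
        )
        assert table.selected_genes() == ["a"]  # 0.05 is not < 0.05
        assert select_genes(table, alpha=0.06) == ["a", "b"]

    def test_all_ones_select_nothing(self):
        table = GeneScoreTable(
            gene_ids=["a", "b"], components=[1], loadings=np.zeros((2, 1)),
            sigmas=np.ones(1), statistic=np.zeros(2), df=1,
            p_raw=np.ones(2), p_adj=np.ones(2), alpha=0.05, adjust_method="bh",
        )
        assert table.selected_genes() == []

    def test_whole_stage_invariant_to_column_sign_flips(self, rng):
        u = rng.normal(size=(100, 6))
        t1 = score_genes(u, [2, 4], [f"g{i}" for i in range(100)])
        flipped = u.copy()
        flipped[:, 1] *= -1
        flipped[:, 3] *= -1
        t2 = score_genes(flipped, [2, 4], [f"g{i}" for i in range(100)])
        np.testing.assert_array_equal(t1.statistic, t2.statistic)
        np.testing.assert_array_equal(t1.p_adj, t2.p_adj)
        assert t1.selected_genes() == t2.selected_genes()

    def test_per_component_mode(self, rng):
        u = rng.normal(size=(80, 4))
        t = score_genes(u, [1, 2, 3], [f"g{i}" for i in range(80)], df_mode="per_component")
        assert t.df == 1
        assert np.all(t.p_adj >= t.p_raw - 1e-15)

    def test_null_calibration_on_iid_normal_loadings(self):
        """No-signal loadings: ~5% raw p < 0.05, BH selects ~none (20 seeds)."""
        fracs, counts = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            u = rng.normal(size=(1000, 5))
            t = score_genes(u, [1, 2, 3], [f"g{i}" for i in range(1000)])
            fracs.append(float(np.mean(t.p_raw < 0.05)))
            counts.append(int(t.selected.sum()))
        assert 0.03 < np.mean(fracs) < 0.07
        assert np.mean(counts) <= 1.0

    def test_tsv_and_gene_list_outputs(self, rng, tmp_path):
        u = rng.normal(size=(30, 3))
        t = score_genes(u, [1, 2], [f"g{i}" for i in range(30)])
        t.write_tsv(tmp_path / "scores.tsv")
        t.write_gene_list(tmp_path / "genes.txt")
        header = (tmp_path / "scores.tsv").read_text().splitlines()[0]
        assert header.split("\t")[:3] == ["gene_id", "u1", "u2"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_adjustment_properties(p):
    """BH output stays in [0, 1], never drops below raw p, and preserves
    the raw ordering (monotone after sorting)."""
    p = np.asarray(p)
    adj = adjust_p(p)
    assert np.all((adj >= 0) & (adj <= 1))
    assert np.all(adj >= p - 1e-12)
    order = np.argsort(p, kind="stable")
    assert np.all(np.diff(adj[order]) >= -1e-12)
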