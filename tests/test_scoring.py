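"""Gene-centric and individual-centric MAE scoring, ranking, thresholds."""

import collections

import numpy as np
import pytest
from scipy import stats

from benfordrna import (
    ExpressionMatrix,
    gene_centric_mae,
    generate_expression,
    individual_centric_mae,
    rank_and_select,
    read_mae_table,
    threshold_select,
    write_mae_table,
)
from benfordrna.simulate import CategorySpec, SyntheticConfig

BENFORD = np.log10(1 + 1 / np.arange(1, 10))


def matrix_of(values, metric="raw", genes=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values=values,
        gene_ids=tuple(genes or (f"g{i:03d}" for i in range(values.shape[0]))),
        sample_ids=tuple(f"s{j:03d}" for j in range(values.shape[1])),
        metric=metric,
    )


def brute_force_gene_mae(values, exclude_below_one=False):
    """Independent per-gene oracle: string digits, Counter tallies, plain sums."""
    out = []
    for row in values:
        digits = []
        for v in row:
            if v == 0 or (exclude_below_one and v < 1):
                continue
            text = np.format_float_positional(float(v), trim="-")
            digits.append(int(next(c for c in text if c in "123456789")))
        if not digits:
            out.append(None)
            continue
        tally = collections.Counter(digits)
        freqs = [tally.get(d, 0) / len(digits) for d in range(1, 10)]
        out.append(sum(abs(a - e) for a, e in zip(freqs, BENFORD)) / 9)
    return out


def benford_proportioned_values():
    """Digit counts proportional to rounded Benford shares over 1000 values."""
    counts = np.round(BENFORD * 1000).astype(int)  # [301, 176, ..., 46]
    values = np.concatenate([np.full(c, float(d)) for d, c in zip(range(1, 10), counts)])
    assert values.size == 1000
    return values


class TestGeneCentric:
    def test_benford_proportioned_gene_scores_near_zero(self):
        m = matrix_of(benford_proportioned_values()[None, :])
        table = gene_centric_mae(m).table
        assert table.loc[0, "mae"] < 1e-3

    def test_constant_gene_closed_form(self):
        # all mass on digit 5: MAE = 2 (1 - E_5) / 9
        m = matrix_of(np.full((1, 100), 5.0))
        table = gene_centric_mae(m).table
        expected = 2 * (1 - np.log10(1 + 1 / 5)) / 9
        assert table.loc[0, "mae"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2046263898, abs=1e-9)

    def test_matches_brute_force_oracle(self, small_counts):
        table = gene_centric_mae(small_counts).table
        oracle = brute_force_gene_mae(small_counts.values)
        assert len(table) == len(oracle)
        for got, want in zip(table["mae"], oracle):
            assert got == pytest.approx(want, rel=1e-12)

    def test_matches_oracle_with_below_one_exclusion(self, rng):
        values = 10 ** rng.uniform(-2, 3, size=(15, 80))
        m = matrix_of(values)
        table = gene_centric_mae(m, exclude_below_one=True).table
        oracle = [v for v in brute_force_gene_mae(values, True) if v is not None]
        assert np.allclose(table["mae"], oracle)

    def test_sample_permutation_invariance(self, small_counts, rng):
        perm = rng.permutation(small_counts.n_samples)
        shuffled = ExpressionMatrix(
            small_counts.values[:, perm],
            small_counts.gene_ids,
            tuple(small_counts.sample_ids[i] for i in perm),
            metric="raw",
        )
        a = gene_centric_mae(small_counts).table
        b = gene_centric_mae(shuffled).table
        assert np.allclose(a["mae"], b["mae"])

    def test_power_of_ten_scale_invariance(self, small_counts):
        scaled = ExpressionMatrix(
            small_counts.values * 10.0,
            small_counts.gene_ids,
            small_counts.sample_ids,
            metric="raw",
        )
        a = gene_centric_mae(small_counts).table
        b = gene_centric_mae(scaled).table
        assert np.array_equal(a["mae"].to_numpy(), b["mae"].to_numpy())

    def test_all_zero_genes_are_omitted_and_reported(self):
        m = matrix_of([[0.0, 0.0], [3.0, 4.0]])
        result = gene_centric_mae(m)
        assert result.omitted == ("g000",)
        assert result.table["gene_id"].tolist() == ["g001"]

    def test_min_used_filter(self):
        m = matrix_of([[5.0, 0.0, 0.0], [3.0, 4.0, 7.0]])
        result = gene_centric_mae(m, min_used=2)
        assert result.omitted == ("g000",)

    def test_mean_expression_on_matrix_scale(self):
        m = matrix_of([[2.0, 4.0]])
        assert gene_centric_mae(m).table.loc[0, "mean_expression"] == 3.0


class TestIndividualCentric:
    def test_single_category_reduces_to_whole_sample_mae(self, small_counts):
        labels = {g: "all" for g in small_counts.gene_ids}
        per_sample = individual_centric_mae(small_counts, labels).table
        whole = brute_force_gene_mae(small_counts.values.T)
        assert np.allclose(per_sample["mae"], whole)

    def test_three_categories_give_three_rows_per_sample(self, small_counts):
        labels = {
            g: ("housekeeping", "tissue_specific", "random")[i % 3]
            for i, g in enumerate(small_counts.gene_ids)
        }
        table = individual_centric_mae(small_counts, labels).table
        assert len(table) == 3 * small_counts.n_samples
        assert set(table["category"]) == {"housekeeping", "tissue_specific", "random"}

    def test_missing_category_raises(self, small_counts):
        labels = {"not_a_gene": "ghost"}
        labels.update({g: "real" for g in small_counts.gene_ids})
        with pytest.raises(ValueError, match="ghost"):
            individual_centric_mae(small_counts, labels)

    def test_empty_pool_is_flagged_not_dropped(self):
        m = matrix_of([[0.0, 5.0], [3.0, 4.0]])
        labels = {"g000": "a", "g001": "b"}
        table = individual_centric_mae(m, labels).table
        row = table[(table["sample_id"] == "s000") & (table["category"] == "a")]
        assert len(row) == 1
        assert not row["defined"].item()
        assert np.isnan(row["mae"].item())

    def test_narrow_housekeeping_scores_above_wide_tissue_specific(self):
        # narrow-range housekeeping set vs wide tissue-specific set
        config = SyntheticConfig(
            n_samples=60,
            seed=11,
            categories=(
                CategorySpec("housekeeping", 250, (2.3, 2.8), 0.15),
                CategorySpec("tissue_specific", 250, (0.5, 3.5), 1.0),
            ),
        )
        m, labels = generate_expression(config)
        table = individual_centric_mae(m, labels).table
        hk = table[table["category"] == "housekeeping"]["mae"]
        ts = table[table["category"] == "tissue_specific"]["mae"]
        assert hk.median() > ts.median()
        p = stats.mannwhitneyu(hk, ts, alternative="greater").pvalue
        assert p < 0.05


class TestRankAndSelect:
    def make_table(self, maes, genes=None):
        values = np.array([[float(d)] * 60 for d in range(1, len(maes) + 1)])
        m = matrix_of(values, genes=genes)
        table = gene_centric_mae(m)
        table.table["mae"] = maes  # overwrite scores for deterministic ranking
        return table

    def test_top_and_bottom_selection(self):
        t = self.make_table([0.5, 0.1, 0.3, 0.2, 0.4, 0.35, 0.15, 0.25, 0.45, 0.05])
        lowest, highest = rank_and_select(t, n_top=3, n_bottom=3)
        assert lowest == ["g009", "g001", "g006"]
        assert highest == ["g000", "g008", "g004"]

    def test_ties_break_toward_smaller_gene_id(self):
        t = self.make_table([0.2, 0.1, 0.2, 0.3], genes=["gB", "gA", "gC", "gD"])
        lowest, highest = rank_and_select(t, n_top=2, n_bottom=1)
        assert lowest == ["gA", "gB"]  # gB beats gC at the tied cut
        assert highest == ["gD"]

    def test_small_table_returns_everything_with_warning(self):
        t = self.make_table([0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="overlap"):
            lowest, highest = rank_and_select(t, n_top=300, n_bottom=300)
        assert len(lowest) == len(highest) == 3

    def test_invalid_counts_rejected(self):
        t = self.make_table([0.1, 0.2])
        with pytest.raises(ValueError, match="positive"):
            rank_and_select(t, n_top=0)


class TestThresholdSelect:
    def make_table(self):
        t = TestRankAndSelect().make_table([0.02, 0.05, 0.064, 0.065, 0.07, 0.1])
        t.table["mean_expression"] = [1.0, 9.0, 5.0, 10.0, 3.0, 12.0]
        return t

    def test_mae_below_is_strict(self):
        got = threshold_select(self.make_table(), mae_below=0.065)
        assert got == ["g000", "g001", "g002"]

    def test_conjunction_of_expression_and_mae(self):
        got = threshold_select(
            self.make_table(), mean_expr_above=8.0, mae_above=0.04
        )
        assert got == ["g001", "g003", "g005"]

    def test_empty_result_is_not_an_error(self):
        assert threshold_select(self.make_table(), mae_below=0.001) == []

    def test_contradictory_bounds_rejected(self):
        with pytest.raises(ValueError, match="contradictory"):
            threshold_select(self.make_table(), mae_below=0.01, mae_above=0.5)

    def test_no_threshold_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            threshold_select(self.make_table())


class TestSerialization:
    def test_round_trip_preserves_scores(self, tmp_path, small_counts):
        table = gene_centric_mae(small_counts)
        path = tmp_path / "mae.tsv"
        write_mae_table(table, path)
        back = read_mae_table(path)
        assert back.table["gene_id"].tolist() == table.table["gene_id"].tolist()
        assert np.allclose(back.table["mae"], table.table["mae"])

    def test_mae_recomputable_from_frequencies(self, small_counts):
        table = gene_centric_mae(small_counts).table
        freqs = table[[f"d{d}" for d in range(1, 10)]].to_numpy()
        recomputed = np.abs(freqs - BENFORD).mean(axis=1)
        assert np.allclose(recomputed, table["mae"], atol=1e-12)
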