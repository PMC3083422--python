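"""Spot filtering, lowess normalization, aggregation and gene selection."""

import numpy as np
import pandas as pd
import pytest

from neutroskin import arrays as arr
from neutroskin import synthetic as syn
from neutroskin.clustering import hierarchical_cluster


def make_array(n=200, seed=0, m_offset=0.0):
    rng = np.random.default_rng(seed)
    a = rng.normal(12, 1.0, n)  # bright spots: none fall below the dim-spot rule
    m = np.full(n, m_offset)
    return pd.DataFrame({
        "spot_id": [f"spot_{i}" for i in range(n)],
        "gene_id": [f"g{i}" for i in range(n)],
        "F_sample": 2.0 ** (a + m / 2),
        "B_sample": np.full(n, 100.0) + rng.normal(0, 5, n),
        "F_ref": 2.0 ** (a - m / 2),
        "B_ref": np.full(n, 100.0) + rng.normal(0, 5, n),
        "flag": np.zeros(n, dtype=int),
    })


class TestIO:
    def test_write_read_round_trip(self, tmp_path):
        table = make_array(50)
        path = tmp_path / "a.tsv"
        arr.write_two_channel_tsv(table, path, header_comment="config=abc seed=0")
        back = arr.read_two_channel_tsv(path)
        pd.testing.assert_frame_equal(back, table, check_exact=False, rtol=1e-12)

    def test_empty_data_section_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(arr.REQUIRED_COLUMNS) + "\n")
        with caplog.at_level("WARNING"):
            table = arr.read_two_channel_tsv(path)
        assert table.empty
        assert any("empty" in r.message for r in caplog.records)

    def test_non_numeric_value_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "\t".join(arr.REQUIRED_COLUMNS) + "\n"
            "s1\tg1\t100\t10\t100\t10\t0\n"
            "s2\tg2\toops\t10\t100\t10\t0\n"
        )
        with pytest.raises(arr.FormatError, match=r"line 3"):
            arr.read_two_channel_tsv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.tsv"
        path.write_text("spot_id\tgene_id\n" "s1\tg1\n")
        with pytest.raises(arr.FormatError, match="missing required columns"):
            arr.read_two_channel_tsv(path)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(arr.FormatError):
            arr.read_two_channel_tsv(tmp_path / "nope.tsv")


class TestFilterSpots:
    def test_clean_spots_all_retained(self):
        table = make_array(100)
        assert arr.filter_spots(table).all()

    def test_rules_on_constructed_fixture(self):
        table = make_array(10, seed=1)
        table.loc[2, "flag"] = -50                      # scanner artifact
        table.loc[4, "F_sample"] = 65535.0              # saturated channel
        table.loc[7, ["F_sample", "F_ref"]] = table.loc[7, ["B_sample", "B_ref"]].to_numpy()
        mask = arr.filter_spots(table)
        assert not mask[2] and not mask[4] and not mask[7]
        assert mask.drop([2, 4, 7]).all()


class TestLowessNormalize:
    def test_constant_offset_removed(self):
        table = make_array(500, m_offset=0.8)
        norm = arr.lowess_normalize(table)
        assert np.abs(norm).max() < 0.02

    def test_planted_cubic_bias_removed(self):
        design = syn.StudyDesign(n_genes=3000, replicates_per_condition=1)
        effects = syn.PlantedEffects.default(design)
        noise = syn.NoiseModel(spot_sd=0.1, flag_rate=0.0, low_signal_rate=0.0, seed=6)
        table = syn.generate_microarrays(design, effects, noise)[(design.condition_labels[0], 1)]
        mask = arr.filter_spots(table)
        norm = arr.lowess_normalize(table, mask)
        truth = effects.log2fc[design.condition_labels[0]].to_numpy()
        resid = (norm.to_numpy() - truth)[mask.to_numpy()]
        a = 0.5 * np.log2(table["F_sample"] * table["F_ref"])[mask].to_numpy()
        # systematic part of the residual: per-intensity-bin means
        bins = np.quantile(a, np.linspace(0, 1, 21))
        idx = np.clip(np.digitize(a, bins) - 1, 0, 19)
        bin_means = np.array([resid[idx == b].mean() for b in range(20)])
        assert np.median(np.abs(bin_means)) < 0.05

    def test_channel_swap_negates_ratio(self):
        rng = np.random.default_rng(3)
        table = make_array(800, seed=2)
        bias = 0.1 * (0.5 * np.log2(table["F_sample"] * table["F_ref"]) - 10) ** 2 * 0.1
        table["F_sample"] = table["F_sample"] * 2.0**bias
        swapped = table.rename(columns={"F_sample": "F_ref", "F_ref": "F_sample",
                                        "B_sample": "B_ref", "B_ref": "B_sample"})
        m1 = arr.lowess_normalize(table)
        m2 = arr.lowess_normalize(swapped)
        assert np.abs(m1 + m2).max() < 0.02

    def test_too_few_spots_rejected(self):
        with pytest.raises(arr.NormalizationError):
            arr.lowess_normalize(make_array(30))


def expr_from_dict(data, conditions):
    """Build an ExpressionMatrix from {gene: {(cond, rep): value}}."""
    table = pd.DataFrame(data).T
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["condition", "replicate"])
    return arr.ExpressionMatrix(replicates=table.sort_index(), conditions=tuple(conditions))


class TestAggregate:
    def _normalized(self, design, values):
        normalized, gene_ids = {}, {}
        for key, series in values.items():
            normalized[key] = pd.Series(series)
            gene_ids[key] = pd.Series([f"g{i}" for i in range(len(series))])
        return normalized, gene_ids

    def test_two_replicates_averaged(self):
        design = syn.StudyDesign(n_genes=2, conditions=((0.2, 6.0),), replicates_per_condition=2)
        normalized, gene_ids = self._normalized(design, {
            ("0p2Gy_6h", 1): [0.8, 0.0], ("0p2Gy_6h", 2): [1.2, 0.0]})
        expr = arr.aggregate_conditions(normalized, design, gene_ids)
        assert expr.means.loc["g0", "0p2Gy_6h"] == pytest.approx(1.0)

    def test_single_replicate_is_identity(self):
        design = syn.StudyDesign(n_genes=2, conditions=((0.2, 6.0),), replicates_per_condition=1)
        normalized, gene_ids = self._normalized(design, {("0p2Gy_6h", 1): [0.5, -0.25]})
        expr = arr.aggregate_conditions(normalized, design, gene_ids)
        assert expr.means.loc["g1", "0p2Gy_6h"] == pytest.approx(-0.25)

    def test_gene_missing_in_one_replicate_dropped(self, caplog):
        design = syn.StudyDesign(n_genes=2, conditions=((0.2, 6.0),), replicates_per_condition=2)
        normalized, gene_ids = self._normalized(design, {
            ("0p2Gy_6h", 1): [0.8, np.nan], ("0p2Gy_6h", 2): [1.2, 0.0]})
        with caplog.at_level("INFO"):
            expr = arr.aggregate_conditions(normalized, design, gene_ids)
        assert list(expr.genes) == ["g0"]

    def test_duplicate_spots_averaged(self):
        design = syn.StudyDesign(n_genes=1, conditions=((0.2, 6.0),), replicates_per_condition=1)
        normalized = {("0p2Gy_6h", 1): pd.Series([0.2, 0.4])}
        gene_ids = {("0p2Gy_6h", 1): pd.Series(["g0", "g0"])}
        expr = arr.aggregate_conditions(normalized, design, gene_ids)
        assert expr.means.loc["g0", "0p2Gy_6h"] == pytest.approx(0.3)


CONDS = ["c1", "c2", "c3", "c4"]


class TestSelectModulated:
    def base_data(self):
        cols = [(c, r) for c in CONDS for r in (1, 2)]
        data = {
            # fold 1.62 in two conditions, tight replicates -> selected
            "gA": dict(zip(cols, [0.69, 0.71, 0.69, 0.71, 0.0, 0.02, 0.0, -0.02])),
            # fold 1.6 in exactly one condition -> rejected
            "gB": dict(zip(cols, [0.68, 0.68, 0.1, 0.1, 0.0, 0.0, 0.05, 0.05])),
            # strong fold but wildly inconsistent replicates -> t-test rejects
            "gC": dict(zip(cols, [2.5, -0.9, 2.4, -1.0, 0.0, 0.1, 0.0, 0.1])),
            # null gene
            "gD": dict(zip(cols, [0.01, -0.01, 0.0, 0.02, 0.0, 0.0, 0.01, 0.0])),
        }
        return expr_from_dict(data, CONDS)

    @pytest.mark.parametrize("t_mode", ["pooled", "per_condition"])
    def test_predicate_examples(self, t_mode):
        selected = arr.select_modulated(self.base_data(), t_mode=t_mode)
        assert "gA" in selected.index
        assert "gB" not in selected.index
        assert "gD" not in selected.index

    def test_inconsistent_replicates_rejected_per_condition(self):
        selected = arr.select_modulated(self.base_data(), t_mode="per_condition")
        assert "gC" not in selected.index

    def test_down_modulation_counts(self):
        cols = [(c, r) for c in CONDS for r in (1, 2)]
        expr = expr_from_dict(
            {"gneg": dict(zip(cols, [-0.8, -0.82, -0.9, -0.88, 0.0, 0.01, 0.0, 0.0]))}, CONDS)
        selected = arr.select_modulated(expr)
        assert "gneg" in selected.index
        assert selected.loc["gneg", "n_passing"] == 2

    def test_rerun_is_identical(self):
        expr = self.base_data()
        a = arr.select_modulated(expr)
        b = arr.select_modulated(expr)
        pd.testing.assert_frame_equal(a, b)

    def test_single_replicate_untestable_excluded(self, caplog):
        cols = [(c, 1) for c in CONDS]
        expr = expr_from_dict({"gA": dict(zip(cols, [1.5, 1.5, 0.0, 0.0]))}, CONDS)
        with caplog.at_level("INFO"):
            selected = arr.select_modulated(expr)
        assert selected.empty

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            arr.select_modulated(self.base_data(), t_mode="bogus")


class TestHeatMatrix:
    def test_clipping_and_leaf_order(self):
        cols = [(c, 1) for c in CONDS]
        expr = expr_from_dict({
            "g0": dict(zip(cols, [5.0, 0.0, 0.0, 0.0])),
            "g1": dict(zip(cols, [-0.2, 0.1, 0.0, 0.0])),
            "g2": dict(zip(cols, [-4.0, 0.2, 0.1, 0.0])),
        }, CONDS)
        dend = hierarchical_cluster(expr.means.to_numpy(), labels=expr.genes)
        heat = arr.export_heat_matrix(expr, dend, clip=3.0)
        assert heat.to_numpy().max() == 3.0
        assert heat.to_numpy().min() == -3.0
        assert heat.loc["g1"].iloc[0] == pytest.approx(-0.2)
        assert list(heat.index) == [dend.labels[i] for i in dend.leaf_order()]
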