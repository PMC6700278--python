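"""Differential splicing: filters, bin testing, event and intron summaries."""

import numpy as np
import pandas as pd
import pytest

from binsplice import (
    BinSplicingTest,
    CountMatrix,
    filter_bins,
    intron_class_comparison,
    summarize_event_frequencies,
)


def small_bins():
    return pd.DataFrame(
        {
            "gene_id": ["gMono", "gA", "gA", "gB"],
            "length": [200, 100, 150, 120],
            "kind": ["exon", "exon", "as", "as"],
            "event_class": ["none", "none", "IR", "IR"],
            "annotated_as": [False, False, True, True],
        },
        index=["gMono:exon1", "gA:exon1", "gA:as1", "gB:as1"],
    )


def cm_from(cols, index):
    df = pd.DataFrame(cols, index=index)
    return CountMatrix(
        counts=df, condition_of={s: s.rsplit("_", 1)[0] for s in df.columns}
    )


class TestFilterBins:
    def _density(self, rows):
        return pd.DataFrame(rows, columns=["wt", "mut"])

    def test_monoexonic_gene_bins_dropped_despite_high_counts(self):
        bins = small_bins()
        cm = cm_from({"wt_1": [100, 50, 50, 50], "mut_1": [100, 50, 50, 50]}, bins.index)
        dens = pd.DataFrame({"wt": [1.0] * 3, "mut": [1.0] * 3}, index=["gMono", "gA", "gB"])
        kept = filter_bins(bins, cm, dens, monoexonic={"gMono"})
        assert "gMono:exon1" not in kept

    def test_mean_below_five_in_any_condition_dropped(self):
        bins = small_bins()
        cm = cm_from({"wt_1": [10, 4, 50, 50], "mut_1": [10, 50, 50, 50]}, bins.index)
        dens = pd.DataFrame({"wt": [1.0] * 3, "mut": [1.0] * 3}, index=["gMono", "gA", "gB"])
        kept = filter_bins(bins, cm, dens, monoexonic=set())
        assert "gA:exon1" not in kept and "gA:as1" in kept

    def test_low_gene_density_drops_all_gene_bins(self):
        bins = small_bins()
        cm = cm_from({"wt_1": [10, 50, 50, 50], "mut_1": [10, 50, 50, 50]}, bins.index)
        dens = pd.DataFrame(
            {"wt": [1.0, 0.06, 1.0], "mut": [1.0, 0.04, 1.0]},
            index=["gMono", "gA", "gB"],
        )
        kept = filter_bins(bins, cm, dens, monoexonic=set())
        assert not any(k.startswith("gA") for k in kept)
        assert "gB:as1" in kept

    def test_density_boundary_is_strict(self):
        bins = small_bins()
        cm = cm_from({"wt_1": [10, 50, 50, 50], "mut_1": [10, 50, 50, 50]}, bins.index)
        dens = pd.DataFrame(
            {"wt": [1.0, 0.05, 1.0], "mut": [1.0, 1.0, 1.0]},
            index=["gMono", "gA", "gB"],
        )
        kept = filter_bins(bins, cm, dens, monoexonic=set())
        assert not any(k.startswith("gA") for k in kept)  # 0.05 is not > 0.05

    def test_filter_idempotent(self):
        bins = small_bins()
        cm = cm_from({"wt_1": [10, 4, 50, 50], "mut_1": [10, 50, 50, 50]}, bins.index)
        dens = pd.DataFrame({"wt": [1.0] * 3, "mut": [1.0] * 3}, index=["gMono", "gA", "gB"])
        once = filter_bins(bins, cm, dens, monoexonic={"gMono"})
        twice = filter_bins(bins.loc[once], cm, dens, monoexonic={"gMono"})
        assert list(once) == list(twice)


class TestEventFrequencies:
    def test_proportions_to_one_decimal(self):
        # 38 significant events split 18/12/7/1 across the four classes
        rows = (
            [("IR", True)] * 18 + [("Alt5SS", True)] * 12
            + [("Alt3SS", True)] * 7 + [("ES", True)] * 1
        )
        table = pd.DataFrame(rows, columns=["event_class", "significant"])
        freq = summarize_event_frequencies(table, "significant")
        assert freq.loc["IR", "percent"] == 47.4
        assert freq.loc["Alt5SS", "percent"] == 31.6
        assert freq.loc["Alt3SS", "percent"] == 18.4
        assert freq.loc["ES", "percent"] == 2.6
        assert abs(freq["percent"].sum() - 100) <= 0.2

    def test_single_class_is_hundred_percent(self):
        table = pd.DataFrame({"event_class": ["IR"] * 7, "significant": [True] * 7})
        freq = summarize_event_frequencies(table, "all_detected")
        assert freq["percent"].tolist() == [100.0]

    def test_equal_classes_quarter_each(self):
        table = pd.DataFrame(
            {"event_class": ["IR", "ES", "Alt5SS", "Alt3SS"] * 5, "significant": True}
        )
        freq = summarize_event_frequencies(table)
        assert set(freq["percent"]) == {25.0}

    def test_empty_scope(self):
        table = pd.DataFrame({"event_class": ["IR"], "significant": [False]})
        assert summarize_event_frequencies(table, "significant").empty

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            summarize_event_frequencies(pd.DataFrame(), "everything")


class TestIntronClassComparison:
    def _table(self, n_as, up_as, n_cs, up_cs):
        rows = []
        for i in range(n_as):
            rows.append((True, i < up_as, 1.0 if i < up_as else 0.0))
        for i in range(n_cs):
            rows.append((False, i < up_cs, 1.0 if i < up_cs else 0.0))
        return pd.DataFrame(rows, columns=["annotated_as", "significant", "log2fc_density"])

    def test_percentages(self):
        got = intron_class_comparison(self._table(1000, 18, 100000, 379))
        assert got["AS"]["percent_up"] == pytest.approx(1.8)
        assert got["CS"]["percent_up"] == pytest.approx(0.379)

    def test_no_significant_introns(self):
        got = intron_class_comparison(self._table(10, 0, 10, 0))
        assert got["AS"]["percent_up"] == 0 and got["CS"]["percent_up"] == 0

    def test_all_up(self):
        got = intron_class_comparison(self._table(5, 5, 5, 5))
        assert got["AS"]["percent_up"] == 100 and got["CS"]["percent_up"] == 100

    def test_empty_class_reported_missing(self):
        got = intron_class_comparison(self._table(0, 0, 4, 1))
        assert got["AS"]["percent_up"] is None

    def test_downward_significant_events_not_counted_as_retention(self):
        table = pd.DataFrame(
            {"annotated_as": [True], "significant": [True], "log2fc_density": [-2.0]}
        )
        assert intron_class_comparison(table)["AS"]["n_retained_up"] == 0


class TestBinSplicingFit:
    def _toy_study(self, seed=7, planted_ratio=3.0, phi=0.05, n_bins=60):
        """One planted IR bin (wt mean 20, mutant 3x) among null bins."""
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_bins // 2)]
        rows, index = [], []
        for i, g in enumerate(genes):
            rows.append((g, 150, "exon", "none", False))
            index.append(f"{g}:exon1")
            rows.append((g, 100, "as", "IR", True))
            index.append(f"{g}:as1")
        bins = pd.DataFrame(
            rows, columns=["gene_id", "length", "kind", "event_class", "annotated_as"],
            index=index,
        )
        mean = pd.Series(60.0, index=bins.index)
        mean[bins["kind"] == "as"] = 20.0
        mean_mut = mean.copy()
        mean_mut["g0:as1"] = 20.0 * planted_ratio
        r = 1 / phi
        cols = {}
        for j in range(1, 4):
            cols[f"wt_{j}"] = rng.negative_binomial(r, r / (r + mean))
            cols[f"mut_{j}"] = rng.negative_binomial(r, r / (r + mean_mut))
        bin_cm = CountMatrix(
            counts=pd.DataFrame(cols, index=bins.index),
            condition_of={s: s.rsplit("_", 1)[0] for s in cols},
        )
        gene_mean = mean.groupby(bins["gene_id"]).sum().reindex(genes)
        gcols = {
            s: rng.negative_binomial(r, r / (r + gene_mean)) for s in cols
        }
        gene_cm = CountMatrix(
            counts=pd.DataFrame(gcols, index=genes),
            condition_of=bin_cm.condition_of,
        )
        lengths = pd.Series(250.0, index=genes)
        return bins, bin_cm, gene_cm, lengths

    def test_planted_retention_called_significant(self):
        bins, bin_cm, gene_cm, lengths = self._toy_study()
        res = BinSplicingTest(bins, bin_cm, gene_cm, lengths, monoexonic=set()).fit()
        assert "g0:as1" in res.significant_bins
        row = res.table.loc["g0:as1"]
        assert row["log2fc_density"] > 0.58 and row["fdr"] < 0.15

    def test_density_fold_change_arithmetic(self):
        bins, bin_cm, gene_cm, lengths = self._toy_study()
        res = BinSplicingTest(bins, bin_cm, gene_cm, lengths, monoexonic=set()).fit()
        row = res.table.loc["g0:as1"]
        expected = np.log2(row["density_mut"] / row["density_wt"])
        assert row["log2fc_density"] == pytest.approx(expected)

    def test_significant_bins_survive_all_filters(self, default_study, default_ds_results):
        res = default_ds_results
        sim = default_study["sim"]
        means = sim.bin_cm.condition_means()
        mono = default_study["ann"].model.monoexonic_genes
        for b in res.significant_bins:
            assert (means.loc[b] >= 5).all()
            assert res.table.loc[b, "gene_id"] not in mono

    def test_symmetric_counts_not_significant(self):
        bins, bin_cm, gene_cm, lengths = self._toy_study(planted_ratio=1.0)
        res = BinSplicingTest(bins, bin_cm, gene_cm, lengths, monoexonic=set()).fit()
        assert res.table["significant"].sum() == 0

    def test_summary_mentions_thresholds(self, default_ds_results):
        text = default_ds_results.summary()
        assert "FDR < 0.15" in text and "0.58" in text
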