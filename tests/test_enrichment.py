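import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnahet.calling import GAIN, LOSS
from cnahet.enrichment import (
    EnrichmentParams,
    enriched_regions,
    enrichment_report,
    export_gene_list,
    fisher_exact_3x2,
    load_gene_annotation,
    penetrance,
    region_table,
)
from cnahet.heterogeneity import CallMatrix, harmonize
from tests._oracles import fisher_3x2_oracle


def matrix_from_states(states, samples=None, region_span=1000):
    """CallMatrix with one chromosome and given (n_regions, n_samples) states."""
    states = np.asarray(states, dtype=np.int8)
    n_regions, n_samples = states.shape
    samples = samples or [f"S{i}" for i in range(n_samples)]
    regions = pd.DataFrame(
        {
            "chromosome": "1",
            "start": np.arange(n_regions) * 2 * region_span,
            "end": np.arange(n_regions) * 2 * region_span + region_span,
        }
    )
    return CallMatrix(regions, states, samples)


class TestPenetrance:
    def test_fraction_of_carriers(self):
        states = np.zeros((1, 18), dtype=np.int8)
        states[0, :8] = GAIN
        m = matrix_from_states(states)
        pen = penetrance(m, m.samples)
        assert pen["frac_gain"].iloc[0] == pytest.approx(0.444, abs=1e-3)

    def test_all_neutral_region(self):
        m = matrix_from_states(np.zeros((1, 5), dtype=np.int8))
        pen = penetrance(m, m.samples)
        assert (pen["frac_gain"].iloc[0], pen["frac_loss"].iloc[0]) == (0.0, 0.0)

    def test_fully_gained_region(self):
        m = matrix_from_states(np.full((1, 5), GAIN, dtype=np.int8))
        pen = penetrance(m, m.samples)
        assert (pen["frac_gain"].iloc[0], pen["frac_loss"].iloc[0]) == (1.0, 0.0)

    def test_empty_group_rejected(self):
        m = matrix_from_states(np.zeros((1, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            penetrance(m, [])

    def test_gain_plus_loss_at_most_one(self, small_cohort):
        states = np.random.default_rng(5).choice([GAIN, LOSS, 0], size=(30, 10))
        m = matrix_from_states(states)
        pen = penetrance(m, m.samples)
        assert ((pen["frac_gain"] + pen["frac_loss"]) <= 1 + 1e-12).all()


class TestFisherExact3x2:
    def test_complete_separation_small_table(self):
        # (3,0,0) vs (0,0,3): reduces to 2x2 with two extreme tables of 1/20 each
        assert fisher_exact_3x2([[3, 0], [0, 0], [0, 3]]) == pytest.approx(0.1)

    def test_single_attainable_table_gives_one(self):
        assert fisher_exact_3x2([[5, 5], [0, 0], [0, 0]]) == pytest.approx(1.0)
        assert fisher_exact_3x2([[5, 0], [0, 0], [0, 0]]) == pytest.approx(1.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact_3x2([[0, 0], [0, 0], [0, 0]])

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(29)
        checked = 0
        while checked < 150:
            t = rng.integers(0, 7, size=(3, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_3x2(t) == pytest.approx(fisher_3x2_oracle(t), abs=1e-9)
            checked += 1

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=6, max_size=6))
    def test_invariance_under_column_swap_and_row_permutation(self, cells):
        t = np.array(cells).reshape(3, 2)
        if t.sum() == 0:
            return
        p = fisher_exact_3x2(t)
        assert fisher_exact_3x2(t[:, ::-1]) == pytest.approx(p, abs=1e-12)
        for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            assert fisher_exact_3x2(t[perm, :]) == pytest.approx(p, abs=1e-12)


class TestEnrichedRegions:
    @staticmethod
    def _group_matrix(gain_a, n_a, gain_b, n_b, extra_neutral=2):
        """One spiked region: gained in gain_a/n_a of group A vs gain_b/n_b of B."""
        states = np.zeros((1 + extra_neutral, n_a + n_b), dtype=np.int8)
        states[0, :gain_a] = GAIN
        states[0, n_a : n_a + gain_b] = GAIN
        m = matrix_from_states(states)
        return m, m.samples[:n_a], m.samples[n_a:]

    def test_strong_group_difference_reported(self):
        m, a, b = self._group_matrix(28, 39, 2, 18)
        regs = enriched_regions(m, a, b, label_a="LNM", label_b="PT")
        assert len(regs) == 1
        assert regs[0].direction == "gain"
        assert regs[0].enriched_in == "LNM"
        assert regs[0].prevalence_a == pytest.approx(28 / 39)
        assert regs[0].p_value <= 0.05

    def test_low_prevalence_not_reported(self):
        m, a, b = self._group_matrix(1, 39, 0, 18)
        assert enriched_regions(m, a, b) == []

    def test_identical_penetrance_not_reported(self):
        m, a, b = self._group_matrix(5, 10, 5, 10)
        assert enriched_regions(m, a, b) == []

    def test_overlapping_groups_rejected(self):
        m, a, b = self._group_matrix(3, 5, 3, 5)
        with pytest.raises(ValueError, match="disjoint"):
            enriched_regions(m, a, a)

    def test_adjacent_identical_regions_merge_into_band(self):
        states = np.zeros((2, 12), dtype=np.int8)
        states[:, :5] = GAIN  # both regions gained in the same 5 of group A
        regions = pd.DataFrame(
            {"chromosome": ["1", "1"], "start": [0, 1000], "end": [1000, 2000]}
        )
        m = CallMatrix(regions, states, [f"S{i}" for i in range(12)])
        regs = enriched_regions(m, m.samples[:6], m.samples[6:])
        assert len(regs) == 1
        assert (regs[0].start, regs[0].end) == (0, 2000)
        assert regs[0].n_regions == 2

    def test_bh_mode_is_no_less_strict(self):
        states = np.zeros((6, 12), dtype=np.int8)
        states[0, :4] = GAIN
        states[1, :6] = GAIN
        m = matrix_from_states(states)
        a, b = m.samples[:6], m.samples[6:]
        raw = enriched_regions(m, a, b, EnrichmentParams())
        bh = enriched_regions(m, a, b, EnrichmentParams(multiple_testing="BH"))
        assert len(bh) <= len(raw)

    def test_region_table_column_sums_are_group_sizes(self):
        m, a, b = self._group_matrix(4, 9, 1, 6)
        t = region_table(m, 0, a, b)
        assert t[:, 0].sum() == 9
        assert t[:, 1].sum() == 6


class TestGeneExport:
    @staticmethod
    def _annotation(tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "1\t100\t200\tGENE_A\n"
            "1\t1500\t4500\tGENE_B\n"
            "2\t50\t80\tGENE_C\n"
        )
        return load_gene_annotation(bed)

    def test_overlapping_gene_listed(self, tmp_path):
        from cnahet.enrichment import EnrichedRegion

        ann = self._annotation(tmp_path)
        regs = [EnrichedRegion("1", 150, 400, "gain", 0.01, "LNM", 0.6, 0.1)]
        table = export_gene_list(regs, ann)
        assert table["gene"].tolist() == ["GENE_A"]
        assert regs[0].genes == ["GENE_A"]

    def test_region_without_genes_gets_empty_entry(self, tmp_path):
        from cnahet.enrichment import EnrichedRegion

        ann = self._annotation(tmp_path)
        regs = [EnrichedRegion("2", 1000, 2000, "loss", 0.02, "PT", 0.1, 0.5)]
        table = export_gene_list(regs, ann)
        assert len(table) == 1
        assert table["gene"].iloc[0] == ""

    def test_gene_spanning_two_regions_listed_under_both(self, tmp_path):
        from cnahet.enrichment import EnrichedRegion

        ann = self._annotation(tmp_path)
        regs = [
            EnrichedRegion("1", 1000, 2000, "gain", 0.01, "LNM", 0.5, 0.0),
            EnrichedRegion("1", 3000, 4000, "gain", 0.02, "LNM", 0.5, 0.0),
        ]
        table = export_gene_list(regs, ann)
        assert (table["gene"] == "GENE_B").sum() == 2

    def test_report_table_shape(self, tmp_path):
        from cnahet.enrichment import EnrichedRegion

        regs = [EnrichedRegion("1", 0, 10, "gain", 0.01, "LNM", 0.7, 0.1)]
        rep = enrichment_report(regs, "LNM_vs_PT", "LNM", "PT")
        assert rep["comparison"].iloc[0] == "LNM_vs_PT"
        assert rep["start"].iloc[0] == 1  # 1-based in reports
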