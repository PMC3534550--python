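"""Gene selection and CNA-expression concordance tables."""

import numpy as np
import pandas as pd
import pytest

from cnaseg import (
    ConcordanceTable,
    concordance_percent,
    segment_gene_concordance,
    select_top_genes,
    snp_gene_concordance,
)
from cnaseg.segmentation import Segment, SegmentationResult


def _de_table(pvals, logfcs, chrom="chr1"):
    n = len(pvals)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "start": np.arange(n) * 1000 + 1,
            "end": np.arange(n) * 1000 + 500,
            "logFC": logfcs,
            "adj_p": pvals,
        }
    )


class TestSelectTopGenes:
    def test_smallest_adjusted_p_wins(self):
        df = _de_table([0.001, 0.01, 0.5], [1.0, -1.0, 2.0])
        top = select_top_genes(df, n=1)
        assert list(top["gene_id"]) == ["g0"]

    def test_direction_from_logfc_sign(self):
        df = _de_table([0.1, 0.2], [0.5, -0.5])
        top = select_top_genes(df, n=2)
        assert list(top["direction"]) == ["up", "down"]

    def test_matches_sort_oracle(self, rng):
        df = _de_table(rng.uniform(0, 1, 50).round(2), rng.normal(0, 2, 50).round(2))
        top = select_top_genes(df, n=10)
        oracle = sorted(
            df.itertuples(index=False),
            key=lambda g: (g.adj_p, -abs(g.logFC), g.gene_id),
        )[:10]
        assert list(top["gene_id"]) == [g.gene_id for g in oracle]

    def test_short_table_returns_all_with_warning(self):
        df = _de_table([0.1], [1.0])
        with pytest.warns(UserWarning, match="only 1"):
            top = select_top_genes(df, n=5)
        assert len(top) == 1

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            select_top_genes(pd.DataFrame({"gene_id": []}), n=1)


class TestSnpConcordance:
    def test_one_gene_three_snps_rule(self):
        track = pd.DataFrame(
            {"chrom": "chr1", "pos": [100, 200, 300], "log2ratio": [0.5, 0.0, -0.5]}
        )
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr1", "start": [50], "end": [350], "direction": ["up"]}
        )
        table = snp_gene_concordance(track, genes)
        assert table.counts.loc["up"].tolist() == [1, 1, 1]  # amp, del, no variation
        assert table.row_totals["up"] == 3
        assert table.n_genes["up"] == 1

    def test_no_snp_in_gene_gives_empty_table(self):
        track = pd.DataFrame({"chrom": "chr1", "pos": [10_000], "log2ratio": [1.0]})
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr1", "start": [1], "end": [100], "direction": ["down"]}
        )
        table = snp_gene_concordance(track, genes)
        assert table.grand_total == 0

    def test_overlapping_genes_count_snp_k_times(self):
        track = pd.DataFrame({"chrom": "chr1", "pos": [100], "log2ratio": [0.9]})
        genes = pd.DataFrame(
            {
                "gene_id": ["a", "b"],
                "chrom": "chr1",
                "start": [50, 60],
                "end": [150, 160],
                "direction": ["up", "up"],
            }
        )
        assert snp_gene_concordance(track, genes).counts.loc["up", "amplification"] == 2

    def test_table_layout_has_direction_rows_and_class_columns(self):
        track = pd.DataFrame({"chrom": "chr1", "pos": [100], "log2ratio": [0.0]})
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr1", "start": [1], "end": [200], "direction": ["up"]}
        )
        frame = snp_gene_concordance(track, genes).to_frame()
        assert list(frame.index) == ["up", "down"]
        assert list(frame.columns) == [
            "n_genes", "amplification", "deletion", "no variation", "total",
        ]


class TestSegmentConcordance:
    def _res(self, means, chrom="chr1"):
        res = SegmentationResult(sample_id="s")
        res.segments[chrom] = [
            Segment(chrom, i * 10, (i + 1) * 10, i * 1000 + 1, i * 1000 + 900, 10, m)
            for i, m in enumerate(means)
        ]
        return res

    def test_spanning_amplified_segment(self):
        res = self._res([0.9])
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr1", "start": [100], "end": [500], "direction": ["up"]}
        )
        table = segment_gene_concordance(res, genes)
        assert table.counts.loc["up"].tolist() == [1, 0, 0]

    def test_gene_in_probe_desert_contributes_nothing(self):
        res = self._res([0.9])
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": "chr2", "start": [1], "end": [100], "direction": ["up"]}
        )
        assert segment_gene_concordance(res, genes).grand_total == 0

    def test_counts_match_interval_sweep_oracle(self, rng):
        means = list(rng.normal(0, 0.5, 8))
        res = self._res(means)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20)],
                "chrom": "chr1",
                "start": rng.integers(1, 8000, 20),
                "end": 0,
                "direction": rng.choice(["up", "down"], 20),
            }
        )
        genes["end"] = genes["start"] + rng.integers(100, 3000, 20)
        table = segment_gene_concordance(res, genes)
        # brute-force sweep
        expected = 0
        for g in genes.itertuples(index=False):
            for seg in res.segments["chr1"]:
                if seg.start_bp <= g.end and g.start <= seg.end_bp:
                    expected += 1
        assert table.grand_total == expected


class TestConcordancePercent:
    def _printed_table(self):
        counts = pd.DataFrame(
            [[358, 104, 3032], [121, 41, 1694]],
            index=["up", "down"],
            columns=["amplification", "deletion", "no variation"],
        )
        return ConcordanceTable(counts, unit="SNPs", n_genes={"up": 330, "down": 170})

    def test_direct_comparison_arithmetic(self):
        table = self._printed_table()
        assert table.concordant == 399
        assert table.grand_total == 5350
        assert concordance_percent(table) == 7.5

    def test_all_concordant_is_hundred(self):
        counts = pd.DataFrame(
            [[10, 0, 0], [0, 5, 0]], index=["up", "down"],
            columns=["amplification", "deletion", "no variation"],
        )
        assert concordance_percent(ConcordanceTable(counts)) == 100.0

    def test_invariant_under_count_scaling(self):
        table = self._printed_table()
        scaled = ConcordanceTable(table.counts * 7, unit="SNPs")
        assert concordance_percent(scaled) == concordance_percent(table)

    def test_row_total_invariants(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 100, (2, 3)), index=["up", "down"],
            columns=["amplification", "deletion", "no variation"],
        )
        table = ConcordanceTable(counts)
        assert table.grand_total == table.row_totals.sum()
        hand = 100.0 * (counts.iloc[0, 0] + counts.iloc[1, 1]) / counts.to_numpy().sum()
        assert concordance_percent(table) == round(hand, 1)

    def test_empty_table_rejected(self):
        counts = pd.DataFrame(
            0, index=["up", "down"], columns=["amplification", "deletion", "no variation"]
        )
        with pytest.raises(ValueError):
            concordance_percent(ConcordanceTable(counts))


class TestCouplingSanity:
    def test_coupled_expression_raises_concordance(self, small_map):
        from dataclasses import replace

        from cnaseg import SimulationConfig, simulate_expression, simulate_profile
        from cnaseg.simulate import random_genes

        cfg = SimulationConfig(
            n_chromosomes=3, probes_per_chromosome=100, chrom_length=5_000_000,
            noise_sd=0.0, seed=19,
        )
        profile = simulate_profile(small_map, cfg, "tumor")
        genes = random_genes(small_map, n=300, seed=19)
        track_rows = []
        states = profile.probe_states(small_map)
        for chrom in small_map.chrom_names:
            track_rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": small_map.positions[chrom],
                        "log2ratio": np.log2(np.maximum(states[chrom], 0.25) / 2.0),
                    }
                )
            )
        track = pd.concat(track_rows, ignore_index=True)

        def percent(kappa):
            de = simulate_expression(
                profile, genes, replace(cfg, expression_coupling=kappa, expression_noise_sd=0.05)
            )
            top = select_top_genes(de, n=150)
            return concordance_percent(snp_gene_concordance(track, top))

        assert percent(1.0) > percent(0.0)
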