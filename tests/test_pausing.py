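"""Pausing-index statistic, genotype comparison and the rank-test /
boxplot / ECDF machinery, each against an independent oracle."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromaquant import (
    FragmentIndex,
    SimulationConfig,
    boxplot_summary,
    delta_pausing,
    ecdf,
    expected_pausing_index,
    gene_pausing_index,
    mann_whitney,
    pausing_table,
    simulate_annotation,
    simulate_polII_fragments,
    transcript_pausing_index,
    window_density,
)
from chromaquant.genomic_core import (
    Fragment,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

CHROMS = {"chr1": 1_000_000}


def frag(start, end, strand=".", chrom="chr1"):
    return Fragment(GenomicInterval(chrom, start, end, strand))


def transcript(start, end, strand="+", tid="t1", gid="g1"):
    return TranscriptModel(
        tid, gid, GenomicInterval("chr1", start, end, strand)
    )


class TestWindowDensity:
    def test_count_over_length(self):
        frags = [frag(1000 + 10 * i, 1000 + 10 * i + 2) for i in range(10)]
        window = GenomicInterval("chr1", 900, 1400)
        assert window_density(frags, window, CHROMS) == pytest.approx(
            10 / 500
        )

    def test_empty_window_is_zero(self):
        assert window_density(
            [], GenomicInterval("chr1", 0, 100), CHROMS
        ) == 0.0

    def test_fully_clipped_window_undefined(self):
        window = GenomicInterval("chr1", -500, -100)
        assert window_density([frag(0, 10)], window, CHROMS) is None

    def test_matches_brute_force_membership_count(self):
        rng = np.random.default_rng(61)
        frags = [
            frag(int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 900_000, 500), rng.integers(20, 400, 500)
            )
        ]
        for _ in range(20):
            a = int(rng.integers(0, 900_000))
            b = a + int(rng.integers(100, 5_000))
            window = GenomicInterval("chr1", a, b)
            expected = sum(a <= f.midpoint < b for f in frags) / (b - a)
            assert window_density(frags, window, CHROMS) == pytest.approx(
                expected
            )

    def test_five_prime_mode_uses_strand(self):
        minus = frag(1000, 1200, "-")  # 5' end at 1199
        window = GenomicInterval("chr1", 1150, 1250)
        assert window_density([minus], window, CHROMS,
                              mode="five_prime") == pytest.approx(1 / 100)
        window_left = GenomicInterval("chr1", 950, 1050)
        assert window_density([minus], window_left, CHROMS,
                              mode="five_prime") == 0.0


class TestTranscriptPausingIndex:
    def test_ratio_of_densities(self):
        t = transcript(10_000, 15_000)
        # 10 midpoints in the 500 bp promoter, 10 in the 5700 bp body
        frags = [frag(9_850 + i, 9_860 + i) for i in range(10)]
        frags += [frag(11_000 + 100 * i, 11_010 + 100 * i)
                  for i in range(10)]
        record = transcript_pausing_index(frags, t, CHROMS)
        assert record.pausing_index == pytest.approx(
            (10 / 500) / (10 / 5_700)
        )

    def test_uniform_density_gives_unity(self):
        t = transcript(10_000, 15_000)
        # one midpoint every 10 bp across promoter + body
        frags = [frag(p - 1, p + 1) for p in range(9_800, 16_000, 10)]
        record = transcript_pausing_index(frags, t, CHROMS)
        assert record.pausing_index == pytest.approx(1.0, rel=0.02)

    def test_zero_body_density_is_undefined(self):
        t = transcript(10_000, 15_000)
        record = transcript_pausing_index(
            [frag(9_900, 9_920)], t, CHROMS
        )
        assert record.pausing_index is None
        assert not record.defined

    def test_zero_promoter_with_body_is_zero(self):
        t = transcript(10_000, 15_000)
        record = transcript_pausing_index(
            [frag(12_000, 12_100)], t, CHROMS
        )
        assert record.pausing_index == 0.0

    def test_short_isoform_filtered_not_raised(self):
        t = transcript(10_000, 10_150)
        record = transcript_pausing_index([frag(10_050, 10_060)], t, CHROMS)
        assert record.pausing_index is None


class TestGenePausingIndex:
    def test_max_pi_isoform_excluding_short(self):
        # long isoform: low PI; mid isoform: higher PI; 150 nt isoform
        # would win but is excluded by the length filter
        long_t = transcript(10_000, 15_000, tid="t.long")
        mid_t = transcript(10_000, 11_500, tid="t.mid")
        tiny_t = transcript(10_000, 10_150, tid="t.tiny")
        gene = GeneModel("g1", (long_t, mid_t, tiny_t))
        frags = [frag(10_040 + i, 10_060 + i) for i in range(40)]
        frags += [frag(11_000 + 150 * i, 11_020 + 150 * i)
                  for i in range(25)]
        record = gene_pausing_index(frags, gene, CHROMS)
        per_iso = {
            t.transcript_id: transcript_pausing_index(frags, t, CHROMS)
            for t in (long_t, mid_t)
        }
        best = max(
            per_iso.values(), key=lambda r: r.pausing_index
        )
        assert record.transcript_id == best.transcript_id
        assert record.pausing_index == best.pausing_index

    def test_single_isoform_equals_transcript_level(self):
        t = transcript(10_000, 15_000)
        gene = GeneModel("g1", (t,))
        frags = [frag(9_900, 9_920), frag(12_000, 12_020)]
        assert gene_pausing_index(frags, gene, CHROMS).pausing_index == \
            transcript_pausing_index(frags, t, CHROMS).pausing_index

    def test_all_isoforms_bodyless_is_undefined(self):
        gene = GeneModel("g1", (transcript(10_000, 15_000),))
        record = gene_pausing_index([frag(9_900, 9_910)], gene, CHROMS)
        assert record.pausing_index is None

    def test_recovers_simulated_pausing_fraction(self):
        cfg = SimulationConfig(
            seed=67, n_genes=8, chrom_length=200_000,
            gene_length_range=(5_000, 5_000),
            second_isoform_fraction=0.0,
            pausing_fraction={"c": 0.8},
        )
        genes, sizes = simulate_annotation(cfg)
        expr = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "fpkm": np.ones(len(genes))}
        )
        frags = simulate_polII_fragments(
            genes, expr, "c", cfg, fragments_per_gene=2_500
        )
        index = FragmentIndex(frags)
        estimates = [
            gene_pausing_index(index, g, sizes).pausing_index
            for g in genes
        ]
        assert np.median(estimates) == pytest.approx(45.6, rel=0.10)


class TestPausingTable:
    def _small_setup(self):
        cfg = SimulationConfig(seed=71, n_genes=30, chrom_length=600_000)
        genes, sizes = simulate_annotation(cfg)
        expr = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "fpkm": np.full(len(genes), 5.0)}
        )
        return cfg, genes, sizes, expr

    def test_one_record_per_sample_gene(self):
        cfg, genes, sizes, expr = self._small_setup()
        frags = {
            c: simulate_polII_fragments(genes, expr, c, cfg)
            for c in ("WT", "DKO")
        }
        table = pausing_table(frags, genes, sizes)
        assert len(table) == 2 * len(genes)

    def test_genotype_shift_in_median(self):
        cfg = SimulationConfig(
            seed=73, n_genes=100, chrom_length=2_000_000,
            pausing_fraction={"WT": 0.30, "DKO": 0.45},
        )
        genes, sizes = simulate_annotation(cfg)
        expr = pd.DataFrame(
            {"gene_id": [g.gene_id for g in genes],
             "fpkm": np.full(len(genes), 10.0)}
        )
        frags = {
            c: simulate_polII_fragments(
                genes, expr, c, cfg, fragments_per_gene=400
            )
            for c in ("WT", "DKO")
        }
        table = pausing_table(frags, genes, sizes)
        medians = table.groupby("sample")["pausing_index"].median()
        assert medians["DKO"] > medians["WT"]

    def test_delta_pausing_antisymmetry(self):
        cfg, genes, sizes, expr = self._small_setup()
        frags = {
            c: simulate_polII_fragments(genes, expr, c, cfg)
            for c in ("WT", "DKO")
        }
        table = pausing_table(frags, genes, sizes)
        ab = delta_pausing(table, "WT", "DKO").set_index("gene_id")
        ba = delta_pausing(table, "DKO", "WT").set_index("gene_id")
        np.testing.assert_allclose(
            ab["delta_pi"].dropna(), -ba["delta_pi"].dropna()
        )

    def test_identical_samples_zero_delta(self):
        cfg, genes, sizes, expr = self._small_setup()
        frags = simulate_polII_fragments(genes, expr, "WT", cfg)
        table = pausing_table({"a": frags, "b": frags}, genes, sizes)
        delta = delta_pausing(table, "a", "b")
        np.testing.assert_allclose(delta["delta_pi"].dropna(), 0.0)


class TestEcdf:
    def test_basic_evaluation(self):
        F = ecdf([1, 2, 3])
        assert F(2) == pytest.approx(2 / 3)
        assert F(3) == 1.0
        assert F(0.5) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecdf([])

    def test_within_dkw_band_of_true_cdf(self):
        """ECDF of exponential draws stays inside the 99%
        Dvoretzky-Kiefer-Wolfowitz band around the analytic CDF."""
        rng = np.random.default_rng(79)
        n = 1_000
        values = rng.exponential(scale=2.0, size=n)
        F = ecdf(values)
        grid = np.linspace(0, 20, 500)
        eps = np.sqrt(np.log(2 / 0.01) / (2 * n))
        true_cdf = 1 - np.exp(-grid / 2.0)
        assert np.max(np.abs(F(grid) - true_cdf)) <= eps


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = [1.0, 2.0, 3.0]
        with pytest.warns(UserWarning):
            result = mann_whitney([5.0] * 3, [5.0] * 3)
        assert result.p_value == 1.0
        result = mann_whitney(x, x)
        assert result.p_value == pytest.approx(1.0)

    def test_worked_exact_example(self):
        result = mann_whitney([1, 2], [3, 4], alternative="two_sided")
        assert result.statistic == 0
        assert result.p_value == pytest.approx(1 / 3)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_matches_full_enumeration(self, alternative):
        """For all no-tie inputs with n1 + n2 <= 10, the p-value equals a
        from-scratch enumeration over rank assignments."""
        rng = np.random.default_rng(83)
        for _ in range(30):
            n1 = int(rng.integers(1, 9))
            n2 = int(rng.integers(1, 11 - n1))
            pooled = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.3)
            x, y = pooled[:n1], pooled[n1:]
            result = mann_whitney(x, y, alternative=alternative)
            # oracle: enumerate every split of the pooled values
            u_obs = sum((xi > yj) for xi in x for yj in y)
            us = []
            idx = range(n1 + n2)
            for combo in combinations(idx, n1):
                xs = pooled[list(combo)]
                ys = pooled[[i for i in idx if i not in combo]]
                us.append(sum((a > b) for a in xs for b in ys))
            us = np.asarray(us, dtype=float)
            if alternative == "greater":
                expected = np.mean(us >= u_obs)
            elif alternative == "less":
                expected = np.mean(us <= u_obs)
            else:
                expected = min(
                    1.0,
                    2 * min(np.mean(us >= u_obs), np.mean(us <= u_obs)),
                )
            assert result.statistic == pytest.approx(u_obs)
            assert result.p_value == pytest.approx(expected)

    def test_large_sample_agrees_with_scipy(self):
        rng = np.random.default_rng(89)
        x = rng.normal(0, 1, 80)
        y = rng.normal(0.5, 1, 90)
        result = mann_whitney(x, y, alternative="less")
        u_ref, p_ref = stats.mannwhitneyu(
            x, y, alternative="less", method="asymptotic"
        )
        assert result.statistic == pytest.approx(float(u_ref))
        assert result.p_value == pytest.approx(float(p_ref))

    def test_detects_planted_shift(self):
        rng = np.random.default_rng(97)
        x = rng.normal(1.0, 1, 200)
        y = rng.normal(0.0, 1, 200)
        assert mann_whitney(x, y, "greater").p_value < 1e-6


class TestBoxplotSummary:
    def test_interpolated_quartiles(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2, 3, 4)
        assert (s.whisker_low, s.whisker_high) == (1, 5)
        assert s.n_outliers == 0

    def test_outlier_beyond_fence(self):
        s = boxplot_summary([1, 2, 3, 4, 100])
        assert s.whisker_high == 4
        assert s.n_outliers == 1

    def test_constant_data(self):
        s = boxplot_summary([7, 7, 7])
        assert s.q1 == s.median == s.q3 == 7
        assert s.whisker_low == s.whisker_high == 7

    def test_whiskers_within_tukey_fences(self):
        rng = np.random.default_rng(101)
        values = rng.standard_cauchy(500)
        s = boxplot_summary(values)
        iqr = s.q3 - s.q1
        assert s.whisker_low >= s.q1 - 1.5 * iqr
        assert s.whisker_high <= s.q3 + 1.5 * iqr
        assert s.q1 <= s.median <= s.q3
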