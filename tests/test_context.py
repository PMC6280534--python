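import numpy as np
import pandas as pd
import pytest

from dmrscan.context import (
    ELEMENT_CLASSES,
    associate_dmrs_to_genes,
    classify_elements,
    enrichment_test,
    metagene_profile,
    methylation_change_matrix,
    read_features_gff3,
    sample_random_regions,
)


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "kind", "id"])


def dmrs_frame(spans, direction="hypo"):
    return pd.DataFrame([
        {"chrom": c, "start": s, "end": e, "direction": direction}
        for c, s, e in spans])


class TestAssociation:
    def test_upstream_within_2kb_associated(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        dmrs = dmrs_frame([("chr1", 8400, 8600)])  # 1.4-1.6 kb upstream
        pairs = associate_dmrs_to_genes(dmrs, genes)
        assert list(pairs["gene_id"]) == ["g1"]
        assert pairs.loc[0, "distance"] < 0  # upstream is negative

    def test_beyond_2kb_not_associated(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        dmrs = dmrs_frame([("chr1", 7400, 7600)])  # 2.4 kb upstream
        assert associate_dmrs_to_genes(dmrs, genes).empty

    def test_minus_strand_upstream_is_right_of_gene(self):
        genes = genes_frame([("chr1", 10000, 12000, "-", "gene", "g1")])
        dmrs = dmrs_frame([("chr1", 13000, 13200)])  # 1 kb beyond right end
        pairs = associate_dmrs_to_genes(dmrs, genes)
        assert list(pairs["gene_id"]) == ["g1"]
        assert pairs.loc[0, "distance"] < 0  # upstream of the minus-strand TSS

    def test_strand_flip_oracle(self):
        # for every DMR placement, a genome-wide strand flip + coordinate
        # mirror must preserve the association outcome
        L = 30000
        genes_plus = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        genes_minus = genes_frame(
            [("chr1", L - 12000, L - 10000, "-", "gene", "g1")])
        rng = np.random.default_rng(0)
        for _ in range(100):
            s = int(rng.integers(0, L - 500))
            e = s + int(rng.integers(50, 500))
            a_plus = not associate_dmrs_to_genes(
                dmrs_frame([("chr1", s, e)]), genes_plus).empty
            a_minus = not associate_dmrs_to_genes(
                dmrs_frame([("chr1", L - e, L - s)]), genes_minus).empty
            assert a_plus == a_minus, (s, e)

    def test_overlap_distance_zero(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        pairs = associate_dmrs_to_genes(dmrs_frame([("chr1", 11000, 11100)]), genes)
        assert pairs.loc[0, "distance"] == 0


class TestClassifyElements:
    SIZES = {"chr1": 50000}

    def test_midpoint_in_gene_body(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        obs, bg = classify_elements(dmrs_frame([("chr1", 10500, 11500)]),
                                    genes, self.SIZES)
        assert obs["gene_body"] == 1.0

    def test_priority_tss_over_tes(self):
        # region upstream of g2 (+) and downstream of g1 (+): tss_up wins
        genes = genes_frame([
            ("chr1", 10000, 12000, "+", "gene", "g1"),
            ("chr1", 13000, 15000, "+", "gene", "g2"),
        ])
        obs, _ = classify_elements(dmrs_frame([("chr1", 12400, 12600)]),
                                   genes, self.SIZES)
        assert obs["tss_up_2kb"] == 1.0

    def test_fractions_sum_to_one(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        dmrs = dmrs_frame([("chr1", 100, 200), ("chr1", 10500, 10600),
                           ("chr1", 9000, 9100), ("chr1", 12500, 12600)])
        obs, bg = classify_elements(dmrs, genes, self.SIZES)
        assert obs.sum() == pytest.approx(1.0)
        assert bg.sum() == pytest.approx(1.0)

    def test_background_fractions_exact(self):
        genes = genes_frame([("chr1", 10000, 12000, "+", "gene", "g1")])
        _, bg = classify_elements(dmrs_frame([("chr1", 0, 10)]), genes, self.SIZES)
        assert bg["gene_body"] == pytest.approx(2000 / 50000)
        assert bg["tss_up_2kb"] == pytest.approx(2000 / 50000)
        assert bg["tes_down_2kb"] == pytest.approx(2000 / 50000)
        assert bg["intergenic"] == pytest.approx(44000 / 50000)


class TestRandomRegions:
    def test_length_multiset_preserved(self):
        dmrs = dmrs_frame([("chr1", 0, 300), ("chr1", 5000, 5800), ("chr1", 9000, 9100)])
        draws = sample_random_regions(dmrs, {"chr1": 50000, "chr2": 30000}, seed=3)
        lengths = sorted(draws[0]["end"] - draws[0]["start"])
        assert lengths == [100, 300, 800]

    def test_seed_reproducibility(self):
        dmrs = dmrs_frame([("chr1", 0, 300)] * 5)
        d1 = sample_random_regions(dmrs, {"chr1": 50000}, seed=9, n_draws=2)
        d2 = sample_random_regions(dmrs, {"chr1": 50000}, seed=9, n_draws=2)
        for a, b in zip(d1, d2):
            pd.testing.assert_frame_equal(a, b)

    def test_oversized_region_raises(self):
        dmrs = dmrs_frame([("chr1", 0, 99999)])
        with pytest.raises(ValueError):
            sample_random_regions(dmrs, {"chr1": 5000}, seed=0)

    def test_hit_rate_matches_analytic_fraction(self):
        # fraction of draws whose midpoint lands in a fixed 10% zone
        dmrs = dmrs_frame([("chr1", 0, 10)] * 400)
        draws = sample_random_regions(dmrs, {"chr1": 100000}, seed=5, n_draws=5)
        rates = []
        for d in draws:
            mid = (d["start"] + d["end"]) // 2
            rates.append(((mid >= 20000) & (mid < 30000)).mean())
        se = np.sqrt(0.1 * 0.9 / (400 * 5))
        assert abs(np.mean(rates) - 0.1) < 3 * se + 1e-9


class TestEnrichment:
    def test_cross_product_odds_ratio(self):
        obs = np.array([True] * 67 + [False] * 33)
        rnd = np.array([True] * 17 + [False] * 83)
        odds, p = enrichment_test(obs, rnd)
        assert odds == pytest.approx((67 * 83) / (33 * 17), rel=1e-12)
        assert p < 1e-10

    def test_identical_composition_null(self):
        obs = np.array([True] * 20 + [False] * 80)
        odds, p = enrichment_test(obs, obs)
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_p_matches_fisher_oracle(self):
        from test_stats import oracle_fisher

        obs = np.array([True] * 12 + [False] * 8)
        rnd = np.array([True] * 3 + [False] * 17)
        _, p = enrichment_test(obs, rnd)
        assert p == pytest.approx(oracle_fisher(12, 8, 3, 17), abs=1e-12)

    def test_degenerate_margin(self):
        obs = np.array([True, True])
        rnd = np.array([True, True])
        odds, p = enrichment_test(obs, rnd)
        assert np.isnan(odds)
        assert p == 1.0


def uniform_signal(length=30000, level=0.5, chrom="chr1"):
    pos = np.arange(0, length, 10)
    return pd.DataFrame({"chrom": chrom, "pos": pos, "value": level, "weight": 1.0})


class TestMetagene:
    GENES = genes_frame([
        ("chr1", 10000, 14000, "+", "gene", "g1"),
        ("chr1", 20000, 24000, "-", "gene", "g2"),
    ])

    def test_uniform_signal_flat_profile(self):
        prof = metagene_profile(uniform_signal(), self.GENES)
        vals = prof["value"].to_numpy()
        assert np.nanmax(vals) - np.nanmin(vals) < 1e-12
        assert np.allclose(vals[~np.isnan(vals)], 0.5)

    def test_minus_strand_tss_peak_appears_left(self):
        # signal only near the minus-strand gene's TSS (its right end)
        sig = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(23800, 24000),
            "value": 1.0, "weight": 1.0})
        prof = metagene_profile(sig, self.GENES[self.GENES["id"] == "g2"])
        filled = prof.dropna(subset=["value"])
        peak_bin = filled.loc[filled["value"].idxmax()]
        # TSS-proximal body bins are at the left edge of the body zone
        body = prof[prof["zone"] == "body"]
        assert peak_bin["bin"] <= body["bin"].iloc[1]

    def test_promoter_density_peaks_upstream(self):
        dmrs = dmrs_frame([("chr1", 9000, 9400), ("chr1", 24500, 24900)])
        prof = metagene_profile(dmrs, self.GENES, mode="density")
        filled = prof.dropna(subset=["value"])
        best = filled.loc[filled["value"].idxmax()]
        assert best["zone"] == "upstream"

    def test_short_feature_no_crash(self):
        tiny = genes_frame([("chr1", 10000, 10008, "+", "gene", "t1")])
        prof = metagene_profile(uniform_signal(), tiny, body_bins=20)
        assert len(prof) == 20 + 2 * 20


class TestChangeMatrix:
    GENES = genes_frame([
        ("chr1", 10000, 14000, "+", "gene", "g1"),
        ("chr1", 20000, 24000, "-", "gene", "g2"),
    ])

    def test_identical_conditions_zero(self):
        sig = uniform_signal()
        mat = methylation_change_matrix(self.GENES, sig, sig)
        vals = mat.drop(columns="gene_id").to_numpy()
        assert np.nanmax(np.abs(vals)) == 0.0

    def test_row_count_equals_genes(self):
        sig = uniform_signal()
        mat = methylation_change_matrix(self.GENES, sig, sig)
        assert len(mat) == 2

    def test_promoter_drop_concentrates_upstream(self):
        sig_a = uniform_signal(level=0.8)
        sig_b = uniform_signal(level=0.8)
        drop = (sig_b["chrom"] == "chr1") & (sig_b["pos"] >= 8000) & (sig_b["pos"] < 10000)
        sig_b = sig_b.copy()
        sig_b.loc[drop, "value"] = 0.2
        mat = methylation_change_matrix(
            self.GENES[self.GENES["id"] == "g1"], sig_a, sig_b)
        row = mat.drop(columns="gene_id").to_numpy()[0]
        up = row[:20]
        body = row[20:40]
        assert np.nanmin(up) == pytest.approx(-0.6)
        assert np.nanmax(np.abs(body)) == 0.0


class TestGff3Reader:
    def test_round_trip_with_simulator(self, small_study, tmp_path):
        from dmrscan.simulate import _write_gff3

        path = tmp_path / "ann.gff3"
        _write_gff3(small_study.genes, small_study.tes, path)
        feats = read_features_gff3(path)
        genes = feats[feats["kind"] == "gene"].sort_values("id").reset_index(drop=True)
        orig = small_study.genes.sort_values("id").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            genes[["chrom", "start", "end", "strand", "id"]],
            orig[["chrom", "start", "end", "strand", "id"]],
            check_dtype=False)
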