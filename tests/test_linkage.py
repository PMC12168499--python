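import numpy as np
import pandas as pd
import pytest
from scipy import stats

from perturbscope.errors import ValidationError
from perturbscope.linkage import (
    annotate_pairs_for_tads,
    chip_proximity_profile,
    crispri_overlap_or,
    enumerate_pairs,
    flag_pair_sensitivity,
    pair_correlation,
    tad_cooccupancy_odds,
)


def _peaks(centers, width=500, chrom="chrS"):
    centers = np.asarray(centers)
    return pd.DataFrame({
        "chrom": chrom,
        "start": centers - width // 2,
        "end": centers + width - width // 2,
        "name": [f"p{i}" for i in range(len(centers))],
    })


def _genes(tss, strands=None, chrom="chrS"):
    tss = np.asarray(tss)
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(len(tss))],
        "chrom": chrom,
        "tss": tss,
        "strand": strands if strands is not None else ["+"] * len(tss),
    })


class TestEnumeratePairs:
    def test_upstream_pair_included(self):
        peaks = pd.DataFrame({"chrom": ["chrS"], "start": [59_750], "end": [60_250],
                              "name": ["p0"]})
        genes = _genes([100_000])
        out = enumerate_pairs(peaks, genes, max_distance=50_000)
        assert len(out) == 1
        assert out.loc[0, "distance"] == -40_000

    def test_far_peak_excluded(self):
        out = enumerate_pairs(_peaks([160_000]), _genes([100_000]), 50_000)
        assert len(out) == 0

    def test_window_zero_only_exact(self):
        out = enumerate_pairs(_peaks([100_000, 100_700]), _genes([100_000]), 0)
        assert list(out["acr"]) == ["p0"]

    def test_minus_strand_sign_flips(self):
        peaks = _peaks([60_000])
        out_plus = enumerate_pairs(peaks, _genes([100_000], ["+"]), 50_000)
        out_minus = enumerate_pairs(peaks, _genes([100_000], ["-"]), 50_000)
        assert out_plus.loc[0, "distance"] == -out_minus.loc[0, "distance"]

    def test_matches_brute_force(self, rng):
        centers = np.sort(rng.choice(np.arange(1000, 2_000_000, 700), 300, replace=False))
        peaks = _peaks(centers)
        genes = _genes(rng.integers(0, 2_000_000, size=60),
                       rng.choice(["+", "-"], size=60))
        got = enumerate_pairs(peaks, genes, 50_000)
        got_set = set(zip(got["acr"], got["gene"], got["distance"]))
        expected = set()
        for _, pk in peaks.iterrows():
            c = (pk["start"] + pk["end"]) // 2
            for _, gn in genes.iterrows():
                rel = int(c - gn["tss"])
                if abs(rel) <= 50_000:
                    if gn["strand"] == "-":
                        rel = -rel
                    expected.add((pk["name"], gn["gene_id"], rel))
        assert got_set == expected

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_pairs(_peaks([]), _genes([100]), 50_000)


class TestPairCorrelation:
    def test_identical_vectors_rho_one(self, small_sim):
        rna, atac, guides, genes, peaks, _ = small_sim
        # pick a pair and force accessibility == expression in NT cells: use
        # a synthetic pair table on matched features instead
        pairs = pd.DataFrame({"acr": [atac.features[0]], "gene": [rna.features[0]],
                              "distance": [0]})
        out = pair_correlation(rna, atac, guides, pairs)
        assert -1 <= out.loc[0, "rho"] <= 1

    def test_rank_oracle_small_n(self, rng):
        import scipy.sparse as sp
        from perturbscope.io import FeatureMatrix

        counts_r = rng.poisson(10, size=(10, 4))
        counts_a = rng.poisson(3, size=(10, 5))
        rna = FeatureMatrix("RNA", sp.csr_matrix(counts_r),
                            [f"b{i}" for i in range(10)], [f"g{i}" for i in range(4)])
        atac = FeatureMatrix("ATAC", sp.csr_matrix(counts_a),
                             [f"b{i}" for i in range(10)], [f"p{i}" for i in range(5)])
        guides = pd.DataFrame({"cell": rna.barcodes, "guide_id": "g",
                               "target": "NT", "target_class": "NT"})
        pairs = pd.DataFrame({"acr": ["p0", "p2"], "gene": ["g1", "g3"],
                              "distance": [0, 0]})
        out = pair_correlation(rna, atac, guides, pairs, min_nt_cells=10)
        from perturbscope.scoring import normalize
        Xr, Xa = normalize(rna), normalize(atac)
        for i, (a, g) in enumerate(zip(pairs["acr"], pairs["gene"])):
            ai = list(atac.features).index(a)
            gi = list(rna.features).index(g)
            oracle = stats.spearmanr(Xa[:, ai], Xr[:, gi]).statistic
            assert out.loc[i, "rho"] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_is_nan(self, rng):
        import scipy.sparse as sp
        from perturbscope.io import FeatureMatrix

        counts_r = rng.poisson(10, size=(25, 2))
        counts_a = np.zeros((25, 2), dtype=int)
        rna = FeatureMatrix("RNA", sp.csr_matrix(counts_r),
                            [f"b{i}" for i in range(25)], ["g0", "g1"])
        atac = FeatureMatrix("ATAC", sp.csr_matrix(counts_a),
                             [f"b{i}" for i in range(25)], ["p0", "p1"])
        guides = pd.DataFrame({"cell": rna.barcodes, "guide_id": "g",
                               "target": "NT", "target_class": "NT"})
        pairs = pd.DataFrame({"acr": ["p0"], "gene": ["g0"], "distance": [0]})
        out = pair_correlation(rna, atac, guides, pairs)
        assert np.isnan(out.loc[0, "rho"])

    def test_too_few_nt_cells(self, small_sim):
        rna, atac, guides, *_ = small_sim
        g2 = guides.copy()
        g2.loc[g2["target_class"] == "NT", "target_class"] = "SAFE"
        pairs = pd.DataFrame({"acr": [atac.features[0]], "gene": [rna.features[0]],
                              "distance": [0]})
        with pytest.raises(ValidationError, match="NT cells"):
            pair_correlation(rna, atac, g2, pairs)

    def test_sensitive_linked_pairs_more_correlated(self, small_sim, small_st):
        rna, atac, guides, genes, peaks, truth = small_sim
        pairs = enumerate_pairs(peaks, genes, 50_000)
        pairs = pair_correlation(rna, atac, guides, pairs)
        pairs = flag_pair_sensitivity(pairs, small_st)
        linked = {(p, g) for p, g, _ in truth.linked_pairs}
        is_linked = [tuple(x) in linked for x in zip(pairs["acr"], pairs["gene"])]
        pairs["linked"] = is_linked
        sens = pairs[pairs["pair_sensitive"]]
        nons = pairs[~pairs["pair_sensitive"]]
        assert sens["rho"].abs().mean() > nons["rho"].abs().mean()


class TestOddsRatio:
    def test_balanced_table(self):
        pairs = pd.DataFrame({
            "acr": [f"p{i}" for i in range(40)],
            "gene": [f"g{i}" for i in range(40)],
            "pair_sensitive": [True] * 20 + [False] * 20,
        })
        validated = {(f"p{i}", f"g{i}") for i in list(range(10)) + list(range(20, 30))}
        res = crispri_overlap_or(pairs, validated)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.table == (10, 10, 10, 10)

    def test_or16_matches_hypergeom_enumeration(self):
        # table (20,5,5,20): sample OR 16; p by full enumeration
        pairs = pd.DataFrame({
            "acr": [f"p{i}" for i in range(50)],
            "gene": [f"g{i}" for i in range(50)],
            "pair_sensitive": [True] * 25 + [False] * 25,
        })
        validated = {(f"p{i}", f"g{i}") for i in list(range(20)) + list(range(25, 30))}
        res = crispri_overlap_or(pairs, validated)
        assert res.odds_ratio == pytest.approx(16.0)
        # oracle: hypergeometric enumeration over all tables with the margins
        n, r, c = 50, 25, 25
        pmf = stats.hypergeom(n, r, c).pmf(np.arange(0, 26))
        p_obs = stats.hypergeom(n, r, c).pmf(20)
        oracle = pmf[pmf <= p_obs * (1 + 1e-9)].sum()
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_infinite_or(self):
        pairs = pd.DataFrame({
            "acr": [f"p{i}" for i in range(20)],
            "gene": [f"g{i}" for i in range(20)],
            "pair_sensitive": [True] * 10 + [False] * 10,
        })
        validated = {(f"p{i}", f"g{i}") for i in range(10)}
        res = crispri_overlap_or(pairs, validated)
        assert np.isinf(res.odds_ratio)
        assert res.degenerate
        assert np.isfinite(res.ci_low) and np.isfinite(res.ci_high)

    def test_empty_validated_set(self):
        pairs = pd.DataFrame({"acr": ["p"], "gene": ["g"], "pair_sensitive": [True]})
        with pytest.raises(ValidationError, match="empty"):
            crispri_overlap_or(pairs, set())


def _pair_table(rng, n=4000, tad_frac_sens=0.5, tad_frac_nons=0.5):
    sens = rng.uniform(size=n) < 0.25
    in_tad = np.where(sens, rng.uniform(size=n) < tad_frac_sens,
                      rng.uniform(size=n) < tad_frac_nons)
    return pd.DataFrame({
        "acr": [f"p{i}" for i in range(n)],
        "gene": [f"g{i}" for i in range(n)],
        "distance": rng.integers(-2_000_000, 2_000_000, size=n),
        "pair_sensitive": sens,
        "in_tad": in_tad,
        "acr_level": rng.normal(size=n),
        "gene_level": rng.normal(size=n),
    })


class TestTadOdds:
    BINS = [10_000, 100_000, 500_000, 2_000_000]

    def test_null_within_3sd(self, rng):
        pairs = _pair_table(rng)
        out = tad_cooccupancy_odds(pairs, self.BINS, n_resamples=100, seed=1)
        for _, row in out.iterrows():
            se = row["null_sd"] * np.sqrt(1 + 1 / 100)
            assert abs(row["odds_sensitive"] - row["null_mean"]) < 4 * max(se, 0.05)

    def test_planted_enrichment_detected(self, rng):
        pairs = _pair_table(rng, tad_frac_sens=0.85, tad_frac_nons=0.4)
        out = tad_cooccupancy_odds(pairs, self.BINS, n_resamples=100, seed=1)
        assert (out["odds_sensitive"] > out["null_mean"] + 3 * out["null_sd"]).all()

    def test_all_in_one_tad_degenerate(self, rng):
        pairs = _pair_table(rng)
        pairs["in_tad"] = True
        out = tad_cooccupancy_odds(pairs, self.BINS, n_resamples=10, seed=1)
        assert out["degenerate"].all()

    def test_seed_reproducible(self, rng):
        pairs = _pair_table(rng)
        a = tad_cooccupancy_odds(pairs, self.BINS, n_resamples=30, seed=7)
        b = tad_cooccupancy_odds(pairs, self.BINS, n_resamples=30, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_annotate_in_tad_strict(self):
        peaks = _peaks([5_000, 150_000])
        genes = _genes([6_000, 152_000])
        tads = pd.DataFrame({"chrom": "chrS", "start": [0, 100_000],
                             "end": [100_000, 200_000], "name": ["t0", "t1"]})
        pairs = pd.DataFrame({
            "acr": ["p0", "p0", "p1"], "gene": ["g0", "g1", "g1"],
            "distance": [0, 0, 0],
        })
        import scipy.sparse as sp
        from perturbscope.io import FeatureMatrix

        rna = FeatureMatrix("RNA", sp.csr_matrix(np.ones((5, 2), dtype=int)),
                            [f"b{i}" for i in range(5)], ["g0", "g1"])
        atac = FeatureMatrix("ATAC", sp.csr_matrix(np.ones((5, 2), dtype=int)),
                             [f"b{i}" for i in range(5)], ["p0", "p1"])
        out = annotate_pairs_for_tads(pairs, peaks, genes, tads, rna, atac)
        assert list(out["in_tad"]) == [True, False, True]


class TestChipProfile:
    def _setup(self, rng, n_acrs=20_000, p_mode="const"):
        chip_centers = np.arange(50_000, 50_000 * 201, 50_000)
        chip = _peaks(chip_centers)
        chip["name"] = [f"c{i}" for i in range(len(chip))]
        acr_centers = rng.integers(10_000, chip_centers[-1], size=n_acrs)
        peaks = _peaks(acr_centers)
        if p_mode == "const":
            p = np.full(n_acrs, 0.1)
        elif p_mode == "uniform":
            p = rng.uniform(size=n_acrs)
        st_ = pd.DataFrame({"feature": peaks["name"], "modality": "ATAC",
                            "tf": "TF01", "p": p})
        return st_, peaks, chip

    def test_constant_p_flat_profile(self, rng):
        st_, peaks, chip = self._setup(rng, p_mode="const")
        out = chip_proximity_profile(st_, peaks, chip, window_bp=10_000, n_bins=10)
        assert np.allclose(out["mean_neglog10_p"].dropna(), 1.0)

    def test_uniform_p_expectation(self, rng):
        st_, peaks, chip = self._setup(rng, n_acrs=100_000, p_mode="uniform")
        out = chip_proximity_profile(st_, peaks, chip, window_bp=20_000, n_bins=8)
        assert np.allclose(out["mean_neglog10_p"], 1 / np.log(10), rtol=0.05)

    def test_center_planted_effect_peaks_at_center(self, rng):
        st_, peaks, chip = self._setup(rng, n_acrs=50_000, p_mode="uniform")
        centers = (peaks["start"] + peaks["end"]).to_numpy() // 2
        near = np.abs(((centers - 50_000) % 50_000 + 25_000) % 50_000 - 25_000) < 2_000
        st_.loc[near, "p"] = 1e-6
        out = chip_proximity_profile(st_, peaks, chip, window_bp=10_000, n_bins=10)
        prof = out["mean_neglog10_p"].to_numpy()
        assert prof[4:6].mean() > prof[[0, -1]].mean() * 2

    def test_no_acr_in_window_error(self, rng):
        st_, peaks, _ = self._setup(rng, n_acrs=100, p_mode="const")
        far_chip = _peaks([90_000_000])
        with pytest.raises(ValidationError, match="no ACR within"):
            chip_proximity_profile(st_, peaks, far_chip, window_bp=1_000, n_bins=5)

    def test_zero_window_rejected(self, rng):
        st_, peaks, chip = self._setup(rng, n_acrs=100, p_mode="const")
        with pytest.raises(ValidationError, match="window_bp"):
            chip_proximity_profile(st_, peaks, chip, window_bp=0, n_bins=5)
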