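"""Synthetic panel generation, LD statistics, filtering, and serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pleiolink.genotypes import (
    MAIZE_LIKE,
    SOYBEAN_LIKE,
    GenotypeMatrix,
    LDProfile,
    filter_markers,
    generate_genotypes,
    ld_decay_curve,
    nested_subsample,
    pairwise_r2,
    read_panel,
    write_panel,
)

from conftest import make_panel


class TestGenerate:
    def test_deterministic_for_fixed_seed(self):
        a = generate_genotypes(50, 2, 40, MAIZE_LIKE, seed=9)
        b = generate_genotypes(50, 2, 40, MAIZE_LIKE, seed=9)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.marker_map.equals(b.marker_map)

    def test_full_inbreeding_gives_homozygous_lines(self):
        G = generate_genotypes(40, 2, 50, MAIZE_LIKE, inbreeding=1.0, seed=1)
        assert set(np.unique(G.dosages)) <= {0, 2}

    def test_outbred_panel_has_heterozygotes(self):
        G = generate_genotypes(80, 1, 60, MAIZE_LIKE, inbreeding=0.0, seed=1)
        assert (G.dosages == 1).any()

    def test_positions_strictly_increasing_within_chromosome(self):
        G = generate_genotypes(20, 3, 30, MAIZE_LIKE, seed=5)
        for _, sub in G.marker_map.groupby("chrom"):
            assert (np.diff(sub["pos"].to_numpy()) > 0).all()

    @pytest.mark.parametrize("bad", [dict(n_individuals=0), dict(markers_per_chromosome=0)])
    def test_zero_counts_rejected(self, bad):
        kwargs = dict(n_individuals=10, n_chromosomes=1, markers_per_chromosome=10,
                      profile=MAIZE_LIKE, seed=1)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_genotypes(**kwargs)

    def test_decay_calibration_at_target_distance(self):
        """Mean r2 near the preset's calibration distance stays in [0.05, 0.20]."""
        vals = []
        for seed in range(6):
            G = generate_genotypes(400, 2, 500, MAIZE_LIKE, seed=100 + seed)
            D = MAIZE_LIKE.target_decay_distance_bp
            tab = ld_decay_curve(G, np.array([0.8 * D, 1.2 * D]), max_pairs=40_000, seed=seed)
            vals.append(tab["mean_r2"].iloc[0])
        assert 0.05 <= np.mean(vals) <= 0.20

    def test_monotone_ld_decay(self):
        """Bin-mean r2 decreases with distance (negative Spearman over seeds)."""
        rhos = []
        bins = np.array([0, 5e3, 10e3, 20e3, 40e3, 80e3])
        for seed in range(20):
            G = generate_genotypes(200, 1, 300, MAIZE_LIKE, seed=200 + seed)
            tab = ld_decay_curve(G, bins, max_pairs=20_000, seed=seed).dropna()
            rhos.append(sps.spearmanr(tab["bin_mid"], tab["mean_r2"]).statistic)
        assert np.mean(rhos) < 0

    def test_species_profile_contrast_at_50kb(self):
        """Soybean-like LD at ~50 kb exceeds maize-like LD (long- vs short-range)."""
        diffs = []
        for seed in range(20):
            bins = np.array([30e3, 70e3])
            Gm = generate_genotypes(200, 1, 300, MAIZE_LIKE, seed=300 + seed)
            Gs = generate_genotypes(200, 1, 300, SOYBEAN_LIKE, seed=300 + seed)
            rm = ld_decay_curve(Gm, bins, max_pairs=20_000, seed=seed)["mean_r2"].iloc[0]
            rs = ld_decay_curve(Gs, bins, max_pairs=20_000, seed=seed)["mean_r2"].iloc[0]
            diffs.append(rs - rm)
        t = sps.ttest_1samp(diffs, 0.0, alternative="greater")
        assert t.pvalue < 0.01


class TestPairwiseR2:
    def test_self_correlation_is_one(self):
        x = np.array([0, 1, 2, 2, 0])
        assert pairwise_r2(x, x) == pytest.approx(1.0)

    def test_perfect_negative_correlation_is_one(self):
        assert pairwise_r2(np.array([0, 0, 2, 2]), np.array([2, 2, 0, 0])) == pytest.approx(1.0)

    def test_matches_squared_pearson_oracle(self):
        x = np.array([0, 1, 2, 2, 0])
        y = np.array([0, 0, 2, 1, 1])
        expected = sps.pearsonr(x, y).statistic ** 2
        assert pairwise_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_r2(np.array([1, 1, 1, 1]), np.array([0, 1, 2, 0]))


def prune_oracle(G, keep_idx, maf, prune_r2, window, step):
    """Literal windowed greedy pruning: per chromosome, slide the window,
    repeatedly remove the smaller-MAF member (tie: later index) of the
    highest-r2 pair at or above the threshold."""
    chroms = G.marker_map["chrom"].to_numpy()
    removed = set()
    for chrom in pd.unique(chroms):
        cidx = [j for j in keep_idx if chroms[j] == chrom]
        for start in range(0, len(cidx), step):
            while True:
                window_idx = [j for j in cidx[start : start + window] if j not in removed]
                best = None
                for a in range(len(window_idx)):
                    for b in range(a + 1, len(window_idx)):
                        ja, jb = window_idx[a], window_idx[b]
                        r2 = pairwise_r2(G.dosages[:, ja], G.dosages[:, jb])
                        if r2 >= prune_r2 and (best is None or r2 > best[0]):
                            best = (r2, ja, jb)
                if best is None:
                    break
                _, ja, jb = best
                if maf[ja] < maf[jb] or (maf[ja] == maf[jb] and ja > jb):
                    removed.add(ja)
                else:
                    removed.add(jb)
            if start + window >= len(cidx):
                break
    return [j for j in keep_idx if j not in removed]


class TestFilterMarkers:
    def test_exact_duplicate_removed(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        d = np.column_stack([base[:, 0], base]).astype(np.int8)  # col1 duplicates col0
        G = make_panel(d)
        out = filter_markers(G, min_mac=1, prune_r2=0.9)
        assert out.n_markers == 4
        assert "m1" not in set(out.marker_map["id"]) or "m0" not in set(out.marker_map["id"])

    def test_minor_allele_count_threshold(self):
        # 10 individuals; marker 0 has minor-allele count 4 (< 5), marker 1 has 6
        d = np.zeros((10, 2), dtype=np.int8)
        d[:2, 0] = 2  # MAC 4
        d[:3, 1] = 2  # MAC 6
        G = make_panel(d)
        out = filter_markers(G, min_mac=5, prune_r2=0.99)
        assert list(out.marker_map["id"]) == ["m1"]

    def test_matches_bruteforce_pruning_oracle(self):
        for seed in range(5):
            G = generate_genotypes(60, 1, 40, MAIZE_LIKE, seed=700 + seed)
            out = filter_markers(G, min_mac=1, prune_r2=0.5, prune_window=10, prune_step=3)
            maf = G.maf()
            keep = [j for j in range(G.n_markers) if maf[j] > 0]
            expected = prune_oracle(G, keep, maf, 0.5, 10, 3)
            got = [int(G.marker_map.index[G.marker_map["id"] == i][0]) for i in out.marker_map["id"]]
            assert got == expected

    def test_all_filtered_raises(self):
        d = np.zeros((10, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="all markers filtered"):
            filter_markers(make_panel(d), min_mac=1)


class TestNestedSubsample:
    def test_identity_when_full_size(self):
        G = generate_genotypes(20, 1, 10, MAIZE_LIKE, seed=1)
        (out,) = nested_subsample(G, [20], seed=0)
        assert np.array_equal(out.dosages, G.dosages)

    def test_containment_chain(self):
        G = generate_genotypes(60, 1, 10, MAIZE_LIKE, seed=1)
        chain = nested_subsample(G, [40, 20, 10], seed=3)
        sets = [set(p.individual_ids) for p in chain]
        assert sets[2] < sets[1] < sets[0]
        assert [len(s) for s in sets] == [40, 20, 10]

    def test_small_subset_verified_exhaustively(self):
        G = generate_genotypes(12, 1, 10, MAIZE_LIKE, seed=1)
        big, small = nested_subsample(G, [10, 5], seed=9)
        assert set(small.individual_ids) <= set(big.individual_ids)
        assert small.marker_map.equals(G.marker_map)

    def test_invalid_sizes_rejected(self):
        G = generate_genotypes(10, 1, 10, MAIZE_LIKE, seed=1)
        with pytest.raises(ValueError):
            nested_subsample(G, [5, 5], seed=0)
        with pytest.raises(ValueError):
            nested_subsample(G, [11], seed=0)


class TestDecayCurve:
    def test_exhaustive_four_marker_check(self):
        d = np.array(
            [[0, 0, 1, 2], [1, 0, 2, 2], [2, 1, 0, 0], [0, 2, 1, 0], [2, 2, 0, 1], [1, 0, 2, 1]],
            dtype=np.int8,
        )
        G = make_panel(d, pos=[100, 200, 400, 800])
        tab = ld_decay_curve(G, np.array([0, 350, 1000]), max_pairs=200_000, seed=0)
        # oracle: enumerate all 6 pairs directly
        import itertools

        pairs = {(i, j): pairwise_r2(d[:, i], d[:, j]) for i, j in itertools.combinations(range(4), 2)}
        pos = [100, 200, 400, 800]
        for lo, hi, row in zip([0, 350], [350, 1000], tab.itertuples()):
            vals = [r2 for (i, j), r2 in pairs.items() if lo <= abs(pos[i] - pos[j]) < hi]
            assert row.mean_r2 == pytest.approx(np.mean(vals), abs=1e-9)

    def test_empty_bin_reported_with_zero_pairs(self):
        G = generate_genotypes(30, 1, 20, MAIZE_LIKE, seed=2)
        tab = ld_decay_curve(G, np.array([0, 1, 2, 1e9]), max_pairs=1000, seed=0)
        assert (tab.loc[tab["n_pairs"] == 0, "mean_r2"].isna()).all()

    def test_position_shuffling_flattens_curve(self):
        """Destroying the physical map removes distance-dependence of r2."""
        G = generate_genotypes(200, 1, 200, MAIZE_LIKE, seed=8)
        rng = np.random.default_rng(0)
        perm = rng.permutation(G.n_markers)
        shuffled = GenotypeMatrix(
            G.dosages[:, perm], G.marker_map.drop(columns="pos").assign(pos=G.marker_map["pos"].values), G.individual_ids
        )
        bins = np.array([0, 20e3, 80e3, 300e3])
        tab = ld_decay_curve(shuffled, bins, max_pairs=40_000, seed=1).dropna()
        overall = np.average(tab["mean_r2"], weights=tab["n_pairs"])
        assert np.all(np.abs(tab["mean_r2"] - overall) < 0.03)


class TestSerialization:
    def test_plink_round_trip(self, tmp_path):
        G = generate_genotypes(13, 2, 15, MAIZE_LIKE, seed=4)
        prefix = str(tmp_path / "panel")
        write_panel(G, prefix)
        back = read_panel(prefix)
        assert np.array_equal(G.dosages, back.dosages)
        assert list(G.individual_ids) == list(back.individual_ids)
        assert list(G.marker_map["pos"]) == list(back.marker_map["pos"])
        assert list(G.marker_map["chrom"]) == list(back.marker_map["chrom"])

    def test_vcf_round_trip(self, tmp_path):
        G = generate_genotypes(7, 2, 10, MAIZE_LIKE, inbreeding=0.5, seed=4)
        path = str(tmp_path / "panel.vcf")
        write_panel(G, path)
        back = read_panel(path)
        assert np.array_equal(G.dosages, back.dosages)
        assert list(G.marker_map["id"]) == list(back.marker_map["id"])

    def test_handwritten_vcf_dosages(self, tmp_path):
        vcf = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\tm1\tA\tT\t.\t.\t.\tGT\t0/0\t1/1
1\t200\tm2\tG\tC\t.\t.\t.\tGT\t0/1\t1/1
1\t300\tm3\tA\tC\t.\t.\t.\tGT\t1/1\t./.
"""
        path = tmp_path / "hand.vcf"
        path.write_text(vcf)
        G = read_panel(str(path))
        expected = np.array([[0, 1, 2], [2, 2, -1]], dtype=np.int8)
        assert np.array_equal(G.dosages, expected)
        assert list(G.marker_map["a1"]) == ["T", "C", "C"]  # ALT is the counted allele

    def test_non_biallelic_vcf_rejected(self, tmp_path):
        vcf = """##fileformat=VCFv4.2
##contig=<ID=1,length=1000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
1\t100\tm1\tA\tT,C\t.\t.\t.\tGT\t0/1
"""
        path = tmp_path / "bad.vcf"
        path.write_text(vcf)
        with pytest.raises(ValueError, match="biallelic"):
            read_panel(str(path))
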