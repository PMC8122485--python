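"""SNP filters, LD, tagging, imputation and haplotype-marker construction."""

import numpy as np
import pytest

from namhap import markers as mk
from namhap import simcore as sc
from tests.conftest import toy_genotype_matrix, toy_marker_set

M = mk.MISSING


def _matrix_with_missing(n_lines, patterns, marker_class):
    """patterns: per SNP, number of missing lines."""
    m = len(patterns)
    a1 = np.zeros((n_lines, m), dtype=np.int16)
    a2 = np.zeros((n_lines, m), dtype=np.int16)
    a1[: n_lines // 2] = 1
    a2[: n_lines // 2] = 1
    for j, k in enumerate(patterns):
        a1[:k, j] = M
        a2[:k, j] = M
    return toy_genotype_matrix(a1, a2, marker_class=marker_class)


class TestMissingnessFilter:
    def test_strict_greater_than_boundaries(self):
        # 100 lines: 40% missing codominant kept, 41% removed;
        # 20% dominant kept, 21% removed
        gm = _matrix_with_missing(
            100, [40, 41, 20, 21], ["codominant", "codominant", "dominant", "dominant"]
        )
        out, report = mk.filter_snps_by_missing(gm)
        assert list(out.snps["snp_id"]) == ["S1", "S3"]
        assert report["removed_codominant"] == 1
        assert report["removed_dominant"] == 1

    def test_fully_observed_matrix_unchanged(self):
        gm = _matrix_with_missing(10, [0, 0, 0], ["codominant"] * 3)
        out, _ = mk.filter_snps_by_missing(gm)
        assert np.array_equal(out.a1, gm.a1)
        assert out.n_snps == 3

    def test_constructed_survivor_count(self):
        # 10 SNPs: 3 codominant above 40%, 2 dominant above 20% -> 5 survive
        patterns = [50, 45, 41, 10, 0, 30, 25, 10, 0, 5]
        classes = ["codominant"] * 5 + ["dominant"] * 5
        gm = _matrix_with_missing(100, patterns, classes)
        out, _ = mk.filter_snps_by_missing(gm)
        assert out.n_snps == 5

    def test_idempotent(self):
        gm = _matrix_with_missing(100, [50, 10, 30], ["codominant", "codominant", "dominant"])
        once, _ = mk.filter_snps_by_missing(gm)
        twice, _ = mk.filter_snps_by_missing(once)
        assert list(once.snps["snp_id"]) == list(twice.snps["snp_id"])
        assert np.array_equal(once.a1, twice.a1)


class TestLdR2:
    def test_identical_vectors_r2_one(self):
        col = np.array([0, 0, 1, 1, 0, 1], dtype=np.int16)
        gm = toy_genotype_matrix(np.stack([col, col], 1), np.stack([col, col], 1))
        assert mk.ld_r2(gm, "S1", "S2") == pytest.approx(1.0)

    def test_hand_worked_vectors_match_direct_formula(self):
        # 6 lines with one heterozygote; oracle computed with the plain
        # Pearson formula on the 0/0.5/1 codings
        a1 = np.array([[0, 0], [0, 0], [1, 0], [1, 1], [0, 1], [1, 1]], dtype=np.int16)
        a2 = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0, 1], [1, 1]], dtype=np.int16)
        gm = toy_genotype_matrix(a1, a2)
        x = (a1[:, 0] + a2[:, 0]) / 2
        y = (a1[:, 1] + a2[:, 1]) / 2
        xc, yc = x - x.mean(), y - y.mean()
        expected = float((xc @ yc) ** 2 / ((xc @ xc) * (yc @ yc)))
        assert mk.ld_r2(gm, "S1", "S2") == pytest.approx(expected, abs=1e-12)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(0)
        a = (rng.random((10_000, 2)) < 0.5).astype(np.int16)
        gm = toy_genotype_matrix(a, a)
        assert mk.ld_r2(gm, "S1", "S2") < 0.01

    def test_zero_variance_is_nan(self):
        a1 = np.array([[0, 0], [0, 1], [0, 0]], dtype=np.int16)
        gm = toy_genotype_matrix(a1, a1)
        assert np.isnan(mk.ld_r2(gm, "S1", "S2"))


def _ld_block_matrix(rng, n=200, m=12, block=(4, 5, 6)):
    """Independent SNPs except a planted perfect-LD block."""
    a = (rng.random((n, m)) < 0.5).astype(np.int16)
    for j in block[1:]:
        a[:, j] = a[:, block[0]]
    return toy_genotype_matrix(a, a.copy())


class TestTagSnps:
    def test_complete_ld_within_window_groups(self):
        col = np.array([0, 1, 0, 1, 1, 0] * 5, dtype=np.int16)
        gm = toy_genotype_matrix(np.stack([col, col], 1), np.stack([col, col], 1))
        # positions 1000 and 2000 bp apart -> within any kb-scale window
        groups = mk.tag_snps(gm, window_kb=5.0)
        assert len(groups) == 1
        assert set(groups[0].members) == {"S1", "S2"}

    def test_window_excludes_distant_perfect_ld(self):
        col = np.array([0, 1, 0, 1, 1, 0] * 5, dtype=np.int16)
        gm = toy_genotype_matrix(np.stack([col, col], 1), np.stack([col, col], 1))
        gm.snps.loc[1, "pos_bp"] = 20_000_000 + 1000  # 20,000 kb away
        groups = mk.tag_snps(gm, window_kb=10_000.0)
        assert len(groups) == 2
        assert all(len(g.members) == 1 for g in groups)

    def test_planted_block_recovered_exactly(self):
        rng = np.random.default_rng(5)
        gm = _ld_block_matrix(rng)
        groups = mk.tag_snps(gm, window_kb=10_000.0)
        block = {"S5", "S6", "S7"}
        grouped = [set(g.members) for g in groups if len(g.members) > 1]
        # oracle: exhaustive pairwise r2 scan
        dos = gm.dosage()
        r2 = np.corrcoef(dos.T) ** 2
        pairs = {
            frozenset((i, j))
            for i in range(12)
            for j in range(i + 1, 12)
            if r2[i, j] >= 0.7
        }
        expected_pairs = {frozenset((4, 5)), frozenset((4, 6)), frozenset((5, 6))}
        assert pairs == expected_pairs
        assert grouped == [block]

    def test_target_of_merged_group_names_leftmost(self):
        rng = np.random.default_rng(5)
        gm = _ld_block_matrix(rng)
        groups = mk.tag_snps(gm, window_kb=10_000.0)
        blk = [g for g in groups if len(g.members) > 1][0]
        assert blk.target == "S5"
        assert blk.pos_bp == 5000


class TestBuildHaplotypeMarkers:
    def test_singleton_biallelic_group_mirrors_snp(self):
        col = np.array([0, 0, 1, 1, 0], dtype=np.int16)
        gm = toy_genotype_matrix(col[:, None], col[:, None])
        groups = [mk.TagGroup("S1", ["S1"], "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        assert hms.n_markers == 1
        assert hms.markers[0].n_alleles == 2
        # allele index 1 = first observed haplotype (allele 0), 2 = allele 1
        assert list(hms.h1[:, 0]) == [1, 1, 2, 2, 1]

    def test_three_snp_group_three_haplotypes(self):
        # haplotypes AAB, ABB, BBB with A=0, B=1 (homozygous lines)
        haps = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1], [0, 0, 1]], dtype=np.int16)
        gm = toy_genotype_matrix(haps, haps.copy())
        groups = [mk.TagGroup("S1", ["S1", "S2", "S3"], "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        assert hms.markers[0].n_alleles == 3
        assert list(hms.h1[:, 0]) == [1, 2, 3, 1]

    def test_single_het_member_is_callable_multiple_het_missing(self):
        a1 = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0]], dtype=np.int16)
        a2 = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=np.int16)
        gm = toy_genotype_matrix(a1, a2)
        groups = [mk.TagGroup("S1", ["S1", "S2", "S3"], "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        assert hms.h1[0, 0] != M  # homozygous line called
        assert hms.h1[1, 0] != M and hms.h1[1, 0] != hms.h2[1, 0]  # 1 het: het call
        assert hms.h1[2, 0] == M  # 2 het members: unphasable

    def test_allele_count_matches_enumeration_on_simulated_nam(self, nam_world):
        gm = nam_world["matrix"]
        sl = nam_world["gmap"].chrom_slice("chr1")
        members = list(gm.snps["snp_id"][sl][:5])
        groups = [mk.TagGroup(members[0], members, "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        # oracle: direct enumeration of distinct homozygous haplotype strings
        cols = [nam_world["gmap"].locus_index(s) for s in members]
        strings = set()
        for i in range(gm.n_lines):
            h = gm.a1[i, cols]
            if (h == gm.a2[i, cols]).all():
                strings.add(tuple(h))
        # het-callable lines can add at most a few extra haplotypes
        assert hms.markers[0].n_alleles >= len(strings)
        # bounded by distinct founder haplotypes + observed recombinants
        assert hms.markers[0].n_alleles <= 2 ** len(members)

    def test_multiallelic_richness_with_many_founders(self):
        gmap = sc.default_genetic_map(1, 100.0, 30)
        rng = np.random.default_rng(42)
        panel = sc.simulate_founders(gmap, 10, rng)
        fams = [sc.FamilySpec(f"F{i}", panel.reference[i % 2], panel.exotic[i], 15) for i in range(10)]
        pop = sc.simulate_nam(sc.NAMDesign(fams), panel, gmap, None, rng)
        gm = sc.genotype_population(pop, gmap, 0.0, rng, include_parents=True)
        members = list(gm.snps["snp_id"][:6])
        groups = [mk.TagGroup(members[0], members, "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        n_founder_haps = len(
            {tuple(panel.alleles[f, :6]) for f in range(len(panel.names))}
        )
        assert hms.markers[0].n_alleles >= 5
        # parental haplotypes plus within-block recombinants bound the count
        assert hms.markers[0].n_alleles <= 2 ** 6

    def test_allele_dictionary_round_trips(self, nam_world):
        gm = nam_world["matrix"]
        groups = [mk.TagGroup("Schr1_1", ["Schr1_1", "Schr1_2"], "chr1", 1000)]
        hms = mk.build_haplotype_markers(gm, groups)
        m = hms.markers[0]
        for h, i in m.alleles.items():
            assert m.haplotype_of(i) == h

    def test_overlapping_groups_rejected(self):
        col = np.array([0, 1], dtype=np.int16)
        gm = toy_genotype_matrix(np.stack([col, col], 1), np.stack([col, col], 1))
        groups = [
            mk.TagGroup("S1", ["S1", "S2"], "chr1", 1000),
            mk.TagGroup("S2", ["S2"], "chr1", 2000),
        ]
        with pytest.raises(ValueError, match="disjoint"):
            mk.build_haplotype_markers(gm, groups)


class TestLdKnnImpute:
    def test_no_missing_identity(self):
        rng = np.random.default_rng(1)
        a = (rng.random((30, 8)) < 0.5).astype(np.int16)
        gm = toy_genotype_matrix(a, a.copy())
        out = mk.ld_knn_impute(gm)
        assert np.array_equal(out.a1, gm.a1)

    def test_masked_call_in_perfect_ld_block_recovered(self):
        rng = np.random.default_rng(2)
        gm = _ld_block_matrix(rng)
        truth = int(gm.a1[3, 5])
        gm.a1[3, 5] = M
        gm.a2[3, 5] = M
        out = mk.ld_knn_impute(gm, k=5, l=3)
        assert int(out.a1[3, 5]) == truth
        assert int(out.a2[3, 5]) == truth

    def test_accuracy_beats_random_allele_baseline(self, nam_world):
        rng = np.random.default_rng(3)
        gm = nam_world["matrix"].subset(
            lines=(nam_world["matrix"].line_table["role"] == "ril").to_numpy()
        )
        mask = rng.random(gm.a1.shape) < 0.05
        truth1, truth2 = gm.a1.copy(), gm.a2.copy()
        gm.a1[mask] = M
        gm.a2[mask] = M
        out = mk.ld_knn_impute(gm, k=5, l=10)
        imputed = mask & (out.a1 != M)
        acc = np.mean(
            (out.a1[imputed] == truth1[imputed]) & (out.a2[imputed] == truth2[imputed])
        )
        # baseline: drawing a genotype from the per-SNP call frequencies
        base = []
        for j in range(gm.n_snps):
            rows = mask[:, j]
            if not rows.any():
                continue
            called = truth1[:, j] != M
            pairs = list(zip(truth1[called, j], truth2[called, j]))
            freq = {}
            for p in pairs:
                freq[p] = freq.get(p, 0) + 1
            probs = np.array(list(freq.values())) / len(pairs)
            base.append(float(np.sum(probs**2)) * rows.sum())
        baseline = sum(base) / mask.sum()
        assert acc > baseline

    def test_all_missing_snp_left_missing(self):
        a = np.array([[0, 0], [1, 0], [0, 1]], dtype=np.int16)
        gm = toy_genotype_matrix(a, a.copy())
        gm.a1[:, 0] = M
        gm.a2[:, 0] = M
        out = mk.ld_knn_impute(gm)
        assert (out.a1[:, 0] == M).all()


class TestMarkerLineFilter:
    def test_call_rate_boundary(self):
        # 10 lines: marker with 7 called kept (70%), 6 called dropped
        h = np.ones((10, 2), dtype=np.int16)
        h[:3, 0] = M
        h[:4, 1] = M
        hms = toy_marker_set(h, h.copy())
        out, report = mk.filter_haplotype_markers_and_lines(hms)
        assert out.n_markers == 1
        assert report["markers_removed_call_rate"] == 1

    def test_clean_set_identity(self):
        h = np.tile(np.array([1, 2], dtype=np.int16), (6, 1))
        hms = toy_marker_set(h, h.copy())
        out, report = mk.filter_haplotype_markers_and_lines(hms)
        assert out.n_markers == 2 and out.n_lines == 6
        assert report["lines_removed_call_rate"] == 0

    def test_planted_violations_exact_counts(self):
        # 20 lines x 20 markers; plant 2 low-call-rate markers, 1 high-het
        # marker, 2 low-call-rate lines -> 17 markers, 18 lines survive
        rng = np.random.default_rng(9)
        h1 = rng.integers(1, 3, size=(20, 20)).astype(np.int16)
        h2 = h1.copy()
        h1[:8, 0] = M
        h2[:8, 0] = M
        h1[:10, 1] = M
        h2[:10, 1] = M
        h2[:2, 2] = h1[:2, 2] % 2 + 1  # 2/20 = 10% het > 6%
        h1[0, 3:16] = M  # line 0: called at 7 of 17 surviving markers (<50%)
        h2[0, 3:16] = M
        h1[1, 3:15] = M
        h2[1, 3:15] = M
        hms = toy_marker_set(h1, h2)
        out, report = mk.filter_haplotype_markers_and_lines(hms)
        assert out.n_markers == 17
        assert out.n_lines == 18
        assert report["markers_removed_call_rate"] == 2
        assert report["markers_removed_het"] == 1
        assert report["lines_removed_call_rate"] == 2

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        h1 = rng.integers(1, 4, size=(15, 10)).astype(np.int16)
        h1[rng.random(h1.shape) < 0.2] = M
        h2 = h1.copy()
        hms = toy_marker_set(h1, h2)
        once, _ = mk.filter_haplotype_markers_and_lines(hms)
        twice, _ = mk.filter_haplotype_markers_and_lines(once)
        assert np.array_equal(once.h1, twice.h1)
        assert once.marker_ids == twice.marker_ids

    def test_all_removed_raises(self):
        h = np.full((4, 2), M, dtype=np.int16)
        hms = toy_marker_set(h, h.copy(), n_alleles=[2, 2])
        with pytest.raises(ValueError):
            mk.filter_haplotype_markers_and_lines(hms)
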