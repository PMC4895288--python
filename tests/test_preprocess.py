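"""SEG parsing, blocking, concatenation, normalization, and PCA."""

import numpy as np
import pandas as pd
import pytest

from medoidshift.preprocess import (
    build_blocks,
    concatenate_chromosomes,
    normalize_unit_range,
    pca_top,
    read_seg,
    write_seg,
)

# hand computation for the packaged toy fixture: chromosome 1 boundaries at
# 0/500/1000/1500/2000 (0-based half-open) and chromosome 2 at 100/300/600/900
TOY_CHR1 = np.array([
    [0.5, 0.5, -0.3, -0.3],   # S1: [0,1000)=0.5, [1000,2000)=-0.3
    [1.2, 1.2, 1.2, 0.0],     # S2: [0,1500)=1.2
    [0.0, 0.8, 0.8, 0.8],     # S3: [500,2000)=0.8
    [0.0, 0.0, 0.0, 0.0],     # S4: no chr1 calls
])
TOY_CHR2 = np.array([
    [-1.0, -1.0, 0.0],        # S1: [100,600)=-1.0
    [0.0, 0.0, 0.0],
    [0.0, 0.0, 0.0],
    [0.0, 0.4, 0.4],          # S4: [300,900)=0.4
])


class TestReadSeg:
    def test_toy_file_parses_and_drops_chrx(self, toy_seg):
        calls = read_seg(toy_seg)
        assert len(calls) == 6  # 7 rows minus the chrX one
        assert set(calls["chromosome"]) == {1, 2}
        assert calls["log2_ratio"].dtype == float

    def test_three_line_file(self, tmp_path):
        p = tmp_path / "mini.seg"
        p.write_text("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n"
                     "A\t1\t1\t100\t0.1\nA\t2\t1\t100\t0.2\nB\t1\t1\t100\t-0.5\n")
        assert len(read_seg(p)) == 3

    def test_round_trip(self, toy_seg, tmp_path):
        calls = read_seg(toy_seg)
        out = tmp_path / "roundtrip.seg"
        write_seg(calls, out)
        again = read_seg(out)
        pd.testing.assert_frame_equal(calls, again)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.seg"
        p.write_text("Sample\tChromosome\tStart\tSegment_Mean\nA\t1\t1\t0.1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            read_seg(p)

    def test_unparseable_row_reported_with_line_number(self, tmp_path):
        p = tmp_path / "bad.seg"
        p.write_text("Sample\tChromosome\tStart\tEnd\tSegment_Mean\n"
                     "A\t1\t1\t100\t0.1\nA\t1\toops\t200\t0.2\n")
        with pytest.raises(ValueError, match="lines \\[3\\]"):
            read_seg(p)


class TestBuildBlocks:
    def test_identical_single_segment_one_block(self):
        calls = pd.DataFrame({
            "sample": ["A", "B"], "chromosome": [1, 1],
            "start": [1, 1], "end": [100, 100], "log2_ratio": [0.3, -0.2],
        })
        bm = build_blocks(calls, 1)
        assert bm.boundaries == [(0, 100)]
        assert bm.values.to_numpy().tolist() == [[0.3], [-0.2]]

    def test_overlapping_samples_boundary_union(self):
        # A covers [0,100), B covers [50,150): three blocks, A = (vA, vA, 0)
        calls = pd.DataFrame({
            "sample": ["A", "B"], "chromosome": [1, 1],
            "start": [1, 51], "end": [100, 150], "log2_ratio": [0.7, -0.4],
        })
        bm = build_blocks(calls, 1)
        assert bm.boundaries == [(0, 50), (50, 100), (100, 150)]
        assert bm.values.loc["A"].tolist() == [0.7, 0.7, 0.0]
        assert bm.values.loc["B"].tolist() == [0.0, -0.4, -0.4]

    def test_abutting_segments_two_blocks(self):
        calls = pd.DataFrame({
            "sample": ["A", "A"], "chromosome": [1, 1],
            "start": [1, 101], "end": [100, 200], "log2_ratio": [1.0, 2.0],
        })
        bm = build_blocks(calls, 1)
        assert bm.boundaries == [(0, 100), (100, 200)]
        assert bm.values.loc["A"].tolist() == [1.0, 2.0]

    def test_uncovered_gap_dropped(self):
        calls = pd.DataFrame({
            "sample": ["A", "A"], "chromosome": [1, 1],
            "start": [1, 201], "end": [100, 300], "log2_ratio": [1.0, 2.0],
        })
        bm = build_blocks(calls, 1)
        assert bm.boundaries == [(0, 100), (200, 300)]

    def test_overlap_within_sample_rejected_by_name(self):
        calls = pd.DataFrame({
            "sample": ["A", "A"], "chromosome": [1, 1],
            "start": [1, 50], "end": [100, 200], "log2_ratio": [1.0, 2.0],
        })
        with pytest.raises(ValueError, match="'A'"):
            build_blocks(calls, 1)

    def test_idempotent_on_block_expressed_data(self, toy_seg):
        calls = read_seg(toy_seg)
        first = build_blocks(calls, 1)
        # re-express the data with one segment per (sample, block) cell
        rows = []
        for sample in first.values.index:
            for (a, b), val in zip(first.boundaries, first.values.loc[sample]):
                rows.append({"sample": sample, "chromosome": 1,
                             "start": a + 1, "end": b, "log2_ratio": val})
        second = build_blocks(pd.DataFrame(rows), 1)
        assert second.boundaries == first.boundaries

    def test_block_count_bounded_by_segments(self, toy_seg):
        calls = read_seg(toy_seg)
        for chrom in (1, 2):
            bm = build_blocks(calls, chrom)
            n_segments = (calls["chromosome"] == chrom).sum()
            assert bm.n_blocks <= 2 * n_segments


class TestConcatenate:
    def test_column_counts_and_zero_fill(self, toy_seg):
        calls = read_seg(toy_seg)
        blocks = [build_blocks(calls, c) for c in (1, 2)]
        matrix, meta = concatenate_chromosomes(blocks)
        assert matrix.shape == (4, 7)
        np.testing.assert_allclose(matrix.to_numpy(),
                                   np.hstack([TOY_CHR1, TOY_CHR2]))

    def test_metadata_round_trips_coordinates(self, toy_seg):
        calls = read_seg(toy_seg)
        blocks = [build_blocks(calls, c) for c in (1, 2)]
        _, meta = concatenate_chromosomes(blocks)
        assert meta["chromosome"].tolist() == [1, 1, 1, 1, 2, 2, 2]
        assert meta["start"].tolist() == [1, 501, 1001, 1501, 101, 301, 601]
        assert meta["end"].tolist() == [500, 1000, 1500, 2000, 300, 600, 900]
        # every original segment boundary is recoverable from the metadata
        for row in calls.itertuples(index=False):
            sub = meta[meta.chromosome == row.chromosome]
            assert row.start in set(sub["start"])
            assert row.end in set(sub["end"])

    def test_single_chromosome_identity(self, toy_seg):
        calls = read_seg(toy_seg)
        bm = build_blocks(calls, 2)
        matrix, meta = concatenate_chromosomes([bm])
        assert matrix.shape[1] == bm.n_blocks


class TestNormalize:
    def test_column_2_4_6(self):
        out = normalize_unit_range(np.array([[2.0], [4.0], [6.0]]))
        assert out.ravel().tolist() == [0.0, 0.5, 1.0]

    def test_already_unit_identity(self):
        col = np.array([[0.0], [0.25], [1.0]])
        assert (normalize_unit_range(col) == col).all()

    def test_constant_column_maps_to_zero(self):
        out = normalize_unit_range(np.array([[3.0, 1.0], [3.0, 2.0]]))
        assert out[:, 0].tolist() == [0.0, 0.0]

    def test_idempotent(self, rng):
        M = rng.normal(size=(20, 6)) * 3 + 1
        once = normalize_unit_range(M)
        np.testing.assert_array_equal(normalize_unit_range(once), once)

    def test_dataframe_labels_preserved(self):
        df = pd.DataFrame([[2.0], [6.0]], index=["a", "b"], columns=["x"])
        out = normalize_unit_range(df)
        assert list(out.index) == ["a", "b"] and list(out.columns) == ["x"]


class TestPCA:
    def test_rank_one_single_component(self, rng):
        u = rng.normal(size=(15, 1))
        v = rng.normal(size=(1, 8))
        scores = pca_top(u @ v, n_components=10)
        assert scores.shape[1] == 1

    def test_pairwise_distances_preserved_in_full_score_space(self, rng):
        M = rng.normal(size=(12, 7))
        scores = pca_top(M, n_components=7)
        centered = M - M.mean(axis=0)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(scores), pdist(centered), atol=1e-8)

    def test_scores_uncorrelated(self, rng):
        M = rng.normal(size=(30, 6))
        scores = pca_top(M, n_components=5)
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-10

    def test_deterministic_sign_convention(self, rng):
        M = rng.normal(size=(10, 4))
        a = pca_top(M, n_components=3)
        b = pca_top(M.copy(), n_components=3)
        np.testing.assert_array_equal(a, b)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            pca_top(np.ones((1, 5)))


class TestEndToEnd:
    def test_toy_fixture_exact_block_matrix(self, toy_seg):
        calls = read_seg(toy_seg)
        chr1 = build_blocks(calls, 1)
        chr2 = build_blocks(calls, 2)
        assert chr1.boundaries == [(0, 500), (500, 1000), (1000, 1500), (1500, 2000)]
        assert chr2.boundaries == [(100, 300), (300, 600), (600, 900)]
        assert list(chr1.values.index) == ["S1", "S2", "S3"]
        np.testing.assert_allclose(chr1.values.to_numpy(), TOY_CHR1[:3])
        np.testing.assert_allclose(chr2.values.to_numpy(), TOY_CHR2[[0, 3]])

    def test_full_chain_to_normalized_pcs(self, toy_seg):
        calls = read_seg(toy_seg)
        blocks = [build_blocks(calls, c) for c in (1, 2)]
        matrix, _ = concatenate_chromosomes(blocks)
        scores = normalize_unit_range(pca_top(matrix, n_components=10))
        assert scores.shape[0] == 4
        vals = scores.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
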