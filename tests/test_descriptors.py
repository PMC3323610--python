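"""Descriptor unit and property tests against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfpheno.descriptors import (
    BLOCK_DIMS,
    BLOCK_ORDER,
    AggregationLayout,
    EdgeConfig,
    GrayImage,
    compute_chd,
    compute_cld,
    compute_gsehd,
    compute_lehd,
    compute_rcd,
    compute_scd_gray,
    count_edges,
    extract,
    haar_forward,
    haar_inverse,
    quantize_frequency,
    subset_blocks,
    subset_dimension,
)

from .conftest import (
    constant_image,
    oracle_block_means,
    oracle_dct2,
    oracle_edge_counts,
    oracle_lehd_freq,
)


class TestGrayImage:
    def test_rejects_non_2d_and_out_of_range(self):
        with pytest.raises(ValueError, match="2-D"):
            GrayImage(np.zeros((64, 64, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="degenerate"):
            GrayImage(np.zeros((8, 64), dtype=np.uint8))
        with pytest.raises(ValueError, match=r"\[0, 255\]"):
            GrayImage(np.full((64, 64), 300, dtype=np.int32))

    def test_dimensions(self):
        img = constant_image(0, shape=(520, 696))
        assert (img.height, img.width) == (520, 696)


class TestDimensions:
    def test_block_dimensions_sum_to_263(self):
        img = constant_image(100)
        dims = {
            "LEHD": compute_lehd(img).dimension,
            "GSEHD": compute_gsehd(img).dimension,
            "CHD": compute_chd(img).dimension,
            "SCD": compute_scd_gray(img).dimension,
            "RCD": compute_rcd(img).dimension,
            "CLD": compute_cld(img).dimension,
        }
        assert dims == BLOCK_DIMS
        assert sum(dims.values()) == 263

    def test_trio_dimensions(self):
        # standard MPEG-7 trio {LEHD, SCD, CLD} and constructed trio
        assert subset_dimension("100101") == 103
        assert subset_dimension("011010") == 160

    @pytest.mark.parametrize(
        "code,expected",
        [("111111", 263), ("001011", 95), ("100000", 80)],
    )
    def test_extract_dimension(self, code, expected, img128):
        assert extract(img128, code).dimension == expected

    def test_extract_single_block_identity(self, img128):
        vec = extract(img128, "100000")
        np.testing.assert_array_equal(vec.values, compute_lehd(img128).values)

    def test_empty_subset_rejected(self, img128):
        with pytest.raises(ValueError, match="000000"):
            extract(img128, "000000")

    def test_component_names_carry_block_prefix(self, img128):
        names = extract(img128, "001011").component_names
        assert names[0] == "CHD_0" and names[-1] == "CLD_14"
        assert len(names) == 95


class TestLEHD:
    def test_constant_image_all_zero(self):
        assert not compute_lehd(constant_image(137)).values.any()

    def test_vertical_stripes_saturate_vertical_bins(self):
        # stripes of width = half an image-block: sub-block means are 0/255
        px = np.zeros((64, 64), dtype=np.uint8)
        px[:, 1::2] = 255
        lehd = compute_lehd(GrayImage(px)).values.reshape(16, 5)
        np.testing.assert_array_equal(lehd[:, 0], np.full(16, 7))
        assert not lehd[:, 1:].any()

    def test_matches_bruteforce_oracle_on_toys(self, toy16, toy_cfg):
        got = compute_lehd(toy16, toy_cfg).values.reshape(16, 5)
        want = quantize_frequency(oracle_lehd_freq(toy16, toy_cfg)).reshape(16, 5)
        np.testing.assert_array_equal(got, want)

    def test_matches_oracle_on_default_grid(self, img128):
        got = compute_lehd(img128).values
        want = quantize_frequency(oracle_lehd_freq(img128, EdgeConfig())).ravel()
        np.testing.assert_array_equal(got, want)

    def test_too_small_image_names_axis(self):
        img = GrayImage(np.zeros((16, 128), dtype=np.uint8))
        with pytest.raises(ValueError, match="height"):
            compute_lehd(img, EdgeConfig(grid=8))

    def test_quantized_range(self, img128):
        v = compute_lehd(img128).values
        assert v.min() >= 0 and v.max() <= 7
        assert np.array_equal(v, np.floor(v))


class TestGSEHD:
    def test_constant_image_all_zero(self):
        assert not compute_gsehd(constant_image(64)).values.any()

    def test_group_mean_matches_oracle(self, img128):
        freq = oracle_lehd_freq(img128, EdgeConfig())
        layout = AggregationLayout()
        want = quantize_frequency(
            np.stack([freq[list(g)].mean(axis=0) for g in layout.groups])
        ).ravel()
        np.testing.assert_array_equal(compute_gsehd(img128).values, want)

    def test_default_layout_has_16_groups_over_the_grid(self):
        layout = AggregationLayout()
        assert len(layout.groups) == 16
        assert layout.groups[0] == tuple(range(16))

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            AggregationLayout(groups=((0, 99),))


class TestColorDescriptors:
    def test_rcd_constant(self):
        np.testing.assert_array_equal(
            compute_rcd(constant_image(200)).values, np.full(64, 200.0)
        )

    def test_rcd_checkerboard_block_means(self):
        # 0/255 checkerboard at pixel scale: every block mean is 127.5
        px = np.zeros((64, 64), dtype=np.uint8)
        px[::2, 1::2] = 255
        px[1::2, ::2] = 255
        np.testing.assert_allclose(compute_rcd(GrayImage(px)).values, 127.5)

    def test_rcd_matches_pixel_mean_oracle(self, toy16):
        np.testing.assert_allclose(
            compute_rcd(toy16).values, oracle_block_means(toy16).ravel(), atol=1e-9
        )

    def test_rcd_range(self, img128):
        v = compute_rcd(img128).values
        assert v.min() >= 0 and v.max() <= 255

    def test_cld_constant_image_dc_only(self):
        v = compute_cld(constant_image(100)).values
        assert v[0] == pytest.approx(800.0, abs=1e-9)
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-9)

    def test_cld_gradient_matches_direct_dct(self):
        # blocks hold a linear horizontal gradient -> known DCT structure
        px = np.repeat(np.repeat(np.arange(8) * 30, 8)[None, :], 64, axis=0)
        img = GrayImage(px.astype(np.uint8))
        full = oracle_dct2(oracle_block_means(img))
        zig = [(0, 0), (0, 1), (1, 0), (2, 0), (1, 1), (0, 2), (0, 3), (1, 2),
               (2, 1), (3, 0), (4, 0), (3, 1), (2, 2), (1, 3), (0, 4)]
        want = np.array([full[r, c] for r, c in zig])
        np.testing.assert_allclose(compute_cld(img).values, want, atol=1e-9)

    def test_cld_matches_direct_dct_on_random_toy(self, toy16):
        full = oracle_dct2(oracle_block_means(toy16))
        got = compute_cld(toy16).values
        assert got[0] == pytest.approx(full[0, 0], abs=1e-9)
        assert got[1] == pytest.approx(full[0, 1], abs=1e-9)
        assert got[3] == pytest.approx(full[2, 0], abs=1e-9)

    def test_chd_all_black_nominal_frame(self):
        hist = compute_chd(constant_image(0, shape=(520, 696))).values
        assert hist[0] == 361_920
        assert not hist[1:].any()

    def test_chd_constant_128(self):
        hist = compute_chd(constant_image(128)).values
        assert hist[8] == 64 * 64 and hist.sum() == 64 * 64

    def test_chd_matches_counting_oracle(self, img128):
        want = [
            int(np.sum((img128.pixels >= 16 * i) & (img128.pixels <= 16 * i + 15)))
            for i in range(16)
        ]
        np.testing.assert_array_equal(compute_chd(img128).values, want)

    def test_scd_constant_image(self):
        v = compute_scd_gray(constant_image(77)).values
        assert v[0] == pytest.approx(1.0 / 8.0)
        # single occupied bin: the reconstruction, not zero details, is the contract
        hist = np.zeros(8)
        hist[77 >> 5] = 1.0
        np.testing.assert_allclose(haar_inverse(v), hist, atol=1e-12)

    def test_scd_dimension(self, img128):
        assert compute_scd_gray(img128).dimension == 8


class TestHaar:
    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=8, max_size=8))
    def test_roundtrip(self, xs):
        np.testing.assert_allclose(haar_inverse(haar_forward(xs)), xs, atol=1e-10)

    def test_average_first(self):
        x = np.arange(8.0)
        assert haar_forward(x)[0] == pytest.approx(x.mean())

    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError, match="power of two"):
            haar_forward(np.arange(6.0))


class TestInvariances:
    """Global descriptors are permutation-invariant; local ones are not."""

    @pytest.mark.parametrize("op", [compute_chd, compute_scd_gray])
    def test_global_descriptors_rotation_invariant(self, op, img128):
        base = op(img128).values
        for transform in (np.rot90, lambda p: np.rot90(p, 2), np.fliplr, np.flipud):
            np.testing.assert_array_equal(op(GrayImage(transform(img128.pixels))).values, base)

    @pytest.mark.parametrize("op", [compute_lehd, compute_rcd, compute_cld])
    def test_local_descriptors_sense_asymmetry(self, op):
        # planted asymmetric content: striped top-left quadrant
        px = np.zeros((64, 64), dtype=np.uint8)
        px[:32, 1:32:2] = 255
        rotated = GrayImage(np.rot90(px, 2).copy())
        assert not np.allclose(op(GrayImage(px)).values, op(rotated).values)


class TestCountEdges:
    def test_constant_zero(self):
        assert count_edges(constant_image(50)) == 0

    def test_planted_edges_counted_exactly(self):
        # bright 1-px vertical line inside n distinct image-blocks
        px = np.zeros((64, 64), dtype=np.uint8)
        for ib in range(5):
            px[0:2, 1 + 2 * ib] = 255  # image-blocks are 2x2 at 64x64
        assert count_edges(GrayImage(px)) == 5

    def test_equals_oracle_total(self, img128):
        cfg = EdgeConfig()
        assert count_edges(img128, cfg) == int(oracle_edge_counts(img128, cfg).sum())


class TestQuantize:
    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 1.0))
    def test_quantize_in_range_and_monotone_formula(self, f):
        q = int(quantize_frequency(np.array([f]))[0])
        assert q == min(int(np.floor(8 * f)), 7)
        assert 0 <= q <= 7


class TestSubsetCodes:
    def test_roundtrip_table_ordering(self):
        assert subset_blocks("001011") == ("CHD", "RCD", "CLD")
        assert subset_blocks("111111") == BLOCK_ORDER

    def test_bad_codes(self):
        for code in ("0011", "00101x", "0000000"):
            with pytest.raises(ValueError):
                subset_blocks(code)
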