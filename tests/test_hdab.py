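import numpy as np
import pytest

from slidetiler.errors import NoDataError, StainBasisError
from slidetiler.hdab import (
    RUIFROK_HDAB,
    StainBasis,
    analyze_image,
    classify_hdab,
    deconvolve,
    hdab_slide_processor,
    hdab_tile_processor,
    max_positivity_tile,
    positivity,
    rgb_to_od,
)
from slidetiler.results_store import ResultsStore
from slidetiler.run_engine import TileContext
from slidetiler.synthetic import stain_rgb


def _context(**kw):
    defaults = dict(
        slide_filename="s.tif", series=1, x_origin=0, y_origin=0,
        tile_width=10, tile_height=10, tile_path="/dev/null",
        tile_index=1, n_tiles=1, overlap=0,
    )
    defaults.update(kw)
    return TileContext(**defaults)


class TestOpticalDensity:
    def test_white_is_zero(self):
        od = rgb_to_od(np.full((2, 2, 3), 255, dtype=np.uint8))
        assert np.array_equal(od, np.zeros((2, 2, 3)))

    def test_mid_gray_value(self):
        od = rgb_to_od(np.full((1, 1, 3), 26, dtype=np.uint8))
        expected = -np.log10(26 / 255)  # ~0.9914
        assert od == pytest.approx(expected, abs=1e-12)

    def test_black_clamped_at_one(self):
        od = rgb_to_od(np.zeros((1, 1, 3), dtype=np.uint8))
        assert od == pytest.approx(-np.log10(1 / 255), abs=1e-12)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            rgb_to_od(np.zeros((4, 4), dtype=np.uint8))

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)
        assert (rgb_to_od(img) >= 0).all()


class TestDeconvolution:
    def test_zero_od_zero_concentration(self):
        c = deconvolve(np.zeros((3, 3, 3)))
        assert np.allclose(c, 0)

    def test_basis_vector_unit_concentration(self):
        m = RUIFROK_HDAB.matrix()
        for i in range(3):
            c = deconvolve(m[:, i].reshape(1, 1, 3))
            expected = np.zeros(3)
            expected[i] = 1.0
            assert np.allclose(c[0, 0], expected, atol=1e-9)

    def test_matches_explicit_inverse_oracle(self):
        """Concentrations equal an independently coded Cramer's-rule solve."""
        m = RUIFROK_HDAB.matrix()

        def solve_cramer(od):
            det = (
                m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
                - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
                + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
            )
            c = np.empty(3)
            for k in range(3):
                mk = m.copy()
                mk[:, k] = od
                det_k = (
                    mk[0, 0] * (mk[1, 1] * mk[2, 2] - mk[1, 2] * mk[2, 1])
                    - mk[0, 1] * (mk[1, 0] * mk[2, 2] - mk[1, 2] * mk[2, 0])
                    + mk[0, 2] * (mk[1, 0] * mk[2, 1] - mk[1, 1] * mk[2, 0])
                )
                c[k] = det_k / det
            return c

        rng = np.random.default_rng(42)
        ods = rng.uniform(0, 2.5, (200, 3))
        got = deconvolve(ods)
        for od, c in zip(ods, got):
            assert np.allclose(c, solve_cramer(od), atol=1e-9)

    def test_reconstruction_residual(self):
        m = RUIFROK_HDAB.matrix()
        rng = np.random.default_rng(1)
        ods = rng.uniform(0, 2.5, (50, 3))
        c = deconvolve(ods)
        assert np.abs(c @ m.T - ods).max() < 1e-6

    def test_singular_basis_rejected(self):
        with pytest.raises(StainBasisError):
            StainBasis((1, 0, 0), (2, 0, 0), (0, 0, 1)).matrix()
        with pytest.raises(StainBasisError):
            StainBasis((0, 0, 0), (0, 1, 0)).matrix()

    def test_synthesis_round_trip_within_quantization(self):
        """Paint H/DAB concentrations, synthesize 8-bit RGB, deconvolve: recover them.

        Only physical mixes of the two real stains are synthesized (the
        residual axis has a negative component, so exciting it would
        demand transmittance above white).  The bound is set by 8-bit
        intensity rounding amplified through the inverse stain matrix.
        """
        m = RUIFROK_HDAB.matrix()
        rng = np.random.default_rng(3)
        concentrations = np.zeros((500, 3))
        concentrations[:, :2] = rng.uniform(0, 0.8, (500, 2))
        intensity = np.clip(np.rint(255.0 * 10 ** (-(concentrations @ m.T))), 1, 255)
        recovered = deconvolve(rgb_to_od(intensity.astype(np.uint8).reshape(1, -1, 3)))[0]
        assert np.abs(recovered - concentrations).max() < 0.02


class TestClassification:
    def test_white_tile_no_masks(self):
        img = np.full((8, 8, 3), 255, dtype=np.uint8)
        result = analyze_image(img)
        assert (result.blue_area, result.brown_area, result.positivity_pct) == (0, 0, 0.0)

    def test_pure_dab_tile_all_brown(self):
        color = stain_rgb(RUIFROK_HDAB, "dab", 1.0)
        img = np.tile(color, (6, 5, 1))
        result = analyze_image(img)
        assert result.brown_area == 30
        assert result.blue_area == 0
        assert result.positivity_pct == 100.0

    def test_mixed_tile_exact_counts(self):
        h = stain_rgb(RUIFROK_HDAB, "hematoxylin", 1.0)
        d = stain_rgb(RUIFROK_HDAB, "dab", 1.0)
        img = np.full((10, 10, 3), 255, dtype=np.uint8)
        img.reshape(-1, 3)[:40] = h
        img.reshape(-1, 3)[40:100] = d
        result = analyze_image(img)
        assert (result.blue_area, result.brown_area) == (40, 60)
        assert result.positivity_pct == 60.0

    def test_masks_disjoint_brown_precedence(self):
        rng = np.random.default_rng(5)
        conc = rng.uniform(-0.5, 2.0, (32, 32, 3))
        blue, brown = classify_hdab(conc[..., 0], conc[..., 1])
        assert not (blue & brown).any()
        assert ((conc[..., 1] >= 0.15) == brown).all()

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_hdab(np.zeros((2, 2)), np.zeros((2, 2)), tau_h=0)


class TestPositivity:
    @pytest.mark.parametrize(
        "blue,brown,expected",
        [(0, 0, 0.0), (0, 500, 100.0), (70, 30, 30.0), (1, 0, 0.0)],
    )
    def test_percentage(self, blue, brown, expected):
        assert positivity(blue, brown).positivity_pct == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            positivity(-1, 0)


class TestProcessors:
    def test_tile_processor_row_per_tile(self, tmp_path):
        store = ResultsStore(tmp_path)
        d = stain_rgb(RUIFROK_HDAB, "dab", 1.0)
        tile = np.tile(d, (4, 4, 1))
        hdab_tile_processor(tile, _context(x_origin=512, y_origin=256), store)
        rows = store.rows("tiles")
        assert rows == [
            {
                "slide": "s.tif", "series": 1, "x": 512, "y": 256,
                "blue_area": 0, "brown_area": 16, "positivity_pct": 100.0,
            }
        ]

    def test_slide_processor_accumulates_until_last_tile(self, tmp_path):
        store = ResultsStore(tmp_path)
        h = stain_rgb(RUIFROK_HDAB, "hematoxylin", 1.0)
        d = stain_rgb(RUIFROK_HDAB, "dab", 1.0)
        blue_tile = np.tile(h, (3, 3, 1))
        brown_tile = np.tile(d, (3, 3, 1))
        hdab_slide_processor(blue_tile, _context(tile_index=1, n_tiles=2), store)
        assert store.n_rows("slides") == 0  # nothing until the last tile
        hdab_slide_processor(brown_tile, _context(tile_index=2, n_tiles=2), store)
        assert store.rows("slides") == [
            {"slide": "s.tif", "blue_area": 9, "brown_area": 9, "positivity_pct": 50.0}
        ]

    def test_max_positivity_tile_and_tie_break(self, tmp_path):
        store = ResultsStore(tmp_path)
        with pytest.raises(NoDataError):
            max_positivity_tile(store)
        for x, pct in [(0, 10.0), (512, 80.0), (1024, 80.0), (1536, 5.0)]:
            store.append_row(
                "tiles",
                {"slide": "s.tif", "series": 1, "x": x, "y": 0,
                 "blue_area": 1, "brown_area": 1, "positivity_pct": pct},
            )
        assert max_positivity_tile(store) == "s.tif__1_512_0.tif"  # first of the tie
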