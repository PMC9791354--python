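"""Landscape containers, raster I/O and pixel-count → hectare accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landesv.coefficients import LegendError
from landesv.lulc import (
    AreaFormatError,
    CategoricalLandscape,
    GeometryError,
    UnsupportedInputError,
    areas_from_landscape,
    read_area_table,
    read_landscape,
    write_landscape,
)


def make_landscape(grid, legend, pixel=30.0, nodata=-1, label=""):
    return CategoricalLandscape(np.asarray(grid, dtype=np.int64), pixel, legend, label, nodata)


class TestAreas:
    def test_constant_grid_area(self, legend):
        # 100x100 pixels of one class at 30 m = 10^4 * 0.09 ha = 900 ha
        table = areas_from_landscape(make_landscape(np.full((100, 100), 4), legend))
        assert table["cropland"] == pytest.approx(900.0)
        assert all(table[c] == 0 for c in table.class_names if c != "cropland")

    def test_nodata_excluded_from_total(self, legend):
        grid = np.full((10, 10), 4)
        grid[:, :5] = -1
        table = areas_from_landscape(make_landscape(grid, legend))
        assert table.total_area == pytest.approx(50 * 0.09)

    def test_known_counts_give_exact_areas(self, legend):
        rng = np.random.default_rng(7)
        grid = rng.choice(legend.codes, size=(40, 50))
        table = areas_from_landscape(make_landscape(grid, legend))
        for code, name in zip(legend.codes, legend.class_names):
            assert table[name] == pytest.approx(np.count_nonzero(grid == code) * 0.09)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_invariance(self, legend, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice(list(legend.codes) + [-1], size=(12, 17))
        shuffled = rng.permutation(grid.ravel()).reshape(grid.shape)
        t1 = areas_from_landscape(make_landscape(grid, legend))
        t2 = areas_from_landscape(make_landscape(shuffled, legend))
        assert t1.areas == t2.areas

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_extent_conservation(self, legend, seed):
        rng = np.random.default_rng(seed)
        grid = rng.choice(list(legend.codes) + [-1], size=(9, 14))
        scape = make_landscape(grid, legend)
        table = areas_from_landscape(scape)
        nodata_area = np.count_nonzero(grid == -1) * scape.pixel_area_ha
        assert table.total_area + nodata_area == pytest.approx(grid.size * scape.pixel_area_ha)

    def test_reporting_rounds_to_ten_hectares(self, legend):
        table = areas_from_landscape(make_landscape(np.full((13, 13), 1), legend))
        assert table["forest"] == pytest.approx(169 * 0.09)  # 15.21 ha, full precision
        assert table.rounded()["forest"] == 20.0


class TestRasterIO:
    @pytest.mark.parametrize("suffix", [".tif", ".asc"])
    def test_round_trip(self, legend, tmp_path, suffix):
        rng = np.random.default_rng(3)
        grid = rng.choice(list(legend.codes) + [-1], size=(20, 30))
        scape = make_landscape(grid, legend, pixel=30.0, label="1995")
        path = tmp_path / f"map{suffix}"
        write_landscape(scape, path)
        back = read_landscape(path, legend, "1995")
        assert np.array_equal(back.grid, scape.grid)
        assert back.pixel_size_m == pytest.approx(30.0)
        assert back.nodata_code == -1

    def test_unknown_code_raises_with_offenders(self, legend, tmp_path):
        path = tmp_path / "bad.asc"
        write_landscape(make_landscape(np.full((3, 3), 4), legend), path)
        text = path.read_text().replace("4", "99")
        path.write_text(text)
        with pytest.raises(LegendError, match="99"):
            read_landscape(path, legend)

    def test_multiband_tiff_rejected(self, legend, tmp_path):
        import tifffile

        path = tmp_path / "multi.tif"
        tifffile.imwrite(path, np.zeros((3, 4, 4), dtype=np.int32), photometric="minisblack")
        with pytest.raises(UnsupportedInputError):
            read_landscape(path, legend, pixel_size_m=30)

    def test_float_grid_rejected(self, legend):
        with pytest.raises(UnsupportedInputError):
            CategoricalLandscape(np.ones((2, 2)), 30.0, legend)

    def test_bad_pixel_size_rejected(self, legend):
        with pytest.raises(GeometryError):
            make_landscape(np.full((2, 2), 1), legend, pixel=0.0)


class TestAreaCSV:
    def test_published_1995_table(self, legend, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text(
            "class_name,area_ha\nforest,3950\nbuilt-up,560\ngrassland,18430\n"
            "cropland,43190\nshrubland,28300\n"
        )
        table = read_area_table(path, legend, "1995")
        assert table["grassland"] == 18430
        assert table.total_area == pytest.approx(94430)

    def test_empty_body_rejected(self, legend, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("class_name,area_ha\n")
        with pytest.raises(AreaFormatError):
            read_area_table(path, legend)

    def test_duplicate_class_rejected(self, legend, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("class_name,area_ha\nforest,10\nforest,20\n")
        with pytest.raises(AreaFormatError, match="forest"):
            read_area_table(path, legend)

    def test_negative_area_rejected(self, legend, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("class_name,area_ha\nforest,-10\n")
        with pytest.raises(AreaFormatError):
            read_area_table(path, legend)

    def test_unknown_class_rejected(self, legend, tmp_path):
        path = tmp_path / "a.csv"
        path.write_text("class_name,area_ha\nswamp,10\n")
        with pytest.raises(LegendError):
            read_area_table(path, legend)
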