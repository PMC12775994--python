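"""Cohort assembly: abundance ranking, species selection, age binning, conservation."""

import numpy as np
import pandas as pd
import pytest

from ricb.cohorts import (
    SpeciesSummary,
    bin_age,
    build_cohorts,
    round_cohorts,
    select_species,
    species_abundance,
)
from ricb.raster import MapcodeRaster, RemapTable
from ricb.tiles import TILE_COLUMNS, LandisTile

CRS = "EPSG:32617"


def tile(plot_id, rows):
    frame = pd.DataFrame(
        [
            {
                "MapCode": pd.NA,
                "SPECIES_SYMBOL": sym,
                "COMMON_NAME": name,
                "E_SPGRPCD": 28,
                "age": age,
                "biomass": bm,
            }
            for sym, name, age, bm in rows
        ],
        columns=TILE_COLUMNS,
    )
    return LandisTile(plot_id, frame)


def raster_from(grid, cell=30.0):
    return MapcodeRaster(np.asarray(grid, dtype=np.int32), 0, 0.0, 1000.0, cell, CRS)


class TestSpeciesAbundance:
    def test_single_species_fraction_one(self):
        tiles = {10: tile(10, [("AA", "a a", 12.0, 5.0)])}
        raster = raster_from([[1, 1], [1, 0]])
        out = species_abundance(tiles, raster, RemapTable({10: 1}))
        assert len(out) == 1
        assert out[0].fraction == pytest.approx(1.0)

    def test_pixel_weighted_fractions(self):
        # A: 300 kg over 2 pixels, B: 100 kg over 4 pixels -> 600:400
        tiles = {
            10: tile(10, [("A", "sp a", 10.0, 300.0)]),
            20: tile(20, [("B", "sp b", 10.0, 100.0)]),
        }
        raster = raster_from([[1, 1, 0], [2, 2, 2], [2, 0, 0]])
        out = species_abundance(tiles, raster, RemapTable({10: 1, 20: 2}))
        by_sym = {s.species_symbol: s for s in out}
        assert by_sym["A"].fraction == pytest.approx(0.6)
        assert by_sym["B"].fraction == pytest.approx(0.4)
        assert by_sym["A"].total_biomass_kg == pytest.approx(600.0)
        assert [s.species_symbol for s in out] == ["A", "B"]  # sorted descending

    def test_fractions_sum_to_one(self, tiles, landscape):
        from ricb.raster import remap_sequential

        remapped, remap = remap_sequential(landscape.raster)
        out = species_abundance(tiles, remapped, remap)
        assert sum(s.fraction for s in out) == pytest.approx(1.0, abs=1e-9)

    def test_unlinked_raster_code_errors(self):
        tiles = {10: tile(10, [("A", "sp a", 10.0, 300.0)])}
        raster = raster_from([[1, 2]])
        with pytest.raises(KeyError, match="2"):
            species_abundance(tiles, raster, RemapTable({10: 1}))
        # code resolves through the remap but the tile itself is missing
        with pytest.raises(KeyError, match="30"):
            species_abundance(tiles, raster, RemapTable({10: 1, 30: 2}))

    def test_no_biomass_errors(self):
        tiles = {10: tile(10, [])}
        raster = raster_from([[1]])
        with pytest.raises(ValueError):
            species_abundance(tiles, raster, RemapTable({10: 1}))


SUMMARIES = [
    SpeciesSummary("A", "a", 600.0, 0.60),
    SpeciesSummary("B", "b", 390.0, 0.39),
    SpeciesSummary("C", "c", 9.0, 0.009),
    SpeciesSummary("D", "d", 1.0, 0.001),
]


class TestSelectSpecies:
    def test_default_threshold_strict(self):
        assert select_species(SUMMARIES) == {"A", "B"}

    def test_include_admits_minor_species(self):
        assert select_species(SUMMARIES, include=["C"]) == {"A", "B", "C"}

    def test_exclude_removes(self):
        assert select_species(SUMMARIES, exclude=["B"]) == {"A"}

    def test_zero_threshold_selects_all_positive(self):
        assert select_species(SUMMARIES, threshold=0.0) == {"A", "B", "C", "D"}

    def test_unknown_include_errors(self):
        with pytest.raises(ValueError, match="ZZ"):
            select_species(SUMMARIES, include=["ZZ"])

    def test_threshold_monotonicity(self):
        prev = select_species(SUMMARIES, threshold=0.0)
        for t in (0.001, 0.005, 0.01, 0.05, 0.5, 0.7):
            cur = select_species(SUMMARIES, threshold=t)
            assert cur <= prev
            prev = cur


class TestBinAge:
    @pytest.mark.parametrize(
        "age,step,want",
        [(15.0, 5, 15), (14.97, 5, 15), (0.3, 5, 5), (0.0, 5, 5), (10.01, 5, 15), (1.0, 1, 1)],
    )
    def test_ceiling_rule(self, age, step, want):
        assert bin_age(age, step) == want

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bin_age(-1.0, 5)
        with pytest.raises(ValueError):
            bin_age(5.0, 0)


class TestBuildCohorts:
    def test_gram_per_square_meter_conversion(self):
        tiles = {10: tile(10, [("A", "a", 3.0, 0.9)])}
        raster = raster_from([[1]], cell=30.0)
        recs = build_cohorts(tiles, raster, RemapTable({10: 1}), {"A"}, timestep=5)
        assert len(recs) == 1
        assert recs[0].cohort_biomass_g_m2 == pytest.approx(1.0)  # 900 g / 900 m2

    def test_age_binning_splits_cohorts(self):
        tiles = {10: tile(10, [("A", "a", 14.97, 2.0), ("A", "a", 8.2, 3.0)])}
        raster = raster_from([[1]])
        recs = build_cohorts(tiles, raster, RemapTable({10: 1}), {"A"}, timestep=5)
        assert [(r.cohort_age_yr, r.cohort_biomass_g_m2) for r in recs] == [
            (10, pytest.approx(3000.0 / 900.0)),
            (15, pytest.approx(2000.0 / 900.0)),
        ]

    def test_default_split_is_all_wood(self):
        tiles = {10: tile(10, [("A", "a", 3.0, 0.9)])}
        recs = build_cohorts(tiles, raster_from([[1]]), RemapTable({10: 1}), {"A"}, 5)
        assert recs[0].wood_biomass_g_m2 == recs[0].cohort_biomass_g_m2
        assert recs[0].leaf_biomass_g_m2 == 0.0

    def test_leaf_fraction_split(self):
        tiles = {10: tile(10, [("A", "a", 3.0, 0.9)])}
        recs = build_cohorts(
            tiles, raster_from([[1]]), RemapTable({10: 1}), {"A"}, 5, leaf_fraction=0.25
        )
        r = recs[0]
        assert r.leaf_biomass_g_m2 == pytest.approx(0.25 * r.cohort_biomass_g_m2)
        assert r.wood_biomass_g_m2 + r.leaf_biomass_g_m2 == pytest.approx(
            r.cohort_biomass_g_m2
        )

    def test_unselected_mapcode_yields_no_records(self, caplog):
        tiles = {
            10: tile(10, [("A", "a", 3.0, 0.9)]),
            20: tile(20, [("B", "b", 3.0, 0.9)]),
        }
        raster = raster_from([[1, 2]])
        with caplog.at_level("WARNING", logger="ricb.cohorts"):
            recs = build_cohorts(tiles, raster, RemapTable({10: 1, 20: 2}), {"A"}, 5)
        assert {r.map_code for r in recs} == {1}
        assert any("empty_mapcode" in r.message for r in caplog.records)

    def test_records_sorted(self, tiles, landscape):
        from ricb.raster import remap_sequential

        remapped, remap = remap_sequential(landscape.raster)
        recs = build_cohorts(tiles, remapped, remap, {"QUNI", "ACRU"}, 10)
        keys = [(r.map_code, r.species_symbol, r.cohort_age_yr) for r in recs]
        assert keys == sorted(keys)

    def test_conservation_and_timestep_refinement(self, tiles, landscape):
        """Binning never creates or destroys biomass, at any timestep."""
        from ricb.raster import remap_sequential

        remapped, remap = remap_sequential(landscape.raster)
        selected = {"QUNI", "PITA", "ACRU"}
        counts = remapped.value_counts()
        cell_area = remapped.cell_size_m**2

        want_g = 0.0
        for code, n in counts.items():
            frame = tiles[remap.to_original[code]].frame
            kg = frame[frame.SPECIES_SYMBOL.isin(selected)].biomass.sum()
            want_g += kg * 1000.0 * n

        totals_by_step = {}
        for step in (1, 5, 10):
            recs = build_cohorts(tiles, remapped, remap, selected, step)
            got_g = sum(
                r.cohort_biomass_g_m2 * cell_area * counts[r.map_code] for r in recs
            )
            assert got_g == pytest.approx(want_g, rel=1e-9)
            per_pair = {}
            for r in recs:
                key = (r.map_code, r.species_symbol)
                per_pair[key] = per_pair.get(key, 0.0) + r.cohort_biomass_g_m2
            totals_by_step[step] = per_pair
        # (mapcode, species) totals invariant under timestep
        for step in (5, 10):
            assert totals_by_step[step].keys() == totals_by_step[1].keys()
            for key, v in totals_by_step[step].items():
                assert v == pytest.approx(totals_by_step[1][key], rel=1e-9)

    def test_finer_timestep_never_fewer_cohorts(self, tiles, landscape):
        from ricb.raster import remap_sequential

        remapped, remap = remap_sequential(landscape.raster)
        fine = build_cohorts(tiles, remapped, remap, {"QUNI"}, 1)
        coarse = build_cohorts(tiles, remapped, remap, {"QUNI"}, 25)

        def per_pair_counts(recs):
            out = {}
            for r in recs:
                out[(r.map_code, r.species_symbol)] = (
                    out.get((r.map_code, r.species_symbol), 0) + 1
                )
            return out

        fine_counts = per_pair_counts(fine)
        for key, n in per_pair_counts(coarse).items():
            assert fine_counts[key] >= n


class TestRoundCohorts:
    def test_half_away_from_zero_and_zero_drop(self, caplog):
        tiles = {10: tile(10, [("A", "a", 3.0, 0.0004), ("B", "b", 3.0, 2.25)])}
        raster = raster_from([[1]])
        recs = build_cohorts(tiles, raster, RemapTable({10: 1}), {"A", "B"}, 5)
        with caplog.at_level("WARNING", logger="ricb.cohorts"):
            rounded = round_cohorts(recs)
        # A: 0.00044 g/m2 rounds to 0 -> dropped; B: 2.5 g/m2 rounds half away to 3
        assert len(rounded) == 1
        assert rounded[0].species_symbol == "B"
        assert rounded[0].cohort_biomass_g_m2 == 3
        assert any("rounded to zero" in r.message for r in caplog.records)
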