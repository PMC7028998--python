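import numpy as np
import pandas as pd
import pytest

from sedsim import energyscape as es
from sedsim import metrics as smx
from sedsim import ranges as rg
from sedsim import simulator as sim
from sedsim import synthetic as syn
from sedsim.hexgrid import great_circle_km


def _option(oid, cells, hemi="EH", lat=0.0, lon=0.0):
    return rg.RangeOption(oid, hemi, np.asarray(cells, dtype=int), int(cells[0]), lat, lon, np.zeros(2))


def _species(sid, breed, nonbreed, hemi="EH", d=0.0):
    return sim.VirtualSpecies(
        species_id=sid, hemisphere=hemi, breeding_option=breed, nonbreeding_option=nonbreed,
        breeding_season="NS", d_m=d, e_assim_ns=1.0, e_assim_nw=1.0, e_prod=0.5,
    )


def _assemblage(options, species, n_cells=10):
    fld = es.SeasonalEnergyField(e_s=np.ones((2, n_cells)), e_a=np.ones((2, n_cells)))
    return sim.Assemblage(
        species=species, field=fld, richness=np.zeros(n_cells, int),
        options=options, params=sim.SimParams(),
    )


class TestDiversityPatterns:
    def test_all_residents_make_empty_migrant_maps(self):
        opts = [_option(0, [0, 1, 2])]
        asm = _assemblage(opts, [_species(0, 0, 0), _species(1, 0, 0)])
        ps = smx.diversity_patterns(asm)
        assert ps.breeding_migrants.sum() == 0 and ps.nonbreeding_migrants.sum() == 0
        assert list(ps.residents[:3]) == [2, 2, 2]

    def test_disjoint_migrant_is_an_indicator(self):
        opts = [_option(0, [0, 1]), _option(1, [5, 6])]
        asm = _assemblage(opts, [_species(0, 0, 1, d=1000.0)])
        ps = smx.diversity_patterns(asm)
        assert list(np.flatnonzero(ps.breeding_migrants)) == [0, 1]
        assert list(np.flatnonzero(ps.nonbreeding_migrants)) == [5, 6]
        assert ps.residents.sum() == 0

    def test_overlap_cells_count_in_neither_migrant_map(self):
        opts = [_option(0, [0, 1, 2]), _option(1, [2, 3, 4])]
        asm = _assemblage(opts, [_species(0, 0, 1, d=500.0)])
        ps = smx.diversity_patterns(asm)
        assert ps.breeding_migrants[2] == 0 and ps.nonbreeding_migrants[2] == 0
        ps2 = smx.diversity_patterns(asm, overlap_as_resident=True)
        assert ps2.residents[2] == 1

    def test_counting_identity_on_a_real_run(self, assemblage_coarse):
        ps = smx.diversity_patterns(assemblage_coarse)
        expected_breed = sum(
            len(np.setdiff1d(*assemblage_coarse.seasonal_ranges(s)))
            for s in assemblage_coarse.species
            if not s.resident
        )
        assert ps.breeding_migrants.sum() == expected_breed
        expected_res = sum(
            len(assemblage_coarse.seasonal_ranges(s)[0])
            for s in assemblage_coarse.species
            if s.resident
        )
        assert ps.residents.sum() == expected_res


class TestSeasonalDifference:
    def test_single_migrant_signs(self):
        opts = [_option(0, [0, 1, 2]), _option(1, [2, 3])]
        asm = _assemblage(opts, [_species(0, 0, 1, d=500.0)])
        diff = smx.seasonal_difference(smx.diversity_patterns(asm))
        assert list(diff[:4]) == [1, 1, 0, -1]

    def test_no_migrants_all_zero(self):
        asm = _assemblage([_option(0, [0])], [_species(0, 0, 0)])
        assert not smx.seasonal_difference(smx.diversity_patterns(asm)).any()

    def test_mirror_world_antisymmetry(self):
        """Mirrored migrants produce a map antisymmetric about the equator."""
        opts = [_option(0, [0], lat=40.0), _option(1, [1], lat=5.0),
                _option(2, [2], lat=-40.0), _option(3, [3], lat=-5.0)]
        species = [_species(0, 0, 1, d=500.0), _species(1, 2, 3, d=500.0)]
        diff = smx.seasonal_difference(smx.diversity_patterns(_assemblage(opts, species)))
        assert diff[0] == diff[2] and diff[1] == diff[3]


class TestMigrationStats:
    def test_proportion(self):
        opts = [_option(0, [0]), _option(1, [1])]
        species = [_species(i, 0, 0) for i in range(7)] + [
            _species(7 + i, 0, 1, d=100.0) for i in range(3)
        ]
        prop, _ = smx.migration_stats(_assemblage(opts, species))
        assert prop == pytest.approx(0.3)

    def test_all_residents_flagged(self):
        asm = _assemblage([_option(0, [0])], [_species(0, 0, 0)])
        prop, mean_d = smx.migration_stats(asm)
        assert prop == 0.0 and np.isnan(mean_d)

    def test_mean_distance_matches_geodesic_oracle(self):
        opts = [
            _option(0, [0], lat=50.0, lon=10.0), _option(1, [1], lat=0.0, lon=10.0),
            _option(2, [2], lat=-30.0, lon=-60.0, hemi="WH"),
            _option(3, [3], lat=10.0, lon=-80.0, hemi="WH"),
        ]
        d1 = great_circle_km((50.0, 10.0), (0.0, 10.0))
        d2 = great_circle_km((-30.0, -60.0), (10.0, -80.0))
        species = [_species(0, 0, 1, d=d1), _species(1, 2, 3, hemi="WH", d=d2)]
        _, mean_d = smx.migration_stats(_assemblage(opts, species))
        assert mean_d == pytest.approx((d1 + d2) / 2.0)
        _, wh_d = smx.migration_stats(_assemblage(opts, species), region="WH")
        assert wh_d == pytest.approx(d2)


class TestPatternCorrelation:
    def test_perfect_agreement_scores_three(self, rng):
        a = smx.PatternSet(*(rng.integers(0, 9, 30) for _ in range(3)))
        rb, rn, rr, comp = smx.pattern_correlation(a, a)
        assert (rb, rn, rr) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))
        assert comp == pytest.approx(3.0)

    def test_negated_pattern(self, rng):
        x = rng.integers(0, 9, 30)
        a = smx.PatternSet(x, x, x)
        b = smx.PatternSet(-x, x, x)
        rb, *_ = smx.pattern_correlation(a, b)
        assert rb == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        x = np.array([0, 1, 2, 3, 4], float)
        y = np.array([1, 0, 2, 4, 3], float)
        r_hand = float(np.sum((x - 2) * (y - 2)) / np.sqrt(np.sum((x - 2) ** 2) * np.sum((y - 2) ** 2)))
        a = smx.PatternSet(x, x, x)
        b = smx.PatternSet(y, x, x)
        rb, *_ = smx.pattern_correlation(a, b)
        assert rb == pytest.approx(r_hand)

    def test_zero_variance_warns_and_excludes(self, rng):
        x = rng.integers(1, 9, 20)
        flat = np.zeros(20)
        with pytest.warns(UserWarning, match="zero-variance"):
            rb, rn, rr, comp = smx.pattern_correlation(
                smx.PatternSet(flat, x, x), smx.PatternSet(x, x, x)
            )
        assert np.isnan(rb)
        assert comp == pytest.approx(rn + rr)

    def test_composite_invariant_to_species_relabelling(self, assemblage_coarse, rng):
        ps = smx.diversity_patterns(assemblage_coarse)
        shuffled = sim.Assemblage(
            species=[assemblage_coarse.species[i] for i in rng.permutation(assemblage_coarse.n_species)],
            field=assemblage_coarse.field, richness=assemblage_coarse.richness,
            options=assemblage_coarse.options, params=assemblage_coarse.params,
        )
        ps2 = smx.diversity_patterns(shuffled)
        assert np.array_equal(ps.breeding_migrants, ps2.breeding_migrants)
        assert np.array_equal(ps.residents, ps2.residents)


@pytest.fixture(scope="module")
def tiny_scape():
    planet = syn.make_planet(syn.fixture_spec("default", frequency=8))
    return syn.planet_energyscape(planet)


TINY_PARAMS = sim.SimParams(n_options={"WH": 12, "EH": 18}, range_sizes={"WH": 5, "EH": 7}, seed=2)


class TestScans:
    def test_beta_scan_emits_full_grid(self, tiny_scape):
        df = smx.beta_scan(tiny_scape, TINY_PARAMS, betas=[0.001, 0.012, 0.02])
        assert len(df) == 3
        assert len(smx.DEFAULT_BETA_GRID) == 33
        assert df.n_species.iloc[0] == 0  # below viability on any world this poor

    def test_scan_reproducible_and_isolated(self, tiny_scape):
        before = tiny_scape.field.e_a.copy()
        a = smx.beta_scan(tiny_scape, TINY_PARAMS, betas=[0.012, 0.015])
        b = smx.beta_scan(tiny_scape, TINY_PARAMS, betas=[0.012, 0.015])
        assert a.equals(b)
        # the scan never mutates the shared pristine field
        assert np.array_equal(before, tiny_scape.field.e_a)

    def test_scoring_against_self_is_perfect(self, tiny_scape):
        asm = sim.run_simulation(tiny_scape, TINY_PARAMS)
        emp = smx.diversity_patterns(asm)
        df = smx.beta_scan(tiny_scape, TINY_PARAMS, betas=[TINY_PARAMS.beta], empirical=emp)
        assert df.composite.iloc[0] == pytest.approx(3.0)

    def test_sensitivity_scan_validates_parameter(self, tiny_scape):
        with pytest.raises(ValueError, match="parameter"):
            smx.sensitivity_scan(tiny_scape, TINY_PARAMS, "beta", [0.01])


class TestTimeSeries:
    def test_identical_slices_are_exactly_flat(self, tiny_scape):
        ts, patterns, _ = smx.timeseries_runner([tiny_scape, tiny_scape, tiny_scape], TINY_PARAMS)
        assert ts.n_species.nunique() == 1
        assert ts.proportion_migrants_global.nunique() == 1
        assert np.array_equal(patterns[0].residents, patterns[2].residents)

    def test_present_relative_series_starts_at_one(self, tiny_scape):
        ts, _, _ = smx.timeseries_runner([tiny_scape, tiny_scape], TINY_PARAMS)
        assert ts.n_species_rel.iloc[0] == pytest.approx(1.0)

    def test_contrast_maps_zero_against_self(self, tiny_scape):
        _, patterns, _ = smx.timeseries_runner([tiny_scape, tiny_scape], TINY_PARAMS)
        cm = smx.contrast_maps(patterns)
        assert not cm[1].breeding_migrants.any()
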