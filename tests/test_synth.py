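"""Synthetic-data generator: determinism, mean functions, terrain oracle."""

import numpy as np
import pytest

from deerseed.synth import (PopulationSpec, SeedLoadSpec, gen_passage_table,
                            gen_seed_data, gen_trajectory, realized_mobility,
                            species_base_rates, terrain_elevation)
from deerseed.passage import interval_midpoint_mean


def _short_spec(**kw):
    defaults = dict(n_individuals=2, rng_seed=5,
                    start_time=np.datetime64("2018-05-01T00:00:00"),
                    end_time=np.datetime64("2018-05-11T00:00:00"))
    defaults.update(kw)
    return PopulationSpec(**defaults)


class TestGenTrajectory:
    def test_zero_step_scale_stays_at_start(self):
        spec = _short_spec(step_scale={"a": 0.0, "b": 100.0})
        t = gen_trajectory(spec, "a")
        assert (t.easting == t.easting[0]).all()
        assert (t.northing == t.northing[0]).all()
        assert (t.elevation == t.elevation[0]).all()

    def test_ten_day_hourly_span_has_241_fixes(self):
        t = gen_trajectory(_short_spec(), "deer_01")
        assert len(t) == 241

    def test_unknown_animal_raises(self):
        with pytest.raises(KeyError):
            gen_trajectory(_short_spec(), "nope")

    def test_mean_step_length_matches_scale_without_attraction(self):
        # Monte-Carlo check of the step construction: exponential lengths
        # with mean step_scale, so the realized mean converges to it.
        spec = PopulationSpec(
            n_individuals=1, rng_seed=8, home_range_attraction=0.0,
            step_scale={"a": 150.0},
            start_time=np.datetime64("2018-05-01T00:00:00"),
            end_time=np.datetime64("2019-06-23T16:00:00"))  # > 10,000 steps
        t = gen_trajectory(spec, "a")
        assert len(t) > 10_000
        steps = np.hypot(np.diff(t.easting), np.diff(t.northing))
        assert abs(steps.mean() - 150.0) / 150.0 < 0.05

    def test_deterministic_under_seed(self):
        a = gen_trajectory(_short_spec(), "deer_01")
        b = gen_trajectory(_short_spec(), "deer_01")
        assert (a.easting == b.easting).all()
        assert (a.times == b.times).all()

    def test_timestamps_strictly_increasing_and_terrain_exact(self):
        spec = _short_spec()
        t = gen_trajectory(spec, "deer_02")
        assert (np.diff(t.times.astype("int64")) > 0).all()
        np.testing.assert_array_equal(
            t.elevation, terrain_elevation(spec, t.easting, t.northing))

    def test_realized_mobility_tracks_step_scale(self):
        spec = PopulationSpec(rng_seed=6, n_individuals=6)
        mob = realized_mobility({a: gen_trajectory(spec, a)
                                 for a in spec.animal_ids()})
        scales = spec.step_scale
        order_true = sorted(scales, key=scales.get)
        order_real = sorted(mob, key=mob.get)
        assert order_true == order_real


class TestGenSeedData:
    def _setup(self, **kw):
        pop = _short_spec(n_individuals=4, months=(5, 6))
        mobility = {a: 100.0 + 50.0 * i
                    for i, a in enumerate(pop.animal_ids())}
        spec = SeedLoadSpec(n_species=10, rng_seed=2, **kw)
        return spec, pop, mobility

    def test_zero_samples_per_cell_gives_empty_list(self):
        spec, pop, mob = self._setup(samples_per_cell=0)
        assert gen_seed_data(spec, pop, mob).samples == []

    def test_counts_are_nonnegative_integers(self):
        spec, pop, mob = self._setup()
        data = gen_seed_data(spec, pop, mob)
        for s in data.samples:
            assert s.volume_ml > 0
            for c in s.species_counts.values():
                assert c >= 1 and c == int(c)

    def test_mean_function_matches_documented_form(self):
        # E[count] = base * month_profile * n_months * exp(a_i + c*z_i)
        spec, pop, mob = self._setup(mobility_coupling=0.7)
        data = gen_seed_data(spec, pop, mob)
        base = species_base_rates(spec.n_species)
        months = tuple(pop.months)
        for ii, aid in enumerate(pop.animal_ids()):
            expected = (base[3] * _profile(data, 3, 0) * len(months)
                        * np.exp(data.individual_effects[aid]
                                 + 0.7 * data.mobility_z[aid]))
            assert data.mean_counts[3, ii, 0] == pytest.approx(
                expected, abs=1e-9)

    def test_coupling_links_expected_load_to_mobility(self):
        from scipy.stats import spearmanr
        spec, pop, mob = self._setup(mobility_coupling=1.0,
                                     individual_effect_sd=1e-9)
        data = gen_seed_data(spec, pop, mob)
        totals = data.mean_counts.sum(axis=(0, 2))
        z = np.array([data.mobility_z[a] for a in pop.animal_ids()])
        rho = spearmanr(totals, z).statistic
        assert rho == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        spec, pop, mob = self._setup()
        a = gen_seed_data(spec, pop, mob)
        b = gen_seed_data(spec, pop, mob)
        assert [s.species_counts for s in a.samples] == \
               [s.species_counts for s in b.samples]

    def test_contaminants_reach_three_control_trays(self):
        spec, pop, mob = self._setup(include_contaminants=True)
        data = gen_seed_data(spec, pop, mob)
        per_sp = data.control.groupby("species")["tray_id"].nunique()
        for w in ("weed_c1", "weed_c2", "weed_c3"):
            assert per_sp[w] >= 3
        assert per_sp["weed_b1"] == 2


def _profile(data, species_i, month_i):
    """Back out a species' month profile from the stored mean function.

    Animal multipliers are month-constant, so normalizing one animal's row
    of the mean across months recovers the profile exactly.
    """
    row = data.mean_counts[species_i, 0, :]
    return (row / row.sum())[month_i]


class TestGenPassageTable:
    def test_default_grid_has_36_normalized_cells(self):
        m = gen_passage_table()
        assert m.n_cells == 36
        for p in m.cell_probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert (p >= 0).all()

    def test_skew_increases_implied_mean(self):
        means = [interval_midpoint_mean(gen_passage_table(skew=s, rng_seed=4))
                 for s in (0.0, 0.5, 1.5)]
        assert means[0] < means[1] < means[2]

    def test_deterministic_under_seed(self):
        a = gen_passage_table(rng_seed=9)
        b = gen_passage_table(rng_seed=9)
        for cell in a.cell_probs:
            assert (a.cell_probs[cell] == b.cell_probs[cell]).all()

    def test_invalid_grid_raises(self):
        with pytest.raises(ValueError):
            gen_passage_table(n_trials=0)


class TestSpeciesBaseRates:
    def test_monotone_decreasing_and_positive(self):
        r = species_base_rates(62)
        assert (np.diff(r) < 0).all()
        assert (r > 0).all()
        assert r[0] == pytest.approx(5.0)
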