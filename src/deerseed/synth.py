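"""Synthetic study generator.

The study's raw movement data are confidential, so every downstream stage is
exercised on synthetic populations with the statistical structure the
analysis assumes: 21 GPS-collared individuals tracked hourly from May to
December, individual-specific mobility (the step-length scale of a
correlated random walk with home-range attraction), a smooth deterministic
terrain supplying elevations, and species x individual x month seed loads
with a rank-abundance community of ~62 species and an optional log-linear
coupling that concentrates seed load on more mobile individuals.

Everything is deterministic under the spec seeds: identical specs produce
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .core import DEFAULT_INTERVAL_BOUNDS, DungSample, PassageTimeModel, Trajectory

DEFAULT_MONTHS = (5, 6, 7, 8, 9, 10, 11, 12)  # May-December


# ---------------------------------------------------------------------------
# Population (movement) generator
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    """Parameters of the synthetic deer population and its landscape.

    ``step_scale`` is the mobility axis: the mean hourly step length (m) of
    each individual's correlated random walk. If None, individual scales are
    drawn log-normally (median ~220 m/h, log-sd 0.5, roughly a four-fold
    spread across 21 animals) from ``rng_seed``.

    ``home_range_attraction`` is the per-step fractional pull toward the
    individual's home-range centre; together with the step scale it sets the
    home-range radius, so more mobile animals also range wider.
    """

    n_individuals: int = 21
    months: tuple[int, ...] = DEFAULT_MONTHS
    year: int = 2018
    fix_interval_h: float = 1.0
    step_scale: Mapping[str, float] | None = None
    turn_concentration: float = 1.0
    terrain_amplitude: float = 200.0
    terrain_wavelength: float = 4000.0
    terrain_base: float = 800.0
    home_range_attraction: float = 0.3
    home_range_spacing: float = 1500.0
    rng_seed: int = 0
    start_time: np.datetime64 | None = None
    end_time: np.datetime64 | None = None

    def __post_init__(self) -> None:
        if self.fix_interval_h <= 0:
            raise ValueError("fix_interval_h must be positive")
        if self.home_range_attraction < 0:
            raise ValueError("home_range_attraction must be >= 0")
        if self.step_scale is None:
            rng = np.random.default_rng(
                np.random.SeedSequence((self.rng_seed, 0)))
            scales = 220.0 * np.exp(rng.normal(0.0, 0.5, self.n_individuals))
            self.step_scale = {
                aid: float(s) for aid, s in zip(self.animal_ids(), scales)}
        else:
            self.step_scale = dict(self.step_scale)
            for aid, s in self.step_scale.items():
                if s < 0:
                    raise ValueError(f"{aid}: step scale must be >= 0")

    def animal_ids(self) -> list[str]:
        if isinstance(self.step_scale, dict) and self.step_scale:
            return list(self.step_scale)
        return [f"deer_{i + 1:02d}" for i in range(self.n_individuals)]

    def span(self) -> tuple[np.datetime64, np.datetime64]:
        """Start and end instants of the tracking window."""
        if self.start_time is not None and self.end_time is not None:
            return (np.datetime64(self.start_time, "s"),
                    np.datetime64(self.end_time, "s"))
        m0, m1 = min(self.months), max(self.months)
        start = np.datetime64(f"{self.year}-{m0:02d}-01T00:00:00", "s")
        if m1 == 12:
            end = np.datetime64(f"{self.year + 1}-01-01T00:00:00", "s")
        else:
            end = np.datetime64(f"{self.year}-{m1 + 1:02d}-01T00:00:00", "s")
        end -= np.timedelta64(int(self.fix_interval_h * 3600), "s")
        return start, end

    def home_range_centre(self, animal_id: str) -> tuple[float, float]:
        i = self.animal_ids().index(animal_id)
        return (i * self.home_range_spacing,
                0.37 * i * self.home_range_spacing)


def terrain_elevation(spec: PopulationSpec, easting, northing):
    """Deterministic smooth terrain: a sum of two incommensurate sinusoids.

    Using an analytic surface instead of a DEM gives exact oracles for
    vertical displacement: elevation is a pure function of (easting,
    northing) at every fix.
    """
    lam = spec.terrain_wavelength
    e = np.asarray(easting, dtype=float)
    n = np.asarray(northing, dtype=float)
    return spec.terrain_base + 0.5 * spec.terrain_amplitude * (
        np.sin(2 * np.pi * e / lam) + np.cos(2 * np.pi * n / (0.63 * lam)))


def _fix_times(spec: PopulationSpec) -> np.ndarray:
    start, end = spec.span()
    step = np.timedelta64(int(round(spec.fix_interval_h * 3600)), "s")
    n = int((end - start) / step) + 1
    return (start + np.arange(n) * step).astype("datetime64[ns]")


def gen_trajectory(spec: PopulationSpec, animal_id: str) -> Trajectory:
    """Simulate one individual's movement path.

    The walk draws exponential step lengths with mean ``step_scale`` and
    von Mises turning angles with the configured concentration; each step is
    then pulled toward the home-range centre by the attraction fraction.
    Because the pull is linear in position, the whole path is the output of
    a first-order linear filter over the step increments and is computed
    without a per-step Python loop.
    """
    if animal_id not in spec.step_scale:
        raise KeyError(f"unknown animal_id {animal_id!r}")
    idx = spec.animal_ids().index(animal_id)
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 1, idx)))
    times = _fix_times(spec)
    n_steps = len(times) - 1
    if n_steps < 1:
        raise ValueError("tracking window shorter than one fix interval")

    if spec.turn_concentration > 0:
        turns = rng.vonmises(0.0, spec.turn_concentration, n_steps)
    else:
        turns = rng.uniform(-np.pi, np.pi, n_steps)
    headings = rng.uniform(0, 2 * np.pi) + np.cumsum(turns)
    lengths = rng.exponential(spec.step_scale[animal_id], n_steps)
    dx = lengths * np.cos(headings)
    dy = lengths * np.sin(headings)

    # u_{t+1} = (1 - a) u_t + step_t, u_0 = 0 (start at the centre)
    a = spec.home_range_attraction
    ux = lfilter([1.0], [1.0, -(1.0 - a)], dx)
    uy = lfilter([1.0], [1.0, -(1.0 - a)], dy)
    cx, cy = spec.home_range_centre(animal_id)
    easting = cx + np.concatenate([[0.0], ux])
    northing = cy + np.concatenate([[0.0], uy])
    elevation = terrain_elevation(spec, easting, northing)
    return Trajectory(animal_id=animal_id, times=times, easting=easting,
                      northing=northing, elevation=elevation)


def gen_population(spec: PopulationSpec) -> dict[str, Trajectory]:
    """Simulate every individual in the spec."""
    return {aid: gen_trajectory(spec, aid) for aid in spec.animal_ids()}


def realized_mobility(trajs: dict[str, Trajectory]) -> dict[str, float]:
    """Mean realized step length (m per fix interval) per individual."""
    out = {}
    for aid, t in trajs.items():
        steps = np.hypot(np.diff(t.easting), np.diff(t.northing))
        out[aid] = float(steps.mean())
    return out


# ---------------------------------------------------------------------------
# Seed-load generator
# ---------------------------------------------------------------------------

def species_base_rates(n_species: int, common_rate: float = 5.0,
                       knee_rank: int = 19, knee_rate: float = 0.015,
                       tail_start_rate: float = 0.0055,
                       tail_rate: float = 0.004) -> np.ndarray:
    """Rank-abundance curve: mean seedlings per sample for each species.

    Piecewise geometric on rank — a steep core of common species down to the
    knee, a sharp drop, then a long, slowly decaying tail of rare species.
    The defaults put roughly the first 19 of 62 species above the abundance
    at which a species is typically dispersed by at least five of 21
    individuals, while keeping the tail frequent enough that nearly the
    whole community shows up across a season of sampling.
    """
    ranks = np.arange(n_species)
    knee = min(knee_rank - 1, max(n_species - 1, 1))
    rates = np.empty(n_species)
    if knee > 0:
        r1 = (knee_rate / common_rate) ** (1.0 / knee)
        rates[: knee + 1] = common_rate * r1 ** ranks[: knee + 1]
    else:
        rates[0] = common_rate
    if n_species > knee + 1:
        n_tail = n_species - knee - 1
        if n_tail == 1:
            rates[knee + 1] = tail_start_rate
        else:
            r2 = (tail_rate / tail_start_rate) ** (1.0 / (n_tail - 1))
            rates[knee + 1:] = tail_start_rate * r2 ** np.arange(n_tail)
    return rates


@dataclass
class SeedLoadSpec:
    """Parameters of the synthetic dung / seedling community.

    ``mobility_coupling`` is the log-linear link between an individual's
    standardized mobility and its expected seed load: 0 makes loads
    independent of movement; positive values concentrate seed load on the
    more mobile individuals.

    ``individual_effect_sd`` and ``sample_noise_sd`` are log-scale standard
    deviations of the per-animal load multiplier and the per-sample
    overdispersion. The defaults leave most of the log-load variance to the
    sample level, as dung seedling counts are strongly overdispersed.
    """

    n_species: int = 62
    samples_per_cell: int | Mapping[tuple[str, int], int] = 3
    mean_volume_ml: float = 172.3
    volume_shape: float = 30.0
    individual_effect_sd: float = 0.5
    sample_noise_sd: float = 1.0
    mobility_coupling: float = 0.0
    month_profile_sd: float = 1.5
    month_profiles: np.ndarray | None = None  # (n_species, n_months)
    include_contaminants: bool = True
    n_control_trays: int = 6
    rng_seed: int = 0

    def species_names(self) -> list[str]:
        return [f"sp_{i + 1:03d}" for i in range(self.n_species)]


CONTAMINANT_SPECIES = ("weed_c1", "weed_c2", "weed_c3")
BORDERLINE_SPECIES = "weed_b1"  # seen in control trays, but below threshold


def _month_profiles(spec: SeedLoadSpec, months: tuple[int, ...],
                    rng: np.random.Generator) -> np.ndarray:
    if spec.month_profiles is not None:
        prof = np.asarray(spec.month_profiles, dtype=float)
        if prof.shape != (spec.n_species, len(months)):
            raise ValueError("month_profiles has the wrong shape")
        return prof / prof.sum(axis=1, keepdims=True)
    idx = np.arange(len(months))
    peaks = rng.integers(0, len(months), spec.n_species)
    prof = np.exp(-0.5 * ((idx[None, :] - peaks[:, None])
                          / spec.month_profile_sd) ** 2)
    return prof / prof.sum(axis=1, keepdims=True)


@dataclass
class SyntheticSeedData:
    """Output of :func:`gen_seed_data` plus the effects it drew.

    ``mean_counts`` is the generator's documented mean function evaluated at
    the drawn effects: expected seedlings per sample (before per-sample
    overdispersion) indexed (species, individual, month).
    """

    samples: list[DungSample]
    control: pd.DataFrame
    species: list[str]
    individual_effects: dict[str, float]
    mobility_z: dict[str, float]
    mean_counts: np.ndarray
    months: tuple[int, ...] = DEFAULT_MONTHS

    def mean_function(self, species_i: int, animal_id: str,
                      month: int) -> float:
        aids = list(self.individual_effects)
        return float(self.mean_counts[species_i, aids.index(animal_id),
                                      self.months.index(month)])


def gen_seed_data(spec: SeedLoadSpec, pop: PopulationSpec,
                  mobility: Mapping[str, float]) -> SyntheticSeedData:
    """Generate dung samples with seedling counts, plus control-tray rows.

    Expected seedlings of species *s* in one sample from individual *i* in
    month *m*:

        E[count] = base_s * profile_{s,m} * n_months
                   * exp(a_i) * exp(coupling * z_i) * exp(eps)

    with ``a_i ~ N(-sd^2/2, sd^2)`` the individual effect, ``z_i`` the
    standardized mobility, and ``eps`` a per-sample log-normal
    overdispersion term (mean-one). Realized counts are Poisson draws around
    that mean; volumes are Gamma around ``mean_volume_ml``.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.rng_seed, 2)))
    aids = pop.animal_ids()
    months = tuple(pop.months)
    n_m = len(months)
    base = species_base_rates(spec.n_species)
    prof = _month_profiles(spec, months, rng)

    mob = np.array([float(mobility[a]) for a in aids])
    sd_m = mob.std()
    z = (mob - mob.mean()) / sd_m if sd_m > 0 else np.zeros_like(mob)
    sd = spec.individual_effect_sd
    a_i = rng.normal(-0.5 * sd ** 2, sd, len(aids))
    ind_mult = np.exp(a_i + spec.mobility_coupling * z)

    # (species, individual, month) conditional mean per sample
    mean_counts = (base[:, None, None] * prof[:, None, :] * n_m
                   * ind_mult[None, :, None])

    species = spec.species_names()
    contaminants = list(CONTAMINANT_SPECIES) if spec.include_contaminants else []
    samples: list[DungSample] = []
    s_noise = spec.sample_noise_sd
    for ii, aid in enumerate(aids):
        for mi, month in enumerate(months):
            if isinstance(spec.samples_per_cell, Mapping):
                n_k = int(spec.samples_per_cell.get((aid, month), 0))
            else:
                n_k = int(spec.samples_per_cell)
            for k in range(n_k):
                volume = rng.gamma(spec.volume_shape,
                                   spec.mean_volume_ml / spec.volume_shape)
                eps = np.exp(rng.normal(-0.5 * s_noise ** 2, s_noise))
                counts = rng.poisson(mean_counts[:, ii, mi] * eps)
                sc = {sp: int(c) for sp, c in zip(species, counts) if c > 0}
                for w in contaminants:
                    c = rng.poisson(0.3)
                    if c > 0:
                        sc[w] = c
                if spec.include_contaminants:
                    c = rng.poisson(0.1)
                    if c > 0:
                        sc[BORDERLINE_SPECIES] = c
                year = pop.year if month >= months[0] else pop.year + 1
                samples.append(DungSample(
                    sample_id=f"{aid}_m{month:02d}_s{k + 1}",
                    animal_id=aid,
                    collection_date=pd.Timestamp(year=year, month=month,
                                                 day=min(10 + 5 * k, 28)),
                    volume_ml=float(volume),
                    species_counts=sc,
                ))

    control_rows = []
    if spec.include_contaminants:
        trays = [f"control_{t + 1:02d}" for t in range(spec.n_control_trays)]
        for w in contaminants:
            n_t = int(rng.integers(3, spec.n_control_trays + 1))
            for t in rng.choice(spec.n_control_trays, n_t, replace=False):
                control_rows.append((trays[t], w))
        # a species seen in only two control trays must survive the filter
        for t in rng.choice(spec.n_control_trays, 2, replace=False):
            control_rows.append((trays[t], BORDERLINE_SPECIES))
    control = pd.DataFrame(control_rows, columns=["tray_id", "species"])

    return SyntheticSeedData(
        samples=samples, control=control, species=species,
        individual_effects=dict(zip(aids, a_i)),
        mobility_z=dict(zip(aids, z)),
        mean_counts=mean_counts, months=months,
    )


# ---------------------------------------------------------------------------
# Passage-table generator
# ---------------------------------------------------------------------------

def gen_passage_table(skew: float = 0.5, n_trials: int = 6,
                      n_species: int = 6, concentration: float = 200.0,
                      rng_seed: int = 0,
                      bounds=DEFAULT_INTERVAL_BOUNDS) -> PassageTimeModel:
    """Generate per-(trial, species) excretion probabilities.

    The base curve is a Gamma retention-time density (shape 3, scale
    ``8 + 6*skew`` hours) integrated over the 14 standard intervals, with
    mass beyond the last bound folded into the final interval; larger
    ``skew`` shifts mass toward long retention and raises the implied mean.
    Each (trial, species) cell perturbs the base curve with a Dirichlet draw
    at the given concentration, mimicking between-trial and between-species
    variation.
    """
    if n_trials < 1 or n_species < 1:
        raise ValueError("n_trials and n_species must be >= 1")
    from scipy.stats import gamma as gamma_dist

    bounds = np.asarray(bounds, dtype=float)
    edges = np.concatenate([[0.0], bounds])
    cdf = gamma_dist.cdf(edges, a=3.0, scale=8.0 + 6.0 * skew)
    base = np.diff(cdf)
    base[-1] += 1.0 - cdf[-1]  # fold the right tail into the last interval
    base /= base.sum()

    rng = np.random.default_rng(np.random.SeedSequence((rng_seed, 3)))
    cells = {}
    for t in range(n_trials):
        for s in range(n_species):
            p = rng.dirichlet(np.maximum(base * concentration, 1e-3))
            cells[(f"trial_{t + 1}", f"passage_sp_{s + 1}")] = p / p.sum()
    return PassageTimeModel(interval_upper_bounds=bounds, cell_probs=cells)
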