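"""The end-to-end dispersal model, statsmodels-style.

:class:`DeerDispersalModel` is built from the three data sources — GPS
trajectories, a gut-passage interval model, and dung samples with seedling
counts (plus control-tray records) — and ``fit()`` runs the full analysis:
passage-time simulation, dispersal-event simulation, per-cell LDD
probabilities, seed loads, variance partitioning, the load-LDD regressions,
and the species LDD potentials with their permutation null. The returned
:class:`DeerDispersalResults` carries every table and test and prints a
summary in the style of the study's Results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, dispersal, inference, passage, potential, seedload, synth
from .config import AnalysisConfig

log = logging.getLogger("deerseed")


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Deterministically fan one master seed out to per-stage generators."""
    ss = np.random.SeedSequence(seed)
    keys = ("passage", "events", "permutation")
    children = ss.spawn(len(keys))
    return {k: np.random.default_rng(c) for k, c in zip(keys, children)}


class DeerDispersalModel:
    """Mechanistic model of endozoochorous seed dispersal by red deer.

    Parameters
    ----------
    trajectories : dict[str, Trajectory]
        Quality-screened, time-sorted GPS paths per individual.
    passage_model : PassageTimeModel
        Interval-probability model of gut passage time.
    samples : list[DungSample]
        Pellet groups with per-species seedling counts.
    control : pandas.DataFrame, optional
        Control-tray rows (tray_id, species) for contaminant screening.
    config : AnalysisConfig, optional
        Analysis settings; defaults reproduce the study configuration.
    """

    def __init__(self, trajectories, passage_model, samples, control=None,
                 config: AnalysisConfig | None = None):
        if not trajectories:
            raise ValueError("need at least one trajectory")
        self.trajectories = dict(trajectories)
        self.passage_model = passage_model
        self.samples = list(samples)
        self.control = control
        self.config = config or AnalysisConfig()

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_csv(cls, fixes_path, passage_path, dung_path, seedlings_path,
                 control_path=None, config: AnalysisConfig | None = None
                 ) -> "DeerDispersalModel":
        """Build the model from the CSV interchange files."""
        trajs = core.filter_and_split(core.read_fixes(fixes_path))
        pm = passage.build_model(core.read_passage(passage_path))
        samples = core.assemble_samples(core.read_dung(dung_path),
                                        core.read_seedlings(seedlings_path))
        control = (core.read_control(control_path)
                   if control_path is not None else None)
        return cls(trajs, pm, samples, control=control, config=config)

    @classmethod
    def from_synthetic(cls, pop_spec: synth.PopulationSpec | None = None,
                       load_spec: synth.SeedLoadSpec | None = None,
                       passage_skew: float = 0.5,
                       config: AnalysisConfig | None = None
                       ) -> "DeerDispersalModel":
        """Build the model from a fully synthetic study."""
        config = config or AnalysisConfig()
        pop_spec = pop_spec or synth.PopulationSpec(rng_seed=config.rng_seed)
        load_spec = load_spec or synth.SeedLoadSpec(rng_seed=config.rng_seed)
        trajs = synth.gen_population(pop_spec)
        mobility = synth.realized_mobility(trajs)
        seed_data = synth.gen_seed_data(load_spec, pop_spec, mobility)
        pm = synth.gen_passage_table(skew=passage_skew,
                                     rng_seed=pop_spec.rng_seed)
        m = cls(trajs, pm, seed_data.samples, control=seed_data.control,
                config=config)
        m.synthetic_truth = seed_data
        return m

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "DeerDispersalResults":
        cfg = self.config
        rngs = stage_rngs(cfg.rng_seed)

        # distribution of p, pooled across (trial, species) cells
        p_samples = passage.sample_passage_times(
            self.passage_model, cfg.n_passage_draws_per_cell, rngs["passage"])

        # dispersal events and LDD probabilities per (individual, month)
        frames, infos = [], []
        for aid in sorted(self.trajectories):
            ev, info = dispersal.simulate_events(
                self.trajectories[aid], p_samples, cfg, rngs["events"])
            frames.append(ev)
            infos.append(info)
        events = pd.concat(frames, ignore_index=True)
        ldd = dispersal.ldd_table(events, cfg)
        kernel = dispersal.kernel_summary(events, cfg)

        # seed load Q with contaminant and species filters
        samples, excluded = seedload.exclude_contaminants(
            self.samples, self.control, cfg)
        richness = seedload.richness_report(self.samples, excluded)
        load_table = seedload.build_seed_load_table(samples, cfg)
        _, kept_species = seedload.species_individual_counts(load_table, cfg)

        res = DeerDispersalResults(
            model=self, config=cfg, p_samples=p_samples, events=events,
            ldd=ldd, kernel=kernel, load_table=load_table,
            excluded_species=excluded, filtered_species=kept_species,
            richness=richness,
            simulation_info=infos,
        )
        res._run_inference(rngs["permutation"])
        return res


@dataclass
class DeerDispersalResults:
    """Fitted results: all tables, tests and diagnostics of one run."""

    model: DeerDispersalModel
    config: AnalysisConfig
    p_samples: np.ndarray
    events: pd.DataFrame
    ldd: pd.DataFrame
    kernel: dict
    load_table: core.SeedLoadTable
    excluded_species: list[str]
    filtered_species: list[str]
    richness: dict
    simulation_info: list
    anova_ldd: dict = field(default_factory=dict)
    anova_load: dict = field(default_factory=dict)
    joint_ldd: dict = field(default_factory=dict)
    regression: dict = field(default_factory=dict)
    interaction: dict = field(default_factory=dict)
    potentials: list = field(default_factory=list)
    meta_test: potential.MetaTestResult | None = None
    deviation_direction: dict = field(default_factory=dict)

    # -- inference over the fitted tables ---------------------------------

    def _run_inference(self, rng: np.random.Generator) -> None:
        cfg = self.config
        ldd = self.ldd

        # Q1: variance in LDD probability between individuals and months
        for orient in dispersal.ORIENTATIONS:
            y = ldd[orient].to_numpy()
            self.anova_ldd[orient] = {
                "individual": inference.one_way_partition(
                    y, ldd["animal_id"], name="individual"),
                "month": inference.one_way_partition(
                    y, ldd["month"], name="month"),
            }
            try:
                res, combined = inference.joint_partition(
                    y, ldd["animal_id"], ldd["month"],
                    names=("individual", "month"))
                self.joint_ldd[orient] = {"parts": res, "combined_r2": combined}
            except ValueError as exc:  # e.g. single month sampled
                log.warning("joint partition (%s) skipped: %s", orient, exc)

        # Q2: variance in log seed load at the sample grain
        sq = self.load_table.sample_q
        if sq is not None and not sq.empty:
            per_sample = (sq.groupby(["sample_id", "animal_id", "month"],
                                     sort=True)["q"].sum().reset_index())
            y = inference.transform(per_sample["q"].to_numpy(), "log",
                                    standardize=False)
            self.anova_load = {
                "individual": inference.one_way_partition(
                    y, per_sample["animal_id"], name="individual"),
                "month": inference.one_way_partition(
                    y, per_sample["month"], name="month"),
            }
            try:
                res, combined = inference.joint_partition(
                    y, per_sample["animal_id"], per_sample["month"],
                    names=("individual", "month"))
                self.anova_load["joint"] = {"parts": res,
                                            "combined_r2": combined}
            except ValueError as exc:
                log.warning("joint load partition skipped: %s", exc)

        # Q3: does seed load covary with LDD probability? One point per
        # individual: load averaged over its sampled months, LDD probability
        # pooled over its events.
        per_animal = (self.load_table.totals.groupby("animal_id")["q_total"]
                      .mean().rename("q").reset_index())
        ldd_animal = ldd.assign(
            **{o: ldd[o] * ldd["n_events"] for o in dispersal.ORIENTATIONS})
        ldd_animal = ldd_animal.groupby("animal_id").agg(
            {**{o: "sum" for o in dispersal.ORIENTATIONS},
             "n_events": "sum"}).reset_index()
        for o in dispersal.ORIENTATIONS:
            ldd_animal[o] = ldd_animal[o] / ldd_animal["n_events"]
        animals = per_animal.merge(ldd_animal, on="animal_id", how="inner")
        for orient in dispersal.ORIENTATIONS:
            if len(animals) >= 3 and animals["q"].gt(0).any():
                try:
                    self.regression[orient] = inference.regress_load_on_ldd(
                        animals["q"], animals[orient],
                        n_events=animals["n_events"])
                except ValueError as exc:
                    log.warning("regression (%s) skipped: %s", orient, exc)

        # Q4: species x LDD interaction on the filtered species
        sp_cells = self.load_table.cells[
            self.load_table.cells["species"].isin(self.filtered_species)]
        sp_cells = sp_cells.merge(ldd, on=["animal_id", "month"], how="inner")
        for orient in dispersal.ORIENTATIONS:
            if sp_cells["species"].nunique() >= 2:
                df = sp_cells.rename(columns={orient: "ldd"})
                try:
                    self.interaction[orient] = (
                        inference.species_interaction_model(
                            df[["species", "q", "ldd", "n_events"]]))
                except ValueError as exc:
                    log.warning("interaction (%s) skipped: %s", orient, exc)

        # Q5: species LDD potentials vs the permutation null
        self.potentials = potential.species_potentials(
            self.load_table.cells, ldd, self.filtered_species,
            cfg.n_permutations, rng,
            permutation_support=cfg.permutation_support)
        if self.potentials:
            self.meta_test = potential.deviation_scan(self.potentials)
            self.deviation_direction = potential.direction_of_deviation(
                self.potentials)

    # -- presentation ------------------------------------------------------

    def potentials_frame(self) -> pd.DataFrame:
        return potential.potentials_frame(self.potentials)

    def summary(self) -> str:
        """Human-readable account of the fitted run."""
        cfg = self.config
        k = self.kernel
        lines = [
            "Red deer seed-dispersal model" ,
            "=" * 64,
            f"individuals: {len(self.model.trajectories)}   "
            f"events: {k['n_events']}   "
            f"passage draws: {self.p_samples.size}",
            "",
            "Dispersal kernel (pooled)",
            f"  mean horizontal displacement: {k['mean_horizontal_m']:.0f} m",
            f"  P(horizontal > {cfg.horizontal_threshold:.0f} m): "
            f"{100 * k['frac_horizontal_ldd']:.1f}%   "
            f"(99% quantile {k['horizontal_q99_m']:.0f} m)",
            f"  P(upward > {cfg.vertical_threshold:.0f} m): "
            f"{100 * k['frac_upward_ldd']:.1f}%   "
            f"P(downward > {cfg.vertical_threshold:.0f} m): "
            f"{100 * k['frac_downward_ldd']:.1f}%",
            f"  vertical 1%/99% quantiles: {k['vertical_q01_m']:.0f} m / "
            f"{k['vertical_q99_m']:.0f} m",
            "",
            "Q1: variance in LDD probability (one-way R^2)",
        ]
        for orient in dispersal.ORIENTATIONS:
            a = self.anova_ldd[orient]
            lines.append(f"  {orient:10s} {a['individual']!s}")
            lines.append(f"  {orient:10s} {a['month']!s}")
        if self.anova_load:
            lines += ["", "Q2: variance in log seed load (sample grain)"]
            for fac in ("individual", "month"):
                lines.append(f"  {self.anova_load[fac]!s}")
            joint = self.anova_load.get("joint")
            if joint:
                lines.append(
                    f"  joint additive R^2 = {joint['combined_r2']:.3f}")
        if self.regression:
            lines += ["", "Q3: log seed load ~ logit LDD probability "
                          "(standardized)"]
            for orient, r in self.regression.items():
                lines.append(
                    f"  {orient:10s} slope = {r.slope:+.3f}, "
                    f"F({r.df_model}, {r.df_residual}) = "
                    f"{r.f_statistic:.2f}, p = {r.p_value:.3f}, "
                    f"R^2 = {r.r_squared:.3f}")
        if self.interaction:
            lines += ["", "Q4: species x LDD interaction"]
            for orient, r in self.interaction.items():
                lines.append(
                    f"  {orient:10s} partial R^2 = "
                    f"{r.partial_r_squared:.3f}, "
                    f"F({r.df_num}, {r.df_den}) = {r.f_statistic:.2f}, "
                    f"p = {r.p_value:.3f}")
        if self.meta_test:
            m = self.meta_test
            d = self.deviation_direction
            pf = self.potentials_frame()
            lines += ["", "Q5: species LDD potential vs permutation null"]
            for orient in dispersal.ORIENTATIONS:
                sub = pf[pf["orientation"] == orient]
                if sub.empty:
                    continue
                lines.append(
                    f"  {orient:10s} range {sub['observed'].min():.3f}-"
                    f"{sub['observed'].max():.3f} over {len(sub)} species, "
                    f"{int(sub['deviates'].sum())} deviations")
            lines.append(
                f"  deviations: {m.n_deviations}/{m.n_tests} "
                f"({d.get('increased', 0)} increased, "
                f"{d.get('decreased', 0)} decreased LDD potential); "
                f"binomial p = {m.p_value:.4g}")
        lines += [
            "",
            f"species: {self.richness['n_species_observed']} observed, "
            f"{len(self.excluded_species)} contaminants excluded, "
            f"{len(self.filtered_species)} pass the "
            f">= {cfg.min_individuals_per_species}-individual filter",
        ]
        dropped = sum(i.n_dropped for i in self.simulation_info)
        asked = sum(i.n_requested for i in self.simulation_info)
        lines.append(f"dropped events (start before tracking): "
                     f"{dropped}/{asked} ({100 * dropped / asked:.2f}%)")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write every result table as CSV/JSON under ``outdir``."""
        import json
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        core.write_table(self.ldd, outdir / "ldd_table.csv")
        paths["ldd"] = outdir / "ldd_table.csv"
        core.write_table(self.load_table.cells, outdir / "seedload.csv")
        core.write_table(self.load_table.totals, outdir / "seedload_totals.csv")
        if self.potentials:
            core.write_table(self.potentials_frame(), outdir / "potential.csv")
        (outdir / "kernel_summary.json").write_text(
            json.dumps(self.kernel, indent=2))
        anova_rows = []
        for orient, d in self.anova_ldd.items():
            for fac, a in d.items():
                anova_rows.append({
                    "response": f"ldd_{orient}", "factor": fac,
                    "r_squared": a.r_squared, "f": a.f_statistic,
                    "df_factor": a.df_factor, "df_residual": a.df_residual,
                    "p": a.p_value, "n": a.n})
        for fac in ("individual", "month"):
            if fac in self.anova_load:
                a = self.anova_load[fac]
                anova_rows.append({
                    "response": "log_seed_load", "factor": fac,
                    "r_squared": a.r_squared, "f": a.f_statistic,
                    "df_factor": a.df_factor, "df_residual": a.df_residual,
                    "p": a.p_value, "n": a.n})
        core.write_table(pd.DataFrame(anova_rows), outdir / "anova.csv")
        if self.meta_test:
            (outdir / "meta.json").write_text(json.dumps({
                "n_deviations": self.meta_test.n_deviations,
                "n_tests": self.meta_test.n_tests,
                "null_rate": self.meta_test.null_rate,
                "p_value": self.meta_test.p_value,
                "p_value_rounded": self.meta_test.p_value_rounded,
                **self.deviation_direction}, indent=2))
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        return paths
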