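"""End-to-end orchestration: synth -> simulate -> seed load -> inference.

``run_pipeline`` drives a full run from a config file (optionally
generating a synthetic study first), writes every stage output, a JSON run
manifest and a Markdown report whose sections mirror the study's Results
structure. Identical config + seed gives byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from . import core, synth  # noqa: E402
from .config import AnalysisConfig  # noqa: E402
from .dispersal import ORIENTATIONS  # noqa: E402
from .model import DeerDispersalModel  # noqa: E402

log = logging.getLogger("deerseed")

UNSTABLE_PERMUTATIONS = 1000


def write_synthetic_study(outdir: str | Path, config: AnalysisConfig,
                          pop_spec: synth.PopulationSpec | None = None,
                          load_spec: synth.SeedLoadSpec | None = None,
                          passage_skew: float = 0.5) -> dict[str, Path]:
    """Generate a complete synthetic study directory in the CSV dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop_spec = pop_spec or synth.PopulationSpec(rng_seed=config.rng_seed)
    load_spec = load_spec or synth.SeedLoadSpec(rng_seed=config.rng_seed)
    trajs = synth.gen_population(pop_spec)
    mobility = synth.realized_mobility(trajs)
    seed_data = synth.gen_seed_data(load_spec, pop_spec, mobility)
    pm = synth.gen_passage_table(skew=passage_skew, rng_seed=pop_spec.rng_seed)

    paths = {
        "fixes": outdir / "fixes.csv",
        "passage": outdir / "passage.csv",
        "dung": outdir / "dung.csv",
        "seedlings": outdir / "seedlings.csv",
        "control": outdir / "control.csv",
    }
    core.write_table(core.trajectories_to_frame(trajs), paths["fixes"])
    core.write_table(pm.to_frame(), paths["passage"])
    dung_rows = pd.DataFrame([{
        "sample_id": s.sample_id, "animal_id": s.animal_id,
        "collection_date": s.collection_date.date().isoformat(),
        "volume_ml": s.volume_ml} for s in seed_data.samples])
    core.write_table(dung_rows, paths["dung"])
    seedling_rows = pd.DataFrame(
        [(s.sample_id, sp, c) for s in seed_data.samples
         for sp, c in sorted(s.species_counts.items())],
        columns=core.SEEDLING_COLUMNS)
    core.write_table(seedling_rows, paths["seedlings"])
    core.write_table(seed_data.control, paths["control"])
    return paths


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: AnalysisConfig | str | Path, outdir: str | Path,
                 synth_inputs: bool = True,
                 inputs: dict[str, Path] | None = None,
                 pop_spec=None, load_spec=None, passage_skew: float = 0.5):
    """Run the full analysis and write outputs, manifest and report.

    With ``synth_inputs`` a synthetic study is generated under
    ``outdir/inputs`` first; otherwise ``inputs`` must map fixes/passage/
    dung/seedlings (and optionally control) to existing CSV paths.
    """
    if not isinstance(config, AnalysisConfig):
        config = AnalysisConfig.from_file(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.n_permutations < UNSTABLE_PERMUTATIONS:
        log.warning("n_permutations = %d: null-interval percentiles will be "
                    "unstable", config.n_permutations)

    manifest: dict = {"config": config.to_dict(),
                      "seed": config.rng_seed,
                      "versions": {"deerseed": _safe_version(),
                                   "numpy": np.__version__,
                                   "pandas": pd.__version__},
                      "stages": {}}
    try:
        if synth_inputs:
            inputs = write_synthetic_study(outdir / "inputs", config,
                                           pop_spec=pop_spec,
                                           load_spec=load_spec,
                                           passage_skew=passage_skew)
            manifest["stages"]["synth"] = {
                k: str(v) for k, v in inputs.items()}
        if inputs is None:
            raise ValueError("inputs required when synth_inputs is False")
        manifest["input_digests"] = {k: _digest(Path(v))
                                     for k, v in inputs.items()}

        model = DeerDispersalModel.from_csv(
            inputs["fixes"], inputs["passage"], inputs["dung"],
            inputs["seedlings"], control_path=inputs.get("control"),
            config=config)
        manifest["stages"]["load"] = {
            "n_individuals": len(model.trajectories),
            "n_fixes": int(sum(len(t) for t in model.trajectories.values())),
            "n_samples": len(model.samples),
        }
        results = model.fit()
        manifest["stages"]["simulate"] = {
            "n_events": int(len(results.events)),
            "dropped_fraction": float(np.mean(
                [i.dropped_fraction for i in results.simulation_info])),
        }
        manifest["stages"]["seedload"] = results.richness
        if results.meta_test:
            manifest["stages"]["potential"] = {
                "n_tests": results.meta_test.n_tests,
                "n_deviations": results.meta_test.n_deviations,
            }
        results.save(outdir)
        core.write_table(results.events, outdir / "events.csv")
        report = make_report(results, outdir)
        (outdir / "report.md").write_text(report)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    finally:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


def _safe_version() -> str:
    try:
        return pkg_version("deerseed")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def make_report(results, outdir: str | Path) -> str:
    """Render a Markdown report with the five Results sections and figures.

    Missing stage outputs mark their section as unavailable instead of
    failing; regeneration from the same results is idempotent.
    """
    outdir = Path(outdir)
    figdir = outdir / "figures"
    figdir.mkdir(parents=True, exist_ok=True)
    cfg = results.config
    k = results.kernel
    lines = ["# Seed dispersal by red deer — run report", ""]

    lines += ["## Dispersal kernel", ""]
    lines.append(f"Pooled over {k['n_events']} simulated dispersal events: "
                 f"mean horizontal displacement {k['mean_horizontal_m']:.0f} m; "
                 f"{100 * k['frac_horizontal_ldd']:.1f}% beyond "
                 f"{cfg.horizontal_threshold:.0f} m "
                 f"(99% quantile {k['horizontal_q99_m']:.0f} m); "
                 f"{100 * k['frac_upward_ldd']:.1f}% / "
                 f"{100 * k['frac_downward_ldd']:.1f}% beyond ±"
                 f"{cfg.vertical_threshold:.0f} m vertically "
                 f"(1%/99% quantiles {k['vertical_q01_m']:.0f} / "
                 f"{k['vertical_q99_m']:.0f} m).")
    _fig_kernel(results, figdir / "kernel.png")
    lines += ["", "![kernel](figures/kernel.png)", ""]

    lines += ["## Q1 — LDD probability between individuals and months", ""]
    for orient in ORIENTATIONS:
        a = results.anova_ldd.get(orient)
        if not a:
            lines.append(f"*{orient}: unavailable*")
            continue
        lines.append(f"- {orient}: individual R² = "
                     f"{a['individual'].r_squared:.2f} "
                     f"(F({a['individual'].df_factor}, "
                     f"{a['individual'].df_residual}) = "
                     f"{a['individual'].f_statistic:.2f}, "
                     f"p = {a['individual'].p_value:.3g}); month R² = "
                     f"{a['month'].r_squared:.2f} "
                     f"(p = {a['month'].p_value:.3g}); "
                     f"n = {a['individual'].n} cells")
    _fig_ldd_cells(results, figdir / "ldd_cells.png")
    lines += ["", "![ldd](figures/ldd_cells.png)", ""]

    lines += ["## Q2 — seed load between individuals and months", ""]
    if results.anova_load:
        for fac in ("individual", "month"):
            a = results.anova_load[fac]
            lines.append(f"- {fac}: R² = {a.r_squared:.2f} "
                         f"(F({a.df_factor}, {a.df_residual}) = "
                         f"{a.f_statistic:.2f}, p = {a.p_value:.3g}); "
                         f"n = {a.n} samples")
        joint = results.anova_load.get("joint")
        if joint:
            lines.append(f"- joint additive R² = {joint['combined_r2']:.2f}")
    else:
        lines.append("*unavailable*")

    lines += ["", "## Q3 — does seed load covary with LDD probability?", ""]
    if results.regression:
        for orient, r in results.regression.items():
            lines.append(f"- {orient}: slope = {r.slope:+.3f}, "
                         f"R² = {r.r_squared:.3f}, p = {r.p_value:.3f} "
                         f"(n = {r.n} deer)")
        _fig_load_vs_ldd(results, figdir / "load_vs_ldd.png")
        lines += ["", "![scatter](figures/load_vs_ldd.png)", ""]
    else:
        lines.append("*unavailable*")

    lines += ["## Q4 — species × LDD interaction", ""]
    if results.interaction:
        for orient, r in results.interaction.items():
            lines.append(f"- {orient}: partial R² = "
                         f"{r.partial_r_squared:.3f}, "
                         f"F({r.df_num}, {r.df_den}) = {r.f_statistic:.2f}, "
                         f"p = {r.p_value:.3f} ({r.n_species} species, "
                         f"n = {r.n})")
    else:
        lines.append("*unavailable*")

    lines += ["", "## Q5 — species LDD potential vs permutation null", ""]
    if results.meta_test:
        m = results.meta_test
        d = results.deviation_direction
        lines.append(f"{m.n_deviations} of {m.n_tests} species × orientation "
                     f"tests deviate from their 95% null interval "
                     f"({d.get('increased', 0)} increase, "
                     f"{d.get('decreased', 0)} decrease LDD potential); "
                     f"binomial p = {m.p_value:.4g}.")
        _fig_potentials(results, figdir / "potentials.png")
        lines += ["", "![potentials](figures/potentials.png)", ""]
    else:
        lines.append("*unavailable*")
    return "\n".join(lines) + "\n"


def _fig_kernel(results, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for aid, g in results.events.groupby("animal_id"):
        for ax, col in zip(axes, ("d_horiz_m", "d_vert_m")):
            vals = g[col].to_numpy()
            hist, edges = np.histogram(vals, bins=60, density=True)
            ax.plot(0.5 * (edges[:-1] + edges[1:]), hist, lw=0.8, alpha=0.6)
    axes[0].axvline(results.config.horizontal_threshold, color="k", ls="--",
                    lw=0.8)
    axes[0].set_yscale("log")
    axes[0].set_xlabel("horizontal displacement (m)")
    for s in (-1, 1):
        axes[1].axvline(s * results.config.vertical_threshold, color="k",
                        ls="--", lw=0.8)
    axes[1].set_xlabel("vertical displacement (m)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_ldd_cells(results, path: Path) -> None:
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    ldd = results.ldd
    order = sorted(ldd["animal_id"].unique())
    data = [ldd.loc[ldd["animal_id"] == a, "horizontal"] for a in order]
    axes[0].boxplot(data, tick_labels=range(1, len(order) + 1))
    axes[0].set_xlabel("individual")
    axes[0].set_ylabel("P(horizontal LDD)")
    months = sorted(ldd["month"].unique())
    data = [ldd.loc[ldd["month"] == m, "horizontal"] for m in months]
    axes[1].boxplot(data, tick_labels=months)
    axes[1].set_xlabel("month")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_load_vs_ldd(results, path: Path) -> None:
    cells = results.load_table.totals.merge(
        results.ldd, on=["animal_id", "month"], how="inner")
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(cells["horizontal"], cells["q_total"], s=12, alpha=0.6)
    ax.set_xlabel("P(horizontal LDD)")
    ax.set_ylabel("seed load (seedlings/g)")
    ax.set_yscale("symlog", linthresh=0.01)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _fig_potentials(results, path: Path) -> None:
    pf = results.potentials_frame()
    fig, axes = plt.subplots(1, 3, figsize=(11, 4), sharey=False)
    for ax, orient in zip(axes, ORIENTATIONS):
        sub = pf[pf["orientation"] == orient].reset_index(drop=True)
        if sub.empty:
            continue
        x = np.arange(len(sub))
        ax.vlines(x, sub["null_low"], sub["null_high"], color="grey", lw=2,
                  alpha=0.7)
        colors = np.where(sub["deviates"], "crimson", "black")
        ax.scatter(x, sub["observed"], c=colors, s=16, zorder=3)
        ax.set_title(orient)
        ax.set_xticks(x)
        ax.set_xticklabels(sub["species"], rotation=90, fontsize=5)
    axes[0].set_ylabel("LDD potential")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
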