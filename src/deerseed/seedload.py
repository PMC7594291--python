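"""Seed load Q: seedlings per gram of dung dry mass.

Dung samples are measured by volume; an average dry-mass-to-volume ratio
(0.13 g/ml by default) converts to dry mass. A sample's seed load for a
species is its seedling count divided by the sample's dry mass; loads
aggregate to the (individual, month) cell by the configured rule (mean of
per-sample loads by default). Greenhouse contaminants — species emerging in
at least three distinct control trays — are excluded before any load is
computed, and per-species analyses are restricted to species dispersed by
at least five distinct individuals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .core import DungSample, SeedLoadTable

log = logging.getLogger("deerseed")


def volume_to_dry_mass(volume_ml: float, cfg: AnalysisConfig) -> float:
    """Convert pellet-group volume (ml) to dry mass (g)."""
    if not volume_ml > 0:
        raise ValueError(f"volume must be positive, got {volume_ml}")
    return volume_ml * cfg.dry_mass_per_ml


def exclude_contaminants(samples: list[DungSample], control_rows: pd.DataFrame,
                         cfg: AnalysisConfig
                         ) -> tuple[list[DungSample], list[str]]:
    """Drop species found in >= ``contamination_tray_min`` distinct control trays.

    Returns new samples with the contaminant species removed from every
    species map, plus the sorted list of excluded species.
    """
    if control_rows is None or len(control_rows) == 0:
        return samples, []
    trays_per_species = (control_rows.drop_duplicates()
                         .groupby("species")["tray_id"].nunique())
    excluded = sorted(trays_per_species[
        trays_per_species >= cfg.contamination_tray_min].index.astype(str))
    if not excluded:
        return samples, []
    log.info("excluding %d contaminant species: %s", len(excluded), excluded)
    out = [
        DungSample(
            sample_id=s.sample_id, animal_id=s.animal_id,
            collection_date=s.collection_date, volume_ml=s.volume_ml,
            species_counts={sp: c for sp, c in s.species_counts.items()
                            if sp not in excluded},
        )
        for s in samples
    ]
    return out, excluded


def _per_sample_q(samples: list[DungSample], cfg: AnalysisConfig
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Per-sample, per-species seed load, zero-filled over observed species."""
    species = sorted({sp for s in samples for sp in s.species_counts})
    rows = []
    for s in samples:
        mass = volume_to_dry_mass(s.volume_ml, cfg)
        for sp in species:
            count = s.species_counts.get(sp, 0)
            if cfg.q_rule == "literal":
                # the study's wording taken at face value (count/ml * g/ml)
                q = count / s.volume_ml * cfg.dry_mass_per_ml
            else:
                q = count / mass
            rows.append((s.sample_id, s.animal_id, s.month, sp, count,
                         s.volume_ml, mass, q))
    df = pd.DataFrame(rows, columns=["sample_id", "animal_id", "month",
                                     "species", "count", "volume_ml",
                                     "dry_mass_g", "q"])
    return df, species


def build_seed_load_table(samples: list[DungSample],
                          cfg: AnalysisConfig) -> SeedLoadTable:
    """Aggregate per-sample seed loads to (individual, month, species) cells.

    A species absent from a sample contributes q = 0 to that sample, so the
    cell aggregate averages over every sample collected in the cell. The
    ``totals`` frame carries the per-cell sum across species.
    """
    if not samples:
        empty = pd.DataFrame(columns=["animal_id", "month", "species", "q"])
        tot = pd.DataFrame(columns=["animal_id", "month", "q_total"])
        return SeedLoadTable(cells=empty, totals=tot, sample_q=None)
    sample_q, _ = _per_sample_q(samples, cfg)
    g = sample_q.groupby(["animal_id", "month", "species"], sort=True)
    if cfg.cell_aggregation == "mean":
        cells = g["q"].mean()
    elif cfg.cell_aggregation == "sum":
        cells = g["q"].sum()
    else:  # pooled: total count over total dry mass
        agg = g[["count", "dry_mass_g"]].sum()
        cells = agg["count"] / agg["dry_mass_g"]
    cells = cells.rename("q").reset_index()
    totals = (cells.groupby(["animal_id", "month"], sort=True)["q"]
              .sum().rename("q_total").reset_index())
    return SeedLoadTable(cells=cells, totals=totals, sample_q=sample_q)


def species_individual_counts(table: SeedLoadTable,
                              cfg: AnalysisConfig | None = None
                              ) -> tuple[pd.Series, list[str]]:
    """Distinct individuals with positive load per species, plus the filter.

    Returns the per-species count of distinct animal_ids with any positive
    cell, and — when a config is given — the sorted species meeting
    ``min_individuals_per_species``.
    """
    if table.cells.empty:
        return pd.Series(dtype=int, name="n_individuals"), []
    pos = table.cells[table.cells["q"] > 0]
    counts = (pos.groupby("species")["animal_id"].nunique()
              .rename("n_individuals"))
    counts = counts.reindex(sorted(table.cells["species"].unique()),
                            fill_value=0)
    if cfg is None:
        return counts, []
    kept = sorted(counts[counts >= cfg.min_individuals_per_species].index)
    return counts, kept


def richness_report(samples: list[DungSample], excluded: list[str]) -> dict:
    """Observed species richness before/after contaminant exclusion."""
    observed = {sp for s in samples for sp in s.species_counts}
    return {
        "n_species_observed": len(observed | set(excluded)),
        "n_species_after_exclusion": len(observed - set(excluded)),
        "n_contaminants_excluded": len(excluded),
        "total_seedlings": int(sum(c for s in samples
                                   for c in s.species_counts.values())),
    }
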