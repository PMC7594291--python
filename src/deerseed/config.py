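"""Run configuration shared by every pipeline stage.

The defaults reproduce the study settings: 1000 m horizontal and 50 m
vertical long-distance thresholds, 100,000 endpoint draws per individual,
100,000 passage-time draws per (trial, species) cell, 100,000 permutations
for the species-potential null, a 0.13 g/ml dung dry-mass conversion, the
>= 5-individual species filter and the >= 3-control-tray contamination rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

_START_RULES = ("interpolate", "nearest")
_Q_RULES = ("per_gram", "literal")
_AGGREGATIONS = ("mean", "sum", "pooled")
_PERM_SUPPORTS = ("sampled", "positive")


@dataclass
class AnalysisConfig:
    """Tunable parameters of the dispersal analysis.

    Parameters
    ----------
    horizontal_threshold : float
        Horizontal displacement (m) beyond which a dispersal event counts as
        long-distance. Default 1000 m.
    vertical_threshold : float
        Absolute vertical displacement (m) defining upward/downward
        long-distance dispersal. Default 50 m.
    n_endpoint_draws : int
        Random endpoint locations drawn per individual trajectory.
    n_passage_draws_per_cell : int
        Passage-time draws per (trial, species) cell of the retention model.
    n_permutations : int
        Permutations for the species-potential null interval.
    min_individuals_per_species : int
        A plant species enters the per-species analyses only if dispersed by
        at least this many distinct individuals.
    contamination_tray_min : int
        Species found in at least this many distinct control trays are
        treated as greenhouse contaminants and excluded.
    dry_mass_per_ml : float
        Dung dry mass per unit volume (g/ml) used to convert pellet-group
        volume to dry mass.
    rng_seed : int
        Master seed; stage seeds are spawned from it deterministically.
    max_redraws : int
        Retries for an (endpoint, passage-time) pair whose reconstructed
        start time falls before the trajectory begins.
    start_rule : str
        "interpolate" places start points linearly between bracketing fixes;
        "nearest" snaps to the nearest fix in time.
    q_rule : str
        "per_gram" computes seed load as count / (volume_ml * dry_mass_per_ml),
        i.e. seedlings per gram dry mass; "literal" computes
        count / volume_ml * dry_mass_per_ml (kept for auditing).
    cell_aggregation : str
        How per-sample seed loads aggregate to an (individual, month) cell:
        "mean" (default), "sum", or "pooled" (total count / total mass).
    permutation_support : str
        "sampled" permutes a species' loads across every sampled cell
        (zero-load cells included); "positive" restricts to positive cells.
    """

    horizontal_threshold: float = 1000.0
    vertical_threshold: float = 50.0
    n_endpoint_draws: int = 100_000
    n_passage_draws_per_cell: int = 100_000
    n_permutations: int = 100_000
    min_individuals_per_species: int = 5
    contamination_tray_min: int = 3
    dry_mass_per_ml: float = 0.13
    rng_seed: int = 0
    max_redraws: int = 100
    start_rule: str = "interpolate"
    q_rule: str = "per_gram"
    cell_aggregation: str = "mean"
    permutation_support: str = "sampled"

    def __post_init__(self) -> None:
        if self.horizontal_threshold <= 0 or self.vertical_threshold <= 0:
            raise ValueError("distance thresholds must be positive")
        for name in ("n_endpoint_draws", "n_passage_draws_per_cell",
                     "n_permutations", "min_individuals_per_species",
                     "contamination_tray_min", "max_redraws"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dry_mass_per_ml <= 0:
            raise ValueError("dry_mass_per_ml must be positive")
        if self.start_rule not in _START_RULES:
            raise ValueError(f"start_rule must be one of {_START_RULES}")
        if self.q_rule not in _Q_RULES:
            raise ValueError(f"q_rule must be one of {_Q_RULES}")
        if self.cell_aggregation not in _AGGREGATIONS:
            raise ValueError(f"cell_aggregation must be one of {_AGGREGATIONS}")
        if self.permutation_support not in _PERM_SUPPORTS:
            raise ValueError(
                f"permutation_support must be one of {_PERM_SUPPORTS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat YAML or JSON mapping of config fields."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
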