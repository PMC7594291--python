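"""Species LDD potential, its permutation null and the across-species test.

A plant species' LDD potential is the mean of the per-(individual, month)
LDD probabilities weighted by that species' seed load in each cell. The
null model breaks any load-mobility association by permuting the species'
load vector uniformly at random across the sampled cells and recomputing
the potential; the 2.5% and 97.5% percentiles of the permutation
distribution form the 95% null interval. Observed potentials strictly
outside their interval are deviations; the across-species test asks how
likely at least the observed number of deviations is under independent
Binomial(n_tests, 0.05) draws.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("deerseed")

#: Exhaustive enumeration is used instead of sampling below this cell count.
EXHAUSTIVE_LIMIT = 7


@dataclass
class PotentialResult:
    """One species x orientation: observed potential vs its null interval."""

    species: str
    orientation: str
    observed: float
    null_low: float
    null_high: float
    deviates: bool
    n_permutations: int
    n_cells: int
    degenerate: bool = False


@dataclass
class MetaTestResult:
    """Binomial test on the count of interval deviations across species."""

    n_deviations: int
    n_tests: int
    null_rate: float
    p_value: float

    @property
    def p_value_rounded(self) -> float:
        return round(self.p_value, 3)


def weighted_potential(loads, probs) -> float:
    """Seed-load-weighted mean of per-cell LDD probabilities.

    ``loads`` and ``probs`` are aligned per-cell vectors; the result is
    sum(q_c * ldd_c) / sum(q_c). All-zero loads leave the potential
    undefined (NaN); callers skip such species with a warning.
    """
    q = np.asarray(loads, dtype=float)
    p = np.asarray(probs, dtype=float)
    if q.shape != p.shape:
        raise ValueError("loads and probabilities must align")
    if (q < 0).any():
        raise ValueError("loads must be >= 0")
    total = q.sum()
    if total == 0:
        return float("nan")
    return float((q * p).sum() / total)


def permutation_null(loads, probs, n_perm: int, rng: np.random.Generator,
                     exhaustive: bool | None = None
                     ) -> tuple[float, float, dict]:
    """95% null interval of the potential under random load-cell association.

    Each permutation shuffles the species' load vector across the sampled
    cells and recomputes the weighted potential (the load total is
    permutation-invariant, so this is a permuted dot product). On toys with
    at most ``EXHAUSTIVE_LIMIT`` cells — or when ``exhaustive=True`` — all
    n! arrangements are enumerated instead of sampled.

    Returns (null_low, null_high, info) where info carries the permutation
    mean/sd and degeneracy flag (fewer than 2 distinct load values collapse
    the interval to the observed potential).
    """
    q = np.asarray(loads, dtype=float)
    p = np.asarray(probs, dtype=float)
    if p.size < 2:
        raise ValueError("need at least 2 cells for a permutation null")
    if len(np.unique(q)) < 2:
        obs = weighted_potential(q, p)
        log.warning("degenerate null: fewer than 2 distinct load values")
        return obs, obs, {"degenerate": True, "n_used": 0,
                          "mean": obs, "sd": 0.0}
    total = q.sum()
    if exhaustive is None:
        exhaustive = q.size <= EXHAUSTIVE_LIMIT
    if exhaustive:
        vals = np.array([np.dot(perm, p) / total
                         for perm in permutations(q)])
    else:
        mat = np.tile(q, (n_perm, 1))
        mat = rng.permuted(mat, axis=1)
        vals = mat @ p / total
    lo, hi = np.percentile(vals, [2.5, 97.5])
    info = {"degenerate": False, "n_used": int(vals.size),
            "mean": float(vals.mean()), "sd": float(vals.std()),
            "exhaustive": bool(exhaustive)}
    return float(lo), float(hi), info


def species_potentials(seed_cells: pd.DataFrame, ldd: pd.DataFrame,
                       species_list: list[str], n_perm: int,
                       rng: np.random.Generator,
                       orientations=("horizontal", "upward", "downward"),
                       permutation_support: str = "sampled"
                       ) -> list[PotentialResult]:
    """Observed potential and null interval per species x orientation.

    ``seed_cells`` is the long seed-load table (animal_id, month, species,
    q); ``ldd`` the per-cell LDD table. Cells are joined on (animal_id,
    month); only sampled cells with an LDD value enter. With
    ``permutation_support="positive"`` the null permutes only over cells
    with positive load for the species.
    """
    merged = seed_cells.merge(ldd, on=["animal_id", "month"], how="inner")
    results: list[PotentialResult] = []
    for sp in species_list:
        sub = merged[merged["species"] == sp]
        if sub.empty or (sub["q"] > 0).sum() == 0:
            log.warning("species %s: no positive load in any sampled cell, "
                        "skipped", sp)
            continue
        if permutation_support == "positive":
            sub = sub[sub["q"] > 0]
        q = sub["q"].to_numpy()
        for orient in orientations:
            p = sub[orient].to_numpy()
            obs = weighted_potential(q, p)
            lo, hi, info = permutation_null(q, p, n_perm, rng,
                                            exhaustive=False)
            results.append(PotentialResult(
                species=sp, orientation=orient, observed=obs,
                null_low=lo, null_high=hi,
                deviates=bool(obs < lo or obs > hi),
                n_permutations=info["n_used"], n_cells=len(sub),
                degenerate=info["degenerate"],
            ))
    return results


def deviation_scan(potentials: list[PotentialResult],
                   null_rate: float = 0.05) -> MetaTestResult:
    """Count interval deviations and test them against a binomial null.

    p = P(X >= n_deviations) with X ~ Binomial(n_tests, null_rate): the
    upper-tail probability of seeing at least as many species x orientation
    tests fall outside their 95% null intervals by chance alone.
    """
    n_tests = len(potentials)
    n_dev = sum(bool(r.deviates) for r in potentials)
    p = binomial_tail(n_dev, n_tests, null_rate)
    return MetaTestResult(n_deviations=n_dev, n_tests=n_tests,
                          null_rate=null_rate, p_value=p)


def binomial_tail(k: int, n: int, rate: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n, rate)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, rate))


def binomial_tail_bruteforce(k: int, n: int, rate: float) -> float:
    """Direct pmf summation of the upper tail; the cross-check oracle."""
    return sum(math.comb(n, j) * rate ** j * (1 - rate) ** (n - j)
               for j in range(k, n + 1))


def direction_of_deviation(potentials: list[PotentialResult]
                           ) -> dict[str, int]:
    """Split deviations by sign: above the interval raises LDD potential."""
    increased = sum(1 for r in potentials if r.deviates
                    and r.observed > r.null_high)
    decreased = sum(1 for r in potentials if r.deviates
                    and r.observed < r.null_low)
    return {"increased": increased, "decreased": decreased}


def potentials_frame(potentials: list[PotentialResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": r.species, "orientation": r.orientation,
        "observed": r.observed, "null_low": r.null_low,
        "null_high": r.null_high, "deviates": r.deviates,
        "n_permutations": r.n_permutations, "n_cells": r.n_cells,
    } for r in potentials])
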