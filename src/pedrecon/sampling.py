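"""Winter genetic sampling designs: population-based and spatially based.

Both schemes mimic noninvasive scat collection at the December census,
under demographic closure (no births or deaths between the census and
sampling).  Individuals are never sampled twice: the cumulative record
of sampled ids persists across years and only previously unsampled
animals can enter.  Samples reveal identity, sex, parent-offspring
relationships and the basic age class (calf vs adult) only.

Population-based sampling draws a fixed fraction of the previously
unsampled animals alive in the study area.  Spatially based sampling
draws 1-km^2 grid cells without replacement with probability
proportional to the number of animals using each cell, then detects
each animal using a drawn cell by a Bernoulli trial at its scaled
winter utilization of that cell.

Either way, the cow-calf rule applies afterwards: cows and their
dependent calves (age < 1) travel together in snow, so sampling either
member of the pair samples both.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spatial import CellWeightMap

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingConfig",
    "SamplingRecord",
    "population_sample",
    "spatial_sample",
    "cow_calf_rule",
]


@dataclass
class SamplingConfig:
    """Validated parameters for one sampling experiment."""

    scheme: str  # "population" | "spatial"
    fraction: float | None = None
    n_cells: int | None = None
    years: int = 5
    burn_in: int = 20
    iterations: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("population", "spatial"):
            raise ValueError(f"unknown sampling scheme {self.scheme!r}")
        if self.scheme == "population":
            if self.fraction is None or not 0.0 < self.fraction <= 1.0:
                raise ValueError("population scheme needs fraction in (0, 1]")
            if self.n_cells is not None:
                raise ValueError("n_cells applies to the spatial scheme only")
        else:
            if self.n_cells is None or self.n_cells < 0:
                raise ValueError("spatial scheme needs a nonnegative n_cells")
            if self.fraction is not None:
                raise ValueError("fraction applies to the population scheme only")
        if self.years < 1 or self.burn_in < 0 or self.iterations < 1:
            raise ValueError("years, burn_in and iterations must be positive")


class SamplingRecord:
    """Cumulative multi-year record of sampled individuals.

    Each id appears at most once, with the year it was first sampled
    and, for the spatial scheme, the grid cell of detection.
    """

    def __init__(self) -> None:
        self._entries: dict[int, tuple[int, int | None]] = {}

    def __contains__(self, ind_id) -> bool:
        return ind_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def sampled_ids(self) -> set:
        return set(self._entries)

    def year_of(self, ind_id) -> int:
        return self._entries[ind_id][0]

    def add(self, ids: Iterable, year: int, cell: int | None = None) -> list:
        """Record previously unsampled ids; returns the ids actually added."""
        added = []
        for i in ids:
            if i not in self._entries:
                self._entries[i] = (year, cell)
                added.append(i)
        return added

    def new_in_year(self, year: int) -> list:
        return [i for i, (y, _) in self._entries.items() if y == year]

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, y, c) for i, (y, c) in self._entries.items()]
        return pd.DataFrame(rows, columns=["id", "year", "cell"])


def _require_census_columns(census: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in census.columns]
    if missing:
        raise ValueError(f"census frame lacks columns: {missing}")


def cow_calf_rule(sampled_ids: set, census: pd.DataFrame) -> set:
    """Augment a sample with cow-calf partners.

    Sampling a cow with a live dependent calf (age 0) also samples the
    calf, and sampling a calf also samples its mother -- the pair
    travels together during the winter sampling window.
    """
    _require_census_columns(census, ("id", "age", "alive", "dam"))
    out = set(sampled_ids)
    calves = census[(census["age"] == 0) & census["alive"]]
    alive_ids = set(census.loc[census["alive"], "id"])
    for calf_id, dam in zip(calves["id"], calves["dam"]):
        if pd.isna(dam):
            continue
        if dam in out and calf_id in alive_ids:
            out.add(calf_id)
        if calf_id in out and dam in alive_ids:
            out.add(dam)
    return out


def population_sample(
    census: pd.DataFrame,
    fraction: float,
    record: SamplingRecord,
    rng: np.random.Generator,
    year: int,
) -> list:
    """Simple random sample of previously unsampled animals in the study area.

    The nominal size is ``round_half_up(fraction * pool)``; the cow-calf
    rule may add animals beyond it.  Returns the newly recorded ids.
    """
    _require_census_columns(census, ("id", "age", "alive", "in_area", "dam"))
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    sampled = record.sampled_ids
    pool = census.loc[
        census["alive"] & census["in_area"] & ~census["id"].isin(sampled), "id"
    ].to_numpy()
    pool.sort()
    n = int(math.floor(fraction * len(pool) + 0.5))
    chosen = set(rng.choice(pool, size=min(n, len(pool)), replace=False).tolist())
    chosen = cow_calf_rule(chosen, census)
    return record.add(sorted(chosen - sampled), year)


def draw_cells(
    weights: CellWeightMap,
    n_cells: int,
    rng: np.random.Generator,
    excluded: set | None = None,
) -> list[int]:
    """Draw distinct cells with probability proportional to their weight.

    Zero-weight cells are drawn (uniformly) only when fewer positive
    cells remain than requested; an all-zero weight map degenerates to a
    uniform draw, which is logged.
    """
    excluded = excluded or set()
    w = weights.weights.copy()
    eligible = np.setdiff1d(np.arange(w.size), np.fromiter(excluded, dtype=int, count=len(excluded)))
    if n_cells > eligible.size:
        raise ValueError("requested more cells than remain available")
    we = w[eligible]
    positive = eligible[we > 0]
    if positive.size == 0:
        logger.warning("all cell weights are zero; drawing cells uniformly")
        return sorted(rng.choice(eligible, size=n_cells, replace=False).tolist())
    if positive.size >= n_cells:
        p = w[positive] / w[positive].sum()
        return sorted(rng.choice(positive, size=n_cells, replace=False, p=p).tolist())
    rest = np.setdiff1d(eligible, positive)
    extra = rng.choice(rest, size=n_cells - positive.size, replace=False)
    return sorted(positive.tolist() + extra.tolist())


def spatial_sample(
    census: pd.DataFrame,
    n_cells: int,
    weights: CellWeightMap,
    utilization_maps: Mapping[int, Mapping[int, float]],
    record: SamplingRecord,
    rng: np.random.Generator,
    year: int,
    excluded_cells: set | None = None,
) -> tuple[list, list[int]]:
    """Abundance-weighted cell survey with utilization-scaled detection.

    ``utilization_maps`` gives, per animal, the scaled winter
    utilization of each grid cell its winter MCP intersects; an animal
    using a drawn cell is detected there by an independent Bernoulli
    trial at that value.  Returns (newly recorded ids, drawn cells).
    """
    _require_census_columns(census, ("id", "age", "alive", "dam"))
    drawn = draw_cells(weights, n_cells, rng, excluded=excluded_cells)
    drawn_set = set(drawn)
    sampled = record.sampled_ids
    detected: dict[int, int | None] = {}
    candidates = census.loc[census["alive"] & ~census["id"].isin(sampled), "id"]
    for ind_id in sorted(candidates):
        umap = utilization_maps.get(ind_id)
        if not umap:
            continue
        for cell in sorted(drawn_set.intersection(umap)):
            if rng.random() < umap[cell]:
                detected[ind_id] = cell
                break
    augmented = cow_calf_rule(set(detected), census)
    new_ids = []
    for ind_id in sorted(augmented - sampled):
        new_ids.extend(record.add([ind_id], year, cell=detected.get(ind_id)))
    return new_ids, drawn
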